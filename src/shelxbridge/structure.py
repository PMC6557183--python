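"""PDB coordinate-file parsing and identifier-level validation.

The fixed columns of the PDB format are authoritative here: the element is
taken from columns 77-78 and inferred from the atom-name columns only when
that field is blank (deposited element fields are unreliable often enough
that the name columns are the better fallback, not the primary source).

SHELX identifier rules enforced downstream of parsing:

* chain identifiers must be A-Z, a-z, 0-9 or blank (63 possibilities) and,
  unusually for SHELX, are case sensitive;
* residue numbers must lie in [-999, 9999] and insertion codes do not exist,
  so decorated or out-of-range numbering is resolved by renumbering;
* residue names consisting only of digits would be indistinguishable from
  residue numbers and are flagged.
"""

from __future__ import annotations

import io
import re
import string
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (CapacityError, ChainExhaustionError, ConversionWarning,
                     DuplicateAtomError, MissingCellError, MultiModelError)
from .geometry import UnitCell

__all__ = [
    "AtomRecord", "StructureModel", "read_pdb", "write_pdb",
    "validate_chain_id", "remap_chains", "validate_residue_name",
    "renumber_residues", "LEGAL_CHAIN_IDS", "RESSEQ_MIN", "RESSEQ_MAX",
]

#: The 63 legal SHELX chain identifiers, in remapping preference order.
LEGAL_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits + " "

RESSEQ_MIN, RESSEQ_MAX = -999, 9999

_TWO_LETTER_ELEMENTS = {
    "HE", "LI", "BE", "NE", "NA", "MG", "AL", "SI", "CL", "AR", "CA", "SC",
    "TI", "CR", "MN", "FE", "CO", "NI", "CU", "ZN", "GA", "GE", "AS", "SE",
    "BR", "KR", "RB", "SR", "ZR", "NB", "MO", "TC", "RU", "RH", "PD", "AG",
    "CD", "IN", "SN", "SB", "TE", "XE", "CS", "BA", "HG", "PB", "BI", "PT",
    "AU", "TL",
}


@dataclass
class AtomRecord:
    """One atom of the coordinate model (Cartesian Angstrom)."""

    name: str
    res_name: str
    chain_id: str
    res_seq: int
    xyz_cart: np.ndarray
    occupancy: float = 1.0
    b_iso: float = 0.0
    u_aniso_cart: np.ndarray | None = None
    element: str = ""
    alt_loc: str = " "
    insertion_code: str = " "
    serial: int = 0
    is_hetatm: bool = False

    @property
    def key(self) -> tuple:
        """Identity tuple that must be unique within one model."""
        return (self.chain_id, self.res_seq, self.insertion_code,
                self.alt_loc, self.name)

    @property
    def residue_key(self) -> tuple:
        return (self.chain_id, self.res_seq, self.insertion_code, self.res_name)


@dataclass
class StructureModel:
    """A single coordinate model plus its cell and symmetry metadata."""

    atoms: list[AtomRecord]
    cell: UnitCell
    space_group_symbol: str
    z_value: int = 1
    title: str = ""
    pdb_code: str = ""
    ssbond_hints: list[tuple] = field(default_factory=list)

    def chains(self) -> list[str]:
        out: list[str] = []
        for atom in self.atoms:
            if atom.chain_id not in out:
                out.append(atom.chain_id)
        return out

    def residues(self) -> list[tuple[tuple, list[AtomRecord]]]:
        """Residues in file order: (residue_key, atoms)."""
        order: dict[tuple, list[AtomRecord]] = {}
        for atom in self.atoms:
            order.setdefault(atom.residue_key, []).append(atom)
        return list(order.items())


def _infer_element(name_field: str, res_name: str) -> str:
    """Element from PDB atom-name columns 13-16 when columns 77-78 are blank."""
    raw = name_field.rstrip()
    two = raw[:2].strip().upper()
    if two in _TWO_LETTER_ELEMENTS and not raw[:1].isspace():
        # a two-character element is left-justified in column 13
        return two.capitalize()
    core = raw.strip().lstrip("0123456789")
    if not core:
        return ""
    first = core[0].upper()
    if first == "D":  # deuterium labels
        return "H"
    return first


def _parse_float(text: str, default: float = 0.0) -> float:
    text = text.strip()
    return float(text) if text else default


def read_pdb(stream) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Accepts a file-like object or a string.  Only single-model files are
    supported: a second MODEL record raises :class:`MultiModelError`.
    A missing CRYST1 record raises :class:`MissingCellError`.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    atoms: list[AtomRecord] = []
    cell = None
    sg_symbol = ""
    z_value = 1
    title_parts: list[str] = []
    pdb_code = ""
    wavelength: float | None = None
    ssbonds: list[tuple] = []
    model_count = 0
    seen_keys: set[tuple] = set()

    for line in stream:
        rec = line[:6]
        if rec == "MODEL ":
            model_count += 1
            if model_count > 1:
                raise MultiModelError(
                    "more than one model in the coordinate file; SHELX "
                    "refinement requires exactly one")
        elif rec == "CRYST1":
            a = _parse_float(line[6:15])
            b = _parse_float(line[15:24])
            c = _parse_float(line[24:33])
            alpha = _parse_float(line[33:40], 90.0)
            beta = _parse_float(line[40:47], 90.0)
            gamma = _parse_float(line[47:54], 90.0)
            sg_symbol = line[55:66].strip()
            z_text = line[66:70].strip()
            z_value = int(z_text) if z_text else 1
            cell = UnitCell(a, b, c, alpha, beta, gamma, z_value=z_value)
        elif rec == "TITLE ":
            title_parts.append(line[10:80].strip())
        elif rec == "HEADER":
            pdb_code = line[62:66].strip()
        elif rec == "REMARK":
            m = re.search(r"WAVELENGTH OR RANGE\s*\(A\)\s*:\s*([\d.]+)", line)
            if m:
                try:
                    wavelength = float(m.group(1))
                except ValueError:
                    pass
        elif rec == "SSBOND":
            ssbonds.append((line[15], int(line[17:21] or 0),
                            line[29], int(line[31:35] or 0)))
        elif rec in ("ATOM  ", "HETATM"):
            name_field = line[12:16]
            element = line[76:78].strip().capitalize() if len(line) > 76 else ""
            if not element:
                element = _infer_element(name_field, line[17:20].strip())
            atom = AtomRecord(
                name=name_field.strip(),
                res_name=line[17:20].strip(),
                chain_id=line[21] if len(line) > 21 else " ",
                res_seq=int(line[22:26]),
                xyz_cart=np.array([_parse_float(line[30:38]),
                                   _parse_float(line[38:46]),
                                   _parse_float(line[46:54])]),
                occupancy=_parse_float(line[54:60], 1.0),
                b_iso=_parse_float(line[60:66]),
                element=element,
                alt_loc=line[16] if len(line) > 16 else " ",
                insertion_code=line[26] if len(line) > 26 else " ",
                serial=int(line[6:11].strip() or 0),
                is_hetatm=(rec == "HETATM"),
            )
            if atom.key in seen_keys:
                raise DuplicateAtomError(
                    f"duplicate atom identity {atom.key}")
            seen_keys.add(atom.key)
            atoms.append(atom)
        elif rec == "ANISOU":
            if not atoms:
                continue
            u = np.array([_parse_float(line[28 + 7 * i:35 + 7 * i])
                          for i in range(6)]) * 1.0e-4
            atoms[-1].u_aniso_cart = np.array([
                [u[0], u[3], u[4]],
                [u[3], u[1], u[5]],
                [u[4], u[5], u[2]],
            ])

    if cell is None:
        raise MissingCellError("no CRYST1 record: cell and space group unknown")
    if wavelength is not None:
        cell.wavelength = wavelength
    return StructureModel(atoms=atoms, cell=cell, space_group_symbol=sg_symbol,
                          z_value=z_value, title=" ".join(title_parts),
                          pdb_code=pdb_code, ssbond_hints=ssbonds)


def write_pdb(model: StructureModel) -> str:
    """Serialize back to PDB text (round-trip and fixture support)."""
    lines = []
    if model.title:
        lines.append(f"TITLE     {model.title[:70]}")
    if model.cell.wavelength is not None:
        lines.append("REMARK 200  WAVELENGTH OR RANGE        (A) : "
                     f"{model.cell.wavelength:.5f}")
    c = model.cell
    lines.append(
        f"CRYST1{c.a:9.3f}{c.b:9.3f}{c.c:9.3f}"
        f"{c.alpha:7.2f}{c.beta:7.2f}{c.gamma:7.2f} "
        f"{model.space_group_symbol:<11s}{model.z_value:4d}")
    serial = 0
    for atom in model.atoms:
        serial += 1
        rec = "HETATM" if atom.is_hetatm else "ATOM  "
        name = atom.name
        if len(name) < 4 and not (name[:2].upper() in _TWO_LETTER_ELEMENTS
                                  and atom.element.upper() == name[:2].upper()):
            name = " " + name
        x, y, z = atom.xyz_cart
        lines.append(
            f"{rec}{serial:5d} {name:<4s}{atom.alt_loc}{atom.res_name:>3s} "
            f"{atom.chain_id}{atom.res_seq:4d}{atom.insertion_code}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_iso:6.2f}"
            f"          {atom.element.upper():>2s}")
        if atom.u_aniso_cart is not None:
            u = atom.u_aniso_cart * 1.0e4
            vals = (u[0, 0], u[1, 1], u[2, 2], u[0, 1], u[0, 2], u[1, 2])
            lines.append(
                f"ANISOU{serial:5d} {name:<4s}{atom.alt_loc}{atom.res_name:>3s} "
                f"{atom.chain_id}{atom.res_seq:4d}{atom.insertion_code} "
                + "".join(f"{v:7.0f}" for v in vals)
                + f"      {atom.element.upper():>2s}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def validate_chain_id(chain_id: str, used: set[str] | None = None) -> str:
    """Pass a legal chain identifier through, or remap an illegal one.

    Legal identifiers are upper/lower-case letters, digits and blank.  An
    illegal character is deterministically remapped to the first identifier
    (in A-Z, a-z, 0-9, blank order) not already in ``used``.
    """
    if len(chain_id) != 1:
        raise ValueError("chain identifier must be a single character")
    if chain_id in LEGAL_CHAIN_IDS:
        return chain_id
    used = used or set()
    for candidate in LEGAL_CHAIN_IDS:
        if candidate not in used:
            return candidate
    raise ChainExhaustionError(
        "structure requires more than the 63 legal chain identifiers")


def remap_chains(model: StructureModel) -> tuple[StructureModel, dict[str, str]]:
    """Apply :func:`validate_chain_id` across the model; report the mapping."""
    chains = model.chains()
    if len(chains) > len(LEGAL_CHAIN_IDS):
        raise ChainExhaustionError(
            f"{len(chains)} chains exceed the 63 legal identifiers")
    mapping: dict[str, str] = {}
    used = {ch for ch in chains if ch in LEGAL_CHAIN_IDS}
    for ch in chains:
        if ch in LEGAL_CHAIN_IDS:
            mapping[ch] = ch
        else:
            new = validate_chain_id(ch, used)
            used.add(new)
            mapping[ch] = new
            warnings.warn(f"chain {ch!r} remapped to {new!r}",
                          ConversionWarning, stacklevel=2)
    if all(k == v for k, v in mapping.items()):
        return model, mapping
    atoms = [replace(a, chain_id=mapping[a.chain_id]) for a in model.atoms]
    return replace(model, atoms=atoms), mapping


def validate_residue_name(res_name: str) -> bool:
    """True when the name is acceptable; all-digit names are flagged.

    A residue name made only of digits could be mistaken for a residue
    number.  The caller decides whether to prompt for a rename (interactive)
    or warn and continue (automated).
    """
    name = res_name.strip()
    if not name or len(name) > 3:
        raise ValueError(f"residue name must be 1-3 characters: {res_name!r}")
    return not name.isdigit()


def renumber_residues(
    model: StructureModel,
) -> tuple[StructureModel, dict[tuple, int]]:
    """Remove insertion codes and force residue numbers into [-999, 9999].

    Chains whose numbering is already legal are left untouched.  Otherwise
    the chain is renumbered sequentially in file order starting from its
    first residue's number (or 1 when that is itself out of range), which
    preserves relative order.  Returns the model and an old->new map keyed by
    (chain, old res_seq, old insertion code).
    """
    by_chain: dict[str, list[tuple]] = {}
    for key, _atoms in model.residues():
        by_chain.setdefault(key[0], []).append(key)

    new_numbers: dict[tuple, int] = {}
    for chain, keys in by_chain.items():
        if len(keys) > RESSEQ_MAX - RESSEQ_MIN + 1:
            raise CapacityError(
                f"chain {chain!r} has {len(keys)} residues; the legal range "
                f"holds only {RESSEQ_MAX - RESSEQ_MIN + 1}")
        numbers = [k[1] for k in keys]
        legal = (all(k[2] == " " for k in keys)
                 and all(RESSEQ_MIN <= n <= RESSEQ_MAX for n in numbers)
                 and len(set(numbers)) == len(numbers))
        if legal:
            for key in keys:
                new_numbers[key] = key[1]
            continue
        start = keys[0][1]
        if not (RESSEQ_MIN <= start and start + len(keys) - 1 <= RESSEQ_MAX):
            start = 1
        for offset, key in enumerate(keys):
            new_numbers[key] = start + offset

    changed = {k: v for k, v in new_numbers.items()
               if v != k[1] or k[2] != " "}
    if not changed:
        return model, {}
    atoms = [replace(a, res_seq=new_numbers[a.residue_key], insertion_code=" ")
             for a in model.atoms]
    mapping = {(k[0], k[1], k[2]): v for k, v in changed.items()}
    return replace(model, atoms=atoms), mapping
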