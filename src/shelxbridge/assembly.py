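"""Assembly of the complete, ordered SHELX instruction (.ins) document.

Card order: TITL, CELL (wavelength + six cell parameters), ZERR (Z + cell
esds), LATT, SYMM block, SFAC, UNIT, DISP block, global displacement-
parameter instructions, restraint and hydrogen-rule cards, the residue
blocks (RESI + atom cards in fractional coordinates), and finally HKLF and
END.  Keywords are upper case; chain identifiers are the one exception to
SHELX case-insensitivity and are preserved as given.

Atom cards carry the site occupancy in SHELX's coded form: 10 + q for an
untied occupancy q (so a full atom reads 11.00000), or fv*10 + q referencing
free variable fv for tied disorder components.  Two-conformer alternate
locations are wrapped in PART 1 / PART 2 with occupancies fv and 1 - fv
tied to one free variable per disorder group (codes 21.0 and -21.0 for free
variable 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cards import Card
from .errors import AssemblyError
from .geometry import UnitCell, b_to_u
from .reflections import ReflectionSet, write_hkl
from .scattering import validate_element
from .stereochemistry import HfixRule, RestraintRecord
from .structure import RESSEQ_MAX, RESSEQ_MIN, AtomRecord, StructureModel
from .symmetry import SpaceGroupSetting, emit_symmetry_cards

__all__ = ["InsDocument", "emit_resi_blocks", "emit_atom_card",
           "emit_global_adp_cards", "assemble", "write_ins"]

_MAX_LINE = 78

_KNOWN_KEYWORDS = {
    "TITL", "CELL", "ZERR", "LATT", "SYMM", "SFAC", "UNIT", "DISP", "NEUT",
    "RIGU", "XNPD", "DELU", "SIMU", "ANIS", "DFIX", "DANG", "FLAT", "CHIV",
    "HFIX", "RESI", "PART", "HKLF", "END", "CGLS", "LIST", "FVAR", "WGHT",
    "FMAP", "PLAN", "CONN", "MORE", "SHEL", "MERG", "BUMP", "ISOR", "SWAT",
    "TEMP", "SADI", "SAME",
}


@dataclass
class InsDocument:
    """Ordered card list forming a complete .ins file."""

    cards: list[Card] = field(default_factory=list)

    def text(self) -> str:
        lines = []
        for card in self.cards:
            lines.append(_wrap(card.text))
        return "\n".join(lines) + "\n"

    def keywords(self) -> list[str]:
        return [c.keyword for c in self.cards if not c.commented]

    def find(self, keyword: str) -> list[Card]:
        return [c for c in self.cards if c.keyword == keyword]


def _wrap(line: str) -> str:
    """SHELX '=' continuation for lines longer than 78 characters."""
    if len(line) <= _MAX_LINE:
        return line
    parts = []
    while len(line) > _MAX_LINE:
        cut = line.rfind(" ", 1, _MAX_LINE - 1)
        if cut <= 0:
            cut = _MAX_LINE - 2
        parts.append(line[:cut] + " =")
        line = "   " + line[cut:].lstrip()
    parts.append(line)
    return "\n".join(parts)


def emit_global_adp_cards() -> list[Card]:
    """Global displacement-parameter instructions.

    RIGU (extended rigid-bond restraint) and XNPD 0.01 (minimum-eigenvalue
    guard against non-positive-definite ellipsoids) are written active,
    always; they only bite once the user activates anisotropy, so ANIS is
    offered as a comment, as are the older DELU and SIMU restraints.
    """
    return [
        Card("RIGU"),
        Card("XNPD", "0.01"),
        Card("ANIS", commented=True),
        Card("DELU", commented=True),
        Card("SIMU", commented=True),
    ]


def _occupancy_code(q: float, free_variable: int | None = None,
                    complement: bool = False) -> float:
    if free_variable is None:
        return 10.0 + q
    code = free_variable * 10.0 + q
    return -code if complement else code


def emit_atom_card(atom: AtomRecord, cell: UnitCell, sfac_index: int,
                   free_variable: int | None = None,
                   complement: bool = False) -> Card:
    """One SHELX atom line: label, SFAC index, fractional x y z, coded
    occupancy, then U_iso or the six U_ij (CIF convention)."""
    frac = cell.cart_to_frac(atom.xyz_cart)
    occ = _occupancy_code(1.0 if free_variable else atom.occupancy,
                          free_variable, complement)
    fields = [f"{sfac_index}",
              f"{frac[0]:.6f}", f"{frac[1]:.6f}", f"{frac[2]:.6f}",
              f"{occ:.5f}"]
    if atom.u_aniso_cart is not None:
        u6 = cell.adp_cart_to_cif(atom.u_aniso_cart)
        fields += [f"{u:.5f}" for u in u6]
    else:
        fields.append(f"{b_to_u(atom.b_iso):.5f}")
    return Card(atom.name.upper(), " ".join(fields))


def emit_resi_blocks(model: StructureModel, sfac_elements: list[str]
                     ) -> list[Card]:
    """RESI cards plus atom cards for every residue, with PART wrapping of
    alternate-location groups.

    The RESI form is ``RESI <name> <chain>:<number>`` when the structure has
    several chains and ``RESI <name> <number>`` for a single (or blank)
    chain.  Residue numbers must already be legal; this stage refuses
    out-of-range numbers rather than renumbering silently.
    """
    sfac_index = {el.upper(): i + 1 for i, el in enumerate(sfac_elements)}
    chains = model.chains()
    multi_chain = len([c for c in chains if c.strip()]) > 1
    cards: list[Card] = []
    free_variable = 1  # fv 1 is the overall scale; disorder groups start at 2
    for key, atoms in model.residues():
        chain, number, _icode, name = key[0], key[1], key[2], key[3]
        if not RESSEQ_MIN <= number <= RESSEQ_MAX:
            raise AssemblyError(
                f"residue number {number} outside [{RESSEQ_MIN}, "
                f"{RESSEQ_MAX}]; renumber before assembly")
        if multi_chain and chain.strip():
            cards.append(Card("RESI", f"{name} {chain}:{number}"))
        else:
            cards.append(Card("RESI", f"{name} {number}"))
        alts = sorted({a.alt_loc for a in atoms if a.alt_loc != " "})
        plain = [a for a in atoms if a.alt_loc == " "]
        for atom in plain:
            cards.append(emit_atom_card(
                atom, model.cell, sfac_index[validate_element(atom.element).upper()]))
        if alts:
            two_state = len(alts) == 2
            if two_state:
                free_variable += 1
            for part, alt in enumerate(alts, start=1):
                cards.append(Card("PART", str(part)))
                for atom in atoms:
                    if atom.alt_loc != alt:
                        continue
                    cards.append(emit_atom_card(
                        atom, model.cell,
                        sfac_index[validate_element(atom.element).upper()],
                        free_variable=free_variable if two_state else None,
                        complement=two_state and part == 2))
            cards.append(Card("PART", "0"))
    return cards


def _restraint_card(record: RestraintRecord) -> Card:
    head, _, payload = record.card_text.partition(" ")
    return Card(head, payload)


def _hfix_card(rule: HfixRule, instance_suffix: str = "") -> Card:
    scope = f"_{rule.residue_name}" if rule.commented else ""
    parents = " ".join(p + instance_suffix for p in rule.parent_atoms)
    return Card(f"HFIX{scope}", f"{rule.hfix_code} {parents}",
                commented=rule.commented)


def assemble(model: StructureModel,
             setting: SpaceGroupSetting,
             sfac_card: Card,
             unit_card: Card,
             disp_cards: list[Card] = (),
             restraints: list[RestraintRecord] = (),
             hfix_cards: list[Card] = (),
             reflection_set: ReflectionSet | None = None,
             cell_esds: tuple | None = None) -> InsDocument:
    """Compose the full instruction document and grammar-check it."""
    cell = model.cell
    doc = InsDocument()
    title = model.title or "converted structure"
    if model.pdb_code:
        title = f"{model.pdb_code} {title}" if model.title else model.pdb_code
    doc.cards.append(Card("TITL", title.strip()[:70]))
    lam = cell.wavelength if cell.wavelength else 1.54184
    doc.cards.append(Card("CELL", f"{lam:.5f} " + " ".join(
        f"{v:.4f}" if i < 3 else f"{v:.3f}"
        for i, v in enumerate(cell.parameters))))
    esds = cell_esds or (0.0,) * 6
    doc.cards.append(Card("ZERR", f"{model.z_value} " + " ".join(
        f"{v:.4f}" if i < 3 else f"{v:.3f}" for i, v in enumerate(esds))))
    doc.cards.extend(emit_symmetry_cards(setting))
    doc.cards.append(sfac_card)
    doc.cards.append(unit_card)
    doc.cards.extend(disp_cards)
    if cell.wavelength is None:
        doc.cards.append(Card("MORE", "wavelength unknown; CELL assumes Cu "
                                      "K-alpha", commented=True))
    doc.cards.append(Card("NEUT", "(insert for neutron data)", commented=True))
    doc.cards.extend(emit_global_adp_cards())
    # conventional refinement template, left to the user to activate
    doc.cards.append(Card("CGLS", "10", commented=True))
    doc.cards.append(Card("LIST", "6", commented=True))
    sfac_elements = sfac_card.payload.split()
    for record in restraints:
        doc.cards.append(_restraint_card(record))
    doc.cards.extend(hfix_cards)
    doc.cards.append(Card("WGHT", "0.1"))
    doc.cards.append(Card("FVAR", "1.0"))
    doc.cards.extend(emit_resi_blocks(model, sfac_elements))
    hklf = reflection_set.hklf_code if reflection_set is not None else 4
    doc.cards.append(Card("HKLF", str(hklf)))
    doc.cards.append(Card("END"))
    _check_grammar(doc, sfac_elements)
    return doc


def _check_grammar(doc: InsDocument, sfac_elements: list[str]) -> None:
    """Internal validity check of the finished document."""
    singles = ("TITL", "CELL", "ZERR", "LATT", "SFAC", "UNIT", "HKLF", "END")
    keywords = doc.keywords()
    for kw in singles:
        if keywords.count(kw) != 1:
            raise AssemblyError(f"expected exactly one {kw} card, found "
                                f"{keywords.count(kw)}")
    latt_pos = keywords.index("LATT")
    symm_pos = [i for i, kw in enumerate(keywords) if kw == "SYMM"]
    if symm_pos and (symm_pos[0] != latt_pos + 1
                     or symm_pos[-1] - symm_pos[0] != len(symm_pos) - 1):
        raise AssemblyError("SYMM cards must directly and contiguously "
                            "follow LATT")
    if keywords[-2:] != ["HKLF", "END"]:
        raise AssemblyError("document must end with HKLF then END")

    resi_names: set[str] = set()
    n_sfac = len(sfac_elements)
    resi_seen = False
    for card in doc.cards:
        base = card.keyword.split("_")[0]
        if not card.commented and base not in _KNOWN_KEYWORDS and not resi_seen:
            raise AssemblyError(f"unknown card keyword {card.keyword!r}")
        if card.keyword == "RESI":
            resi_seen = True
            resi_names.add(card.payload.split()[0])
        elif resi_seen and base not in _KNOWN_KEYWORDS:
            # atom card: first payload field is the SFAC index
            idx = int(card.payload.split()[0])
            if not 1 <= idx <= n_sfac:
                raise AssemblyError(
                    f"atom {card.keyword} references SFAC index {idx} "
                    f"outside 1..{n_sfac}")
    for card in doc.cards:
        if "_" in card.keyword:
            scope = card.keyword.split("_", 1)[1]
            if scope and not scope.isdigit() and scope not in resi_names \
                    and scope != "*":
                raise AssemblyError(
                    f"card {card.keyword!r} references residue name "
                    f"{scope!r} absent from every RESI card")


def write_ins(doc: InsDocument, path) -> None:
    with open(path, "w") as fh:
        fh.write(doc.text())


def write_pair(doc: InsDocument, reflection_set: ReflectionSet | None,
               basename: str) -> list[str]:
    """Write .ins (and .hkl when data exist) side by side, same basename."""
    written = [f"{basename}.ins"]
    write_ins(doc, f"{basename}.ins")
    if reflection_set is not None:
        with open(f"{basename}.hkl", "w") as fh:
            write_hkl(reflection_set, fh)
        written.append(f"{basename}.hkl")
    return written
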