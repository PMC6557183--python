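"""End-to-end conversion: coordinates (+ reflections) in, .ins/.hkl out.

The run orchestrates the whole bridge: parse and validate the PDB file,
normalize identifiers, expand the space-group symmetry, transform
coordinates and displacement parameters, generate restraints and hydrogen
rules, build the scattering cards, and assemble the paired instruction and
reflection files.  In automated mode warnings never halt the run; errors
carry the defect-class labels used in the run report.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field
from urllib.error import HTTPError, URLError

from . import assembly, reflections, scattering, stereochemistry, structure
from .errors import NetworkError, NotFoundError, ShelxBridgeError
from .stereochemistry import AMINO_ACIDS
from .symmetry import lookup_space_group

__all__ = ["RunConfig", "RunReport", "run", "fetch_by_code",
           "PUBLIC_ARCHIVE_URL", "REDO_ARCHIVE_URL"]

PUBLIC_ARCHIVE_URL = "https://files.rcsb.org/download"
REDO_ARCHIVE_URL = "https://pdb-redo.eu/db"


@dataclass
class RunConfig:
    """Inputs and switches for one conversion run."""

    pdb_path: str | None = None
    hkl_path: str | None = None  # mmCIF reflection file, despite the name
    pdb_code: str | None = None
    use_redo: bool = False
    interactive: bool = False
    output_basename: str = "converted"
    wavelength: float | None = None
    space_group: str | None = None
    disulfide_window: tuple = stereochemistry.DISULFIDE_WINDOW
    chain_break: float = stereochemistry.CHAIN_BREAK_CA_DISTANCE
    fetcher: object = None  # injectable: fetcher(url) -> text
    prompter: object = None  # injectable: prompter(message) -> str

    def __post_init__(self) -> None:
        if (self.pdb_path is None) == (self.pdb_code is None):
            raise ValueError("exactly one input source (path or code) required")
        if self.pdb_code is not None and (
                len(self.pdb_code) != 4 or not self.pdb_code.isalnum()):
            raise ValueError("archive codes are 4 alphanumeric characters")


@dataclass
class RunReport:
    """What a run did: warnings, errors, remappings, files written."""

    warnings: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)
    chain_map: dict = field(default_factory=dict)
    renumber_map: dict = field(default_factory=dict)
    dropped_reflections: dict = field(default_factory=dict)
    files: list[str] = field(default_factory=list)
    n_atoms: int = 0
    n_reflections: int = 0
    n_free: int = 0

    @property
    def ok(self) -> bool:
        return not self.errors


def _default_fetcher(url: str) -> str:
    import urllib.request
    try:
        with urllib.request.urlopen(url, timeout=60) as resp:
            return resp.read().decode()
    except HTTPError as exc:
        if exc.code == 404:
            raise NotFoundError(f"{url}: not found") from exc
        raise NetworkError(f"{url}: HTTP {exc.code}") from exc
    except URLError as exc:
        raise NetworkError(f"{url}: {exc.reason}") from exc


def fetch_by_code(code: str, use_redo: bool = False,
                  fetcher=None) -> tuple[str, str | None]:
    """Fetch (coordinate text, reflection text or None) for a 4-char code.

    The reflection file may legitimately be absent; that path returns the
    coordinates alone and the caller warns.  ``fetcher`` is injectable so
    tests never touch the network.
    """
    fetch = fetcher or _default_fetcher
    code = code.lower()
    if use_redo:
        pdb_url = f"{REDO_ARCHIVE_URL}/{code}/{code}_final.pdb"
        sf_url = f"{REDO_ARCHIVE_URL}/{code}/{code}_final.cif"
    else:
        pdb_url = f"{PUBLIC_ARCHIVE_URL}/{code.upper()}.pdb"
        sf_url = f"{PUBLIC_ARCHIVE_URL}/{code.upper()}-sf.cif"
    coords = fetch(pdb_url)
    try:
        sf = fetch(sf_url)
    except NotFoundError:
        sf = None
    return coords, sf


def run(config: RunConfig) -> RunReport:
    """Execute a conversion run; returns the report.

    Errors are collected (with their defect-class labels) rather than
    raised, so a caller can render the report; no .ins is written when an
    error occurred.
    """
    report = RunReport()
    try:
        _run_inner(config, report)
    except ShelxBridgeError as exc:
        report.errors.append(f"[{exc.label}] {exc}")
    return report


def _run_inner(config: RunConfig, report: RunReport) -> None:
    if config.pdb_code is not None:
        pdb_text, refl_text = fetch_by_code(config.pdb_code, config.use_redo,
                                            config.fetcher)
        if refl_text is None:
            report.warnings.append(
                "no reflection data available for this entry; writing the "
                "instruction file only")
    else:
        with open(config.pdb_path) as fh:
            pdb_text = fh.read()
        refl_text = None
        if config.hkl_path:
            with open(config.hkl_path) as fh:
                refl_text = fh.read()

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = structure.read_pdb(pdb_text)
        model, report.chain_map = structure.remap_chains(model)
        model, report.renumber_map = structure.renumber_residues(model)

        for key, _atoms in model.residues():
            name = key[3]
            if not structure.validate_residue_name(name):
                if config.interactive and config.prompter is not None:
                    new = config.prompter(
                        f"residue name {name!r} consists only of digits; "
                        f"enter a replacement: ").strip()
                    if new:
                        for atom in model.atoms:
                            if atom.res_name == name:
                                atom.res_name = new[:3].upper()
                        continue
                warnings.warn(
                    f"residue name {name!r} consists only of digits; "
                    f"continuing without renaming", UserWarning)

        for atom in model.atoms:
            scattering.validate_element(atom.element)

        if config.wavelength is not None:
            model.cell.wavelength = config.wavelength
        elif model.cell.wavelength is None and config.interactive \
                and config.prompter is not None:
            answer = config.prompter("wavelength in Angstrom (blank for "
                                     "Cu K-alpha): ").strip()
            if answer:
                model.cell.wavelength = float(answer)
        symbol = config.space_group or model.space_group_symbol
        setting = lookup_space_group(symbol)

        refl_set = None
        if refl_text is not None:
            refl_set = reflections.read_refln_cif(refl_text)
            report.dropped_reflections = dict(refl_set.dropped)
            report.n_reflections = len(refl_set)
            report.n_free = refl_set.n_free

        sfac_card, unit_card = scattering.build_sfac(
            model, n_operators=len(setting.operators),
            centering_multiplicity=setting.centering_multiplicity)
        disp_cards = scattering.emit_disp_cards(
            sfac_card.payload.split(), model.cell.wavelength)

        restraints: list = []
        segments = stereochemistry.detect_termini(model, config.chain_break)
        oxt_residue_names = {seg.c_terminal[3] for seg in segments
                             if seg.has_oxt}
        seen_types: set[str] = set()
        residue_atom_names: dict[str, set] = {}
        for key, atoms_ in model.residues():
            residue_atom_names.setdefault(key[3], set()).update(
                a.name for a in atoms_)
        for key, _atoms in model.residues():
            name = key[3]
            if name in seen_types:
                continue
            seen_types.add(name)
            restraints.extend(stereochemistry.restraints_for_residue(
                name, terminal_oxt=name in oxt_residue_names))

        bridges = stereochemistry.detect_disulfides(
            model.atoms, config.disulfide_window)
        bridged_sg: set[tuple] = set()
        for a, b in bridges:
            bridged_sg.add(a.residue_key)
            bridged_sg.add(b.residue_key)
            restraints.append(stereochemistry.RestraintRecord(
                "DFIX", stereochemistry.DISULFIDE_TARGET, 0.02,
                (f"SG_{a.res_seq}", f"SG_{b.res_seq}")))
        restraints.extend(
            stereochemistry.peptide_planarity(model, config.chain_break))

        n_terminal_keys = {seg.n_terminal for seg in segments}
        hfix_cards: list = []
        emitted_types: set[str] = set()
        for key, atoms_ in model.residues():
            name = key[3]
            if name.upper() not in AMINO_ACIDS and name not in ("GOL", "EDO"):
                continue
            if name in emitted_types:
                continue
            emitted_types.add(name)
            suppress = {"SG"} if any(k[3] == name for k in bridged_sg) else set()
            rules = stereochemistry.hfix_for_residue(
                name, residue_atom_names[name],
                n_terminal=key in n_terminal_keys, suppress=suppress)
            hfix_cards.extend(assembly._hfix_card(rule) for rule in rules)

        doc = assembly.assemble(model, setting, sfac_card, unit_card,
                                disp_cards, restraints, hfix_cards, refl_set)

    for w in caught:
        report.warnings.append(str(w.message))
    report.n_atoms = len(model.atoms)
    report.files = assembly.write_pair(doc, refl_set, config.output_basename)


def print_report(report: RunReport, stream=None) -> None:
    stream = stream or sys.stdout
    for err in report.errors:
        print(f"ERROR   {err}", file=stream)
    for warning in report.warnings:
        print(f"WARNING {warning}", file=stream)
    for old, new in report.chain_map.items():
        if old != new:
            print(f"REMAP   chain {old!r} -> {new!r}", file=stream)
    if report.renumber_map:
        print(f"RENUMBER {len(report.renumber_map)} residues", file=stream)
    for status, count in report.dropped_reflections.items():
        print(f"DROPPED {count} reflections with status {status!r}",
              file=stream)
    for path in report.files:
        print(f"WROTE   {path}", file=stream)
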