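"""Stereochemical restraints and hydrogen-generation rules.

Distance restraints for amino acids follow the Engh & Huber-style target
library embedded as package data: DFIX cards restrain 1,2 (bonded)
distances, DANG cards restrain 1,3 distances.  Angle targets are converted
to 1,3-distance targets by the law of cosines on the two bounding bond
targets, since SHELX restrains distances rather than angles.  Planarity of
the peptide link is enforced with FLAT restraints (no torsion restraint, so
a cis/trans flip remains possible if the data demand it).

Disulfide bridges and chain termini are detected geometrically from the
coordinates; detected disulfides get an S-S distance restraint and lose
their thiol hydrogen rule.

Hydrogen atoms themselves are generated later, inside the refinement, by
HFIX riding-model codes (43 amide/aromatic, 13 methine, 23 methylene,
33 methyl/ammonium, 93 terminal sp2 NH2, 147 rotating hydroxyl/thiol).
The per-residue HFIX rules are written as comments (``REM HFIX_...``) so
the user activates them deliberately; rules whose parent atoms are missing
from the model are converted to active ``HFIX 0`` placeholders so later
hydrogen generation cannot fail on an incomplete side chain.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import NoRestraintsWarning
from .structure import AtomRecord, StructureModel

__all__ = [
    "RestraintRecord", "HfixRule", "Segment", "restraints_for_residue",
    "detect_disulfides", "detect_termini", "peptide_planarity",
    "hfix_for_residue", "residue_library", "AMINO_ACIDS",
    "DISULFIDE_WINDOW", "DISULFIDE_TARGET", "CHAIN_BREAK_CA_DISTANCE",
]

#: Valid riding-hydrogen HFIX codes.
HFIX_CODES = {0, 13, 23, 33, 43, 83, 93, 137, 147}

#: SG-SG distance window (A) accepted as a disulfide bridge, and the
#: restraint target applied to a detected bridge.
DISULFIDE_WINDOW = (1.8, 2.5)
DISULFIDE_TARGET = 2.031

#: Consecutive residues whose CA-CA distance exceeds this (A) start a new
#: segment with its own termini.
CHAIN_BREAK_CA_DISTANCE = 4.5

_DANG_ESD = 0.04
_FLAT_ESD = 0.1


@dataclass(frozen=True)
class RestraintRecord:
    """One SHELX geometrical restraint card's content."""

    kind: str  # DFIX | DANG | FLAT | CHIV
    target: float | None
    esd: float
    atom_names: tuple[str, ...]
    residue_scope: str = ""  # e.g. "_VAL"; empty for explicit atom lists

    def __post_init__(self) -> None:
        if self.kind in ("DFIX", "DANG"):
            if self.target is None or self.target <= 0:
                raise ValueError("distance restraints need a positive target")
            if len(self.atom_names) < 2:
                raise ValueError("distance restraints need at least 2 atoms")
        if self.kind == "FLAT" and len(self.atom_names) < 4:
            raise ValueError("FLAT needs at least 4 atoms")
        if self.esd <= 0:
            raise ValueError("esd must be positive")

    @property
    def card_text(self) -> str:
        head = f"{self.kind}{self.residue_scope}"
        if self.kind in ("DFIX", "DANG"):
            body = f"{self.target:.3f} {self.esd:.3f} " + " ".join(self.atom_names)
        else:
            body = f"{self.esd:.2f} " + " ".join(self.atom_names)
        return f"{head} {body}"


@dataclass(frozen=True)
class HfixRule:
    """One HFIX card: riding-hydrogen code applied to parent atoms."""

    residue_name: str
    hfix_code: int
    parent_atoms: tuple[str, ...]
    commented: bool = True

    def __post_init__(self) -> None:
        if self.hfix_code not in HFIX_CODES:
            raise ValueError(f"unknown HFIX code {self.hfix_code}")


@dataclass
class Segment:
    """A continuous run of amino-acid residues within one chain."""

    chain_id: str
    residues: list[tuple] = field(default_factory=list)  # residue keys
    has_oxt: bool = False

    @property
    def n_terminal(self) -> tuple:
        return self.residues[0]

    @property
    def c_terminal(self) -> tuple:
        return self.residues[-1]


_LIBRARY: dict | None = None
_HFIX: dict | None = None


def residue_library() -> dict:
    global _LIBRARY
    if _LIBRARY is None:
        text = resources.files("shelxbridge.data").joinpath(
            "amino_restraints.json").read_text()
        _LIBRARY = json.loads(text)
    return _LIBRARY


def _hfix_library() -> dict:
    global _HFIX
    if _HFIX is None:
        text = resources.files("shelxbridge.data").joinpath(
            "hfix_rules.json").read_text()
        _HFIX = json.loads(text)
    return _HFIX


AMINO_ACIDS = frozenset({
    "GLY", "ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "TYR", "TRP", "SER",
    "THR", "CYS", "MET", "ASN", "GLN", "ASP", "GLU", "LYS", "ARG", "HIS",
})

_EXEMPT = {"HOH", "WAT", "DOD"}  # solvent: single heavy atom, nothing to restrain


def _bond_map(entry: dict) -> dict[tuple[str, str], tuple[float, float]]:
    out = {}
    for a1, a2, target, esd in entry["bonds"]:
        out[(a1, a2)] = (target, esd)
        out[(a2, a1)] = (target, esd)
    return out


def _angle_target(entry: dict, a: str, center: str, c: str) -> float:
    angles = entry.get("angles", {})
    for key in (f"{a} {center} {c}", f"{c} {center} {a}"):
        if key in angles:
            return angles[key]
    return 120.0 if center in entry.get("sp2", []) else 109.5


def one_three_pairs(entry: dict) -> list[tuple[str, str, str]]:
    """(a, center, c) triples at graph distance two in the bond graph."""
    neighbours: dict[str, list[str]] = {}
    for a1, a2, _t, _e in entry["bonds"]:
        neighbours.setdefault(a1, []).append(a2)
        neighbours.setdefault(a2, []).append(a1)
    triples = []
    seen = set()
    for center, nbrs in neighbours.items():
        for i in range(len(nbrs)):
            for j in range(i + 1, len(nbrs)):
                a, c = nbrs[i], nbrs[j]
                if (a, c) in seen or (c, a) in seen:
                    continue
                seen.add((a, c))
                triples.append((a, center, c))
    return triples


def restraints_for_residue(res_name: str,
                           terminal_oxt: bool = False) -> list[RestraintRecord]:
    """DFIX and DANG restraints for one residue type.

    Unknown residue types return an empty list after a
    :class:`NoRestraintsWarning`; waters are exempt (nothing to restrain).
    With ``terminal_oxt`` the carboxylate form of the C terminus is added
    (C-OXT bond plus its 1,3 partners).
    """
    name = res_name.strip().upper()
    if name in _EXEMPT:
        return []
    lib = residue_library()
    entry = lib.get(name)
    if entry is None:
        warnings.warn(
            f"residue {name!r} is not in the restraint library; its atoms "
            f"will not be subject to appropriate restraints",
            NoRestraintsWarning, stacklevel=2)
        return []
    entry = dict(entry)
    entry["bonds"] = [list(b) for b in entry["bonds"]]
    if terminal_oxt and entry.get("kind") == "amino":
        entry["bonds"].append(["C", "OXT", 1.249, 0.019])
        # terminal carboxylate: both C-O bonds become equivalent
        for bond in entry["bonds"]:
            if bond[0] == "C" and bond[1] == "O":
                bond[2], bond[3] = 1.249, 0.019

    scope = f"_{name}"
    records = []
    bonds = _bond_map(entry)
    for a1, a2, target, esd in entry["bonds"]:
        records.append(RestraintRecord("DFIX", target, esd, (a1, a2), scope))
    for a, center, c in one_three_pairs(entry):
        d1, _ = bonds[(a, center)]
        d2, _ = bonds[(center, c)]
        theta = math.radians(_angle_target(entry, a, center, c))
        d13 = math.sqrt(d1 * d1 + d2 * d2 - 2 * d1 * d2 * math.cos(theta))
        records.append(RestraintRecord("DANG", round(d13, 3), _DANG_ESD,
                                       (a, c), scope))
    return records


def detect_disulfides(
    atoms: list[AtomRecord],
    window: tuple[float, float] = DISULFIDE_WINDOW,
) -> list[tuple[AtomRecord, AtomRecord]]:
    """Pair cysteine SG atoms whose separation falls in the bridge window.

    Greedy nearest-wins matching: candidate pairs are sorted by distance and
    accepted while both partners are still free, so each SG joins at most
    one bridge and the result is independent of input order.
    """
    sgs = [a for a in atoms if a.res_name.upper() == "CYS" and a.name == "SG"]
    lo, hi = window
    candidates = []
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            d = float(np.linalg.norm(sgs[i].xyz_cart - sgs[j].xyz_cart))
            if lo <= d <= hi:
                candidates.append((d, i, j))
    candidates.sort(key=lambda t: (t[0], sgs[t[1]].key, sgs[t[2]].key))
    paired: set[int] = set()
    pairs = []
    for _d, i, j in candidates:
        if i in paired or j in paired:
            continue
        paired.update((i, j))
        first, second = sorted((sgs[i], sgs[j]), key=lambda a: a.key)
        pairs.append((first, second))
    return pairs


def _segments(model: StructureModel,
              break_distance: float = CHAIN_BREAK_CA_DISTANCE) -> list[Segment]:
    ca_by_residue: dict[tuple, np.ndarray] = {}
    for atom in model.atoms:
        if atom.name == "CA" and atom.alt_loc in (" ", "A"):
            ca_by_residue[atom.residue_key] = atom.xyz_cart
    oxt_residues = {a.residue_key for a in model.atoms if a.name == "OXT"}

    segments: list[Segment] = []
    current: Segment | None = None
    prev_ca: np.ndarray | None = None
    prev_chain = None
    for key, _atoms in model.residues():
        chain, res_name = key[0], key[3]
        if res_name.upper() not in AMINO_ACIDS:
            continue
        ca = ca_by_residue.get(key)
        broken = (
            current is None
            or chain != prev_chain
            or (ca is not None and prev_ca is not None
                and float(np.linalg.norm(ca - prev_ca)) > break_distance)
        )
        if broken:
            current = Segment(chain_id=chain)
            segments.append(current)
        current.residues.append(key)
        prev_ca = ca if ca is not None else prev_ca
        prev_chain = chain
    for seg in segments:
        seg.has_oxt = seg.c_terminal in oxt_residues
    return segments


def detect_termini(model: StructureModel,
                   break_distance: float = CHAIN_BREAK_CA_DISTANCE
                   ) -> list[Segment]:
    """Split each chain into continuous segments and flag their termini.

    A CA-CA step longer than ``break_distance`` starts a new segment; each
    segment has its own N and C terminus.  ``has_oxt`` records whether the
    C-terminal residue carries the carboxylate OXT atom.
    """
    return _segments(model, break_distance)


def peptide_planarity(model: StructureModel,
                      break_distance: float = CHAIN_BREAK_CA_DISTANCE
                      ) -> list[RestraintRecord]:
    """One FLAT restraint per peptide link within each segment.

    The plane covers CA(i), C(i), O(i), N(i+1), CA(i+1).  Atom names carry
    the residue-number suffix used by SHELX for explicit references.
    """
    records = []
    for seg in _segments(model, break_distance):
        for prev, nxt in zip(seg.residues, seg.residues[1:]):
            names = (f"CA_{prev[1]}", f"C_{prev[1]}", f"O_{prev[1]}",
                     f"N_{nxt[1]}", f"CA_{nxt[1]}")
            records.append(RestraintRecord("FLAT", None, _FLAT_ESD, names))
    return records


def hfix_for_residue(res_name: str,
                     present_atoms: set[str] | None = None,
                     n_terminal: bool = False,
                     suppress: set[str] = frozenset()) -> list[HfixRule]:
    """HFIX rules for a residue type, adapted to the atoms actually present.

    Rules are returned commented (``REM HFIX_<res> <code> <atoms>``).
    Parent atoms missing from ``present_atoms`` move to one active
    ``HFIX 0`` rule.  ``n_terminal`` swaps the backbone amide code (43) for
    the ammonium code (33); ``suppress`` drops parents entirely (e.g. the
    SG of a bridged cysteine).
    """
    name = res_name.strip().upper()
    rules_raw = _hfix_library().get(name)
    if not rules_raw:
        return []
    rules: list[HfixRule] = []
    missing: list[str] = []
    for code, parents in rules_raw:
        kept = []
        for parent in parents:
            if parent in suppress:
                continue
            if present_atoms is not None and parent not in present_atoms:
                missing.append(parent)
                continue
            kept.append(parent)
        if not kept:
            continue
        if n_terminal and code == 43 and "N" in kept:
            others = tuple(p for p in kept if p != "N")
            rules.append(HfixRule(name, 33, ("N",)))
            if others:
                rules.append(HfixRule(name, 43, others))
        else:
            rules.append(HfixRule(name, code, tuple(kept)))
    if missing:
        rules.append(HfixRule(name, 0, tuple(missing), commented=False))
    return rules
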