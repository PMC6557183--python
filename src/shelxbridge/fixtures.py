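"""Synthetic test crystals: tiny peptides with matching reflection loops.

The generator builds an extended-conformation polypeptide with ideal
bond lengths and angles taken from the embedded restraint library, places
it in a given cell and space group, adds a terminal carboxylate oxygen and
a few waters, and fabricates an mmCIF ``_refln`` loop of random reflections
with positive intensities, uncertainties and a chosen free-R fraction.
Defect injections reproduce, one per tag, the real-world deposit problems
the converter must diagnose.  Generation is seeded and byte-reproducible.

Side chains are placed algorithmically from the residue bond graph
(ideal lengths, library angles, deterministic staggered torsions), which is
chemically sensible for open chains but leaves closed rings (Pro, His,
Phe, ...) only approximately closed; the fixtures exercise bookkeeping and
formats, not side-chain geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import UnknownDefectError
from .geometry import UnitCell
from .stereochemistry import residue_library, _angle_target
from .structure import AtomRecord, StructureModel, write_pdb

__all__ = ["FixtureSpec", "generate_fixture", "build_polypeptide", "DEFECTS"]

DEFECTS = ("digit_residue_name", "element_x", "extra_model",
           "missing_sigma", "oversized_index")

ONE_TO_THREE = {
    "G": "GLY", "A": "ALA", "V": "VAL", "L": "LEU", "I": "ILE", "P": "PRO",
    "F": "PHE", "Y": "TYR", "W": "TRP", "S": "SER", "T": "THR", "C": "CYS",
    "M": "MET", "N": "ASN", "Q": "GLN", "D": "ASP", "E": "GLU", "K": "LYS",
    "R": "ARG", "H": "HIS",
}


@dataclass
class FixtureSpec:
    """Recipe for one synthetic crystal."""

    sequence: str
    space_group: str = "P 1"
    cell: tuple = (30.0, 24.0, 20.0, 90.0, 90.0, 90.0)
    wavelength: float = 1.54184
    n_reflections: int = 200
    free_fraction: float = 0.05
    seed: int = 0
    defects: tuple = ()
    n_waters: int = 4
    d_min: float = 1.8

    def __post_init__(self) -> None:
        for defect in self.defects:
            if defect not in DEFECTS:
                raise UnknownDefectError(f"unknown defect tag {defect!r}")
        if not 0.0 <= self.free_fraction < 1.0:
            raise ValueError("free_fraction must be in [0, 1)")


def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Natural-extension (NeRF) placement of atom d bonded to c."""
    theta = math.radians(angle_deg)
    chi = math.radians(torsion_deg)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(chi),
        bond * math.sin(theta) * math.sin(chi),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-9:  # collinear reference; pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        norm = np.linalg.norm(n)
    n /= norm
    m = np.column_stack([bc, np.cross(n, bc), n])
    return c + m @ d_local


def _sidechain_tree(entry: dict) -> list[tuple[str, str]]:
    """(child, parent) pairs, BFS from CA over the residue bond graph."""
    neighbours: dict[str, list[str]] = {}
    for a1, a2, _t, _e in entry["bonds"]:
        neighbours.setdefault(a1, []).append(a2)
        neighbours.setdefault(a2, []).append(a1)
    backbone = {"N", "CA", "C", "O", "OXT"}
    order: list[tuple[str, str]] = []
    seen = set(backbone)
    queue = ["CA", "N", "C"]
    while queue:
        parent = queue.pop(0)
        for child in neighbours.get(parent, []):
            if child in seen:
                continue
            seen.add(child)
            order.append((child, parent))
            queue.append(child)
    return order


def _bond_length(entry: dict, a1: str, a2: str) -> float:
    for b1, b2, target, _e in entry["bonds"]:
        if {b1, b2} == {a1, a2}:
            return target
    return 1.53


_BRANCH_TORSIONS = (180.0, -60.0, 60.0, 0.0, 120.0, -120.0)


def build_polypeptide(sequence: str) -> list[AtomRecord]:
    """Extended-conformation peptide in Cartesian space, chain A, residue 1..n.

    Backbone torsions are all-trans (phi = psi = omega = 180 degrees); the
    final residue carries OXT.
    """
    lib = residue_library()
    atoms: list[AtomRecord] = []
    coords: dict[tuple[int, str], np.ndarray] = {}

    def add(i_res: int, res_name: str, name: str, pos: np.ndarray,
            element: str | None = None) -> None:
        coords[(i_res, name)] = pos
        el = element or ("S" if name.startswith("S") else name[0])
        atoms.append(AtomRecord(name=name, res_name=res_name, chain_id="A",
                                res_seq=i_res, xyz_cart=pos,
                                occupancy=1.0, b_iso=15.0, element=el))

    prev_c = prev_ca = prev_n = None
    for i, letter in enumerate(sequence.upper(), start=1):
        res_name = ONE_TO_THREE.get(letter)
        if res_name is None:
            raise ValueError(f"unknown one-letter residue code {letter!r}")
        entry = lib[res_name]
        if prev_c is None:
            n = np.array([0.0, 0.0, 0.0])
            ca = n + np.array([1.458, 0.0, 0.0])
            c = _place(n + np.array([0.0, 1.0, 0.0]), n, ca,
                       1.525, 111.2, 180.0)
        else:
            n = _place(prev_n, prev_ca, prev_c, 1.329, 116.2, 180.0)
            ca = _place(prev_ca, prev_c, n, 1.458, 121.7, 180.0)
            c = _place(prev_c, n, ca, 1.525, 111.2, 180.0)
        add(i, res_name, "N", n)
        add(i, res_name, "CA", ca)
        add(i, res_name, "C", c)
        o = _place(n, ca, c, 1.231, 120.8, 0.0)
        add(i, res_name, "O", o)
        if i == len(sequence):
            oxt = _place(n, ca, c, 1.249, 117.0, 180.0)
            add(i, res_name, "OXT", oxt)

        # side chain, staggered torsions per branch
        branch_count: dict[str, int] = {}
        tree_parent: dict[str, str] = {"CA": "N", "N": "CA", "C": "CA"}
        for child, parent in _sidechain_tree(entry):
            tree_parent[child] = parent
            grand = tree_parent.get(parent, "N")
            great = tree_parent.get(grand)
            if great in (None, parent):
                great = "C" if "C" not in (grand, parent) else "O"
            b_pos = coords.get((i, grand))
            a_pos = coords.get((i, great))
            idx = branch_count.get(parent, 0)
            branch_count[parent] = idx + 1
            # substituents on the peptide N must dodge the preceding C
            torsions = (75.0, -75.0) if parent == "N" else _BRANCH_TORSIONS
            torsion = torsions[idx % len(torsions)]
            angle = _angle_target(entry, grand, parent, child)
            pos = _place(a_pos, b_pos, coords[(i, parent)],
                         _bond_length(entry, parent, child), angle, torsion)
            add(i, res_name, child, pos)
        prev_n, prev_ca, prev_c = n, ca, c
    return atoms


def _water_positions(n: int, origin: np.ndarray, rng) -> list[np.ndarray]:
    out = []
    for i in range(n):
        jitter = rng.uniform(-0.3, 0.3, size=3)
        out.append(origin + np.array([2.8 * (i % 2), 2.8 * ((i // 2) % 2),
                                      2.8 * (i // 4)]) + jitter)
    return out


def _reflection_loop(spec: FixtureSpec, cell: UnitCell, rng,
                     drop_sigma: bool, oversized: bool) -> str:
    h_max = int(cell.a / spec.d_min)
    k_max = int(cell.b / spec.d_min)
    l_max = int(cell.c / spec.d_min)
    chosen: dict[tuple, None] = {}
    while len(chosen) < spec.n_reflections:
        h = int(rng.integers(-h_max, h_max + 1))
        k = int(rng.integers(-k_max, k_max + 1))
        l = int(rng.integers(0, l_max + 1))
        if (h, k, l) == (0, 0, 0) or (h, k, l) in chosen:
            continue
        if cell.d_spacing((h, k, l)) < spec.d_min:
            continue
        chosen[(h, k, l)] = None
    hkls = list(chosen)
    n_free = int(round(spec.free_fraction * len(hkls)))
    free_idx = set(rng.choice(len(hkls), size=n_free, replace=False).tolist()
                   ) if n_free else set()
    tags = ["_refln.index_h", "_refln.index_k", "_refln.index_l",
            "_refln.intensity_meas"]
    if not drop_sigma:
        tags.append("_refln.intensity_sigma")
    tags.append("_refln.status")
    lines = ["data_synthetic_fixture", "#", "loop_"] + tags
    for idx, (h, k, l) in enumerate(hkls):
        if oversized and idx == 0:
            h = 1000
        intensity = float(np.exp(rng.normal(4.0, 1.2)))
        sigma = 0.05 * intensity + 1.0
        status = "f" if idx in free_idx else "o"
        row = f"{h} {k} {l} {intensity:.2f}"
        if not drop_sigma:
            row += f" {sigma:.2f}"
        row += f" {status}"
        lines.append(row)
    return "\n".join(lines) + "\n"


def generate_fixture(spec: FixtureSpec) -> tuple[str, str]:
    """Build (PDB text, reflection mmCIF text) for a fixture spec."""
    rng = np.random.default_rng(spec.seed)
    cell = UnitCell(*spec.cell, wavelength=spec.wavelength)
    atoms = build_polypeptide(spec.sequence)
    offset = np.array([5.0, 5.0, 5.0])
    for atom in atoms:
        atom.xyz_cart = atom.xyz_cart + offset
        atom.b_iso = float(15.0 + rng.uniform(-3.0, 3.0))
    peptide_max = np.max([a.xyz_cart for a in atoms], axis=0)
    for i, pos in enumerate(_water_positions(
            spec.n_waters, peptide_max + np.array([3.0, -2.0, 1.0]), rng)):
        atoms.append(AtomRecord(name="O", res_name="HOH", chain_id="A",
                                res_seq=101 + i, xyz_cart=pos, occupancy=1.0,
                                b_iso=float(25.0 + rng.uniform(-5.0, 5.0)),
                                element="O", is_hetatm=True))

    if "digit_residue_name" in spec.defects:
        last = atoms[-1]
        for atom in atoms:
            if atom.residue_key == last.residue_key:
                atom.res_name = "123"
    if "element_x" in spec.defects:
        atoms[-1].element = "X"

    model = StructureModel(atoms=atoms, cell=cell,
                           space_group_symbol=spec.space_group,
                           z_value=1, title="synthetic fixture")
    pdb_text = write_pdb(model)

    if "extra_model" in spec.defects:
        head, _, tail = pdb_text.partition("ATOM")
        body = ("ATOM" + tail).replace("END\n", "")
        pdb_text = (head + "MODEL        1\n" + body + "ENDMDL\n"
                    + "MODEL        2\n" + body + "ENDMDL\nEND\n")

    cif_text = _reflection_loop(
        spec, cell, rng,
        drop_sigma="missing_sigma" in spec.defects,
        oversized="oversized_index" in spec.defects)
    return pdb_text, cif_text
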