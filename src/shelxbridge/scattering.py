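"""Element bookkeeping (SFAC/UNIT) and anomalous-dispersion (DISP) cards.

SHELX stores scattering factors for the first 98 elements only; anything
else in the input is a hard error (deposited files occasionally carry the
placeholder element 'X').  DISP cards supply the wavelength-dependent
anomalous corrections f', f'' and the absorption coefficient mu for the
heavier elements; wavelengths below 0.1 Angstrom signal electron
diffraction, for which no X-ray dispersion applies.

The dispersion values come from an embedded per-element grid of
(wavelength, f', f'', mu) nodes covering 0.2-3.0 Angstrom, interpolated
between nodes (linearly in log-wavelength for the signed f', log-log for
f'' and mu).  The grid is a synthetic tabulation: indicative magnitudes
with the correct qualitative behaviour near absorption edges, intended for
card generation and easily overridden by hand-edited SFAC/DISP cards.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

from .cards import Card
from .errors import NoTabulationError, UnknownElementError
from .structure import StructureModel

__all__ = [
    "ELEMENTS", "DispersionEntry", "validate_element", "atomic_number",
    "build_sfac", "dispersion_for", "classify_radiation", "emit_disp_cards",
    "snap_wavelength", "ELECTRON_WAVELENGTH_LIMIT", "ANODE_WAVELENGTHS",
]

#: The first 98 elements (H..Cf), index + 1 = atomic number.
ELEMENTS = (
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd",
    "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb",
    "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn", "Fr", "Ra", "Ac", "Th",
    "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk", "Cf",
)

_Z = {sym.upper(): i + 1 for i, sym in enumerate(ELEMENTS)}

#: Below this wavelength (Angstrom) the data are electron diffraction.
ELECTRON_WAVELENGTH_LIMIT = 0.1

#: Common in-house anode Kalpha wavelengths (Angstrom), snapped on input.
ANODE_WAVELENGTHS = {
    "Cu": 1.54184, "Mo": 0.71073, "Ag": 0.56087, "Ga": 1.34139, "In": 0.51360,
}

_SNAP_TOL = 0.0005

#: Elements light enough that SHELX's internal defaults suffice; DISP cards
#: are emitted only for elements heavier than oxygen.
_LIGHT_DEFAULT_Z = 8


@dataclass(frozen=True)
class DispersionEntry:
    """Anomalous corrections for one element at one wavelength."""

    element: str
    wavelength: float
    f_prime: float
    f_double_prime: float
    mu: float  # mass absorption coefficient, cm^2/g


def validate_element(symbol: str) -> str:
    """Return the canonical symbol, or raise for anything beyond element 98."""
    sym = symbol.strip()
    if not sym:
        raise UnknownElementError("empty element symbol")
    z = _Z.get(sym.upper())
    if z is None:
        raise UnknownElementError(
            f"element {symbol!r} is not among the first 98 elements")
    return ELEMENTS[z - 1]


def atomic_number(symbol: str) -> int:
    return _Z[validate_element(symbol).upper()]


def build_sfac(model: StructureModel, n_operators: int = 1,
               centering_multiplicity: int = 1) -> tuple[Card, Card]:
    """SFAC and UNIT cards for a structure.

    SFAC lists the distinct elements, carbon first when present, then
    nitrogen and oxygen, then the rest in order of first appearance (the
    customary SHELX ordering for organic and biological structures).  UNIT
    gives per-cell atom counts: occupancy-summed asymmetric-unit contents
    multiplied by the symmetry-operator count and centering multiplicity.
    """
    counts: dict[str, float] = {}
    order: list[str] = []
    for atom in model.atoms:
        el = validate_element(atom.element)
        if el not in counts:
            counts[el] = 0.0
            order.append(el)
        counts[el] += atom.occupancy
    elements = [el for el in ("C", "N", "O") if el in counts]
    elements += [el for el in order if el not in ("C", "N", "O")]
    mult = n_operators * centering_multiplicity
    unit = [counts[el] * mult for el in elements]
    sfac_card = Card("SFAC", " ".join(elements))
    unit_card = Card("UNIT", " ".join(str(int(round(v))) for v in unit))
    return sfac_card, unit_card


def classify_radiation(wavelength: float) -> str:
    """'electron' for wavelengths strictly below 0.1 Angstrom, else 'xray'."""
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    return "electron" if wavelength < ELECTRON_WAVELENGTH_LIMIT else "xray"


def snap_wavelength(wavelength: float) -> float:
    """Snap to the nearest in-house anode Kalpha line when within 0.0005 A."""
    for lam in ANODE_WAVELENGTHS.values():
        if abs(wavelength - lam) < _SNAP_TOL:
            return lam
    return wavelength


def _load_grid() -> dict[str, list[list[float]]]:
    text = resources.files("shelxbridge.data").joinpath(
        "dispersion_synthetic.json").read_text()
    return json.loads(text)


_GRID: dict[str, list[list[float]]] | None = None


def dispersion_for(element: str, wavelength: float) -> DispersionEntry:
    """Interpolate f', f'' and mu for an element at an X-ray wavelength.

    f' is interpolated linearly in log-wavelength (it changes sign near
    edges); f'' and mu, both strictly positive, are interpolated log-log.
    Exactly at a grid node the tabulated values are returned unchanged.
    """
    global _GRID
    if _GRID is None:
        _GRID = _load_grid()
    el = validate_element(element)
    if wavelength <= ELECTRON_WAVELENGTH_LIMIT:
        raise ValueError("dispersion corrections apply to X-ray data only")
    nodes = _GRID.get(el)
    if nodes is None:
        raise NoTabulationError(f"no dispersion tabulation for element {el}")
    lams = [n[0] for n in nodes]
    if not lams[0] <= wavelength <= lams[-1]:
        raise NoTabulationError(
            f"wavelength {wavelength} A outside the tabulated range "
            f"[{lams[0]}, {lams[-1]}] for {el}")
    for i, lam in enumerate(lams):
        if abs(lam - wavelength) < 1e-9:
            _, fp, fpp, mu = nodes[i]
            return DispersionEntry(el, wavelength, fp, fpp, mu)
    hi = next(i for i, lam in enumerate(lams) if lam > wavelength)
    lo = hi - 1
    x0, x1 = math.log(lams[lo]), math.log(lams[hi])
    w = (math.log(wavelength) - x0) / (x1 - x0)

    def lin(a: float, b: float) -> float:
        return a + w * (b - a)

    def loglog(a: float, b: float) -> float:
        return math.exp(lin(math.log(a), math.log(b)))

    fp = lin(nodes[lo][1], nodes[hi][1])
    fpp = loglog(max(nodes[lo][2], 1e-6), max(nodes[hi][2], 1e-6))
    mu = loglog(max(nodes[lo][3], 1e-6), max(nodes[hi][3], 1e-6))
    return DispersionEntry(el, wavelength, fp, fpp, mu)


def emit_disp_cards(elements: list[str], wavelength: float | None) -> list[Card]:
    """DISP cards for the heavy elements of a structure.

    Emitted only when a wavelength is known and the radiation is X-ray;
    elements up to oxygen rely on SHELX's internal defaults.
    """
    if wavelength is None or classify_radiation(wavelength) == "electron":
        return []
    lam = snap_wavelength(wavelength)
    cards = []
    for el in elements:
        if atomic_number(el) <= _LIGHT_DEFAULT_Z:
            continue
        entry = dispersion_for(el, lam)
        cards.append(Card("DISP", f"{el} {entry.f_prime:.3f} "
                                  f"{entry.f_double_prime:.3f} {entry.mu:.1f}"))
    return cards
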