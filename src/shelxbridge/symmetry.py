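"""Space-group handling for chiral macromolecular crystals.

SHELX defines symmetry by the coordinates of the general position (LATT and
SYMM cards) rather than by the space-group name, which also accommodates
non-standard settings.  This module keeps a dictionary of symmetry
*generators* for every Sohncke space-group symbol (the 65 groups containing
only proper rotations, the only ones accessible to chiral molecules), expands
them to the full operator set by iterative multiplication, and renders the
LATT/SYMM card block.

Operators are exact: integer rotation matrices and rational translations,
so group-theoretic comparisons need no tolerance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from typing import Iterable, Sequence

from .cards import Card
from .errors import CentrosymmetricError, DivergenceError, UnknownSpaceGroupError

__all__ = [
    "SymOp",
    "SpaceGroupSetting",
    "lookup_space_group",
    "expand_generators",
    "emit_symmetry_cards",
    "parse_triplet",
    "CENTERING_VECTORS",
    "LATT_CODES",
    "available_symbols",
]

# LATT magnitude by centering letter; sign is negative for the
# non-centrosymmetric groups handled here.
LATT_CODES = {"P": 1, "I": 2, "R": 3, "F": 4, "A": 5, "B": 6, "C": 7}

_HALF = Fraction(1, 2)
_THIRD = Fraction(1, 3)

#: Pure lattice translations implied by each LATT magnitude (excluding zero).
CENTERING_VECTORS: dict[int, tuple[tuple[Fraction, Fraction, Fraction], ...]] = {
    1: (),
    2: ((_HALF, _HALF, _HALF),),
    3: ((2 * _THIRD, _THIRD, _THIRD), (_THIRD, 2 * _THIRD, 2 * _THIRD)),
    4: ((0, _HALF, _HALF), (_HALF, 0, _HALF), (_HALF, _HALF, 0)),
    5: ((0, _HALF, _HALF),),
    6: ((_HALF, 0, _HALF),),
    7: ((_HALF, _HALF, 0),),
}

_AXES = "XYZ"


@dataclass(frozen=True)
class SymOp:
    """A symmetry operation on fractional coordinates: x' = R x + t."""

    rotation: tuple[tuple[int, ...], ...]
    translation: tuple[Fraction, Fraction, Fraction]

    @classmethod
    def identity(cls) -> "SymOp":
        return cls(((1, 0, 0), (0, 1, 0), (0, 0, 1)),
                   (Fraction(0), Fraction(0), Fraction(0)))

    @property
    def is_identity(self) -> bool:
        return self == SymOp.identity()

    @property
    def is_pure_translation(self) -> bool:
        return self.rotation == ((1, 0, 0), (0, 1, 0), (0, 0, 1))

    def determinant(self) -> int:
        (a, b, c), (d, e, f), (g, h, i) = self.rotation
        return a * (e * i - f * h) - b * (d * i - f * g) + c * (d * h - e * g)

    def compose(self, other: "SymOp") -> "SymOp":
        """Composition applying ``other`` first; translations reduced mod 1."""
        r1, r2 = self.rotation, other.rotation
        rot = tuple(
            tuple(sum(r1[i][k] * r2[k][j] for k in range(3)) for j in range(3))
            for i in range(3)
        )
        tra = tuple(
            (sum(r1[i][k] * other.translation[k] for k in range(3))
             + self.translation[i]) % 1
            for i in range(3)
        )
        return SymOp(rot, tra)  # type: ignore[arg-type]

    def __mul__(self, other: "SymOp") -> "SymOp":
        return self.compose(other)

    def inverse(self) -> "SymOp":
        det = self.determinant()
        if det not in (1, -1):
            raise ValueError("rotation is not unimodular")
        (a, b, c), (d, e, f), (g, h, i) = self.rotation
        adj = ((e * i - f * h, c * h - b * i, b * f - c * e),
               (f * g - d * i, a * i - c * g, c * d - a * f),
               (d * h - e * g, b * g - a * h, a * e - b * d))
        rinv = tuple(tuple(v * det for v in row) for row in adj)
        tinv = tuple(
            (-sum(rinv[i][k] * self.translation[k] for k in range(3))) % 1
            for i in range(3)
        )
        return SymOp(rinv, tinv)  # type: ignore[arg-type]

    def apply(self, frac: Sequence[float]) -> tuple[float, float, float]:
        return tuple(
            sum(self.rotation[i][k] * frac[k] for k in range(3))
            + float(self.translation[i])
            for i in range(3)
        )  # type: ignore[return-value]

    def reduced_mod(self, centering: Iterable[tuple[Fraction, ...]]) -> "SymOp":
        """Canonical coset representative modulo centering translations."""
        best = None
        for cen in ((Fraction(0),) * 3, *centering):
            t = tuple((self.translation[i] - cen[i]) % 1 for i in range(3))
            if best is None or t < best:
                best = t
        return SymOp(self.rotation, best)  # type: ignore[arg-type]

    # -- text form ---------------------------------------------------------

    def triplet(self) -> str:
        """SHELX-style triplet: terms ordered X, Y, Z, translation last."""
        parts = []
        for i in range(3):
            terms = ""
            for j in range(3):
                coeff = self.rotation[i][j]
                if coeff == 0:
                    continue
                sign = "-" if coeff < 0 else ("+" if terms else "")
                mag = abs(coeff)
                terms += f"{sign}{'' if mag == 1 else mag}{_AXES[j]}"
            t = self.translation[i]
            if t:
                terms += f"+{t.numerator}/{t.denominator}" if terms else \
                    f"{t.numerator}/{t.denominator}"
            parts.append(terms or "0")
        return ", ".join(parts)


_TERM_RE = re.compile(
    r"\s*([+-]?)\s*(?:(\d+(?:\.\d+)?)\s*(?:/\s*(\d+))?\s*\*?\s*)?([XYZ])?",
    re.IGNORECASE,
)


def parse_triplet(text: str) -> SymOp:
    """Parse ``-Y, X-Y+1/2, Z`` (or ``0.5-x`` style) into a SymOp."""
    rows = text.split(",")
    if len(rows) != 3:
        raise ValueError(f"expected three components: {text!r}")
    rot = [[0, 0, 0] for _ in range(3)]
    tra = [Fraction(0)] * 3
    for i, row in enumerate(rows):
        pos = 0
        row = row.strip()
        while pos < len(row):
            m = _TERM_RE.match(row, pos)
            if not m or m.end() == pos:
                raise ValueError(f"cannot parse {row!r} at {pos}")
            sign = -1 if m.group(1) == "-" else 1
            num, den, axis = m.group(2), m.group(3), m.group(4)
            if axis:
                coeff = 1 if num is None else int(float(num))
                rot[i]["XYZ".index(axis.upper())] += sign * coeff
            elif num is not None:
                if den:
                    tra[i] += sign * Fraction(int(float(num)), int(den))
                else:
                    tra[i] += sign * Fraction(num)
            pos = m.end()
        tra[i] %= 1
    return SymOp(tuple(tuple(r) for r in rot), tuple(tra))  # type: ignore[arg-type]


@dataclass
class SpaceGroupSetting:
    """A Sohncke space group in a definite setting."""

    symbol: str
    latt_code: int  # magnitude of the LATT card argument
    generators: list[SymOp] = field(default_factory=list)
    operators: list[SymOp] = field(default_factory=list)
    centrosymmetric: bool = False

    @property
    def centering_vectors(self):
        return CENTERING_VECTORS[self.latt_code]

    @property
    def centering_multiplicity(self) -> int:
        return len(self.centering_vectors) + 1

    @property
    def multiplicity(self) -> int:
        """General-position multiplicity (operators x centering)."""
        return len(self.operators) * self.centering_multiplicity


def _normalize(symbol: str) -> tuple[str, str]:
    """Return (key, axes-suffix) for a Hermann-Mauguin spelling."""
    s = symbol.strip().upper()
    suffix = ""
    for tag in (":R", ":H"):
        if s.endswith(tag):
            suffix = tag
            s = s[: -len(tag)].strip()
    return s.replace(" ", ""), suffix


def _load_table() -> dict[str, tuple[int, tuple[str, ...]]]:
    table: dict[str, tuple[int, tuple[str, ...]]] = {}
    text = resources.files("shelxbridge.data").joinpath(
        "sohncke_generators.txt").read_text()
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        symbol, latt, gens, _order = line.split("|")
        key, suffix = _normalize(symbol)
        gen_list = tuple(g for g in gens.split(";") if g)
        table[key + suffix] = (int(latt), gen_list)
    return table


_TABLE = _load_table()

# Aliases: short monoclinic symbols, and the PDB's "H" spelling for the
# hexagonal setting of rhombohedral groups.
_ALIASES = {
    "P2": "P121", "P21": "P1211", "C2": "C121", "A2": "A121",
    "I2": "I121", "I21": "I1211", "B2": "B112",
    "H3": "R3", "H32": "R32",
}

_IMPROPER_HINT = re.compile(r"(-|/|(?<=.)[MCDNABE](?![A-Z0-9]))")


def available_symbols() -> list[str]:
    """All normalized symbols in the generator dictionary."""
    return sorted(_TABLE)


def lookup_space_group(symbol: str) -> SpaceGroupSetting:
    """Resolve a Hermann-Mauguin symbol to generators and lattice type.

    ``:R`` selects the primitive rhombohedral setting of the R groups; the
    default (or ``:H``) is the hexagonal setting.  Case and spacing are
    ignored except that they disambiguate nothing here: space-stripped
    Sohncke symbols are unique.
    """
    key, suffix = _normalize(symbol)
    key = _ALIASES.get(key, key)
    if suffix == ":H":
        suffix = ""  # hexagonal is the stored default for R groups
    full = key + suffix
    if full not in _TABLE:
        if suffix == ":R" and key in _TABLE:
            raise UnknownSpaceGroupError(
                f"no rhombohedral setting stored for {symbol!r}")
        if _IMPROPER_HINT.search(key):
            raise CentrosymmetricError(
                f"{symbol!r} implies improper symmetry (inversion, mirror or "
                f"glide); chiral macromolecules require a Sohncke group")
        raise UnknownSpaceGroupError(f"unrecognized space-group symbol {symbol!r}")
    latt, gen_triplets = _TABLE[full]
    generators = [parse_triplet(t) for t in gen_triplets]
    setting = SpaceGroupSetting(symbol=symbol.strip(), latt_code=latt,
                                generators=generators)
    setting.operators = expand_generators(
        generators, centering=CENTERING_VECTORS[latt])
    return setting


def expand_generators(
    generators: Sequence[SymOp],
    centering: Iterable[tuple[Fraction, ...]] = (),
    limit: int = 192,
) -> list[SymOp]:
    """Closure of {identity} and the generators under composition.

    Breadth-first over generator products, translations reduced mod 1 and
    modulo the lattice-centering translations, duplicates removed by exact
    rational comparison.  The identity comes first and the order is
    deterministic.
    """
    centering = tuple(tuple(c) for c in centering)
    ident = SymOp.identity()
    seen: dict[SymOp, None] = {ident: None}
    frontier = [ident]
    while frontier:
        nxt = []
        for op in frontier:
            for gen in generators:
                prod = op.compose(gen).reduced_mod(centering)
                if prod not in seen:
                    seen[prod] = None
                    nxt.append(prod)
        frontier = nxt
        if len(seen) > limit:
            raise DivergenceError(
                f"generator closure exceeded {limit} operators")
    return list(seen)


def emit_symmetry_cards(setting: SpaceGroupSetting) -> list[Card]:
    """LATT card plus one SYMM card per non-identity operator.

    The LATT argument is negative (non-centrosymmetric) with magnitude equal
    to the centering code.  The identity and pure centering translations are
    implied by LATT and never written as SYMM.
    """
    cards = [Card("LATT", str(-setting.latt_code))]
    for op in setting.operators:
        if op.is_identity or op.is_pure_translation:
            continue
        cards.append(Card("SYMM", op.triplet()))
    return cards
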