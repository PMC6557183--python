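"""Unit-cell geometry: orthogonalization and displacement-parameter transforms.

The PDB stores Cartesian coordinates (under the convention a along x, b in
the x-y plane) and Cartesian anisotropic U tensors; SHELX refines fractional
coordinates and U_ij in the crystallographic (CIF) convention.  This module
owns those basis changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import NegativeBError, SingularCellError

__all__ = ["UnitCell", "b_to_u", "u_to_b", "EIGHT_PI_SQ"]

EIGHT_PI_SQ = 8.0 * math.pi ** 2


@dataclass
class UnitCell:
    """Crystallographic unit cell with derived transformation matrices.

    Parameters are lengths in Angstrom and angles in degrees; ``z_value`` is
    the number of chemical formula units per cell and ``wavelength`` the
    radiation wavelength in Angstrom (None when unknown).
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    z_value: int = 1
    wavelength: float | None = None

    _ortho: np.ndarray = field(init=False, repr=False)
    _frac: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise SingularCellError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise SingularCellError("cell angles must lie in (0, 180)")
        ca, cb, cg = (math.cos(math.radians(x))
                      for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        vol_term = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if vol_term <= 1e-12 or abs(sg) < 1e-12:
            raise SingularCellError(
                f"degenerate angle combination "
                f"({self.alpha}, {self.beta}, {self.gamma})")
        v = self.a * self.b * self.c * math.sqrt(vol_term)
        # PDB orthogonalization: a along x, b in the x-y plane.
        self._ortho = np.array([
            [self.a, self.b * cg, self.c * cb],
            [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
            [0.0, 0.0, v / (self.a * self.b * sg)],
        ])
        self._frac = np.linalg.inv(self._ortho)
        self._volume = v

    @property
    def volume(self) -> float:
        """Cell volume in cubic Angstrom."""
        return self._volume

    @property
    def ortho_matrix(self) -> np.ndarray:
        """M such that x_cart = M x_frac."""
        return self._ortho.copy()

    @property
    def frac_matrix(self) -> np.ndarray:
        """M^-1, mapping Cartesian to fractional."""
        return self._frac.copy()

    @property
    def recip_lengths(self) -> np.ndarray:
        """Reciprocal axis lengths a*, b*, c* in 1/Angstrom."""
        g_inv = self._frac @ self._frac.T
        return np.sqrt(np.diag(g_inv))

    @property
    def parameters(self) -> tuple[float, ...]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    # -- coordinate transforms --------------------------------------------

    def cart_to_frac(self, xyz_cart) -> np.ndarray:
        return self._frac @ np.asarray(xyz_cart, dtype=float)

    def frac_to_cart(self, xyz_frac) -> np.ndarray:
        return self._ortho @ np.asarray(xyz_frac, dtype=float)

    def d_spacing(self, hkl) -> float:
        """Resolution of a reflection in Angstrom."""
        s = self._frac.T @ np.asarray(hkl, dtype=float)
        return 1.0 / float(np.linalg.norm(s))

    # -- displacement parameters ------------------------------------------

    def adp_cart_to_cif(self, u_cart) -> tuple[float, ...]:
        """Cartesian U tensor -> (U11, U22, U33, U23, U13, U12), CIF convention.

        U* = M^-1 U_cart M^-T, then U_cif(ij) = U*(ij) / (a*_i a*_j).  The
        transform preserves the equivalent isotropic U and positive
        definiteness; non-positive-definite input passes through unchanged in
        character (flagging is a downstream concern).
        """
        u = np.asarray(u_cart, dtype=float)
        if u.shape != (3, 3) or not np.allclose(u, u.T, atol=1e-8):
            raise ValueError("u_cart must be a symmetric 3x3 tensor")
        u_star = self._frac @ u @ self._frac.T
        rl = self.recip_lengths
        u_cif = u_star / np.outer(rl, rl)
        return (u_cif[0, 0], u_cif[1, 1], u_cif[2, 2],
                u_cif[1, 2], u_cif[0, 2], u_cif[0, 1])

    def adp_cif_to_cart(self, u6) -> np.ndarray:
        """Inverse of :meth:`adp_cart_to_cif` (testing and round-trips)."""
        u11, u22, u33, u23, u13, u12 = u6
        u_cif = np.array([[u11, u12, u13], [u12, u22, u23], [u13, u23, u33]])
        rl = self.recip_lengths
        u_star = u_cif * np.outer(rl, rl)
        return self._ortho @ u_star @ self._ortho.T

    def u_eq_cif(self, u6) -> float:
        """Equivalent isotropic U from CIF-convention components."""
        return float(np.trace(self.adp_cif_to_cart(u6))) / 3.0


def b_to_u(b_iso: float) -> float:
    """Isotropic B (A^2) to isotropic U (A^2): U = B / (8 pi^2)."""
    if b_iso < 0:
        raise NegativeBError(f"negative isotropic B: {b_iso}")
    return b_iso / EIGHT_PI_SQ


def u_to_b(u_iso: float) -> float:
    return u_iso * EIGHT_PI_SQ
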