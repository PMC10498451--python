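"""Buckled Euler elastica: exact force law and its series expansion.

A membrane strip buckled along x at fixed strain ``lam = (L0 - Lx)/L0``
(arc length L0, projected length Lx) behaves, per unit length in y, as a
planar Euler elastica with periodic boundary conditions.  Using the pendulum
first integral, the shape is parameterized by an elliptic modulus m with

    lam = 2 * (1 - E(m)/K(m))           (strain)
    f   = k_C * (4 K(m) / L0)^2          (restoring force per unit length)

where K and E are the complete elliptic integrals of the first and second
kind.  We report the dimensionless force

    f_hat(lam) = F_x * L0^2 / (4 pi^2 * k_C * L_y) = (2 K(m) / pi)^2,

which equals 1 at the Euler buckling threshold (lam -> 0) and grows
monotonically with strain.  Its Taylor coefficients in lam, derived exactly
by series reversion of the elliptic relations, are the ``b_i`` used by the
series form of the buckling estimator; the leading terms are
1, 1/2, 9/32, 21/128, 795/8192, 945/16384, ...
"""
from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy.optimize import brentq
from scipy.special import ellipe, ellipk

__all__ = ["BUCKLING_B_EXACT", "BUCKLING_B", "elastica_reference", "series_force"]

#: Exact rational Taylor coefficients of f_hat(lam) through order 10.
BUCKLING_B_EXACT: tuple[Fraction, ...] = (
    Fraction(1),
    Fraction(1, 2),
    Fraction(9, 32),
    Fraction(21, 128),
    Fraction(795, 8192),
    Fraction(945, 16384),
    Fraction(2247, 65536),
    Fraction(42639, 2097152),
    Fraction(6446547, 536870912),
    Fraction(7574715, 1073741824),
    Fraction(70769457, 17179869184),
)

BUCKLING_B: np.ndarray = np.array([float(b) for b in BUCKLING_B_EXACT])


def _strain_of_modulus(m: float) -> float:
    return 2.0 * (1.0 - ellipe(m) / ellipk(m))


def elastica_reference(lam: float, tol: float = 1e-13) -> float:
    """Dimensionless buckling force f_hat(lam) from the exact elastica.

    Solves the elliptic strain relation for the modulus by bracketed root
    finding and evaluates ``(2 K(m)/pi)**2``.  Valid for 0 < lam < 0.5;
    this is the series-free oracle used to validate (or replace) the
    truncated ``b_i`` expansion.
    """
    if not 0.0 < lam < 0.5:
        raise ValueError(f"strain must lie in (0, 0.5), got {lam}")
    # lam(m) is monotonically increasing; lam(0)=0, lam(0.99)≈1.4
    m = brentq(lambda mm: _strain_of_modulus(mm) - lam, 1e-15, 0.99, xtol=tol)
    return float((2.0 * ellipk(m) / np.pi) ** 2)


def series_force(lam: float | np.ndarray, b: np.ndarray | None = None) -> float | np.ndarray:
    """Truncated series f_hat(lam) = sum_i b_i lam^i (default: exact b_i to i=10)."""
    if b is None:
        b = BUCKLING_B
    lam = np.asarray(lam, dtype=float)
    out = np.polynomial.polynomial.polyval(lam, np.asarray(b, dtype=float))
    return float(out) if out.ndim == 0 else out
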