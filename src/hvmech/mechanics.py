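"""Elastic-moduli estimators for flat coarse-grained membranes.

Three moduli are estimated from independent observables:

* area compressibility k_A from equilibrium fluctuations of the lateral
  box area,  k_A = k_B T <A> / <(A - <A>)^2>;
* Gaussian curvature modulus kappa_G from the second moment of the lateral
  stress profile tau0(z) = tau_L - tau_N, valid only at zero membrane
  tension (vanishing zeroth moment);
* bending modulus k_C from the force needed to hold a membrane buckled at
  fixed compressive strain, via the elastica series (or the exact elliptic
  oracle), optionally corrected for the thermal undulation force.

A toy Irving-Kirkwood pairwise stress binner is included so the stress-
profile route can be validated end-to-end on analytic pair potentials; it
is not a substitute for force-field local-stress calculations.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import units
from .elastica import BUCKLING_B, elastica_reference, series_force
from .model import Trajectory

__all__ = [
    "AreaSeries",
    "StressProfile",
    "BucklingObservation",
    "BucklingCoefficients",
    "ElasticModuli",
    "KaResult",
    "KcResult",
    "area_compressibility",
    "stress_profile_moments",
    "gaussian_modulus",
    "buckling_force",
    "bending_modulus_buckling",
    "pairwise_stress_profile",
    "CentralPotential",
    "elastic_ratio",
]


@dataclass
class AreaSeries:
    """Instantaneous lateral box areas (nm^2) at temperature T (K)."""

    areas: np.ndarray
    temperature: float

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float).ravel()
        if len(self.areas) < 2:
            raise ValueError("area series needs at least 2 samples")
        if np.any(self.areas <= 0):
            raise ValueError("areas must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class StressProfile:
    """Binned lateral-minus-normal stress tau0(z) = tau_L - tau_N.

    z in nm with the membrane center at 0; tau in kJ mol^-1 nm^-3.
    """

    z: np.ndarray
    tau: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float).ravel()
        self.tau = np.asarray(self.tau, dtype=float).ravel()
        if self.z.size != self.tau.size or self.z.size < 2:
            raise ValueError("z and tau must be equal-length with >= 2 points")
        dz = np.diff(self.z)
        if np.any(dz <= 0):
            raise ValueError("z grid must be strictly increasing")
        if not np.allclose(dz, dz[0], rtol=1e-6, atol=1e-12):
            raise ValueError("z grid must be uniform")
        if not (np.all(np.isfinite(self.z)) and np.all(np.isfinite(self.tau))):
            raise ValueError("profile contains non-finite values")

    @property
    def bin_width(self) -> float:
        return float(self.z[1] - self.z[0])


@dataclass
class BucklingObservation:
    """One buckled-membrane measurement.

    lam is the compressive strain (L0 - L_compressed)/L0; P_xx the xx
    pressure-tensor component (kJ mol^-1 nm^-3) of the restrained run; box
    lengths in nm with L_x the *compressed* x dimension; T in K.
    force_std optionally carries the standard error of F_x for
    inverse-variance combination.
    """

    lam: float
    p_xx: float
    l_x: float
    l_y: float
    l_z: float
    temperature: float = 300.0
    force_std: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.lam < 1.0:
            raise ValueError(f"strain must lie in (0, 1), got {self.lam}")
        if min(self.l_x, self.l_y, self.l_z) <= 0:
            raise ValueError("box lengths must be positive")


@dataclass
class BucklingCoefficients:
    """Series coefficients of the buckling force law.

    b are the Taylor coefficients of the dimensionless elastica force
    (derived exactly in :mod:`hvmech.elastica`); d are the thermal-
    undulation force coefficients, which must be supplied by the user —
    they are not derivable from the elastica alone.
    """

    b: np.ndarray = field(default_factory=lambda: BUCKLING_B.copy())
    d: np.ndarray | None = None
    truncation_order: int = 10

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        if len(self.b) < self.truncation_order + 1:
            raise ValueError(
                f"need b coefficients through order {self.truncation_order}"
            )
        if self.d is not None:
            self.d = np.asarray(self.d, dtype=float)
            if len(self.d) < self.truncation_order + 1:
                raise ValueError(
                    f"need d coefficients through order {self.truncation_order}"
                )


@dataclass
class ElasticModuli:
    """Bundle of reported moduli: k_A in J m^-2, k_C and kappa_G in kJ mol^-1."""

    k_a: float | None = None
    k_c: float | None = None
    kappa_g: float | None = None
    temperature: float = 300.0

    @property
    def elastic_ratio(self) -> float:
        if self.k_c is None or self.kappa_g is None:
            raise ValueError("both k_C and kappa_G required for the elastic ratio")
        return elastic_ratio(self.k_c, self.kappa_g)

    @property
    def k_c_kbt(self) -> float:
        return units.energy_in_kbt(self.k_c, self.temperature)


@dataclass
class KaResult:
    k_a: float  # J m^-2
    k_a_internal: float  # kJ mol^-1 nm^-2
    stderr: float  # J m^-2, block estimate
    mean_area: float
    area_variance: float
    n_samples: int


def area_compressibility(series: AreaSeries, n_blocks: int = 5) -> KaResult:
    """Area compressibility modulus from lateral-area fluctuations.

    k_A = k_B T <A> / var(A), with the variance taken about the time mean.
    The standard error comes from re-estimating k_A on ``n_blocks``
    contiguous blocks.
    """
    a = series.areas
    n = len(a)
    if n < 100:
        warnings.warn(f"only {n} area samples; fluctuation estimate will be noisy")
    var = float(np.var(a))
    if var == 0.0:
        raise ValueError("area series has zero variance; k_A undefined")
    mean = float(np.mean(a))
    ka_internal = units.KB * series.temperature * mean / var
    ka_si = units.ka_to_si(ka_internal)

    stderr = float("nan")
    if n >= 2 * n_blocks:
        blocks = np.array_split(a, n_blocks)
        vals = []
        for b in blocks:
            v = np.var(b)
            if v > 0:
                vals.append(units.KB * series.temperature * np.mean(b) / v)
        if len(vals) > 1:
            stderr = units.ka_to_si(float(np.std(vals, ddof=1) / np.sqrt(len(vals))))
    return KaResult(ka_si, ka_internal, stderr, mean, var, n)


def stress_profile_moments(profile: StressProfile) -> tuple[float, float, float]:
    """Zeroth, first and second moments of tau0(z) by the trapezoid rule.

    Units: M0 kJ mol^-1 nm^-2 (membrane tension), M1 kJ mol^-1 nm^-1,
    M2 kJ mol^-1.
    """
    z, tau = profile.z, profile.tau
    return tuple(float(np.trapezoid(tau * z**k, z)) for k in range(3))


def gaussian_modulus(
    profile: StressProfile,
    tension_tolerance: float | None = None,
) -> float:
    """Gaussian curvature modulus as the second moment of the stress profile.

    Requires (and enforces) vanishing membrane tension: |M0| below
    ``tension_tolerance`` (default 1% of max|tau| times the profile span).
    The sign convention follows the input profile directly — cohesive
    interfaces give negative kappa_G, favoring closed (vesicular)
    topologies.  Returned in kJ mol^-1.
    """
    m0, _m1, m2 = stress_profile_moments(profile)
    if tension_tolerance is None:
        span = float(profile.z[-1] - profile.z[0])
        scale = float(np.max(np.abs(profile.tau)))
        tension_tolerance = 0.01 * scale * span
        if tension_tolerance == 0.0:  # all-zero profile: any M0 would be exact 0
            tension_tolerance = 1e-12
    if abs(m0) > tension_tolerance:
        raise ValueError(
            "nonzero membrane tension: |M0| = "
            f"{abs(m0):.4g} kJ mol^-1 nm^-2 exceeds tolerance "
            f"{tension_tolerance:.4g}; the second-moment route to kappa_G "
            "requires a tensionless membrane"
        )
    return m2


def buckling_force(obs: BucklingObservation) -> float:
    """Restoring force F_x = P_xx L_y L_z (kJ mol^-1 nm^-1)."""
    return obs.p_xx * obs.l_y * obs.l_z


def _thermal_force(obs: BucklingObservation, coeffs: BucklingCoefficients) -> float:
    """sigma_F = -1.5 k_B T sum_i d_i lam^i / L_x, the undulation force."""
    if obs.temperature == 0.0:
        return 0.0
    if coeffs.d is None:
        raise ValueError(
            "thermal correction requested but no d coefficients are available; "
            "supply BucklingCoefficients(d=...) or disable include_thermal"
        )
    s = float(np.polynomial.polynomial.polyval(obs.lam, coeffs.d))
    return -1.5 * units.KB * obs.temperature * s / obs.l_x


@dataclass
class KcResult:
    k_c: float  # kJ mol^-1
    stderr: float
    per_observation: np.ndarray
    temperature: float

    @property
    def k_c_kbt(self) -> float:
        return units.energy_in_kbt(self.k_c, self.temperature)


def bending_modulus_buckling(
    observations: Sequence[BucklingObservation] | BucklingObservation,
    coeffs: BucklingCoefficients | None = None,
    include_thermal: bool = False,
    method: str = "series",
) -> KcResult:
    """Bending modulus from buckled-membrane force measurements.

    For each observation the mechanical force per unit length
    f = F_x / L_y (thermal undulation force subtracted when enabled) is
    matched to k_C (2 pi / L0)^2 f_hat(lam) with arc length
    L0 = L_x / (1 - lam), giving

        k_C = F_x L0^2 / (4 pi^2 L_y f_hat(lam)).

    ``method="series"`` evaluates f_hat by the order-10 series;
    ``method="elastica"`` uses the exact elliptic oracle.  Observations are
    combined by inverse-variance weighting when force uncertainties are
    given, otherwise by the unweighted mean.
    """
    if isinstance(observations, BucklingObservation):
        observations = [observations]
    if not observations:
        raise ValueError("no buckling observations given")
    if coeffs is None:
        coeffs = BucklingCoefficients()
    if method not in ("series", "elastica"):
        raise ValueError(f"unknown method {method!r}")

    kcs, sigmas = [], []
    for obs in observations:
        if obs.lam > 0.3 and method == "series":
            warnings.warn(
                f"strain {obs.lam} is outside the validated range of the "
                "truncated series (lam <= 0.3)"
            )
        f_x = buckling_force(obs)
        if include_thermal:
            f_x = f_x - _thermal_force(obs, coeffs)
        if method == "series":
            f_hat = series_force(obs.lam, coeffs.b[: coeffs.truncation_order + 1])
        else:
            f_hat = elastica_reference(obs.lam)
        l0 = obs.l_x / (1.0 - obs.lam)
        kc = f_x * l0**2 / (4.0 * np.pi**2 * obs.l_y * f_hat)
        kcs.append(kc)
        if obs.force_std is not None and f_x != 0:
            sigmas.append(abs(kc) * obs.force_std / abs(f_x))
        else:
            sigmas.append(None)

    kcs = np.array(kcs)
    t_mean = float(np.mean([o.temperature for o in observations]))
    if all(s is not None for s in sigmas) and len(kcs) > 0:
        w = 1.0 / np.array([s**2 for s in sigmas])
        kc = float(np.sum(w * kcs) / np.sum(w))
        stderr = float(np.sqrt(1.0 / np.sum(w)))
    else:
        kc = float(np.mean(kcs))
        stderr = (
            float(np.std(kcs, ddof=1) / np.sqrt(len(kcs))) if len(kcs) > 1 else float("nan")
        )
    return KcResult(kc, stderr, kcs, t_mean)


@dataclass
class CentralPotential:
    """Analytic central pair potential: force magnitude f(r) (> 0 repulsive)."""

    force: Callable[[np.ndarray], np.ndarray]
    cutoff: float
    central: bool = True


def pairwise_stress_profile(
    trajectory: Trajectory,
    potential: CentralPotential,
    n_slices: int = 100,
) -> StressProfile:
    """Toy Irving-Kirkwood lateral stress profile for analytic pair forces.

    Each pair's configurational virial is attributed to z slabs in
    proportion to the length of the straight (minimum-image) segment
    joining the pair inside each slab.  Only the configurational part is
    computed (frames carry no velocities); a homogeneous toy fluid should
    give a flat tau0 and a non-interacting one exactly zero.  This exists
    to validate the stress-profile consumers, not to analyze force fields.
    """
    if not potential.central:
        raise ValueError("only central pair potentials are supported")
    box = trajectory[0].box
    l_z = box[2]
    edges = np.linspace(0.0, l_z, n_slices + 1)
    dz_bin = edges[1] - edges[0]
    area = box[0] * box[1]
    v_slab = area * dz_bin
    acc = np.zeros(n_slices)  # accumulates tau_L - tau_N contributions

    for frame in trajectory:
        coords = np.mod(frame.coordinates, frame.box)
        n = len(coords)
        # minimum-image pair separations (toy scale: O(n^2) is fine)
        diff = coords[None, :, :] - coords[:, None, :]
        diff -= frame.box * np.round(diff / frame.box)
        r = np.linalg.norm(diff, axis=-1)
        iu, ju = np.triu_indices(n, k=1)
        rij = r[iu, ju]
        within = rij < potential.cutoff
        iu, ju, rij = iu[within], ju[within], rij[within]
        if len(rij) == 0:
            continue
        d = diff[iu, ju]  # vector from i to j
        f = np.asarray(potential.force(rij), dtype=float)
        # virial tensor components per pair: w_ab = f * r_a r_b / r
        w_xx = f * d[:, 0] ** 2 / rij
        w_yy = f * d[:, 1] ** 2 / rij
        w_zz = f * d[:, 2] ** 2 / rij
        w_lat_minus_norm = 0.5 * (w_xx + w_yy) - w_zz
        z_i = coords[iu, 2]
        z_j = z_i + d[:, 2]  # minimum-image partner position (may leave box)
        lo = np.minimum(z_i, z_j)
        hi = np.maximum(z_i, z_j)
        span = hi - lo
        for k in range(n_slices):
            # overlap of [lo, hi] with slab k, periodically folded
            ov = _periodic_overlap(lo, hi, edges[k], edges[k + 1], l_z)
            frac = np.where(span > 1e-12, ov / np.maximum(span, 1e-300), 0.0)
            # zero-span pairs sit entirely in one slab
            point = (span <= 1e-12) & (np.mod(lo, l_z) >= edges[k]) & (
                np.mod(lo, l_z) < edges[k + 1]
            )
            frac = np.where(point, 1.0, frac)
            acc[k] += np.sum(w_lat_minus_norm * frac)

    tau = acc / (v_slab * len(trajectory))
    centers = 0.5 * (edges[:-1] + edges[1:]) - l_z / 2.0
    return StressProfile(z=centers, tau=tau)


def _periodic_overlap(lo, hi, a, b, period):
    """Length of [lo, hi] inside [a, b) after folding into [0, period)."""
    out = np.zeros_like(lo)
    for shift in (-period, 0.0, period):
        s_lo = np.maximum(lo + shift, a)
        s_hi = np.minimum(hi + shift, b)
        out += np.maximum(s_hi - s_lo, 0.0)
    return out


def elastic_ratio(k_c: float, kappa_g: float) -> float:
    """Dimensionless stability indicator k_C / kappa_G (same units in and out).

    Negative values (kappa_G < 0 with k_C > 0) indicate that closed
    vesicular topologies are favored.
    """
    if kappa_g == 0:
        raise ValueError("kappa_G is zero; elastic ratio undefined")
    return float(k_c / kappa_g)
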