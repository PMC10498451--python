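"""Umbrella-sampling bookkeeping and WHAM free-energy reconstruction.

Windows restrain a reaction coordinate z with harmonic biases
U_i(z) = k/2 (z - z_i)^2; the weighted histogram analysis method combines
the biased histograms into an unbiased potential of mean force G(z).
Utilities cover adjacent-window overlap diagnostics, referencing the PMF
to bulk water, and classifying the global minimum as transmembrane,
interfacial or solvated.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .units import KB

__all__ = [
    "UmbrellaWindowSet",
    "PMFResult",
    "OverlapResult",
    "wham",
    "overlap_matrix",
    "reference_to_bulk",
    "classify_minimum",
]


@dataclass
class UmbrellaWindowSet:
    """Per-window restraint centers, force constant(s) and samples.

    centers in nm (sorted); k_restraint in kJ mol^-1 nm^-2, scalar or one
    per window; samples is a list of 1D arrays of reaction-coordinate
    values; temperature in K.
    """

    centers: np.ndarray
    k_restraint: float | np.ndarray
    samples: list[np.ndarray]
    temperature: float = 300.0

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).ravel()
        if np.any(np.diff(self.centers) < 0):
            raise ValueError("window centers must be sorted")
        if len(self.samples) != len(self.centers):
            raise ValueError("one sample array per window required")
        self.samples = [np.asarray(s, dtype=float).ravel() for s in self.samples]
        if any(len(s) == 0 for s in self.samples):
            raise ValueError("every window must contain samples")
        k = np.asarray(self.k_restraint, dtype=float)
        self.k_per_window = (
            np.full(len(self.centers), float(k)) if k.ndim == 0 else k.ravel()
        )
        if len(self.k_per_window) != len(self.centers):
            raise ValueError("k_restraint must be scalar or one per window")
        if np.any(self.k_per_window <= 0):
            raise ValueError("force constants must be positive")

    @property
    def n_windows(self) -> int:
        return len(self.centers)


@dataclass
class PMFResult:
    """Reconstructed free-energy profile G(z) in kJ mol^-1.

    Bins without sample support carry NaN.  ``window_free_energies`` are
    the converged per-window WHAM shift constants f_i (kJ mol^-1).
    """

    z: np.ndarray
    g: np.ndarray
    converged: bool
    iterations: int
    temperature: float
    reference_region: tuple[float, float] | None = None
    window_free_energies: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class OverlapResult:
    matrix: np.ndarray  # (n_w, n_w) histogram-intersection fractions
    adjacent: np.ndarray  # (n_w - 1,) overlaps of consecutive windows
    flagged: list[tuple[int, int]]  # adjacent pairs below threshold


def _histograms(windows: UmbrellaWindowSet, bin_width: float):
    all_samples = np.concatenate(windows.samples)
    lo = all_samples.min() - 0.5 * bin_width
    hi = all_samples.max() + 0.5 * bin_width
    n_bins = max(int(np.ceil((hi - lo) / bin_width)), 1)
    edges = lo + np.arange(n_bins + 1) * bin_width
    counts = np.stack(
        [np.histogram(s, bins=edges)[0] for s in windows.samples]
    ).astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts


def overlap_matrix(
    windows: UmbrellaWindowSet,
    bin_width: float = 0.02,
    flag_threshold: float = 0.05,
) -> OverlapResult:
    """Pairwise histogram-intersection fractions between windows.

    For each pair the normalized histograms p, q on a common grid give
    overlap = sum_b min(p_b, q_b) in [0, 1].  Adjacent pairs below
    ``flag_threshold`` are flagged as convergence risks.
    """
    _, counts = _histograms(windows, bin_width)
    probs = counts / counts.sum(axis=1, keepdims=True)
    n_w = windows.n_windows
    mat = np.zeros((n_w, n_w))
    for i in range(n_w):
        mat[i, i] = 1.0
        for j in range(i + 1, n_w):
            ov = float(np.minimum(probs[i], probs[j]).sum())
            mat[i, j] = mat[j, i] = ov
    adjacent = np.array([mat[i, i + 1] for i in range(n_w - 1)])
    flagged = [(i, i + 1) for i in range(n_w - 1) if adjacent[i] < flag_threshold]
    return OverlapResult(mat, adjacent, flagged)


def wham(
    windows: UmbrellaWindowSet,
    bin_width: float = 0.02,
    tolerance: float = 1e-4,
    max_iter: int = 100_000,
    check_overlap: bool = True,
) -> PMFResult:
    """Self-consistent WHAM over binned window histograms.

    Iterates the coupled equations

        P_b  proportional to  n_b / sum_i N_i f_i c_ib
        1/f_i = sum_b c_ib P_b,        c_ib = exp(-U_i(z_b)/k_B T)

    in log space until the largest change in the window free energies
    -k_B T ln f_i falls below ``tolerance`` (kJ mol^-1).  Bins with no
    samples are masked (NaN).  Adjacent windows with strictly zero
    histogram overlap abort with an error naming the gap.
    """
    kbt = KB * windows.temperature
    if check_overlap and windows.n_windows > 1:
        ov = overlap_matrix(windows, bin_width, flag_threshold=0.0)
        dead = [(i, j) for i, j in zip(range(windows.n_windows - 1), range(1, windows.n_windows)) if ov.adjacent[i] <= 0.0]
        if dead:
            i, j = dead[0]
            raise ValueError(
                f"no histogram overlap between adjacent windows {i} "
                f"(center {windows.centers[i]:.3f} nm) and {j} "
                f"(center {windows.centers[j]:.3f} nm); WHAM cannot bridge the gap"
            )

    centers, counts = _histograms(windows, bin_width)
    n_i = counts.sum(axis=1)  # samples per window
    n_b = counts.sum(axis=0)  # samples per bin
    support = n_b > 0
    # bias Boltzmann factors, log space: (n_windows, n_bins)
    du = 0.5 * windows.k_per_window[:, None] * (
        centers[None, :] - windows.centers[:, None]
    ) ** 2
    log_c = -du / kbt
    log_n_i = np.log(n_i)

    log_f = np.zeros(windows.n_windows)  # log f_i
    log_p = np.full(len(centers), -np.inf)
    converged = False
    iterations = 0
    with np.errstate(divide="ignore"):
        log_n_b = np.where(support, np.log(np.where(support, n_b, 1.0)), -np.inf)
    for iterations in range(1, max_iter + 1):
        denom = logsumexp(
            log_n_i[:, None] + log_f[:, None] + log_c, axis=0
        )
        log_p = log_n_b - denom
        new_log_f = -logsumexp(log_c[:, support] + log_p[None, support], axis=1)
        delta = kbt * np.max(np.abs(new_log_f - log_f))
        log_f = new_log_f
        if delta < tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"WHAM did not converge in {max_iter} iterations "
            f"(last change {delta:.2e} kJ/mol)"
        )

    g = np.full(len(centers), np.nan)
    g[support] = -kbt * log_p[support]
    g[support] -= np.nanmin(g[support])
    return PMFResult(
        z=centers,
        g=g,
        converged=converged,
        iterations=iterations,
        temperature=windows.temperature,
        window_free_energies=-kbt * log_f,
    )


def reference_to_bulk(pmf: PMFResult, bulk_region: tuple[float, float]) -> PMFResult:
    """Shift the PMF so its mean over the bulk-water region is zero.

    The aqueous region far from the membrane serves as the zero baseline;
    free-energy differences (well depths, barriers) are unchanged.
    """
    lo, hi = sorted(bulk_region)
    mask = (pmf.z >= lo) & (pmf.z <= hi) & np.isfinite(pmf.g)
    if not mask.any():
        raise ValueError(
            f"bulk region [{lo}, {hi}] nm contains no sampled PMF bins"
        )
    shift = float(np.mean(pmf.g[mask]))
    return PMFResult(
        z=pmf.z,
        g=pmf.g - shift,
        converged=pmf.converged,
        iterations=pmf.iterations,
        temperature=pmf.temperature,
        reference_region=(lo, hi),
        window_free_energies=pmf.window_free_energies,
    )


_LABELS = {"core": "transmembrane", "hydrophilic": "interfacial", "water": "solvated"}


def classify_minimum(
    pmf: PMFResult,
    region_bounds: Mapping[str, Sequence[tuple[float, float]] | tuple[float, float]],
    flat_tolerance: float = 1e-6,
) -> str:
    """Classify the PMF global minimum by membrane region.

    ``region_bounds`` maps "core", "hydrophilic" and "water" to z intervals
    (or lists of intervals) partitioning the sampled span.  The minimum in
    the hydrophobic core means a transmembrane state; in the head-group
    region, interfacial; in water, solvated.  If the minimum falls on a
    region boundary the region closer to the membrane center wins (core >
    hydrophilic > water).  A flat profile is labeled solvated with a
    warning.
    """
    finite = np.isfinite(pmf.g)
    if not finite.any():
        raise ValueError("PMF has no supported bins")
    g = pmf.g[finite]
    z = pmf.z[finite]
    if g.max() - g.min() < flat_tolerance:
        warnings.warn("PMF is flat to tolerance; labeling as solvated")
        return "solvated"
    z_min = float(z[np.argmin(g)])

    def intervals(spec):
        spec = list(spec) if not isinstance(spec, tuple) else [spec]
        if spec and not isinstance(spec[0], (tuple, list, np.ndarray)):
            spec = [tuple(spec)]
        return [tuple(sorted(iv)) for iv in spec]

    for region in ("core", "hydrophilic", "water"):  # inner regions win ties
        if region not in region_bounds:
            continue
        for lo, hi in intervals(region_bounds[region]):
            if lo <= z_min <= hi:
                return _LABELS[region]
    raise ValueError(
        f"PMF minimum at z = {z_min:.3f} nm lies in no declared region"
    )
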