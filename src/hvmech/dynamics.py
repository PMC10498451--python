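"""Lateral diffusion from mean-square displacement and Einstein's relation."""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import units
from .model import Trajectory

__all__ = ["MSDCurve", "DiffusionResult", "msd", "lateral_diffusion"]


@dataclass
class MSDCurve:
    """Time-origin-averaged lateral MSD: lag (ps), msd (nm^2), origins per lag."""

    lag: np.ndarray
    msd: np.ndarray
    n_origins: np.ndarray


@dataclass
class DiffusionResult:
    d: float  # nm^2 ps^-1
    d_cm2_s: float
    stderr: float  # nm^2 ps^-1, from the slope standard error
    slope: float
    intercept: float
    r_squared: float
    negative_slope: bool = False


def _msd_fft(x: np.ndarray) -> np.ndarray:
    """Per-lag MSD of one coordinate component, shape (T, N) -> (T, N).

    FFT autocorrelation form of the time-origin average:
    MSD(m) = S1(m) - 2 S2(m) with S2 the autocorrelation and S1 built from
    a running sum of squares.
    """
    t, n = x.shape
    fft = np.fft.rfft(x, n=2 * t, axis=0)
    acf = np.fft.irfft(fft * np.conj(fft), axis=0)[:t].real
    norm = (t - np.arange(t))[:, None]
    s2 = acf / norm
    x2 = x**2
    q = 2.0 * np.sum(x2, axis=0)
    s1 = np.empty_like(s2)
    for m in range(t):
        if m > 0:
            q = q - x2[m - 1] - x2[t - m]
        s1[m] = q / (t - m)
    return s1 - 2.0 * s2


def msd(
    trajectory: Trajectory,
    selection: np.ndarray | None = None,
    max_lag_fraction: float = 0.5,
) -> MSDCurve:
    """Lateral (x, y) mean-square displacement, averaged over time origins
    and selected beads.

    The trajectory must be unwrapped; an inter-frame jump larger than half
    a box length is taken as evidence of wrapped coordinates and raises.
    """
    if len(trajectory) < 10:
        raise ValueError("need at least 10 frames for an MSD")
    coords = trajectory.coordinate_stack()  # (T, N, 3)
    if selection is not None:
        selection = np.asarray(selection)
        coords = coords[:, selection, :]
    box = trajectory[0].box
    jumps = np.abs(np.diff(coords, axis=0))
    if np.any(jumps > 0.5 * box[None, None, :] + 1e-9):
        raise ValueError(
            "inter-frame displacement exceeds half a box length; the "
            "trajectory looks wrapped — run unwrap_pbc first"
        )
    t = coords.shape[0]
    per_particle = _msd_fft(coords[:, :, 0]) + _msd_fft(coords[:, :, 1])
    curve = per_particle.mean(axis=1)
    max_lag = max(int(np.floor(max_lag_fraction * (t - 1))), 1)
    lags_idx = np.arange(max_lag + 1)
    times = trajectory.times
    dt = times[1] - times[0] if t > 1 else 1.0
    curve = np.maximum(curve, 0.0)  # clip FFT round-off at lag 0
    return MSDCurve(
        lag=lags_idx * dt,
        msd=curve[: max_lag + 1],
        n_origins=(t - lags_idx),
    )


def lateral_diffusion(
    curve: MSDCurve,
    fit_window: tuple[float, float] = (0.1, 0.5),
    fit_intercept: bool = False,
) -> DiffusionResult:
    """Diffusion coefficient from the MSD slope: D = slope / 4 (2D).

    The fit uses lags between ``fit_window`` fractions of the maximum lag
    and weights each point by n_origins / lag^3, the inverse of the
    leading-order variance of a time-origin-averaged MSD (error amplitude
    grows linearly with lag, and longer lags average fewer effectively
    independent origins).  By default the line is anchored at the origin,
    the exact Einstein form MSD = 4 D tau; ``fit_intercept=True`` frees
    the intercept for data with short-time artifacts the window does not
    exclude.
    """
    lo, hi = fit_window
    max_lag = curve.lag[-1]
    mask = (curve.lag >= lo * max_lag) & (curve.lag <= hi * max_lag)
    mask &= curve.lag > 0
    if int(np.sum(mask)) < 5:
        raise ValueError("fewer than 5 lag points inside the fit window")
    x, y = curve.lag[mask], curve.msd[mask]
    w = curve.n_origins[mask] / x**3
    if fit_intercept:
        design = np.column_stack([x, np.ones_like(x)])
    else:
        design = x[:, None]
    wd = design * w[:, None]
    gram = design.T @ wd
    beta = np.linalg.solve(gram, wd.T @ y)
    resid = y - design @ beta
    dof = len(x) - design.shape[1]
    s2 = float(np.sum(w * resid**2) / dof) if dof > 0 else np.nan
    cov = np.linalg.inv(gram) * s2
    slope = float(beta[0])
    intercept = float(beta[1]) if fit_intercept else 0.0
    tss = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
    r_squared = 1.0 - float(np.sum(w * resid**2)) / tss if tss > 0 else 1.0
    d = slope / 4.0
    negative = d < 0
    if negative:
        warnings.warn("negative MSD slope; reporting D as fitted (check sampling)")
    return DiffusionResult(
        d=float(d),
        d_cm2_s=units.diffusion_to_cm2_s(float(d)),
        stderr=float(np.sqrt(max(cov[0, 0], 0.0)) / 4.0),
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        negative_slope=bool(negative),
    )
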