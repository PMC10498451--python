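"""Detergent-induced vesicle leakage: four-parameter logistic (4PL) fits.

Normalized dye-release fluorescence F versus Triton X-100 concentration
[T] (% m/v) follows

    F = d + (a - d) / (1 + ([T]/c)^b)

with the floor a = 0 (intact vesicles) and ceiling d = 1 (complete
disruption) fixed by the normalization, leaving the slope factor b and the
mid-range (inflection) concentration c to fit.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["LeakageDataset", "FourPLFit", "fit_4pl", "predict_4pl", "four_pl"]


@dataclass
class LeakageDataset:
    """Normalized fluorescence vs detergent concentration for one composition."""

    concentrations: np.ndarray  # % (m/v)
    fluorescence: np.ndarray  # normalized, ~[0, 1]
    composition: str = ""
    temperature: float = 298.0

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float).ravel()
        self.fluorescence = np.asarray(self.fluorescence, dtype=float).ravel()
        if len(self.concentrations) != len(self.fluorescence):
            raise ValueError("concentration and fluorescence lengths differ")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if len(np.unique(self.concentrations)) < 4:
            raise ValueError(
                "need at least 4 distinct concentrations for a 2-parameter fit"
            )


@dataclass
class FourPLFit:
    b: float  # slope factor
    c: float  # inflection concentration, % (m/v)
    b_stderr: float
    c_stderr: float
    rss: float
    converged: bool
    n_points: int
    a: float = 0.0
    d: float = 1.0


def four_pl(conc: np.ndarray, b: float, c: float) -> np.ndarray:
    """4PL response with a=0, d=1: F = 1 - 1/(1 + ([T]/c)^b).

    The zero-concentration point is the exact limit F(0) = 0 (for b > 0)
    rather than a log-transformed evaluation.
    """
    conc = np.asarray(conc, dtype=float)
    out = np.zeros(conc.shape)
    pos = conc > 0
    # compute via logs for conditioning at extreme ratios
    ratio_pow = np.exp(b * (np.log(conc[pos]) - np.log(c)))
    out[pos] = ratio_pow / (1.0 + ratio_pow)
    return out


def fit_4pl(data: LeakageDataset) -> FourPLFit:
    """Least-squares fit of (b, c) with the floor and ceiling fixed.

    c is fitted on a log scale for conditioning; the initial c is the
    positive concentration whose response is nearest 0.5 and the initial
    slope factor is 1.  Data that never cross the half-response warn,
    since the inflection is then an extrapolation.
    """
    conc, f = data.concentrations, data.fluorescence
    if np.ptp(f) == 0:
        raise ValueError("all responses identical; (b, c) unidentifiable")
    if not (np.any(f < 0.5) and np.any(f > 0.5)):
        warnings.warn(
            "responses do not bracket F = 0.5; the fitted inflection "
            "extrapolates beyond the data"
        )
    pos = conc > 0
    if not pos.any():
        raise ValueError("need at least one positive concentration")
    c0 = conc[pos][np.argmin(np.abs(f[pos] - 0.5))]

    def residuals(theta):
        b, log_c = theta
        return four_pl(conc, b, np.exp(log_c)) - f

    sol = least_squares(residuals, x0=[1.0, np.log(c0)], method="lm")
    b_hat, log_c_hat = sol.x
    c_hat = float(np.exp(log_c_hat))
    rss = float(np.sum(sol.fun**2))
    n = len(conc)

    b_se = c_se = float("nan")
    dof = n - 2
    if dof > 0:
        jtj = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.inv(jtj) * (rss / dof)
            b_se = float(np.sqrt(cov[0, 0]))
            c_se = float(c_hat * np.sqrt(cov[1, 1]))  # delta method from log c
        except np.linalg.LinAlgError:
            pass
    return FourPLFit(
        b=float(b_hat),
        c=c_hat,
        b_stderr=b_se,
        c_stderr=c_se,
        rss=rss,
        converged=bool(sol.success),
        n_points=n,
    )


def predict_4pl(fit: FourPLFit, concentrations: np.ndarray) -> np.ndarray:
    """Evaluate the fitted curve: F(0) = 0 and F -> 1 as [T] -> inf for b > 0."""
    if not fit.converged:
        raise ValueError("fit did not converge; refusing to predict")
    return four_pl(np.asarray(concentrations, dtype=float), fit.b, fit.c)
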