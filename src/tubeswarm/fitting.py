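"""Angle-ratio laws for tube traffic and their goodness of fit.

Two empirical laws relate a tube's opening angle ``theta`` to the
middle/edge ratios of the swarm passing through it:

* speed ratio (linear):   ``V_middle / V_edge = a * cos(theta) + c``
* count ratio (log-linear): ``N_middle / N_edge = exp(alpha * cos(theta) - beta)``

The reference coefficients measured in the eight-tube experiments are
``a = 1.5033, c = 0.1545`` and ``alpha = 3.5971, beta = 2.0173``; both laws
are strictly decreasing in ``theta`` on (0, 90) degrees.  This module fits
the laws from tube summaries (ordinary least squares; the exponential law by
OLS on the log ratio) and evaluates Pearson correlation and mean squared
error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "SPEED_LAW_SLOPE", "SPEED_LAW_INTERCEPT",
    "COUNT_LAW_ALPHA", "COUNT_LAW_BETA",
    "LinearLaw", "ExponentialLaw",
    "pearson_corr", "fit_linear_law", "fit_exponential_law", "mse",
    "predict_speed_ratio", "predict_number_ratio",
]

# Reference coefficients of the two measured laws.
SPEED_LAW_SLOPE = 1.5033
SPEED_LAW_INTERCEPT = 0.1545
COUNT_LAW_ALPHA = 3.5971
COUNT_LAW_BETA = 2.0173


@dataclass(frozen=True)
class LinearLaw:
    """``ratio_s = slope * cos(theta) + intercept`` with Pearson r."""

    slope: float
    intercept: float
    corr: float
    n_points: int = 0

    def predict(self, cosines) -> np.ndarray:
        return self.slope * np.asarray(cosines, dtype=float) + self.intercept

    def to_dict(self) -> dict:
        return {"law": "linear", "coefficients": {"slope": self.slope,
                                                  "intercept": self.intercept},
                "corr": self.corr, "n_points": self.n_points}


@dataclass(frozen=True)
class ExponentialLaw:
    """``ratio_n = exp(alpha * cos(theta) - beta)`` with its MSE."""

    alpha: float
    beta: float
    mse: float
    n_points: int = 0
    mse_scale: str = "linear"
    excluded_rows: tuple = field(default_factory=tuple)

    def predict(self, cosines) -> np.ndarray:
        return np.exp(self.alpha * np.asarray(cosines, dtype=float) - self.beta)

    def to_dict(self) -> dict:
        return {"law": "exponential", "coefficients": {"alpha": self.alpha,
                                                       "beta": self.beta},
                "mse": self.mse, "mse_scale": self.mse_scale,
                "n_points": self.n_points,
                "excluded_rows": list(self.excluded_rows)}


def _check_xy(x, y, min_len=2):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < min_len:
        raise ValueError(f"need at least {min_len} points")
    return x, y


def pearson_corr(x, y) -> float:
    """Pearson correlation coefficient of two equal-length samples."""
    x, y = _check_xy(x, y)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance sample")
    return float(sps.pearsonr(x, y).statistic)


def mse(y, y_hat) -> float:
    """Mean squared error between observed and predicted values."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("length mismatch")
    if y.size == 0:
        raise ValueError("need at least one point")
    return float(np.mean((y - y_hat) ** 2))


def fit_linear_law(cosines, ratios_s) -> LinearLaw:
    """OLS fit of the speed-ratio law on (cos(theta), ratio_s) points."""
    x, y = _check_xy(cosines, ratios_s)
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: all cosines equal")
    res = sps.linregress(x, y)
    return LinearLaw(slope=float(res.slope), intercept=float(res.intercept),
                     corr=float(res.rvalue), n_points=x.size)


def fit_exponential_law(cosines, ratios_n, mse_scale: str = "linear") -> ExponentialLaw:
    """Log-linear OLS fit of the count-ratio law.

    Rows with non-positive ratios cannot enter the log fit; they are dropped
    and reported in ``excluded_rows``.  ``mse_scale`` selects whether the MSE
    is computed on the ratio itself ("linear") or on its log ("log").
    """
    x, y = _check_xy(cosines, ratios_n)
    keep = y > 0
    excluded = tuple(int(i) for i in np.nonzero(~keep)[0])
    x_fit, y_fit = x[keep], y[keep]
    if x_fit.size < 2:
        raise ValueError("fewer than two positive ratios")
    if np.ptp(x_fit) == 0:
        raise ValueError("degenerate regressor: all cosines equal")
    res = sps.linregress(x_fit, np.log(y_fit))
    alpha, beta = float(res.slope), float(-res.intercept)
    pred = np.exp(alpha * x_fit - beta)
    if mse_scale == "linear":
        err = mse(y_fit, pred)
    elif mse_scale == "log":
        err = mse(np.log(y_fit), np.log(pred))
    else:
        raise ValueError(f"unknown mse_scale {mse_scale!r}")
    return ExponentialLaw(alpha=alpha, beta=beta, mse=err, n_points=x_fit.size,
                          mse_scale=mse_scale, excluded_rows=excluded)


def _check_theta(theta_deg: float) -> float:
    t = float(theta_deg)
    if not (0.0 <= t < 90.0):
        raise ValueError(f"tube angle {t} deg outside [0, 90)")
    return t


def predict_speed_ratio(theta_deg: float, law: LinearLaw | None = None) -> float:
    """Speed ratio predicted at an opening angle (reference law by default)."""
    t = _check_theta(theta_deg)
    c = math.cos(math.radians(t))
    if law is None:
        return SPEED_LAW_SLOPE * c + SPEED_LAW_INTERCEPT
    return float(law.predict(c))


def predict_number_ratio(theta_deg: float, law: ExponentialLaw | None = None) -> float:
    """Count ratio predicted at an opening angle (reference law by default)."""
    t = _check_theta(theta_deg)
    c = math.cos(math.radians(t))
    if law is None:
        return math.exp(COUNT_LAW_ALPHA * c - COUNT_LAW_BETA)
    return float(law.predict(c))
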