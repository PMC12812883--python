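"""Logistic growth-curve fitting and condition comparison.

Batch cultures of motile microalgae follow a logistic trajectory

    P(t) = K / (1 + ((K − P0)/P0) · exp(−r t))

with carrying capacity K (cells mL⁻¹), specific growth rate r (h⁻¹) and
initial population P0.  The doubling time during exponential growth is
Td = ln 2 / r.  Hydrodynamic perturbation experiments compare a perturbed
population against a static control: the growth index

    IG(t) = P_perturbed(t) / P_static(t)

is the ratio of the two fitted logistic curves and converges to the
ratio of carrying capacities at late times.  Carrying capacities and
doubling times are compared across replicates with Welch two-sample
t-tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "GrowthCurve",
    "LogisticFit",
    "GrowthIndexSeries",
    "GrowthComparison",
    "NonIdentifiableError",
    "logistic",
    "fit_logistic",
    "doubling_time",
    "growth_index",
    "compare_growth",
]

ALPHA = 0.05


class NonIdentifiableError(ValueError):
    """The data cannot constrain the logistic parameters."""


def logistic(t, K: float, r: float, P0: float):
    """Evaluate the logistic growth model P(t)."""
    t = np.asarray(t, dtype=float)
    return K / (1.0 + (K - P0) / P0 * np.exp(-r * t))


@dataclass
class GrowthCurve:
    """One replicate's concentration time series.

    times in hours (strictly increasing), concentrations in cells mL⁻¹
    (strictly positive).
    """

    times: np.ndarray
    concentrations: np.ndarray
    replicate_id: str | int | None = None
    condition: str | None = None
    scenario: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must have the same length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")


@dataclass(frozen=True)
class LogisticFit:
    """Fitted logistic parameters for one growth curve."""

    K: float
    r: float
    P0: float
    Td: float
    residual_sse: float
    converged: bool

    def predict(self, t):
        return logistic(t, self.K, self.r, self.P0)


@dataclass(frozen=True)
class GrowthIndexSeries:
    """Perturbed-over-static model-concentration ratio over time."""

    times: np.ndarray
    IG: np.ndarray


@dataclass(frozen=True)
class GrowthComparison:
    """Welch t-test comparison of K and Td across replicate fits."""

    K_static: tuple[float, float]  # mean, sd
    K_perturbed: tuple[float, float]
    Td_static: tuple[float, float]
    Td_perturbed: tuple[float, float]
    t_K: float
    p_K: float
    t_Td: float
    p_Td: float
    alpha: float = ALPHA
    notes: tuple[str, ...] = field(default_factory=tuple)

    @property
    def K_significant(self) -> bool:
        return self.p_K < self.alpha

    @property
    def Td_significant(self) -> bool:
        return self.p_Td < self.alpha


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """K from the observed plateau, P0 from the first point, r from the
    steepest increasing segment of log-concentration."""
    K0 = 1.05 * float(np.max(y))
    P00 = float(y[0])
    logy = np.log(y)
    slopes = np.diff(logy) / np.diff(t)
    pos = slopes[slopes > 0]
    r0 = float(np.max(pos)) if pos.size else 0.01
    return K0, r0, P00


def fit_logistic(curve: GrowthCurve, weighting: str = "relative") -> LogisticFit:
    """Least-squares logistic fit on the linear concentration scale.

    Microscopy counting error is relative (roughly constant coefficient
    of variation), so by default residuals are weighted by 1/y
    (``weighting="relative"``); ``weighting="absolute"`` gives the
    unweighted fit.  Both reduce to exact recovery on noiseless data.

    Raises
    ------
    NonIdentifiableError
        For fewer than 5 time points or monotone-decreasing data, where
        the logistic parameters are not jointly identifiable.
    """
    if weighting not in ("relative", "absolute"):
        raise ValueError("weighting must be 'relative' or 'absolute'")
    t, y = curve.times, curve.concentrations
    if t.size < 5:
        raise NonIdentifiableError(
            f"need at least 5 time points for a logistic fit, got {t.size}"
        )
    if np.all(np.diff(y) <= 0):
        raise NonIdentifiableError("monotone-decreasing data: no growth to fit")

    p0 = _initial_guess(t, y)
    converged = True
    try:
        popt, _ = optimize.curve_fit(
            logistic,
            t,
            y,
            p0=p0,
            sigma=y if weighting == "relative" else None,
            bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        popt, converged = np.asarray(p0), False
    K, r, P0 = (float(v) for v in popt)
    sse = float(np.sum((logistic(t, K, r, P0) - y) ** 2))
    return LogisticFit(K=K, r=r, P0=P0, Td=math.log(2.0) / r, residual_sse=sse,
                       converged=converged)


def doubling_time(fit: LogisticFit | float) -> float:
    """Exponential-phase doubling time Td = ln 2 / r (hours)."""
    r = fit.r if isinstance(fit, LogisticFit) else float(fit)
    if r <= 0:
        raise ValueError(f"growth rate must be positive, got {r!r}")
    return math.log(2.0) / r


def growth_index(
    fit_static: LogisticFit, fit_perturbed: LogisticFit, times
) -> GrowthIndexSeries:
    """IG(t) = P_perturbed(t)/P_static(t) from the two fitted models.

    The late-time limit equals K_perturbed / K_static.
    """
    if not (fit_static.converged and fit_perturbed.converged):
        raise ValueError("growth index requires two converged fits")
    times = np.asarray(times, dtype=float)
    return GrowthIndexSeries(times=times,
                             IG=fit_perturbed.predict(times) / fit_static.predict(times))


def _welch(x: np.ndarray, y: np.ndarray) -> tuple[float, float, list[str]]:
    notes: list[str] = []
    if np.var(x) == 0 and np.var(y) == 0:
        # degenerate variances: identical means are a perfect null,
        # distinct means an infinitely strong signal
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0, ["degenerate variance, equal means: p set to 1"]
        sign = math.copysign(1.0, np.mean(x) - np.mean(y))
        return sign * math.inf, 0.0, ["degenerate variance, unequal means: |t|=inf"]
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p), notes


def compare_growth(
    fits_static: Sequence[LogisticFit], fits_perturbed: Sequence[LogisticFit]
) -> GrowthComparison:
    """Welch two-sample t-tests of K and Td across per-replicate fits."""
    if len(fits_static) < 2 or len(fits_perturbed) < 2:
        raise ValueError("need at least 2 replicate fits per condition")
    Ks = np.array([f.K for f in fits_static])
    Kp = np.array([f.K for f in fits_perturbed])
    Ts = np.array([f.Td for f in fits_static])
    Tp = np.array([f.Td for f in fits_perturbed])
    t_K, p_K, notes_K = _welch(Kp, Ks)
    t_T, p_T, notes_T = _welch(Tp, Ts)
    return GrowthComparison(
        K_static=(float(Ks.mean()), float(Ks.std(ddof=1))),
        K_perturbed=(float(Kp.mean()), float(Kp.std(ddof=1))),
        Td_static=(float(Ts.mean()), float(Ts.std(ddof=1))),
        Td_perturbed=(float(Tp.mean()), float(Tp.std(ddof=1))),
        t_K=t_K, p_K=p_K, t_Td=t_T, p_Td=p_T,
        notes=tuple(notes_K + notes_T),
    )
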