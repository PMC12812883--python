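"""PAM chlorophyll-fluorescence parameters and rapid-light-curve fitting.

From a dark-adapted reference (F0, Fm) and a stepped rapid light curve
(16 actinic steps from 0 to 2500 µmol photons m⁻² s⁻¹ by default, each
yielding steady-state F′ and saturation-pulse Fm′) this module computes
the standard photophysiology quantities:

    Fv/Fm  = (Fm − F0)/Fm            maximum PSII quantum yield
    Y(II)  = (Fm′ − F′)/Fm′          effective PSII quantum yield
    NPQ    = (Fm − Fm′)/Fm′          non-photochemical quenching
    rETR   = E · Y(II) · 0.5         relative electron transport rate

The rETR–E light response is fitted with the Eilers–Peeters model

    rETR(E) = E / (a E² + b E + c)

whose maximum, optimum irradiance and initial slope have closed forms:
rETR_max = 1/(b + 2√(a c)),  E_opt = √(c/a),  α = 1/c.  NPQ at a
reference irradiance (500 µmol m⁻² s⁻¹ by default, a typical
near-surface light level) is interpolated by local least-squares
regression over the steps bracketing the target.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "PSII_FRACTION",
    "DarkReference",
    "LightCurveStep",
    "LightCurveRecord",
    "StepParameters",
    "EPFit",
    "PhotoPhysSummary",
    "max_quantum_yield",
    "step_parameters",
    "eilers_peeters",
    "fit_light_curve",
    "npq_at",
    "summarize_light_curve",
]

#: Fraction of absorbed quanta assumed to reach PSII (PSI/PSII partition).
PSII_FRACTION = 0.5


@dataclass(frozen=True)
class DarkReference:
    """Dark-adapted minimal (F0) and maximal (Fm) fluorescence yields."""

    F0: float
    Fm: float

    def __post_init__(self) -> None:
        if not self.Fm > 0:
            raise ValueError(f"Fm must be positive, got {self.Fm!r}")
        if not self.F0 > 0:
            raise ValueError(f"F0 must be positive, got {self.F0!r}")
        if self.F0 > self.Fm:
            warnings.warn(
                "F0 exceeds Fm: dark reference is physiologically inverted",
                stacklevel=2,
            )

    @property
    def inverted(self) -> bool:
        return self.F0 > self.Fm


@dataclass(frozen=True)
class LightCurveStep:
    """One actinic-irradiance step of a rapid light curve."""

    E: float
    F_prime: float
    Fm_prime: float

    def __post_init__(self) -> None:
        if self.E < 0:
            raise ValueError("actinic irradiance E must be non-negative")
        if not (self.F_prime > 0 and self.Fm_prime > 0):
            raise ValueError("fluorescence yields must be positive")


@dataclass(frozen=True)
class LightCurveRecord:
    """A dark reference plus steps ordered by increasing irradiance."""

    dark: DarkReference
    steps: tuple[LightCurveStep, ...]

    def __init__(self, dark: DarkReference, steps: Sequence[LightCurveStep]):
        steps = tuple(steps)
        E = [s.E for s in steps]
        if any(b <= a for a, b in zip(E, E[1:])):
            raise ValueError("steps must be ordered by strictly increasing E")
        object.__setattr__(self, "dark", dark)
        object.__setattr__(self, "steps", steps)

    @property
    def par(self) -> np.ndarray:
        return np.array([s.E for s in self.steps])


@dataclass(frozen=True)
class StepParameters:
    Y_II: float
    NPQ: float
    rETR: float


@dataclass(frozen=True)
class EPFit:
    """Eilers–Peeters fit of an rETR–E light-response curve."""

    a: float
    b: float
    c: float
    rETR_max: float
    E_opt: float
    alpha: float
    converged: bool


@dataclass(frozen=True)
class PhotoPhysSummary:
    """Per-record photophysiology summary."""

    FvFm: float
    E: np.ndarray
    Y_II: np.ndarray
    NPQ: np.ndarray
    rETR: np.ndarray
    rETR_max: float
    NPQ_500: float
    ep_fit: EPFit


def max_quantum_yield(dark: DarkReference) -> float:
    """Fv/Fm = (Fm − F0)/Fm; negative (flagged by DarkReference) if F0 > Fm."""
    return (dark.Fm - dark.F0) / dark.Fm


def step_parameters(step: LightCurveStep, dark: DarkReference) -> StepParameters:
    """Effective yield, NPQ and rETR for one light-curve step."""
    y = (step.Fm_prime - step.F_prime) / step.Fm_prime
    npq = (dark.Fm - step.Fm_prime) / step.Fm_prime
    retr = step.E * y * PSII_FRACTION
    return StepParameters(Y_II=y, NPQ=npq, rETR=retr)


def eilers_peeters(E, a: float, b: float, c: float):
    """rETR(E) = E/(aE² + bE + c); defined as 0 at E = 0."""
    E = np.asarray(E, dtype=float)
    return E / (a * E**2 + b * E + c)


def _ep_initial_guess(E: np.ndarray, retr: np.ndarray) -> tuple[float, float, float]:
    # initial slope from the first 3 nonzero-E points -> c = 1/alpha;
    # empirical maximum and its location -> b and a
    slope = float(np.sum(E[:3] * retr[:3]) / np.sum(E[:3] ** 2))
    c0 = 1.0 / max(slope, 1e-12)
    i_max = int(np.argmax(retr))
    E_max = max(float(E[i_max]), 1e-6)
    a0 = c0 / E_max**2
    b0 = 1.0 / max(float(retr[i_max]), 1e-12) - 2.0 * math.sqrt(a0 * c0)
    return a0, b0, c0


def fit_light_curve(record: LightCurveRecord) -> EPFit:
    """Least-squares Eilers–Peeters fit of rETR versus E.

    Requires at least 6 steps with E > 0.  On optimizer failure the fit
    is flagged unconverged and reports the empirical maximum rETR.
    """
    dark = record.dark
    params = [step_parameters(s, dark) for s in record.steps]
    E = record.par
    retr = np.array([p.rETR for p in params])
    mask = E > 0
    if int(mask.sum()) < 6:
        raise ValueError("need at least 6 steps with E > 0 to fit the light curve")
    E_fit, retr_fit = E[mask], retr[mask]

    p0 = _ep_initial_guess(E_fit, retr_fit)
    try:
        popt, _ = optimize.curve_fit(
            eilers_peeters,
            E_fit,
            retr_fit,
            p0=p0,
            bounds=([1e-15, -np.inf, 1e-15], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        a, b, c = (float(v) for v in popt)
        converged = True
    except RuntimeError:
        a, b, c = p0
        converged = False

    root = 2.0 * math.sqrt(a * c)
    retr_max = 1.0 / (b + root) if b + root > 0 else float(np.max(retr_fit))
    if not converged:
        retr_max = float(np.max(retr_fit))
    return EPFit(a=a, b=b, c=c, rETR_max=retr_max,
                 E_opt=math.sqrt(c / a), alpha=1.0 / c, converged=converged)


def npq_at(record: LightCurveRecord, E_target: float = 500.0,
           window: int = 4) -> float:
    """NPQ at ``E_target`` by local least-squares regression of NPQ vs PAR.

    The regression window is the two steps bracketing the target plus
    their nearest neighbour on each side (``window``/2 per side); a step
    exactly at the target is included in the window.
    """
    E = record.par
    npq = np.array([step_parameters(s, record.dark).NPQ for s in record.steps])
    if E_target < E.min() or E_target > E.max():
        raise ValueError(
            f"E_target={E_target} outside the measured irradiance range "
            f"[{E.min()}, {E.max()}]: refusing to extrapolate"
        )
    per_side = window // 2
    below = np.where(E < E_target)[0]
    above = np.where(E > E_target)[0]
    exact = np.where(E == E_target)[0]
    if len(exact) == 0 and (len(below) < per_side or len(above) < per_side):
        raise ValueError(
            f"need {per_side} steps on each side of E_target={E_target} "
            "(or one step exactly at it)"
        )
    idx = sorted(set(below[-per_side:]) | set(above[:per_side]) | set(exact))
    if len(idx) == 1:
        return float(npq[idx[0]])
    coef = np.polyfit(E[idx], npq[idx], 1)
    return float(np.polyval(coef, E_target))


def summarize_light_curve(record: LightCurveRecord,
                          E_npq: float = 500.0) -> PhotoPhysSummary:
    """Full per-record summary: Fv/Fm, per-step Y(II)/NPQ/rETR, the EP fit
    and NPQ at the reference irradiance."""
    params = [step_parameters(s, record.dark) for s in record.steps]
    fit = fit_light_curve(record)
    return PhotoPhysSummary(
        FvFm=max_quantum_yield(record.dark),
        E=record.par,
        Y_II=np.array([p.Y_II for p in params]),
        NPQ=np.array([p.NPQ for p in params]),
        rETR=np.array([p.rETR for p in params]),
        rETR_max=fit.rETR_max,
        NPQ_500=npq_at(record, E_target=E_npq),
        ep_fit=fit,
    )
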