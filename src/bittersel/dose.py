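"""Dose-response fitting for receptor titrations and preference trials.

Two sigmoid models are fit by Levenberg-Marquardt least squares on the
per-concentration mean responses:

* cell-assay titration (calcium imaging, response ``dF/F``), an increasing
  four-parameter logistic
  ``f(x) = i_min + (i_max - i_min) / (1 + (ec50/x)**h)``, and
* two-bottle preference, a declining half-logistic anchored at the 0.5
  indifference level, ``f(x) = 0.5 / (1 + (x/ec50)**h)``; by construction
  the fitted curve equals 0.25 — half the chance level — exactly at its
  EC50.

EC50 is fit on a log scale so positivity holds without bound constraints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DegenerateFitError",
    "TitrationCurve",
    "TitrationFit",
    "PreferenceTrialSet",
    "PreferenceFit",
    "delta_f_over_f",
    "titration_model",
    "preference_model",
    "fit_titration",
    "fit_preference",
    "fold_difference",
]


class DegenerateFitError(ValueError):
    """Raised when the data carry no dose-response signal to fit."""


def delta_f_over_f(f_peak, f_baseline):
    """Baseline-normalized fluorescence response (F - F0)/F0 (elementwise)."""
    f_peak = np.asarray(f_peak, dtype=float)
    f_baseline = np.asarray(f_baseline, dtype=float)
    if np.any(f_baseline <= 0):
        raise ValueError("baseline fluorescence must be positive")
    out = (f_peak - f_baseline) / f_baseline
    return float(out) if out.ndim == 0 else out


@dataclass
class TitrationCurve:
    """Replicate dF/F responses at each ligand concentration (uM)."""

    concentrations: np.ndarray      # strictly increasing, positive
    responses: list[np.ndarray]     # replicates per concentration

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        order = np.argsort(conc)
        self.concentrations = conc[order]
        self.responses = [np.atleast_1d(np.asarray(self.responses[i], float)) for i in order]
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if len(set(self.concentrations.tolist())) != self.concentrations.size:
            raise ValueError("concentrations must be distinct")

    @property
    def means(self) -> np.ndarray:
        return np.array([float(np.mean(r)) for r in self.responses])

    @property
    def sems(self) -> np.ndarray:
        return np.array(
            [float(np.std(r, ddof=1) / math.sqrt(r.size)) if r.size > 1 else math.nan for r in self.responses]
        )


@dataclass
class PreferenceTrialSet:
    """Per-trial preference ratios (tastant volume / total volume) per dose."""

    concentrations: np.ndarray
    ratios: list[np.ndarray]  # trials per concentration, each in [0, 1]

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        order = np.argsort(conc)
        self.concentrations = conc[order]
        self.ratios = [np.atleast_1d(np.asarray(self.ratios[i], float)) for i in order]
        for r in self.ratios:
            if np.any((r < 0) | (r > 1)):
                raise ValueError("preference ratios must lie in [0, 1]")

    @property
    def means(self) -> np.ndarray:
        return np.array([float(np.mean(r)) for r in self.ratios])


@dataclass
class TitrationFit:
    i_min: float
    i_max: float
    ec50: float
    hill: float
    rss: float
    converged: bool
    extrapolated: bool  # EC50 outside the observed concentration range


@dataclass
class PreferenceFit:
    ec50: float
    hill: float
    rss: float
    converged: bool


def titration_model(x, i_min, i_max, ec50, h):
    """Increasing 4PL: i_min + (i_max - i_min)/(1 + (ec50/x)**h)."""
    x = np.asarray(x, dtype=float)
    return i_min + (i_max - i_min) / (1.0 + (ec50 / x) ** h)


def preference_model(x, ec50, h):
    """Declining preference: 0.5/(1 + (x/ec50)**h); equals 0.25 at x = ec50."""
    x = np.asarray(x, dtype=float)
    return 0.5 / (1.0 + (x / ec50) ** h)


def fit_titration(curve: TitrationCurve, init: tuple[float, float, float, float] | None = None) -> TitrationFit:
    """Least-squares 4PL fit of (i_min, i_max, ec50, hill) on mean responses.

    Needs >= 4 distinct concentrations; a flat response raises
    :class:`DegenerateFitError`.  ``init`` overrides the default start
    (observed extremes, geometric-mean EC50, hill 1).
    """
    x = curve.concentrations
    y = curve.means
    if x.size < 4:
        raise ValueError("titration fit needs >= 4 distinct concentrations")
    if float(np.ptp(y)) < 1e-12:
        raise DegenerateFitError("response does not vary with concentration")
    if init is None:
        init = (float(y.min()), float(y.max()), float(np.exp(np.mean(np.log(x)))), 1.0)
    i_min0, i_max0, ec50_0, h0 = init

    def resid(p):
        return titration_model(x, p[0], p[1], math.exp(p[2]), p[3]) - y

    sol = least_squares(resid, [i_min0, i_max0, math.log(ec50_0), h0], method="lm")
    i_min, i_max, log_ec50, h = sol.x
    ec50 = math.exp(log_ec50)
    return TitrationFit(
        i_min=float(i_min),
        i_max=float(i_max),
        ec50=float(ec50),
        hill=float(h),
        rss=float(np.sum(sol.fun**2)),
        converged=bool(sol.success),
        extrapolated=not (x.min() <= ec50 <= x.max()),
    )


def fit_preference(trials: PreferenceTrialSet, init: tuple[float, float] | None = None) -> PreferenceFit:
    """Least-squares fit of (ec50, hill) on mean preference ratios.

    Needs >= 3 concentrations and a declining signal; means all at or above
    the 0.5 indifference level raise :class:`DegenerateFitError`.
    """
    x = trials.concentrations
    y = trials.means
    if x.size < 3:
        raise ValueError("preference fit needs >= 3 concentrations")
    if float(np.ptp(y)) < 1e-12 or float(y.min()) >= 0.5 - 1e-9:
        raise DegenerateFitError("no decline in preference with concentration")
    if init is None:
        init = (float(np.exp(np.mean(np.log(x)))), 1.0)
    ec50_0, h0 = init

    def resid(p):
        return preference_model(x, math.exp(p[0]), p[1]) - y

    sol = least_squares(resid, [math.log(ec50_0), h0], method="lm")
    ec50 = math.exp(sol.x[0])
    return PreferenceFit(
        ec50=float(ec50),
        hill=float(sol.x[1]),
        rss=float(np.sum(sol.fun**2)),
        converged=bool(sol.success),
    )


def fold_difference(ec50_a: float, ec50_b: float, round_to_ten: bool = False) -> float:
    """max/min ratio of two EC50s, optionally rounded to the nearest ten."""
    if ec50_a <= 0 or ec50_b <= 0:
        raise ValueError("EC50 values must be positive")
    ratio = max(ec50_a, ec50_b) / min(ec50_a, ec50_b)
    if round_to_ten:
        return float(round(ratio / 10.0) * 10)
    return float(ratio)
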