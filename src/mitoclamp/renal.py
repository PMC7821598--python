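"""FITC-inulin clearance and GFR.

After a bolus of FITC-inulin, blood fluorescence decays as the sum of a
fast distribution phase and a slow elimination phase:

    F(t) = A exp(-alpha t) + B exp(-beta t),   alpha > beta > 0

GFR is the dose divided by the area under the fitted curve:

    GFR = dose / (A/alpha + B/beta)

Dose is supplied in the same fluorescence-equivalent units as the curve
(via a dilution standard); absolute calibration is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, InsufficientDataError, InvalidInputError


@dataclass
class TwoPhaseFit:
    A: float
    alpha: float  # min^-1, fast phase
    B: float
    beta: float  # min^-1, slow phase; nan when single-phase fallback
    fallback_single: bool = False
    rss: float = float("nan")

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        y = self.A * np.exp(-self.alpha * t)
        if not self.fallback_single and self.B > 0:
            y = y + self.B * np.exp(-self.beta * t)
        return y

    @property
    def auc(self) -> float:
        """Closed-form area under the fitted curve on [0, inf)."""
        auc = self.A / self.alpha
        if not self.fallback_single and self.B > 0:
            auc += self.B / self.beta
        return auc


@dataclass
class ClearanceCurve:
    """Background-corrected blood fluorescence vs time for one animal."""

    time_min: np.ndarray
    fluorescence: np.ndarray
    dose: float  # injected amount, fluorescence-equivalent AU
    animal_id: str = ""
    body_weight_g: float | None = None
    fit: TwoPhaseFit | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise InvalidInputError("time and fluorescence must be 1-D arrays of equal length")
        if len(t) < 6:
            raise InsufficientDataError(f"need >= 6 time points, got {len(t)}")
        if np.any(f <= 0):
            raise InvalidInputError("fluorescence values must be positive")
        if self.dose <= 0:
            raise InvalidInputError("dose must be positive")
        order = np.argsort(t)  # fits are order-invariant
        self.time_min = t[order]
        self.fluorescence = f[order]


@dataclass
class GFRResult:
    gfr: float  # volume cleared per minute (uL/min when dose is uL-scaled)
    gfr_per_gram: float | None  # per gram body weight
    fit: TwoPhaseFit


def _biexp(t, A, alpha, B, beta):
    return A * np.exp(-alpha * t) + B * np.exp(-beta * t)


def _strip_initial_guess(t: np.ndarray, f: np.ndarray) -> tuple[float, float, float, float]:
    """Curve stripping: log-linear tail fit gives (B, beta); the early
    residual above the tail gives (A, alpha)."""
    n = len(t)
    tail = slice(max(n - max(3, n // 3), 2), n)
    b_slope, b_inter = np.polyfit(t[tail], np.log(f[tail]), 1)
    beta = max(-b_slope, 1e-6)
    B = float(np.exp(b_inter))
    resid = f - B * np.exp(-beta * t)
    early = resid[: max(3, n // 3)]
    t_early = t[: max(3, n // 3)]
    pos = early > 0
    if pos.sum() < 2:
        return float("nan"), float("nan"), B, beta  # effectively single-phase
    a_slope, a_inter = np.polyfit(t_early[pos], np.log(early[pos]), 1)
    return float(np.exp(a_inter)), max(-a_slope, 1e-5), B, beta


def _fit_single(t: np.ndarray, f: np.ndarray) -> TwoPhaseFit:
    slope, inter = np.polyfit(t, np.log(f), 1)
    p0 = (np.exp(inter), max(-slope, 1e-6))
    try:
        popt, _ = curve_fit(
            lambda tt, A, a: A * np.exp(-a * tt), t, f, p0=p0,
            bounds=([0, 0], [np.inf, np.inf]), maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:  # pragma: no cover
        raise FitError(f"single-exponential fallback failed: {exc}") from exc
    resid = f - popt[0] * np.exp(-popt[1] * t)
    return TwoPhaseFit(
        A=float(popt[0]), alpha=float(popt[1]), B=0.0, beta=float("nan"),
        fallback_single=True, rss=float(resid @ resid),
    )


def fit_two_phase(curve: ClearanceCurve) -> TwoPhaseFit:
    """Nonlinear least-squares biexponential fit with positivity constraints.

    Initialized by curve stripping.  When the fast component is absent or
    the biexponential fit fails or degenerates (alpha ~= beta, or a
    component contributing nothing), the fit falls back to a single
    exponential and is flagged ``fallback_single``.  The result is stored
    on ``curve.fit`` and returned.
    """
    t, f = curve.time_min, curve.fluorescence
    A0, alpha0, B0, beta0 = _strip_initial_guess(t, f)
    if not np.isfinite(A0):
        fit = _fit_single(t, f)
        curve.fit = fit
        return fit
    try:
        popt, _ = curve_fit(
            _biexp, t, f, p0=(A0, alpha0, B0, beta0),
            bounds=([0, 0, 0, 0], [np.inf, np.inf, np.inf, np.inf]), maxfev=20000,
        )
    except (RuntimeError, ValueError):
        fit = _fit_single(t, f)
        curve.fit = fit
        return fit
    A, alpha, B, beta = (float(x) for x in popt)
    if alpha < beta:  # enforce fast phase first
        A, alpha, B, beta = B, beta, A, alpha
    resid = f - _biexp(t, A, alpha, B, beta)
    degenerate = (
        B <= 0 or A <= 0 or beta <= 0
        or (alpha - beta) / alpha < 1e-3
    )
    if degenerate:
        fit = _fit_single(t, f)
    else:
        fit = TwoPhaseFit(A=A, alpha=alpha, B=B, beta=beta, rss=float(resid @ resid))
    curve.fit = fit
    return fit


def compute_gfr(
    fit: TwoPhaseFit,
    dose: float,
    body_weight_g: float | None = None,
) -> GFRResult:
    """GFR = dose over the closed-form AUC of the fitted decay.

    Linear in dose; optionally normalized per gram body weight.
    """
    if dose <= 0:
        raise InvalidInputError("dose must be positive")
    auc = fit.auc
    if not np.isfinite(auc) or auc <= 0:
        raise FitError(f"non-positive AUC ({auc}); fit unusable for GFR")
    gfr = dose / auc
    per_gram = None
    if body_weight_g is not None:
        if body_weight_g <= 0:
            raise InvalidInputError("body weight must be positive")
        per_gram = gfr / body_weight_g
    return GFRResult(gfr=float(gfr), gfr_per_gram=per_gram, fit=fit)
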