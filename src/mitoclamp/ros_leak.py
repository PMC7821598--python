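"""Amplex-UltraRed H2O2 flux and percentage electron leak.

Resorufin fluorescence rates are converted to pmol H2O2 min^-1 mg^-1 via a
linear standard curve; electron leak is (JH2O2 / JO2) x 100 under matched
substrate and demand conditions.  JH2O2 is kept in the plate reader's
per-minute convention and divided by 60 only inside the leak ratio, where
it must meet the per-second JO2.

Succinate leak is never computed: the paired JO2 assay contains rotenone
(to block reverse electron flow) while the H2O2 assay does not, so the two
fluxes are not measured under identical conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .constants import RESTING_DG_ATP_KCAL_MOL, SECONDS_PER_MINUTE, STANDARD_CURVE_R2
from .errors import (
    CurveRejectedError,
    DisallowedConditionError,
    InsufficientDataError,
    InvalidInputError,
    PairingError,
)

#: demand conditions of the leak assay; resting_clamp is the 30 mM PCr
#: composition with dG_ATP = -15.24 kcal/mol
Condition = Literal["state2", "resting_clamp"]

CONDITION_DG_ATP = {"state2": None, "resting_clamp": RESTING_DG_ATP_KCAL_MOL}


@dataclass
class StandardCurve:
    """Linear calibration: signal = slope * amount + intercept."""

    amounts: np.ndarray  # known amounts (e.g. pmol H2O2)
    signals: np.ndarray  # fluorescence AU
    slope: float = float("nan")
    intercept: float = float("nan")
    r_squared: float = float("nan")

    @property
    def usable(self) -> bool:
        return self.slope > 0 and self.r_squared >= STANDARD_CURVE_R2

    def invert(self, signal: float) -> float:
        """Amount corresponding to a signal (inverse prediction)."""
        return (signal - self.intercept) / self.slope


@dataclass
class H2O2Flux:
    jh2o2: float  # pmol min^-1 mg^-1
    condition: Condition
    substrate_label: str = ""


@dataclass
class LeakResult:
    percent_leak: float
    jo2_reference: float  # pmol s^-1 mg^-1
    condition: Condition
    substrate_label: str = ""


def fit_standard_curve(amounts, signals) -> StandardCurve:
    """OLS fit of signal on known amount.

    Requires >= 3 distinct amounts and a positive slope; curves with
    r^2 below the quality gate are returned but flagged unusable.
    """
    amounts = np.asarray(amounts, dtype=float)
    signals = np.asarray(signals, dtype=float)
    if amounts.shape != signals.shape or amounts.ndim != 1:
        raise InsufficientDataError("amounts and signals must be 1-D arrays of equal length")
    if len(np.unique(amounts)) < 3:
        raise InsufficientDataError("standard curve needs >= 3 distinct known amounts")
    xc = amounts - amounts.mean()
    slope = float(xc @ (signals - signals.mean())) / float(xc @ xc)
    intercept = float(signals.mean() - slope * amounts.mean())
    resid = signals - (slope * amounts + intercept)
    syy = float(((signals - signals.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / syy if syy > 0 else 0.0
    if slope <= 0:
        raise CurveRejectedError(f"standard-curve slope must be positive, got {slope:.4g}")
    return StandardCurve(amounts=amounts, signals=signals, slope=slope,
                         intercept=intercept, r_squared=r2)


def compute_jh2o2(
    fluorescence_slope_per_min: float,
    curve: StandardCurve,
    protein_mg: float,
    condition: Condition = "state2",
    substrate_label: str = "",
    reaction_volume_uL: float = 200.0,
) -> H2O2Flux:
    """Convert a well's fluorescence rate (AU/min) to pmol H2O2 min^-1 mg^-1.

    The standard curve is amount-based (AU per pmol in the same well
    volume), so the reaction volume cancels and is carried as metadata
    only.  Small negative rates (fluorescence drift) are clipped to zero
    with a warning rather than propagated.
    """
    if protein_mg <= 0:
        raise InvalidInputError(f"protein_mg must be positive, got {protein_mg}")
    if not curve.usable:
        raise CurveRejectedError(
            f"standard curve unusable (slope {curve.slope:.4g}, r^2 {curve.r_squared:.4f} "
            f"< {STANDARD_CURVE_R2})"
        )
    rate = fluorescence_slope_per_min / curve.slope / protein_mg
    if rate < 0:
        warnings.warn(
            f"negative JH2O2 ({rate:.3g} pmol/min/mg) clipped to 0 "
            "(fluorescence drift artifact)",
            stacklevel=2,
        )
        rate = 0.0
    return H2O2Flux(jh2o2=float(rate), condition=condition, substrate_label=substrate_label)


def electron_leak(
    jh2o2: H2O2Flux,
    jo2: float,
    jo2_condition: Condition,
    jo2_substrate_label: str = "",
) -> LeakResult:
    """Percentage electron leak = (JH2O2 per second / JO2 per second) x 100.

    Both fluxes must come from the same substrate and demand condition;
    succinate pairings are disallowed outright (rotenone mismatch between
    the two assays).
    """
    substrate = jh2o2.substrate_label or jo2_substrate_label
    if "succinate" in substrate.lower():
        raise DisallowedConditionError(
            "electron leak is not defined for succinate: the JO2 assay contains "
            "rotenone while the JH2O2 assay does not"
        )
    if jo2_condition != jh2o2.condition:
        raise PairingError(
            f"demand condition mismatch: JH2O2 {jh2o2.condition!r} vs JO2 {jo2_condition!r}"
        )
    if jo2_substrate_label and jh2o2.substrate_label and (
        jo2_substrate_label != jh2o2.substrate_label
    ):
        raise PairingError(
            f"substrate mismatch: JH2O2 {jh2o2.substrate_label!r} vs "
            f"JO2 {jo2_substrate_label!r}"
        )
    if jo2 <= 0:
        raise InvalidInputError(f"JO2 reference must be positive, got {jo2}")
    percent = (jh2o2.jh2o2 / SECONDS_PER_MINUTE) / jo2 * 100.0
    return LeakResult(
        percent_leak=float(percent),
        jo2_reference=float(jo2),
        condition=jh2o2.condition,
        substrate_label=substrate,
    )
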