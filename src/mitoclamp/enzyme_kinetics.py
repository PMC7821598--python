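"""Calibrated kinetic-slope engine for enzyme activity assays.

One computational core serves all plate-based activities: matrix
dehydrogenases read as NAD(P)H autofluorescence appearance (JNADH,
ex/em 340:450), ETS complex and ATP synthase assays read as absorbance
kinetics, and citrate synthase via DTNB.  The engine finds the earliest
linear window (initial-rate convention), subtracts a paired blank when
given, and calibrates AU/min to nmol min^-1 mg^-1 through either a
standard curve or an extinction coefficient (Beer-Lambert).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .constants import LINEARITY_MIN_POINTS, LINEARITY_R2
from .errors import (
    CalibrationError,
    DuplicateRowError,
    InsufficientDataError,
    InvalidInputError,
    NonlinearTraceError,
)
from .ros_leak import StandardCurve

ASSAY_LABELS = frozenset(
    {
        "PDH", "GDH", "MDH", "AKGDH", "BCKDH", "ICDH", "malic_enzyme",
        "CI", "CII", "CIII", "CIV", "CV", "citrate_synthase",
    }
)

CalibrationMode = Literal["standard_curve", "extinction_coefficient", "uncalibrated"]


@dataclass
class KineticTrace:
    """One well's kinetic read (fluorescence or absorbance AU vs time)."""

    time_s: np.ndarray
    signal: np.ndarray
    assay_label: str
    protein_mg: float
    blank_trace: "KineticTrace | None" = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_s.shape != self.signal.shape or self.time_s.ndim != 1:
            raise InvalidInputError("time_s and signal must be 1-D arrays of equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise InvalidInputError("time must be strictly increasing")
        if self.assay_label not in ASSAY_LABELS:
            raise InvalidInputError(
                f"unknown assay label {self.assay_label!r}; expected one of {sorted(ASSAY_LABELS)}"
            )
        if self.protein_mg <= 0:
            raise InvalidInputError("protein_mg must be positive")


@dataclass
class ActivityResult:
    rate: float  # nmol min^-1 mg^-1 when calibrated, else AU min^-1 mg^-1
    linear_window: tuple[float, float]
    r_squared: float
    calibration_mode: CalibrationMode
    assay_label: str = ""
    units: str = "AU/min/mg"


def _ols(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    tc = t - t.mean()
    slope = float(tc @ (y - y.mean())) / float(tc @ tc)
    resid = y - y.mean() - slope * tc
    syy = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / syy if syy > 0 else 1.0
    return slope, r2


def kinetic_slope(
    trace: KineticTrace,
    min_points: int = LINEARITY_MIN_POINTS,
    r2_min: float = LINEARITY_R2,
) -> tuple[float, tuple[float, float], float]:
    """Initial-rate slope in AU/min with its window and r^2.

    Policy: at the earliest start index admitting a window of
    ``min_points`` with r^2 >= ``r2_min``, extend the window forward while
    linearity holds (maximal early window); ties break toward the earlier
    start.  A paired blank's slope (same policy) is subtracted.
    Deterministic given the policy parameters.
    """
    t, y = trace.time_s, trace.signal
    n = len(t)
    if n < max(min_points, 5):
        raise InsufficientDataError(f"need >= {max(min_points, 5)} points, got {n}")
    chosen = None
    for start in range(0, n - min_points + 1):
        slope, r2 = _ols(t[start : start + min_points], y[start : start + min_points])
        if r2 >= r2_min:
            end = start + min_points
            best = (slope, r2, end)
            while end < n:
                s2, q2 = _ols(t[start : end + 1], y[start : end + 1])
                if q2 < r2_min:
                    break
                end += 1
                best = (s2, q2, end)
            chosen = (start, best)
            break
    if chosen is None:
        raise NonlinearTraceError(
            f"no window of >= {min_points} points reaches r^2 >= {r2_min}"
        )
    start, (slope, r2, end) = chosen
    slope_per_min = slope * 60.0
    if trace.blank_trace is not None:
        blank_slope, _, _ = kinetic_slope(trace.blank_trace, min_points, r2_min)
        slope_per_min -= blank_slope
    return slope_per_min, (float(t[start]), float(t[end - 1])), r2


def calibrate_activity(
    slope_au_per_min: float,
    protein_mg: float,
    calibration: StandardCurve | float | None = None,
    path_cm: float = 1.0,
    volume_mL: float = 1.0,
    linear_window: tuple[float, float] = (float("nan"), float("nan")),
    r_squared: float = float("nan"),
    assay_label: str = "",
) -> ActivityResult:
    """Convert an AU/min slope to an activity normalized by protein.

    Calibration is one of: a :class:`StandardCurve` in AU per nmol
    (amount = slope / curve.slope); an extinction coefficient in
    mM^-1 cm^-1 with path length and reaction volume (Beer-Lambert:
    concentration rate = slope / (eps * path) in mM/min, times volume in mL
    gives umol/min, i.e. x1000 nmol/min); or None for an uncalibrated
    AU/min/mg result.
    """
    if protein_mg <= 0:
        raise InvalidInputError("protein_mg must be positive")
    if calibration is None:
        return ActivityResult(
            rate=slope_au_per_min / protein_mg,
            linear_window=linear_window,
            r_squared=r_squared,
            calibration_mode="uncalibrated",
            assay_label=assay_label,
            units="AU/min/mg",
        )
    if isinstance(calibration, StandardCurve):
        if not calibration.usable:
            raise CalibrationError("standard curve unusable (slope or r^2 gate)")
        amount_per_min = slope_au_per_min / calibration.slope  # nmol/min
        mode: CalibrationMode = "standard_curve"
    else:
        eps = float(calibration)
        if eps <= 0 or path_cm <= 0 or volume_mL <= 0:
            raise CalibrationError(
                "extinction coefficient, path length, and volume must be positive"
            )
        # AU/min / (mM^-1 cm^-1 * cm) = mM/min; * mL = umol/min; * 1000 = nmol/min
        amount_per_min = slope_au_per_min / (eps * path_cm) * volume_mL * 1000.0
        mode = "extinction_coefficient"
    return ActivityResult(
        rate=amount_per_min / protein_mg,
        linear_window=linear_window,
        r_squared=r_squared,
        calibration_mode=mode,
        assay_label=assay_label,
        units="nmol/min/mg",
    )


def dehydrogenase_panel(
    records: list[dict],
    expected_assays: list[str] | None = None,
) -> pd.DataFrame:
    """Tidy activity table: one row per animal x assay.

    Each record carries ``animal``, ``sex``, ``group``, ``assay``,
    ``trace`` (:class:`KineticTrace`) and optional calibration keyword
    fields (``calibration``, ``path_cm``, ``volume_mL``).  Duplicate
    animal x assay entries are an error.  When ``expected_assays`` is
    given, missing animal x assay combinations appear as rows flagged
    ``present=False`` with NaN rate — absent, never imputed.
    """
    seen: set[tuple[str, str]] = set()
    rows = []
    animals: dict[str, tuple[str, str]] = {}
    for rec in records:
        key = (rec["animal"], rec["assay"])
        if key in seen:
            raise DuplicateRowError(f"duplicate animal x assay row: {key}")
        seen.add(key)
        animals.setdefault(rec["animal"], (rec.get("sex", ""), rec.get("group", "")))
        trace: KineticTrace = rec["trace"]
        slope, window, r2 = kinetic_slope(trace)
        res = calibrate_activity(
            slope,
            trace.protein_mg,
            calibration=rec.get("calibration"),
            path_cm=rec.get("path_cm", 1.0),
            volume_mL=rec.get("volume_mL", 1.0),
            linear_window=window,
            r_squared=r2,
            assay_label=rec["assay"],
        )
        rows.append(
            {
                "animal": rec["animal"],
                "sex": rec.get("sex", ""),
                "group": rec.get("group", ""),
                "assay": rec["assay"],
                "rate": res.rate,
                "units": res.units,
                "calibration_mode": res.calibration_mode,
                "r_squared": res.r_squared,
                "present": True,
            }
        )
    if expected_assays is not None:
        for animal, (sex, group) in animals.items():
            for assay in expected_assays:
                if (animal, assay) not in seen:
                    rows.append(
                        {
                            "animal": animal, "sex": sex, "group": group,
                            "assay": assay, "rate": float("nan"), "units": "",
                            "calibration_mode": "uncalibrated", "r_squared": float("nan"),
                            "present": False,
                        }
                    )
    return pd.DataFrame(rows).sort_values(["animal", "assay"], ignore_index=True)
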