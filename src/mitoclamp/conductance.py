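"""Force-flow analysis: OXPHOS conductance from JO2 vs dG_ATP.

Across a PCr titration the steady-state oxygen flux falls linearly as
dG_ATP becomes more negative (demand decreases).  The slope of that line —
the conductance of the energy-transduction system — is the per-sample
summary statistic; group comparisons are then made on the per-sample
slopes, never on pooled points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, MissingCellError, SingularDesignError


@dataclass
class ForceFlowCurve:
    """(dG_ATP, JO2) pairs for one sample and substrate, by titration step."""

    dg_atp: np.ndarray  # kcal/mol, strictly decreasing across steps
    jo2: np.ndarray  # pmol O2 s^-1 mg^-1
    substrate_label: str = ""
    sample_id: str = ""
    group: str = ""
    sex: str = ""

    def __post_init__(self) -> None:
        self.dg_atp = np.asarray(self.dg_atp, dtype=float)
        self.jo2 = np.asarray(self.jo2, dtype=float)
        if self.dg_atp.shape != self.jo2.shape or self.dg_atp.ndim != 1:
            raise InsufficientDataError("dg_atp and jo2 must be 1-D arrays of equal length")
        if len(self.dg_atp) < 3:
            raise InsufficientDataError(f"need >= 3 titration points, got {len(self.dg_atp)}")


@dataclass
class ConductanceResult:
    """Fitted force-flow line for one sample."""

    slope: float  # conductance magnitude, pmol s^-1 mg^-1 per kcal/mol
    raw_slope: float  # signed OLS slope in (dG, JO2) coordinates
    intercept: float
    r_squared: float
    n_points: int
    low_linearity: bool = False  # r^2 < 0.9 flag; sample kept, not dropped
    substrate_label: str = ""
    sample_id: str = ""
    group: str = ""
    sex: str = ""


def fit_force_flow(curve: ForceFlowCurve) -> ConductanceResult:
    """OLS fit of JO2 on dG_ATP; conductance is the slope magnitude.

    A constant-flux curve yields slope 0 with r^2 reported as 0 and the
    low-linearity flag set.  Zero variance in dG is a singular design.
    """
    x, y = curve.dg_atp, curve.jo2
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InsufficientDataError("non-finite values in force-flow curve")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise SingularDesignError("zero variance in dG_ATP; slope undefined")
    yc = y - y.mean()
    slope = float(xc @ yc) / sxx
    intercept = float(y.mean() - slope * x.mean())
    syy = float(yc @ yc)
    r2 = (slope * slope * sxx / syy) if syy > 0 else 0.0
    return ConductanceResult(
        slope=abs(slope),
        raw_slope=slope,
        intercept=intercept,
        r_squared=float(r2),
        n_points=len(x),
        low_linearity=r2 < 0.9,
        substrate_label=curve.substrate_label,
        sample_id=curve.sample_id,
        group=curve.group,
        sex=curve.sex,
    )


def results_to_frame(results: list[ConductanceResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "sex": [r.sex for r in results],
            "group": [r.group for r in results],
            "substrate": [r.substrate_label for r in results],
            "conductance": [r.slope for r in results],
            "r_squared": [r.r_squared for r in results],
            "n_points": [r.n_points for r in results],
            "low_linearity": [r.low_linearity for r in results],
        }
    )


def conductance_group_summary(
    results: list[ConductanceResult] | pd.DataFrame,
    control_label: str = "control",
    disease_label: str = "ckd",
) -> pd.DataFrame:
    """Per sex x substrate group means, SD, n, and percent change vs control.

    percent_change = (mean_disease - mean_control) / mean_control * 100.
    Raises :class:`MissingCellError` when any sex x substrate cell lacks one
    of the two groups or has fewer than 2 samples.
    """
    df = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    rows = []
    for (sex, substrate), cell in df.groupby(["sex", "substrate"], sort=True):
        by_group = {g: sub["conductance"].to_numpy() for g, sub in cell.groupby("group")}
        for label in (control_label, disease_label):
            if label not in by_group or len(by_group[label]) < 2:
                raise MissingCellError(
                    f"cell sex={sex} substrate={substrate} group={label} "
                    "is empty or has < 2 samples"
                )
        mc, md = by_group[control_label].mean(), by_group[disease_label].mean()
        rows.append(
            {
                "sex": sex,
                "substrate": substrate,
                "mean_control": mc,
                "sd_control": by_group[control_label].std(ddof=1),
                "n_control": len(by_group[control_label]),
                "mean_disease": md,
                "sd_disease": by_group[disease_label].std(ddof=1),
                "n_disease": len(by_group[disease_label]),
                "percent_change": (md - mc) / mc * 100.0,
            }
        )
    return pd.DataFrame(rows)
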