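"""The study-design statistical workflow.

Phenotypes measured on a sex x group (control vs CKD) cohort are gated by
per-cell Shapiro-Wilk normality: normal phenotypes go to two-way ANOVA
with Tukey pairwise comparisons only when the interaction is significant;
non-normal phenotypes fall back to Kruskal-Wallis across the four cells.
Metabolite feature tables (peak intensities, no filtering or
normalization) are screened per sex with two-tailed Pearson correlations
against OXPHOS conductance at an unadjusted P < 0.1, and with within-sex
two-group one-way ANOVA at P < 0.05 for differential abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .constants import ALPHA, DIFFERENTIAL_ALPHA, SCREEN_ALPHA
from .errors import (
    AlignmentError,
    DesignError,
    InvalidInputError,
    UndefinedCorrelationError,
)

SEXES = ("M", "F")
GROUPS = ("control", "ckd")


# ---------------------------------------------------------------------------
# cohort-level tests


def normality_gate(cells: dict[str, np.ndarray], alpha: float = ALPHA) -> str:
    """Route a phenotype to ``"parametric"`` or ``"nonparametric"``.

    Shapiro-Wilk per cell at ``alpha``; any failing cell routes the whole
    phenotype to the nonparametric branch.  Cells with fewer than 3 values
    or zero variance are undecidable and route to nonparametric with a
    warning (conservative).
    """
    for name, values in cells.items():
        values = np.asarray(values, dtype=float)
        if len(values) < 3 or np.ptp(values) == 0:
            warnings.warn(
                f"normality undecidable for cell {name!r} "
                f"(n={len(values)}, range={np.ptp(values) if len(values) else 0}); "
                "defaulting to nonparametric",
                stacklevel=2,
            )
            return "nonparametric"
        if sps.shapiro(values).pvalue < alpha:
            return "nonparametric"
    return "parametric"


@dataclass
class TwoWayAnovaResult:
    """Two-way ANOVA table with the gated Tukey table.

    ``table`` is indexed by term (group, sex, interaction, residual) with
    sum_sq, df, F, p columns; ``tukey`` is None unless the interaction
    reached ``alpha``.
    """

    table: pd.DataFrame
    tukey: pd.DataFrame | None
    ss_type: int
    method: str  # "closed_form_balanced" | "statsmodels"

    @property
    def p_group(self) -> float:
        return float(self.table.loc["group", "p"])

    @property
    def p_sex(self) -> float:
        return float(self.table.loc["sex", "p"])

    @property
    def p_interaction(self) -> float:
        return float(self.table.loc["sex:group", "p"])


def _is_balanced_2x2(df: pd.DataFrame) -> bool:
    counts = df.groupby(["sex", "group"], observed=True).size()
    return (
        df["sex"].nunique() == 2
        and df["group"].nunique() == 2
        and len(counts) == 4
        and counts.nunique() == 1
    )


def _anova_2x2_balanced(df: pd.DataFrame) -> pd.DataFrame:
    """Closed-form sums of squares for the balanced 2x2 design.

    In a balanced design type I/II/III sums of squares coincide, so this
    path is exactly the statsmodels result at a fraction of the cost.
    """
    y = df["value"].to_numpy(dtype=float)
    grand = y.mean()
    n_cell = len(df) // 4
    cell_means = df.groupby(["sex", "group"], observed=True)["value"].mean()
    sex_means = df.groupby("sex", observed=True)["value"].mean()
    group_means = df.groupby("group", observed=True)["value"].mean()
    ss_sex = 2 * n_cell * float(((sex_means - grand) ** 2).sum())
    ss_group = 2 * n_cell * float(((group_means - grand) ** 2).sum())
    ss_cells = n_cell * float(((cell_means - grand) ** 2).sum())
    ss_inter = ss_cells - ss_sex - ss_group
    fitted = df.set_index(["sex", "group"]).index.map(cell_means)
    ss_err = float(((y - np.asarray(fitted)) ** 2).sum())
    df_err = len(y) - 4
    rows = {}
    ms_err = ss_err / df_err if df_err > 0 else float("nan")
    for term, ss in (("sex", ss_sex), ("group", ss_group), ("sex:group", ss_inter)):
        ss = max(ss, 0.0)
        f = ss / ms_err if ms_err > 0 else 0.0
        p = float(sps.f.sf(f, 1, df_err)) if ms_err > 0 else 1.0
        rows[term] = {"sum_sq": ss, "df": 1.0, "F": f, "p": p}
    rows["residual"] = {"sum_sq": ss_err, "df": float(df_err), "F": np.nan, "p": np.nan}
    return pd.DataFrame(rows).T


def _anova_statsmodels(df: pd.DataFrame, ss_type: int) -> pd.DataFrame:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    model = smf.ols("value ~ C(sex) * C(group)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=ss_type)
    tab = tab.rename(
        index={
            "C(sex)": "sex",
            "C(group)": "group",
            "C(sex):C(group)": "sex:group",
            "Residual": "residual",
        },
        columns={"PR(>F)": "p"},
    )
    return tab[["sum_sq", "df", "F", "p"]]


def two_way_anova_tukey(
    df: pd.DataFrame,
    alpha: float = ALPHA,
    ss_type: int = 2,
) -> TwoWayAnovaResult:
    """Two-way (sex x group) ANOVA with interaction-gated Tukey post hoc.

    ``df`` needs ``value``, ``sex``, ``group`` columns with >= 2
    observations per cell.  Balanced 2x2 designs use a closed-form path
    (identical to statsmodels in that case); unbalanced designs use
    statsmodels with type-II sums of squares by default.  Tukey pairwise
    comparisons across the four sex-group cells are emitted only when the
    interaction P is below ``alpha``.
    """
    counts = df.groupby(["sex", "group"], observed=True).size()
    if len(counts) < 4 or (counts < 2).any():
        raise DesignError(f"each sex x group cell needs >= 2 observations, got\n{counts}")
    if _is_balanced_2x2(df):
        table = _anova_2x2_balanced(df)
        method = "closed_form_balanced"
    else:
        table = _anova_statsmodels(df, ss_type)
        method = "statsmodels"
    tukey = None
    if float(table.loc["sex:group", "p"]) < alpha:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        labels = df["sex"].astype(str) + ":" + df["group"].astype(str)
        res = pairwise_tukeyhsd(df["value"].to_numpy(dtype=float), labels.to_numpy())
        tukey = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
    return TwoWayAnovaResult(table=table, tukey=tukey, ss_type=ss_type, method=method)


def kruskal_wallis(cells: dict[str, np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H and P across cells (nonparametric fallback)."""
    groups = [np.asarray(v, dtype=float) for v in cells.values()]
    if len(groups) < 2:
        raise DesignError("Kruskal-Wallis needs >= 2 cells")
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def pearson_two_tailed(x, y) -> tuple[float, float]:
    """Pearson r with the two-tailed P from the t transform (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise InvalidInputError(f"need n >= 3, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidInputError("non-finite values in correlation input")
    xc, yc = x - x.mean(), y - y.mean()
    sx, sy = float(xc @ xc), float(yc @ yc)
    if sx == 0 or sy == 0:
        raise UndefinedCorrelationError("zero variance; correlation undefined")
    r = float(xc @ yc) / np.sqrt(sx * sy)
    r = min(1.0, max(-1.0, r))
    return r, p_from_r(r, n)


def p_from_r(r: float, n: int) -> float:
    """Two-tailed P for a Pearson r at sample size n (t with n-2 df)."""
    df = n - 2
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * sps.t.sf(t, df))


# ---------------------------------------------------------------------------
# metabolite feature tables


@dataclass
class FeatureTable:
    """Peak intensities (features x samples) with sample design labels.

    Intensities are used raw — no filtering or normalization — to keep the
    feature count maximal; the permissive screen threshold accounts for
    the small cohort instead.
    """

    intensities: pd.DataFrame  # index: feature_id, columns: sample ids
    sample_meta: pd.DataFrame  # index: sample ids; columns include sex, group
    ion_mode: str = "positive"

    def __post_init__(self) -> None:
        if self.intensities.index.duplicated().any():
            raise InvalidInputError("duplicate feature ids")
        if (self.intensities.to_numpy() < 0).any():
            raise InvalidInputError("negative peak intensities")
        if self.ion_mode not in ("positive", "negative"):
            raise InvalidInputError(f"ion_mode must be positive|negative, got {self.ion_mode!r}")
        missing = set(self.intensities.columns) - set(self.sample_meta.index)
        if missing:
            raise AlignmentError(f"samples missing from metadata: {sorted(missing)}")

    def samples_of_sex(self, sex: str) -> list[str]:
        keep = self.sample_meta.index[self.sample_meta["sex"] == sex]
        return [s for s in self.intensities.columns if s in set(keep)]


@dataclass
class ScreenResult:
    """Per-feature correlation screen against a phenotype, within sex."""

    frame: pd.DataFrame  # feature_id, sex, r, p, flag
    phenotype: str = "conductance"
    alpha: float = SCREEN_ALPHA
    expected_false_flags: float = field(init=False)

    def __post_init__(self) -> None:
        # multiplicity is reported, not corrected (the design applies none)
        self.expected_false_flags = self.alpha * len(self.frame)

    def top(self, sign: str, k: int = 10) -> pd.DataFrame:
        sub = self.frame[self.frame["flag"] == sign]
        ascending = sign == "negative"
        return sub.sort_values("r", ascending=ascending).head(k)


def _vectorized_pearson(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows of X against y: (r, two-tailed p) per row."""
    n = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sy = float(yc @ yc)
    sx = (Xc**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / np.sqrt(sx * sy)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.abs(r) * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * sps.t.sf(t, df)
    p[np.abs(r) >= 1.0] = 0.0
    p[~np.isfinite(r)] = np.nan
    return r, p


def metabolite_screen(
    features: FeatureTable,
    conductance: pd.Series,
    alpha: float = SCREEN_ALPHA,
) -> ScreenResult:
    """Two-tailed Pearson screen of every feature against conductance, per sex.

    ``conductance`` is indexed by sample id.  Features with P < ``alpha``
    are flagged ``positive`` or ``negative`` by the sign of r; everything
    else is ``none``.  Flags are unadjusted; the expected number of false
    flags is carried on the result.
    """
    frames = []
    for sex in sorted(features.sample_meta["sex"].unique()):
        samples = features.samples_of_sex(sex)
        missing = [s for s in samples if s not in conductance.index]
        if missing:
            raise AlignmentError(f"samples without conductance values: {missing}")
        if len(samples) < 3:
            raise DesignError(f"sex {sex!r} has fewer than 3 samples")
        X = features.intensities[samples].to_numpy(dtype=float)
        y = conductance.loc[samples].to_numpy(dtype=float)
        r, p = _vectorized_pearson(X, y)
        flag = np.where(
            p < alpha, np.where(r > 0, "positive", "negative"), "none"
        )
        flag[~np.isfinite(p)] = "none"
        frames.append(
            pd.DataFrame(
                {
                    "feature_id": features.intensities.index,
                    "sex": sex,
                    "r": r,
                    "p": p,
                    "flag": flag,
                }
            )
        )
    return ScreenResult(frame=pd.concat(frames, ignore_index=True), alpha=alpha)


def differential_metabolites(
    features: FeatureTable,
    alpha: float = DIFFERENTIAL_ALPHA,
) -> dict:
    """Within-sex two-group one-way ANOVA per feature; counts at P < alpha.

    For two groups the one-way ANOVA F equals the squared equal-variance
    two-sample t, which is how the vectorized path computes it.  Returns
    per-sex counts, flagged feature lists, and the full P-value frame.
    """
    out: dict = {"ion_mode": features.ion_mode, "alpha": alpha, "by_sex": {}}
    frames = []
    for sex in sorted(features.sample_meta["sex"].unique()):
        samples = features.samples_of_sex(sex)
        meta = features.sample_meta.loc[samples]
        groups = meta["group"].unique()
        if len(groups) < 2:
            raise DesignError(f"sex {sex!r} has a single group; ANOVA undefined")
        g1 = [s for s in samples if meta.loc[s, "group"] == groups[0]]
        g2 = [s for s in samples if meta.loc[s, "group"] == groups[1]]
        X1 = features.intensities[g1].to_numpy(dtype=float)
        X2 = features.intensities[g2].to_numpy(dtype=float)
        n1, n2 = X1.shape[1], X2.shape[1]
        m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
        v1 = X1.var(axis=1, ddof=1)
        v2 = X2.var(axis=1, ddof=1)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            t2 = (m1 - m2) ** 2 / (sp2 * (1.0 / n1 + 1.0 / n2))
        p = sps.f.sf(t2, 1, n1 + n2 - 2)
        sig = pd.Series(p, index=features.intensities.index)
        flagged = sig.index[sig < alpha].tolist()
        out["by_sex"][sex] = {"count": len(flagged), "features": flagged}
        frames.append(
            pd.DataFrame({"feature_id": features.intensities.index, "sex": sex, "p": p})
        )
    out["frame"] = pd.concat(frames, ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# muscle phenotypes


def degradation_rate(
    tyrosine_nmol: float, wet_weight_mg: float, incubation_h: float
) -> float:
    """Protein degradation rate: tyrosine released per muscle mass per time.

    nmol h^-1 mg^-1; tyrosine release in the presence of a protein
    synthesis inhibitor is a net proteolysis readout, normalized by muscle
    wet weight.
    """
    if wet_weight_mg <= 0 or incubation_h <= 0:
        raise InvalidInputError("wet weight and incubation time must be positive")
    if tyrosine_nmol < 0:
        raise InvalidInputError("tyrosine amount cannot be negative")
    return tyrosine_nmol / (wet_weight_mg * incubation_h)


def csa_summary(
    fibers_by_animal: dict[str, np.ndarray],
    bin_edges: np.ndarray,
    gfr_by_animal: pd.Series | None = None,
    min_fibers: int = 30,
) -> dict:
    """Myofiber cross-sectional-area summaries.

    Shared-edge histogram (relative frequencies) and per-animal mean CSA;
    when GFR values are supplied, the cohort Pearson correlation of mean
    CSA against GFR is included.  Animals with no fibers are flagged
    missing rather than dropped silently.
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    means, hists, missing = {}, {}, []
    for animal, areas in fibers_by_animal.items():
        areas = np.asarray(areas, dtype=float)
        if len(areas) == 0:
            missing.append(animal)
            continue
        if len(areas) < min_fibers:
            warnings.warn(
                f"animal {animal!r} has {len(areas)} fibers (< {min_fibers})",
                stacklevel=2,
            )
        counts, _ = np.histogram(areas, bins=bin_edges)
        hists[animal] = counts / counts.sum()
        means[animal] = float(areas.mean())
    result: dict = {
        "bin_edges": bin_edges,
        "histograms": pd.DataFrame(hists).T,
        "mean_csa": pd.Series(means, name="mean_csa"),
        "missing_animals": missing,
    }
    if gfr_by_animal is not None:
        common = [a for a in means if a in gfr_by_animal.index]
        if len(common) >= 3:
            r, p = pearson_two_tailed(
                [means[a] for a in common], gfr_by_animal.loc[common].to_numpy()
            )
            result["csa_vs_gfr"] = {"r": r, "p": p, "n": len(common)}
    return result
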