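"""Normality gating, two-way ANOVA, correlation screens, and summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mitoclamp.errors import (
    AlignmentError,
    DesignError,
    InvalidInputError,
    UndefinedCorrelationError,
)
from mitoclamp.stats_screens import (
    FeatureTable,
    _anova_statsmodels,
    csa_summary,
    degradation_rate,
    differential_metabolites,
    metabolite_screen,
    normality_gate,
    p_from_r,
    pearson_two_tailed,
    two_way_anova_tukey,
)
from mitoclamp.synthetic import SynthConfig, gen_cohort, gen_feature_table


def _design(cell_values):
    rows = []
    for (sex, group), values in cell_values.items():
        rows += [{"sex": sex, "group": group, "value": v} for v in values]
    return pd.DataFrame(rows)


class TestNormalityGate:
    def test_constant_cell_is_undecidable_and_nonparametric(self):
        with pytest.warns(UserWarning, match="undecidable"):
            route = normality_gate({"a": np.full(8, 3.0), "b": np.random.default_rng(0).normal(size=8)})
        assert route == "nonparametric"

    def test_small_cell_is_undecidable(self):
        with pytest.warns(UserWarning):
            assert normality_gate({"a": np.array([1.0, 2.0])}) == "nonparametric"

    def test_gaussian_cells_mostly_parametric(self):
        rng = np.random.default_rng(0)
        hits = sum(
            normality_gate({"a": rng.normal(size=8), "b": rng.normal(size=8)}) == "parametric"
            for _ in range(100)
        )
        # two cells each tested at alpha=0.05 -> ~0.95^2 = 90% pass rate
        assert hits > 75

    def test_exponential_cells_mostly_nonparametric(self):
        rng = np.random.default_rng(0)
        hits = sum(
            normality_gate({"a": rng.exponential(size=12) ** 2}) == "nonparametric"
            for _ in range(60)
        )
        assert hits > 30


class TestTwoWayAnova:
    def test_balanced_closed_form_matches_hand_arithmetic(self):
        # cells (n=2): M/control {10,12}, M/ckd {7,9}, F/control {11,13}, F/ckd {8,10}
        # grand = 10; sex means M=9.5 F=10.5 -> SS_sex = 4*(0.25+0.25)=2
        # group means control=11.5 ckd=8.5 -> SS_group = 4*(1.5^2*2)=18
        # cell means 11,8,12,9 all equal sex+group offsets -> SS_inter = 0
        # SS_err = 8*(1) = 8 on 4 df -> MS_err = 2; F_group = 18/2 = 9
        df = _design(
            {
                ("M", "control"): [10.0, 12.0], ("M", "ckd"): [7.0, 9.0],
                ("F", "control"): [11.0, 13.0], ("F", "ckd"): [8.0, 10.0],
            }
        )
        res = two_way_anova_tukey(df)
        assert res.method == "closed_form_balanced"
        assert res.table.loc["sex", "sum_sq"] == pytest.approx(2.0)
        assert res.table.loc["group", "sum_sq"] == pytest.approx(18.0)
        assert res.table.loc["sex:group", "sum_sq"] == pytest.approx(0.0, abs=1e-12)
        assert res.table.loc["group", "F"] == pytest.approx(9.0)
        assert res.tukey is None

    def test_closed_form_agrees_with_statsmodels(self, rng):
        df = _design(
            {
                (s, g): rng.normal(10.0, 2.0, size=5)
                for s in ("M", "F") for g in ("control", "ckd")
            }
        )
        fast = two_way_anova_tukey(df).table
        slow = _anova_statsmodels(df, ss_type=2)
        for term in ("sex", "group", "sex:group"):
            assert fast.loc[term, "F"] == pytest.approx(slow.loc[term, "F"], rel=1e-8)
            assert fast.loc[term, "p"] == pytest.approx(slow.loc[term, "p"], rel=1e-8)

    def test_all_equal_data_gives_zero_f_and_no_tukey(self):
        df = _design({(s, g): [5.0, 5.0, 5.0] for s in "MF" for g in ("control", "ckd")})
        res = two_way_anova_tukey(df)
        assert res.table.loc["group", "F"] == 0.0
        assert res.tukey is None

    def test_tukey_emitted_only_on_significant_interaction(self, rng):
        base = {
            ("M", "control"): rng.normal(10, 0.5, 6), ("F", "control"): rng.normal(10, 0.5, 6),
            ("F", "ckd"): rng.normal(10, 0.5, 6),
        }
        crossed = {**base, ("M", "ckd"): rng.normal(20, 0.5, 6)}
        res = two_way_anova_tukey(_design(crossed))
        assert res.p_interaction < 0.05
        assert res.tukey is not None and len(res.tukey) == 6  # 4 cells -> 6 pairs
        flat = {**base, ("M", "ckd"): rng.normal(10, 0.5, 6)}
        assert two_way_anova_tukey(_design(flat)).tukey is None

    def test_empty_cell_rejected(self):
        df = _design({("M", "control"): [1.0, 2.0], ("M", "ckd"): [1.0, 2.0]})
        with pytest.raises(DesignError):
            two_way_anova_tukey(df)


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson_two_tailed(x, x)[0] == pytest.approx(1.0)
        r, p = pearson_two_tailed(x, -2.0 * x + 3.0)
        assert r == pytest.approx(-1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_printed_r_p_pair_is_consistent_at_df_35(self):
        """r = 0.5249 with 35 df corresponds to a two-tailed P of ~0.00084."""
        assert p_from_r(0.5249, 37) == pytest.approx(0.00084, abs=5e-5)

    def test_matches_scipy_on_random_data(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        r, p = pearson_two_tailed(x, y)
        ref = sps.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_two_tailed(np.ones(5), np.arange(5.0))

    def test_too_short_rejected(self):
        with pytest.raises(InvalidInputError):
            pearson_two_tailed([1.0, 2.0], [3.0, 4.0])


def _feature_table(intensities: dict, meta: dict, ion_mode="positive"):
    # intensities: sample -> {feature: value}; DataFrame gives features x samples
    return FeatureTable(
        intensities=pd.DataFrame(intensities),
        sample_meta=pd.DataFrame(meta, index=["sex", "group"]).T,
        ion_mode=ion_mode,
    )


class TestMetaboliteScreen:
    def test_feature_equal_to_conductance_flagged_positive(self):
        cond = pd.Series({"s1": 10.0, "s2": 20.0, "s3": 30.0, "s4": 40.0})
        table = _feature_table(
            {s: {"f1": cond[s]} for s in cond.index},
            {s: ("M", "control") for s in cond.index},
        )
        res = metabolite_screen(table, cond)
        row = res.frame.iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["flag"] == "positive"

    def test_sample_mismatch_rejected(self):
        cond = pd.Series({"s1": 1.0, "s2": 2.0, "s9": 3.0})
        table = _feature_table(
            {s: {"f1": 1.0} for s in ("s1", "s2", "s3")},
            {s: ("M", "control") for s in ("s1", "s2", "s3")},
        )
        with pytest.raises(AlignmentError):
            metabolite_screen(table, cond)

    def test_planted_correlates_recovered_with_correct_sign(self):
        config = SynthConfig(seed=21, n_per_cell=4, n_features=60,
                             n_group_shift=0, n_conductance_correlates=10)
        cohort, _ = gen_cohort(config)
        table, truth = gen_feature_table(config, cohort)
        cond = cohort.set_index("animal")["conductance_pyruvate_malate"]
        res = metabolite_screen(table, cond)
        planted = truth["conductance_correlates"]
        hits = 0
        for fid, sign in planted.items():
            sub = res.frame[res.frame["feature_id"] == fid]
            expected = "positive" if sign > 0 else "negative"
            hits += int((sub["flag"] == expected).all())
        assert hits >= 0.8 * len(planted)

    def test_negative_intensities_rejected(self):
        with pytest.raises(InvalidInputError):
            _feature_table(
                {"s1": {"f1": -1.0}, "s2": {"f1": 1.0}, "s3": {"f1": 1.0}},
                {s: ("M", "control") for s in ("s1", "s2", "s3")},
            )


class TestDifferentialMetabolites:
    def test_two_group_f_equals_squared_t(self, rng):
        meta = {f"s{i}": ("M", "control" if i < 5 else "ckd") for i in range(10)}
        intens = {s: {f"f{j}": float(rng.lognormal(3, 0.4)) for j in range(8)} for s in meta}
        table = _feature_table(intens, meta)
        res = differential_metabolites(table)
        frame = res["frame"]
        X = table.intensities
        g1 = [s for s in meta if meta[s][1] == "control"]
        g2 = [s for s in meta if meta[s][1] == "ckd"]
        for fid in X.index:
            t_ref = sps.ttest_ind(X.loc[fid, g1], X.loc[fid, g2])
            f_ref = sps.f_oneway(X.loc[fid, g1], X.loc[fid, g2])
            p = frame[frame["feature_id"] == fid]["p"].iloc[0]
            assert p == pytest.approx(t_ref.pvalue, rel=1e-8)
            assert p == pytest.approx(f_ref.pvalue, rel=1e-8)

    def test_single_group_rejected(self):
        meta = {f"s{i}": ("M", "control") for i in range(4)}
        table = _feature_table({s: {"f1": 1.0 + i} for i, s in enumerate(meta)}, meta)
        with pytest.raises(DesignError):
            differential_metabolites(table)


class TestMusclePhenotypes:
    def test_degradation_rate_arithmetic(self):
        assert degradation_rate(30.0, 10.0, 3.0) == pytest.approx(1.0)
        assert degradation_rate(0.0, 10.0, 3.0) == 0.0
        with pytest.raises(InvalidInputError):
            degradation_rate(30.0, 0.0, 3.0)

    def test_identical_fibers_occupy_single_bin(self):
        summary = csa_summary(
            {"a1": np.full(40, 1500.0)}, bin_edges=np.linspace(0, 3000, 11)
        )
        hist = summary["histograms"].loc["a1"].to_numpy()
        assert summary["mean_csa"]["a1"] == pytest.approx(1500.0)
        assert np.count_nonzero(hist) == 1

    def test_atrophied_group_shifts_left(self):
        rng = np.random.default_rng(3)
        fibers = {
            "ctl": rng.lognormal(7.5, 0.3, 300),
            "ckd": rng.lognormal(7.5, 0.3, 300) * 0.85,
        }
        summary = csa_summary(fibers, np.linspace(0, 6000, 25))
        assert summary["mean_csa"]["ckd"] < summary["mean_csa"]["ctl"]

    def test_csa_gfr_correlation_reported(self):
        rng = np.random.default_rng(4)
        animals = [f"a{i}" for i in range(8)]
        gfr = pd.Series(rng.uniform(50, 250, 8), index=animals)
        fibers = {a: np.full(40, 800.0 + 5.0 * gfr[a]) for a in animals}
        summary = csa_summary(fibers, np.linspace(0, 6000, 25), gfr_by_animal=gfr)
        assert summary["csa_vs_gfr"]["r"] == pytest.approx(1.0, abs=1e-9)

    def test_empty_animal_flagged_missing(self):
        summary = csa_summary(
            {"a1": np.full(40, 1500.0), "a2": np.empty(0)}, np.linspace(0, 3000, 11)
        )
        assert summary["missing_animals"] == ["a2"]
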