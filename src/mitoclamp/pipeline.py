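"""End-to-end orchestration of the synthetic mitochondrial phenotyping run.

``run_pipeline`` generates a full synthetic study from one seed and pushes
it through every analysis stage in dependency order: thermodynamics ->
respirometry + QC -> conductance -> electron leak -> enzyme panel ->
renal function -> statistics.  The run report is deterministic given
(config, seed): rerunning writes byte-identical JSON.  No stage imputes;
every excluded sample carries its triggering rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .constants import (
    ALPHA,
    CV_MAX_PERCENT,
    CYTC_THRESHOLD_PERCENT,
    DIFFERENTIAL_ALPHA,
    MIN_WINDOW_S,
    SCREEN_ALPHA,
)
from .conductance import (
    ForceFlowCurve,
    conductance_group_summary,
    fit_force_flow,
    results_to_frame,
)
from .enzyme_kinetics import KineticTrace, dehydrogenase_panel
from .errors import ConfigError
from .renal import compute_gfr, fit_two_phase
from .respirometry import adp_capacity, cytochrome_c_test, segment_steady_states
from .ros_leak import compute_jh2o2, electron_leak
from .stats_screens import (
    csa_summary,
    differential_metabolites,
    kruskal_wallis,
    metabolite_screen,
    normality_gate,
    two_way_anova_tukey,
)
from .synthetic import (
    SUBSTRATES,
    SynthConfig,
    default_schedule,
    gen_capacity_trace,
    gen_clearance,
    gen_cohort,
    gen_feature_table,
    gen_force_flow_curve,
    gen_kinetic_trace_arrays,
    gen_oxygraph,
    gen_standard_curve,
)
from .thermo import default_constants


@dataclass
class RunConfig:
    """Schema-validated run options; unknown keys are rejected."""

    seed: int = 0
    outdir: str | None = None
    n_per_cell: int = 6
    qc_threshold_percent: float = CYTC_THRESHOLD_PERCENT
    min_window_s: float = MIN_WINDOW_S
    cv_max_percent: float = CV_MAX_PERCENT
    ss_type: int = 2
    alpha: float = ALPHA
    screen_alpha: float = SCREEN_ALPHA
    differential_alpha: float = DIFFERENTIAL_ALPHA

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        try:
            cfg = cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        if cfg.n_per_cell < 2:
            raise ConfigError("n_per_cell must be >= 2")
        for name in ("alpha", "screen_alpha", "differential_alpha"):
            if not 0 < getattr(cfg, name) < 1:
                raise ConfigError(f"{name} must be in (0, 1)")
        if cfg.qc_threshold_percent < 0:
            raise ConfigError("qc_threshold_percent must be >= 0")
        return cfg


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="list"))
    if isinstance(obj, pd.Series):
        return _jsonify(obj.to_dict())
    return obj


def _phenotype_stats(cohort: pd.DataFrame, column: str, alpha: float, ss_type: int) -> dict:
    cells = {
        f"{sex}:{group}": sub[column].to_numpy(dtype=float)
        for (sex, group), sub in cohort.groupby(["sex", "group"])
    }
    route = normality_gate(cells, alpha=alpha)
    entry: dict = {"phenotype": column, "route": route}
    if route == "parametric":
        res = two_way_anova_tukey(
            cohort.rename(columns={column: "value"})[["value", "sex", "group"]],
            alpha=alpha,
            ss_type=ss_type,
        )
        entry.update(
            p_group=res.p_group,
            p_sex=res.p_sex,
            p_interaction=res.p_interaction,
            ss_type=res.ss_type,
            tukey=None if res.tukey is None else res.tukey.to_dict(orient="list"),
        )
    else:
        h, p = kruskal_wallis(cells)
        entry.update(kruskal_h=h, kruskal_p=p)
    return entry


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic study and return the report dict.

    When ``config.outdir`` is set, stage tables are written as CSV and the
    summary as ``report.json`` there.
    """
    synth = SynthConfig(seed=config.seed, n_per_cell=config.n_per_cell)
    rng = np.random.default_rng(config.seed)
    constants = default_constants()
    schedule = default_schedule()

    report: dict = {
        "provenance": {
            "package": "mitoclamp",
            "version": __version__,
            "seed": config.seed,
            "thermo_constants": {
                "label": constants.source_label,
                "K_CK_apparent": constants.K_CK_apparent,
                "dG0_ATP_kcal_mol": constants.dG0_ATP,
                "temperature_K": constants.temperature,
            },
            "qc_threshold_percent": config.qc_threshold_percent,
            "steady_state_policy": {
                "min_window_s": config.min_window_s,
                "cv_max_percent": config.cv_max_percent,
            },
            "alpha": config.alpha,
            "screen_alpha": config.screen_alpha,
            "differential_alpha": config.differential_alpha,
            "ss_type": config.ss_type,
        }
    }

    # --- cohort -----------------------------------------------------------
    cohort, truth = gen_cohort(synth)

    # --- respirometry: capacity traces + cytochrome-c QC ------------------
    exclusions = []
    capacity_rows = []
    for _, row in cohort.iterrows():
        fail = rng.random() < synth.cytc_fail_fraction
        response = synth.cytc_fail_response if fail else synth.cytc_pass_response
        trace = gen_capacity_trace(
            state2_jo2=row["state3_jo2"] / 8.0,
            state3_jo2=row["state3_jo2"],
            config=synth,
            seed=int(rng.integers(2**31)),
            cytc_response_percent=response,
            sample_id=row["animal"],
            group=row["group"],
            sex=row["sex"],
            substrate_label="pyruvate_malate",
        )
        cap = adp_capacity(trace, config.min_window_s, config.cv_max_percent)
        fluxes = segment_steady_states(trace, config.min_window_s, config.cv_max_percent)
        post_cytc = fluxes[-1]
        qc = cytochrome_c_test(
            cap.state3.jo2, post_cytc.jo2, config.qc_threshold_percent
        )
        if not qc.passed:
            exclusions.append(
                {
                    "animal": row["animal"],
                    "rule": f"cytochrome-c response {qc.cytc_response_percent:.1f}% "
                    f"> {qc.threshold_percent:g}%",
                }
            )
        capacity_rows.append(
            {
                "animal": row["animal"],
                "sex": row["sex"],
                "group": row["group"],
                "state3_jo2": cap.state3.jo2,
                "state2_jo2": cap.baseline.jo2,
                "state3_state2_ratio": cap.ratio,
                "cytc_response_percent": qc.cytc_response_percent,
                "qc_pass": qc.passed,
            }
        )
    capacity = pd.DataFrame(capacity_rows)
    included = capacity[capacity["qc_pass"]]
    report["qc"] = {
        "excluded": exclusions,
        "n_excluded": len(exclusions),
        "n_total": len(capacity),
    }
    cap_change = {}
    for sex, sub in included.groupby("sex"):
        means = sub.groupby("group")["state3_jo2"].mean()
        if {"control", "ckd"} <= set(means.index):
            cap_change[sex] = float(
                (means["ckd"] - means["control"]) / means["control"] * 100.0
            )
    report["capacity"] = {
        "table": capacity,
        "percent_change_state3_by_sex": cap_change,
    }

    # --- conductance ------------------------------------------------------
    # one full oxygraph trace per animal for the first substrate (exercises
    # steady-state extraction); direct force-flow points for the rest
    fits = []
    for _, row in cohort.iterrows():
        for si, substrate in enumerate(SUBSTRATES):
            truth_g = truth["animals"][row["animal"]]["conductance"][substrate]
            meta = dict(
                sample_id=row["animal"], group=row["group"], sex=row["sex"],
                substrate_label=substrate,
            )
            if si == 0:
                trace, _tr = gen_oxygraph(
                    truth_g, schedule, synth, seed=int(rng.integers(2**31)), **meta
                )
                fluxes = segment_steady_states(
                    trace, config.min_window_s, config.cv_max_percent
                )
                pcr_fluxes = [f for f in fluxes if f.event_label.startswith("PCr_")]
                pairs = [
                    (dg, f.jo2)
                    for dg, f in zip(schedule.dG_values, pcr_fluxes)
                    if f.ok
                ]
                curve = ForceFlowCurve(
                    dg_atp=np.asarray([p[0] for p in pairs]),
                    jo2=np.asarray([p[1] for p in pairs]),
                    **meta,
                )
            else:
                curve = gen_force_flow_curve(truth_g, schedule, synth, rng, **meta)
            fits.append(fit_force_flow(curve))
    cond_table = results_to_frame(fits)
    cond_summary = conductance_group_summary(cond_table)
    report["conductance"] = {"per_sample": cond_table, "group_summary": cond_summary}

    # --- electron leak ----------------------------------------------------
    aur_curve = gen_standard_curve(
        slope_truth=12.0, seed=int(rng.integers(2**31)), noise_sd=2.0
    )
    leak_rows = []
    protein_mg = 0.020
    for _, row in cohort.iterrows():
        jo2_ref = row["state3_jo2"] / 10.0  # resting-demand JO2 reference
        jh2o2_truth = row["leak_percent"] / 100.0 * jo2_ref * 60.0
        well_slope = jh2o2_truth * protein_mg * aur_curve.slope
        flux = compute_jh2o2(
            well_slope, aur_curve, protein_mg,
            condition="resting_clamp", substrate_label="pyruvate_malate",
        )
        leak = electron_leak(flux, jo2_ref, "resting_clamp", "pyruvate_malate")
        leak_rows.append(
            {
                "animal": row["animal"], "sex": row["sex"], "group": row["group"],
                "jh2o2_pmol_min_mg": flux.jh2o2,
                "jo2_pmol_s_mg": jo2_ref,
                "percent_leak": leak.percent_leak,
            }
        )
    leak_table = pd.DataFrame(leak_rows)
    report["leak"] = {
        "table": leak_table,
        "standard_curve_r2": aur_curve.r_squared,
    }

    # --- enzyme panel -----------------------------------------------------
    records = []
    for _, row in cohort.iterrows():
        for assay, mean in synth.enzyme_control_mean.items():
            eff = synth.enzyme_ckd_effects.get(assay, 1.0) if row["group"] == "ckd" else 1.0
            rate_truth = mean * eff * float(
                np.exp(rng.normal(0.0, synth.enzyme_cv) - synth.enzyme_cv**2 / 2)
            )
            # signal in AU with a 0.01 AU-per-nmol gain; calibrated back out
            t, y = gen_kinetic_trace_arrays(
                rate_truth * 0.01 * 0.005, seed=int(rng.integers(2**31)),
                duration_s=60.0, dt_s=2.0,
            )
            records.append(
                {
                    "animal": row["animal"], "sex": row["sex"], "group": row["group"],
                    "assay": assay,
                    "trace": KineticTrace(
                        time_s=t, signal=y, assay_label=assay, protein_mg=0.005
                    ),
                    "calibration": None,
                }
            )
    panel = dehydrogenase_panel(records)
    # uncalibrated AU/min/mg with a fixed known gain -> convert to nmol/min/mg
    panel["rate"] = panel["rate"] / 0.01
    panel["units"] = "nmol/min/mg"
    enzyme_stats = {}
    for assay, sub in panel.groupby("assay"):
        res = _phenotype_stats(
            sub.rename(columns={"rate": assay}), assay, config.alpha, config.ss_type
        )
        enzyme_stats[assay] = {
            k: res.get(k) for k in ("route", "p_group", "kruskal_p") if k in res
        }
    report["enzymes"] = {"table": panel, "stats": enzyme_stats}

    # --- renal function ---------------------------------------------------
    gfr_rows = []
    for _, row in cohort.iterrows():
        truth_gfr = truth["animals"][row["animal"]]["gfr"]
        curve = gen_clearance(
            truth_gfr, dose=50000.0, seed=int(rng.integers(2**31)),
            animal_id=row["animal"], body_weight_g=row["body_weight_g"],
        )
        fit = fit_two_phase(curve)
        res = compute_gfr(fit, curve.dose, row["body_weight_g"])
        gfr_rows.append(
            {
                "animal": row["animal"], "sex": row["sex"], "group": row["group"],
                "gfr_ul_min": res.gfr,
                "gfr_ul_min_g": res.gfr_per_gram,
                "fallback_single": fit.fallback_single,
            }
        )
    gfr_table = pd.DataFrame(gfr_rows)
    report["renal"] = {
        "table": gfr_table,
        "group_means": gfr_table.groupby("group")["gfr_ul_min"].mean(),
    }

    # --- statistics -------------------------------------------------------
    phenotype_cols = [
        "state3_jo2", "conductance_pyruvate_malate", "gfr_ul_min",
        "degradation_rate", "soleus_mg",
    ]
    stats_entries = [
        _phenotype_stats(cohort, col, config.alpha, config.ss_type)
        for col in phenotype_cols
    ]
    deg = cohort.groupby("group")["degradation_rate"].mean()
    report["stats"] = {
        "phenotypes": stats_entries,
        "degradation_percent_change": float(
            (deg["ckd"] - deg["control"]) / deg["control"] * 100.0
        ),
    }

    # --- metabolite screens -----------------------------------------------
    cond_series = cohort.set_index("animal")["conductance_pyruvate_malate"]
    screens = {}
    diffs = {}
    for mode_i, ion_mode in enumerate(("positive", "negative")):
        table, ftruth = gen_feature_table(synth, cohort, ion_mode, seed_offset=mode_i)
        screen = metabolite_screen(table, cond_series, alpha=config.screen_alpha)
        counts = screen.frame.groupby(["sex", "flag"]).size()
        screens[ion_mode] = {
            "flag_counts": {f"{s}:{f}": int(c) for (s, f), c in counts.items()},
            "expected_false_flags": screen.expected_false_flags,
        }
        diff = differential_metabolites(table, alpha=config.differential_alpha)
        diffs[ion_mode] = {
            sex: info["count"] for sex, info in diff["by_sex"].items()
        }
    report["metabolites"] = {"screen": screens, "differential_counts": diffs}

    # --- CSA --------------------------------------------------------------
    fibers = {}
    for _, row in cohort.iterrows():
        mu = np.log(row["mean_csa_um2"]) - synth.csa_log_sd**2 / 2.0
        child = np.random.default_rng(int(rng.integers(2**31)))
        fibers[row["animal"]] = child.lognormal(mu, synth.csa_log_sd, synth.fibers_per_animal)
    edges = np.linspace(0.0, 6000.0, 25)
    csa = csa_summary(
        fibers, edges, gfr_by_animal=gfr_table.set_index("animal")["gfr_ul_min"]
    )
    report["csa"] = {
        "mean_by_group": pd.Series(
            {g: float(sub["mean_csa_um2"].mean()) for g, sub in cohort.groupby("group")}
        ),
        "csa_vs_gfr": csa.get("csa_vs_gfr"),
    }

    report["cohort"] = cohort
    if config.outdir:
        write_report(report, config.outdir)
    return report


def report_to_json(report: dict) -> str:
    """Deterministic JSON rendering of the (summary part of the) report."""
    summary = {
        k: _jsonify(v)
        for k, v in report.items()
    }
    return json.dumps(summary, sort_keys=True, indent=2)


def write_report(report: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report["cohort"].to_csv(outdir / "cohort.csv", index=False)
    report["conductance"]["per_sample"].to_csv(outdir / "conductance.csv", index=False)
    report["conductance"]["group_summary"].to_csv(
        outdir / "conductance_summary.csv", index=False
    )
    report["capacity"]["table"].to_csv(outdir / "capacity.csv", index=False)
    report["leak"]["table"].to_csv(outdir / "leak.csv", index=False)
    report["enzymes"]["table"].to_csv(outdir / "enzyme_activities.csv", index=False)
    report["renal"]["table"].to_csv(outdir / "gfr.csv", index=False)
    (outdir / "report.json").write_text(report_to_json(report))
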