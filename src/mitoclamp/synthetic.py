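"""Seeded generators for every input the pipeline consumes.

The generators emulate the study conditions of an adenine-CKD mouse
cohort: per-sex/group conductance and capacity deficits, a severe GFR
deficit, increased protein degradation, myofiber atrophy, and metabolite
feature tables with planted group shifts and planted conductance
correlates.  Every generator is a pure function of (config, seed) and
retains its ground truth so downstream recovery tests can score the
analysis stages against what was actually planted.

Default effect sizes are the phenotype the pipeline is built to detect:
CKD conductance multiplier 0.70 (a ~30% deficit), state-3 capacity
multipliers 0.78 (male, ~22%) and 0.86 (female, ~14%), and a 1.25x
protein-degradation effect (~25% increase).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .conductance import ForceFlowCurve
from .errors import ConfigError
from .renal import ClearanceCurve
from .respirometry import OxygraphTrace
from .ros_leak import StandardCurve, fit_standard_curve
from .stats_screens import FeatureTable
from .thermo import ClampState, TitrationSchedule, default_constants, design_titration

SUBSTRATES = (
    "pyruvate_malate",
    "glutamate_malate",
    "succinate_rotenone",
    "octanoyl_malate",
)

#: default cumulative-PCr titration (mM); spans roughly -13.1 to -15.24
#: kcal/mol with the shipped constants
DEFAULT_PCR_STEPS_MM = (1.0, 3.0, 6.0, 9.0, 12.0, 15.0, 21.0, 30.0)


@dataclass
class SynthConfig:
    """Study-condition knobs for the whole synthetic cohort."""

    seed: int = 0
    n_per_cell: int = 6  # animals per sex x group

    # conductance truths: control mean (pmol s^-1 mg^-1 per kcal/mol) per
    # substrate, between-animal CV, and the CKD multiplier
    conductance_control_mean: dict = field(
        default_factory=lambda: {
            "pyruvate_malate": 2000.0,
            "glutamate_malate": 1800.0,
            "succinate_rotenone": 2600.0,
            "octanoyl_malate": 1200.0,
        }
    )
    conductance_cv: float = 0.10
    ckd_conductance_multiplier: float = 0.70

    # ADP-stimulated maximal capacity (state 3), pmol s^-1 mg^-1
    state3_control_mean: float = 8000.0
    state3_cv: float = 0.10
    state3_male_multiplier: float = 0.78
    state3_female_multiplier: float = 0.86

    # renal function
    gfr_control_mean_ul_min: float = 250.0
    gfr_ckd_mean_ul_min: float = 80.0
    gfr_cv: float = 0.12

    # electron leak (%), equal across groups by default (the null the
    # resting-demand comparison is expected to show)
    leak_mean_percent: float = 1.0
    leak_cv: float = 0.15

    # protein degradation, nmol tyrosine h^-1 mg^-1
    degradation_control_mean: float = 0.20
    degradation_cv: float = 0.10
    degradation_effect: float = 1.25

    # myofiber CSA (um^2), log-normal; CKD multiplier on the median
    csa_log_mean: float = 7.5
    csa_log_sd: float = 0.35
    csa_ckd_multiplier: float = 0.85
    fibers_per_animal: int = 200

    # oxygraph trace synthesis
    plateau_s: float = 60.0
    sampling_hz: float = 1.0
    o2_noise_uM: float = 0.005
    o2_start_uM: float = 220.0
    jo2_floor: float = 400.0  # flux at the most negative dG step
    flux_noise_cv: float = 0.03

    # enzyme activities, nmol min^-1 mg^-1 control means and CKD multipliers
    # (matrix-dehydrogenase deficit concentrated in PDH/AKGDH, BCKDH milder;
    # ETS complexes and citrate synthase unaffected)
    enzyme_control_mean: dict = field(
        default_factory=lambda: {
            "PDH": 300.0, "GDH": 450.0, "MDH": 2500.0, "AKGDH": 180.0,
            "BCKDH": 90.0, "ICDH": 600.0, "malic_enzyme": 120.0,
            "CI": 800.0, "CII": 350.0, "CIII": 900.0, "CIV": 1200.0,
            "CV": 700.0, "citrate_synthase": 1000.0,
        }
    )
    enzyme_ckd_effects: dict = field(
        default_factory=lambda: {"PDH": 0.65, "AKGDH": 0.73, "BCKDH": 0.85}
    )
    enzyme_cv: float = 0.10

    # fraction of capacity runs given a failing (>15%) cytochrome-c response
    cytc_fail_fraction: float = 0.08
    cytc_pass_response: float = 5.0
    cytc_fail_response: float = 25.0

    # feature tables
    n_features: int = 300
    n_group_shift: int = 30
    group_shift_fold: float = 2.0
    n_conductance_correlates: int = 20
    correlate_abs_r: float = 0.9
    intensity_log_mean: float = 12.0
    intensity_log_sd: float = 0.8

    def validate(self) -> None:
        if self.n_per_cell < 2:
            raise ConfigError("n_per_cell must be >= 2")
        for name in (
            "ckd_conductance_multiplier",
            "state3_male_multiplier",
            "state3_female_multiplier",
            "degradation_effect",
            "csa_ckd_multiplier",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 <= self.correlate_abs_r <= 1:
            raise ConfigError("correlate_abs_r must be in [0, 1]")


def default_schedule(substrate_label: str = "") -> TitrationSchedule:
    start = ClampState(atp_mM=5.0, pcr_mM=1.0, cr_mM=5.0, pi_mM=10.0)
    return design_titration(
        start, list(DEFAULT_PCR_STEPS_MM), default_constants(), substrate_label
    )


def _lognoise(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Multiplicative noise with unit mean and the given CV."""
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(-sigma * sigma / 2.0, sigma, size)


def gen_cohort(config: SynthConfig) -> tuple[pd.DataFrame, dict]:
    """Animal-level cohort table plus the per-animal truth record.

    One row per animal: sex, group, body/muscle weights, GFR, BUN,
    state-3 capacity, conductance per substrate, leak, degradation rate,
    and mean CSA.  A shared per-animal severity latent couples the GFR
    deficit to the mitochondrial deficit in CKD animals, which is what
    makes conductance-vs-GFR (and planted metabolite) correlations
    recoverable.  The truth record carries the imposed multipliers and
    per-animal conductance truths for recovery tests.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    truth_animals = {}
    i = 0
    for sex in ("M", "F"):
        for group in ("control", "ckd"):
            for _ in range(config.n_per_cell):
                animal = f"{sex}{group[:3].upper()}{i:03d}"
                i += 1
                severity = rng.normal(0.0, 1.0)  # shared CKD-severity latent
                is_ckd = group == "ckd"

                def scale(cv: float, share: float = 0.6) -> float:
                    eps = share * severity + np.sqrt(1 - share**2) * rng.normal()
                    return float(np.exp(cv * eps - cv * cv / 2.0))

                cond_mult = config.ckd_conductance_multiplier if is_ckd else 1.0
                conds = {
                    s: config.conductance_control_mean[s] * cond_mult
                    * scale(config.conductance_cv)
                    for s in SUBSTRATES
                }
                s3_mult = 1.0
                if is_ckd:
                    s3_mult = (
                        config.state3_male_multiplier
                        if sex == "M"
                        else config.state3_female_multiplier
                    )
                state3 = config.state3_control_mean * s3_mult * scale(config.state3_cv)
                gfr_mean = (
                    config.gfr_ckd_mean_ul_min if is_ckd else config.gfr_control_mean_ul_min
                )
                gfr = gfr_mean * scale(config.gfr_cv)
                deg_mult = config.degradation_effect if is_ckd else 1.0
                deg = config.degradation_control_mean * deg_mult * float(
                    _lognoise(rng, config.degradation_cv)
                )
                csa_mult = config.csa_ckd_multiplier if is_ckd else 1.0
                mean_csa = float(
                    np.exp(config.csa_log_mean + config.csa_log_sd**2 / 2.0) * csa_mult
                    * _lognoise(rng, 0.05)
                )
                body = (27.0 if sex == "M" else 22.0) * (0.92 if is_ckd and sex == "M" else 1.0)
                body *= float(_lognoise(rng, 0.05))
                leak = config.leak_mean_percent * float(_lognoise(rng, config.leak_cv))
                bun = (85.0 if is_ckd and sex == "M" else 28.0 if not is_ckd else 38.0)
                bun *= float(_lognoise(rng, 0.12))
                row = {
                    "animal": animal,
                    "sex": sex,
                    "group": group,
                    "body_weight_g": body,
                    "soleus_mg": 9.5 * (0.88 if is_ckd else 1.0) * float(_lognoise(rng, 0.08)),
                    "gfr_ul_min": gfr,
                    "bun_mg_dl": bun,
                    "state3_jo2": state3,
                    "leak_percent": leak,
                    "degradation_rate": deg,
                    "mean_csa_um2": mean_csa,
                }
                for s in SUBSTRATES:
                    row[f"conductance_{s}"] = conds[s]
                rows.append(row)
                truth_animals[animal] = {
                    "severity": severity,
                    "conductance": conds,
                    "state3": state3,
                    "gfr": gfr,
                }
    cohort = pd.DataFrame(rows)
    truth = {
        "config": asdict(config),
        "imposed": {
            "conductance_multiplier": config.ckd_conductance_multiplier,
            "state3_male_multiplier": config.state3_male_multiplier,
            "state3_female_multiplier": config.state3_female_multiplier,
            "degradation_effect": config.degradation_effect,
        },
        "animals": truth_animals,
    }
    return cohort, truth


def force_flow_points(
    conductance_truth: float,
    schedule: TitrationSchedule,
    jo2_floor: float,
    noise_cv: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """True (dG, JO2) pairs for a titration: linear force-flow plus noise."""
    dg = np.asarray(schedule.dG_values)
    dg_min = dg.min()
    jo2 = jo2_floor + conductance_truth * (dg - dg_min)
    if noise_cv > 0:
        jo2 = jo2 * _lognoise(rng, noise_cv, size=len(jo2))
    return dg, jo2


def gen_force_flow_curve(
    conductance_truth: float,
    schedule: TitrationSchedule,
    config: SynthConfig,
    rng: np.random.Generator,
    **meta,
) -> ForceFlowCurve:
    dg, jo2 = force_flow_points(
        conductance_truth, schedule, config.jo2_floor, config.flux_noise_cv, rng
    )
    return ForceFlowCurve(dg_atp=dg, jo2=jo2, **meta)


def gen_oxygraph(
    conductance_truth: float,
    schedule: TitrationSchedule,
    config: SynthConfig,
    seed: int,
    cytc_response_percent: float | None = None,
    chamber_volume_mL: float = 2.0,
    protein_mg: float = 0.025,
    **meta,
) -> tuple[OxygraphTrace, dict]:
    """Piecewise-plateau O2 trace whose segment slopes encode the titration.

    Each PCr step contributes a plateau of constant flux
    ``jo2_floor + conductance * (dG - dG_min)`` (times multiplicative
    noise); an optional final cytochrome-c event raises the flux by the
    configured percentage.  Returns the trace and its truth record
    (per-step fluxes).
    """
    rng = np.random.default_rng(seed)
    dg, jo2_steps = force_flow_points(
        conductance_truth, schedule, config.jo2_floor, config.flux_noise_cv, rng
    )
    labels = [f"PCr_{s.pcr_mM:g}mM" for s in schedule.states]
    fluxes = list(jo2_steps)
    if cytc_response_percent is not None:
        labels.append("cytochrome_c")
        fluxes.append(fluxes[-1] * (1.0 + cytc_response_percent / 100.0))
    dt = 1.0 / config.sampling_hz
    n_per = int(round(config.plateau_s / dt))
    scale = chamber_volume_mL * 1000.0 / protein_mg  # jo2 -> uM/s slope factor
    t_all, o2_all, events = [], [], []
    t = 0.0
    o2 = config.o2_start_uM
    # short substrate-only lead-in so the first event has a preceding interval
    for _ in range(n_per // 2):
        t_all.append(t)
        o2_all.append(o2)
        t += dt
        o2 -= (config.jo2_floor / scale) * dt
    for label, flux in zip(labels, fluxes):
        events.append((t, label))
        slope = flux / scale  # uM/s decline
        for _ in range(n_per):
            t_all.append(t)
            o2_all.append(o2)
            t += dt
            o2 -= slope * dt
    o2_arr = np.asarray(o2_all)
    if config.o2_noise_uM > 0:
        o2_arr = o2_arr + rng.normal(0.0, config.o2_noise_uM, size=len(o2_arr))
    trace = OxygraphTrace(
        time_s=np.asarray(t_all),
        o2_uM=o2_arr,
        events=events,
        chamber_volume_mL=chamber_volume_mL,
        protein_mg=protein_mg,
        **meta,
    )
    truth = {"dg": dg.tolist(), "jo2_steps": list(map(float, jo2_steps)),
             "labels": labels, "conductance": conductance_truth}
    return trace, truth


def gen_capacity_trace(
    state2_jo2: float,
    state3_jo2: float,
    config: SynthConfig,
    seed: int,
    cytc_response_percent: float | None = None,
    chamber_volume_mL: float = 2.0,
    protein_mg: float = 0.025,
    **meta,
) -> OxygraphTrace:
    """Substrate baseline -> ADP bolus -> (optional) cytochrome c trace."""
    rng = np.random.default_rng(seed)
    dt = 1.0 / config.sampling_hz
    n_per = int(round(config.plateau_s / dt))
    scale = chamber_volume_mL * 1000.0 / protein_mg
    segments = [("substrate", state2_jo2), ("ADP", state3_jo2)]
    if cytc_response_percent is not None:
        segments.append(
            ("cytochrome_c", state3_jo2 * (1.0 + cytc_response_percent / 100.0))
        )
    t_all, o2_all, events = [], [], []
    t, o2 = 0.0, config.o2_start_uM
    for _ in range(n_per // 2):
        t_all.append(t)
        o2_all.append(o2)
        t += dt
    for label, flux in segments:
        events.append((t, label))
        for _ in range(n_per):
            t_all.append(t)
            o2_all.append(o2)
            t += dt
            o2 -= (flux / scale) * dt
    o2_arr = np.asarray(o2_all)
    if config.o2_noise_uM > 0:
        o2_arr = o2_arr + rng.normal(0.0, config.o2_noise_uM, size=len(o2_arr))
    return OxygraphTrace(
        time_s=np.asarray(t_all), o2_uM=o2_arr, events=events,
        chamber_volume_mL=chamber_volume_mL, protein_mg=protein_mg, **meta,
    )


DEFAULT_CLEARANCE_TIMES_MIN = (1.0, 3.0, 7.0, 10.0, 15.0, 25.0, 35.0, 55.0, 75.0)


def gen_clearance(
    gfr_truth: float,
    dose: float,
    seed: int,
    times_min=DEFAULT_CLEARANCE_TIMES_MIN,
    noise_cv: float = 0.05,
    fast_fraction: float = 0.7,
    alpha: float = 0.35,
    beta: float = 0.035,
    single_phase: bool = False,
    **meta,
) -> ClearanceCurve:
    """Biexponential clearance curve with AUC = dose/gfr by construction.

    ``fast_fraction`` is the share of the AUC carried by the fast
    (distribution) phase.  ``single_phase=True`` collapses the curve to a
    single exponential (exercises the fallback fit path).
    """
    auc = dose / gfr_truth
    if single_phase:
        A, B = auc * alpha, 0.0
    else:
        A = fast_fraction * auc * alpha
        B = (1.0 - fast_fraction) * auc * beta
    t = np.asarray(times_min, dtype=float)
    f = A * np.exp(-alpha * t) + B * np.exp(-beta * t)
    rng = np.random.default_rng(seed)
    if noise_cv > 0:
        f = f * _lognoise(rng, noise_cv, size=len(f))
    return ClearanceCurve(time_min=t, fluorescence=f, dose=dose, **meta)


def gen_standard_curve(
    slope_truth: float,
    seed: int,
    amounts=(0.0, 20.0, 40.0, 80.0, 160.0, 320.0),
    intercept: float = 50.0,
    noise_sd: float = 0.0,
) -> StandardCurve:
    rng = np.random.default_rng(seed)
    amounts = np.asarray(amounts, dtype=float)
    signals = intercept + slope_truth * amounts
    if noise_sd > 0:
        signals = signals + rng.normal(0.0, noise_sd, size=len(signals))
    return fit_standard_curve(amounts, signals)


def gen_kinetic_trace_arrays(
    rate_au_per_min: float,
    seed: int,
    duration_s: float = 120.0,
    dt_s: float = 2.0,
    signal0: float = 100.0,
    noise_sd: float = 0.0,
    saturating_tau_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear (or saturating-exponential) kinetic read.

    With ``saturating_tau_s`` the trace is signal0 + rate*tau*(1-exp(-t/tau)),
    whose initial slope is exactly ``rate_au_per_min``.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    rate_per_s = rate_au_per_min / 60.0
    if saturating_tau_s is None:
        y = signal0 + rate_per_s * t
    else:
        tau = saturating_tau_s
        y = signal0 + rate_per_s * tau * (1.0 - np.exp(-t / tau))
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(y))
    return t, y


def gen_feature_table(
    config: SynthConfig,
    cohort: pd.DataFrame,
    ion_mode: str = "positive",
    seed_offset: int = 0,
) -> tuple[FeatureTable, dict]:
    """Peak-intensity table with planted structure, per ion mode.

    Layout of feature ids: the first ``n_group_shift`` features carry a
    CKD fold change of ``group_shift_fold``; the next
    ``n_conductance_correlates`` are constructed within sex to correlate
    with each animal's (pyruvate/malate) conductance at ``correlate_abs_r``
    (alternating sign); the remainder are independent log-normal noise.
    The truth record lists the planted ids and their signs.
    """
    rng = np.random.default_rng(config.seed + 7919 * (seed_offset + 1))
    samples = cohort["animal"].tolist()
    n = len(samples)
    is_ckd = (cohort["group"] == "ckd").to_numpy()
    cond = cohort["conductance_pyruvate_malate"].to_numpy(dtype=float)
    sex = cohort["sex"].to_numpy()

    n_shift = config.n_group_shift
    n_corr = config.n_conductance_correlates
    X = np.empty((config.n_features, n))
    feature_ids = [f"{ion_mode[:3]}_f{j:04d}" for j in range(config.n_features)]
    base = rng.lognormal(config.intensity_log_mean, config.intensity_log_sd,
                         size=config.n_features)
    r_target = config.correlate_abs_r
    corr_signs = {}
    for j in range(config.n_features):
        noise = _lognoise(rng, 0.25, size=n)
        if j < n_shift:
            fold = np.where(is_ckd, config.group_shift_fold, 1.0)
            X[j] = base[j] * fold * noise
        elif j < n_shift + n_corr:
            sign = 1.0 if (j - n_shift) % 2 == 0 else -1.0
            corr_signs[feature_ids[j]] = int(sign)
            row = np.empty(n)
            for s in ("M", "F"):
                m = sex == s
                z = (cond[m] - cond[m].mean()) / cond[m].std()
                eps = rng.normal(size=m.sum())
                eps -= eps.mean()
                if eps.std() > 0:
                    eps /= eps.std()
                # exact in-sample correlation r_target (up to intensity floor)
                latent = sign * (r_target * z + np.sqrt(1 - r_target**2) * eps)
                row[m] = base[j] * (1.0 + 0.2 * latent)
            X[j] = np.clip(row, base[j] * 1e-3, None)
        else:
            X[j] = base[j] * noise
    intensities = pd.DataFrame(X, index=feature_ids, columns=samples)
    meta = cohort.set_index("animal")[["sex", "group"]]
    table = FeatureTable(intensities=intensities, sample_meta=meta, ion_mode=ion_mode)
    truth = {
        "group_shift_features": feature_ids[:n_shift],
        "conductance_correlates": corr_signs,
    }
    return table, truth
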