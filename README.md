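# mitoclamp

Comprehensive mitochondrial phenotyping for skeletal muscle, built around
the creatine-kinase (CK) energetic clamp. The package is aimed at muscle
and renal physiologists analyzing isolated-mitochondria experiments from
rodent chronic kidney disease (CKD) models — or any study that titrates
extramitochondrial energy demand and needs the downstream bookkeeping done
reproducibly: oxygraph steady states, OXPHOS conductance, electron leak,
calibrated enzyme flux, FITC-inulin GFR, and the sex × group statistical
workflow, including untargeted-metabolomics screens against mitochondrial
function.

## The models at the core

**CK-clamp thermodynamics.** Creatine kinase couples ATP/ADP to
PCr/Cr, so a chamber with excess CK pins the free energy of ATP
hydrolysis at

ΔG_ATP = ΔG°′_ATP + RT·ln( [Cr][Pi] / (K′_CK·[PCr]) )

Titrating PCr upward makes ΔG_ATP more negative — lower energy demand.
The shipped apparent constants (K′_CK = 177, ΔG°′_ATP = −8.11 kcal/mol,
pH ~7.1, 37 °C, Mg-containing buffer Z) place the canonical resting
composition (ATP 5, Cr 5, PCr 30, Pi 10 mM) at −15.24 kcal/mol.

**OXPHOS conductance.** Steady-state oxygen flux *J*O₂ (pmol O₂·s⁻¹·mg⁻¹,
extracted from annotated oxygraph traces as −d[O₂]/dt × volume ÷ protein)
falls linearly as ΔG_ATP falls. The slope of the per-sample OLS line of
*J*O₂ on ΔG_ATP is the conductance of the energy-transduction system;
group comparisons are made on per-animal slopes. Samples whose *J*O₂
rises by more than 15% on cytochrome-c addition are excluded
(outer-membrane damage).

**Electron leak.** Amplex-UltraRed fluorescence rates are calibrated to
*J*H₂O₂ (pmol·min⁻¹·mg⁻¹) by a standard curve; percentage electron leak is
(*J*H₂O₂/*J*O₂) × 100 with explicit per-minute → per-second harmonization,
under matched substrate and demand (state 2 or the −15.24 kcal/mol resting
clamp). Succinate leak is never computed (rotenone mismatch between the
paired assays).

**Renal function.** Blood FITC-inulin decays as
F(t) = A·e^(−αt) + B·e^(−βt); GFR = dose / (A/α + B/β).

**Statistics.** Shapiro-Wilk per-cell normality gates phenotypes into
two-way (sex × group) ANOVA — Tukey pairwise only when the interaction is
significant — or Kruskal-Wallis. Metabolite feature tables are screened
per sex with two-tailed Pearson correlations against conductance at an
unadjusted P < 0.1, and for within-sex differential abundance at P < 0.05.

All of it is exercised end to end on seeded synthetic cohorts whose
planted truths (conductance deficit ×0.70, male/female state-3 deficits
×0.78/×0.86, degradation effect ×1.25, GFR deficit, planted metabolite
correlates) are retained for recovery testing.

## Worked example

```python
import numpy as np
from mitoclamp import SynthConfig, fit_force_flow
from mitoclamp.synthetic import default_schedule, gen_force_flow_curve

sched = default_schedule()          # PCr 1 -> 30 mM
print(sched.to_frame().tail(1))
#  step  PCr_added_mM  PCr_total_mM  dG_ATP_kcal_mol
#     8           9.0          30.0       -15.242852

rng = np.random.default_rng(7)
curve = gen_force_flow_curve(2000.0, sched, SynthConfig(seed=7), rng)
res = fit_force_flow(curve)
print(res.slope, res.r_squared)
# 2005.99 0.99964
```

The titration's final step sits at −15.24 kcal/mol (resting demand), and
a force-flow curve generated with a true conductance of 2000
pmol·s⁻¹·mg⁻¹ per kcal/mol under 3% flux noise is fit back to within 0.3%
with r² ≈ 1.

The same from the shell, then a full synthetic study:

```sh
$ mitoclamp thermo dg --pcr 30
dG_ATP = -15.243 kcal/mol

$ mitoclamp run --seed 17
sex          substrate  ...  percent_change
  F    pyruvate_malate  ...      -29.869406
  M    pyruvate_malate  ...      -31.052947
  ...
QC: excluded 3/24 samples
```

With the default study conditions (6 animals per sex per group), the
recovered CKD conductance change clusters around the imposed −30%, and
three capacity runs drew a failing cytochrome-c response and are listed —
each with its triggering rule — in the report's QC section.

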