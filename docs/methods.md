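# Methods

## CK-clamp thermodynamics

The clamp holds the extramitochondrial ATP/ADP ratio through the creatine
kinase equilibrium K′_CK = [ATP][Cr]/([ADP][PCr]). Substituting the
implied [ADP] into the hydrolysis quotient gives

ΔG_ATP = ΔG°′_ATP + RT·ln([Cr][Pi]/(K′_CK·[PCr])),

with the [ATP] terms cancelling. Concentrations are molar inside the
formula and mM at every interface; energies are kcal/mol (kJ/mol via a
formatting helper). Assumptions: CK activity is in excess so the
equilibrium holds at steady state; buffer phosphate (10 mM K₂HPO₄) is
constant across titration steps because the clamp regenerates ATP; no
explicit ionic-strength/Mg speciation is attempted (a full
binding-polynomial treatment is out of scope).

No apparent constants are measured by this package, so it ships a named,
versioned set (`data/thermo_constants.csv`): K′_CK = 177 as an apparent
equilibrium constant for Mg-containing media near pH 7.1 and 37 °C, and
ΔG°′_ATP = −8.11 kcal/mol, calibrated once so the canonical
resting-demand composition (ATP 5, Cr 5, PCr 30, Pi 10 mM) evaluates to
−15.24 kcal/mol. Every run report records the constant set used.
Temperature defaults to 310.15 K and is configurable. The conductance
assay's buffer uses 5 mM creatine and the capacity assay 20 mM; which
creatine concentration feeds ΔG is a plain field on the clamp state, so
either configuration is expressible.

PCr inversion (`invert_for_pcr`) is the closed-form rearrangement of the
log relation; round trips hold to 1e-9 kcal/mol. The default titration
(1, 3, 6, 9, 12, 15, 21, 30 mM PCr) spans −13.15 to −15.24 kcal/mol; the
number and spacing of steps is configurable since no single schedule is
canonical.

## Oxygraph steady states

Flux is −d[O₂]/dt × chamber volume ÷ protein, in pmol O₂·s⁻¹·mg⁻¹
(defaults: 2 mL, 25 µg mitochondrial protein). The steady-state rule is a
design choice (instrument software conventions vary): within each
inter-event interval, a 21-point rolling OLS slope forms a point-flux
series, and the *latest* window of ≥ 30 s whose point-flux CV ≤ 5% is
accepted; the reported flux is the OLS slope over that window. The latest
qualifying window best approximates the settled plateau; windows never
cross addition events; intervals with no qualifying window are flagged
absent rather than interpolated. On noiseless piecewise-linear traces the
extraction is exact to machine precision.

The cytochrome-c integrity test excludes a sample when its flux response
is *strictly greater* than 15% ("greater than" is taken literally, so a
response of exactly 15.0% passes). Pass/fail is invariant to rescaling
both fluxes. The ADP bolus concentration is metadata only; the default
annotation follows the 16 mM protocol figure, and any label containing
"adp" is recognized.

## Conductance

Per-sample OLS of JO₂ on ΔG_ATP; conductance is reported as the slope
magnitude with the raw sign retained (flux falls as ΔG_ATP becomes more
negative, so the raw slope is positive in these coordinates). Points are
unweighted — nothing in the assay suggests heteroskedastic weighting.
Fits with r² < 0.9 are flagged, not dropped. Group summaries average
per-animal slopes (never pooled points) per sex × substrate and report
percent change vs control; inference is delegated to the statistics
module.

## H₂O₂ flux and electron leak

Standard curves must have ≥ 3 distinct known amounts, positive slope, and
r² ≥ 0.98 to be used. JH₂O₂ stays in the plate reader's pmol·min⁻¹·mg⁻¹
convention; the 1/60 conversion is applied exactly once, inside the leak
ratio. Demand conditions are the enumeration {state2, resting_clamp},
the latter carrying ΔG_ATP = −15.24 kcal/mol as metadata. Small negative
rates (fluorescence drift) are clipped to zero with a logged warning.
Succinate pairings raise an error by design: the paired JO₂ assay
contains rotenone and the H₂O₂ assay does not, so the ratio would compare
different respiratory states.

## Enzyme kinetics

One windowed-slope engine serves all 13 assays (7 matrix dehydrogenases
by NAD(P)H autofluorescence, complexes I–V by absorbance, citrate
synthase by DTNB). Linearity policy: the earliest window of ≥ 10 points
with r² ≥ 0.98, extended forward while linearity holds — the
initial-rate convention, deterministic given its parameters. Blanks are
fit with the same policy and subtracted in AU/min, which commutes with
calibration (everything is linear). Calibration modes: standard curve
(AU per nmol), extinction coefficient via Beer-Lambert (ε·path, scaled by
reaction volume; DTNB default ε = 13.6 mM⁻¹cm⁻¹), or uncalibrated
AU·min⁻¹·mg⁻¹ with the unit label carried explicitly — output units are
never assumed. Assay identity is metadata; the chemistry lives upstream.

## GFR

Two-phase exponential decay fit by constrained nonlinear least squares,
initialized by curve stripping (log-linear tail → slow phase; early
residuals → fast phase). Fast phase is enforced as α > β. Degenerate or
non-converging biexponential fits fall back to a single exponential,
flagged in the output. GFR = dose/(A/α + B/β); the closed-form AUC agrees
with quadrature to well under 0.1%. Dose is in fluorescence-equivalent
units via a user dilution standard; absolute calibration and sampling
schedule design are out of scope. BUN values pass through untransformed.

## Statistics

- Normality gating is per phenotype with an any-cell-fails rule (Shapiro-
  Wilk per sex × group cell at α = 0.05) — conservative; undecidable
  cells (n < 3 or zero variance) route to the nonparametric branch with a
  warning.
- Two-way ANOVA uses type-II sums of squares for unbalanced designs
  (order-independent main effects), recorded in the output. Balanced 2×2
  designs use a closed-form numpy path (type I/II/III coincide there);
  tests cross-check it against the statsmodels fit. Tukey pairwise
  comparisons across the four cells are emitted only when the interaction
  P < 0.05.
- Pearson tests are two-tailed via the t transform at n − 2 df. The
  published r = 0.5249 / P = 0.00084 pair is used in tests only as a
  consistency check of that transform at df = 35 (the implied df exceeds
  any single-cohort n, so it is not treated as a data-level target).
- The metabolite screen runs within sex at an unadjusted two-tailed
  P < 0.1 — deliberately permissive for small metabolomics cohorts; the
  expected number of false flags is reported, and no multiplicity
  correction is applied because the screening design applies none.
  Intensities are used raw (no filtering or normalization) to keep the
  feature count maximal.
- Differential abundance is within-sex two-group one-way ANOVA at
  P < 0.05, computed vectorized as squared equal-variance t (identical by
  the F = t² identity, verified against scipy per feature).

## Synthetic data

Generators are pure functions of (config, seed) and retain ground truth.
The defaults encode the study conditions the pipeline targets: 6 animals
per sex per group; CKD conductance multiplier 0.70 across substrates
(≈ −30%); state-3 multipliers 0.78 (male) and 0.86 (female); degradation
effect 1.25; GFR 250 → 80 µL/min; equal leak means across groups (the
expected null under resting demand); PDH/AKGDH/BCKDH activity multipliers
0.65/0.73/0.85 with ETS complexes and citrate synthase unaffected; CKD
myofiber CSA multiplier 0.85. Control-group magnitudes (conductance
≈ 1200–2600 pmol·s⁻¹·mg⁻¹ per kcal/mol by substrate, state 3
8000 pmol·s⁻¹·mg⁻¹, ~1% leak) and noise levels (10–15% between-animal
CV, 3% flux noise, 5 nM O₂ sensor noise, 5% clearance noise) were chosen
once as realistic for isolated-mitochondria and telemetry assays of this
kind. A shared per-animal severity latent couples the GFR deficit to the
mitochondrial deficit in CKD animals, which is what makes
conductance-vs-GFR and planted metabolite correlations recoverable.
Feature tables are log-normal with 300 features per ion mode, 30 planted
2× group shifts, and 20 planted conductance correlates at |r| = 0.9
constructed within sex with exact in-sample correlation before the
intensity floor.

What the generators do *not* emulate: LC-MS raw spectra and
retention-time structure, instrument drift and background O₂ correction,
biological covariance between phenotypes beyond the single severity
latent, batch effects, and missing values. Passing recovery tests
therefore demonstrates the correctness of the computations and their
calibration, not robustness to every artifact of real acquisitions.

## Orchestration and problem sizes

`run_pipeline` is deterministic given (config, seed): all randomness
derives from one generator, the JSON summary is key-sorted, and reruns
are byte-identical. Reports carry provenance (constants set, thresholds,
seed, version) and enumerate every exclusion with its triggering rule;
no stage imputes. The default end-to-end run simulates 24 animals ×
4 substrates with one full oxygraph trace per animal, 13 enzyme assays
and a clearance curve per animal, and two 300-feature ion modes —
about four seconds on one core. Calibration suites use 50-replicate
effect-recovery cohorts, 200 noisy clearance curves, 2000 null ANOVA
replicates, and 1000–2000-feature null screens: sizes at which binomial
sampling error is well inside the asserted bands while the whole suite
stays fast.

The library functions and the `run` subcommand are the interface for the
plate-level stages (respirometry, leak, enzymes, statistics); dedicated
shell subcommands exist only where a bench scientist would plausibly
invoke a single computation directly (`thermo`, `conductance`, `gfr`,
`synth`, `run`).

## Known limitations

- The shipped ΔG°′/K′_CK pair is an apparent-constant convention, not a
  speciation calculation; absolute ΔG values inherit its calibration.
- The steady-state CV rule assumes near-uniform sampling and modest
  sensor noise; very noisy traces fail to absent windows rather than
  degrade gracefully.
- The biexponential fit can be ill-conditioned when α ≈ β; such fits
  deliberately fall back to single-phase rather than report unstable
  phase parameters.
- Kruskal-Wallis is an omnibus across the four cells and does not
  decompose sex × group interactions.
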