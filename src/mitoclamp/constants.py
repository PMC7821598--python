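"""Named defaults shared across the pipeline.

Every threshold that gates a sample or a statistical call lives here so a run
report can cite a single provenance point.
"""

from importlib import resources

import pandas as pd

#: Gas constant, kcal / (mol K).
R_KCAL_MOL_K = 1.987204259e-3

#: Assay temperature (37 C), K.
T_ASSAY_K = 310.15

#: Buffer Z inorganic phosphate (10 mM K2HPO4), mM; held constant across
#: PCr titration steps because the clamp regenerates ATP at steady state.
BUFFER_Z_PI_MM = 10.0

#: Free energy of ATP hydrolysis defining the "resting demand" clamp
#: condition (30 mM PCr step), kcal/mol.
RESTING_DG_ATP_KCAL_MOL = -15.24

#: Cytochrome-c outer-membrane integrity test: a JO2 increase strictly
#: greater than this percentage excludes the sample.
CYTC_THRESHOLD_PERCENT = 15.0

#: Steady-state extraction policy defaults (respirometry).
MIN_WINDOW_S = 30.0
CV_MAX_PERCENT = 5.0

#: Kinetic-slope linearity policy defaults (enzyme assays).
LINEARITY_R2 = 0.98
LINEARITY_MIN_POINTS = 10

#: Standard curves must reach this r^2 to be used for calibration.
STANDARD_CURVE_R2 = 0.98

#: Significance level for ANOVA terms, normality gating, and Tukey gating.
ALPHA = 0.05

#: Within-sex differential-metabolite threshold (one-way ANOVA P).
DIFFERENTIAL_ALPHA = 0.05

#: Metabolite-vs-conductance Pearson screen threshold (two-tailed,
#: unadjusted; deliberately permissive for small metabolomics cohorts).
SCREEN_ALPHA = 0.10

#: DTNB extinction coefficient for citrate synthase, mM^-1 cm^-1.
EPSILON_DTNB_MM_CM = 13.6

#: Conversion between JH2O2 (per minute) and JO2 (per second) conventions.
SECONDS_PER_MINUTE = 60.0


def load_thermo_constants_table() -> pd.DataFrame:
    """Return the shipped, versioned table of apparent thermodynamic constants.

    One row per assay condition: label, pH, temperature, apparent CK
    equilibrium constant K'_CK = [ATP][Cr]/([ADP][PCr]), apparent standard
    free energy of ATP hydrolysis (kcal/mol), and provenance text.
    """
    with resources.files("mitoclamp.data").joinpath("thermo_constants.csv").open() as fh:
        return pd.read_csv(fh)
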