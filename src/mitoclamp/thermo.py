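"""Creatine-kinase-clamp thermodynamics.

The CK clamp pins the extramitochondrial ATP/ADP ratio through the creatine
kinase equilibrium, so the free energy of ATP hydrolysis is set by the
added PCr/Cr ratio:

    dG_ATP = dG0' + R T ln( [Cr][Pi] / (K'_CK [PCr]) )

(the [ATP] terms cancel between the hydrolysis quotient [ADP][Pi]/[ATP] and
the CK equilibrium [ADP] = [ATP][Cr]/(K'_CK [PCr])).  Titrating PCr upward
makes dG_ATP more negative, i.e. lowers the energy demand presented to the
mitochondria.

Concentrations are molar inside the formula and mM at every interface;
free energies are kcal/mol (kJ/mol available via :func:`kcal_to_kj`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

from .constants import (
    BUFFER_Z_PI_MM,
    R_KCAL_MOL_K,
    T_ASSAY_K,
    load_thermo_constants_table,
)
from .errors import InvalidInputError, InvalidScheduleError, NoSolutionError

KCAL_TO_KJ = 4.184


def kcal_to_kj(x: float) -> float:
    return x * KCAL_TO_KJ


@dataclass(frozen=True)
class ThermoConstants:
    """Apparent equilibrium constants for one assay condition.

    K_CK_apparent is the dimensionless apparent CK equilibrium constant
    [ATP][Cr]/([ADP][PCr]); dG0_ATP the apparent standard free energy of
    ATP hydrolysis in kcal/mol (negative).
    """

    K_CK_apparent: float
    dG0_ATP: float
    gas_constant: float = R_KCAL_MOL_K
    temperature: float = T_ASSAY_K
    pH: float = 7.1
    source_label: str = "unspecified"

    def __post_init__(self) -> None:
        if self.K_CK_apparent <= 0:
            raise InvalidInputError("K_CK_apparent must be positive")
        if self.dG0_ATP >= 0:
            raise InvalidInputError("dG0_ATP must be negative (hydrolysis is exergonic)")
        if not 273.0 <= self.temperature <= 320.0:
            raise InvalidInputError(
                f"temperature {self.temperature} K outside the plausible assay range [273, 320]"
            )

    @property
    def RT(self) -> float:
        return self.gas_constant * self.temperature


def default_constants() -> ThermoConstants:
    """Constants for buffer Z at pH 7.1, 37 C (first row of the shipped table)."""
    row = load_thermo_constants_table().iloc[0]
    return ThermoConstants(
        K_CK_apparent=float(row["K_CK_apparent"]),
        dG0_ATP=float(row["dG0_ATP_kcal_mol"]),
        temperature=float(row["temperature_K"]),
        pH=float(row["pH"]),
        source_label=str(row["condition_label"]),
    )


@dataclass
class ClampState:
    """One CK-clamp assay composition (concentrations in mM)."""

    atp_mM: float
    pcr_mM: float
    cr_mM: float
    pi_mM: float = BUFFER_Z_PI_MM
    dG_ATP: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name in ("atp_mM", "pcr_mM", "cr_mM", "pi_mM"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive, got {getattr(self, name)}")


@dataclass
class TitrationSchedule:
    """Ordered clamp states of a PCr titration (energy demand decreasing)."""

    states: list[ClampState]
    pcr_additions_mM: list[float]
    substrate_label: str = ""

    def __len__(self) -> int:
        return len(self.states)

    @property
    def dG_values(self) -> list[float]:
        return [s.dG_ATP for s in self.states]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": range(1, len(self.states) + 1),
                "PCr_added_mM": self.pcr_additions_mM,
                "PCr_total_mM": [s.pcr_mM for s in self.states],
                "dG_ATP_kcal_mol": self.dG_values,
            }
        )


def compute_dG_ATP(state: ClampState, constants: ThermoConstants | None = None) -> float:
    """Free energy of ATP hydrolysis set by the clamp composition, kcal/mol.

    Stores the result on ``state.dG_ATP`` and returns it.  More PCr at fixed
    Cr and Pi gives a strictly more negative result.  A non-negative result
    is thermodynamically implausible for the assay and triggers a warning.
    """
    constants = constants or default_constants()
    # mM -> M; the 1e-3 factors do not cancel: [Cr][Pi]/[PCr] carries one
    # net concentration dimension.
    cr = state.cr_mM * 1e-3
    pi = state.pi_mM * 1e-3
    pcr = state.pcr_mM * 1e-3
    dg = constants.dG0_ATP + constants.RT * math.log(cr * pi / (constants.K_CK_apparent * pcr))
    if dg >= 0:
        warnings.warn(
            f"computed dG_ATP = {dg:.3f} kcal/mol is non-negative; "
            "composition is thermodynamically implausible for a CK clamp",
            stacklevel=2,
        )
    state.dG_ATP = dg
    return dg


def design_titration(
    start: ClampState,
    pcr_steps_mM: list[float],
    constants: ThermoConstants | None = None,
    substrate_label: str = "",
) -> TitrationSchedule:
    """Build the clamp-state sequence for a cumulative PCr titration.

    ``pcr_steps_mM`` are total PCr concentrations per step, strictly
    increasing, the first at least the starting PCr.  Each state's dG_ATP is
    computed; the sequence is strictly decreasing by construction.
    """
    constants = constants or default_constants()
    steps = list(pcr_steps_mM)
    if not steps:
        raise InvalidScheduleError("empty titration schedule")
    if steps[0] < start.pcr_mM:
        raise InvalidScheduleError(
            f"first step {steps[0]} mM below starting PCr {start.pcr_mM} mM"
        )
    if any(b <= a for a, b in zip(steps, steps[1:])):
        raise InvalidScheduleError(f"PCr steps must be strictly increasing: {steps}")

    states: list[ClampState] = []
    additions: list[float] = []
    prev_pcr = start.pcr_mM
    for total in steps:
        s = replace(start, pcr_mM=total, dG_ATP=None)
        compute_dG_ATP(s, constants)
        states.append(s)
        additions.append(total - prev_pcr)
        prev_pcr = total
    return TitrationSchedule(states=states, pcr_additions_mM=additions, substrate_label=substrate_label)


def invert_for_pcr(
    target_dG: float,
    template: ClampState,
    constants: ThermoConstants | None = None,
) -> float:
    """PCr (mM) that sets ``target_dG`` for the template's Cr and Pi.

    Closed-form inversion of the log relation; the forward computation on
    the modified state reproduces the target to ~1e-9 kcal/mol.
    """
    constants = constants or default_constants()
    if target_dG >= 0:
        raise NoSolutionError(f"target dG_ATP must be negative, got {target_dG}")
    cr = template.cr_mM * 1e-3
    pi = template.pi_mM * 1e-3
    pcr = cr * pi / (constants.K_CK_apparent * math.exp((target_dG - constants.dG0_ATP) / constants.RT))
    if not math.isfinite(pcr) or pcr <= 0:
        raise NoSolutionError(f"target {target_dG} kcal/mol unreachable with positive PCr")
    return pcr * 1e3
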