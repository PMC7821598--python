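"""CK-clamp free-energy engine: closed forms, monotonicity, inversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoclamp.errors import InvalidInputError, InvalidScheduleError, NoSolutionError
from mitoclamp.thermo import (
    ClampState,
    ThermoConstants,
    compute_dG_ATP,
    default_constants,
    design_titration,
    invert_for_pcr,
)

conc = st.floats(min_value=0.1, max_value=100.0, allow_nan=False)


def test_resting_composition_reproduces_known_free_energy(constants, resting_state):
    """30 mM PCr with the assay Cr and buffer phosphate sets ~-15.24 kcal/mol."""
    dg = compute_dG_ATP(resting_state, constants)
    assert dg == pytest.approx(-15.24, abs=0.3)
    assert resting_state.dG_ATP == dg


def test_unit_log_argument_collapses_to_standard_free_energy(constants):
    # choose PCr so [Cr][Pi]/(K'[PCr]) = 1 exactly
    pcr_mM = 0.005 * 0.010 / constants.K_CK_apparent * 1e3
    state = ClampState(atp_mM=5.0, pcr_mM=pcr_mM, cr_mM=5.0, pi_mM=10.0)
    assert compute_dG_ATP(state, constants) == pytest.approx(constants.dG0_ATP, abs=1e-12)


def test_doubling_pcr_shifts_by_exactly_rt_ln2(constants, resting_state):
    dg1 = compute_dG_ATP(resting_state, constants)
    doubled = ClampState(atp_mM=5.0, pcr_mM=60.0, cr_mM=5.0, pi_mM=10.0)
    dg2 = compute_dG_ATP(doubled, constants)
    assert dg2 - dg1 == pytest.approx(-constants.RT * math.log(2), abs=1e-12)
    assert constants.RT * math.log(2) == pytest.approx(0.427, abs=0.002)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(cr=conc, pi=conc, pcr=conc, k=st.floats(min_value=1.0, max_value=8.0))
def test_pcr_scaling_additivity(cr, pi, pcr, k):
    """dG(k*PCr) - dG(PCr) = -RT ln k for all k > 0."""
    c = default_constants()
    base = compute_dG_ATP(ClampState(5.0, pcr, cr, pi), c)
    scaled = compute_dG_ATP(ClampState(5.0, k * pcr, cr, pi), c)
    assert scaled - base == pytest.approx(-c.RT * math.log(k), abs=1e-9)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(cr=conc, pi=conc, pcr=conc)
def test_partial_derivative_signs(cr, pi, pcr):
    """More PCr lowers dG; more Cr or Pi raises it."""
    c = default_constants()
    base = compute_dG_ATP(ClampState(5.0, pcr, cr, pi), c)
    assert compute_dG_ATP(ClampState(5.0, pcr * 1.01, cr, pi), c) < base
    assert compute_dG_ATP(ClampState(5.0, pcr, cr * 1.01, pi), c) > base
    assert compute_dG_ATP(ClampState(5.0, pcr, cr, pi * 1.01), c) > base


def test_nonpositive_concentration_rejected():
    with pytest.raises(InvalidInputError):
        ClampState(atp_mM=5.0, pcr_mM=0.0, cr_mM=5.0, pi_mM=10.0)


def test_implausible_composition_warns(constants):
    state = ClampState(atp_mM=5.0, pcr_mM=1e-6, cr_mM=1e5, pi_mM=1e5)
    with pytest.warns(UserWarning, match="implausible"):
        compute_dG_ATP(state, constants)


def test_invalid_constants_rejected():
    with pytest.raises(InvalidInputError):
        ThermoConstants(K_CK_apparent=-1.0, dG0_ATP=-8.0)
    with pytest.raises(InvalidInputError):
        ThermoConstants(K_CK_apparent=177.0, dG0_ATP=1.0)
    with pytest.raises(InvalidInputError):
        ThermoConstants(K_CK_apparent=177.0, dG0_ATP=-8.0, temperature=400.0)


class TestTitrationDesign:
    def test_final_step_reaches_resting_demand(self, constants):
        start = ClampState(atp_mM=5.0, pcr_mM=1.0, cr_mM=5.0, pi_mM=10.0)
        sched = design_titration(start, [1.0, 3.0, 9.0, 30.0], constants)
        assert sched.dG_values[-1] == pytest.approx(-15.24, abs=0.3)
        assert all(b < a for a, b in zip(sched.dG_values, sched.dG_values[1:]))

    def test_single_step_equals_direct_computation(self, constants):
        start = ClampState(atp_mM=5.0, pcr_mM=2.0, cr_mM=5.0, pi_mM=10.0)
        sched = design_titration(start, [2.0], constants)
        assert len(sched) == 1
        direct = compute_dG_ATP(ClampState(5.0, 2.0, 5.0, 10.0), constants)
        assert sched.dG_values[0] == direct

    def test_schedule_matches_elementwise_calls(self, constants):
        steps = list(np.geomspace(1.0, 30.0, 6))
        start = ClampState(atp_mM=5.0, pcr_mM=1.0, cr_mM=5.0, pi_mM=10.0)
        sched = design_titration(start, steps, constants)
        expected = [
            compute_dG_ATP(ClampState(5.0, p, 5.0, 10.0), constants) for p in steps
        ]
        assert sched.dG_values == pytest.approx(expected, abs=1e-12)
        assert sched.pcr_additions_mM == pytest.approx(np.diff([1.0] + steps), abs=1e-12)

    def test_non_monotone_steps_rejected(self, constants):
        start = ClampState(atp_mM=5.0, pcr_mM=1.0, cr_mM=5.0, pi_mM=10.0)
        with pytest.raises(InvalidScheduleError):
            design_titration(start, [3.0, 2.0, 9.0], constants)
        with pytest.raises(InvalidScheduleError):
            design_titration(start, [0.5, 2.0], constants)


class TestInversion:
    def test_resting_target_needs_about_30_mM_pcr(self, constants):
        template = ClampState(atp_mM=5.0, pcr_mM=1.0, cr_mM=5.0, pi_mM=10.0)
        pcr = invert_for_pcr(-15.24, template, constants)
        assert pcr == pytest.approx(30.0, rel=0.05)

    def test_round_trip_is_identity(self, constants, resting_state):
        target = compute_dG_ATP(resting_state, constants)
        assert invert_for_pcr(target, resting_state, constants) == pytest.approx(
            resting_state.pcr_mM, abs=1e-9
        )

    def test_random_targets_round_trip_below_1e9(self, constants, rng):
        template = ClampState(atp_mM=5.0, pcr_mM=1.0, cr_mM=5.0, pi_mM=10.0)
        for target in rng.uniform(-16.0, -13.0, size=20):
            pcr = invert_for_pcr(target, template, constants)
            back = compute_dG_ATP(ClampState(5.0, pcr, 5.0, 10.0), constants)
            assert abs(back - target) < 1e-9

    def test_unreachable_target_rejected(self, constants, resting_state):
        with pytest.raises(NoSolutionError):
            invert_for_pcr(0.5, resting_state, constants)
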