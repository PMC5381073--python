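"""Core map iteration: fixed points, analytic limits, dilution handling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microlv import (
    ModelParameters,
    PopulationState,
    Trajectory,
    axenic_predator_solution,
    build_schedule,
    control_regime,
    simulate,
    step_once,
)
from microlv.disturbance import DilutionSchedule
from microlv.dynamics import ClampingWarning, iterate_daily


@pytest.mark.parametrize(
    "P, C, expected_P, expected_C",
    [
        # carrying capacity with no predator is a fixed point
        (4.9e8, 0.0, 4.9e8, 0.0),
        # no prey: one pure exponential predator step, (1 + r_C) * C
        (0.0, 1000.0, 0.0, 1012.0),
        # general point, evaluated by hand from the update rule
        (1e7, 1e4, 10570816.326530613, 10121.4),
    ],
)
def test_step_once_known_values(params, P, C, expected_P, expected_C):
    out = step_once(PopulationState(P=P, C=C), params, d=0.0)
    assert out.P == pytest.approx(expected_P, rel=1e-14)
    assert out.C == pytest.approx(expected_C, rel=1e-14)
    assert out.t == 1


def test_step_once_input_validation(params):
    with pytest.raises(ValueError):
        step_once(PopulationState(P=1.0, C=1.0), params, d=1.5)
    state = PopulationState(P=1.0, C=1.0)
    object.__setattr__(state, "P", float("nan"))
    with pytest.raises(ValueError):
        step_once(state, params)


def test_step_once_clamps_negative_overshoot(params):
    # huge predator density makes the prey loss term exceed the population
    state = PopulationState(P=1e6, C=1e7)
    with pytest.warns(ClampingWarning):
        out = step_once(state, params.replace(c_P=1e-3))
    assert out.P == 0.0


def test_one_day_is_192_fine_steps(params):
    schedule = build_schedule(control_regime(), 1)
    traj = simulate(params, schedule, PopulationState(P=1e6, C=1e3), record_fine=True)
    assert params.steps_per_day == 192
    assert params.step_minutes * params.steps_per_day == 1440
    assert len(traj.fine_step) == 193  # initial state + 192 iterations


def test_zero_state_is_fixed_point(params):
    schedule = build_schedule(control_regime(), 5)
    traj = simulate(params, schedule, PopulationState(P=0.0, C=0.0))
    assert np.all(traj.prey == 0.0)
    assert np.all(traj.predator == 0.0)


@pytest.mark.parametrize("dilution_mode", ["transfer", "in_step"])
def test_axenic_predator_matches_closed_form_every_step(params, dilution_mode):
    """With no prey and no dilution the map is exactly geometric."""
    schedule = build_schedule(control_regime(baseline_fold=1.0), 3)
    traj = simulate(
        params, schedule, PopulationState(P=0.0, C=2500.0),
        dilution_mode=dilution_mode, record_fine=True,
    )
    expected = np.array(
        [axenic_predator_solution(2500.0, params, n) for n in traj.fine_step]
    )
    np.testing.assert_allclose(traj.fine_predator, expected, rtol=1e-12)
    assert axenic_predator_solution(2500.0, params, 0) == 2500.0
    assert axenic_predator_solution(1.0, params, 2) == pytest.approx(1.024144, abs=1e-12)


@pytest.mark.parametrize("P0_frac", [1e-6, 0.01, 0.5, 0.99])
def test_logistic_limit_monotone_convergence(params, P0_frac):
    """Without predation or dilution, prey rises monotonically to K_P."""
    schedule = build_schedule(control_regime(baseline_fold=1.0), 10)
    traj = simulate(
        params, schedule, PopulationState(P=P0_frac * params.K_P, C=0.0),
        record_fine=True,
    )
    diffs = np.diff(traj.fine_prey)
    assert np.all(diffs >= -1e-9 * params.K_P)
    assert traj.fine_prey[-1] == pytest.approx(params.K_P, rel=1e-9)
    # K_P itself is invariant
    at_K = simulate(params, schedule, PopulationState(P=params.K_P, C=0.0))
    assert np.all(at_K.prey == params.K_P)


@pytest.mark.parametrize("dilution_mode", ["transfer", "in_step"])
@pytest.mark.parametrize("fold", [2.0, 10.0, 40.0, 2500.0])
def test_dilution_conserves_exact_fold_without_growth(fold, dilution_mode):
    """With all growth terms zero, each day divides both species by the fold."""
    params = ModelParameters(r_P=0.0, r_C=0.0, c_P=0.0, c_C=0.0)
    schedule = build_schedule(control_regime(baseline_fold=fold), 3)
    traj = simulate(
        params, schedule, PopulationState(P=1e8, C=1e5), dilution_mode=dilution_mode
    )
    for day in range(4):
        assert traj.prey[day] == 1e8 / fold**day
        assert traj.predator[day] == 1e5 / fold**day


def test_sampling_conventions_differ_by_transfer(params):
    """post_dilution samples the freshly diluted state, pre_dilution the
    grown culture at transfer time."""
    zero_growth = ModelParameters(r_P=0.0, r_C=0.0, c_P=0.0, c_C=0.0)
    schedule = build_schedule(control_regime(), 2)
    pre = simulate(zero_growth, schedule, PopulationState(P=1e6, C=1e3))
    post = simulate(
        zero_growth, schedule, PopulationState(P=1e6, C=1e3),
        sampling_convention="post_dilution",
    )
    assert post.prey[1] == pytest.approx(pre.prey[0] / 10.0)
    assert post.prey[2] == pytest.approx(pre.prey[1] / 10.0)


def test_determinism_bit_identical(params):
    schedule = build_schedule(control_regime(), 10)
    init = PopulationState(P=3.6e7, C=4.2e4)
    a = simulate(params, schedule, init)
    b = simulate(params, schedule, init)
    np.testing.assert_array_equal(a.prey, b.prey)
    np.testing.assert_array_equal(a.predator, b.predator)


def test_schedule_shorter_than_run_is_an_error(params):
    schedule = build_schedule(control_regime(), 5)
    with pytest.raises(ValueError, match="schedule covers"):
        simulate(params, schedule, PopulationState(P=1.0, C=1.0), n_days=10)


def test_control_day22_regression(control_trajectory):
    """Pinned day-22 pre-dilution state of the reference control run."""
    assert control_trajectory.prey[22] == pytest.approx(298139.59050294757, rel=1e-12)
    assert control_trajectory.predator[22] == pytest.approx(59340.724559940725, rel=1e-12)
    assert control_trajectory.n_days == 22
    assert len(control_trajectory.day) == 23  # includes day 0


def test_control_run_approaches_coexistence_equilibrium(params):
    """Long control runs settle to a strictly positive daily cycle."""
    schedule = build_schedule(control_regime(), 200)
    traj = simulate(params, schedule, PopulationState(P=3.6e7, C=4.2e4))
    last = traj.prey[-5:]
    assert np.all(last > 0)
    assert np.ptp(last) / last.mean() < 1e-3
    assert np.ptp(traj.predator[-5:]) / traj.predator[-5:].mean() < 1e-3


@settings(max_examples=30, deadline=None)
@given(
    r_P=st.floats(0.01, 0.2),
    r_C=st.floats(0.0, 0.02),
    c_P=st.floats(0.0, 1e-5),
    c_C=st.floats(0.0, 1e-10),
    fold=st.floats(1.0, 100.0),
    P0=st.floats(0.0, 1e9),
    C0=st.floats(0.0, 1e6),
)
def test_abundances_never_negative(r_P, r_C, c_P, c_C, fold, P0, C0):
    params = ModelParameters(r_P=r_P, r_C=r_C, c_P=c_P, c_C=c_C)
    schedule = build_schedule(control_regime(baseline_fold=fold), 5)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ClampingWarning)
        traj = simulate(params, schedule, PopulationState(P=P0, C=C0))
    assert np.all(traj.prey >= 0)
    assert np.all(traj.predator >= 0)


def test_batched_parameters_match_scalar_runs(params):
    """iterate_daily broadcasts over parameter vectors consistently."""
    other = params.replace(r_C=0.008, c_P=2e-6)
    schedule = build_schedule(control_regime(), 8)
    prey, pred, _ = iterate_daily(
        schedule.folds, 3.6e7, 4.2e4, 8,
        np.array([params.r_P, other.r_P]),
        np.array([params.r_C, other.r_C]),
        np.array([params.K_P, other.K_P]),
        np.array([params.c_P, other.c_P]),
        np.array([params.c_C, other.c_C]),
    )
    for i, p in enumerate([params, other]):
        ref = simulate(p, schedule, PopulationState(P=3.6e7, C=4.2e4))
        np.testing.assert_array_equal(prey[:, i], ref.prey)
        np.testing.assert_array_equal(pred[:, i], ref.predator)


def test_trajectory_csv_round_trip(tmp_path, control_trajectory):
    path = tmp_path / "traj.csv"
    control_trajectory.write_csv(path)
    assert path.read_text().splitlines()[0] == "day,prey,predator"
    back = Trajectory.from_csv(path)
    np.testing.assert_array_equal(back.day, control_trajectory.day)
    np.testing.assert_array_equal(back.prey, control_trajectory.prey)
    np.testing.assert_array_equal(back.predator, control_trajectory.predator)


def test_trajectory_validation():
    with pytest.raises(ValueError, match="strictly increasing"):
        Trajectory(day=[0, 0, 1], prey=[1, 1, 1], predator=[1, 1, 1])
    with pytest.raises(ValueError, match=">= 0"):
        Trajectory(day=[0, 1], prey=[1, -1], predator=[1, 1])


def test_dilution_schedule_rejects_inconsistent_rates():
    with pytest.raises(ValueError, match="inconsistent"):
        DilutionSchedule(folds=np.array([10.0]), rates=np.array([0.5]))
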