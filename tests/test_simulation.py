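import dataclasses

import numpy as np
import pytest

from adcascade.model_core import (
    BiomarkerState,
    CarryingCapacities,
    HostFactors,
    RateParameters,
    TherapySchedule,
)
from adcascade.scenarios import ScenarioConfig, preset
from adcascade.simulation import (
    AgeGrid,
    Trajectory,
    export_risk_pair_csv,
    load_risk_pair_csv,
    simulate,
    simulate_risk_pair,
)


def logistic_closed_form(t, x0, lam, k):
    """Exact solution of dx/dt = lam * x * (k - x)."""
    return k * x0 / (x0 + (k - x0) * np.exp(-lam * k * t))


def decoupled_config(**kwargs):
    """A scenario with a single active logistic cascade and no couplings."""
    defaults = dict(
        name="decoupled",
        initial=BiomarkerState(a_beta=0.05),
        rates=RateParameters(lam_ab=0.08),
        caps=CarryingCapacities(),
        host=HostFactors(as_level=0.0),
    )
    defaults.update(kwargs)
    return ScenarioConfig(**defaults)


def test_age_grid_points_span_and_spacing():
    pts = AgeGrid(0, 100, 0.1).points()
    assert len(pts) == 1001
    assert pts[0] == 0.0 and pts[-1] == 100.0
    assert np.all(np.diff(pts) > 0)
    with pytest.raises(ValueError):
        AgeGrid(100, 0, 0.1)
    with pytest.raises(ValueError):
        AgeGrid(0, 100, -1)


def test_null_dynamics_stay_zero():
    cfg = ScenarioConfig(name="null", initial=BiomarkerState())
    traj = simulate(cfg)
    for name in ("a_beta", "tau_p", "tau_o", "n_deg", "cog"):
        assert np.all(traj.series(name) == 0.0)


@pytest.mark.parametrize(
    "column,config",
    [
        ("a_beta", decoupled_config()),
        (
            "tau_p",
            decoupled_config(
                initial=BiomarkerState(tau_p=0.05), rates=RateParameters(lam_tp=0.05)
            ),
        ),
        (
            "n_deg",
            decoupled_config(
                initial=BiomarkerState(n_deg=0.05), rates=RateParameters(lam_n=0.05)
            ),
        ),
        (
            "cog",
            decoupled_config(
                initial=BiomarkerState(cog=0.05), rates=RateParameters(lam_c=0.05)
            ),
        ),
    ],
)
def test_decoupled_cascade_matches_logistic_closed_form(column, config):
    traj = simulate(config)
    x0 = getattr(config.initial, column)
    lam = {
        "a_beta": config.rates.lam_ab,
        "tau_p": config.rates.lam_tp,
        "n_deg": config.rates.lam_n,
        "cog": config.rates.lam_c,
    }[column]
    exact = logistic_closed_form(traj.ages, x0, lam, 1.0)
    assert np.max(np.abs(traj.series(column) - exact)) < 1e-6


def test_integrator_tolerance_refinement_converges():
    cfg = preset("early_onset")
    a = simulate(cfg)
    b = simulate(cfg, rtol=5e-9, atol=5e-11)
    for name in ("a_beta", "tau_p", "tau_o", "n_deg", "cog"):
        assert np.max(np.abs(a.series(name) - b.series(name))) < 1e-6


def test_pre_therapy_invariance():
    """Trajectories with and without therapy agree before the onset age."""
    rx = simulate(preset("late_amyloid_first_rx"))
    nat = simulate(preset("late_amyloid_first"))
    mask = rx.ages < 65.0
    for name in ("a_beta", "tau_p", "tau_o", "n_deg", "cog"):
        assert np.max(np.abs(rx.series(name)[mask] - nat.series(name)[mask])) < 1e-8


@pytest.mark.parametrize("name", ["early_onset", "late_tau_first", "late_amyloid_first_rx"])
def test_nonnegativity_of_all_outputs(name):
    traj = simulate(preset(name))
    for col in ("a_beta", "tau_p", "tau_o", "n_deg", "cog"):
        assert np.all(traj.series(col) >= 0.0)


def test_amyloid_floored_at_zero_under_strong_clearance():
    """A state-independent sink would go negative without the clamp."""
    cfg = dataclasses.replace(
        preset("late_amyloid_first_rx"),
        rates=dataclasses.replace(preset("late_amyloid_first_rx").rates, delta_ab=0.5),
    )
    traj = simulate(cfg)
    assert np.all(traj.a_beta >= 0.0)
    assert traj.a_beta[-1] == 0.0  # clearance overwhelms growth entirely


def test_cognition_does_not_feed_back():
    cfg = preset("early_onset")
    bumped = dataclasses.replace(cfg, initial=dataclasses.replace(cfg.initial, cog=0.2))
    a, b = simulate(cfg), simulate(bumped)
    for name in ("a_beta", "tau_p", "tau_o", "n_deg"):
        np.testing.assert_allclose(a.series(name), b.series(name), atol=1e-12)
    assert np.any(a.cog != b.cog)


def test_risk_pair_shares_everything_but_cognition(early_pair):
    low, high = early_pair
    for name in ("a_beta", "tau_p", "tau_o", "n_deg"):
        np.testing.assert_allclose(low.series(name), high.series(name), atol=1e-10)
    assert np.max(high.cog - low.cog) > 0.01


def test_risk_pair_equal_reserve_identical():
    cfg = dataclasses.replace(
        preset("early_onset"),
        host=dataclasses.replace(preset("early_onset").host, reserve_high=1.0),
    )
    low, high = simulate_risk_pair(cfg)
    np.testing.assert_array_equal(low.cog, high.cog)


def test_trajectory_csv_round_trip(tmp_path, early_pair):
    low, _ = early_pair
    path = tmp_path / "traj.csv"
    low.to_csv(path)
    header = path.read_text().splitlines()[0]
    assert header == "age,a_beta,tau_p,tau_o,tau_total,n_deg,cog"
    back = Trajectory.from_csv(path)
    np.testing.assert_allclose(back.a_beta, low.a_beta)
    np.testing.assert_allclose(back.tau_total, low.tau_total)


def test_risk_pair_csv_round_trip(tmp_path, early_pair):
    low, high = early_pair
    path = tmp_path / "pair.csv"
    export_risk_pair_csv(low, high, path)
    header = path.read_text().splitlines()[0]
    assert header == "age,a_beta,tau_p,tau_o,tau_total,n_deg,cog_low,cog_high"
    back_low, back_high = load_risk_pair_csv(path)
    np.testing.assert_allclose(back_low.cog, low.cog)
    np.testing.assert_allclose(back_high.cog, high.cog)


def test_invalid_config_raises():
    bad = dataclasses.replace(
        preset("early_onset"),
        rates=dataclasses.replace(preset("early_onset").rates, lam_ab=-1.0),
    )
    with pytest.raises(ValueError, match="lam_ab"):
        simulate(bad)
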