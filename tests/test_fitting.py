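import dataclasses

import numpy as np
import pytest

from adcascade.fitting import (
    FREE_PARAMETERS,
    ObservationSet,
    fit_parameters,
    generate_observations,
)
from adcascade.scenarios import preset
from adcascade.simulation import AgeGrid, simulate

AGES = np.arange(0.0, 101.0, 5.0)  # 21 timepoints


@pytest.fixture(scope="module")
def early():
    return preset("early_onset")


@pytest.fixture(scope="module")
def coarse_early(early):
    # coarser output grid for replicate-heavy studies
    return dataclasses.replace(early, grid=AgeGrid(0.0, 100.0, 1.0))


def test_noiseless_observations_equal_trajectory(early):
    obs = generate_observations(early, AGES, ("a_beta", "tau_total"), noise_sd=0.0, seed=7)
    traj = simulate(early)
    for b in ("a_beta", "tau_total"):
        np.testing.assert_allclose(
            obs.values[b], np.interp(AGES, traj.ages, traj.series(b)), atol=1e-12
        )


def test_same_seed_reproduces_observations(early):
    a = generate_observations(early, AGES, ("a_beta",), noise_sd=0.05, seed=11)
    b = generate_observations(early, AGES, ("a_beta",), noise_sd=0.05, seed=11)
    np.testing.assert_array_equal(a.values["a_beta"], b.values["a_beta"])
    c = generate_observations(early, AGES, ("a_beta",), noise_sd=0.05, seed=12)
    assert np.any(a.values["a_beta"] != c.values["a_beta"])


def test_observation_noise_is_unbiased(coarse_early):
    """Replicate means converge to the noiseless levels (law of large numbers)."""
    sd, reps = 0.05, 400
    clean = generate_observations(coarse_early, AGES, ("n_deg",), 0.0, 0).values["n_deg"]
    draws = np.array(
        [
            generate_observations(coarse_early, AGES, ("n_deg",), sd, seed).values["n_deg"]
            for seed in range(reps)
        ]
    )
    # truncation at zero biases ages where the level is ~0; compare where clean >> sd
    mask = clean > 3 * sd
    assert np.all(np.abs(draws.mean(axis=0)[mask] - clean[mask]) < 3 * sd / np.sqrt(reps))


def test_observations_truncated_at_zero(coarse_early):
    obs = generate_observations(coarse_early, AGES, ("cog",), noise_sd=0.5, seed=3)
    assert np.all(obs.values["cog"] >= 0.0)


def test_ages_outside_grid_rejected(early):
    with pytest.raises(ValueError, match="within"):
        generate_observations(early, [0.0, 120.0], ("a_beta",), 0.0, 0)


def test_observation_csv_round_trip(tmp_path, early):
    obs = generate_observations(early, AGES, ("a_beta", "n_deg"), noise_sd=0.02, seed=5)
    path = tmp_path / "obs.csv"
    obs.to_csv(path)
    assert path.read_text().splitlines()[0] == "age,biomarker,value"
    back = ObservationSet.from_csv(path)
    np.testing.assert_allclose(back.ages, obs.ages)
    for b in ("a_beta", "n_deg"):
        np.testing.assert_allclose(back.values[b], obs.values[b])


def test_zero_free_parameters_returns_noise_residual(early):
    obs = generate_observations(early, AGES, ("a_beta",), noise_sd=0.02, seed=9)
    clean = generate_observations(early, AGES, ("a_beta",), noise_sd=0.0, seed=9)
    fit = fit_parameters(obs, early, free=[])
    assert fit.fitted_params == {}
    expected = np.sum((obs.values["a_beta"] - clean.values["a_beta"]) ** 2)
    assert fit.residual_ss == pytest.approx(expected, rel=1e-9)


def test_noiseless_single_parameter_recovery(early):
    """Identifiability smoke test: the amyloid growth rate is recovered from
    its own cascade to three decimals."""
    obs = generate_observations(early, AGES, ("a_beta",), noise_sd=0.0, seed=0)
    start = dataclasses.replace(
        early, rates=dataclasses.replace(early.rates, lam_ab=0.05)
    )
    fit = fit_parameters(obs, start, free=["lam_ab"])
    assert fit.converged
    assert abs(fit.fitted_params["lam_ab"] - 0.08) < 1e-3


def test_noisy_two_parameter_recovery(early):
    obs = generate_observations(early, AGES, ("a_beta",), noise_sd=0.02, seed=21)
    fit = fit_parameters(
        obs, early, free=["lam_ab", "a_beta0"], init={"lam_ab": 0.05, "a_beta0": 0.03}
    )
    assert abs(fit.fitted_params["lam_ab"] - 0.08) / 0.08 < 0.2
    assert abs(fit.fitted_params["a_beta0"] - 0.05) / 0.05 < 0.2


def test_residual_at_truth_not_worse_than_at_start(early, coarse_early):
    obs = generate_observations(coarse_early, AGES, ("a_beta",), noise_sd=0.02, seed=4)

    def rss(lam):
        cfg = dataclasses.replace(
            coarse_early, rates=dataclasses.replace(coarse_early.rates, lam_ab=lam)
        )
        traj = simulate(cfg)
        sim = np.interp(AGES, traj.ages, traj.a_beta)
        return np.sum((sim - obs.values["a_beta"]) ** 2)

    assert rss(0.08) <= rss(0.05)


def test_recovery_error_grows_with_noise(coarse_early):
    """Median absolute error of the recovered rate increases with noise sd."""

    def errors(sd):
        errs = []
        for seed in range(20):
            obs = generate_observations(coarse_early, AGES, ("a_beta",), sd, seed)
            fit = fit_parameters(obs, coarse_early, free=["lam_ab"], init={"lam_ab": 0.06})
            errs.append(abs(fit.fitted_params["lam_ab"] - 0.08))
        return np.median(errs)

    assert errors(0.05) >= errors(0.01)


def test_unknown_free_parameter_rejected(early):
    obs = generate_observations(early, AGES, ("a_beta",), 0.0, 0)
    with pytest.raises(ValueError, match="unknown free parameters"):
        fit_parameters(obs, early, free=["lam_bogus"])
    assert "lam_ab" in FREE_PARAMETERS and "a_beta0" in FREE_PARAMETERS


def test_empty_observation_set_rejected(early):
    empty = ObservationSet(ages=np.array([]), values={})
    with pytest.raises(ValueError, match="empty"):
        fit_parameters(empty, early, free=["lam_ab"])
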