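"""Hierarchical drift-rate inference: sampler, contrasts, cross-fit tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from maskddm import hier
from maskddm.hier import (
    ModelSpec,
    build_model,
    compare_fits,
    ez_diffusion,
    posterior_prob,
    sample_posterior,
)
from maskddm.simulate import simulate_drift_cells


@pytest.fixture(scope="module")
def small_fit():
    """One moderate synthetic dataset and its posterior (shared by tests)."""
    truth = {"lower": 0.7, "upper": 1.1, "none": 1.6}
    trials = simulate_drift_cells(truth, 24, 16, seed=10)
    model, draws = hier.fit_mask_drift(
        trials, n_samples=1500, burn_in=200, tune=200, seed=11
    )
    return truth, trials, model, draws


def test_model_bookkeeping():
    trials = simulate_drift_cells({"lower": 1.0, "none": 1.5}, 5, 6, seed=0)
    model = build_model(trials)
    assert model.masks == ["lower", "none"]
    assert len(model.pids) == 5
    assert model.rt.size == 5 * 2 * 6
    # CSR layouts partition the trials
    assert model.mask_ptr[-1] == model.rt.size
    assert model.pid_ptr[-1] == model.rt.size


def test_model_rejects_malformed_trials():
    trials = simulate_drift_cells({"lower": 1.0, "none": 1.5}, 4, 5, seed=1)
    with pytest.raises(ValueError, match="missing"):
        build_model(trials.rename(columns={"mask": "nomask"}))


def test_boundary_variant_layout():
    trials = simulate_drift_cells({"lower": 1.0, "none": 1.5}, 6, 8, seed=2)
    model = build_model(trials, ModelSpec(boundary_by_mask=True))
    draws = sample_posterior(model, n_samples=300, burn_in=100, tune=50, seed=3)
    assert {"a_lower", "a_none", "v_lower", "v_none"} <= set(draws.draws.columns)


def test_single_condition_reduces_to_plain_fit():
    trials = simulate_drift_cells({"none": 1.2}, 8, 20, seed=4)
    model, draws = hier.fit_mask_drift(
        trials, n_samples=800, burn_in=100, tune=150, seed=5
    )
    assert list(model.masks) == ["none"]
    assert abs(draws.draws["v_none"].mean() - 1.2) < 0.35


def test_sampler_determinism_and_draw_counts(small_fit):
    _, trials, _, draws = small_fit
    assert draws.n_retained == 1500 - 200
    _, draws2 = hier.fit_mask_drift(
        trials, n_samples=1500, burn_in=200, tune=200, seed=11
    )
    pd.testing.assert_frame_equal(draws.draws, draws2.draws)


def test_posterior_concentrates_near_truth(small_fit):
    truth, _, _, draws = small_fit
    means = draws.draws.mean()
    for mask, v in truth.items():
        assert abs(means[f"v_{mask}"] - v) < 0.35
    # shared parameters in plausible range (generator: a=1.8, t=0.35)
    assert 1.4 < means["a"] < 2.2
    assert 0.2 < means["t"] < 0.5
    lo, hi = np.percentile(draws.draws["v_none"], [2.5, 97.5])
    assert lo < hi


def test_retained_draws_burnin_protocol():
    """Default protocol: 5000 samples, 200 burn-in, 4800 retained."""
    trials = simulate_drift_cells({"none": 1.2}, 3, 4, seed=6)
    model = build_model(trials)
    draws = sample_posterior(model, n_samples=500, burn_in=200, seed=7, tune=50)
    assert draws.n_retained == 300
    with pytest.raises(ValueError):
        sample_posterior(model, n_samples=100, burn_in=200, seed=0)


def test_prior_only_sampling_reproduces_prior_moments():
    model = build_model(None, masks=["lower", "none"])
    draws = sample_posterior(model, n_samples=4000, burn_in=500, seed=8, tune=200)
    pri = model.spec.priors
    for col in ("v_lower", "v_none"):
        x = draws.draws[col]
        assert abs(x.mean()) < 0.25 * pri.drift_sd
        assert abs(x.std() - pri.drift_sd) < 0.25 * pri.drift_sd
    # half-normal prior on the intercept SD: mean = scale * sqrt(2/pi)
    sd_draws = draws.draws["sigma_u"]
    assert abs(sd_draws.mean() - pri.intercept_sd_scale * np.sqrt(2 / np.pi)) < 0.25


def test_posterior_prob_tie_and_extremes():
    df = pd.DataFrame({"A": [1.0, 1.0, 1.0], "B": [1.0, 1.0, 1.0]})
    assert posterior_prob(df, "A > B").probability == 0.5
    df2 = pd.DataFrame({"A": [2.0, 3.0], "B": [0.0, 1.0]})
    assert posterior_prob(df2, "A > B").probability == 1.0
    assert posterior_prob(df2, "A < B").probability == 0.0
    assert posterior_prob(df2, "B > 0").probability == 0.75  # tie at 0 counts 1/2


def test_posterior_prob_matches_normal_difference():
    rng = np.random.default_rng(12)
    n = 4800
    df = pd.DataFrame({"A": rng.normal(1, 1, n), "B": rng.normal(0, 1, n)})
    p = posterior_prob(df, "A > B").probability
    expect = stats.norm.cdf(1 / np.sqrt(2))
    assert abs(p - expect) < 3 * np.sqrt(expect * (1 - expect) / n)


def test_posterior_prob_unknown_parameter():
    df = pd.DataFrame({"A": [1.0]})
    with pytest.raises(KeyError, match="unknown parameter"):
        posterior_prob(df, "A > C")
    with pytest.raises(ValueError, match="parse"):
        posterior_prob(df, "A >=< B")


def test_compare_fits_properties():
    rng = np.random.default_rng(13)
    d1 = pd.DataFrame(
        {"v_lower": rng.normal(-0.4, 0.05, 4800), "v_none": np.zeros(4800)}
    )
    same = compare_fits(d1, d1.copy())
    assert same.probability == 0.5  # identical fits
    d2 = pd.DataFrame(
        {"v_lower": rng.normal(-0.8, 0.05, 4800), "v_none": np.zeros(4800)}
    )
    forward = compare_fits(d1, d2)
    assert forward.probability < 0.01  # doubled deficit: diff_2 < diff_1 a.s.
    backward = compare_fits(d2, d1)
    assert backward.probability == pytest.approx(1 - forward.probability, abs=1e-9)


def test_compare_fits_resamples_mismatched_draws():
    rng = np.random.default_rng(14)
    d1 = pd.DataFrame({"v_lower": rng.normal(0, 1, 1000), "v_none": np.zeros(1000)})
    d2 = pd.DataFrame({"v_lower": rng.normal(2, 1, 500), "v_none": np.zeros(500)})
    res = compare_fits(d1, d2, seed=3)
    assert 0.85 < res.probability <= 1.0


def test_ez_diffusion_roundtrip():
    """EZ initializer recovers moments of its own generating parameters."""
    from maskddm.simulate import simulate_trials
    from maskddm.wfpt import DDMParams

    p = DDMParams(v=1.0, a=1.8, z=0.5, t=0.3)
    df = simulate_trials(p, 20000, seed=15)
    correct = df[df["boundary"] == "upper"]
    v, a, ter = ez_diffusion(
        (df["boundary"] == "upper").mean(),
        correct["rt"].var(),
        correct["rt"].mean(),
    )
    assert abs(v - 1.0) < 0.2
    assert abs(a - 1.8) < 0.25
    assert abs(ter - 0.3) < 0.1
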