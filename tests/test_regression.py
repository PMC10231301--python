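"""Mixed regressions: closed forms, oracles, bootstrap, cascade staging."""

import numpy as np
import pandas as pd
import pytest

from maskddm import regression
from maskddm.regression import (
    SeparationError,
    bootstrap_ci,
    chance_test,
    fit_linear_mixed,
    fit_logistic_mixed,
    fp_cascade,
)
from maskddm.task_design import EMOTIONS


def _toy_2x2(n_yes_none=40, n_no_none=10, n_yes_lower=25, n_no_lower=25):
    rows = []
    for mask, yes, no in (("none", n_yes_none, n_no_none),
                          ("lower", n_yes_lower, n_no_lower)):
        rows += [{"participant_id": "p1", "mask": mask, "y": 1.0}] * yes
        rows += [{"participant_id": "p1", "mask": mask, "y": 0.0}] * no
    return pd.DataFrame(rows)


def test_logistic_matches_closed_form_log_odds():
    df = _toy_2x2()
    fit = fit_logistic_mixed(df, outcome=df["y"])
    expect = np.log((25 * 10) / (25 * 40))  # ln(0.25)
    assert abs(fit.coef("lower > none") - expect) < 1e-4
    assert fit.sigma_u <= 1e-6  # no clustering -> boundary


def test_logistic_matches_glmer_reference(clustered_binary):
    """Frozen oracle: lme4::glmer (nAGQ=15) on the same generated dataset."""
    fit = fit_logistic_mixed(clustered_binary,
                             outcome=clustered_binary["y"].astype(float))
    # glmer: intercept 1.0459 (z 5.70), lower -0.7654 (z -4.26),
    #        upper -0.5910 (z -3.27), sigma_u 0.4844
    assert fit.coef("intercept") == pytest.approx(1.0459, abs=0.01)
    assert fit.coef("lower > none") == pytest.approx(-0.7654, abs=0.01)
    assert fit.coef("upper > none") == pytest.approx(-0.5910, abs=0.01)
    assert fit.sigma_u == pytest.approx(0.4844, abs=0.01)
    assert fit.terms["lower > none"]["stat"] == pytest.approx(-4.26, abs=0.05)


def test_logistic_null_coefficient_small():
    rng = np.random.default_rng(0)
    rows = []
    for j in range(30):
        for mask in ("none", "lower"):
            for yy in rng.random(20) < 0.6:
                rows.append({"participant_id": j, "mask": mask, "y": float(yy)})
    df = pd.DataFrame(rows)
    fit = fit_logistic_mixed(df, outcome=df["y"])
    assert abs(fit.coef("lower > none")) < 0.3
    assert abs(fit.terms["lower > none"]["stat"]) < 2.5


def test_logistic_detects_simulated_accuracy_drop():
    rng = np.random.default_rng(1)
    rows = []
    for j in range(40):
        u = rng.normal(0, 0.4)
        for mask, b in (("none", 1.2), ("lower", 0.3)):
            for yy in rng.random(30) < 1 / (1 + np.exp(-(b + u))):
                rows.append({"participant_id": j, "mask": mask, "y": float(yy)})
    df = pd.DataFrame(rows)
    fit = fit_logistic_mixed(df, outcome=df["y"])
    assert fit.coef("lower > none") < -0.5
    assert fit.terms["lower > none"]["p"] < 1e-4


def test_complete_separation_raises():
    df = _toy_2x2(n_yes_lower=50, n_no_lower=0)
    with pytest.raises(SeparationError):
        fit_logistic_mixed(df, outcome=df["y"])


def test_linear_mixed_matches_ols_without_clustering():
    """With a single participant the mixed fit collapses to OLS."""
    rng = np.random.default_rng(2)
    n = 60
    df = pd.DataFrame(
        {
            "participant_id": "p1",
            "mask": np.repeat(["none", "lower", "upper"], n // 3),
            "log_rt": rng.normal(6.8, 0.2, n),
        }
    )
    fit = fit_linear_mixed(df, by_accuracy=False)
    import statsmodels.api as sm

    X = np.column_stack(
        [
            np.ones(n),
            (df["mask"] == "lower").astype(float),
            (df["mask"] == "upper").astype(float),
        ]
    )
    ols = sm.OLS(df["log_rt"].to_numpy(), X).fit()
    assert fit.coef("lower > none") == pytest.approx(ols.params[1], abs=1e-8)
    assert fit.coef("upper > none") == pytest.approx(ols.params[2], abs=1e-8)


def test_linear_mixed_identical_cells_give_null_coefficients():
    rng = np.random.default_rng(3)
    rows = []
    for j in range(20):
        u = rng.normal(0, 0.1)
        for mask in ("none", "lower"):
            for correct in (True, False):
                for _ in range(10):
                    rows.append(
                        {
                            "participant_id": j,
                            "mask": mask,
                            "correct": correct,
                            "log_rt": 6.8 + u + rng.normal(0, 0.15),
                        }
                    )
    fit = fit_linear_mixed(pd.DataFrame(rows))
    for term, vals in fit.terms.items():
        assert abs(vals["b"]) < 0.06, term


def test_linear_mixed_detects_slower_correct_rts_under_mask():
    rng = np.random.default_rng(4)
    rows = []
    for j in range(30):
        u = rng.normal(0, 0.1)
        for mask in ("none", "lower"):
            for correct in (True, False):
                shift = 0.12 if (mask == "lower" and correct) else 0.0
                for _ in range(12):
                    rows.append(
                        {
                            "participant_id": j,
                            "mask": mask,
                            "correct": correct,
                            "log_rt": 6.7 + u + shift + rng.normal(0, 0.2),
                        }
                    )
    fit = fit_linear_mixed(pd.DataFrame(rows))
    assert fit.coef("Correct: lower > none") > 0.06
    assert fit.terms["Correct: lower > none"]["p"] < 0.001
    assert abs(fit.coef("Incorrect: lower > none")) < 0.06
    assert "lower x rating" in fit.terms


def test_interaction_requires_both_accuracy_levels():
    df = pd.DataFrame(
        {
            "participant_id": ["p1"] * 8,
            "mask": ["none", "lower"] * 4,
            "correct": [True] * 8,
            "log_rt": np.linspace(6, 7, 8),
        }
    )
    with pytest.raises(ValueError, match="accuracy levels"):
        fit_linear_mixed(df)


def test_bootstrap_determinism_and_consistency():
    df = _toy_2x2()
    fn = lambda d: fit_logistic_mixed(d, outcome=d["y"], compute_se=False)
    ci1 = bootstrap_ci(fn, df, n_boot=60, seed=5)
    ci2 = bootstrap_ci(fn, df, n_boot=60, seed=5)
    t1 = ci1.terms["lower > none"]
    assert t1 == ci2.terms["lower > none"]
    # point estimate inside its own CI (single cluster -> zero-width here)
    assert t1["ci_low"] <= t1["b"] <= t1["ci_high"]
    assert t1["ci_low"] == pytest.approx(np.log(0.25), abs=1e-3)
    assert t1["ci_high"] == pytest.approx(np.log(0.25), abs=1e-3)


def test_bootstrap_failure_budget():
    rng = np.random.default_rng(6)
    # two tiny clusters where resamples often lose a mask level entirely
    df = pd.DataFrame(
        {
            "participant_id": np.repeat(["a", "b"], 4),
            "mask": ["none"] * 4 + ["lower"] * 4,
            "y": rng.integers(0, 2, 8).astype(float),
        }
    )
    fn = lambda d: fit_logistic_mixed(d, outcome=d["y"], compute_se=False)
    with pytest.raises(RuntimeError, match="bootstrap refits failed"):
        bootstrap_ci(fn, df, n_boot=40, seed=7)


def test_chance_test_all_correct_is_above_chance():
    df = pd.DataFrame(
        {"participant_id": ["a", "b"] * 5, "mask": "none", "correct": True}
    )
    out = chance_test(df)
    assert bool(out.loc["none", "above_chance"])
    df2 = df.assign(correct=False)
    assert not bool(chance_test(df2).loc["none", "above_chance"])


def test_chance_test_verdicts():
    rng = np.random.default_rng(8)
    rows = []
    for j in range(25):
        for mask, acc in (("none", 0.9), ("lower", 0.5)):
            for yy in rng.random(24) < acc:
                rows.append({"participant_id": j, "mask": mask, "correct": bool(yy)})
    out = chance_test(pd.DataFrame(rows))
    assert bool(out.loc["none", "above_chance"])
    assert not bool(out.loc["lower", "above_chance"])
    with pytest.raises(ValueError, match="fewer than 2"):
        chance_test(pd.DataFrame(
            [{"participant_id": "a", "mask": "none", "correct": True}]
        ))


def _cascade_trials(effect_pairing=None, seed=9):
    """30-pairing incongruent table; optionally one pairing with strong
    rating and RT mask effects."""
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(24):
        u = rng.normal(0, 0.3)
        for expr in EMOTIONS:
            for rated in EMOTIONS:
                if expr == rated:
                    continue
                pairing = f"{expr}|{rated}"
                for mask in ("none", "lower", "upper"):
                    boost = (
                        2.0
                        if (pairing == effect_pairing and mask == "lower")
                        else 0.0
                    )
                    for _ in range(4):
                        yes = rng.random() < 1 / (1 + np.exp(-(-1.0 + u + boost)))
                        rt = np.exp(6.6 + u + 0.3 * boost + rng.normal(0, 0.25))
                        rows.append(
                            {
                                "participant_id": j,
                                "mask": mask,
                                "expression": expr,
                                "rated_emotion": rated,
                                "pairing": pairing,
                                "congruent": False,
                                "response": "yes" if yes else "no",
                                "rt_ms": rt,
                            }
                        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def null_cascade():
    return fp_cascade(_cascade_trials())


def test_cascade_covers_30_pairings(null_cascade):
    assert len(null_cascade) == 30


def test_cascade_mostly_stops_at_stage_one_under_null(null_cascade):
    assert (null_cascade["stage_reached"] == 1).mean() >= 0.8


def test_cascade_advances_for_simulated_effect():
    out = fp_cascade(
        _cascade_trials(effect_pairing="disgust|anger"),
        drift_fitter=lambda sub: 0.123,
    )
    assert out.loc["disgust|anger", "stage_reached"] == 3
    assert out.loc["disgust|anger", "drift_prob"] == pytest.approx(0.123)
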