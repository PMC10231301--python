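"""First-passage density: symmetry, normalization, variability marginals."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from maskddm.wfpt import (
    DDMParams,
    QuadratureError,
    choice_probability,
    integrate_variabilities,
    loglik,
    wfpt_density,
)

GRID = [
    DDMParams(v=0.0, a=2.0, z=0.5),
    DDMParams(v=1.0, a=2.0, z=0.5),
    DDMParams(v=-0.8, a=1.5, z=0.4),
    DDMParams(v=2.0, a=1.0, z=0.6),
    DDMParams(v=0.5, a=2.5, z=0.3),
]


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        DDMParams(v=1, a=-1, z=0.5)
    with pytest.raises(ValueError):
        DDMParams(v=1, a=1, z=1.2)
    with pytest.raises(ValueError):
        DDMParams(v=1, a=1, z=0.5, t=0.1, st=0.3)
    with pytest.raises(ValueError):
        DDMParams(v=1, a=1, z=0.05, sz=0.2)


def test_density_zero_before_diffusion_starts():
    p = DDMParams(v=1.0, a=2.0, z=0.5, t=0.3)
    assert wfpt_density(0.2, "upper", p, from_stimulus_onset=True) == 0.0
    assert wfpt_density(-0.1, "upper", p) == 0.0
    assert wfpt_density(0.0, "lower", p) == 0.0


@pytest.mark.parametrize("p", GRID)
def test_mirror_identity(p):
    """density(upper; v, z) == density(lower; -v, 1-z) at matched times."""
    mirrored = DDMParams(v=-p.v, a=p.a, z=1 - p.z)
    for t in (0.05, 0.2, 0.5, 1.0, 2.5):
        np.testing.assert_allclose(
            wfpt_density(t, "upper", p),
            wfpt_density(t, "lower", mirrored),
            rtol=1e-9,
        )


@pytest.mark.parametrize("p", GRID)
def test_upper_mass_equals_absorption_probability(p):
    mass = quad(lambda t: wfpt_density(t, "upper", p), 0, 60, limit=300)[0]
    np.testing.assert_allclose(mass, choice_probability(p), atol=2e-5)


def test_choice_probability_closed_form_values():
    assert choice_probability(DDMParams(v=0.0, a=2.0, z=0.5)) == 0.5
    expected = (1 - math.exp(-2)) / (1 - math.exp(-4))
    np.testing.assert_allclose(
        choice_probability(DDMParams(v=1.0, a=2.0, z=0.5)), expected, rtol=1e-12
    )
    assert choice_probability(DDMParams(v=500.0, a=2.0, z=0.5)) == 1.0
    assert choice_probability(DDMParams(v=-500.0, a=2.0, z=0.5)) < 1e-100


def test_choice_probability_requires_no_variabilities():
    with pytest.raises(ValueError):
        choice_probability(DDMParams(v=1, a=2, z=0.5, sv=0.5))


def test_sv_marginal_matches_numeric_integration():
    base = dict(a=2.0, z=0.5)
    psv = DDMParams(v=1.0, sv=0.6, **base)
    for t in (0.3, 0.8, 1.5):
        numeric = quad(
            lambda v: wfpt_density(t, "upper", DDMParams(v=v, **base))
            * stats.norm.pdf(v, 1.0, 0.6),
            -5,
            7,
            limit=200,
        )[0]
        np.testing.assert_allclose(wfpt_density(t, "upper", psv), numeric, rtol=1e-7)


def test_variability_marginal_reduces_to_base_density():
    p = DDMParams(v=1.0, a=1.8, z=0.5, sv=0.3)
    ts = np.array([0.1, 0.4, 1.0])
    np.testing.assert_allclose(
        integrate_variabilities(ts, "upper", p),
        wfpt_density(ts, "upper", p),
        rtol=1e-12,
    )


def test_sz_st_marginal_total_mass_is_one():
    p = DDMParams(v=1.0, a=1.5, z=0.5, sv=0.3, sz=0.15, st=0.0)
    up = quad(lambda t: integrate_variabilities(t, "upper", p)[0], 0, 40,
              limit=200)[0]
    lo = quad(lambda t: integrate_variabilities(t, "lower", p)[0], 0, 40,
              limit=200)[0]
    np.testing.assert_allclose(up + lo, 1.0, atol=1e-4)


def test_sv_spreads_normalized_density():
    """More drift variability increases the variance of the normalized density."""
    ts = np.linspace(0.005, 8, 3000)
    variances = []
    for sv in (0.0, 0.4, 0.8):
        d = wfpt_density(ts, "upper", DDMParams(v=1.5, a=1.5, z=0.5, sv=sv))
        dn = d / np.trapezoid(d, ts)
        m = np.trapezoid(ts * dn, ts)
        variances.append(np.trapezoid((ts - m) ** 2 * dn, ts))
    assert variances[0] < variances[1] < variances[2]


def test_loglik_matches_per_trial_loop_and_is_order_independent():
    rng = np.random.default_rng(0)
    p = DDMParams(v=0.0, a=1.8, z=0.5, t=0.25, sv=0.2)
    rt = rng.uniform(0.3, 2.0, 100)
    hit = rng.random(100) < 0.5
    v = rng.normal(1.0, 0.5, 100)
    total = loglik(rt, hit, v, p)
    brute = sum(
        math.log(
            wfpt_density(
                rt[i] - p.t, "upper" if hit[i] else "lower",
                DDMParams(v=v[i], a=p.a, z=p.z, sv=p.sv),
            )
        )
        for i in range(100)
    )
    np.testing.assert_allclose(total, brute, rtol=1e-9)
    perm = rng.permutation(100)
    np.testing.assert_allclose(total, loglik(rt[perm], hit[perm], v[perm], p))


def test_loglik_identifies_offending_trial():
    p = DDMParams(v=1.0, a=2.0, z=0.5, t=0.5)
    with pytest.raises(ValueError, match="trial 1"):
        loglik([1.0, 0.4], [True, True], 1.0, p)


def test_loglik_single_trial_is_log_density():
    p = DDMParams(v=1.0, a=2.0, z=0.5)
    d = wfpt_density(0.7, "upper", p)
    np.testing.assert_allclose(loglik([0.7], [True], 1.0, p), math.log(d))


def test_quadrature_nonconvergence_reports_nodes():
    p = DDMParams(v=1.0, a=1.5, z=0.5, sz=0.4)
    with pytest.raises(QuadratureError, match="nodes"):
        integrate_variabilities(np.array([0.5]), "upper", p, rel_tol=1e-3,
                                max_nodes=4)


def test_rel_tol_bounds_enforced():
    p = DDMParams(v=1.0, a=2.0, z=0.5)
    with pytest.raises(ValueError):
        wfpt_density(0.5, "upper", p, rel_tol=1e-2)
    with pytest.raises(ValueError):
        wfpt_density(0.5, "middle", p)
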