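"""Wiener first-passage-time (WFPT) density for the two-boundary diffusion.

This is the likelihood kernel behind all drift-rate inference in the
package.  A particle starts at relative position ``z`` between two absorbing
boundaries separated by ``a`` (lower boundary at 0, upper at ``a``) and
drifts with rate ``v`` under unit-variance Brownian noise (diffusion
coefficient fixed at 1; the common alternative 0.1 only rescales all
parameters).  The density of the time of first absorption at either boundary
is evaluated with the classic two-regime series expansion: a small-time
representation based on image charges and a large-time eigenfunction
expansion, switching to whichever needs fewer terms for the requested
relative tolerance.

Drift enters the density only through the factor ``exp(-v*a*w - v^2 t / 2)``
(lower boundary, relative start ``w``), which allows the across-trial drift
variability ``sv`` (drift drawn Normal(v, sv^2) per trial) to be integrated
in closed form.  Uniform across-trial variability in the start point (range
``sz``) and non-decision time (range ``st``) is handled by Gauss-Legendre
quadrature with adaptive node doubling.

Times are in seconds throughout this module; the I/O layer converts from
milliseconds once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "DDMParams",
    "QuadratureError",
    "wfpt_density",
    "choice_probability",
    "integrate_variabilities",
    "loglik",
]


@dataclass(frozen=True)
class DDMParams:
    """Diffusion parameter bundle.

    v : drift rate (evidence units/s, signed toward the upper boundary)
    a : boundary separation (> 0)
    z : relative starting point in (0, 1); 0.5 = unbiased
    t : non-decision time in seconds (>= 0)
    sv : across-trial SD of drift (>= 0)
    sz : across-trial range of the start point (>= 0)
    st : across-trial range of non-decision time (>= 0)
    """

    v: float
    a: float
    z: float = 0.5
    t: float = 0.0
    sv: float = 0.0
    sz: float = 0.0
    st: float = 0.0

    def __post_init__(self):
        if not (self.a > 0):
            raise ValueError(f"boundary separation a={self.a} must be > 0")
        if not (0.0 < self.z < 1.0):
            raise ValueError(f"start point z={self.z} must lie in (0, 1)")
        if self.t < 0:
            raise ValueError(f"non-decision time t={self.t} must be >= 0")
        if min(self.sv, self.sz, self.st) < 0:
            raise ValueError("variabilities sv, sz, st must be >= 0")
        if self.t - self.st / 2 < 0:
            raise ValueError("t - st/2 must be >= 0")
        if not (0.0 < self.z - self.sz / 2 and self.z + self.sz / 2 < 1.0):
            raise ValueError("z +/- sz/2 must stay within (0, 1)")


class QuadratureError(RuntimeError):
    """Raised when adaptive quadrature over sz/st fails to converge."""


@njit(cache=False)
def _fpt_norm(u, w, eps):
    """Density of the normalized FPT (a=1, v=0) at the *lower* boundary.

    ``u`` is decision time divided by a^2, ``w`` the relative start point.
    Term counts for the small-time and large-time series follow the
    published switching rule driven by the tolerance ``eps``.
    """
    if u <= 0.0:
        return 0.0
    # number of terms needed by the large-time series
    if math.pi * u * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * u * eps) / (math.pi * math.pi * u))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(u)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(u))
    # number of terms needed by the small-time series
    if 2.0 * math.sqrt(2.0 * math.pi * u) * eps < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * u * math.log(2.0 * eps * math.sqrt(2.0 * math.pi * u)))
        ks = max(ks, math.sqrt(u) + 1.0)
    else:
        ks = 2.0
    p = 0.0
    if ks < kl:
        K = int(math.ceil(ks))
        lo = -((K - 1) // 2)
        hi = (K - 1) // 2 + (K - 1) % 2
        for k in range(lo, hi + 1):
            x = w + 2.0 * k
            p += x * math.exp(-x * x / (2.0 * u))
        p /= math.sqrt(2.0 * math.pi * u * u * u)
    else:
        K = int(math.ceil(kl))
        for k in range(1, K + 1):
            p += (
                k
                * math.exp(-k * k * math.pi * math.pi * u / 2.0)
                * math.sin(k * math.pi * w)
            )
        p *= math.pi
    if p < 0.0:
        p = 0.0  # truncation can leave tiny negative values in the far tail
    return p


@njit(cache=False)
def _logpdf_one(t_dec, hit_upper, v, a, z, sv, eps):
    """Log density of one first passage; -inf when t_dec <= 0 or underflow.

    ``sv`` > 0 applies the closed-form normal-drift marginal:
    int exp(-v*a*w - v^2 t/2) N(v; mu, sv^2) dv
      = (1+sv^2 t)^(-1/2) exp((sv^2 (a w)^2/2 - mu a w - mu^2 t/2)/(1+sv^2 t)).
    """
    if t_dec <= 0.0:
        return -np.inf
    if hit_upper:
        v = -v
        w = 1.0 - z
    else:
        w = z
    u = t_dec / (a * a)
    f = _fpt_norm(u, w, eps)
    if f <= 0.0:
        return -np.inf
    aw = a * w
    if sv > 0.0:
        denom = 1.0 + sv * sv * t_dec
        mult = (
            (sv * sv * aw * aw / 2.0 - v * aw - v * v * t_dec / 2.0) / denom
            - 0.5 * math.log(denom)
        )
    else:
        mult = -v * aw - v * v * t_dec / 2.0
    return math.log(f) - 2.0 * math.log(a) + mult


@njit(cache=False)
def _logpdf_marginal(t_dec, hit_upper, v, a, z, sv, sz, st, gl_x, gl_w, eps):
    """Log density marginalized over uniform z (range sz) and t (range st).

    ``gl_x``/``gl_w`` are Gauss-Legendre nodes/weights on [-1, 1]; the
    uniform mixing densities make the marginal a plain weighted average.
    """
    if sz <= 0.0 and st <= 0.0:
        return _logpdf_one(t_dec, hit_upper, v, a, z, sv, eps)
    acc = 0.0
    if sz > 0.0 and st > 0.0:
        for i in range(gl_x.size):
            zi = z + 0.5 * sz * gl_x[i]
            for j in range(gl_x.size):
                tj = t_dec - 0.5 * st * gl_x[j]
                lp = _logpdf_one(tj, hit_upper, v, a, zi, sv, eps)
                if lp > -np.inf:
                    acc += 0.25 * gl_w[i] * gl_w[j] * math.exp(lp)
    elif sz > 0.0:
        for i in range(gl_x.size):
            zi = z + 0.5 * sz * gl_x[i]
            lp = _logpdf_one(t_dec, hit_upper, v, a, zi, sv, eps)
            if lp > -np.inf:
                acc += 0.5 * gl_w[i] * math.exp(lp)
    else:
        for j in range(gl_x.size):
            tj = t_dec - 0.5 * st * gl_x[j]
            lp = _logpdf_one(tj, hit_upper, v, a, z, sv, eps)
            if lp > -np.inf:
                acc += 0.5 * gl_w[j] * math.exp(lp)
    if acc <= 0.0:
        return -np.inf
    return math.log(acc)


@njit(cache=False)
def _loglik_sum(rt, hit_upper, v, a, z, t0, sv, eps):
    """Sum of per-trial log densities; per-trial drift and boundary arrays."""
    total = 0.0
    for i in range(rt.size):
        lp = _logpdf_one(rt[i] - t0, hit_upper[i], v[i], a[i], z, sv, eps)
        if lp == -np.inf:
            return -np.inf
        total += lp
    return total


def _as_params_tuple(params: DDMParams):
    return params.v, params.a, params.z, params.t, params.sv, params.sz, params.st


def wfpt_density(
    t,
    boundary: str,
    params: DDMParams,
    rel_tol: float = 1e-6,
    from_stimulus_onset: bool = False,
) -> np.ndarray | float:
    """WFPT density (1/s) at the given boundary.

    Parameters
    ----------
    t
        Decision time(s) in seconds (time inside the diffusion).  With
        ``from_stimulus_onset=True``, ``t`` is instead measured from stimulus
        onset and the non-decision time ``params.t`` is subtracted first.
    boundary
        ``"upper"`` or ``"lower"``.
    params
        Diffusion parameters; ``sv`` is marginalized in closed form, and
        nonzero ``sz``/``st`` are marginalized by adaptive quadrature.
    rel_tol
        Relative tolerance in (0, 1e-3] controlling series term counts and
        quadrature convergence.

    Non-positive decision times have density 0 by contract (no passage can
    occur before the diffusion starts).
    """
    if not (0.0 < rel_tol <= 1e-3):
        raise ValueError(f"rel_tol={rel_tol} must lie in (0, 1e-3]")
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    hit_upper = boundary == "upper"
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    t_dec = t_arr - params.t if from_stimulus_onset else t_arr

    if params.sz > 0 or params.st > 0:
        vals = integrate_variabilities(
            t_dec, boundary, params, rel_tol=rel_tol
        )
    else:
        vals = np.empty_like(t_dec)
        for i, td in enumerate(t_dec):
            lp = _logpdf_one(
                td, hit_upper, params.v, params.a, params.z, params.sv, rel_tol
            )
            vals[i] = 0.0 if lp == -np.inf else math.exp(lp)
    return vals if np.ndim(t) else float(vals[0])


def integrate_variabilities(
    t_dec,
    boundary: str,
    params: DDMParams,
    rel_tol: float = 1e-6,
    max_nodes: int = 128,
) -> np.ndarray:
    """Marginal density over start-point and non-decision-time variability.

    Gauss-Legendre nodes are doubled until the result changes by less than
    ``rel_tol`` in relative terms (on values above an absolute floor of
    1e-12); raises :class:`QuadratureError` with the node count otherwise.
    Reduces exactly to :func:`wfpt_density` when ``sz == st == 0``.
    """
    hit_upper = boundary == "upper"
    t_arr = np.atleast_1d(np.asarray(t_dec, dtype=float))
    v, a, z, _, sv, sz, st = _as_params_tuple(params)

    def evaluate(n_nodes: int) -> np.ndarray:
        gl_x, gl_w = np.polynomial.legendre.leggauss(n_nodes)
        out = np.empty_like(t_arr)
        for i, td in enumerate(t_arr):
            lp = _logpdf_marginal(
                td, hit_upper, v, a, z, sv, sz, st, gl_x, gl_w, rel_tol
            )
            out[i] = 0.0 if lp == -np.inf else math.exp(lp)
        return out

    if sz == 0.0 and st == 0.0:
        return evaluate(1)

    n = 8
    prev = evaluate(n)
    while n < max_nodes:
        n *= 2
        cur = evaluate(n)
        scale = np.maximum(np.abs(cur), 1e-12)
        if np.max(np.abs(cur - prev) / scale) < rel_tol:
            return cur
        prev = cur
    raise QuadratureError(
        f"sz/st quadrature did not converge within {max_nodes} nodes per axis"
    )


def choice_probability(params: DDMParams) -> float:
    """Probability of absorption at the upper boundary (no variabilities).

    For drift v, boundary separation a and relative start z (start position
    x0 = a z) with unit diffusion coefficient:

        P(upper) = (1 - exp(-2 v a z)) / (1 - exp(-2 v a)),   v != 0
        P(upper) = z,                                          v == 0
    """
    if params.sv != 0 or params.sz != 0 or params.st != 0:
        raise ValueError(
            "closed-form choice probability requires sv = sz = st = 0"
        )
    v, a, z = params.v, params.a, params.z
    if v == 0.0:
        return z
    x = -2.0 * v * a
    # guard the large-|v| limits against overflow
    if x > 700:  # v -> -inf: ratio ~ exp(x (z - 1)) -> 0
        return float(math.exp(x * (z - 1.0)))
    if x < -700:  # v -> +inf
        return 1.0
    return float(np.expm1(x * z) / np.expm1(x))


def loglik(
    rt,
    hit_upper,
    v,
    params: DDMParams,
    rel_tol: float = 1e-6,
) -> float:
    """Total log-likelihood of trials under per-trial drift rates.

    Parameters
    ----------
    rt
        Response times from stimulus onset, in seconds.
    hit_upper
        Boolean array; True where the upper boundary was hit.
    v
        Scalar drift or per-trial drift array (params.v is ignored).
    params
        Shared a, z, t, sv (sz/st must be 0 here; use
        :func:`integrate_variabilities` for the marginal density).

    The sum is order-independent; any non-finite per-trial term raises with
    the offending trial index.
    """
    rt = np.asarray(rt, dtype=float)
    hit = np.asarray(hit_upper, dtype=bool)
    v_arr = np.broadcast_to(np.asarray(v, dtype=float), rt.shape).copy()
    a_arr = np.full_like(rt, params.a)
    if params.sz != 0 or params.st != 0:
        raise ValueError("loglik handles sv analytically but not sz/st")
    total = _loglik_sum(rt, hit, v_arr, a_arr, params.z, params.t, params.sv, rel_tol)
    if not np.isfinite(total):
        # locate the offender for the error message
        for i in range(rt.size):
            lp = _logpdf_one(
                rt[i] - params.t, bool(hit[i]), v_arr[i], params.a, params.z,
                params.sv, rel_tol,
            )
            if not np.isfinite(lp):
                raise ValueError(
                    f"non-finite log density at trial {i} "
                    f"(rt={rt[i]:.4f}s, decision time {rt[i]-params.t:.4f}s)"
                )
        raise ValueError("non-finite total log-likelihood")
    return float(total)
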