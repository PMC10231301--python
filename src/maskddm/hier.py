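"""Hierarchical Bayesian drift-diffusion inference.

The model estimates one drift-rate coefficient per mask condition
(cell-means coding) with participant random intercepts on drift, while
boundary separation, start point, non-decision time and across-trial drift
variability are shared across conditions ("averaging over mask conditions").
A follow-up variant instead indexes boundary separation by mask while
keeping drift-by-mask as a covariate.

Accuracy coding: the upper boundary is the correct response, so trials enter
the Wiener first-passage likelihood with ``hit_upper = correct`` and drift

    v_trial = beta[mask(trial)] + u[participant(trial)],
    u_j ~ Normal(0, sigma_u^2).

Sampling is adaptive Metropolis-within-Gibbs with scalar random-walk updates
in blocks (drift coefficients | participant intercepts | shared parameters),
proposal scales tuned toward ~30% acceptance during an initial tuning phase
and the burn-in, then frozen.  The recording protocol draws 5000 samples and
discards the first 200 as burn-in, retaining 4800.  Priors are weakly
informative and configuration-exposed (see :class:`Priors`).

Posterior hypothesis tests are fractions of retained draws satisfying a
contrast ("A > B", "A > 0", "A < 0"); exact ties contribute 1/2.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .wfpt import _logpdf_one

__all__ = [
    "Priors",
    "ModelSpec",
    "PosteriorDraws",
    "HypothesisTestResult",
    "build_model",
    "sample_posterior",
    "posterior_prob",
    "compare_fits",
    "fit_mask_drift",
    "ez_diffusion",
]


@dataclass(frozen=True)
class Priors:
    """Weakly informative priors (units as in :class:`~maskddm.wfpt.DDMParams`)."""

    drift_sd: float = 2.0           # Normal(0, drift_sd^2) on mask drift coefficients
    intercept_sd_scale: float = 1.0  # HalfNormal on the intercept SD
    a_mean: float = 1.5
    a_sd: float = 1.0               # Normal truncated to a > 0
    z_mean: float = 0.5
    z_sd: float = 0.25              # Normal truncated to (0, 1)
    t_mean: float = 0.3
    t_sd: float = 0.25              # Normal truncated to t >= 0
    sv_scale: float = 2.0           # HalfNormal


@dataclass(frozen=True)
class ModelSpec:
    """What the hierarchical model estimates.

    ``boundary_by_mask`` switches to the follow-up model: one boundary
    separation per mask, drift-by-mask retained as covariate.  ``estimate_z``
    and ``estimate_sv`` free the start point and drift variability; the
    start-point/non-decision ranges sz and st are fixed at zero in the
    likelihood (outliers are handled by exclusion upstream and the uniform
    ranges are weakly identified at these trial counts).
    """

    boundary_by_mask: bool = False
    estimate_z: bool = True
    estimate_sv: bool = True
    priors: Priors = field(default_factory=Priors)


@njit(cache=False)
def _ll_subset(idx, rt, hit, beta, u, mask_idx, pid_idx, a_by_mask, z, t0, sv, eps):
    total = 0.0
    for kk in range(idx.size):
        k = idx[kk]
        v = beta[mask_idx[k]] + u[pid_idx[k]]
        lp = _logpdf_one(rt[k] - t0, hit[k], v, a_by_mask[mask_idx[k]], z, sv, eps)
        if lp == -np.inf:
            return -np.inf
        total += lp
    return total


@njit(cache=False)
def _mh_groups(rt, hit, beta, u, mask_idx, pid_idx, a_by_mask, z, t0, sv, eps,
               order, ptr, update_beta, deltas, log_unif, prior_mu, prior_sd):
    """One Metropolis pass over the drift coefficients (``update_beta=True``)
    or the participant intercepts (False).

    ``order``/``ptr`` give the trials of each group in CSR layout; ``deltas``
    are the proposal increments and ``log_unif`` the log acceptance draws.
    Returns the per-group acceptance flags.  Updates ``beta``/``u`` in place.
    """
    n_groups = ptr.size - 1
    accepted = np.zeros(n_groups, np.bool_)
    for g in range(n_groups):
        cur = beta[g] if update_beta else u[g]
        prop = cur + deltas[g]
        shift = prop - cur
        ll_cur = 0.0
        ll_prop = 0.0
        bad = False
        for kk in range(ptr[g], ptr[g + 1]):
            i = order[kk]
            vc = beta[mask_idx[i]] + u[pid_idx[i]]
            td = rt[i] - t0
            ai = a_by_mask[mask_idx[i]]
            lc = _logpdf_one(td, hit[i], vc, ai, z, sv, eps)
            lp = _logpdf_one(td, hit[i], vc + shift, ai, z, sv, eps)
            if lp == -np.inf:
                bad = True
                break
            if lc == -np.inf:
                # current state unsupported here: accept any supported move
                ll_cur = -np.inf
            ll_cur += lc
            ll_prop += lp
        if bad:
            continue
        d = ll_prop - ll_cur
        d += (
            -0.5 * ((prop - prior_mu) / prior_sd) ** 2
            + 0.5 * ((cur - prior_mu) / prior_sd) ** 2
        )
        if d >= 0.0 or log_unif[g] < d:
            accepted[g] = True
            if update_beta:
                beta[g] = prop
            else:
                u[g] = prop
    return accepted


def ez_diffusion(p_correct: float, rt_var: float, rt_mean: float):
    """Closed-form method-of-moments diffusion estimates (unit diffusion).

    Maps accuracy, correct-RT variance and mean to (v, a, non-decision time);
    used only to initialize the sampler near a reasonable state.
    """
    pc = min(max(p_correct, 0.02), 0.98)
    if abs(pc - 0.5) < 1e-3:
        pc = 0.5 + 1e-3
    L = math.log(pc / (1 - pc))
    x = L * (L * pc * pc - L * pc + pc - 0.5) / max(rt_var, 1e-4)
    v = math.copysign(abs(x) ** 0.25, pc - 0.5)
    a = L / v
    y = -v * a
    mdt = (a / (2 * v)) * (1 - math.exp(y)) / (1 + math.exp(y))
    ter = rt_mean - mdt
    return v, a, ter


class HierarchicalDDM:
    """Compiled trial arrays plus the block-wise log-posterior pieces."""

    def __init__(self, trials: pd.DataFrame | None, spec: ModelSpec,
                 masks: list[str] | None = None):
        self.spec = spec
        if trials is None or len(trials) == 0:
            # prior-only mode: no data, sampler reproduces the prior
            self.masks = list(masks) if masks else ["none"]
            self.pids = []
            self.rt = np.empty(0)
            self.hit = np.empty(0, bool)
            self.mask_idx = np.empty(0, np.int64)
            self.pid_idx = np.empty(0, np.int64)
            self.mask_trial_idx = [np.empty(0, np.int64) for _ in self.masks]
            self.pid_trial_idx = []
            self.all_idx = np.empty(0, np.int64)
            self.mask_order = np.empty(0, np.int64)
            self.mask_ptr = np.zeros(len(self.masks) + 1, np.int64)
            self.pid_order = np.empty(0, np.int64)
            self.pid_ptr = np.zeros(1, np.int64)
            self.min_rt = np.inf
            return
        required = {"participant_id", "mask", "correct", "rt_ms"}
        missing = required - set(trials.columns)
        if missing:
            raise ValueError(f"trials missing columns: {sorted(missing)}")
        order = ["lower", "upper", "none"]
        present = [m for m in order if m in set(trials["mask"])]
        present += sorted(set(trials["mask"]) - set(order))
        self.masks = present
        counts = trials.groupby(["mask"]).size()
        empty = [m for m in self.masks if counts.get(m, 0) == 0]
        if empty:
            raise ValueError(f"empty drift cells for masks: {empty}")
        self.pids = sorted(trials["participant_id"].unique().tolist())
        pid_map = {p: i for i, p in enumerate(self.pids)}
        mask_map = {m: i for i, m in enumerate(self.masks)}
        self.rt = trials["rt_ms"].to_numpy(float) / 1000.0
        self.hit = trials["correct"].to_numpy(bool)
        self.mask_idx = trials["mask"].map(mask_map).to_numpy(np.int64)
        self.pid_idx = trials["participant_id"].map(pid_map).to_numpy(np.int64)
        self.all_idx = np.arange(len(trials), dtype=np.int64)
        self.mask_trial_idx = [
            np.flatnonzero(self.mask_idx == i) for i in range(len(self.masks))
        ]
        self.pid_trial_idx = [
            np.flatnonzero(self.pid_idx == j) for j in range(len(self.pids))
        ]
        self.mask_order, self.mask_ptr = self._csr(self.mask_idx, len(self.masks))
        self.pid_order, self.pid_ptr = self._csr(self.pid_idx, len(self.pids))
        self.min_rt = float(self.rt.min())

    @staticmethod
    def _csr(idx: np.ndarray, n_groups: int) -> tuple[np.ndarray, np.ndarray]:
        order = np.argsort(idx, kind="stable").astype(np.int64)
        counts = np.bincount(idx, minlength=n_groups)
        ptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        return order, ptr

    # -- initial state ------------------------------------------------------
    def initial_state(self) -> dict:
        n_mask, n_pid = len(self.masks), len(self.pids)
        state = {
            "beta": np.zeros(n_mask),
            "u": np.zeros(n_pid),
            "sigma_u": 0.2,
            "a": np.full(n_mask if self.spec.boundary_by_mask else 1, 1.5),
            "z": 0.5,
            "t": 0.2,
            "sv": 0.2 if self.spec.estimate_sv else 0.0,
        }
        if self.rt.size == 0:
            state["a"] = np.full_like(state["a"], self.spec.priors.a_mean)
            state["t"] = self.spec.priors.t_mean
            return state
        a_list, t_list = [], []
        for i, idx in enumerate(self.mask_trial_idx):
            pc = float(self.hit[idx].mean())
            rt_c = self.rt[idx][self.hit[idx]]
            if rt_c.size < 5:
                rt_c = self.rt[idx]
            v, a, ter = ez_diffusion(pc, float(rt_c.var()), float(rt_c.mean()))
            state["beta"][i] = np.clip(v, -4.0, 4.0)
            a_list.append(a)
            t_list.append(ter)
        a0 = float(np.clip(np.mean(a_list), 0.5, 3.5))
        t0 = float(np.clip(np.mean(t_list), 0.05, 0.9 * self.min_rt))
        t0 = min(t0, 0.9 * self.min_rt)
        state["a"] = np.full_like(state["a"], a0)
        state["t"] = max(t0, 1e-3)
        return state

    # -- likelihood pieces --------------------------------------------------
    def ll(self, idx, state, beta=None, u=None, a=None, z=None, t=None, sv=None):
        beta = state["beta"] if beta is None else beta
        u = state["u"] if u is None else u
        a_vec = state["a"] if a is None else a
        a_by_mask = (
            a_vec if self.spec.boundary_by_mask
            else np.full(len(self.masks), float(a_vec[0]))
        )
        return _ll_subset(
            idx, self.rt, self.hit, beta, u, self.mask_idx, self.pid_idx,
            a_by_mask,
            state["z"] if z is None else z,
            state["t"] if t is None else t,
            state["sv"] if sv is None else sv,
            1e-6,
        )


def build_model(trials: pd.DataFrame | None, spec: ModelSpec | None = None,
                masks: list[str] | None = None) -> HierarchicalDDM:
    """Compile preprocessed trials into a sampler-ready model object.

    ``trials=None`` (or an empty table) enters prior-only mode for sampler
    validation.  Raises when any mask cell is empty, naming the cell.
    """
    return HierarchicalDDM(trials, spec or ModelSpec(), masks=masks)


@dataclass
class PosteriorDraws:
    """Retained MCMC draws plus protocol metadata and diagnostics."""

    draws: pd.DataFrame            # retained draws x named parameters
    intercepts: pd.DataFrame       # retained draws x participant intercepts
    n_samples: int
    burn_in: int
    seed: int
    accept_rates: dict
    ess: dict
    rhat: dict

    @property
    def n_retained(self) -> int:
        return len(self.draws)


@dataclass(frozen=True)
class HypothesisTestResult:
    label: str
    probability: float
    contrast: str


def _norm_logpdf(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - math.log(sd) - 0.5 * math.log(2 * math.pi)


class _Adapt:
    """Robbins-Monro scale adaptation toward a target acceptance rate."""

    def __init__(self, scale, target=0.3):
        self.log_s = math.log(scale)
        self.target = target
        self.k = 0

    def update(self, accepted: bool, adapting: bool):
        if adapting:
            self.k += 1
            gamma = min(0.5, 2.0 / math.sqrt(self.k))
            self.log_s += gamma * ((1.0 if accepted else 0.0) - self.target)

    @property
    def scale(self):
        return math.exp(self.log_s)


def sample_posterior(
    model: HierarchicalDDM,
    n_samples: int = 5000,
    burn_in: int = 200,
    seed: int = 0,
    tune: int = 300,
) -> PosteriorDraws:
    """Draw from the posterior with adaptive Metropolis-within-Gibbs.

    ``tune`` extra adaptation-only sweeps precede the recorded run; proposal
    scales keep adapting through the ``burn_in`` recorded sweeps and are
    frozen for the retained draws.  Identical seeds yield identical draws.
    """
    if burn_in >= n_samples:
        raise ValueError("burn_in must be smaller than n_samples")
    rng = np.random.default_rng(seed)
    spec = model.spec
    pri = spec.priors
    state = model.initial_state()
    n_mask, n_pid = len(model.masks), len(model.pids)
    have_data = model.rt.size > 0

    if have_data:
        ll0 = model.ll(model.all_idx, state)
        if not np.isfinite(ll0):
            # fall back to a conservative non-decision time and retry
            state["t"] = min(0.5 * model.min_rt, 0.1)
            ll0 = model.ll(model.all_idx, state)
            if not np.isfinite(ll0):
                raise RuntimeError("non-finite log-posterior at initialization")

    ad_beta = [_Adapt(0.15) for _ in range(n_mask)]
    ad_u = [_Adapt(0.3) for _ in range(n_pid)]
    ad_a = [_Adapt(0.05) for _ in range(len(state["a"]))]
    ad = {"z": _Adapt(0.08), "t": _Adapt(0.02), "sv": _Adapt(0.25),
          "sigma_u": _Adapt(0.3)}
    acc_count: dict[str, list] = {"beta": [0, 0], "u": [0, 0], "shared": [0, 0]}

    def mh(delta_logpost, name):
        acc_count[name][1] += 1
        if delta_logpost >= 0 or math.log(rng.random()) < delta_logpost:
            acc_count[name][0] += 1
            return True
        return False

    records = np.empty((n_samples, n_mask + len(state["a"]) + 4), float)
    u_records = np.empty((n_samples, n_pid), float)

    eps = 1e-6
    total_sweeps = tune + n_samples
    for sweep in range(total_sweeps):
        adapting = sweep < tune + burn_in
        a_by_mask = (
            state["a"] if spec.boundary_by_mask
            else np.full(n_mask, float(state["a"][0]))
        )
        # --- drift coefficients (fused Metropolis pass) -------------------
        deltas = rng.standard_normal(n_mask) * np.array([x.scale for x in ad_beta])
        log_unif = np.log(rng.random(n_mask))
        acc = _mh_groups(
            model.rt, model.hit, state["beta"], state["u"],
            model.mask_idx, model.pid_idx, a_by_mask,
            state["z"], state["t"], state["sv"], eps,
            model.mask_order, model.mask_ptr, True, deltas, log_unif,
            0.0, pri.drift_sd,
        )
        for m in range(n_mask):
            ad_beta[m].update(bool(acc[m]), adapting)
        acc_count["beta"][0] += int(acc.sum())
        acc_count["beta"][1] += n_mask
        # --- participant intercepts (fused Metropolis pass) ---------------
        if n_pid:
            deltas = rng.standard_normal(n_pid) * np.array([x.scale for x in ad_u])
            log_unif = np.log(rng.random(n_pid))
            acc = _mh_groups(
                model.rt, model.hit, state["beta"], state["u"],
                model.mask_idx, model.pid_idx, a_by_mask,
                state["z"], state["t"], state["sv"], eps,
                model.pid_order, model.pid_ptr, False, deltas, log_unif,
                0.0, state["sigma_u"],
            )
            for j in range(n_pid):
                ad_u[j].update(bool(acc[j]), adapting)
            acc_count["u"][0] += int(acc.sum())
            acc_count["u"][1] += n_pid
        # --- intercept SD (log random walk, half-normal prior) ------------
        cur = state["sigma_u"]
        prop_s = cur * math.exp(rng.normal(0.0, ad["sigma_u"].scale))
        d = (
            -0.5 * (prop_s / pri.intercept_sd_scale) ** 2
            + 0.5 * (cur / pri.intercept_sd_scale) ** 2
            + math.log(prop_s) - math.log(cur)  # Jacobian of the log walk
        )
        if n_pid:
            d += sum(_norm_logpdf(x, 0.0, prop_s) for x in state["u"]) - sum(
                _norm_logpdf(x, 0.0, cur) for x in state["u"]
            )
        ok = mh(d, "shared")
        ad["sigma_u"].update(ok, adapting)
        if ok:
            state["sigma_u"] = prop_s
        # --- boundary separation(s) ---------------------------------------
        if spec.boundary_by_mask:
            for k in range(len(state["a"])):
                idx = model.mask_trial_idx[k]
                prop = state["a"].copy()
                prop[k] *= math.exp(rng.normal(0.0, ad_a[k].scale))
                d = (
                    _norm_logpdf(prop[k], pri.a_mean, pri.a_sd)
                    - _norm_logpdf(state["a"][k], pri.a_mean, pri.a_sd)
                    + math.log(prop[k]) - math.log(state["a"][k])
                )
                if have_data and idx.size:
                    d += model.ll(idx, state, a=prop) - model.ll(idx, state)
                ok = mh(d, "shared")
                ad_a[k].update(ok, adapting)
                if ok:
                    state["a"] = prop
            ll_total = model.ll(model.all_idx, state) if have_data else 0.0
        else:
            ll_total = model.ll(model.all_idx, state) if have_data else 0.0
            prop = state["a"].copy()
            prop[0] *= math.exp(rng.normal(0.0, ad_a[0].scale))
            d = (
                _norm_logpdf(prop[0], pri.a_mean, pri.a_sd)
                - _norm_logpdf(state["a"][0], pri.a_mean, pri.a_sd)
                + math.log(prop[0]) - math.log(state["a"][0])
            )
            ll_prop = model.ll(model.all_idx, state, a=prop) if have_data else 0.0
            d += ll_prop - ll_total
            ok = mh(d, "shared")
            ad_a[0].update(ok, adapting)
            if ok:
                state["a"] = prop
                ll_total = ll_prop
        # --- start point (logit random walk, truncated-normal prior) ------
        if spec.estimate_z:
            cur = state["z"]
            logit = math.log(cur / (1 - cur)) + rng.normal(0.0, ad["z"].scale)
            prop_z = 1.0 / (1.0 + math.exp(-logit))
            d = (
                _norm_logpdf(prop_z, pri.z_mean, pri.z_sd)
                - _norm_logpdf(cur, pri.z_mean, pri.z_sd)
                + math.log(prop_z * (1 - prop_z)) - math.log(cur * (1 - cur))
            )
            ll_prop = model.ll(model.all_idx, state, z=prop_z) if have_data else 0.0
            d += ll_prop - ll_total
            ok = mh(d, "shared")
            ad["z"].update(ok, adapting)
            if ok:
                state["z"] = prop_z
                ll_total = ll_prop
        # --- non-decision time --------------------------------------------
        cur = state["t"]
        prop_t = cur + rng.normal(0.0, ad["t"].scale)
        if prop_t <= 0:
            d = -np.inf
        else:
            d = _norm_logpdf(prop_t, pri.t_mean, pri.t_sd) - _norm_logpdf(
                cur, pri.t_mean, pri.t_sd
            )
            ll_prop = model.ll(model.all_idx, state, t=prop_t) if have_data else 0.0
            d += ll_prop - ll_total
        ok = mh(d, "shared")
        ad["t"].update(ok, adapting)
        if ok:
            state["t"] = prop_t
            ll_total = ll_prop
        # --- drift variability (log random walk, half-normal prior) -------
        if spec.estimate_sv:
            cur = state["sv"]
            prop_sv = cur * math.exp(rng.normal(0.0, ad["sv"].scale))
            d = (
                -0.5 * (prop_sv / pri.sv_scale) ** 2
                + 0.5 * (cur / pri.sv_scale) ** 2
                + math.log(prop_sv) - math.log(cur)
            )
            ll_prop = model.ll(model.all_idx, state, sv=prop_sv) if have_data else 0.0
            d += ll_prop - ll_total
            ok = mh(d, "shared")
            ad["sv"].update(ok, adapting)
            if ok:
                state["sv"] = prop_sv
                ll_total = ll_prop

        if sweep >= tune:
            i = sweep - tune
            rec = [*state["beta"], *state["a"], state["z"], state["t"],
                   state["sv"], state["sigma_u"]]
            records[i] = rec
            u_records[i] = state["u"]

    if model.spec.boundary_by_mask:
        a_names = [f"a_{m}" for m in model.masks]
    else:
        a_names = ["a"]
    names = [f"v_{m}" for m in model.masks] + a_names + ["z", "t", "sv", "sigma_u"]
    draws = pd.DataFrame(records[burn_in:], columns=names)
    intercepts = pd.DataFrame(
        u_records[burn_in:], columns=[f"u_{p}" for p in model.pids]
    )

    accept_rates = {
        k: (v[0] / v[1] if v[1] else float("nan")) for k, v in acc_count.items()
    }
    ess, rhat = _diagnostics(draws)
    return PosteriorDraws(
        draws=draws, intercepts=intercepts, n_samples=n_samples,
        burn_in=burn_in, seed=seed, accept_rates=accept_rates,
        ess=ess, rhat=rhat,
    )


def _diagnostics(draws: pd.DataFrame) -> tuple[dict, dict]:
    """Split-chain convergence statistic and effective sample size (arviz)."""
    import arviz as az

    ess, rhat = {}, {}
    for col in draws.columns:
        x = draws[col].to_numpy()
        if np.allclose(x, x[0]):
            ess[col] = float("nan")
            rhat[col] = float("nan")
            continue
        half = len(x) // 2
        split = np.stack([x[:half], x[half: 2 * half]])
        ess[col] = float(az.ess(np.asarray([x])))
        rhat[col] = float(az.rhat(split))
    return ess, rhat


_CONTRAST_RE = re.compile(r"^\s*(\S+)\s*([<>])\s*(\S+)\s*$")


def posterior_prob(
    draws: PosteriorDraws | pd.DataFrame, contrast: str, label: str | None = None
) -> HypothesisTestResult:
    """Posterior probability of a contrast over retained draws.

    ``contrast`` is of the form ``"A > B"``, ``"A > 0"`` or ``"A < 0"``
    where A/B name draw columns.  Exact ties count 1/2 (so identical columns
    give probability 0.5).
    """
    df = draws.draws if isinstance(draws, PosteriorDraws) else draws
    m = _CONTRAST_RE.match(contrast)
    if not m:
        raise ValueError(f"cannot parse contrast {contrast!r}")
    left, op, right = m.groups()

    def column(name):
        try:
            return float(name) * np.ones(len(df))
        except ValueError:
            pass
        if name not in df.columns:
            raise KeyError(f"unknown parameter {name!r}; have {list(df.columns)}")
        return df[name].to_numpy()

    lhs, rhs = column(left), column(right)
    if op == "<":
        lhs, rhs = rhs, lhs
    prob = float(np.mean(lhs > rhs) + 0.5 * np.mean(lhs == rhs))
    return HypothesisTestResult(label or contrast, prob, contrast)


def compare_fits(
    draws_study1: PosteriorDraws | pd.DataFrame,
    draws_study2: PosteriorDraws | pd.DataFrame,
    coef: str = "v_lower",
    reference: str = "v_none",
    seed: int = 0,
) -> HypothesisTestResult:
    """P((coef - reference) in fit 2  >  (coef - reference) in fit 1).

    The two fits are treated as independent; draws are paired by index, and
    mismatched draw counts are reconciled by resampling both margins with
    replacement to the larger count (seeded).
    """
    d1 = draws_study1.draws if isinstance(draws_study1, PosteriorDraws) else draws_study1
    d2 = draws_study2.draws if isinstance(draws_study2, PosteriorDraws) else draws_study2
    diff1 = (d1[coef] - d1[reference]).to_numpy()
    diff2 = (d2[coef] - d2[reference]).to_numpy()
    if len(diff1) != len(diff2):
        rng = np.random.default_rng(seed)
        n = max(len(diff1), len(diff2))
        diff1 = rng.choice(diff1, n, replace=True)
        diff2 = rng.choice(diff2, n, replace=True)
    prob = float(np.mean(diff2 > diff1) + 0.5 * np.mean(diff2 == diff1))
    label = f"P(({coef}-{reference})_2 > ({coef}-{reference})_1)"
    return HypothesisTestResult(label, prob, label)


def fit_mask_drift(
    trials: pd.DataFrame,
    spec: ModelSpec | None = None,
    n_samples: int = 5000,
    burn_in: int = 200,
    seed: int = 0,
    tune: int = 300,
) -> tuple[HierarchicalDDM, PosteriorDraws]:
    """Convenience: build the mask-drift model on (a subset of) trials and sample."""
    model = build_model(trials, spec)
    draws = sample_posterior(model, n_samples=n_samples, burn_in=burn_in,
                             seed=seed, tune=tune)
    return model, draws
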