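"""Mixed-effect regressions for ratings and response times.

Emotion ratings (binary) are analysed with mixed binomial logistic models
with participant random intercepts; the random effect is integrated out by
Gauss-Hermite quadrature and the marginal likelihood maximized directly.
With the intercept SD at zero this reduces exactly to ordinary logistic
regression, so on a 2x2 table without clustering the mask coefficient equals
the closed-form log odds ratio.

Log response times use a mixed linear model (statsmodels ``MixedLM``) with
mask x accuracy interactions and simple effects of mask within correct and
incorrect responses, mirroring the standard RT-table layout.

Confidence intervals come from a cluster bootstrap: participants (the
random-effect unit) are resampled with replacement and the model refit; the
95% interval is the percentile interval over 1,000 iterations by default.

``fp_cascade`` runs the staged false-positive analysis over all 30
incongruent expression/judgment pairings: ratings always, response times
only where the rating effect is significant, drift rates only where the RT
effect is significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionResult",
    "fit_logistic_mixed",
    "fit_linear_mixed",
    "bootstrap_ci",
    "chance_test",
    "fp_cascade",
]

MASK_LEVELS = ("lower", "upper", "none")


@dataclass
class RegressionResult:
    """Fixed-effect estimates with optional bootstrap CIs.

    ``terms`` maps term name -> dict with keys ``b``, ``stat`` (z or t),
    ``p``, and once bootstrapped ``ci_low``/``ci_high``.
    """

    terms: dict = field(default_factory=dict)
    kind: str = "logistic"          # "logistic" | "linear"
    sigma_u: float = 0.0            # random-intercept SD (point estimate)
    n_obs: int = 0
    n_groups: int = 0
    n_boot: int | None = None
    seed: int | None = None
    converged: bool = True

    def coef(self, term: str) -> float:
        return self.terms[term]["b"]

    def table(self) -> pd.DataFrame:
        df = pd.DataFrame(self.terms).T
        df.index.name = "term"
        return df


class SeparationError(RuntimeError):
    """Complete separation: the logistic likelihood has no finite maximizer."""


def _design_mask(trials: pd.DataFrame, reference: str = "none",
                 extra_cols: tuple = ()) -> tuple[np.ndarray, list[str]]:
    levels = [m for m in MASK_LEVELS if m in set(trials["mask"])]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} absent from data")
    others = [m for m in levels if m != reference]
    cols = [np.ones(len(trials))]
    names = ["intercept"]
    for m in others:
        cols.append((trials["mask"] == m).to_numpy(float))
        names.append(f"{m} > {reference}")
    for c in extra_cols:
        cols.append(trials[c].to_numpy(float))
        names.append(c)
    return np.column_stack(cols), names


def _check_separation(y: np.ndarray, X: np.ndarray, names: list[str]) -> None:
    # a dummy column whose level is all-success or all-failure separates
    for j in range(1, X.shape[1]):
        col = X[:, j]
        if set(np.unique(col)) <= {0.0, 1.0}:
            for val in (0.0, 1.0):
                sub = y[col == val]
                if sub.size and (sub.all() or not sub.any()):
                    raise SeparationError(
                        f"complete separation on term {names[j]!r}"
                    )
    if y.all() or not y.any():
        raise SeparationError("outcome is constant")


def fit_logistic_mixed(
    trials: pd.DataFrame,
    outcome: str = "response_yes",
    reference: str = "none",
    group: str | None = "participant_id",
    n_gh: int = 15,
    mask_term: bool = True,
    compute_se: bool = True,
    start_params: np.ndarray | None = None,
) -> RegressionResult:
    """Random-intercept logistic regression of a binary outcome on mask.

    The participant intercept is integrated out with ``n_gh``-node
    Gauss-Hermite quadrature and (beta, sigma_u) estimated by maximum
    marginal likelihood (sigma_u bounded at 0, where the model collapses to
    ordinary logistic regression).  Two-tailed z statistics come from the
    inverse observed information.

    ``outcome`` may be a column name or a boolean Series aligned to trials.
    Set ``mask_term=False`` for an intercept-only model (chance testing).
    """
    y = (
        np.asarray(outcome, dtype=float)
        if not isinstance(outcome, str)
        else trials[outcome].to_numpy(float)
    )
    if mask_term:
        if trials["mask"].nunique() < 2:
            raise ValueError("need at least two mask levels")
        X, names = _design_mask(trials, reference)
    else:
        X, names = np.ones((len(trials), 1)), ["intercept"]
    _check_separation(y.astype(bool), X, names)

    if group is None:
        group_idx = np.zeros(len(trials), dtype=int)
        n_groups = 1
        free_sigma = False
    else:
        codes, uniques = pd.factorize(trials[group])
        group_idx = codes
        n_groups = len(uniques)
        free_sigma = n_groups > 1

    # presort by group so within-group sums are contiguous reduceat slices
    order = np.argsort(group_idx, kind="stable")
    X = X[order]
    y = y[order]
    group_sorted = group_idx[order]
    ptr = np.concatenate([[0], np.flatnonzero(np.diff(group_sorted)) + 1])

    gh_x, gh_w = np.polynomial.hermite_e.hermegauss(n_gh)  # weight e^{-x^2/2}
    log_gh_w = np.log(gh_w) - 0.5 * np.log(2 * np.pi)

    def nll(params):
        beta, sigma = params[:-1], params[-1]
        eta = X @ beta
        if sigma <= 1e-8:
            ll = y * eta - np.logaddexp(0.0, eta)
            return -float(ll.sum())
        # per-trial log-lik at each node, summed within participant
        b_nodes = sigma * gh_x  # (K,)
        eta_k = eta[:, None] + b_nodes[None, :]
        ll_k = y[:, None] * eta_k - np.logaddexp(0.0, eta_k)
        grouped = np.add.reduceat(ll_k, ptr, axis=0)  # (J, K)
        return -float(special.logsumexp(grouped + log_gh_w, axis=1).sum())

    def nll_grad(params):
        beta, sigma = params[:-1], params[-1]
        eta = X @ beta
        if sigma <= 1e-8:
            p = special.expit(eta)
            ll = y * eta - np.logaddexp(0.0, eta)
            g = np.append(-X.T @ (y - p), 0.0)
            return -float(ll.sum()), g
        b_nodes = sigma * gh_x
        eta_k = eta[:, None] + b_nodes[None, :]
        p_k = special.expit(eta_k)
        ll_k = y[:, None] * eta_k - np.logaddexp(0.0, eta_k)
        grouped = np.add.reduceat(ll_k, ptr, axis=0) + log_gh_w  # (J, K)
        lse = special.logsumexp(grouped, axis=1, keepdims=True)
        alpha = np.exp(grouped - lse)  # responsibilities over nodes
        r_k = y[:, None] - p_k  # (n, K)
        grad = np.empty(len(params))
        for d in range(X.shape[1]):
            g_jk = np.add.reduceat(r_k * X[:, d, None], ptr, axis=0)
            grad[d] = -(alpha * g_jk).sum()
        g_sigma = np.add.reduceat(r_k, ptr, axis=0) * gh_x[None, :]
        grad[-1] = -(alpha * g_sigma).sum()
        return -float(lse.sum()), grad

    if start_params is not None and len(start_params) == X.shape[1] + 1:
        start = np.asarray(start_params, dtype=float).copy()
        start[-1] = max(start[-1], 0.0) if free_sigma else 0.0
    else:
        start = np.append(np.zeros(X.shape[1]), 0.3 if free_sigma else 0.0)
    bounds = [(None, None)] * X.shape[1] + [(0.0, None) if free_sigma else (0.0, 0.0)]
    res = optimize.minimize(nll_grad, start, jac=True, method="L-BFGS-B",
                            bounds=bounds)
    params = res.x
    beta, sigma = params[:-1], params[-1]

    if compute_se:
        # observed information for the fixed effects (profile over free params)
        free = list(range(X.shape[1])) + (
            [X.shape[1]] if free_sigma and sigma > 1e-6 else []
        )
        hess = _numeric_hessian(nll, params, free)
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(hess)
        se = np.sqrt(np.clip(np.diag(cov)[: X.shape[1]], 0, np.inf))
    else:
        se = np.full(X.shape[1], np.nan)

    terms = {}
    for j, name in enumerate(names):
        z = beta[j] / se[j] if se[j] > 0 else np.nan
        terms[name] = {
            "b": float(beta[j]),
            "stat": float(z),
            "p": float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
        }
    return RegressionResult(
        terms=terms, kind="logistic", sigma_u=float(sigma),
        n_obs=len(trials), n_groups=n_groups, converged=bool(res.success),
    )


def _numeric_hessian(f, x, free, eps=1e-4):
    n = len(free)
    H = np.zeros((n, n))
    for ii, i in enumerate(free):
        for jj, j in enumerate(free):
            if jj < ii:
                H[ii, jj] = H[jj, ii]
                continue
            xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
            xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
            H[ii, jj] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * eps * eps)
    # guard the sigma=0 boundary where the row can be degenerate
    full = np.zeros((len(x), len(x)))
    for ii, i in enumerate(free):
        for jj, j in enumerate(free):
            full[i, j] = H[ii, jj]
    for i in range(len(x)):
        if i not in free:
            full[i, i] = 1.0
    return full[np.ix_(free, free)]


def fit_linear_mixed(
    trials: pd.DataFrame,
    outcome: str = "log_rt",
    reference: str = "none",
    by_accuracy: bool = True,
    group: str = "participant_id",
) -> RegressionResult:
    """Mixed linear model of log RT on mask (x accuracy) with participant intercepts.

    With ``by_accuracy=True`` the model is ``log_rt ~ mask * correct`` and the
    result includes, per non-reference mask level m, the interaction term
    ``m x rating`` plus simple effects ``Correct: m > none`` and
    ``Incorrect: m > none`` (fit within the accuracy subsets, as the RT
    tables report them).  Requires both accuracy levels when interactions are
    requested.  Raises on rank deficiency, naming the collinear term.
    """
    import statsmodels.api as sm

    def _mixedlm(sub: pd.DataFrame, with_inter: bool):
        X, names = _design_mask(sub, reference)
        if with_inter:
            corr = sub["correct"].to_numpy(float)
            inter_cols, inter_names = [], []
            for j, nm in enumerate(names[1:], start=1):
                inter_cols.append(X[:, j] * corr)
                inter_names.append(f"{nm.split(' > ')[0]} x rating")
            X = np.column_stack([X, corr[:, None], *[c[:, None] for c in inter_cols]])
            names = names + ["rating"] + inter_names
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ValueError(
                f"rank-deficient design ({rank} < {X.shape[1]}); "
                f"collinear terms among {names}"
            )
        yv = sub[outcome].to_numpy(float)
        groups = sub[group].to_numpy()
        if len(np.unique(groups)) > 1 and np.ptp(yv) > 0:
            model = sm.MixedLM(yv, X, groups=groups)
            try:
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = model.fit(reml=True, method="lbfgs")
                params = fit.fe_params
                tvals = fit.tvalues[: len(names)]
                pvals = fit.pvalues[: len(names)]
                sig = float(np.sqrt(max(fit.cov_re.iloc[0, 0], 0.0)))
                return names, params, tvals, pvals, sig, True
            except Exception as exc:  # singular random-effect fits fall back to OLS
                logger.debug("MixedLM failed (%s); falling back to OLS", exc)
        fit = sm.OLS(yv, X).fit()
        return names, fit.params, fit.tvalues, fit.pvalues, 0.0, True

    terms: dict = {}
    if by_accuracy:
        if trials["correct"].nunique() < 2:
            raise ValueError("interaction model needs both accuracy levels")
        names, params, tvals, pvals, sigma, ok = _mixedlm(trials, with_inter=True)
        for nm, b, t, p in zip(names, params, tvals, pvals):
            if nm.endswith("x rating"):
                terms[nm] = {"b": float(b), "stat": float(t), "p": float(p)}
        for label, flag in (("Correct", True), ("Incorrect", False)):
            sub = trials[trials["correct"] == flag]
            s_names, s_params, s_t, s_p, _, _ = _mixedlm(sub, with_inter=False)
            for nm, b, t, p in zip(s_names, s_params, s_t, s_p):
                if nm == "intercept":
                    continue
                terms[f"{label}: {nm}"] = {
                    "b": float(b), "stat": float(t), "p": float(p)
                }
    else:
        names, params, tvals, pvals, sigma, ok = _mixedlm(trials, with_inter=False)
        for nm, b, t, p in zip(names, params, tvals, pvals):
            terms[nm] = {"b": float(b), "stat": float(t), "p": float(p)}
    return RegressionResult(
        terms=terms, kind="linear", sigma_u=float(sigma),
        n_obs=len(trials), n_groups=trials[group].nunique(),
    )


def bootstrap_ci(
    fit_fn,
    trials: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    group: str = "participant_id",
    max_fail_frac: float = 0.05,
) -> RegressionResult:
    """Cluster-bootstrap percentile CIs for every term of ``fit_fn(trials)``.

    Participants are resampled with replacement (and relabelled so repeated
    draws stay distinct clusters); each resample is refit and the 2.5/97.5
    percentiles attached to the point-estimate result.  More than
    ``max_fail_frac`` failed refits raises with the failure log.
    """
    base = fit_fn(trials)
    rng = np.random.default_rng(seed)
    group_vals = trials[group].to_numpy()
    pids = trials[group].unique()
    row_idx = {p: np.flatnonzero(group_vals == p) for p in pids}
    samples: dict[str, list] = {t: [] for t in base.terms}
    failures: list[str] = []
    for _ in range(n_boot):
        chosen = rng.choice(pids, size=len(pids), replace=True)
        parts = [row_idx[p] for p in chosen]
        idx = np.concatenate(parts)
        resampled = trials.iloc[idx].copy()
        # relabel so repeated draws stay distinct clusters
        resampled[group] = np.repeat(
            [f"boot_{k}" for k in range(len(chosen))],
            [len(p) for p in parts],
        )
        try:
            fit = fit_fn(resampled)
        except Exception as exc:
            failures.append(str(exc))
            continue
        for t in samples:
            samples[t].append(fit.terms.get(t, {}).get("b", np.nan))
    if len(failures) > max_fail_frac * n_boot:
        raise RuntimeError(
            f"{len(failures)}/{n_boot} bootstrap refits failed; first: {failures[0]}"
        )
    for t, vals in samples.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[np.isfinite(arr)]
        lo, hi = np.percentile(arr, [2.5, 97.5])
        base.terms[t]["ci_low"] = float(lo)
        base.terms[t]["ci_high"] = float(hi)
    base.n_boot = n_boot
    base.seed = seed
    return base


def chance_test(trials: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Above-chance accuracy per mask condition.

    Fits an intercept-only mixed logistic per condition on the correctness
    outcome; the intercept's two-tailed test against 0 is the test of
    accuracy against chance (50%).  Returns one row per mask with the
    intercept estimate, z, p, and the verdict.
    """
    rows = []
    for mask, sub in trials.groupby("mask"):
        if len(sub) < 2:
            raise ValueError(f"condition {mask!r} has fewer than 2 trials")
        y = sub["correct"].astype(float)
        if y.all() or not y.any():
            # degenerate accuracy: the log-odds diverges but the verdict is
            # immediate (every response on one side of chance)
            sign = 1.0 if y.all() else -1.0
            rows.append(
                {
                    "mask": mask,
                    "b": sign * np.inf,
                    "z": sign * np.inf,
                    "p": 0.0,
                    "above_chance": bool(y.all()),
                }
            )
            continue
        fit = fit_logistic_mixed(sub, outcome=y, mask_term=False)
        term = fit.terms["intercept"]
        rows.append(
            {
                "mask": mask,
                "b": term["b"],
                "z": term["stat"],
                "p": term["p"],
                "above_chance": bool(term["p"] < alpha and term["b"] > 0),
            }
        )
    return pd.DataFrame(rows).set_index("mask")


def fp_cascade(
    trials: pd.DataFrame,
    alpha: float = 0.05,
    correct_pvalues: bool = False,
    drift_fitter=None,
) -> pd.DataFrame:
    """Staged false-positive analysis over the 30 incongruent pairings.

    Stage 1 (always): mixed logistic of the rating on mask.  Stage 2 (only
    when some mask coefficient is significant): mixed linear model of log RT.
    Stage 3 (only when an RT mask effect is significant): drift-rate analysis
    via ``drift_fitter(pairing_trials)``; omitted when no fitter is supplied.
    Gates use uncorrected two-tailed p < alpha on the mask coefficients;
    ``correct_pvalues=True`` switches the stage-1 gate to Benjamini-Hochberg
    across the 30 pairings.

    Returns one row per pairing with the stage reached and per-stage details.
    """
    incong = trials[~trials["congruent"]]
    pairings = sorted(incong["pairing"].unique())
    stage1 = {}
    for pairing in pairings:
        sub = incong[incong["pairing"] == pairing]
        yes = (sub["response"] == "yes").astype(float)
        try:
            fit = fit_logistic_mixed(sub, outcome=yes)
            pvals = [t["p"] for nm, t in fit.terms.items() if nm != "intercept"]
            stage1[pairing] = (fit, min(pvals))
        except (SeparationError, ValueError) as exc:
            stage1[pairing] = (None, np.nan)
            logger.warning("stage-1 fit failed for %s: %s", pairing, exc)

    gate_p = {p: v[1] for p, v in stage1.items()}
    if correct_pvalues:
        ps = pd.Series(gate_p).dropna().sort_values()
        m = len(ps)
        passed = set()
        thresh = 0.0
        for rank, (pairing, p) in enumerate(ps.items(), start=1):
            if p <= alpha * rank / m:
                thresh = p
        passed = {p for p, v in gate_p.items() if np.isfinite(v) and v <= thresh}
    else:
        passed = {p for p, v in gate_p.items() if np.isfinite(v) and v < alpha}

    rows = []
    for pairing in pairings:
        sub = incong[incong["pairing"] == pairing]
        fit1, p1 = stage1[pairing]
        row = {
            "pairing": pairing,
            "stage_reached": 1,
            "rating_min_p": p1,
            "rt_min_p": np.nan,
            "drift_prob": np.nan,
        }
        if pairing in passed and fit1 is not None:
            try:
                fit2 = fit_linear_mixed(sub.assign(
                    log_rt=np.log(sub["rt_ms"])), by_accuracy=False)
                p2 = min(t["p"] for nm, t in fit2.terms.items() if nm != "intercept")
                row["stage_reached"] = 2
                row["rt_min_p"] = p2
                if p2 < alpha and drift_fitter is not None:
                    row["drift_prob"] = float(drift_fitter(sub))
                    row["stage_reached"] = 3
            except ValueError as exc:
                logger.warning("stage-2 fit failed for %s: %s", pairing, exc)
        rows.append(row)
    return pd.DataFrame(rows).set_index("pairing")
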