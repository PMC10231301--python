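"""Simulate complete study datasets from a drift-diffusion process.

The generator stands in for the study's raw behavioural data: two-alternative
forced-choice responses and response times produced by a Wiener diffusion
with condition-specific drift rates, participant random intercepts on drift,
across-trial variabilities, fast-guess contaminants (< 100 ms) and
attention-check failures.  Accuracy coding is used throughout: the upper
boundary is the correct response, so positive drift means evidence toward the
correct judgment.  On congruent trials the correct response is "yes", on
incongruent trials "no".

Paths are simulated by small-step Euler-Maruyama (default dt = 1e-4 s) with
unit diffusion coefficient.  Absorption uses the Broadie-Glasserman-Kou
continuity correction (barriers shifted inward by 0.5826 * sigma * sqrt(dt))
so that discretely monitored passages match the continuous-time law to
higher order in dt.  Paths that fail to absorb within the time cap are
resampled and counted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from numba import njit

from .task_design import EMOTIONS, MASKS, classify_congruency
from .wfpt import DDMParams

logger = logging.getLogger(__name__)

__all__ = [
    "GroundTruth",
    "default_ground_truth",
    "simulate_trial",
    "simulate_trials",
    "simulate_study",
]


@dataclass
class GroundTruth:
    """Generative parameters for a synthetic study.

    ``drift`` maps (emotion, mask) to the drift rate toward the correct
    "yes" on congruent trials.  ``incongruent_drift`` is the drift toward the
    correct "no" on incongruent trials (a single value; correct rejections
    are not the focus of the recovery tests).  Participant intercepts are
    drawn Normal(0, ``intercept_sd``^2) and added to the drift of every trial
    of that participant.  Remaining diffusion parameters are shared.
    """

    drift: dict = field(default_factory=dict)  # (emotion, mask) -> v
    incongruent_drift: float = 1.6
    intercept_sd: float = 0.3
    a: float = 1.8
    z: float = 0.5
    t: float = 0.35
    sv: float = 0.3
    sz: float = 0.05
    st: float = 0.1
    contamination_rate: float = 0.005
    attention_fail_rate: float = 0.0

    def validate(self) -> None:
        for key, v in self.drift.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite drift for cell {key}")
        for rate in (self.contamination_rate, self.attention_fail_rate):
            if not (0.0 <= rate < 1.0):
                raise ValueError("rates must lie in [0, 1)")
        # reuse the DDMParams invariant checks for the shared block
        DDMParams(v=0.0, a=self.a, z=self.z, t=self.t,
                  sv=self.sv, sz=self.sz, st=self.st)

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["drift"] = {f"{e}|{m}": v for (e, m), v in self.drift.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        drift = {tuple(k.split("|")): v for k, v in payload.pop("drift").items()}
        return cls(drift=drift, **payload)


def default_ground_truth(study: int = 1) -> GroundTruth:
    """Ground truth emulating the study conditions.

    Drift toward correct identification is highest for unoccluded faces and
    reduced under occlusion, with the lower-face occlusion penalty roughly
    doubling between study 1 and study 2 (the replication showed a stronger
    lower-mask effect).  Magnitudes are typical of fits to fast binary
    emotion judgments (drift ~1-2 evidence units/s, boundary ~1.8, 350 ms
    non-decision time).
    """
    if study == 1:
        per_mask = {"none": 1.5, "upper": 1.1, "lower": 1.05}
        attention_fail = 72 / 300
    elif study == 2:
        per_mask = {"none": 1.5, "upper": 1.1, "lower": 0.8}
        attention_fail = 26 / 290
    else:
        raise ValueError("study must be 1 or 2")
    drift = {(emo, mask): per_mask[mask] for emo in EMOTIONS for mask in MASKS}
    return GroundTruth(drift=drift, attention_fail_rate=attention_fail)


#: Broadie-Glasserman-Kou constant: discretely monitored barriers behave like
#: continuous ones shifted by this multiple of sigma * sqrt(dt)
_BGK_BETA = 0.5826


@njit(cache=False, fastmath=True)
def _em_consume(x, x0, steps, done, hit, v, lo, hi_b, mid, dt, sqdt,
                max_steps, resampled, buf, start):
    """Advance unfinished paths through one noise buffer.

    Absorption is tested against the continuity-corrected barriers ``lo`` and
    ``hi_b`` (the nominal boundaries moved inward by the BGK shift), which
    removes the O(sqrt(dt)) late-passage bias of discretely monitored
    barriers.  Paths are processed sequentially from index ``start``; each
    consumes consecutive buffer entries until absorption, the step cap
    (restart with fresh noise, counted in ``resampled``), or buffer
    exhaustion (partial state kept for the next buffer).  Returns the index
    to resume from.
    """
    ptr = 0
    nbuf = buf.size
    i = start
    n = x.size
    while i < n:
        if done[i]:
            i += 1
            continue
        vd = v[i] * dt
        xi = x[i]
        si = steps[i]
        while True:
            if ptr == nbuf:
                x[i] = xi
                steps[i] = si
                return i
            xi += vd + sqdt * buf[ptr]
            ptr += 1
            si += 1
            if xi <= lo or xi >= hi_b:
                done[i] = True
                hit[i] = xi >= mid
                steps[i] = si
                break
            if si >= max_steps:
                xi = x0[i]
                si = 0
                resampled[0] += 1
        i += 1
    return n


def _em_paths(v, a, z_rel, dt, max_steps, seed, buf_size=1 << 23):
    """Euler-Maruyama first passages for per-trial drift/start arrays.

    Gaussian increments come from a seeded numpy generator in large buffers
    (the sequential consumption makes the result independent of the buffer
    size).  Returns (hit_upper, decision_time, n_resampled); a path
    exceeding ``max_steps`` without absorption restarts with fresh noise.
    """
    rng = np.random.Generator(np.random.SFC64(seed))
    n = v.size
    x0 = a * np.asarray(z_rel, float)
    x = x0.copy()
    steps = np.zeros(n, np.int64)
    done = np.zeros(n, np.bool_)
    hit = np.zeros(n, np.bool_)
    resampled = np.zeros(1, np.int64)
    sqdt = np.sqrt(dt)
    shift = _BGK_BETA * sqdt  # continuity correction for discrete monitoring
    lo, hi_b = shift, a - shift
    start = 0
    while start < n:
        size = min(buf_size, max(1 << 16, (n - start) * 256))
        buf = rng.standard_normal(size, dtype=np.float32)
        start = _em_consume(
            x, x0, steps, done, hit, v, lo, hi_b, a / 2.0, dt, sqdt,
            max_steps, resampled, buf, start,
        )
    return hit, steps * dt, int(resampled[0])


def simulate_trials(
    params: DDMParams,
    n: int,
    seed: int = 0,
    dt: float = 1e-4,
    time_cap_s: float = 20.0,
) -> pd.DataFrame:
    """Simulate ``n`` diffusion trials under one parameter set.

    Across-trial variabilities are applied per trial (drift Normal(v, sv),
    start Uniform(z +/- sz/2), non-decision Uniform(t +/- st/2)).  Returns a
    DataFrame with ``boundary`` ("upper"/"lower"), ``decision_time`` and
    ``rt`` (decision + non-decision), both in seconds.
    """
    rng = np.random.default_rng(seed)
    v = rng.normal(params.v, params.sv, n) if params.sv > 0 else np.full(n, params.v)
    z = (
        rng.uniform(params.z - params.sz / 2, params.z + params.sz / 2, n)
        if params.sz > 0
        else np.full(n, params.z)
    )
    t0 = (
        rng.uniform(params.t - params.st / 2, params.t + params.st / 2, n)
        if params.st > 0
        else np.full(n, params.t)
    )
    max_steps = int(round(time_cap_s / dt))
    em_seed = int(rng.integers(2**31 - 1))
    hit_upper, t_dec, n_resampled = _em_paths(v, params.a, z, dt, max_steps, em_seed)
    if n_resampled:
        logger.info("resampled %d paths that hit the %.0f s cap", n_resampled, time_cap_s)
    return pd.DataFrame(
        {
            "boundary": np.where(hit_upper, "upper", "lower"),
            "decision_time": t_dec,
            "rt": t_dec + t0,
        }
    )


def simulate_trial(params: DDMParams, seed: int = 0, dt: float = 1e-4):
    """Single-trial convenience wrapper; returns (boundary, decision_time, rt)."""
    row = simulate_trials(params, 1, seed=seed, dt=dt).iloc[0]
    return str(row["boundary"]), float(row["decision_time"]), float(row["rt"])


def simulate_drift_cells(
    drift_by_mask: dict,
    n_participants: int,
    trials_per_cell: int,
    intercept_sd: float = 0.3,
    a: float = 1.8,
    z: float = 0.5,
    t: float = 0.35,
    sv: float = 0.3,
    sz: float = 0.05,
    st: float = 0.1,
    seed: int = 0,
    dt: float = 1e-4,
) -> pd.DataFrame:
    """Simulate a single-emotion congruent analysis set, cell by cell.

    Generates ``trials_per_cell`` accuracy-coded trials per participant and
    mask condition with drift ``drift_by_mask[mask] + u_j``; a compact
    stand-in for the congruent trials of one rated emotion, used by the
    parameter-recovery suites.  Returns columns ``participant_id``, ``mask``,
    ``correct``, ``rt_ms``.
    """
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, intercept_sd, n_participants)
    masks = list(drift_by_mask)
    n = n_participants * len(masks) * trials_per_cell
    pid = np.repeat(np.arange(n_participants), len(masks) * trials_per_cell)
    mask_col = np.tile(np.repeat(masks, trials_per_cell), n_participants)
    v_mean = np.array([drift_by_mask[m] for m in mask_col]) + u[pid]
    v_trial = rng.normal(v_mean, sv) if sv > 0 else v_mean
    z_trial = rng.uniform(z - sz / 2, z + sz / 2, n) if sz > 0 else np.full(n, z)
    t_trial = rng.uniform(t - st / 2, t + st / 2, n) if st > 0 else np.full(n, t)
    hit, t_dec, _ = _em_paths(
        v_trial, a, z_trial, dt, int(round(20.0 / dt)), int(rng.integers(2**31 - 1))
    )
    return pd.DataFrame(
        {
            "participant_id": [f"p{i:03d}" for i in pid],
            "mask": mask_col,
            "correct": hit,
            "rt_ms": (t_dec + t_trial) * 1000.0,
        }
    )


def simulate_study(
    design: pd.DataFrame,
    schedule: pd.DataFrame,
    truth: GroundTruth,
    seed: int = 0,
    dt: float = 1e-4,
    time_cap_s: float = 20.0,
) -> pd.DataFrame:
    """Simulate every scheduled stimulus presentation as one trial.

    For each participant round, the scheduled block's stimuli are presented
    in random order; the trial's drift toward the correct response is the
    ground-truth cell value (congruent) or ``incongruent_drift``
    (incongruent), plus the participant's intercept.  Contaminant trials are
    replaced by uniform fast guesses below 100 ms at the stated rate, and
    participants failing the attention check are flagged (not removed).

    Returns the long-format trial table in the pipeline schema: columns
    ``participant_id``, ``round_index``, ``rated_emotion``, ``actor_id``,
    ``expression``, ``mask``, ``block_index``, ``congruent``, ``pairing``,
    ``response`` (yes/no), ``correct``, ``rt_ms``, ``attention_failed``.
    """
    truth.validate()
    rng = np.random.default_rng(seed)
    pids = schedule["participant_id"].unique()
    intercepts = dict(zip(pids, rng.normal(0.0, truth.intercept_sd, len(pids))))
    attention = dict(
        zip(pids, rng.random(len(pids)) < truth.attention_fail_rate)
    )

    blocks = {b: sub for b, sub in design.groupby("block_index")}
    frames = []
    for _, round_row in schedule.iterrows():
        pid = round_row["participant_id"]
        block = blocks[round_row["block_index"]]
        order = rng.permutation(len(block))
        sub = block.iloc[order][["actor_id", "expression", "mask"]].reset_index(drop=True)
        sub["participant_id"] = pid
        sub["round_index"] = round_row["round_index"]
        sub["rated_emotion"] = round_row["rated_emotion"]
        sub["block_index"] = round_row["block_index"]
        frames.append(sub)
    trials = classify_congruency(pd.concat(frames, ignore_index=True))

    n = len(trials)
    v_correct = np.where(
        trials["congruent"].to_numpy(),
        np.array(
            [
                truth.drift[(e, m)]
                for e, m in zip(trials["expression"], trials["mask"])
            ]
        ),
        truth.incongruent_drift,
    )
    v_correct = v_correct + np.array(
        [intercepts[p] for p in trials["participant_id"]]
    )
    v_trial = rng.normal(v_correct, truth.sv) if truth.sv > 0 else v_correct
    z_trial = (
        rng.uniform(truth.z - truth.sz / 2, truth.z + truth.sz / 2, n)
        if truth.sz > 0
        else np.full(n, truth.z)
    )
    t_trial = (
        rng.uniform(truth.t - truth.st / 2, truth.t + truth.st / 2, n)
        if truth.st > 0
        else np.full(n, truth.t)
    )
    max_steps = int(round(time_cap_s / dt))
    em_seed = int(rng.integers(2**31 - 1))
    hit_upper, t_dec, n_resampled = _em_paths(
        v_trial, truth.a, z_trial, dt, max_steps, em_seed
    )
    if n_resampled:
        logger.info("resampled %d capped paths", n_resampled)

    correct = hit_upper.copy()
    rt_ms = (t_dec + t_trial) * 1000.0

    if truth.contamination_rate > 0:
        contam = rng.random(n) < truth.contamination_rate
        rt_ms[contam] = rng.uniform(0.0, 100.0, int(contam.sum()))
        correct[contam] = rng.random(int(contam.sum())) < 0.5

    congruent = trials["congruent"].to_numpy()
    # accuracy coding back to the response key: correct means "yes" on
    # congruent trials and "no" on incongruent trials
    response_yes = np.where(congruent, correct, ~correct)

    trials = trials.copy()
    trials["response"] = np.where(response_yes, "yes", "no")
    trials["correct"] = correct
    trials["rt_ms"] = rt_ms
    trials["attention_failed"] = trials["participant_id"].map(attention).astype(bool)
    return trials
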