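"""Pre-registered exclusions and response-time transforms.

Three rules, applied in this order:

1. drop all trials of participants who failed the attention check;
2. drop trials with RT < 100 ms (anticipatory fast guesses);
3. drop trials with RT strictly above the empirical top-0.5% quantile,
   computed over all remaining trials of the study (one threshold per
   dataset, recorded in the report).

The quantile uses linear interpolation; ties exactly at the threshold are
retained.  Re-applying the fast-RT rule is idempotent, but the quantile rule
is not (it recomputes the threshold on the trimmed sample) — callers should
apply the full sequence once.

Response times are modelled on the natural-log scale; the flipped value
(multiplied by -1 so that higher means faster) exists only for plotting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "ExclusionReport",
    "exclude_participants",
    "exclude_rts",
    "preprocess_trials",
    "transform_rt",
    "flip_log_rt",
    "split_analysis_sets",
]


@dataclass
class ExclusionReport:
    n_participants_in: int = 0
    n_participants_excluded: int = 0
    n_trials_in: int = 0
    n_trials_fast: int = 0
    rt_upper_threshold_ms: float = float("nan")
    n_trials_slow: int = 0
    n_trials_out: int = 0

    def check(self) -> None:
        """Conservation: counts on retained participants must reconcile."""
        if self.n_trials_out != self.n_trials_in - self.n_trials_fast - self.n_trials_slow:
            raise ValueError(f"exclusion counts do not reconcile: {self}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def exclude_participants(
    trials: pd.DataFrame,
    attention_flags: pd.Series | dict | None = None,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Remove all trials of attention-check failures.

    ``attention_flags`` maps participant_id -> failed (True/False); if
    omitted, the trial table's ``attention_failed`` column is used.  Every
    participant present in the trials must have a flag.
    """
    pids = pd.Index(trials["participant_id"].unique())
    if attention_flags is None:
        if "attention_failed" not in trials.columns:
            raise ValueError("no attention flags provided and no attention_failed column")
        flags = trials.groupby("participant_id")["attention_failed"].first()
    else:
        flags = pd.Series(attention_flags)
        missing = pids.difference(flags.index)
        if len(missing):
            raise ValueError(f"missing attention flags for participants: {list(missing)[:5]}")
    flags = flags.reindex(pids).astype(bool)
    failed = set(flags.index[flags])
    kept = trials[~trials["participant_id"].isin(failed)].reset_index(drop=True)
    report = ExclusionReport(
        n_participants_in=len(pids),
        n_participants_excluded=len(failed),
        n_trials_in=len(kept),
        n_trials_out=len(kept),
    )
    return kept, report


def exclude_rts(
    trials: pd.DataFrame,
    min_ms: float = 100.0,
    upper_quantile: float = 0.995,
    report: ExclusionReport | None = None,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the fast-guess floor and the top-quantile trim.

    The upper threshold is the linear-interpolation empirical quantile of
    RTs over all trials retained after the floor; trials strictly above it
    are removed.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    if (trials["rt_ms"] <= 0).any():
        raise ValueError("all rt_ms must be positive")
    report = report or ExclusionReport(
        n_participants_in=trials["participant_id"].nunique(),
        n_trials_in=len(trials),
    )
    report.n_trials_in = len(trials)

    fast = trials["rt_ms"] < min_ms
    kept = trials[~fast]
    report.n_trials_fast = int(fast.sum())

    threshold = float(np.quantile(kept["rt_ms"].to_numpy(), upper_quantile))
    slow = kept["rt_ms"] > threshold
    report.rt_upper_threshold_ms = threshold
    report.n_trials_slow = int(slow.sum())

    out = kept[~slow].reset_index(drop=True)
    report.n_trials_out = len(out)
    report.check()
    return out, report


def preprocess_trials(
    trials: pd.DataFrame,
    attention_flags: pd.Series | dict | None = None,
    min_ms: float = 100.0,
    upper_quantile: float = 0.995,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Full exclusion sequence; adds a ``log_rt`` column (natural log of ms)."""
    kept, report = exclude_participants(trials, attention_flags)
    kept, report = exclude_rts(kept, min_ms=min_ms, upper_quantile=upper_quantile,
                               report=report)
    kept = kept.copy()
    kept["log_rt"] = transform_rt(kept["rt_ms"].to_numpy())
    return kept, report


def transform_rt(rt_ms):
    """Natural log of RT (ms); raises on non-positive input."""
    rt = np.asarray(rt_ms, dtype=float)
    if (rt <= 0).any():
        raise ValueError("rt_ms must be positive")
    out = np.log(rt)
    return float(out) if np.ndim(rt_ms) == 0 else out


def flip_log_rt(log_rt):
    """Flip (multiply by -1) for plotting so higher = faster; never modelled."""
    return -np.asarray(log_rt, dtype=float)


def split_analysis_sets(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition into the false-negative (congruent) and false-positive
    (incongruent) analysis sets."""
    if "congruent" not in trials.columns:
        raise ValueError("trials must be congruency-annotated (classify_congruency)")
    cong = trials[trials["congruent"]].reset_index(drop=True)
    incong = trials[~trials["congruent"]].reset_index(drop=True)
    return cong, incong
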