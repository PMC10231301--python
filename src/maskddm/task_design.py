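"""Counterbalanced task design for the masked-expression judgment study.

The study shows every actor's portrayal of each of six basic emotions under
three occlusion conditions (lower half of the face covered, upper half
covered, or unoccluded).  Stimuli are organised into six blocks such that

* each (actor, expression, mask) triple occurs exactly once overall,
* within a block each actor contributes exactly one expression, shown with
  all three masks, and
* within a block each expression is contributed by ``n_actors / 6`` actors.

Participants complete six rounds; on each round they see one block and rate
a single emotion ("does this face express X? yes/no"), so that across the
session every participant makes all six ratings of all six expressions under
all three masks.

The block construction is a balanced Latin square over actor groups of size
``n_actors / 6``: group *g* contributes expression ``(g + b) mod 6`` in block
*b*.  Groups are filled round-robin within gender (and ethnicity, when
provided) strata so that blocks remain approximately balanced on those actor
attributes as well.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EMOTIONS: tuple[str, ...] = (
    "anger",
    "disgust",
    "fear",
    "happiness",
    "sadness",
    "surprise",
)
MASKS: tuple[str, ...] = ("lower", "upper", "none")

#: number of congruent (expression == rated emotion) pairings in the design
N_CONGRUENT_PAIRINGS = 6
#: number of incongruent pairings in the design
N_INCONGRUENT_PAIRINGS = 30


class DesignInfeasibleError(ValueError):
    """Raised when the requested design cannot satisfy the counterbalancing."""


def _stratified_groups(
    actor_ids: np.ndarray,
    strata: np.ndarray,
    n_groups: int,
    rng: np.random.Generator,
) -> list[list]:
    """Deal actors into ``n_groups`` groups, round-robin within each stratum.

    Shuffles within strata first so the assignment is random but balanced;
    logs a warning when a stratum is not divisible by the group count (the
    balance then degrades gracefully to within one actor per group).
    """
    groups: list[list] = [[] for _ in range(n_groups)]
    offset = 0
    for stratum in sorted(set(strata.tolist())):
        members = actor_ids[strata == stratum].copy()
        rng.shuffle(members)
        if len(members) % n_groups != 0:
            logger.warning(
                "stratum %r has %d actors, not divisible by %d groups; "
                "using approximate balance",
                stratum,
                len(members),
                n_groups,
            )
        for i, actor in enumerate(members):
            groups[(offset + i) % n_groups].append(actor)
        offset += len(members)
    return groups


def generate_blocks(
    n_actors: int,
    emotions: Sequence[str] = EMOTIONS,
    masks: Sequence[str] = MASKS,
    n_blocks: int = 6,
    seed: int = 0,
    actor_genders: Sequence[str] | None = None,
    actor_ethnicities: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Generate the fully counterbalanced stimulus design.

    Parameters
    ----------
    n_actors
        Number of distinct actors; must be divisible by ``len(emotions)``.
    emotions, masks
        Expression and occlusion vocabularies (six emotions, three masks).
    n_blocks
        Number of blocks; must equal ``len(emotions)``.
    seed
        Seed for the stratified group assignment and Latin-square phase.
    actor_genders, actor_ethnicities
        Optional per-actor attributes used to stratify group assignment.
        When ``actor_genders`` is omitted, genders alternate female/male so
        the synthetic roster is balanced.

    Returns
    -------
    pandas.DataFrame
        One row per stimulus with columns ``actor_id``, ``actor_gender``,
        ``actor_ethnicity``, ``expression``, ``mask``, ``block_index``
        (1-based).  Total rows = ``n_actors * len(emotions) * len(masks)``.
    """
    emotions = list(emotions)
    masks = list(masks)
    n_emo = len(emotions)
    if n_actors <= 0 or n_actors % n_emo != 0:
        raise DesignInfeasibleError(
            f"n_actors={n_actors} must be a positive multiple of the number of "
            f"emotions ({n_emo}) so each block assigns n_actors/{n_emo} actors "
            "per expression"
        )
    if n_blocks != n_emo:
        raise DesignInfeasibleError(
            f"n_blocks={n_blocks} must equal the number of emotions ({n_emo}) "
            "for the Latin-square counterbalancing"
        )
    if len(set(emotions)) != n_emo or len(set(masks)) != len(masks):
        raise DesignInfeasibleError("emotions and masks must be unique")

    rng = np.random.default_rng(seed)
    actor_ids = np.arange(1, n_actors + 1)
    if actor_genders is None:
        genders = np.array(["female", "male"])[actor_ids % 2]
    else:
        genders = np.asarray(actor_genders, dtype=object)
    if actor_ethnicities is None:
        ethnicities = np.array(["unspecified"] * n_actors, dtype=object)
    else:
        ethnicities = np.asarray(actor_ethnicities, dtype=object)
    if len(genders) != n_actors or len(ethnicities) != n_actors:
        raise DesignInfeasibleError("actor attribute lengths must match n_actors")

    strata = np.array(
        [f"{g}|{e}" for g, e in zip(genders, ethnicities)], dtype=object
    )
    groups = _stratified_groups(actor_ids, strata, n_emo, rng)

    # Random Latin-square phase: permute which emotion sequence each group
    # starts on while preserving the "all six emotions across blocks" cycle.
    emo_order = list(rng.permutation(emotions))
    phase = int(rng.integers(n_emo))

    gender_of = dict(zip(actor_ids.tolist(), genders.tolist()))
    ethnicity_of = dict(zip(actor_ids.tolist(), ethnicities.tolist()))

    rows = []
    for b in range(n_blocks):
        for g, group in enumerate(groups):
            expression = emo_order[(g + b + phase) % n_emo]
            for actor in group:
                for mask in masks:
                    rows.append(
                        {
                            "actor_id": int(actor),
                            "actor_gender": gender_of[actor],
                            "actor_ethnicity": ethnicity_of[actor],
                            "expression": expression,
                            "mask": mask,
                            "block_index": b + 1,
                        }
                    )
    design = pd.DataFrame(rows)
    validate_design(design, emotions=emotions, masks=masks)
    return design


def validate_design(
    design: pd.DataFrame,
    emotions: Sequence[str] = EMOTIONS,
    masks: Sequence[str] = MASKS,
) -> None:
    """Check the counterbalancing invariants, raising ``ValueError`` on failure."""
    emotions = list(emotions)
    masks = list(masks)
    triples = design.groupby(["actor_id", "expression", "mask"]).size()
    if not (triples == 1).all():
        raise ValueError("each (actor, expression, mask) triple must occur exactly once")
    n_actors = design["actor_id"].nunique()
    expected_total = n_actors * len(emotions) * len(masks)
    if len(design) != expected_total:
        raise ValueError(
            f"design has {len(design)} rows, expected {expected_total}"
        )
    for block, sub in design.groupby("block_index"):
        per_actor = sub.groupby("actor_id")["expression"].nunique()
        if not (per_actor == 1).all():
            raise ValueError(f"block {block}: an actor contributes >1 expression")
        per_actor_masks = sub.groupby("actor_id")["mask"].nunique()
        if not (per_actor_masks == len(masks)).all():
            raise ValueError(f"block {block}: an actor is missing a mask condition")
        per_expr = sub.groupby("expression")["actor_id"].nunique()
        if set(per_expr.index) != set(emotions):
            raise ValueError(f"block {block}: missing expressions")
        if not (per_expr == n_actors // len(emotions)).all():
            raise ValueError(f"block {block}: unequal actors per expression")


def schedule_rounds(
    participant_ids: Sequence,
    n_rounds: int = 6,
    seed: int = 0,
    emotions: Sequence[str] = EMOTIONS,
) -> pd.DataFrame:
    """Assign each participant a randomized round schedule.

    Each participant rates each emotion exactly once and views each block
    exactly once; the emotion-to-round and block-to-round pairings are
    randomized jointly and independently per participant.  The yes/no key
    mapping is drawn once per participant.

    Returns a DataFrame with columns ``participant_id``, ``round_index``
    (1-based), ``rated_emotion``, ``block_index``, ``key_mapping``.
    """
    emotions = list(emotions)
    if n_rounds != len(emotions):
        raise ValueError(
            f"n_rounds={n_rounds} must equal the number of rated emotions "
            f"({len(emotions)})"
        )
    ids = list(participant_ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({p for p in ids if ids.count(p) > 1})
        raise ValueError(f"duplicate participant ids: {dupes}")

    rng = np.random.default_rng(seed)
    rows = []
    for pid in ids:
        emo_perm = rng.permutation(emotions)
        block_perm = rng.permutation(np.arange(1, n_rounds + 1))
        key = "left=yes" if rng.integers(2) == 0 else "right=yes"
        for r in range(n_rounds):
            rows.append(
                {
                    "participant_id": pid,
                    "round_index": r + 1,
                    "rated_emotion": emo_perm[r],
                    "block_index": int(block_perm[r]),
                    "key_mapping": key,
                }
            )
    return pd.DataFrame(rows)


def classify_congruency(
    trials: pd.DataFrame, emotions: Sequence[str] = EMOTIONS
) -> pd.DataFrame:
    """Annotate trials as congruent/incongruent with a pairing label.

    A trial is congruent when the viewed expression matches the emotion rated
    that round; an incorrect "no" there is a false-negative error.  On
    incongruent trials an incorrect "yes" is a false-positive error.  The
    pairing label is ``"<expression>|<rated_emotion>"``; a full crossing of
    the six-emotion vocabulary yields 6 congruent and 30 incongruent labels.
    """
    vocab = set(emotions)
    for col in ("expression", "rated_emotion"):
        if col not in trials.columns:
            raise ValueError(f"trials missing required column {col!r}")
        bad = set(trials[col].unique()) - vocab
        if bad:
            raise ValueError(f"unknown emotion labels in {col!r}: {sorted(bad)}")
    out = trials.copy()
    out["congruent"] = out["expression"] == out["rated_emotion"]
    out["pairing"] = out["expression"].astype(str) + "|" + out["rated_emotion"].astype(str)
    return out


def design_manifest(design: pd.DataFrame, seed: int) -> dict:
    """Compact JSON-ready summary of a generated design."""
    return {
        "seed": seed,
        "n_actors": int(design["actor_id"].nunique()),
        "n_blocks": int(design["block_index"].nunique()),
        "n_stimuli_total": int(len(design)),
        "n_stimuli_per_block": int(
            design.groupby("block_index").size().iloc[0]
        ),
        "emotions": sorted(design["expression"].unique().tolist()),
        "masks": sorted(design["mask"].unique().tolist()),
    }


def write_design(design: pd.DataFrame, csv_path, manifest_path=None, seed: int = 0) -> None:
    design.to_csv(csv_path, index=False)
    if manifest_path is not None:
        with open(manifest_path, "w") as fh:
            json.dump(design_manifest(design, seed), fh, indent=2)
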