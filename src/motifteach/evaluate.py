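"""Scoring learner responses and the baseline-learner benchmark.

Two outcome measures: *correct motifs* — how many of the three
ground-truth motifs the learner reported (0-3) — and *minimum edit
distance* — the fewest bead substitutions turning a produced necklace
into any necklace consistent with the ground-truth motifs (0-10; both
strings have fixed length 10, so insertions and deletions cannot help
and "edits" are bead flips).

The baseline learner benchmark inverts strong sampling: shown a
necklace, it samples a motif triplet from the baseline posterior, then
samples two new necklaces uniformly from all necklaces containing that
triplet (resampling until both differ from the shown necklace and from
each other, mirroring the task interface constraint).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .space import TeachingSpace, canonical_hypothesis

__all__ = [
    "LearnerTrial",
    "count_correct_motifs",
    "min_edit_distance",
    "baseline_learner_rollout",
    "score_learner_dataset",
]


@dataclass(frozen=True)
class LearnerTrial:
    participant_id: str
    village_id: str
    shown_necklace: str
    teacher_type: str
    reported_motifs: tuple[str, str, str]
    produced_necklaces: tuple[str, str]

    def __post_init__(self) -> None:
        if len(set(self.reported_motifs)) != 3:
            raise ValueError("reported motifs must be three distinct motifs")
        a, b = self.produced_necklaces
        if a == b or self.shown_necklace in (a, b):
            raise ValueError("produced necklaces must be unique and differ "
                             "from the shown necklace")


def count_correct_motifs(reported: Iterable[str], true_h: Iterable[str]) -> int:
    """Number of ground-truth motifs among the reported ones (0-3)."""
    return len(set(reported) & set(true_h))


def _bits(space: TeachingSpace) -> np.ndarray:
    cached = getattr(space, "_bead_bits", None)
    if cached is None:
        cached = np.array([[int(c) for c in d] for d in space.necklaces], dtype=np.uint8)
        space._bead_bits = cached
    return cached


def min_edit_distance(d: str, true_h: Iterable[str], space: TeachingSpace) -> int:
    """Fewest bead flips from ``d`` to any necklace consistent with ``true_h``."""
    j = space.col(true_h)
    mask = space.C[:, j] > 0
    if not mask.any():
        raise ValueError(f"hypothesis {tuple(true_h)} has no consistent necklace")
    bits = _bits(space)
    target = np.array([int(c) for c in d], dtype=np.uint8)
    return int((bits[mask] != target).sum(axis=1).min())


def baseline_learner_rollout(
    shown: str,
    posterior: np.ndarray,
    p_strong: np.ndarray,
    space: TeachingSpace,
    rng: np.random.Generator,
    max_resample: int = 100,
) -> tuple[tuple[str, str, str], tuple[str, str]]:
    """Simulate one baseline-learner trial for a shown necklace.

    Samples a hypothesis from the learner posterior row at ``shown``,
    then two distinct new necklaces from the strong-sampling column of
    that hypothesis.  Returns ``(sampled_hypothesis, (neck1, neck2))``.
    """
    row = posterior[space.row(shown)]
    total = row.sum()
    if total <= 0:
        raise ValueError(f"necklace {shown!r} is consistent with no hypothesis")
    j = rng.choice(len(row), p=row / total)
    h = space.hypotheses[j]
    col = p_strong[:, j]
    produced: list[str] = []
    for _ in range(max_resample):
        d = space.necklaces[rng.choice(len(col), p=col)]
        if d != shown and d not in produced:
            produced.append(d)
            if len(produced) == 2:
                return h, (produced[0], produced[1])
    raise RuntimeError(
        f"could not draw two distinct new necklaces for {shown!r} "
        f"within {max_resample} samples"
    )


def score_learner_dataset(
    trials: Sequence[LearnerTrial],
    villages: Mapping[str, tuple[str, str, str]],
    space: TeachingSpace,
    exclude_inconsistent_reports: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trial outcome scores plus per-teacher-type summaries.

    Each produced necklace contributes its own edit distance; the
    per-trial score averages the two.  ``consistent_report`` flags
    whether the reported motif triplet is consistent with the shown
    necklace; with ``exclude_inconsistent_reports`` those trials are
    dropped from the summary (they still appear in the per-trial table).
    """
    rows = []
    for t in trials:
        if t.village_id not in villages:
            raise KeyError(f"unknown village id {t.village_id!r}")
        true_h = canonical_hypothesis(villages[t.village_id])
        reported = canonical_hypothesis(t.reported_motifs)
        consistent = bool(space.C[space.row(t.shown_necklace), space.col(reported)])
        dists = [min_edit_distance(d, true_h, space) for d in t.produced_necklaces]
        rows.append(
            {
                "participant_id": t.participant_id,
                "village_id": t.village_id,
                "teacher_type": t.teacher_type,
                "correct_motifs": count_correct_motifs(reported, true_h),
                "min_edit_distance": float(np.mean(dists)),
                "consistent_report": consistent,
            }
        )
    scores = pd.DataFrame(rows)
    pool = scores[scores.consistent_report] if exclude_inconsistent_reports else scores
    summary = (
        pool.groupby("teacher_type")[["correct_motifs", "min_edit_distance"]]
        .agg(["mean", "sem", "count"])
    )
    return scores, summary
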