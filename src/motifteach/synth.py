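"""Synthetic villages, teachers, and learner stimuli.

Emulates the structure of the behavioral study designs so that the full
analysis pipeline (fitting, model comparison, learner scoring) runs
end-to-end on generated data: 18 villages, each a unique set of three
motifs; one 10-bead necklace response per (teacher, village), drawn from
the teacher's model family; learner stimulus sets of 18 necklaces — six
per teacher source (human-like, pedagogical, strong) — interleaved in a
seeded random order.

Teacher optimality parameters alpha are drawn from a log-normal
distribution with median 1.0 and log-scale spread 0.5 unless fixed
explicitly: alpha near 1 makes the pedagogical teacher clearly distinct
from strong sampling while keeping responses stochastic, and the spread
produces the kind of between-participant heterogeneity random-effects
model comparison assumes.

Randomness: a single master seed expands into independent per-stage
substreams through ``numpy``'s ``SeedSequence`` spawning; every output
table records the substream key it was drawn with.  Ground-truth
parameters are returned separately from the analysis-facing trial
tables so a pipeline cannot accidentally condition on them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import models
from .models import FixedPointConfig
from .space import TeachingSpace

__all__ = [
    "SynthConfig",
    "generate_villages",
    "sample_alphas",
    "simulate_teachers",
    "simulate_learner_stimuli",
]

# stage labels -> fixed spawn offsets, so each stage gets its own stream
_STAGES = {"villages": 0, "alphas": 1, "teachers": 2, "learners": 3}


def _stage_rng(master_seed: int, stage: str) -> tuple[np.random.Generator, str]:
    ss = np.random.SeedSequence(master_seed, spawn_key=(_STAGES[stage],))
    return np.random.default_rng(ss), f"{master_seed}.{_STAGES[stage]}"


@dataclass(frozen=True)
class SynthConfig:
    """Study-shaped defaults for a synthetic dataset."""

    n_villages: int = 18
    n_teachers: int = 30
    teacher_family: str = "pedagogical"
    alpha: float | None = None          # fixed alpha; None -> log-normal draw
    alpha_median: float = 1.0
    alpha_sigma: float = 0.5
    n_learners: int = 30
    master_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_villages, self.n_teachers, self.n_learners) < 1:
            raise ValueError("all counts must be >= 1")


def generate_villages(
    n_villages: int, space: TeachingSpace, master_seed: int
) -> list[tuple[str, str, str]]:
    """Sample distinct village hypotheses uniformly without replacement."""
    if n_villages > len(space.hypotheses):
        raise ValueError(
            f"cannot draw {n_villages} distinct villages from "
            f"{len(space.hypotheses)} hypotheses"
        )
    rng, _ = _stage_rng(master_seed, "villages")
    idx = rng.choice(len(space.hypotheses), size=n_villages, replace=False)
    return [space.hypotheses[j] for j in idx]


def sample_alphas(
    n: int, master_seed: int, median: float = 1.0, sigma: float = 0.5
) -> np.ndarray:
    """Participant alphas from a log-normal with the given median and spread."""
    rng, _ = _stage_rng(master_seed, "alphas")
    return np.exp(rng.normal(np.log(median), sigma, size=n))


def simulate_teachers(
    villages: Sequence[tuple[str, str, str]],
    space: TeachingSpace,
    config: SynthConfig,
    fp_config: FixedPointConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One response per (teacher, village) drawn from the teacher model.

    Returns ``(trials, ground_truth)``: the analysis-facing trial table
    (participant_id, village_id, motif1-3, response) and a separate
    per-participant ground-truth table (family, alpha, rng substream).
    """
    family = config.teacher_family
    if family not in ("strong", "pedagogical"):
        raise ValueError("simulate_teachers supports the strong and pedagogical families")
    rng, stream = _stage_rng(config.master_seed, "teachers")
    if family == "pedagogical":
        if config.alpha is not None:
            alphas = np.full(config.n_teachers, float(config.alpha))
        else:
            alphas = sample_alphas(config.n_teachers, config.master_seed,
                                   config.alpha_median, config.alpha_sigma)
    else:
        alphas = np.full(config.n_teachers, np.nan)

    cols = [space.col(h) for h in villages]
    rows_out = []
    teacher_mats: dict[int, np.ndarray] = {}
    if family == "strong":
        P_strong = models.strong_sampling(space.C)
    for p in range(config.n_teachers):
        if family == "strong":
            teacher_mats[p] = P_strong
        else:
            # each participant gets the canonical (cold-start) solution
            teacher_mats[p] = models.pedagogical_fixed_point(
                space.C, float(alphas[p]), fp_config
            ).teacher
    for p in range(config.n_teachers):
        P = teacher_mats[p]
        for v, (h, j) in enumerate(zip(villages, cols)):
            d_idx = rng.choice(len(space.necklaces), p=P[:, j])
            rows_out.append(
                {
                    "participant_id": f"T{p:03d}",
                    "village_id": f"V{v:02d}",
                    "motif1": h[0],
                    "motif2": h[1],
                    "motif3": h[2],
                    "response": space.necklaces[d_idx],
                }
            )
    trials = pd.DataFrame(rows_out)
    truth = pd.DataFrame(
        {
            "participant_id": [f"T{p:03d}" for p in range(config.n_teachers)],
            "family": family,
            "alpha": alphas,
            "rng_substream": stream,
        }
    )
    return trials, truth


def simulate_learner_stimuli(
    pools: dict[str, pd.DataFrame],
    n_learners: int,
    master_seed: int,
    trials_per_source: int = 6,
) -> pd.DataFrame:
    """Assemble interleaved learner stimulus sets from per-source trial pools.

    ``pools`` maps a teacher-type label (e.g. ``human``, ``pedagogical``,
    ``strong``) to a teacher-trial table; for each learner,
    ``trials_per_source`` (village, necklace) pairs are drawn from each
    pool over distinct villages, then the combined set is shuffled with
    a per-learner substream.  The ``teacher_type`` column is retained
    for scoring but the trial order carries no information about it.
    """
    rng, stream = _stage_rng(master_seed, "learners")
    for label, pool in pools.items():
        if pool["village_id"].nunique() < trials_per_source:
            raise ValueError(
                f"pool {label!r} covers {pool['village_id'].nunique()} villages; "
                f"need >= {trials_per_source}"
            )
    out = []
    for l in range(n_learners):
        chosen = []
        for label, pool in pools.items():
            villages = rng.choice(pool["village_id"].unique(),
                                  size=trials_per_source, replace=False)
            for v in villages:
                cand = pool[pool["village_id"] == v]
                row = cand.iloc[rng.integers(len(cand))]
                chosen.append(
                    {
                        "participant_id": f"L{l:03d}",
                        "village_id": v,
                        "motif1": row["motif1"],
                        "motif2": row["motif2"],
                        "motif3": row["motif3"],
                        "shown_necklace": row["response"],
                        "teacher_type": label,
                        "rng_substream": stream,
                    }
                )
        perm = rng.permutation(len(chosen))
        for order, idx in enumerate(perm):
            chosen[idx]["trial_order"] = order
        out.extend(chosen)
    df = pd.DataFrame(out).sort_values(["participant_id", "trial_order"])
    return df.reset_index(drop=True)
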