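"""End-to-end analysis pipeline on synthetic data.

Chains the stages space -> models -> synth -> inference -> evaluate:
build the consistency matrix, simulate teacher datasets from the three
teacher sources (a human-like biased-pedagogical pool, the pedagogical
model, and strong sampling), fit teacher model families per participant
and compare them with random-effects Bayesian model selection, then
assemble interleaved learner stimulus sets, roll out baseline learners
on them, and score the outcomes.

Every run writes flat CSV/JSON outputs plus the echoed configuration
(with package version and a config hash) into its output directory, and
is bit-reproducible given the same configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, complexity, evaluate, inference, models, synth
from .models import FixedPointConfig, TeacherModelSpec
from .space import TeachingSpace

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("motifteach")


@dataclass(frozen=True)
class RunConfig:
    """Serializable configuration for one pipeline run."""

    out_dir: str
    seed: int = 0
    necklace_length: int = 10
    n_villages: int = 18
    n_teachers: int = 6
    n_learners: int = 6
    teacher_alpha_median: float = 1.0
    teacher_alpha_sigma: float = 0.5
    families: tuple[str, ...] = ("strong", "pedagogical")
    alpha_grid_max: float = 5.0
    alpha_grid_step: float = 0.25
    fixed_point_tolerance: float = 1e-12
    bms_samples: int = 1_000_000
    learner_trials_per_source: int = 6
    human_like_lr_weight: float = 8.0
    human_like_alpha: float = 1.0

    def validate(self) -> None:
        if not self.out_dir:
            raise ValueError("out_dir is required")
        if self.n_villages < self.learner_trials_per_source:
            raise ValueError("need at least learner_trials_per_source villages")
        if min(self.n_villages, self.n_teachers, self.n_learners) < 1:
            raise ValueError("all counts must be >= 1")
        unknown = set(self.families) - set(models.FAMILIES)
        if unknown:
            raise ValueError(f"unknown families: {sorted(unknown)}")
        if self.alpha_grid_step <= 0 or self.alpha_grid_max <= 0:
            raise ValueError("alpha grid must be positive")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages; returns the output directory.

    On a stage failure, partial outputs are kept and a ``FAILED`` marker
    file naming the stage is written before the exception propagates.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = config.to_json()
    cfg_hash = hashlib.sha256(cfg_json.encode()).hexdigest()[:16]
    (out / "config.json").write_text(
        json.dumps(
            {"package_version": __version__, "config_hash": cfg_hash,
             "config": json.loads(cfg_json)},
            indent=2,
        )
    )
    stage = "space"
    try:
        t0 = time.time()
        log.info("stage space: building %d-bead consistency matrix", config.necklace_length)
        space = TeachingSpace(config.necklace_length)
        fp_cfg = FixedPointConfig(tolerance=config.fixed_point_tolerance)
        log.info("stage space done in %.1fs (%d x %d)", time.time() - t0,
                 len(space.necklaces), len(space.hypotheses))

        stage = "synth"
        t0 = time.time()
        villages = synth.generate_villages(config.n_villages, space, config.seed)
        village_map = {f"V{v:02d}": h for v, h in enumerate(villages)}
        _write(
            pd.DataFrame(
                [{"village_id": k, "motif1": h[0], "motif2": h[1], "motif3": h[2]}
                 for k, h in village_map.items()]
            ),
            out / "villages.csv",
        )
        ped_cfg = synth.SynthConfig(
            n_villages=config.n_villages, n_teachers=config.n_teachers,
            teacher_family="pedagogical",
            alpha_median=config.teacher_alpha_median,
            alpha_sigma=config.teacher_alpha_sigma,
            n_learners=config.n_learners, master_seed=config.seed,
        )
        teacher_trials, teacher_truth = synth.simulate_teachers(
            villages, space, ped_cfg, fp_cfg
        )
        _write(teacher_trials, out / "teacher_trials.csv")
        _write(teacher_truth, out / "teacher_truth.csv")
        log.info("stage synth done in %.1fs (%d teacher trials)",
                 time.time() - t0, len(teacher_trials))

        stage = "inference"
        t0 = time.time()
        trials = inference.load_teacher_trials(teacher_trials, space)
        grid = np.round(
            np.arange(0.0, config.alpha_grid_max + 1e-9, config.alpha_grid_step), 6
        )
        fitter = inference.AlphaFitter(space, grid=grid, config=fp_cfg)
        K = complexity.complexity_table(space.necklaces)
        fits = []
        for pid in teacher_trials.participant_id.unique():
            tt = [t for t in trials if t.participant_id == pid]
            for fam in config.families:
                fits.append(
                    inference.fit_participant(
                        tt, fam, space, fitter=fitter,
                        complexity_scores=K, config=fp_cfg,
                    )
                )
        fits_df = pd.DataFrame(
            [
                {
                    "participant_id": f.participant_id, "family": f.family,
                    "log_likelihood": f.log_likelihood, "k": f.k, "n": f.n,
                    "bic": f.bic, "alpha_hat": f.alpha_hat,
                    "boundary": f.boundary,
                    **{f"param_{k}": v for k, v in f.params.items()},
                }
                for f in fits
            ]
        )
        _write(fits_df, out / "fits.csv")
        if len(config.families) >= 2:
            ev = (
                fits_df.assign(ev=-0.5 * fits_df.bic)
                .pivot(index="participant_id", columns="family", values="ev")
                [list(config.families)]
            )
            bms = inference.random_effects_bms(
                ev.to_numpy(), config.families,
                n_samples=config.bms_samples, seed=config.seed,
            )
            (out / "bms.json").write_text(
                json.dumps(
                    {
                        "families": list(bms.families),
                        "frequencies": bms.frequencies.tolist(),
                        "exceedance": bms.exceedance.tolist(),
                        "protected_exceedance": bms.protected_exceedance.tolist(),
                        "bayesian_omnibus_risk": bms.bayesian_omnibus_risk,
                        "config_hash": cfg_hash,
                    },
                    indent=2,
                )
            )
        log.info("stage inference done in %.1fs (%d fits)", time.time() - t0, len(fits))

        stage = "evaluate"
        t0 = time.time()
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(9,)))
        strong_cfg = dataclasses.replace(ped_cfg, teacher_family="strong")
        strong_trials, _ = synth.simulate_teachers(villages, space, strong_cfg, fp_cfg)
        lr_ind = models.lr_bias_matrix(space.necklaces, space.hypotheses)
        T_human = models.variant_teacher(
            space.C,
            TeacherModelSpec("pedagogical_lr", alpha=config.human_like_alpha,
                             lr_weight=config.human_like_lr_weight),
            lr_indicator=lr_ind, config=fp_cfg,
        )
        human_rows = []
        for v, h in enumerate(villages):
            j = space.col(h)
            for _ in range(max(1, config.n_teachers // 2)):
                d = space.necklaces[rng.choice(len(space.necklaces), p=T_human[:, j])]
                human_rows.append(
                    {"participant_id": "HLIKE", "village_id": f"V{v:02d}",
                     "motif1": h[0], "motif2": h[1], "motif3": h[2], "response": d}
                )
        pools = {
            "human": pd.DataFrame(human_rows),
            "pedagogical": teacher_trials,
            "strong": strong_trials,
        }
        stimuli = synth.simulate_learner_stimuli(
            pools, config.n_learners, config.seed,
            trials_per_source=config.learner_trials_per_source,
        )
        posterior = models.baseline_learner(space.C)
        p_strong = models.strong_sampling(space.C)
        learner_trials = []
        for rec in stimuli.itertuples(index=False):
            h_rep, produced = evaluate.baseline_learner_rollout(
                rec.shown_necklace, posterior, p_strong, space, rng
            )
            learner_trials.append(
                evaluate.LearnerTrial(
                    rec.participant_id, rec.village_id, rec.shown_necklace,
                    rec.teacher_type, h_rep, produced,
                )
            )
        stim_out = stimuli.copy()
        stim_out[["reported_motif1", "reported_motif2", "reported_motif3"]] = [
            t.reported_motifs for t in learner_trials
        ]
        stim_out[["produced_necklace1", "produced_necklace2"]] = [
            t.produced_necklaces for t in learner_trials
        ]
        _write(stim_out, out / "learner_trials.csv")
        scores, summary = evaluate.score_learner_dataset(
            learner_trials, village_map, space
        )
        _write(scores, out / "learner_scores.csv")
        summary.to_csv(out / "learner_summary.csv")
        log.info("stage evaluate done in %.1fs (%d learner trials)",
                 time.time() - t0, len(learner_trials))
    except Exception:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        log.error("pipeline failed at stage %s", stage)
        raise
    return out
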