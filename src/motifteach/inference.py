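"""Model fitting and random-effects model comparison for teacher data.

Each participant contributes a set of trials (village hypothesis, chosen
necklace).  For every model family we compute the maximized trial
log-likelihood, score it with the Bayesian information criterion
``BIC = k*log(n) - 2*log(L)``, take ``-0.5*BIC`` as an approximate log
model evidence, and compare families across participants with
random-effects Bayesian model selection: a variational Dirichlet scheme
over population model frequencies, exceedance probabilities by
Monte-Carlo sampling of the fitted Dirichlet, and protected exceedance
probabilities ``pxp = ep*(1-BOR) + BOR/K`` where the Bayesian omnibus
risk BOR is the posterior probability that all families are equally
frequent.

The pedagogical family's alpha is fitted per participant by a coarse
grid search (0 to 20 in steps of 0.05) followed by bounded scalar
refinement; an ``AlphaFitter`` caches the converged teacher matrix at
every grid point so that fits across many participants and simulated
datasets reuse one grid sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import digamma, gammaln

from . import models
from .models import FixedPointConfig
from .space import TeachingSpace, canonical_hypothesis

__all__ = [
    "TeacherTrial",
    "FitResult",
    "BMSResult",
    "load_teacher_trials",
    "trials_to_frame",
    "trial_log_likelihood",
    "AlphaFitter",
    "fit_alpha",
    "fit_participant",
    "bic",
    "log_model_evidence",
    "random_effects_bms",
    "ALPHA_GRID",
]

#: Default alpha search grid: 0 to 20 in steps of 0.05.
ALPHA_GRID = np.round(np.arange(0.0, 20.0 + 1e-9, 0.05), 4)


@dataclass(frozen=True)
class TeacherTrial:
    participant_id: str
    village_id: str
    hypothesis: tuple[str, str, str]
    response: str


@dataclass(frozen=True)
class FitResult:
    participant_id: str
    family: str
    log_likelihood: float
    k: int
    n: int
    bic: float
    alpha_hat: float | None = None
    params: Mapping[str, float] = field(default_factory=dict)
    boundary: bool = False


@dataclass(frozen=True)
class BMSResult:
    families: tuple[str, ...]
    frequencies: np.ndarray           # E[r_k], posterior mean model frequencies
    exceedance: np.ndarray            # EP
    protected_exceedance: np.ndarray  # pxp
    bayesian_omnibus_risk: float
    dirichlet_alpha: np.ndarray


def load_teacher_trials(source, space: TeachingSpace) -> list[TeacherTrial]:
    """Read teacher trials from a CSV path or DataFrame and validate them.

    Expected columns: participant_id, village_id, motif1, motif2, motif3,
    response.  Responses inconsistent with their village hypothesis are
    rejected (the task interface enforced consistency, so such rows are
    data corruption).
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, dtype=str)
    trials = []
    for rec in df.itertuples(index=False):
        h = canonical_hypothesis([rec.motif1, rec.motif2, rec.motif3])
        d = str(rec.response)
        if not space.C[space.row(d), space.col(h)]:
            raise ValueError(
                f"trial (participant {rec.participant_id}, village {rec.village_id}): "
                f"response {d} is not consistent with hypothesis {h}"
            )
        trials.append(TeacherTrial(str(rec.participant_id), str(rec.village_id), h, d))
    return trials


def trials_to_frame(trials: Iterable[TeacherTrial]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": t.participant_id,
                "village_id": t.village_id,
                "motif1": t.hypothesis[0],
                "motif2": t.hypothesis[1],
                "motif3": t.hypothesis[2],
                "response": t.response,
            }
            for t in trials
        ]
    )


def trial_log_likelihood(trial: TeacherTrial, P: np.ndarray, space: TeachingSpace) -> float:
    """log P(response | hypothesis) under a teacher distribution matrix."""
    p = P[space.row(trial.response), space.col(trial.hypothesis)]
    return float(np.log(p)) if p > 0 else -np.inf


def _trial_indices(trials: Sequence[TeacherTrial], space: TeachingSpace):
    rows = np.array([space.row(t.response) for t in trials])
    cols = np.array([space.col(t.hypothesis) for t in trials])
    return rows, cols


class AlphaFitter:
    """Caches converged pedagogical teacher matrices over the alpha grid.

    The fixed point depends only on (C, alpha), not on the data, so one
    grid sweep serves every participant and every simulated dataset.
    Every grid point is solved from the canonical cold start (the
    column-normalized ``C``): the system can have multiple fixed points
    at larger ``alpha``, so solutions are never chained across grid
    points.  Grid solutions are stored as float32 log-probabilities
    (~360 MB for the default grid and the full space).
    """

    def __init__(
        self,
        space: TeachingSpace,
        grid: np.ndarray = ALPHA_GRID,
        config: FixedPointConfig | None = None,
    ) -> None:
        self.space = space
        self.grid = np.asarray(grid, dtype=float)
        self.config = config or FixedPointConfig()
        self._log_teacher: dict[float, np.ndarray] = {}

    def _sweep(self) -> None:
        if self._log_teacher:
            return
        with np.errstate(divide="ignore"):
            for a in self.grid:
                res = models.pedagogical_fixed_point(self.space.C, float(a), self.config)
                T = res.teacher
                self._log_teacher[float(a)] = np.log(
                    T, out=np.full_like(T, -np.inf), where=T > 0
                ).astype(np.float32)

    def grid_log_likelihood(self, trials: Sequence[TeacherTrial]) -> np.ndarray:
        """Summed trial log-likelihood at every grid alpha."""
        self._sweep()
        rows, cols = _trial_indices(trials, self.space)
        return np.array(
            [self._log_teacher[float(a)][rows, cols].sum() for a in self.grid],
            dtype=float,
        )

    def log_likelihood(self, alpha: float, trials: Sequence[TeacherTrial]) -> float:
        """Exact (float64) summed log-likelihood at an arbitrary alpha."""
        res = models.pedagogical_fixed_point(self.space.C, float(alpha), self.config)
        rows, cols = _trial_indices(trials, self.space)
        with np.errstate(divide="ignore"):
            return float(np.log(res.teacher[rows, cols]).sum())


def _parabolic_vertex(x: np.ndarray, y: np.ndarray) -> float | None:
    """Abscissa of the parabola through three points; None if degenerate."""
    denom = (x[0] - x[1]) * (x[0] - x[2]) * (x[1] - x[2])
    if denom == 0 or not np.isfinite(y).all():
        return None
    a = (x[2] * (y[1] - y[0]) + x[1] * (y[0] - y[2]) + x[0] * (y[2] - y[1])) / denom
    b = (x[2] ** 2 * (y[0] - y[1]) + x[1] ** 2 * (y[2] - y[0]) + x[0] ** 2 * (y[1] - y[2])) / denom
    if a >= 0:  # not a maximum
        return None
    return float(-b / (2 * a))


def fit_alpha(
    trials: Sequence[TeacherTrial],
    fitter: AlphaFitter,
    family: str = "pedagogical",
    refine: bool = True,
) -> FitResult:
    """Maximum-likelihood alpha for one participant's trials.

    Coarse grid search over ``fitter.grid``, then bounded local
    refinement: a parabola through the grid maximum and its neighbours
    proposes a vertex inside the bracketing interval, the exact
    likelihood is evaluated there, and the better of vertex and grid
    maximum is returned.  A maximum on the upper grid boundary is
    reported with ``boundary=True``.
    """
    if len(trials) == 0:
        raise ValueError("need at least one trial")
    if family != "pedagogical":
        raise ValueError("fit_alpha handles the plain pedagogical family; "
                         "use fit_participant for biased variants")
    pid = trials[0].participant_id
    ll_grid = fitter.grid_log_likelihood(trials)
    if not np.isfinite(ll_grid).any():
        raise RuntimeError(
            f"participant {pid}: all grid alphas give zero likelihood "
            f"(offending trials: {[t.response for t in trials]})"
        )
    i = int(np.argmax(ll_grid))
    a_hat, ll_hat = float(fitter.grid[i]), float(ll_grid[i])
    boundary = i == len(fitter.grid) - 1
    if refine and 0 < i < len(fitter.grid) - 1:
        xs = fitter.grid[i - 1 : i + 2]
        vertex = _parabolic_vertex(xs, ll_grid[i - 1 : i + 2])
        if vertex is not None and xs[0] < vertex < xs[2] and abs(vertex - a_hat) > 1e-4:
            ll_v = fitter.log_likelihood(vertex, trials)
            if ll_v > ll_hat:
                a_hat, ll_hat = float(vertex), float(ll_v)
    n = len(trials)
    b = bic(ll_hat, 1, n)
    return FitResult(pid, "pedagogical", ll_hat, 1, n, b,
                     alpha_hat=a_hat, params={"alpha": a_hat}, boundary=boundary)


def _fit_heuristic(trials, space, family, complexity_scores):
    rows, cols = _trial_indices(trials, space)
    Cf = space.C.astype(float)
    if family == "lr_heuristic":
        B0 = models.lr_bias_matrix(space.necklaces, space.hypotheses).astype(float)

        def ll(theta):  # theta = log(w), w >= 1
            W = np.where(B0 > 0, np.exp(theta), 1.0)
            P = Cf * W
            P /= P.sum(axis=0, keepdims=True)
            with np.errstate(divide="ignore"):
                return float(np.log(P[rows, cols]).sum())

        grid = np.log(np.array([1, 1.5, 2, 3, 5, 8, 15, 30, 60, 120.0]))
        pname = "lr_weight"
    elif family == "simplicity_heuristic":
        K = np.asarray(complexity_scores, dtype=float).reshape(-1, 1)

        def ll(theta):  # theta = lambda >= 0
            P = Cf * np.exp(-theta * K)
            P /= P.sum(axis=0, keepdims=True)
            with np.errstate(divide="ignore"):
                return float(np.log(P[rows, cols]).sum())

        grid = np.linspace(0.0, 2.0, 41)
        pname = "simplicity_penalty"
    else:  # pragma: no cover
        raise ValueError(family)
    lls = np.array([ll(t) for t in grid])
    i = int(np.argmax(lls))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    opt = minimize_scalar(lambda t: -ll(t), bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-4})
    theta, ll_hat = (float(opt.x), float(-opt.fun)) if -opt.fun >= lls[i] else (float(grid[i]), float(lls[i]))
    value = float(np.exp(theta)) if family == "lr_heuristic" else theta
    n = len(trials)
    return FitResult(trials[0].participant_id, family, ll_hat, 1, n,
                     bic(ll_hat, 1, n), params={pname: value},
                     boundary=i == len(grid) - 1)


def _fit_biased_pedagogical(trials, space, family, complexity_scores, config):
    """Joint coarse-grid ML fit of (alpha, bias parameter).

    Runs a fixed point per grid cell, so it is markedly slower than the
    plain pedagogical fit; grids are deliberately coarse.
    """
    rows, cols = _trial_indices(trials, space)
    cfg = config or FixedPointConfig()
    alphas = np.arange(0.0, 6.0 + 1e-9, 0.5)
    if family == "pedagogical_lr":
        B0 = models.lr_bias_matrix(space.necklaces, space.hypotheses).astype(bool)
        thetas = np.array([1, 2, 4, 8, 16, 32.0])  # w
        make_bias = lambda w: np.where(B0, w, 1.0)
        pname = "lr_weight"
    elif family == "pedagogical_simplicity":
        K = np.asarray(complexity_scores, dtype=float).reshape(-1, 1)
        thetas = np.linspace(0.0, 1.0, 6)  # lambda
        make_bias = lambda lam: np.exp(-lam * K) * np.ones_like(space.C, dtype=float)
        pname = "simplicity_penalty"
    else:  # pragma: no cover
        raise ValueError(family)
    best = (-np.inf, None, None)
    for th in thetas:
        B = make_bias(float(th))
        for a in alphas:
            T = models.pedagogical_fixed_point(space.C, float(a), cfg, bias=B).teacher
            with np.errstate(divide="ignore"):
                ll = float(np.log(T[rows, cols]).sum())
            if ll > best[0]:
                best = (ll, float(a), float(th))
    ll_hat, a_hat, th_hat = best
    n = len(trials)
    return FitResult(trials[0].participant_id, family, ll_hat, 2, n,
                     bic(ll_hat, 2, n), alpha_hat=a_hat,
                     params={"alpha": a_hat, pname: th_hat},
                     boundary=a_hat == alphas[-1] or th_hat == thetas[-1])


def fit_participant(
    trials: Sequence[TeacherTrial],
    family: str,
    space: TeachingSpace,
    fitter: AlphaFitter | None = None,
    complexity_scores: np.ndarray | None = None,
    config: FixedPointConfig | None = None,
) -> FitResult:
    """Fit any model family to one participant's trials.

    ``strong`` has no free parameters; ``pedagogical`` uses the cached
    grid ``fitter``; the biased and heuristic families optimize their
    own parameters.
    """
    if len(trials) == 0:
        raise ValueError("need at least one trial")
    if family == "strong":
        P = models.strong_sampling(space.C)
        ll = sum(trial_log_likelihood(t, P, space) for t in trials)
        n = len(trials)
        return FitResult(trials[0].participant_id, "strong", ll, 0, n, bic(ll, 0, n))
    if family == "pedagogical":
        if fitter is None:
            fitter = AlphaFitter(space, config=config or FixedPointConfig())
        return fit_alpha(trials, fitter)
    if family in ("lr_heuristic", "simplicity_heuristic"):
        return _fit_heuristic(trials, space, family, complexity_scores)
    if family in ("pedagogical_lr", "pedagogical_simplicity"):
        return _fit_biased_pedagogical(trials, space, family, complexity_scores, config)
    raise ValueError(f"unknown family {family!r}")


def bic(log_likelihood: float, k: int, n: int) -> float:
    """Bayesian information criterion, ``k*ln(n) - 2*log(L)``."""
    if n < 1 or k < 0:
        raise ValueError("need n >= 1 and k >= 0")
    return k * float(np.log(n)) - 2.0 * float(log_likelihood)


def log_model_evidence(fit: FitResult) -> float:
    """Per-participant log model evidence approximated as ``-BIC/2``."""
    return -0.5 * fit.bic


def random_effects_bms(
    log_evidence: np.ndarray,
    families: Sequence[str] | None = None,
    alpha0: float = 1.0,
    n_samples: int = 1_000_000,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> BMSResult:
    """Random-effects Bayesian model selection over a participants x families
    evidence matrix.

    Variational scheme: model frequencies follow a Dirichlet whose
    counts are updated from per-participant posterior model assignments
    ``u_nk ∝ exp(lme_nk + digamma(a_k) - digamma(sum a))`` until the
    frequency estimates move less than ``tol``.  Exceedance
    probabilities come from Monte-Carlo samples of the fitted Dirichlet;
    the Bayesian omnibus risk compares the free energy of this model
    against the null model of equal frequencies, and shrinks EP toward
    uniform: ``pxp = ep*(1 - BOR) + BOR/K``.

    ``-inf`` evidence entries are allowed (a family that assigns a
    participant's data zero probability); ``nan`` or ``+inf`` are not.
    """
    lme = np.asarray(log_evidence, dtype=float)
    if lme.ndim != 2 or lme.shape[0] < 1 or lme.shape[1] < 2:
        raise ValueError("evidence must be (participants x >=2 families)")
    if np.isnan(lme).any() or np.isposinf(lme).any():
        raise ValueError("evidence entries must be finite or -inf")
    if not np.isfinite(lme).any(axis=1).all():
        raise ValueError("some participant has -inf evidence under every family")
    N, K = lme.shape
    fams = tuple(families) if families is not None else tuple(f"model_{k}" for k in range(K))
    # per-participant normalization: invariant for the scheme, avoids overflow
    lme_n = lme - np.nanmax(np.where(np.isfinite(lme), lme, -np.inf), axis=1, keepdims=True)

    a = np.full(K, alpha0, dtype=float)
    for _ in range(max_iter):
        ln_u = lme_n + (digamma(a) - digamma(a.sum()))
        ln_u -= ln_u.max(axis=1, keepdims=True)
        u = np.exp(ln_u)
        u /= u.sum(axis=1, keepdims=True)
        a_new = alpha0 + u.sum(axis=0)
        if np.abs(a_new / a_new.sum() - a / a.sum()).max() < tol:
            a = a_new
            break
        a = a_new
    else:  # pragma: no cover
        raise RuntimeError("BMS variational scheme did not converge")

    freq = a / a.sum()
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(a, size=n_samples)
    ep = np.bincount(np.argmax(draws, axis=1), minlength=K) / n_samples

    bor = _bayesian_omnibus_risk(lme_n, u, a, alpha0)
    pxp = ep * (1.0 - bor) + bor / K
    return BMSResult(fams, freq, ep, pxp, bor, a)


def _bayesian_omnibus_risk(lme, u, a, alpha0) -> float:
    """BOR = 1 / (1 + exp(F1 - F0)): null (equal frequencies) vs RFX."""
    N, K = lme.shape
    # F0: evidence under fixed uniform frequencies
    F0 = float(np.sum(_logsumexp_rows(lme - np.log(K))))
    # F1: variational free energy of the random-effects model
    Elogr = digamma(a) - digamma(a.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ulogu = np.where(u > 0, u * np.log(u), 0.0)
    Sqm = -float(ulogu.sum())
    ELJ = (
        gammaln(alpha0 * K) - K * gammaln(alpha0)
        + float(((alpha0 - 1) * Elogr).sum())
        + float((u * (np.where(np.isfinite(lme), lme, 0.0) * np.isfinite(lme) + Elogr)).sum())
    )
    Sqf = float(gammaln(a).sum() - gammaln(a.sum()) - ((a - 1) * Elogr).sum())
    F1 = ELJ + Sqf + Sqm
    return float(1.0 / (1.0 + np.exp(F1 - F0)))


def _logsumexp_rows(x: np.ndarray) -> np.ndarray:
    m = np.max(np.where(np.isfinite(x), x, -np.inf), axis=1, keepdims=True)
    return (m + np.log(np.exp(x - m).sum(axis=1, keepdims=True))).ravel()
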