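"""Teacher and learner models over the necklace-hypothesis space.

All models are expressed as operations on the binary consistency matrix
``C`` (rows = necklaces ``d``, columns = hypotheses ``h``):

* **Strong sampling** — the teacher draws uniformly from all necklaces
  consistent with the target hypothesis: ``P(d|h) = c(d,h) / sum_d' c(d',h)``.
* **Baseline learner** — inverts strong sampling by Bayes' rule under a
  uniform prior over hypotheses, i.e. row-normalizes the strong-sampling
  matrix.
* **Pedagogical sampling** — teacher and learner reason recursively about
  each other: ``P_learner(h|d) ∝ P_teacher(d|h)`` (row normalization) and
  ``P_teacher(d|h) ∝ P_learner(h|d)**alpha`` (column normalization), solved
  by fixed-point iteration of the two renormalizations.  ``alpha >= 0``
  controls how strongly the teacher favours necklaces that maximize the
  learner's posterior on the true hypothesis; ``alpha = 0`` recovers
  strong sampling.
* **Variants** — a left-to-right bias (extra weight ``w >= 1`` on
  necklaces whose three motifs can be read consecutively from the first
  bead) and a simplicity bias (weight ``exp(-lam * K(d))`` with ``K`` an
  algorithmic-complexity score), each applied either inside the
  pedagogical fixed point or alone as a heuristic reweighting of ``C``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "FixedPointConfig",
    "FixedPointResult",
    "TeacherModelSpec",
    "ConvergenceError",
    "FAMILIES",
    "strong_sampling",
    "baseline_learner",
    "pedagogical_fixed_point",
    "lr_bias_indicator",
    "lr_bias_matrix",
    "variant_teacher",
]

#: Model family names, in canonical order.
FAMILIES = (
    "strong",
    "pedagogical",
    "pedagogical_lr",
    "pedagogical_simplicity",
    "lr_heuristic",
    "simplicity_heuristic",
)


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to reach tolerance within the cap."""


@dataclass(frozen=True)
class FixedPointConfig:
    """Numerical settings for the pedagogical fixed point."""

    tolerance: float = 1e-12
    #: near the concentration transition (alpha ~ 1.1 on the full space)
    #: the iteration exhibits critical slowing; the cap leaves headroom
    max_iterations: int = 50_000

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


class FixedPointResult(NamedTuple):
    teacher: np.ndarray  # column-stochastic P(d|h)
    learner: np.ndarray  # row-stochastic P(h|d) on nonzero rows
    n_iterations: int
    residual: float


@dataclass(frozen=True)
class TeacherModelSpec:
    """Which teacher model to compute, with its free parameters.

    ``alpha`` is the pedagogical optimality parameter (ignored by the
    heuristic-only families), ``lr_weight`` the multiplicative weight
    ``w >= 1`` on left-to-right-readable necklaces, ``simplicity_penalty``
    the exponential complexity penalty ``lam >= 0``.
    """

    family: str
    alpha: float | None = None
    lr_weight: float | None = None
    simplicity_penalty: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.alpha is not None and self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.lr_weight is not None and self.lr_weight < 1:
            raise ValueError("lr_weight must be >= 1")
        if self.simplicity_penalty is not None and self.simplicity_penalty < 0:
            raise ValueError("simplicity_penalty must be >= 0")


def _column_normalize(M: np.ndarray) -> np.ndarray:
    colsum = M.sum(axis=0, keepdims=True)
    if np.any(colsum == 0):
        raise ValueError("consistency matrix has an all-zero column; every "
                         "hypothesis must admit at least one necklace")
    return M / colsum


def _row_normalize(M: np.ndarray) -> np.ndarray:
    rowsum = M.sum(axis=1, keepdims=True)
    out = np.divide(M, rowsum, out=np.zeros_like(M), where=rowsum > 0)
    return out


def strong_sampling(C: np.ndarray) -> np.ndarray:
    """Column-normalize ``C``: uniform choice among consistent necklaces."""
    return _column_normalize(np.asarray(C, dtype=float))


def baseline_learner(C: np.ndarray) -> np.ndarray:
    """Posterior over hypotheses for a learner assuming strong sampling.

    Rows of necklaces consistent with no hypothesis remain all-zero.
    """
    return _row_normalize(strong_sampling(C))


_FP_KERNEL = None


def _fp_kernel():
    """Compiled alternating-renormalization loop (built on first use)."""
    global _FP_KERNEL
    if _FP_KERNEL is not None:
        return _FP_KERNEL
    from numba import njit

    @njit(cache=True)
    def kernel(T, L, bias, alpha, tol, max_iter):
        # Kahan-compensated sums keep the renormalizations accurate
        # enough that the 1e-12 convergence criterion is reachable.
        n_d, n_h = T.shape
        colmax = np.empty(n_h)
        colsum = np.empty(n_h)
        colc = np.empty(n_h)
        W = np.empty_like(T)
        for it in range(1, max_iter + 1):
            # teacher step: W = (L/colmax)^alpha * bias, column-normalized
            for j in range(n_h):
                colmax[j] = 0.0
                colsum[j] = 0.0
                colc[j] = 0.0
            for i in range(n_d):
                for j in range(n_h):
                    if L[i, j] > colmax[j]:
                        colmax[j] = L[i, j]
            for i in range(n_d):
                for j in range(n_h):
                    v = L[i, j]
                    if v > 0.0:
                        v = (v / colmax[j]) ** alpha * bias[i, j]
                    W[i, j] = v
                    y = v - colc[j]
                    t = colsum[j] + y
                    colc[j] = (t - colsum[j]) - y
                    colsum[j] = t
            resid = 0.0
            for i in range(n_d):
                rowsum = 0.0
                comp = 0.0
                for j in range(n_h):
                    t = W[i, j] / colsum[j]
                    d = abs(t - T[i, j])
                    if d > resid:
                        resid = d
                    T[i, j] = t
                    y = t - comp
                    s = rowsum + y
                    comp = (s - rowsum) - y
                    rowsum = s
                if rowsum > 0.0:
                    for j in range(n_h):
                        l = T[i, j] / rowsum
                        d = abs(l - L[i, j])
                        if d > resid:
                            resid = d
                        L[i, j] = l
            if resid < tol:
                return it, resid
        return -max_iter, resid

    _FP_KERNEL = kernel
    return kernel


def pedagogical_fixed_point(
    C: np.ndarray,
    alpha: float,
    config: FixedPointConfig | None = None,
    bias: np.ndarray | None = None,
    init_teacher: np.ndarray | None = None,
) -> FixedPointResult:
    """Solve the recursive teacher-learner system by alternating renormalization.

    Starting from the column-normalized ``C`` (strong sampling), iterate
    pairs of steps — row-normalize to get the learner posterior, then
    raise to the power ``alpha`` (times the optional ``bias`` weights)
    and column-normalize to get the teacher distribution — until the
    largest absolute change of both matrices between successive
    iterations falls below ``config.tolerance``.

    Parameters
    ----------
    bias
        Optional positive weight matrix (broadcastable to ``C``'s shape)
        multiplied into each teacher step before column normalization;
        used by the biased model variants.
    init_teacher
        Optional starting teacher matrix.  The system of equations can
        have multiple fixed points (at large ``alpha`` any
        support-respecting concentration is stationary), and the
        canonical solution is defined by starting from the
        column-normalized ``C``; supply a different start only when that
        is explicitly intended.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    cfg = config or FixedPointConfig()
    Cf = np.asarray(C, dtype=float)
    support = Cf > 0
    if bias is not None:
        bias = np.broadcast_to(np.asarray(bias, dtype=float), Cf.shape)
        if np.any(bias[support] <= 0):
            raise ValueError("bias weights must be strictly positive on the support")
        bias = np.where(support, bias, 0.0)

    T = _column_normalize(Cf) if init_teacher is None else np.array(init_teacher, dtype=float)
    L = _row_normalize(T)
    bias_arr = np.ascontiguousarray(bias) if bias is not None else np.ones_like(T)
    it, residual = _fp_kernel()(
        T, L, bias_arr, float(alpha), float(cfg.tolerance), int(cfg.max_iterations)
    )
    if it < 0:
        raise ConvergenceError(
            f"pedagogical fixed point did not converge in {cfg.max_iterations} "
            f"iterations (alpha={alpha}, residual={residual:.3e}, "
            f"tolerance={cfg.tolerance:.0e})"
        )
    return FixedPointResult(T, L, it, residual)


def lr_bias_indicator(d: str, h: Iterable[str]) -> int:
    """1 iff the motifs of ``h`` can be read off consecutively from bead 1.

    True when some ordering of the three motifs concatenates to a prefix
    of ``d`` (each motif exactly once, no gaps, starting at the leftmost
    bead).
    """
    motifs = list(h)
    return int(any(d.startswith("".join(p)) for p in itertools.permutations(motifs)))


def lr_bias_matrix(
    necklaces: Sequence[str], hypotheses: Sequence[Sequence[str]]
) -> np.ndarray:
    """Binary matrix of the left-to-right indicator for every (d, h) pair."""
    out = np.zeros((len(necklaces), len(hypotheses)), dtype=np.int8)
    for j, h in enumerate(hypotheses):
        prefixes = {"".join(p) for p in itertools.permutations(list(h))}
        for i, d in enumerate(necklaces):
            if any(d.startswith(p) for p in prefixes):
                out[i, j] = 1
    return out


def _bias_weights(
    C: np.ndarray,
    spec: TeacherModelSpec,
    lr_indicator: np.ndarray | None,
    complexity_scores: np.ndarray | None,
) -> np.ndarray:
    if spec.family in ("pedagogical_lr", "lr_heuristic"):
        if spec.lr_weight is None:
            raise ValueError(f"family {spec.family!r} requires lr_weight")
        if lr_indicator is None:
            raise ValueError(f"family {spec.family!r} requires the LR indicator matrix")
        return np.where(np.asarray(lr_indicator, dtype=bool), float(spec.lr_weight), 1.0)
    if spec.family in ("pedagogical_simplicity", "simplicity_heuristic"):
        if spec.simplicity_penalty is None:
            raise ValueError(f"family {spec.family!r} requires simplicity_penalty")
        if complexity_scores is None:
            raise ValueError(f"family {spec.family!r} requires complexity scores")
        K = np.asarray(complexity_scores, dtype=float).reshape(-1, 1)
        if K.shape[0] != C.shape[0]:
            raise ValueError("complexity scores must align with necklace rows")
        return np.exp(-float(spec.simplicity_penalty) * K) * np.ones_like(
            C, dtype=float
        )
    raise ValueError(f"family {spec.family!r} takes no bias weights")


def variant_teacher(
    C: np.ndarray,
    spec: TeacherModelSpec,
    lr_indicator: np.ndarray | None = None,
    complexity_scores: np.ndarray | None = None,
    config: FixedPointConfig | None = None,
) -> np.ndarray:
    """Teacher choice-probability matrix for any non-strong model family.

    The pedagogical families run the fixed point with the bias weights
    folded into every teacher step; the heuristic families reweight and
    column-normalize ``C`` once, with no learner reasoning.
    """
    if spec.family == "strong":
        raise ValueError("use strong_sampling() for the strong family")
    if spec.family == "pedagogical":
        if spec.alpha is None:
            raise ValueError("pedagogical family requires alpha")
        return pedagogical_fixed_point(C, spec.alpha, config).teacher

    B = _bias_weights(np.asarray(C, dtype=float), spec, lr_indicator, complexity_scores)
    if spec.family in ("pedagogical_lr", "pedagogical_simplicity"):
        if spec.alpha is None:
            raise ValueError(f"family {spec.family!r} requires alpha")
        return pedagogical_fixed_point(C, spec.alpha, config, bias=B).teacher
    # heuristic-only: single biased column normalization of C
    return _column_normalize(np.asarray(C, dtype=float) * B)
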