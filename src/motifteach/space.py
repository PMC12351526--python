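"""Hypothesis space of motifs, necklaces, and their consistency structure.

A *necklace* is a linear string of beads in two colours, encoded as a
binary string (e.g. ``"0001100011"``).  A *motif* is a short reusable
bead pattern of length 2 or 3, and a *hypothesis* is an unordered set of
exactly three distinct motifs — the "favourite motifs" of one village.
A necklace is *consistent* with a hypothesis when it could have been
built by combining the three motifs: each motif must occur at least once
as a contiguous substring, and the three certified occurrences must not
overlap each other.  Extra filler beads outside the occurrences are
allowed, the motifs may appear in any order, and repeats beyond the one
certified occurrence per motif are permitted but not required.

The consistency indicator over every (necklace, hypothesis) pair forms
the binary matrix ``C`` (rows = necklaces, columns = hypotheses) that
every teacher and learner model in this package is built on.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DEFAULT_MOTIF_POOL",
    "DEFAULT_NECKLACE_LENGTH",
    "TeachingSpace",
    "default_space",
    "enumerate_necklaces",
    "enumerate_motifs",
    "canonical_hypothesis",
    "enumerate_hypotheses",
    "substring_motifs",
    "occurrence_masks",
    "is_consistent",
    "build_consistency_matrix",
    "count_alternative_hypotheses",
]

DEFAULT_NECKLACE_LENGTH = 10

#: All 4 two-bead and 8 three-bead binary motifs, in canonical
#: (length, lexicographic) order.
DEFAULT_MOTIF_POOL: tuple[str, ...] = tuple(
    "".join(bits)
    for length in (2, 3)
    for bits in itertools.product("01", repeat=length)
)


def _check_binary(s: str, name: str) -> None:
    if not s or any(ch not in "01" for ch in s):
        raise ValueError(f"{name} must be a nonempty binary string, got {s!r}")


def enumerate_necklaces(length: int) -> list[str]:
    """All ``2**length`` binary necklaces of a given length, lexicographic.

    Parameters
    ----------
    length
        Number of beads; must be >= 1.
    """
    if not isinstance(length, (int, np.integer)) or length < 1:
        raise ValueError(f"necklace length must be a positive integer, got {length!r}")
    return ["".join(bits) for bits in itertools.product("01", repeat=length)]


def enumerate_motifs(lengths: Iterable[int] = (2, 3)) -> list[str]:
    """All binary motifs of the given lengths, in (length, lex) order."""
    return [
        "".join(bits)
        for length in sorted(set(lengths))
        for bits in itertools.product("01", repeat=length)
    ]


def canonical_hypothesis(motifs: Iterable[str]) -> tuple[str, str, str]:
    """Canonical form of a hypothesis: its 3 motifs sorted by (length, lex)."""
    ms = sorted(set(motifs), key=lambda m: (len(m), m))
    if len(ms) != 3:
        raise ValueError(f"a hypothesis needs exactly 3 distinct motifs, got {ms}")
    for m in ms:
        _check_binary(m, "motif")
        if len(m) not in (2, 3):
            raise ValueError(f"motif length must be 2 or 3, got {m!r}")
    return tuple(ms)  # type: ignore[return-value]


def enumerate_hypotheses(
    motif_pool: Sequence[str] = DEFAULT_MOTIF_POOL,
) -> list[tuple[str, str, str]]:
    """All size-3 subsets of the motif pool, canonically ordered.

    For the default 12-motif pool this yields C(12, 3) = 220 hypotheses.
    """
    pool = sorted(set(motif_pool), key=lambda m: (len(m), m))
    if len(pool) < 3:
        raise ValueError(f"motif pool must contain >= 3 distinct motifs, got {len(pool)}")
    return list(itertools.combinations(pool, 3))


def substring_motifs(d: str, motif_pool: Sequence[str] = DEFAULT_MOTIF_POOL) -> set[str]:
    """Every motif in the pool occurring as a contiguous substring of ``d``."""
    _check_binary(d, "necklace")
    return {m for m in motif_pool if m in d}


def occurrence_masks(d: str, motif: str) -> list[int]:
    """Bitmasks of every occurrence interval of ``motif`` inside ``d``.

    Bit ``i`` of a mask is set when bead ``i`` of the necklace is covered
    by that occurrence.
    """
    k = len(motif)
    return [
        ((1 << k) - 1) << start
        for start in range(len(d) - k + 1)
        if d[start : start + k] == motif
    ]


def is_consistent(d: str, h: Iterable[str]) -> bool:
    """Whether necklace ``d`` could have been built from hypothesis ``h``.

    True iff one occurrence interval per motif can be chosen such that
    each interval matches its motif and the three intervals are mutually
    non-overlapping.  Filler beads outside the intervals are allowed and
    motif order is free.
    """
    motifs = list(h)
    occs = [occurrence_masks(d, m) for m in motifs]
    if any(not o for o in occs):
        return False
    # Backtrack over motifs with fewest occurrences first.
    occs.sort(key=len)

    def place(i: int, used: int) -> bool:
        if i == len(occs):
            return True
        return any(
            place(i + 1, used | mask) for mask in occs[i] if not (used & mask)
        )

    return place(0, 0)


def build_consistency_matrix(
    necklaces: Sequence[str], hypotheses: Sequence[Sequence[str]]
) -> np.ndarray:
    """Dense binary matrix ``C`` with ``C[d, h] = 1`` iff ``is_consistent``.

    Rows follow the order of ``necklaces``, columns the order of
    ``hypotheses`` (both canonical when produced by the enumerators).
    """
    if len(necklaces) == 0 or len(hypotheses) == 0:
        raise ValueError("necklace and hypothesis lists must be nonempty")
    C = np.zeros((len(necklaces), len(hypotheses)), dtype=np.int8)
    # Group hypotheses by motif membership is possible, but the full
    # default space (1024 x 220) builds in a couple of seconds as is.
    for j, h in enumerate(hypotheses):
        motifs = list(h)
        for i, d in enumerate(necklaces):
            occs = [occurrence_masks(d, m) for m in motifs]
            if any(not o for o in occs):
                continue
            occs.sort(key=len)

            def place(k: int, used: int) -> bool:
                if k == 3:
                    return True
                return any(
                    place(k + 1, used | mask)
                    for mask in occs[k]
                    if not (used & mask)
                )

            if place(0, 0):
                C[i, j] = 1
    return C


def count_alternative_hypotheses(
    d: str,
    true_h: Iterable[str],
    necklaces: Sequence[str],
    hypotheses: Sequence[tuple[str, str, str]],
    C: np.ndarray,
) -> int:
    """Number of hypotheses other than ``true_h`` consistent with ``d``.

    Raises if ``d`` is not itself consistent with ``true_h`` — the count
    of *alternative* parses is only meaningful for a valid teaching
    example.
    """
    h = canonical_hypothesis(true_h)
    i = necklaces.index(d)
    j = hypotheses.index(h)
    if not C[i, j]:
        raise ValueError(f"necklace {d!r} is not consistent with hypothesis {h}")
    return int(C[i, :].sum()) - 1


class TeachingSpace:
    """The enumerated necklace/hypothesis space with its consistency matrix.

    Bundles the canonical orderings, the matrix ``C`` and O(1) index
    lookups; every downstream model, fitter and simulator works against
    one of these.
    """

    def __init__(self, necklace_length: int = DEFAULT_NECKLACE_LENGTH,
                 motif_pool: Sequence[str] = DEFAULT_MOTIF_POOL) -> None:
        self.necklace_length = necklace_length
        self.motif_pool = tuple(sorted(set(motif_pool), key=lambda m: (len(m), m)))
        self.necklaces = enumerate_necklaces(necklace_length)
        self.hypotheses = enumerate_hypotheses(self.motif_pool)
        self.C = build_consistency_matrix(self.necklaces, self.hypotheses)
        self.necklace_index = {d: i for i, d in enumerate(self.necklaces)}
        self.hypothesis_index = {h: j for j, h in enumerate(self.hypotheses)}

    def row(self, d: str) -> int:
        return self.necklace_index[d]

    def col(self, h: Iterable[str]) -> int:
        return self.hypothesis_index[canonical_hypothesis(h)]


_DEFAULT_SPACE: TeachingSpace | None = None


def default_space() -> TeachingSpace:
    """The full 1024 x 220 ten-bead space, built once and cached."""
    global _DEFAULT_SPACE
    if _DEFAULT_SPACE is None:
        _DEFAULT_SPACE = TeachingSpace()
    return _DEFAULT_SPACE
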