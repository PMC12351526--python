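# Methods

This note records the modelling choices, numerical conventions, and
known limitations behind `motifteach`.

## The space and the consistency relation

Necklaces are linear binary strings (default length 10); motifs are
binary strings of length 2 or 3; a hypothesis is an unordered set of
three distinct motifs.  Canonical orderings — necklaces lexicographic,
motifs by (length, lexicographic), hypotheses by their sorted motif
triple — fix the row/column indexing of the consistency matrix `C`
across runs.  Bead colours are presentation-level; everything internal
is 0/1.

**Consistency semantics.** `c(d,h) = 1` iff one occurrence interval per
motif can be chosen such that each interval matches its motif as a
contiguous substring of `d` and the three intervals are mutually
non-overlapping.  Extra beads outside the chosen intervals are
unconstrained, motif order is free, and repeats beyond the one certified
occurrence are allowed but not required.  This is the only reading we
found that is simultaneously compatible with (a) parse displays of the
form `[000]00[001][11]` and `0[001]1[000][11]`, in which filler beads
appear between and around motif occurrences, including single-bead
fillers, and (b) the validity of examples such as `1000000101` for the
motif set `{00, 100, 101}`, where the motifs cannot be read as one
contiguous chain.  Alternative readings were tested exhaustively
(substring-only presence, full block segmentation, bounded-overlap
placements, suffix–prefix chain merges, and others) and each conflicts
with at least one of these constraints.  Under the implemented
semantics the two worked-example necklaces `0000000111` and
`0001100011` admit 8 and 45 consistent-but-incorrect alternative
hypotheses for the true set `{000, 11, 001}`; counts of 13 and 46 that
circulate for this example are not reproducible under any placement
rule we tested that also respects the constraints above.

The matcher is a backtracking search over occurrence bitmasks
(fewest-occurrences motif first); the test suite checks it against an
independent exhaustive placement search on all 1024 × 220 pairs, plus a
reversal-symmetry property test.

## Teacher and learner models

Strong sampling is column normalization of `C`; the baseline learner is
row normalization of the strong-sampling matrix (uniform prior over
hypotheses).  Rows of necklaces consistent with no hypothesis stay
identically zero everywhere.

**Pedagogical fixed point.**  Starting from the column-normalized `C`,
each iteration performs a learner step (row normalization) and a
teacher step (elementwise power α, then column normalization), and
stops when the largest absolute entry change of both matrices between
successive iterations falls below the tolerance (default 1e-12; cap
50,000 iterations).  Numerical conventions:

* α is applied at **every** teacher step, since it is part of the
  teacher map itself.
* Before the power, each column is rescaled by its maximum; column
  normalization cancels the rescaling exactly, and it prevents
  underflow of entire columns at large α.
* The inner loop uses Kahan-compensated sums.  Without compensation the
  iterate-to-iterate rounding noise (~4e-12 on the full space) can
  exceed the 1e-12 tolerance and stall the stopping rule.
* **The fixed point is not unique.**  For α beyond a critical value
  (~1.1 on the full space) the map also has fully concentrated fixed
  points, and iterates started from a neighbouring α's solution can
  converge to a different fixed point than iterates started from
  column-normalized `C`.  The canonical solution is therefore defined
  by the cold start, and the implementation never chains solutions
  across α values.  Near the critical α the iteration shows critical
  slowing (up to ~10^4 iterations), which is why the iteration cap is
  generous.
* α = 0 reproduces strong sampling exactly (the power flattens each
  column over its support).

**Bias variants.**  The left-to-right indicator is 1 iff some ordering
of the three motifs concatenates to a prefix of the necklace.  The LR
bias multiplies LR-satisfying cells by a weight `w ≥ 1`; the simplicity
bias multiplies each row by `exp(−λ·K(d))`.  Pedagogical variants fold
the weights into every teacher step before column normalization;
heuristic variants apply them to `C` once, with no learner reasoning.
These functional forms (multiplicative column reweighting; exponential
complexity penalty) are the package's commitment where the choice was
open; `w = 1` and λ = 0 reduce exactly to the unbiased models.

## Algorithmic complexity

`bdm_complexity` implements the block decomposition method:
`BDM(d) = Σ_blocks [CTM(block) + log2(multiplicity)]`.  Ten-bead
necklaces are decomposed with the largest block the lookup table fully
covers (6 beads), following standard BDM practice; because a 6+4 split
is asymmetric, the score averages the left-aligned and right-aligned
decompositions, which restores exact invariance under string reversal
(the table itself is symmetric under reversal and complementation by
construction).

**The bundled lookup table is synthetic.**  Published CTM tables come
from exhaustive censuses of 5-state 2-symbol Turing machines (~10^13
machine runs) and are distributed only as precomputed data, which this
package does not ship.  Instead, `motifteach.ctm` runs the complete
census of 3-state 2-symbol machines (16.8 million machines, busy-beaver
formalism, blank-0 tape, 60-step cap against a 21-step halting bound),
estimates `CTM(s) = −log2 D(s)` from halting-output frequencies,
symmetrizes over the complement/reversal group, and keeps all fully
covered string lengths (2–6).  `scripts/build_ctm_table.py` regenerates
the bundled CSV deterministically in about half a minute.

Consequences, stated plainly:

* Absolute scores differ from published values; two reference necklaces
  whose published BDM scores are 26.99 and 27.69 bits score 27.37 and
  27.44 here.  A `ComplexityTableMismatchWarning` is raised on table
  load so this cannot pass silently.
* Some orderings differ qualitatively: alternation (`0101…`) is cheap
  for 5-state machines but not for 3-state machines, so the alternating
  necklace is *not* among the simplest here (uniform runs are).
  Within-package ordinal uses of complexity — the simplicity-bias
  variants, the pedagogical-vs-strong complexity contrast, the
  complexity-performance correlations — are unaffected in direction.

## Fitting and model comparison

Trials are (participant, village hypothesis, response necklace) rows;
responses inconsistent with their village are rejected at load, since
the task interface enforces consistency.  The pedagogical α is fitted
per participant by a grid search (0 to 20 in steps of 0.05; the
converged teacher matrix at every grid point is computed once per
session and shared across participants and datasets) followed by a
bounded local refinement: a parabola through the grid maximum and its
two neighbours proposes a vertex, the exact likelihood is evaluated
there with a fresh cold-started fixed point, and the better of vertex
and grid maximum is kept.  This one-evaluation refinement replaces a
multi-evaluation scalar search because every likelihood evaluation
requires a full fixed-point solve from the canonical start; the
likelihood surface is smooth at the 0.05 grid scale away from the
concentration transition, and at the transition no local search is
reliable anyway.  Fits on the upper grid boundary carry a flag.

A practical identifiability note: beyond the concentration transition
the teacher is near-deterministic, so responses generated at large α
that are not the column argmax are heavily penalized; fitted α
therefore saturates just below the transition unless a participant's
responses are exactly modal.  Parameter recovery is consequently
accurate in relative terms for generating α below ~1.5 and compressed
above.

Model comparison uses `BIC = k·log(n) − 2·log(L)` per participant
(k = 0 strong; 1 pedagogical and each heuristic; 2 for each biased
pedagogical variant), `−BIC/2` as log model evidence, and
random-effects Bayesian model selection: variational Dirichlet updates
(prior count 1 per family) iterated to 1e-6 on the frequency estimates,
exceedance probabilities from 10^6 seeded Dirichlet draws, the Bayesian
omnibus risk from the variational free-energy comparison against the
equal-frequency null, and `pxp = ep·(1 − BOR) + BOR/K`.  Families
assigning a participant zero likelihood receive −∞ evidence rather than
being dropped; a participant with −∞ under every family is an error.

## Synthetic data

The generator emulates the study design the analysis assumes: 18
villages drawn uniformly without replacement from the 220 hypotheses;
one response per (teacher, village) drawn from the teacher's model
column; learner stimulus sets of 18 necklaces, six per source (a
human-like pool, pedagogical simulations, strong-sampling simulations),
interleaved by a seeded permutation with the source label retained only
for scoring.  Teacher α values are log-normal with median 1.0 and
log-scale σ 0.5: the median sits where the pedagogical and strong
models are clearly distinguishable yet stochastic, and the spread
supplies the between-participant heterogeneity that random-effects
comparison is built for.  The human-like pool is generated from the
LR-biased pedagogical model (α = 1, w = 8), since real behavioural data
are not packaged.  A single master seed expands into per-stage
substreams (`SeedSequence` spawn keys); ground-truth parameters are
written to sidecar tables, never into analysis-facing files.

What the generator does **not** emulate: response times, attention
lapses, inconsistent motif reports as a cognitive process (scoring
exposes a consistency flag and an exclusion switch instead), or the
specific village sets and human necklaces of the original experiments.
Passing recovery tests therefore show that the estimation machinery is
correct and well-powered under the assumed generative process — not
that human behaviour follows it.

## Simulation sizes and statistical checks

Chosen once for power and runtime on one CPU, and fixed: α recovery
uses 30 participants × 18 villages (median relative error ≤ 25%);
model recovery uses 20 replicate datasets per generating family, 30
participants each, asserting correct selection (pxp > 0.5) by a
one-sided binomial test at the 5% level; the complexity
direction-of-effect uses 40 teachers per family on 18 matched villages
with a sign test (the per-village expected-complexity difference is
positive for 208 of the 220 possible villages, so 18-village samples
are well-powered); the baseline-learner benchmark uses 30 learners × 18
trials and asserts the qualitative regime (about one motif of three
recovered; under one bead of edit distance).

## Known limitations

* The complexity table is a reduced-scale stand-in (see above);
  absolute complexity values are not comparable to published ones.
* Fitted α is compressed above the concentration transition; comparing
  fitted α across participants is safest below ~1.5.
* The two-parameter biased-variant fits use deliberately coarse grids;
  they are adequate for model comparison demos, not for precise
  parameter interpretation.
* Circular necklaces, non-binary alphabets, non-uniform hypothesis
  priors, and depth-limited (finite-recursion) teacher variants are out
  of scope.
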