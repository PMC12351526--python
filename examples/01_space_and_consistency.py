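"""Enumerate the necklace-hypothesis space and inspect a worked example.

Builds the full 10-bead space, then asks: if a village's motifs are
{000, 11, 001}, which necklaces are valid teaching examples, and how
ambiguous is each one?
"""

from motifteach import space

sp = space.TeachingSpace()
print(f"necklaces: {len(sp.necklaces)}, hypotheses: {len(sp.hypotheses)}, "
      f"consistency matrix: {sp.C.shape}")

h = ("11", "000", "001")
for d in ("0000000111", "0001100011"):
    extra = sorted(space.substring_motifs(d) - set(h), key=lambda m: (len(m), m))
    n_alt = space.count_alternative_hypotheses(
        d, h, sp.necklaces, sp.hypotheses, sp.C
    )
    print(f"\nnecklace {d} teaching {h}:")
    print(f"  incorrect motifs present as substrings: {extra}")
    print(f"  alternative hypotheses with a valid parse: {n_alt}")

# The first necklace admits fewer wrong parses, so a learner shown it is
# less likely to walk away with the wrong motifs — the seed of the
# pedagogical teacher's preference demonstrated in example 02.
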