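"""Score necklaces with the block decomposition method.

BDM approximates algorithmic complexity by splitting a sequence into
short blocks, looking each block up in a precomputed coding-theorem
table, and charging log2 for repeats.  The bundled table comes from the
package's own reduced-scale Turing-machine census (see docs/methods.md),
so absolute values differ from published large-scale tables — a warning
says so on first load — while within-package comparisons remain valid.
"""

import warnings

from motifteach import complexity, space

with warnings.catch_warnings():
    warnings.simplefilter("ignore", complexity.ComplexityTableMismatchWarning)
    sp = space.default_space()
    K = complexity.complexity_table(sp.necklaces)

examples = ["0000000000", "0101010101", "0010010100", "1000000101", "0111100001"]
print("necklace      BDM (bits)")
for d in examples:
    print(f"{d}    {K[sp.row(d)]:.3f}")

print(f"\nacross all 1024 necklaces: min {K.min():.2f} "
      f"({sp.necklaces[K.argmin()]}), max {K.max():.2f} "
      f"({sp.necklaces[K.argmax()]}), mean {K.mean():.2f}")
# Uniform runs score lowest; irregular mixes of runs score highest.
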