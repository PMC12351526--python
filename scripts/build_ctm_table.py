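"""Regenerate the bundled synthetic CTM lookup table.

Runs the exhaustive 3-state 2-symbol Turing-machine census (see
``motifteach.ctm``) and writes the symmetrized coding-theorem complexity
estimates for all fully-covered string lengths (2-6) to
``src/motifteach/data/ctm32_synthetic.csv``.  Deterministic; takes about
half a minute on one CPU.

Usage: python scripts/build_ctm_table.py
"""

from __future__ import annotations

import csv
import itertools
from pathlib import Path

from motifteach import ctm


def main() -> None:
    table = ctm.ctm_table(ctm.DEFAULT_N_STATES, ctm.DEFAULT_STEP_CAP, max_len=8)
    # keep only fully covered lengths so every block lookup is total
    keep_lengths = [
        L
        for L in range(1, 9)
        if all("".join(b) in table for b in itertools.product("01", repeat=L))
    ]
    out = Path(__file__).resolve().parents[1] / "src" / "motifteach" / "data" / "ctm32_synthetic.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    with out.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["string", "ctm_bits"])
        for s in sorted(table, key=lambda s: (len(s), s)):
            if len(s) in keep_lengths:
                w.writerow([s, f"{table[s]:.6f}"])
    print(f"wrote {out} (lengths {keep_lengths})")


if __name__ == "__main__":
    main()
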