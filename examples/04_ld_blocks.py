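"""Pairwise D' and confidence-interval LD blocks.

Shows the disequilibrium arithmetic on toy haplotype counts, then recovers
ancestral haplotype blocks of 0.8 cM (400 kb at 2 cM/Mb) planted in a
simulated inbred panel.
"""

import numpy as np
import pandas as pd

from svqtl import GeneticMap, GenotypeMatrix, find_blocks, pair_ld, qc_filter, simulate_founders

for counts, label in [
    ((40, 10, 10, 40), "moderate coupling"),
    ((50, 0, 0, 50), "complete LD"),
    ((25, 25, 25, 25), "independence"),
]:
    pl = pair_ld(counts)
    print(f"{label}: counts(AB,Ab,aB,ab)={counts} -> D={pl.d:.3f} "
          f"|D'|={pl.dprime:.2f} CI=[{pl.ci_low:.2f},{pl.ci_high:.2f}] "
          f"-> {pl.classification}")

gmap = GeneticMap.dense({"A01": 4_800_000}, spacing_bp=50_000, cm_per_mb=2.0)
founders = simulate_founders(200, gmap, seed=5, block_cm=0.8, n_ancestral=2)
panel = GenotypeMatrix(
    founders.haplotypes["A01"].T,
    gmap.table.copy(),
    pd.DataFrame(
        {"subfamily": "panel"},
        index=pd.Index([f"L{i}" for i in range(200)], name="individual"),
    ),
)
filtered, _ = qc_filter(panel)  # drops markers monomorphic across haplotypes
blocks = find_blocks(filtered)
print(f"\nplanted 0.8 cM ancestral blocks; recovered {len(blocks)} blocks:")
for b in blocks:
    print(f"  {b.chrom}:{b.start:>9,}-{b.end:>9,}  {b.size_kb:6.0f} kb  "
          f"{len(b.markers)} markers")
print("block sizes cluster at/below 400 kb (edge markers that are")
print("monomorphic between the two ancestral haplotypes carry no LD signal).")
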