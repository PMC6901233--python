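"""PBSnj scan: population-specific branch lengths for four populations.

Pairwise comparisons cannot tell *which* population changed. PBSnj answers
this: per SNP, all pairwise Hudson F_ST values are transformed to drift
times T = −ln(1 − F_ST) and neighbor-joining assigns each population an
external branch length. Long branches mark SNPs whose frequency changed in
that population specifically. The script plants 50 sweeps in pop1 and shows
that they are recovered in pop1's tail (scaled score ≥ 0.8) and that only
pop1's tail is genically enriched.
"""

import numpy as np

from diffsel import SyntheticSpec, build_snp_table
from diffsel.pbsnj import pbsnj_scan, pbsnj_tail_ratio

spec = SyntheticSpec(seed=42)          # 4 populations, 38/36/20/22 haploids
ds = build_snp_table(spec)
scores, spectra = pbsnj_scan(ds.snps)

print("per-population PBSnj tail genic enrichment (tail = scaled score >= 0.8):")
for pop, sp in spectra.items():
    flag = "*" if sp.ci_low[4] > 1 else " "
    print(f"  {pop}: {sp.enrichment[4]:.3f} [{sp.ci_low[4]:.3f}, "
          f"{sp.ci_high[4]:.3f}] {flag}")
print("(* = CI excludes 1: genic excess beyond the genome-wide rate)")

lookup = {s: i for i, s in enumerate(scores.snp_index)}
rows = np.array([lookup[s] for s in ds.truth["snp"] if s in lookup])
tail = scores.tail_mask("pop1")
print(f"\nplanted sweeps recovered in pop1's tail: {tail[rows].mean():.0%} "
      f"(tail holds {tail.sum()} of {len(tail)} SNPs)")

r = pbsnj_tail_ratio(ds.snps, scores, "pop1", "pop2")
print(f"pop1 vs pop2 tail log2 ratio: {r.log2_ratio:.3f} "
      f"[{r.ci_low:.3f}, {r.ci_high:.3f}]")
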