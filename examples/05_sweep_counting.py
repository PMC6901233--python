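"""How many sweeps explain an excess tail enrichment?

Blocks of 200 kb are ranked by their count of tail genic SNPs and removed
one at a time, recomputing the focal population's tail genic enrichment,
until it falls below a null threshold (here: a non-swept population's upper
95% confidence limit). The number of removals k estimates how many discrete
sweep regions carry the signal; a random-removal baseline shows how
informative the ranking is.
"""

import numpy as np

from diffsel import SyntheticSpec, build_snp_table
from diffsel.pbsnj import pbsnj_scan
from diffsel.sweeps import estimate_sweep_number, rank_blocks, shuffle_baseline

spec = SyntheticSpec(n_snps=100_000, n_sweeps=60, sweep_blocks=10, seed=31)
ds = build_snp_table(spec)
scores, spectra = pbsnj_scan(ds.snps)

keep = np.zeros(len(ds.snps), bool)
keep[scores.snp_index] = True
sub = ds.snps.subset(keep)
tail = scores.tail_mask("pop1")
planted_blocks = len(np.unique(ds.snps.df["block"].to_numpy()[ds.truth["snp"]]))

threshold = spectra["pop2"].ci_high[4]
ranking = rank_blocks(sub, tail, ordering="genic")
k, traj, reached = estimate_sweep_number(sub, tail, ranking, threshold)
print(f"sweeps were planted in {planted_blocks} blocks; "
      f"null threshold (pop2 upper CI) = {threshold:.3f}")
print(f"ranked removal reaches the threshold after k = {k} blocks")
print("enrichment trajectory:", np.round(traj[: k + 3], 3))

base = shuffle_baseline(sub, tail, ranking, threshold, n_shuffles=300, seed=2)
print(f"random-order baseline: median k = {base.attrs['median']:.0f} "
      f"(90% range {base.attrs['q05']:.0f}-{base.attrs['q95']:.0f})")
print("ranked removal needs far fewer blocks than random order: the excess "
      "is concentrated in a small number of sweep regions.")
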