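# Methods

This note documents the models, estimators and numerical conventions the
package implements, the design choices made where several reasonable options
existed, and what the synthetic-data tests do and do not establish.

## δ binning and genic enrichment

δ = DAF₁ − DAF₂ is binned with edges
{−1, −0.8, −0.6, −0.4, −0.2, 0.0, 0.2, 0.4, 0.6, 0.79, 1}; every bin is
lower-open/upper-closed except bin 1, which is closed at both ends. Both
tails are therefore 0.2-wide up to a 0.01 shaving of the bin below the high
tail — a deliberately asymmetric convention that keeps the high tail
(δ > 0.79) from losing frequency-grid values just under 0.8. Consequences:

* δ = 0 falls in the bin whose upper edge is 0.0;
* swap antisymmetry (pair reversal flips the sign of the tail log₂ ratio) is
  exact on frequency grids without values in (0.79, 0.8) and approximate
  otherwise. δ values are quantized at 10 decimals before binning so that
  floating-point artefacts (0.85 − 0.05 = 0.7999999999999999) cannot move a
  SNP across an edge.

Genic status means "within a merged gene span padded by 2 kb on each side",
inclusive at both padded ends. Per-bin enrichment is normalised by the
global genic fraction, so the SNP-count-weighted mean enrichment is exactly
1; empty bins carry NaN (a zero would fabricate signal) and are excluded
from jackknifing.

## Weighted block jackknife

Confidence intervals come from the delete-m_j jackknife over non-overlapping
200 kb windows anchored at position 1 (windows [kL+1, (k+1)L] per
chromosome), with each window weighted by its total SNP count. With g blocks
of sizes m_j (n = Σm_j) and h_j = n/m_j:

    θ_J  = g·θ̂ − Σ_j (1 − m_j/n)·θ̂_j
    Var  = (1/g) Σ_j [h_j·θ̂ − (h_j − 1)·θ̂_j − θ_J]² / (h_j − 1)

Equal block sizes recover Tukey's delete-1 jackknife exactly (tested
longhand). CIs use normal critical values (large block counts), matching the
z-test interpretation of the tail-asymmetry p-value. Blocks whose removal
leaves a tail empty produce NaN leave-one-out values and are dropped from
the variance sum.

## PBSnj

Per SNP, pairwise Hudson F̂_ST (unbiased under unequal sample sizes; the
reason this estimator is used at all) is transformed to drift time
T = −ln(1 − F_ST). Conventions:

* negative F̂ (common for undifferentiated SNPs) is clamped to 0 — drift
  time cannot be negative;
* F̂ = 1 (reciprocally fixed differences) is replaced by the largest
  observed F̂ < 1 for that population pair (a global two-pass scan);
* F̂ undefined (both populations fixed for the same allele) contributes
  distance 0; SNPs undefined for *every* pair are dropped and counted.

Neighbor-joining (Saitou–Nei) then assigns every population an external
branch length; ties at the join-selection step break to the lowest taxon
pair for determinism, and the K = 4 case is fully vectorised (the first
join partitions SNPs into six topology classes; the remaining three-node
tree is the analytic three-point formula). For K = 3 the output equals the
classical PBS formula to 1e−9, which the test-suite asserts over 10⁴ random
triples alongside exact recovery of additive 4-taxon matrices and agreement
with an independent NJ implementation.

**0–1 normalisation.** Negative branch lengths are clamped to 0, then scores
are scaled per population. The default divides by the per-population 99.9th
percentile of the clamped branch lengths and caps at 1 ("quantile" scaling).
Rationale: scaling by the raw maximum lets a single near-fixed-difference
SNP (branch ≈ 3–4 drift units) set the scale, pushing typical swept loci
(branch ≈ 1–2) far below the 0.8 tail threshold and emptying the tail of
everything but reciprocally fixed sites; rank scaling, at the other extreme,
makes the "tail" the top 20% of all SNPs and dilutes the enrichment to
nothing. The 99.9th percentile anchors the tail at the conventional ~0.1%
outlier fraction of a genome scan while keeping the score monotone in the
branch length. `max`, `minmax` and `rank` scaling remain available via
`scale_scores(..., method=...)` since the field has no single convention.
Tail membership for K = 3 is identical to a classical PBS scan under any of
these monotone scalings.

## Demographic model and simulation

The packaged reference model (`src/diffsel/data/chimp_demography.msms`) is a
five-population history — bonobo plus the four chimpanzee subspecies — in
ms/msms notation: sizes relative to N0, times in 4N0 generations, migration
as 4N0m. The parser recovers N0 from θ = 4N0μL (N0 = 10⁴ at μ = 1.2e−8 and
L = 2001) and converts everything to natural units for msprime. Model
utilities implement the two calibration steps used to build such merged
models: population-size grafting by the ratio of two inferred sizes, and
split-time adjustment t = (F_obs + c)/F_model × t_base with c = −0.008.
Simulated pairwise F_ST reproduces the observed ladder (eastern–central
≈ 0.09).

Background selection enters as a B value multiplying every epoch size of a
population: E[diversity] scales linearly in B, verified against Watterson's
θ·a_{n−1} and a 2% linearity check at B ∈ {0.5, 0.8, 0.9}. Genic loci draw
B from a per-class source (fixed value or empirical distribution, shifted by
a constant and capped at 1 to sweep the genome-average B); non-genic loci
default to B = 1, and a per-population B dict expresses
heterogeneous-across-populations BGS. Loci are independent 2 kb fragments
(no intra-locus recombination by default; ρ ≈ 0.77/2 kb changes these
summaries negligibly) and each locus is its own jackknife block.

Two variance-reduction devices are used in tests, not in the library
defaults: a mutation-rate multiplier (more mutational draws per genealogy at
unchanged demography — the per-SNP frequency distribution is exactly the
model's, with within-locus correlation absorbed by the locus-level
jackknife), and a common random seed across the B-library entries of the
SSD fit, which makes the non-genic half of each library entry identical and
cancels most between-entry noise.

**SSD fitting.** fit_b minimises Σ_pairs Σ_bins (E_obs − E_sim(B))² over a
library of simulated spectra, with `all`, `no-tails` and `tails` bin
subsets; bins missing in either spectrum are skipped symmetrically.

**Closed-form checks.** Two textbook identities used as oracles deserve
care, because both are often quoted in a different variant: for Hudson's
F_ST = 1 − T_w/T_b, the symmetric 2-deme island model gives
F = 1/(1 + 8Nm) (not Wright's 1/(1 + 16Nm) pooled-total variant), and two
populations drifting F₁, F₂ from a shared root give ratio-of-averages
F_ST = (F₁ + F₂)/2 (not 1 − e^{−t_total}).

## Synthetic data generator

Frequency-level, not genealogical: a root frequency p₀ ~ U(0.05, 0.95) per
SNP drifts along a fixed tree — ((pop1,pop2),(pop3,pop4)) — by
Balding–Nichols Beta steps with branch variance p(1−p)(1 − e^{−τ}).
Defaults state the reference world: 38/36/20/22 haploids, 2×10⁵ SNPs on two
10 Mb chromosomes (100 blocks of 200 kb), genic fraction 0.4, drift times
(0.10, 0.09, 0.18, 0.35) leaf and (0.13, 0.15) internal, chosen via the
(F₁+F₂)/2 identity to produce the F_ST ladder 0.09–0.3. Within-block
correlation — what the jackknife exists to absorb — is induced by a shared
Gamma(3, 1/3) multiplier on each (block, branch) drift time.

Sweeps: 50 SNPs (default) among genic sites whose derived allele is at
DAF ≤ 0.25 in every non-target population get a target-population frequency
drawn from U(0.9, 1.0). The rarity restriction is the model of a
population-specific sweep (a *rise* of an allele rare elsewhere); planting
on alleles already common everywhere would model no sweep and produce no
differentiation. Options plant at non-genic sites (specificity tests),
confine sweeps to a set number of blocks (sweep counting), or concentrate
them in a named gene set (set-removal counterfactuals).

What a green test establishes: the estimators, their jackknife calibration
(coverage 90–98% on block-correlated nulls; z-test type-I error at 5%), and
end-to-end recovery of planted signals. What it does not: realism of the
site-frequency spectrum (use the coalescent engine for SFS-shaped
questions), selection at linked sites, or any property of real chimpanzee
data — the study's headline values (tail enrichments 1.58/1.19, log₂ ratio
0.41, PBSnj tails 1.35/1.13, best-fit B = 0.92) require the full 58-genome
dataset and are reproduced here only as directional properties.

## Resampling tests

Empirical p-values use the +1 rule, p = (1 + #extreme)/(1 + n), so p > 0
always. The resampling FDR at threshold p is R_exp(p)/R_obs(p), capped at 1,
with R_exp the *mean* per-resample count of pseudo p-values ≤ p — the only
reading that keeps the quantity in [0, 1]. Gene-mode resampling draws
background SNPs without replacement until the candidate's distinct-gene
count is matched, restricted to SNPs in genes that belong to at least one
set (hence the "all genes" device: a set containing every gene keeps the
sampling universe intact and has p = 1 by construction). A SNP inside
overlapping genes counts toward all of them. The two-sided binomial overlap
test uses the minimum-likelihood method (sum of outcome probabilities no
larger than the observed one).

## Sweep counting

Blocks are ranked by tail genic SNP count (ties to the lower block id;
`total` ordering available) and removed whole — numerator and denominator
both recomputed on the remaining data — until the focal tail genic
enrichment drops below a caller-supplied threshold, typically another
population's jackknife upper confidence limit or point estimate. A
tail-SNPs-only removal mode is provided since either reading of "remove
blocks" is defensible. On sweep-structured data the genic-ordered
trajectory decreases essentially monotonically, but whole-block removal
also perturbs the genome-wide genic fraction, so estimator-noise-sized
upward wiggles are possible and no strict monotonicity is asserted. The
random-shuffle baseline quantifies the ranking's information content.

## Known limitations

* The coalescent engine is msprime only; the ms-compatible parser covers
  the flags the reference command uses (-t, -r, -I, -n, -m, -en, -em, -ej),
  not the full ms grammar.
* PBSnj normalisation is a package convention (see above); results near the
  0.8 tail threshold depend on it, and cross-study comparisons should state
  the scaling used.
* The heterogeneous-BGS asymmetry ceiling is checked at desk scale as a
  one-sided bound: the δ tails of a closely related pair hold only tens of
  SNPs per ~10⁶ simulated SNPs, so a full confidence-interval exclusion of
  the observed asymmetry would require orders of magnitude more genealogies
  than a test suite can afford.
* Frequency-level fixtures have no realistic SFS and no selection at linked
  sites; conclusions about those require the coalescent path.
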