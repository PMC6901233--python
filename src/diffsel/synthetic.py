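"""Frequency-level synthetic datasets with the structure the scans assume.

The generator emulates a four-population system with nested splits and
unequal sample sizes (defaults: 38/36/20/22 haploids, the study design of a
published chimpanzee panel): a root derived-allele frequency is drawn per
SNP, then drifted along each branch of a fixed population tree using
Balding–Nichols Beta sampling, where a branch of drift time τ contributes
variance p(1−p)·F with F = 1 − e^{−τ}. For two leaves whose paths to their
common ancestor accumulate F_1 and F_2, the ratio-of-averages Hudson F_ST
is (F_1 + F_2)/2, and the default drift times produce an F_ST ladder of
~0.09 (closest pair) to ~0.3 (most diverged pairs).

Linkage is emulated by a shared per-block Gamma-distributed drift
multiplier, so SNPs in a 200 kb block are correlated and the block
jackknife has real block structure to absorb. Planted sweeps set the target
population's derived frequency into a high range at chosen genic SNPs,
leaving other populations untouched.

This generator is frequency-level plumbing for testing the scan machinery;
it does not model genealogies or background selection (use ``bgs_sim``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from diffsel.variant_io import (
    GENIC_PAD, BLOCK_LENGTH, GeneAnnotation, PopulationPanel, SnpTable,
    annotate_genic, assign_blocks,
)


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic dataset (the defaults are the reference
    fixture used across the test-suite)."""

    populations: tuple[str, ...] = ("pop1", "pop2", "pop3", "pop4")
    haploid_sizes: tuple[int, ...] = (38, 36, 20, 22)
    # balanced topology ((pop1,pop2),(pop3,pop4)); drift in diffusion time units
    leaf_drift: tuple[float, ...] = (0.10, 0.09, 0.18, 0.35)
    internal_drift: tuple[float, float] = (0.13, 0.15)
    n_snps: int = 200_000
    n_chromosomes: int = 2
    chromosome_length: int = 10_000_000
    genic_fraction: float = 0.4
    gene_length_range: tuple[int, int] = (5_000, 40_000)
    block_length: int = BLOCK_LENGTH
    block_drift_shape: float = 3.0      # Gamma shape of the shared block deviate
    n_sweeps: int = 50
    sweep_population: str = "pop1"
    sweep_freq_range: tuple[float, float] = (0.9, 1.0)
    sweep_genic: bool = True            # plant at genic SNPs (False: non-genic)
    sweep_max_other_daf: float | None = 0.25  # sweeps act on alleles rare elsewhere
    sweep_blocks: int | None = None     # confine sweeps to this many blocks
    n_gene_sets: int = 20
    gene_set_size_range: tuple[int, int] = (3, 30)
    planted_overlap_fraction: float = 0.0  # fraction of sweeps inside the "planted" set
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.genic_fraction <= 1):
            raise ValueError("genic_fraction must lie in [0, 1]")
        lo, hi = self.sweep_freq_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("sweep_freq_range must lie inside [0, 1]")
        if any(t < 0 for t in self.leaf_drift + self.internal_drift):
            raise ValueError("drift times must be >= 0")
        if len(self.haploid_sizes) != len(self.populations):
            raise ValueError("one haploid size per population")
        if self.n_sweeps and self.sweep_population not in self.populations:
            raise ValueError(f"unknown sweep population {self.sweep_population!r}")


def _bn_drift(p: np.ndarray, f: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Balding–Nichols one-branch drift: Beta with mean p, variance p(1-p)f."""
    out = p.copy()
    active = (p > 0) & (p < 1) & (f > 0)
    if active.any():
        c = 1.0 / f[active] - 1.0
        out[active] = rng.beta(p[active] * c, (1 - p[active]) * c)
    return out


def _branch_f(tau: float, block_of_snp: np.ndarray, n_blocks: int,
              shape: float, rng: np.random.Generator) -> np.ndarray:
    """Per-SNP branch fixation index with a shared per-block multiplier."""
    if tau == 0:
        return np.zeros(len(block_of_snp))
    w = rng.gamma(shape, 1.0 / shape, size=n_blocks)
    return 1.0 - np.exp(-tau * w[block_of_snp])


def generate_frequencies(spec: SyntheticSpec, rng: np.random.Generator,
                         block_of_snp: np.ndarray | None = None,
                         n_blocks: int | None = None) -> np.ndarray:
    """Per-SNP per-population derived frequencies under tree drift.

    Root frequencies are Uniform(0.05, 0.95); each branch applies
    Balding–Nichols drift with the branch's time, modulated by the shared
    block deviate when block assignments are given.
    """
    n = spec.n_snps
    if block_of_snp is None:
        block_of_snp = np.zeros(n, dtype=int)
        n_blocks = 1
    k = len(spec.populations)
    p0 = rng.uniform(0.05, 0.95, size=n)

    def branch(p, tau):
        f = _branch_f(tau, block_of_snp, n_blocks, spec.block_drift_shape, rng)
        return _bn_drift(p, f, rng)

    freqs = np.empty((n, k))
    if k == 2:
        freqs[:, 0] = branch(p0, spec.leaf_drift[0])
        freqs[:, 1] = branch(p0, spec.leaf_drift[1])
    elif k == 3:
        anc12 = branch(p0, spec.internal_drift[0])
        freqs[:, 0] = branch(anc12, spec.leaf_drift[0])
        freqs[:, 1] = branch(anc12, spec.leaf_drift[1])
        freqs[:, 2] = branch(p0, spec.leaf_drift[2])
    elif k == 4:
        anc12 = branch(p0, spec.internal_drift[0])
        anc34 = branch(p0, spec.internal_drift[1])
        freqs[:, 0] = branch(anc12, spec.leaf_drift[0])
        freqs[:, 1] = branch(anc12, spec.leaf_drift[1])
        freqs[:, 2] = branch(anc34, spec.leaf_drift[2])
        freqs[:, 3] = branch(anc34, spec.leaf_drift[3])
    else:
        raise ValueError("supported population counts: 2, 3 or 4")
    return freqs


def plant_sweeps(freqs: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator,
                 genic_mask: np.ndarray, block_of_snp: np.ndarray | None = None,
                 candidate_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Plant population-specific frequency jumps in-place; return the truth table.

    ``spec.n_sweeps`` SNPs are chosen from the genic (or non-genic, per
    ``sweep_genic``) SNPs — optionally confined to ``spec.sweep_blocks``
    blocks and/or an extra ``candidate_mask`` — and the target population's
    frequency is redrawn uniformly from ``sweep_freq_range``. Other
    populations are untouched.
    """
    if spec.n_sweeps == 0:
        return pd.DataFrame(columns=["snp", "target_freq"])
    pool = np.asarray(genic_mask, bool) if spec.sweep_genic else ~np.asarray(genic_mask, bool)
    if candidate_mask is not None:
        pool = pool & np.asarray(candidate_mask, bool)
    if spec.sweep_max_other_daf is not None:
        kpop_ = spec.populations.index(spec.sweep_population)
        others = np.delete(freqs, kpop_, axis=1)
        pool = pool & (others.max(axis=1) <= spec.sweep_max_other_daf)
    idx_pool = np.flatnonzero(pool)
    if spec.sweep_blocks is not None:
        if block_of_snp is None:
            raise ValueError("sweep_blocks requires block assignments")
        blocks_avail = np.unique(block_of_snp[idx_pool])
        chosen_blocks = rng.choice(blocks_avail, size=min(spec.sweep_blocks,
                                                          len(blocks_avail)),
                                   replace=False)
        idx_pool = idx_pool[np.isin(block_of_snp[idx_pool], chosen_blocks)]
    if spec.n_sweeps > len(idx_pool):
        raise ValueError("fewer eligible SNPs than requested sweeps")
    chosen = np.sort(rng.choice(idx_pool, size=spec.n_sweeps, replace=False))
    lo, hi = spec.sweep_freq_range
    target = rng.uniform(lo, hi, size=spec.n_sweeps)
    kpop = spec.populations.index(spec.sweep_population)
    freqs[chosen, kpop] = target
    return pd.DataFrame({"snp": chosen, "target_freq": target})


def _layout_genome(spec: SyntheticSpec, rng: np.random.Generator):
    """SNP positions and non-overlapping genes whose padded intervals cover
    ~``genic_fraction`` of each chromosome."""
    per_chrom = spec.n_snps // spec.n_chromosomes
    counts = [per_chrom] * spec.n_chromosomes
    counts[-1] += spec.n_snps - sum(counts)
    chroms, positions = [], []
    gene_rows = []
    gid = 0
    for c in range(spec.n_chromosomes):
        name = str(c + 1)
        L = spec.chromosome_length
        # SNP positions: oversample, dedupe, trim
        want = counts[c]
        pos = np.unique(rng.integers(1, L + 1, size=int(want * 1.05) + 16))
        while len(pos) < want:  # pragma: no cover - astronomically unlikely
            pos = np.unique(np.concatenate([pos, rng.integers(1, L + 1, size=want)]))
        pos = np.sort(rng.choice(pos, size=want, replace=False))
        chroms.extend([name] * want)
        positions.append(pos)
        # genes: draw padded spans until the genic budget is met, then spread
        budget = spec.genic_fraction * L
        spans = []
        total = 0.0
        lo, hi = spec.gene_length_range
        while total < budget:
            glen = int(rng.integers(lo, hi + 1))
            spans.append(glen)
            total += glen + 2 * GENIC_PAD
        free = max(L - int(total), 0)
        gaps = rng.multinomial(free, np.ones(len(spans) + 1) / (len(spans) + 1))
        cursor = 1 + GENIC_PAD
        for glen, gap in zip(spans, gaps[:-1]):
            start = cursor + gap
            end = start + glen - 1
            if end + GENIC_PAD > L:
                break
            gene_rows.append((f"g{gid}", name, start, end, "+"))
            gid += 1
            cursor = end + 2 * GENIC_PAD + 1
    genes = GeneAnnotation(pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"]))
    return np.asarray(chroms), np.concatenate(positions), genes


def _make_gene_sets(spec: SyntheticSpec, genes: GeneAnnotation,
                    planted_genes, rng: np.random.Generator) -> dict[str, frozenset]:
    ids = genes.df["gene_id"].to_numpy()
    sets = {}
    lo, hi = spec.gene_set_size_range
    for s in range(spec.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        sets[f"set{s}"] = frozenset(rng.choice(ids, size=min(size, len(ids)),
                                               replace=False))
    if planted_genes:
        sets["planted"] = frozenset(planted_genes)
    return sets


@dataclass
class SyntheticDataset:
    """An in-memory synthetic dataset plus its generating truth."""

    spec: SyntheticSpec
    snps: SnpTable
    genes: GeneAnnotation
    gene_sets: dict[str, frozenset]
    truth: pd.DataFrame        # planted sweeps: snp row index, target freq, gene
    frequencies: np.ndarray    # (n_snps, K) true per-population frequencies

    @property
    def panel(self) -> PopulationPanel:
        mapping = {}
        for pop, n_hap in zip(self.spec.populations, self.spec.haploid_sizes):
            for i in range(n_hap // 2):
                mapping[f"{pop}_{i}"] = pop
        return PopulationPanel(self.spec.populations, mapping)


def build_snp_table(spec: SyntheticSpec, seed: int | None = None) -> SyntheticDataset:
    """Generate the full dataset in memory (no files touched)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    chroms, positions, genes = _layout_genome(spec, rng)

    core = pd.DataFrame({"chrom": chroms, "pos": positions,
                         "anc": "A", "der": "G"})
    for pop in spec.populations:
        core[f"der_{pop}"] = 0
        core[f"called_{pop}"] = 0
    stub = SnpTable(core, spec.populations, validate=False)
    stub = annotate_genic(stub, genes)
    stub = assign_blocks(stub, spec.block_length)
    genic = stub.df["genic"].to_numpy(bool)
    block_raw = stub.df["block"].to_numpy()
    uniq_blocks, block_of_snp = np.unique(block_raw, return_inverse=True)

    freqs = generate_frequencies(spec, rng, block_of_snp, len(uniq_blocks))

    # sweeps, optionally concentrated inside the "planted" gene set
    planted_genes: list[str] = []
    candidate_mask = None
    if spec.n_sweeps and spec.planted_overlap_fraction > 0:
        gi = genes.gene_intervals()
        inside = np.zeros(spec.n_snps, bool)
        snp_gene = np.full(spec.n_snps, "", dtype=object)
        for _, g in gi.iterrows():
            m = (stub.df["chrom"].to_numpy() == g["chrom"]) & \
                (positions >= g["start"]) & (positions <= g["end"])
            inside |= m
            snp_gene[m] = g["gene_id"]
        truth = plant_sweeps(freqs, spec, rng, genic, block_of_snp,
                             candidate_mask=inside)
        n_in = int(round(spec.planted_overlap_fraction * len(truth)))
        planted_genes = sorted({snp_gene[s] for s in truth["snp"][:n_in] if snp_gene[s]})
    else:
        truth = plant_sweeps(freqs, spec, rng, genic, block_of_snp)

    # binomial genotype sampling
    for k, (pop, n_hap) in enumerate(zip(spec.populations, spec.haploid_sizes)):
        stub.df[f"der_{pop}"] = rng.binomial(n_hap, freqs[:, k])
        stub.df[f"called_{pop}"] = n_hap

    gene_sets = _make_gene_sets(spec, genes, planted_genes, rng)
    return SyntheticDataset(spec=spec, snps=stub, genes=genes,
                            gene_sets=gene_sets, truth=truth, frequencies=freqs)


def emit_dataset(spec: SyntheticSpec, outdir, seed: int | None = None) -> dict:
    """Write the dataset to disk: VCF + panel + gene BED + genetic map +
    gene sets (GMT) + truth TSV. Returns the path map.

    All files round-trip through ``variant_io``: derived counts read back
    from the VCF match the generating binomial draws exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = build_snp_table(spec, seed=seed)
    paths = {
        "vcf": outdir / "synthetic.vcf",
        "panel": outdir / "panel.tsv",
        "genes": outdir / "genes.bed",
        "map": outdir / "genetic_map.tsv",
        "gmt": outdir / "gene_sets.gmt",
        "truth": outdir / "truth.tsv",
    }
    panel = ds.panel
    samples = list(panel.sample_to_population)
    with open(paths["panel"], "w") as fh:
        for s in samples:
            fh.write(f"{s}\t{panel.sample_to_population[s]}\n")

    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(set(ds.snps.df["chrom"]), key=str):
            fh.write(f"##contig=<ID={c},length={spec.chromosome_length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        df = ds.snps.df
        der = {p: df[f"der_{p}"].to_numpy() for p in spec.populations}
        for i in range(len(df)):
            gts = []
            for pop, n_hap in zip(spec.populations, spec.haploid_sizes):
                d = int(der[pop][i])
                n_ind = n_hap // 2
                homs, het = divmod(d, 2)
                for j in range(n_ind):
                    if j < homs:
                        gts.append("1/1")
                    elif j == homs and het:
                        gts.append("0/1")
                    else:
                        gts.append("0/0")
            fh.write(f"{df['chrom'].iat[i]}\t{df['pos'].iat[i]}\t.\tA\tG\t.\t.\t"
                     f"AA=A\tGT\t" + "\t".join(gts) + "\n")

    with open(paths["genes"], "w") as fh:
        for _, g in ds.genes.df.iterrows():
            fh.write(f"{g['chrom']}\t{g['start'] - 1}\t{g['end']}\t{g['gene_id']}\t0\t{g['strand']}\n")

    rng = np.random.default_rng((spec.seed if seed is None else seed) + 7)
    with open(paths["map"], "w") as fh:
        for c in range(spec.n_chromosomes):
            marker_pos = np.arange(1, spec.chromosome_length, 100_000)
            rates = np.round(rng.lognormal(mean=0.0, sigma=0.7, size=len(marker_pos)), 4)
            for p, r in zip(marker_pos, rates):
                fh.write(f"{c + 1}\t{p}\t{r}\n")

    with open(paths["gmt"], "w") as fh:
        for name, genes_ in ds.gene_sets.items():
            fh.write(name + "\tsynthetic\t" + "\t".join(sorted(genes_)) + "\n")

    ds.truth.to_csv(paths["truth"], sep="\t", index=False)
    return {"dataset": ds, **{k: str(v) for k, v in paths.items()}}
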