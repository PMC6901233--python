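"""Variant input, polarization, annotation and block partitioning.

Coordinates are 1-based inclusive everywhere internally (VCF/GFF convention);
BED inputs are converted on read. Sex chromosomes and unplaced scaffolds are
excluded at VCF read time: only chromosomes whose name (after stripping a
``chr`` prefix) is a positive integer are treated as autosomes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: genic intervals are gene spans extended by this many bp on each side
GENIC_PAD = 2000

#: jackknife block length in bp
BLOCK_LENGTH = 200_000


def _is_autosome(chrom: str) -> bool:
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    # chimp-style names like "2A"/"2B" count as autosomes too
    if name and name[-1] in "AB" and name[:-1].isdigit():
        return True
    return name.isdigit() and int(name) > 0


@dataclass(frozen=True)
class PopulationPanel:
    """Sample-to-population assignment with per-population haploid sizes.

    ``haploid_sizes`` are 2x the diploid sample counts; a minimum of 4
    haploids per population is required for the unbiased F_ST correction
    terms (which divide by n-1).
    """

    populations: tuple[str, ...]
    sample_to_population: dict[str, str]

    def __post_init__(self):
        if len(set(self.populations)) != len(self.populations):
            raise ValueError("population names must be unique")
        extra = set(self.sample_to_population.values()) - set(self.populations)
        if extra:
            raise ValueError(f"samples assigned to unknown populations: {sorted(extra)}")
        for pop, n in self.haploid_sizes.items():
            if n < 4:
                raise ValueError(
                    f"population {pop!r} has {n} haploids; at least 4 are required"
                )

    @property
    def haploid_sizes(self) -> dict[str, int]:
        sizes = {p: 0 for p in self.populations}
        for pop in self.sample_to_population.values():
            sizes[pop] += 2
        return sizes

    def samples_for(self, population: str) -> list[str]:
        return [s for s, p in self.sample_to_population.items() if p == population]

    @classmethod
    def from_file(cls, path) -> "PopulationPanel":
        """Read a two-column ``sample<TAB>population`` text file."""
        mapping: dict[str, str] = {}
        order: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                sample, pop = line.split("\t")[:2]
                mapping[sample] = pop
                if pop not in order:
                    order.append(pop)
        return cls(populations=tuple(order), sample_to_population=mapping)


class SnpTable:
    """Per-SNP, per-population derived-allele counts plus annotation columns.

    Backed by a :class:`pandas.DataFrame` with columns ``chrom``, ``pos``,
    ``anc``, ``der``, ``der_<pop>``/``called_<pop>`` per population, and the
    annotation columns ``genic`` (bool), ``block`` (int, -1 = unassigned) and
    ``rate`` (cM/Mb, NaN = unknown).
    """

    CORE = ["chrom", "pos", "anc", "der"]

    def __init__(self, df: pd.DataFrame, populations: tuple[str, ...], validate: bool = True):
        self.df = df.reset_index(drop=True)
        self.populations = tuple(populations)
        for col, default in (("genic", False), ("block", -1), ("rate", np.nan)):
            if col not in self.df.columns:
                self.df[col] = default
        if validate:
            self._validate()

    def _validate(self):
        df = self.df
        for pop in self.populations:
            d, c = df[f"der_{pop}"].to_numpy(), df[f"called_{pop}"].to_numpy()
            if len(d) and (np.any(d < 0) or np.any(d > c)):
                raise ValueError(f"derived counts outside [0, called] for {pop!r}")
        for chrom, sub in df.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if len(pos) > 1 and np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "SnpTable":
        return SnpTable(self.df.copy(), self.populations, validate=False)

    def subset(self, mask) -> "SnpTable":
        return SnpTable(self.df.loc[np.asarray(mask)], self.populations, validate=False)

    def daf(self, population: str) -> np.ndarray:
        """Derived allele frequency per SNP for one population."""
        d = self.df[f"der_{population}"].to_numpy(float)
        c = self.df[f"called_{population}"].to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(c > 0, d / c, np.nan)

    def counts(self, population: str) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.df[f"der_{population}"].to_numpy(),
            self.df[f"called_{population}"].to_numpy(),
        )

    # -- sidecar TSV format ------------------------------------------------
    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("#populations=" + ",".join(self.populations) + "\n")
            self.df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SnpTable":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("#populations="):
                raise ValueError("missing #populations header line")
            pops = tuple(p for p in header.split("=", 1)[1].split(",") if p)
            df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
        df["genic"] = df["genic"].astype(bool)
        return cls(df, pops, validate=False)


@dataclass
class PolarizationStats:
    flipped: int = 0
    dropped_missing: int = 0
    dropped_mismatch: int = 0


@dataclass
class GeneAnnotation:
    """Gene spans (1-based inclusive). Genic intervals are spans +- 2 kb,
    clipped at 1 and merged when overlapping."""

    df: pd.DataFrame  # gene_id, chrom, start, end, strand

    def __post_init__(self):
        if (self.df["start"] > self.df["end"]).any():
            raise ValueError("gene start > end")
        if self.df["gene_id"].duplicated().any():
            raise ValueError("gene ids must be unique")

    def merged_intervals(self, pad: int = GENIC_PAD) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome merged, padded intervals as (starts, ends) arrays."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            starts = np.maximum(sub["start"].to_numpy() - pad, 1)
            ends = sub["end"].to_numpy() + pad
            order = np.argsort(starts, kind="stable")
            starts, ends = starts[order], ends[order]
            m_starts, m_ends = [starts[0]], [ends[0]]
            for s, e in zip(starts[1:], ends[1:]):
                if s <= m_ends[-1] + 1:
                    m_ends[-1] = max(m_ends[-1], e)
                else:
                    m_starts.append(s)
                    m_ends.append(e)
            out[str(chrom)] = (np.asarray(m_starts), np.asarray(m_ends))
        return out

    def gene_intervals(self, pad: int = GENIC_PAD) -> pd.DataFrame:
        """Per-gene padded (unmerged) intervals, for SNP-to-gene assignment."""
        df = self.df.copy()
        df["start"] = np.maximum(df["start"] - pad, 1)
        df["end"] = df["end"] + pad
        return df

    @classmethod
    def from_bed(cls, path) -> "GeneAnnotation":
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.rstrip("\n").split("\t")
                chrom, start0, end = parts[0], int(parts[1]), int(parts[2])
                gene = parts[3] if len(parts) > 3 else f"{chrom}:{start0}-{end}"
                strand = parts[5] if len(parts) > 5 else "+"
                rows.append((gene, chrom, start0 + 1, end, strand))
        return cls(pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"]))

    @classmethod
    def from_gff3(cls, path, feature: str = "gene") -> "GeneAnnotation":
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9 or parts[2] != feature:
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                )
                gene = attrs.get("ID", attrs.get("gene_id", f"{parts[0]}:{parts[3]}"))
                rows.append((gene, parts[0], int(parts[3]), int(parts[4]), parts[6]))
        return cls(pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"]))


@dataclass
class GeneticMap:
    """Per-chromosome sorted markers: position (bp) + local rate (cM/Mb)."""

    markers: dict[str, pd.DataFrame]  # chrom -> DataFrame(pos, rate)

    def __post_init__(self):
        for chrom, df in self.markers.items():
            pos = df["pos"].to_numpy()
            if len(pos) > 1 and np.any(np.diff(pos) <= 0):
                raise ValueError(f"map positions not strictly increasing on {chrom}")
            if (df["rate"] < 0).any():
                raise ValueError(f"negative recombination rate on {chrom}")

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        """Three-column TSV: chrom, pos, rate (cM/Mb). Header optional."""
        df = pd.read_csv(path, sep="\t", comment="#",
                         names=["chrom", "pos", "rate"], dtype={"chrom": str})
        if df.iloc[0]["pos"] == "pos" or not str(df.iloc[0]["pos"]).replace(".", "").isdigit():
            df = df.iloc[1:]
        df["pos"] = df["pos"].astype(int)
        df["rate"] = df["rate"].astype(float)
        return cls({c: sub[["pos", "rate"]].reset_index(drop=True)
                    for c, sub in df.groupby("chrom", sort=False)})


# ---------------------------------------------------------------------------
# operations


def read_variants(vcf_path, panel: PopulationPanel, ancestral_tag: str | None = None) -> SnpTable:
    """Read bi-allelic autosomal SNPs with zero missing genotypes from a VCF.

    Multi-allelic records and non-SNPs are skipped (counted in the log);
    records with any missing genotype across the panel samples are removed,
    so every retained SNP has ``called == haploid size`` per population.
    Derived counts are provisionally the ALT counts (REF treated as
    ancestral) until :func:`polarize` is applied. If ``ancestral_tag`` is
    given, that INFO field is stored in an ``aa`` column for later use.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    vcf_samples = list(vcf.samples)
    missing = [s for s in panel.sample_to_population if s not in vcf_samples]
    if missing:
        raise ValueError(f"samples absent from VCF: {missing}")

    pop_idx = {
        pop: np.array([vcf_samples.index(s) for s in panel.samples_for(pop)], dtype=int)
        for pop in panel.populations
    }
    panel_idx = np.concatenate(list(pop_idx.values())) if pop_idx else np.array([], int)

    rows = []
    n_multi = n_missing = n_nonsnp = n_nonauto = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1 or v.ALT[0] not in "ACGT":
            n_nonsnp += 1
            continue
        if not _is_autosome(v.CHROM):
            n_nonauto += 1
            continue
        # gts012: 0=hom ref, 1=het, 2=hom alt, 3=unknown
        gts = v.gt_types
        if np.any(gts[panel_idx] == 3):
            n_missing += 1
            continue
        row = [v.CHROM, v.POS, v.REF, v.ALT[0]]
        for pop in panel.populations:
            g = gts[pop_idx[pop]]
            row.append(int(g.sum()))          # ALT allele count
            row.append(2 * len(g))            # called haploids
        if ancestral_tag is not None:
            row.append(v.INFO.get(ancestral_tag))
        rows.append(row)

    cols = ["chrom", "pos", "anc", "der"]
    for pop in panel.populations:
        cols += [f"der_{pop}", f"called_{pop}"]
    if ancestral_tag is not None:
        cols.append("aa")
    df = pd.DataFrame(rows, columns=cols)
    if n_multi or n_missing or n_nonsnp or n_nonauto:
        logger.info(
            "read_variants: skipped %d multi-allelic, %d non-SNP, %d non-autosomal, "
            "%d with missing genotypes", n_multi, n_nonsnp, n_nonauto, n_missing,
        )
    table = SnpTable(df, panel.populations, validate=bool(len(df)))
    table.read_stats = {
        "multiallelic": n_multi, "non_snp": n_nonsnp,
        "non_autosomal": n_nonauto, "missing_genotypes": n_missing,
    }
    return table


def polarize(snps: SnpTable, ancestral) -> SnpTable:
    """Polarize derived counts against an ancestral-allele source.

    ``ancestral`` is either the name of a column of ``snps.df`` holding the
    ancestral base (e.g. ``"aa"`` captured from an INFO tag), or a mapping
    ``(chrom, pos) -> base`` (e.g. looked up from an outgroup reference).

    Where the ancestral call equals ALT the derived counts are flipped and
    anc/der swapped; SNPs whose ancestral call is missing or matches neither
    allele are dropped and counted (``.polarization`` on the result).
    """
    df = snps.df
    if isinstance(ancestral, str):
        anc_call = df[ancestral].astype(object).to_numpy()
    else:
        anc_call = np.array(
            [ancestral.get((c, p)) for c, p in zip(df["chrom"], df["pos"])], dtype=object
        )
    anc_call = np.array(
        [a.upper() if isinstance(a, str) else None for a in anc_call], dtype=object
    )
    ref = df["anc"].to_numpy()
    alt = df["der"].to_numpy()
    is_ref = anc_call == ref
    is_alt = anc_call == alt
    missing = np.array([a is None or a not in "ACGT" for a in anc_call])
    mismatch = ~is_ref & ~is_alt & ~missing

    out = df[is_ref | is_alt].copy()
    flip = is_alt[is_ref | is_alt]
    for pop in snps.populations:
        d = out[f"der_{pop}"].to_numpy()
        c = out[f"called_{pop}"].to_numpy()
        out[f"der_{pop}"] = np.where(flip, c - d, d)
    anc_new = np.where(flip, out["der"], out["anc"])
    der_new = np.where(flip, out["anc"], out["der"])
    out["anc"], out["der"] = anc_new, der_new

    result = SnpTable(out, snps.populations, validate=False)
    result.polarization = PolarizationStats(
        flipped=int(flip.sum()),
        dropped_missing=int(missing.sum()),
        dropped_mismatch=int(mismatch.sum()),
    )
    return result


def annotate_genic(snps: SnpTable, genes: GeneAnnotation, pad: int = GENIC_PAD) -> SnpTable:
    """Flag SNPs lying in any merged +-``pad`` bp gene interval (inclusive ends)."""
    intervals = genes.merged_intervals(pad)
    out = snps.copy()
    genic = np.zeros(len(out), dtype=bool)
    for chrom, sub in out.df.groupby("chrom", sort=False):
        if str(chrom) not in intervals:
            warnings.warn(f"chromosome {chrom} absent from gene annotation; "
                          "all its SNPs marked non-genic")
            continue
        starts, ends = intervals[str(chrom)]
        pos = sub["pos"].to_numpy()
        # index of the last interval starting at or before pos
        i = np.searchsorted(starts, pos, side="right") - 1
        inside = (i >= 0) & (pos <= ends[np.clip(i, 0, None)])
        genic[sub.index] = inside
    out.df["genic"] = genic
    return out


def assign_blocks(snps: SnpTable, block_length: int = BLOCK_LENGTH) -> SnpTable:
    """Assign each SNP a non-overlapping window id of ``block_length`` bp.

    Windows are [k*L+1, (k+1)*L] per chromosome, anchored at position 1.
    Ids are stable: sorted (chrom, window) pairs are enumerated from 0.
    """
    out = snps.copy()
    k = (out.df["pos"].to_numpy() - 1) // block_length
    keys = list(zip(out.df["chrom"].to_numpy(), k))
    uniq = sorted(set(keys))
    lookup = {key: i for i, key in enumerate(uniq)}
    out.df["block"] = np.array([lookup[key] for key in keys], dtype=int)
    return out


def interpolate_rates(gmap: GeneticMap, chrom: str, positions) -> np.ndarray:
    """Recombination rate (cM/Mb) at each position.

    A position strictly between consecutive markers receives the *average*
    of the two flanking marker rates; a position at a marker receives that
    marker's rate; positions outside the marker span receive the nearest
    terminal marker's rate. With fewer than 2 markers rates are NaN.
    """
    positions = np.asarray(positions)
    if chrom not in gmap.markers or len(gmap.markers[chrom]) < 2:
        warnings.warn(f"fewer than 2 genetic-map markers on {chrom}; rates undefined")
        return np.full(len(positions), np.nan)
    mk = gmap.markers[chrom]
    mpos = mk["pos"].to_numpy()
    mrate = mk["rate"].to_numpy()
    right = np.searchsorted(mpos, positions, side="left")
    rates = np.empty(len(positions), dtype=float)

    below = right == 0
    above = right == len(mpos)
    at = ~below & ~above & (mpos[np.clip(right, 0, len(mpos) - 1)] == positions)
    between = ~below & ~above & ~at
    rates[below] = mrate[0]
    rates[above] = mrate[-1]
    rates[at] = mrate[right[at]]
    rates[between] = 0.5 * (mrate[right[between] - 1] + mrate[right[between]])
    return rates


def filter_by_rate(snps: SnpTable, max_rate: float = 0.5) -> SnpTable:
    """Keep SNPs with recombination rate strictly below ``max_rate`` cM/Mb.

    SNPs without a rate are dropped. ``max_rate = inf`` is the identity.
    """
    if np.isinf(max_rate):
        return snps.copy()
    rate = snps.df["rate"].to_numpy(float)
    keep = rate < max_rate  # NaN compares False -> dropped
    if not keep.any():
        warnings.warn("filter_by_rate removed every SNP")
    return snps.subset(keep)


def filter_by_region(snps: SnpTable, excluded) -> SnpTable:
    """Remove SNPs inside any excluded (chrom, start, end) 1-based inclusive interval."""
    if not excluded:
        return snps.copy()
    remove = np.zeros(len(snps), dtype=bool)
    chrom_arr = snps.df["chrom"].to_numpy()
    pos = snps.df["pos"].to_numpy()
    for chrom, start, end in excluded:
        remove |= (chrom_arr == chrom) & (pos >= start) & (pos <= end)
    return snps.subset(~remove)
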