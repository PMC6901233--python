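"""Resampling-based enrichment tests for SNP categories and gene sets.

All empirical p-values use the +1 rule, p = (1 + #{resamples at least as
extreme}) / (1 + n), so p never equals 0 with finite resampling. The
resampling false-discovery rate at threshold p is R_exp(p) / R_obs(p),
where R_exp is the mean per-resample count of pseudo p-values <= p and
R_obs the count of observed p-values <= p, capped at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets; sets smaller than ``min_size`` are dropped on load."""

    sets: dict[str, frozenset]
    min_size: int = 3

    def __post_init__(self):
        kept = {}
        for name, genes in self.sets.items():
            genes = frozenset(genes)
            if len(genes) < self.min_size:
                logger.info("dropping gene set %s (size %d < %d)",
                            name, len(genes), self.min_size)
                continue
            kept[name] = genes
        self.sets = kept

    def __len__(self):
        return len(self.sets)

    @classmethod
    def from_two_column(cls, path, min_size: int = 3) -> "GeneSetCollection":
        """Two-column "set<TAB>gene" text."""
        sets: dict[str, set] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                name, gene = line.rstrip("\n").split("\t")[:2]
                sets.setdefault(name, set()).add(gene)
        return cls({k: frozenset(v) for k, v in sets.items()}, min_size)

    @classmethod
    def from_gmt(cls, path, min_size: int = 3) -> "GeneSetCollection":
        sets = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                sets[parts[0]] = frozenset(g for g in parts[2:] if g)
        return cls(sets, min_size)


def empirical_p(observed: float, resampled, direction: str = "ge") -> float:
    """Empirical p with the +1 rule; ``direction`` is "ge" (enrichment) or
    "le" (depletion). Monotone in the observed value, never 0."""
    r = np.asarray(resampled, float)
    if len(r) == 0:
        raise ValueError("need at least one resample")
    if direction == "ge":
        extreme = int((r >= observed).sum())
    elif direction == "le":
        extreme = int((r <= observed).sum())
    else:
        raise ValueError("direction must be 'ge' or 'le'")
    return (1 + extreme) / (1 + len(r))


def snp_category_test(candidates, background, categories: pd.Series,
                      n_resamples: int = 1000, seed: int = 1) -> pd.DataFrame:
    """Category-proportion permutation test for a candidate SNP set.

    ``candidates``/``background`` are SNP identifiers (candidates must be a
    subset of background); ``categories`` maps SNP id -> label (NaN = no
    label). For each category the observed candidate proportion is compared
    against size-matched random draws from the background; both one-sided
    empirical p-values are reported.
    """
    cand = pd.Index(candidates)
    bg = pd.Index(background)
    if len(cand) > len(bg):
        raise ValueError("candidate set larger than background")
    if not cand.isin(bg).all():
        raise ValueError("candidates must be a subset of the background")
    rng = np.random.default_rng(seed)
    labels = categories.dropna().unique()
    cat = categories.reindex(bg)
    cat_codes = pd.Categorical(cat, categories=labels).codes  # -1 = unlabelled
    n_lab = len(labels)
    cand_mask = bg.isin(cand)
    n_cand = int(cand_mask.sum())

    def _props(mask):
        codes = cat_codes[mask]
        counts = np.bincount(codes[codes >= 0], minlength=n_lab)
        return counts / mask.sum()

    obs = _props(cand_mask)
    sims = np.empty((n_resamples, n_lab))
    for r in range(n_resamples):
        pick = rng.choice(len(bg), size=n_cand, replace=False)
        mask = np.zeros(len(bg), bool)
        mask[pick] = True
        sims[r] = _props(mask)
    rows = []
    for k, lab in enumerate(labels):
        rows.append({
            "category": lab,
            "observed": obs[k],
            "expected": sims[:, k].mean(),
            "p_greater": empirical_p(obs[k], sims[:, k], "ge"),
            "p_less": empirical_p(obs[k], sims[:, k], "le"),
        })
    return pd.DataFrame(rows)


@dataclass
class GeneModeResult:
    table: pd.DataFrame          # set, observed, expected, p, fdr
    pseudo_p: np.ndarray         # (n_resamples, n_sets) pseudo p-values
    candidate_gene_count: int


def _pseudo_ps(counts: np.ndarray) -> np.ndarray:
    """Per-resample pseudo p-values from the resample count matrix.

    For resample r and set s: the +1-rule proportion of resamples with a
    count >= counts[r, s], computed against the full resample distribution.
    """
    n = counts.shape[0]
    order = np.sort(counts, axis=0)
    # number of resamples with count >= c, via searchsorted on the sorted column
    ge = n - np.stack([
        np.searchsorted(order[:, s], counts[:, s], side="left")
        for s in range(counts.shape[1])
    ], axis=1)
    return (1 + ge) / (1 + n)


def gene_mode_resample(candidate_snps, background_snps, snp_genes: dict,
                       sets: GeneSetCollection, n_resamples: int = 1000,
                       seed: int = 1) -> GeneModeResult:
    """Gene-mode resampling enrichment (GOWINDA-style).

    ``snp_genes`` maps SNP id -> iterable of gene ids (a SNP in overlapping
    genes counts toward all of them). The background is restricted to SNPs
    in genes belonging to at least one set. Each resample draws background
    SNPs without replacement until the distinct-gene count matches the
    candidate gene count; per set, the observed statistic is the number of
    genes hit by candidate SNPs that belong to the set.
    """
    set_names = list(sets.sets)
    universe_genes = frozenset().union(*sets.sets.values()) if set_names else frozenset()
    bg = [s for s in background_snps
          if any(g in universe_genes for g in snp_genes.get(s, ()))]
    cand = [s for s in candidate_snps
            if any(g in universe_genes for g in snp_genes.get(s, ()))]

    def genes_of(snp_list):
        out = set()
        for s in snp_list:
            out.update(g for g in snp_genes.get(s, ()) if g in universe_genes)
        return out

    cand_genes = genes_of(cand)
    target = len(cand_genes)
    all_bg_genes = genes_of(bg)
    if target > len(all_bg_genes):
        raise ValueError("candidate gene count unattainable from the background")

    observed = np.array([len(cand_genes & sets.sets[s]) for s in set_names])

    rng = np.random.default_rng(seed)
    bg_arr = np.array(bg, dtype=object)
    counts = np.zeros((n_resamples, len(set_names)), dtype=int)
    for r in range(n_resamples):
        perm = rng.permutation(len(bg_arr))
        seen: set = set()
        for idx in perm:
            seen.update(g for g in snp_genes[bg_arr[idx]] if g in universe_genes)
            if len(seen) >= target:
                break
        for k, name in enumerate(set_names):
            counts[r, k] = len(seen & sets.sets[name])

    ps = np.array([
        empirical_p(observed[k], counts[:, k], "ge") for k in range(len(set_names))
    ])
    pseudo = _pseudo_ps(counts)
    fdr = np.array([resampling_fdr(ps, pseudo, p) for p in ps])
    table = pd.DataFrame({
        "set": set_names,
        "observed": observed,
        "expected": counts.mean(axis=0),
        "p": ps,
        "fdr": fdr,
    })
    return GeneModeResult(table=table, pseudo_p=pseudo, candidate_gene_count=target)


def resampling_fdr(observed_ps, pseudo_ps: np.ndarray, p: float) -> float:
    """FDR at threshold p: mean per-resample count of pseudo p <= p, divided
    by the count of observed p <= p, capped at 1."""
    observed_ps = np.asarray(observed_ps, float)
    r_obs = int((observed_ps <= p).sum())
    if r_obs == 0:
        raise ValueError("no observed p-values at or below the threshold")
    r_exp = float((np.asarray(pseudo_ps) <= p).sum(axis=1).mean())
    return min(r_exp / r_obs, 1.0)


def weighted_gene_resample(candidate_sets: dict, target_genes, weights: pd.Series,
                           n_resamples: int = 1000, seed: int = 1) -> pd.DataFrame:
    """SNP-count-weighted gene resampling with a family-level FDR.

    ``candidate_sets`` maps a family member (e.g. population) to its
    candidate gene set; ``weights`` maps gene -> sampling probability
    (proportion of SNPs in the gene, correcting gene-length bias; must sum
    to 1). For each member, random gene sets of matched size are drawn with
    probability proportional to weight and the overlap with ``target_genes``
    gives an empirical p. The FDR at each p pools pseudo p-values over the
    whole family (R_exp summed over members).
    """
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    target = frozenset(target_genes)
    genes = weights.index.to_numpy(dtype=object)
    probs = weights.to_numpy(float)
    rng = np.random.default_rng(seed)
    is_target = np.isin(genes, list(target))

    rows = []
    pseudo_cols = []
    for name, cand in candidate_sets.items():
        cand = frozenset(cand)
        size = len(cand)
        if size > len(genes):
            raise ValueError("matched size exceeds the gene universe")
        observed = len(cand & target)
        overlaps = np.empty(n_resamples, dtype=int)
        for r in range(n_resamples):
            pick = rng.choice(len(genes), size=size, replace=False, p=probs)
            overlaps[r] = int(is_target[pick].sum())
        p = empirical_p(observed, overlaps, "ge")
        rows.append({"member": name, "observed": observed,
                     "expected": overlaps.mean(), "p": p})
        pseudo_cols.append(_pseudo_ps(overlaps[:, None])[:, 0])
    df = pd.DataFrame(rows)
    pseudo = np.stack(pseudo_cols, axis=1)   # (n_resamples, family size)
    df["fdr"] = [resampling_fdr(df["p"], pseudo, p) for p in df["p"]]
    return df


def binomial_overlap_test(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p by the minimum-likelihood method (the sum
    of P(i) over outcomes no more likely than the observed k)."""
    if not (0 <= k <= n):
        raise ValueError("k must lie in [0, n]")
    if not (0 <= p0 <= 1):
        raise ValueError("p0 must lie in [0, 1]")
    if n == 0:
        return 1.0
    return float(stats.binomtest(k, n, p0).pvalue)


def remove_geneset_snps(snp_ids, snp_genes: dict, gene_set, tail_masks: dict,
                        population: str) -> dict:
    """Counterfactual removal of one gene set's tail SNPs for one population.

    Returns a copy of ``tail_masks`` where SNPs of ``population``'s tail
    that lie in any gene of ``gene_set`` are removed; other populations'
    tails are untouched. Downstream enrichments are then recomputed on the
    modified masks.
    """
    gene_set = frozenset(gene_set)
    snp_ids = np.asarray(snp_ids, dtype=object)
    in_set = np.array([
        any(g in gene_set for g in snp_genes.get(s, ())) for s in snp_ids
    ])
    out = {p: np.array(m, copy=True) for p, m in tail_masks.items()}
    out[population] = out[population] & ~in_set
    return out
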