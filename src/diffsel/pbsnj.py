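"""Per-SNP multi-population branch lengths (PBSnj).

For each SNP the pairwise Hudson F_ST matrix across K populations is
transformed to drift time T = −ln(1 − F_ST) and fed to neighbor-joining
(Saitou–Nei). Each population's external branch length measures its
population-specific allele-frequency change; for K = 3 the branch lengths
equal the classical PBS three-point formula.

The Hudson estimator is used because it is unbiased under unequal sample
sizes:

    F̂ = [(p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)]
        / [p1(1−p2) + p2(1−p1)]

with p the derived allele frequency and n the called haploid count. The
denominator is 0 only when both populations are fixed for the same allele,
in which case F̂ is undefined (NaN).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from diffsel.variant_io import SnpTable
from diffsel import differentiation

logger = logging.getLogger(__name__)

#: PBSnj bin edges on the 0-1 scale; the tail bin is scores >= 0.8
PBSNJ_BIN_EDGES = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
PBSNJ_TAIL = 0.8


def hudson_fst(der1, called1, der2, called2):
    """Hudson's unbiased pairwise F_ST from derived/called haploid counts.

    Vectorized; returns NaN where the denominator is 0 (both populations
    fixed for the same allele). Raises for called counts <= 1.
    """
    d1 = np.asarray(der1, float)
    n1 = np.asarray(called1, float)
    d2 = np.asarray(der2, float)
    n2 = np.asarray(called2, float)
    if np.any(n1 <= 1) or np.any(n2 <= 1):
        raise ValueError("called haploid counts must be >= 2")
    p1, p2 = d1 / n1, d2 / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(den > 0, num / den, np.nan)
    return fst if fst.ndim else float(fst)


def hudson_fst_components(der1, called1, der2, called2):
    """(numerator, denominator) arrays for ratio-of-averages F_ST."""
    d1 = np.asarray(der1, float); n1 = np.asarray(called1, float)
    d2 = np.asarray(der2, float); n2 = np.asarray(called2, float)
    p1, p2 = d1 / n1, d2 / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def pair_replacement(fst_values) -> float:
    """Largest observed F_ST strictly below 1 for a population pair.

    Used to replace F_ST = 1 (fixed differences) before the log transform,
    which is otherwise undefined. Requires at least one non-1 value.
    """
    f = np.asarray(fst_values, float)
    f = f[np.isfinite(f) & (f < 1)]
    if len(f) == 0:
        raise ValueError("no observed F_ST below 1; replacement undefined")
    return float(f.max())


def drift_distance(fst, replacement: float | None = None):
    """Transform F_ST to drift time T = −ln(1 − F_ST').

    F_ST' is ``replacement`` where F_ST = 1, and max(F_ST, 0) otherwise
    (negative unbiased estimates are clamped to 0: drift time cannot be
    negative). NaN inputs (undefined F_ST: both populations identical and
    fixed) yield T = 0, the distance between identical populations.
    """
    f = np.atleast_1d(np.asarray(fst, float))
    if replacement is not None and replacement >= 1:
        raise ValueError("replacement value must be < 1")
    out = np.where(np.isnan(f), 0.0, np.clip(f, 0.0, None))
    is_one = out >= 1.0
    if np.any(is_one):
        if replacement is None:
            raise ValueError("F_ST = 1 present but no replacement value given")
        out = np.where(is_one, replacement, out)
    T = -np.log1p(-out)
    return T if np.asarray(fst).ndim else float(T[0])


# ---------------------------------------------------------------------------
# neighbor-joining


def nj_branch_lengths(dist: np.ndarray) -> tuple[np.ndarray, str]:
    """Saitou–Nei neighbor-joining external branch lengths for one matrix.

    Returns (external branch length per taxon, unrooted topology as a
    newick string with taxa labelled by index). Ties at the join-selection
    step break to the lowest (i, j) pair for determinism. For K = 3 the
    result equals the three-point formula.
    """
    D = np.asarray(dist, float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite entry in distance matrix")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    K = D.shape[0]
    if K < 3:
        raise ValueError("need at least 3 taxa")

    external = np.zeros(K)
    nodes = list(range(K))          # active node ids; < K are leaves
    labels = {i: str(i) for i in range(K)}
    D = D.copy()

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        iu = np.triu_indices(n, k=1)
        best = np.argmin(Q[iu])     # row-major upper triangle -> lowest pair wins ties
        i, j = iu[0][best], iu[1][best]
        dij = D[i, j]
        bi = 0.5 * dij + (r[i] - r[j]) / (2 * (n - 2))
        bj = dij - bi
        for node, b in ((nodes[i], bi), (nodes[j], bj)):
            if node < K:
                external[node] = b
        # merge i, j into a new internal node
        new_label = f"({labels[nodes[i]]},{labels[nodes[j]]})"
        d_new = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(n) if k not in (i, j)]
        D_next = np.empty((n - 1, n - 1))
        D_next[: n - 2, : n - 2] = D[np.ix_(keep, keep)]
        D_next[-1, : n - 2] = d_new[keep]
        D_next[: n - 2, -1] = d_new[keep]
        D_next[-1, -1] = 0.0
        new_id = K + len(labels)    # fresh id
        labels[new_id] = new_label
        nodes = [nodes[k] for k in keep] + [new_id]
        D = D_next

    # final 3 nodes: three-point formula
    a, b, c = nodes
    ba = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    bb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    bc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    for node, blen in ((a, ba), (b, bb), (c, bc)):
        if node < K:
            external[node] = blen
    topology = f"({labels[a]},{labels[b]},{labels[c]});"
    return external, topology


def _nj_batch4(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized NJ external branch lengths for a batch of 4x4 matrices.

    Returns (branches (n, 4), join_pair_code (n,)) where the code indexes
    the first-joined pair among the 6 (i<j) pairs, which fully determines
    the unrooted 4-taxon topology.
    """
    n = D.shape[0]
    r = D.sum(axis=2)                           # (n, 4)
    Q = 2 * D - r[:, :, None] - r[:, None, :]
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    Qp = np.stack([Q[:, i, j] for i, j in pairs], axis=1)   # (n, 6)
    choice = np.argmin(Qp, axis=1)              # ties -> lowest pair index
    branches = np.empty((n, 4))
    for code, (i, j) in enumerate(pairs):
        mask = choice == code
        if not mask.any():
            continue
        a, b = [k for k in range(4) if k not in (i, j)]
        d = D[mask]
        rm = r[mask]
        dij = d[:, i, j]
        bi = 0.5 * dij + (rm[:, i] - rm[:, j]) / 4.0
        bj = dij - bi
        # distances from the new node u to the remaining taxa a, b
        dua = 0.5 * (d[:, i, a] + d[:, j, a] - dij)
        dub = 0.5 * (d[:, i, b] + d[:, j, b] - dij)
        dab = d[:, a, b]
        ba_ = 0.5 * (dua + dab - dub)
        bb_ = 0.5 * (dub + dab - dua)
        branches[mask, i] = bi
        branches[mask, j] = bj
        branches[mask, a] = ba_
        branches[mask, b] = bb_
    return branches, choice


def pbs_three(t_ab, t_ac, t_bc):
    """Classical three-population PBS for population A: (T_AB + T_AC − T_BC)/2."""
    return (np.asarray(t_ab) + np.asarray(t_ac) - np.asarray(t_bc)) / 2.0


def scale_scores(raw: np.ndarray, method: str = "quantile",
                 quantile: float = 0.999) -> np.ndarray:
    """Normalise raw branch lengths to the 0-1 scale, per population (column).

    Negative branch lengths are clamped to 0 first (negative drift is
    meaningless for tail enrichment). Methods:

    * ``quantile`` — divide by the per-population ``quantile`` (default
      99.9th percentile) of the clamped values and cap at 1. Robust: the
      scale is not set by the single most extreme fixed-difference SNP, and
      the tail (score >= 0.8) captures the conventional ~0.1% outlier
      fraction of a selection scan.
    * ``max``   — divide by the per-population maximum.
    * ``minmax`` — subtract the per-population minimum of the clamped values
      then divide by the range.
    * ``rank``  — fractional rank (average ties) of the clamped values.
    """
    raw = np.asarray(raw, float)
    x = np.clip(raw, 0.0, None)
    if x.ndim == 1:
        x = x[:, None]
        squeeze = True
    else:
        squeeze = False
    out = np.zeros_like(x)
    for k in range(x.shape[1]):
        col = x[:, k]
        if method == "quantile":
            q = np.quantile(col, quantile) if len(col) else 0.0
            if q == 0:
                q = col.max() if len(col) else 0.0
            if q == 0:
                warnings.warn("per-population scale is 0; all scores set to 0")
            else:
                out[:, k] = np.minimum(col / q, 1.0)
        elif method == "max":
            mx = col.max() if len(col) else 0.0
            if mx == 0:
                warnings.warn("per-population maximum is 0; all scores set to 0")
            else:
                out[:, k] = col / mx
        elif method == "minmax":
            mn, mx = col.min(), col.max()
            if mx == mn:
                warnings.warn("degenerate score range; all scores set to 0")
            else:
                out[:, k] = (col - mn) / (mx - mn)
        elif method == "rank":
            from scipy.stats import rankdata
            out[:, k] = (rankdata(col, method="average") - 1) / max(len(col) - 1, 1)
        else:
            raise ValueError(f"unknown scaling method {method!r}")
    return out[:, 0] if squeeze else out


@dataclass
class PbsnjScores:
    """Per-SNP raw and 0-1-scaled population branch lengths."""

    populations: tuple[str, ...]
    raw: np.ndarray        # (n_snps, K) external branch lengths, drift-time units
    scaled: np.ndarray     # (n_snps, K) in [0, 1]
    topology: np.ndarray   # per-SNP topology code or newick label
    snp_index: np.ndarray  # row index into the originating SnpTable
    n_dropped: int = 0     # SNPs with F_ST undefined for every pair

    def tail_mask(self, population: str, threshold: float = PBSNJ_TAIL) -> np.ndarray:
        k = self.populations.index(population)
        return self.scaled[:, k] >= threshold

    def to_frame(self) -> pd.DataFrame:
        data = {"snp": self.snp_index}
        for k, pop in enumerate(self.populations):
            data[f"raw_{pop}"] = self.raw[:, k]
            data[f"scaled_{pop}"] = self.scaled[:, k]
        return pd.DataFrame(data)


def bin_pbsnj(scores) -> np.ndarray:
    """Bin index 1..5 for scaled scores in [0, 1]; bin 5 is the tail (>= 0.8)."""
    x = np.asarray(scores, float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("scaled scores must lie in [0, 1]")
    return np.minimum(np.digitize(x, PBSNJ_BIN_EDGES[1:-1], right=False), 4) + 1


def pbsnj_scan(snps: SnpTable, populations=None, scale_method: str = "quantile",
               alpha: float = 0.05):
    """Full PBSnj scan: per-SNP branch lengths, scaled scores, and per-
    population genic-enrichment spectra with jackknife CIs.

    Returns (PbsnjScores, {population: EnrichmentSpectrum}). SNPs whose
    F_ST is undefined for every pair are dropped (counted on the result).
    """
    pops = tuple(populations) if populations else snps.populations
    K = len(pops)
    if K < 3:
        raise ValueError("PBSnj needs at least 3 populations")
    n = len(snps)
    counts = {p: snps.counts(p) for p in pops}
    pair_list = list(itertools.combinations(range(K), 2))

    fst = {}
    for i, j in pair_list:
        d1, c1 = counts[pops[i]]
        d2, c2 = counts[pops[j]]
        fst[(i, j)] = hudson_fst(d1, c1, d2, c2)

    all_nan = np.ones(n, dtype=bool)
    for f in fst.values():
        all_nan &= np.isnan(f)
    keep = ~all_nan
    n_dropped = int(all_nan.sum())
    if n_dropped:
        logger.info("pbsnj_scan: dropped %d SNPs with F_ST undefined for every pair",
                    n_dropped)

    T = np.zeros((keep.sum(), K, K))
    for i, j in pair_list:
        f = fst[(i, j)][keep]
        try:
            repl = pair_replacement(f)
        except ValueError:
            repl = None
        t = drift_distance(f, replacement=repl)
        T[:, i, j] = t
        T[:, j, i] = t

    if K == 4:
        raw, topo = _nj_batch4(T)
    else:
        raw = np.empty((T.shape[0], K))
        topo = np.empty(T.shape[0], dtype=object)
        for s in range(T.shape[0]):
            raw[s], topo[s] = nj_branch_lengths(T[s])

    scaled = scale_scores(raw, method=scale_method)
    scores = PbsnjScores(
        populations=pops, raw=raw, scaled=scaled, topology=topo,
        snp_index=np.flatnonzero(keep), n_dropped=n_dropped,
    )

    sub = snps.subset(keep)
    spectra = {}
    for k, pop in enumerate(pops):
        bins = bin_pbsnj(scaled[:, k])
        spectra[pop] = differentiation.enrichment_with_ci(sub, bins, alpha=alpha, n_bins=5)
    return scores, spectra


def pbsnj_tail_ratio(snps: SnpTable, scores: PbsnjScores, pop1: str, pop2: str,
                     alpha: float = 0.05):
    """log2 ratio of two populations' PBSnj tail genic enrichments, with
    weighted block-jackknife CI and z-test (tail = scaled score >= 0.8).

    The global genic fraction cancels in the ratio, so the leave-one-out
    values reduce to the ratio of the two tails' genic fractions computed
    from per-block counts.
    """
    keep = np.zeros(len(snps), dtype=bool)
    keep[scores.snp_index] = True
    sub = snps.subset(keep)
    genic = sub.df["genic"].to_numpy(bool)
    blocks = sub.df["block"].to_numpy()
    m1 = scores.tail_mask(pop1)
    m2 = scores.tail_mask(pop2)

    uniq, inv = np.unique(blocks, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 non-empty blocks")

    def _counts(mask):
        t = np.bincount(inv[mask], minlength=len(uniq)).astype(float)
        g = np.bincount(inv[mask & genic], minlength=len(uniq)).astype(float)
        return g, t

    g1, t1 = _counts(m1)
    g2, t2 = _counts(m2)
    tall = np.bincount(inv, minlength=len(uniq)).astype(float)
    gall = np.bincount(inv[genic], minlength=len(uniq)).astype(float)
    frac = gall.sum() / tall.sum()
    if t1.sum() == 0 or t2.sum() == 0 or g1.sum() == 0 or g2.sum() == 0:
        raise ValueError(
            f"empty or all-non-genic tail (pop1 tail n={t1.sum():.0f} genic={g1.sum():.0f}, "
            f"pop2 tail n={t2.sum():.0f} genic={g2.sum():.0f}); log2 ratio undefined"
        )
    e1 = (g1.sum() / t1.sum()) / frac
    e2 = (g2.sum() / t2.sum()) / frac
    L = float(np.log2(e1 / e2))

    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = (g1.sum() - g1) / (t1.sum() - t1)
        f2 = (g2.sum() - g2) / (t2.sum() - t2)
        L_loo = np.log2(f1 / f2)
    L_loo[~np.isfinite(L_loo)] = np.nan
    jk = differentiation.weighted_jackknife(L, L_loo, tall, alpha=alpha)
    return differentiation.TailAsymmetry(
        pop1=pop1, pop2=pop2, log2_ratio=L, se=jk.se, ci_low=jk.ci_low,
        ci_high=jk.ci_high, p_value=jk.p_value,
        enrichment_high=e1, enrichment_low=e2,
        pseudovalues=jk.loo_estimates,
    )
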