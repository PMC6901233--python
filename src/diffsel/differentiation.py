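"""δ spectra, genic enrichment, weighted block jackknife and asymmetry tests.

δ = DAF_pop1 − DAF_pop2 is binned into 10 bins. Both tail bins are exactly
0.2 wide: bin 1 is [−1, −0.8] (closed) and bin 10 is (0.79, 1], which makes
the bin whose upper edge is 0.79 narrower by 0.01. Interior bins are
lower-open/upper-closed, so δ = 0 falls in the bin with upper edge 0.0.

Confidence intervals come from a weighted delete-m_j block jackknife
(Busing et al. 1999) over non-overlapping 200 kb genomic windows, with each
window weighted by its total SNP count.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from diffsel.variant_io import SnpTable

#: the 11 bin edges; bin b spans (edges[b-1], edges[b]] except bin 1, closed at -1
DELTA_BIN_EDGES = np.array([-1.0, -0.8, -0.6, -0.4, -0.2, 0.0, 0.2, 0.4, 0.6, 0.79, 1.0])

N_BINS = 10
TAIL_BINS = (1, 10)


@dataclass
class DeltaValues:
    """Per-SNP signed difference in derived allele frequency for one pair."""

    pop1: str
    pop2: str
    values: np.ndarray

    def swapped(self) -> "DeltaValues":
        return DeltaValues(self.pop2, self.pop1, -self.values)


@dataclass
class EnrichmentSpectrum:
    """Per-bin genic/total counts and enrichment ratios.

    ``enrichment[b]`` is (genic_b / total_b) / (genic_all / total_all);
    empty bins carry NaN (undefined, not zero). The SNP-count-weighted mean
    of the defined enrichments is 1 by construction.
    """

    bin_edges: np.ndarray
    genic_counts: np.ndarray
    total_counts: np.ndarray
    enrichment: np.ndarray
    global_fraction: float
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return len(self.total_counts)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "bin": np.arange(1, self.n_bins + 1),
            "genic": self.genic_counts,
            "total": self.total_counts,
            "enrichment": self.enrichment,
        })
        if self.ci_low is not None:
            df["lo95"] = self.ci_low
            df["hi95"] = self.ci_high
        return df


@dataclass
class JackknifeEstimate:
    """Weighted delete-m_j jackknife summary (Busing et al.)."""

    estimate: float            # plug-in estimate on the full data
    bias_corrected: float
    se: float
    ci_low: float
    ci_high: float
    alpha: float
    loo_estimates: np.ndarray  # per-block leave-one-out estimates
    weights: np.ndarray        # m_j, SNPs per block

    @property
    def z(self) -> float:
        return self.estimate / self.se if self.se > 0 else np.inf * np.sign(self.estimate)

    @property
    def p_value(self) -> float:
        """Two-sided normal p for H0: parameter = 0."""
        if self.se == 0:
            return 0.0 if self.estimate != 0 else 1.0
        return 2 * stats.norm.sf(abs(self.estimate) / self.se)


# ---------------------------------------------------------------------------


def delta(snps: SnpTable, pop1: str, pop2: str) -> DeltaValues:
    """Signed DAF difference, one value per SNP. Antisymmetric in the pair."""
    for pop in (pop1, pop2):
        if pop not in snps.populations:
            raise KeyError(f"unknown population {pop!r}")
    return DeltaValues(pop1, pop2, snps.daf(pop1) - snps.daf(pop2))


def bin_delta(values) -> np.ndarray:
    """Bin index 1..10 for each δ in [−1, 1] (hard error outside)."""
    x = np.atleast_1d(np.asarray(values, dtype=float))
    if np.any((x < -1 - 1e-9) | (x > 1 + 1e-9) | np.isnan(x)):
        raise ValueError("delta values must lie in [-1, 1]")
    # quantize away float artifacts (e.g. 0.85 - 0.05 = 0.7999999999999999)
    # so allele-count ratios that are exactly on a bin edge bin consistently
    x = np.clip(np.round(x, 10), -1.0, 1.0)
    bins = np.digitize(x, DELTA_BIN_EDGES[1:-1], right=True) + 1
    return bins


def genic_enrichment(bins, genic, n_bins: int = N_BINS,
                     bin_edges: np.ndarray | None = None) -> EnrichmentSpectrum:
    """Per-bin genic enrichment normalized by the global genic fraction."""
    bins = np.asarray(bins)
    genic = np.asarray(genic, dtype=bool)
    if len(bins) != len(genic):
        raise ValueError("bins and genic flags must align")
    genic_all = genic.sum()
    total_all = len(bins)
    if genic_all == 0:
        raise ValueError("no genic SNPs: enrichment undefined")
    total = np.bincount(bins, minlength=n_bins + 1)[1:].astype(float)
    gcount = np.bincount(bins, weights=genic.astype(float), minlength=n_bins + 1)[1:]
    global_fraction = genic_all / total_all
    with np.errstate(invalid="ignore", divide="ignore"):
        enr = (gcount / total) / global_fraction
    enr[total == 0] = np.nan
    edges = DELTA_BIN_EDGES if bin_edges is None and n_bins == N_BINS else bin_edges
    return EnrichmentSpectrum(edges, gcount, total, enr, global_fraction)


def weighted_jackknife(theta_hat: float, theta_loo, m, alpha: float = 0.05) -> JackknifeEstimate:
    """Weighted delete-m_j jackknife (Busing et al. 1999).

    With g blocks of sizes m_j (n = Σ m_j) and h_j = n / m_j:

      θ_J  = g·θ̂ − Σ_j (1 − m_j/n)·θ̂_j
      Var  = (1/g)·Σ_j [1/(h_j − 1)]·(h_j·θ̂ − (h_j − 1)·θ̂_j − θ_J)²

    With all m_j equal this reduces to the classical Tukey delete-1
    jackknife. The CI is θ̂ ± z_{α/2}·SE.
    """
    theta_loo = np.asarray(theta_loo, dtype=float)
    m = np.asarray(m, dtype=float)
    ok = ~np.isnan(theta_loo)
    theta_loo, m = theta_loo[ok], m[ok]
    g = len(theta_loo)
    if g < 2:
        raise ValueError("need at least 2 non-empty blocks")
    n = m.sum()
    if np.any(m >= n):
        raise ValueError("a single block contains all SNPs; h_j undefined")
    h = n / m
    theta_j = g * theta_hat - np.sum((1 - m / n) * theta_loo)
    pseudo = h * theta_hat - (h - 1) * theta_loo
    var = np.sum((pseudo - theta_j) ** 2 / (h - 1)) / g
    se = float(np.sqrt(var))
    zcrit = stats.norm.ppf(1 - alpha / 2)
    return JackknifeEstimate(
        estimate=float(theta_hat), bias_corrected=float(theta_j), se=se,
        ci_low=float(theta_hat - zcrit * se), ci_high=float(theta_hat + zcrit * se),
        alpha=alpha, loo_estimates=theta_loo, weights=m,
    )


def block_jackknife(statistic, snps: SnpTable, alpha: float = 0.05) -> JackknifeEstimate:
    """Weighted block jackknife of an arbitrary statistic of a SnpTable.

    ``statistic`` is called once on the full table and once per block on the
    table with that block deleted. Blocks are weighted by their SNP counts.
    """
    blocks = snps.df["block"].to_numpy()
    uniq, counts = np.unique(blocks, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 non-empty blocks")
    theta_hat = statistic(snps)
    loo = np.array([statistic(snps.subset(blocks != b)) for b in uniq], dtype=float)
    return weighted_jackknife(theta_hat, loo, counts, alpha=alpha)


def _block_bin_counts(bins, genic, blocks, n_bins):
    """Per-block per-bin genic and total count matrices (g x n_bins)."""
    uniq, inv = np.unique(blocks, return_inverse=True)
    g = len(uniq)
    flat = inv * (n_bins + 1) + bins
    total = np.bincount(flat, minlength=g * (n_bins + 1)).reshape(g, n_bins + 1)[:, 1:]
    gen = np.bincount(flat, weights=np.asarray(genic, float),
                      minlength=g * (n_bins + 1)).reshape(g, n_bins + 1)[:, 1:]
    return uniq, gen.astype(float), total.astype(float)


def enrichment_with_ci(snps: SnpTable, bins, alpha: float = 0.05,
                       n_bins: int = N_BINS) -> EnrichmentSpectrum:
    """Enrichment spectrum with per-bin weighted block-jackknife CIs.

    Leave-one-out spectra are computed from per-block count matrices, so the
    cost is O(blocks x bins) rather than a full recomputation per block.
    """
    genic = snps.df["genic"].to_numpy(bool)
    blocks = snps.df["block"].to_numpy()
    spec = genic_enrichment(bins, genic, n_bins=n_bins)
    uniq, gmat, tmat = _block_bin_counts(np.asarray(bins), genic, blocks, n_bins)
    if len(uniq) < 2:
        raise ValueError("need at least 2 non-empty blocks")
    G, T = gmat.sum(axis=0), tmat.sum(axis=0)   # per-bin totals
    g_all, t_all = G.sum(), T.sum()
    m = tmat.sum(axis=1)                        # SNPs per block

    # leave-one-out enrichment per block (rows) and bin (cols)
    with np.errstate(invalid="ignore", divide="ignore"):
        loo = ((G - gmat) / (T - tmat)) / (
            ((g_all - gmat.sum(axis=1)) / (t_all - m))[:, None]
        )
    lo = np.full(n_bins, np.nan)
    hi = np.full(n_bins, np.nan)
    for b in range(n_bins):
        if T[b] == 0 or np.isnan(spec.enrichment[b]):
            continue
        jk = weighted_jackknife(spec.enrichment[b], loo[:, b], m, alpha=alpha)
        lo[b], hi[b] = jk.ci_low, jk.ci_high
    spec.ci_low, spec.ci_high = lo, hi
    return spec


@dataclass
class TailAsymmetry:
    """log2 ratio of the two tail-bin genic enrichments with jackknife CI."""

    pop1: str
    pop2: str
    log2_ratio: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    enrichment_high: float   # bin-10 (δ > 0.79) enrichment: pop1-specific tail
    enrichment_low: float    # bin-1 (δ ≤ −0.8) enrichment: pop2-specific tail
    pseudovalues: np.ndarray  # leave-one-out log2 ratios, for outlier tests


def _tail_log2_ratio_jackknife(bins, genic, blocks, alpha,
                               hi_bin=10, lo_bin=1, n_bins=N_BINS):
    bins = np.asarray(bins)
    genic = np.asarray(genic, bool)
    spec = genic_enrichment(bins, genic, n_bins=n_bins)
    e_hi, e_lo = spec.enrichment[hi_bin - 1], spec.enrichment[lo_bin - 1]
    if not (e_hi > 0) or not (e_lo > 0):
        raise ValueError(
            f"tail enrichment is zero/undefined (bin{hi_bin}={e_hi}, bin{lo_bin}={e_lo}); "
            "log2 ratio undefined"
        )
    L = np.log2(e_hi / e_lo)
    uniq, gmat, tmat = _block_bin_counts(bins, genic, blocks, n_bins)
    G, T = gmat.sum(axis=0), tmat.sum(axis=0)
    g_all, t_all = G.sum(), T.sum()
    m = tmat.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        glob = (g_all - gmat.sum(axis=1)) / (t_all - m)
        e_hi_loo = ((G[hi_bin - 1] - gmat[:, hi_bin - 1]) / (T[hi_bin - 1] - tmat[:, hi_bin - 1])) / glob
        e_lo_loo = ((G[lo_bin - 1] - gmat[:, lo_bin - 1]) / (T[lo_bin - 1] - tmat[:, lo_bin - 1])) / glob
        L_loo = np.log2(e_hi_loo / e_lo_loo)
    L_loo[~np.isfinite(L_loo)] = np.nan
    jk = weighted_jackknife(L, L_loo, m, alpha=alpha)
    return L, spec, jk


def tail_asymmetry(snps: SnpTable, pop1: str, pop2: str,
                   alpha: float = 0.05) -> TailAsymmetry:
    """Test whether the two δ tail genic enrichments are asymmetric.

    L = log2(enrichment_bin10 / enrichment_bin1); SE and CI from the
    weighted 200 kb block jackknife; two-sided normal z-test for L = 0.
    Swapping the populations flips the sign of L.
    """
    d = delta(snps, pop1, pop2)
    bins = bin_delta(d.values)
    genic = snps.df["genic"].to_numpy(bool)
    blocks = snps.df["block"].to_numpy()
    L, spec, jk = _tail_log2_ratio_jackknife(bins, genic, blocks, alpha)
    return TailAsymmetry(
        pop1=pop1, pop2=pop2, log2_ratio=L, se=jk.se,
        ci_low=jk.ci_low, ci_high=jk.ci_high, p_value=jk.p_value,
        enrichment_high=spec.enrichment[9], enrichment_low=spec.enrichment[0],
        pseudovalues=jk.loo_estimates,
    )


def tail_asymmetry_all_pairs(snps: SnpTable, alpha: float = 0.05) -> pd.DataFrame:
    """Tail asymmetry for every unordered population pair, Bonferroni-corrected
    across exactly those pairs (6 for four populations)."""
    pairs = list(itertools.combinations(snps.populations, 2))
    rows = []
    for p1, p2 in pairs:
        t = tail_asymmetry(snps, p1, p2, alpha=alpha)
        rows.append((p1, p2, t.log2_ratio, t.ci_low, t.ci_high, t.p_value))
    df = pd.DataFrame(rows, columns=["pop1", "pop2", "log2_ratio", "lo95", "hi95", "p"])
    df["p_bonferroni"] = np.minimum(df["p"] * len(pairs), 1.0)
    return df


def ks_outlier_test(a, b) -> float:
    """Two-sided Kolmogorov-Smirnov p comparing two pseudovalue distributions."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both pseudovalue sets must be non-empty")
    if min(len(a), len(b)) < 2:
        warnings.warn("KS test with n=1 sample; exact small-sample p-value")
    return float(stats.ks_2samp(a, b, method="auto").pvalue)
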