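"""Demographic models, background-selection scaling and coalescent simulation.

Background selection (BGS) is modelled through its B value: the fractional
reduction in effective population size at a neutral site caused by linked
purifying selection. Applying a B multiplies every epoch size of a
population, so expected neutral diversity scales linearly with B.

Demographic models follow the ms/msms convention (sizes relative to a
reference N0, times in units of 4*N0 generations on the command line) but
are stored in natural units (diploids, generations). ``parse_msms`` loads a
verbatim msms command line into a :class:`DemographicModel`; the simulation
engine is msprime.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

import msprime


@dataclass(frozen=True)
class SizeChange:
    time: float      # generations before present
    population: str
    size: float      # diploids

@dataclass(frozen=True)
class MigrationChange:
    time: float
    source: str      # lineage movement source (backwards in time)
    dest: str
    rate: float      # per-generation lineage migration rate

@dataclass(frozen=True)
class MassMigration:
    time: float
    source: str
    dest: str
    proportion: float = 1.0


@dataclass
class DemographicModel:
    """Populations, epochs, splits and migration, in natural units."""

    populations: tuple[str, ...]
    initial_sizes: dict[str, float]              # diploids at time 0
    sample_sizes: dict[str, int]                 # haploids sampled per population
    events: list = field(default_factory=list)   # SizeChange / MigrationChange / MassMigration
    migration: dict[tuple[str, str], float] = field(default_factory=dict)  # (src, dest) at t=0
    mutation_rate: float = 1.2e-8                # per site per generation
    recombination_rate: float = 0.0              # per site per generation

    def __post_init__(self):
        for p, s in self.initial_sizes.items():
            if s <= 0:
                raise ValueError(f"population {p} has non-positive size")
        times = [e.time for e in self.events]
        if any(t < 0 for t in times):
            raise ValueError("event times must be >= 0")
        self.events = sorted(self.events, key=lambda e: e.time)

    def copy(self) -> "DemographicModel":
        return DemographicModel(
            populations=self.populations,
            initial_sizes=dict(self.initial_sizes),
            sample_sizes=dict(self.sample_sizes),
            events=list(self.events),
            migration=dict(self.migration),
            mutation_rate=self.mutation_rate,
            recombination_rate=self.recombination_rate,
        )

    def to_demography(self) -> msprime.Demography:
        dem = msprime.Demography()
        for p in self.populations:
            dem.add_population(name=p, initial_size=self.initial_sizes[p])
        for (src, dst), rate in self.migration.items():
            if rate > 0:
                dem.set_migration_rate(source=src, dest=dst, rate=rate)
        for ev in self.events:
            if isinstance(ev, SizeChange):
                dem.add_population_parameters_change(
                    time=ev.time, population=ev.population, initial_size=ev.size)
            elif isinstance(ev, MigrationChange):
                dem.add_migration_rate_change(
                    time=ev.time, source=ev.source, dest=ev.dest, rate=ev.rate)
            elif isinstance(ev, MassMigration):
                dem.add_mass_migration(
                    time=ev.time, source=ev.source, dest=ev.dest, proportion=ev.proportion)
            else:
                raise TypeError(f"unknown event type {type(ev)}")
        dem.sort_events()
        return dem


def parse_msms(command: str, mutation_rate: float = 1.2e-8,
               population_names=None) -> tuple[DemographicModel, float, int]:
    """Parse an ms/msms command line into a :class:`DemographicModel`.

    Handles -t, -r, -I, -n, -m, -en, -em, -ej. The reference size N0 is
    recovered from theta = 4*N0*mu*L, times are converted from 4*N0 units to
    generations, sizes from N0 units to diploids, and migration entries
    M_ij from 4*N0*m units to per-generation rates.

    Returns (model, N0, locus_length).
    """
    tok = command.split()
    if tok[0].startswith("msms") or tok[0].startswith("ms"):
        tok = tok[1:]
    theta = None
    length = None
    rec_rho = 0.0
    npop = 1
    samples = []
    sizes = {}
    mig0 = {}
    raw_events = []  # (time_4N0, kind, args)

    i = 0
    # first two positional arguments: total samples, replicates
    positional = []
    while i < len(tok) and not tok[i].startswith("-"):
        positional.append(tok[i]); i += 1
    while i < len(tok):
        flag = tok[i]
        if flag == "-t":
            theta = float(tok[i + 1]); i += 2
        elif flag == "-r":
            rec_rho = float(tok[i + 1]); length = int(float(tok[i + 2])); i += 3
        elif flag == "-I":
            npop = int(tok[i + 1])
            samples = [int(tok[i + 2 + k]) for k in range(npop)]
            i += 2 + npop
            # optional symmetric migration parameter
            if i < len(tok) and not tok[i].startswith("-"):
                sym = float(tok[i]); i += 1
                if sym > 0:
                    for a in range(npop):
                        for b in range(npop):
                            if a != b:
                                mig0[(a, b)] = sym / (npop - 1)
        elif flag == "-n":
            sizes[int(tok[i + 1]) - 1] = float(tok[i + 2]); i += 3
        elif flag == "-m":
            mig0[(int(tok[i + 1]) - 1, int(tok[i + 2]) - 1)] = float(tok[i + 3]); i += 4
        elif flag == "-en":
            raw_events.append((float(tok[i + 1]), "en",
                               (int(tok[i + 2]) - 1, float(tok[i + 3])))); i += 4
        elif flag == "-em":
            raw_events.append((float(tok[i + 1]), "em",
                               (int(tok[i + 2]) - 1, int(tok[i + 3]) - 1, float(tok[i + 4])))); i += 5
        elif flag == "-ej":
            raw_events.append((float(tok[i + 1]), "ej",
                               (int(tok[i + 2]) - 1, int(tok[i + 3]) - 1))); i += 4
        else:
            # skip unknown flag and its (assumed single) argument
            i += 1
            while i < len(tok) and not tok[i].startswith("-"):
                i += 1
    if theta is None or length is None:
        raise ValueError("command must carry -t and -r to recover N0 and locus length")
    n0 = theta / (4 * mutation_rate * length)
    names = tuple(population_names) if population_names else tuple(
        f"pop{k + 1}" for k in range(npop))
    four_n0 = 4 * n0

    model = DemographicModel(
        populations=names,
        initial_sizes={names[k]: sizes.get(k, 1.0) * n0 for k in range(npop)},
        sample_sizes={names[k]: (samples[k] if samples else 0) for k in range(npop)},
        migration={(names[a], names[b]): M / four_n0 for (a, b), M in mig0.items() if M > 0},
        mutation_rate=mutation_rate,
        recombination_rate=rec_rho / (four_n0 * max(length - 1, 1)),
    )
    for t, kind, args in raw_events:
        time = t * four_n0
        if kind == "en":
            model.events.append(SizeChange(time, names[args[0]], args[1] * n0))
        elif kind == "em":
            model.events.append(MigrationChange(time, names[args[0]], names[args[1]],
                                                args[2] / four_n0))
        elif kind == "ej":
            model.events.append(MassMigration(time, names[args[0]], names[args[1]]))
    model.events.sort(key=lambda e: e.time)
    return model, n0, length


def rescale_population(model: DemographicModel, population: str,
                       numerator: float, denominator: float) -> DemographicModel:
    """Multiply every epoch size of one population by numerator/denominator."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if population not in model.populations:
        raise KeyError(f"unknown population {population!r}")
    ratio = numerator / denominator
    out = model.copy()
    out.initial_sizes[population] *= ratio
    out.events = [
        replace(e, size=e.size * ratio)
        if isinstance(e, SizeChange) and e.population == population else e
        for e in out.events
    ]
    return out


def adjust_split_time(fst_obs: float, fst_model: float, base_time: float,
                      correction: float = -0.008) -> float:
    """Rescale a split time by the observed:model F_ST ratio.

    t = (fst_obs + correction) / fst_model * base_time. The correction
    absorbs the average model-vs-observed F_ST offset of the calibrating
    population pairs.
    """
    if fst_model <= 0:
        raise ValueError("model F_ST must be > 0")
    t = (fst_obs + correction) / fst_model * base_time
    if t <= 0:
        raise ValueError("adjusted split time is non-positive")
    return t


# ---------------------------------------------------------------------------
# B values


@dataclass
class BDistribution:
    """Empirical distribution of B values for one class of sites (genic or
    non-genic), with values constrained to (0, 1]."""

    label: str
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if np.any((v <= 0) | (v > 1)):
            raise ValueError("B values must lie in (0, 1]")
        self.values = v

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @classmethod
    def from_file(cls, path, label: str) -> "BDistribution":
        return cls(label, np.loadtxt(path, ndmin=1))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(self.values, size=n, replace=True)


def shift_b(dist: BDistribution, constant: float) -> BDistribution:
    """Add a fixed constant to all B values, capped at 1."""
    return BDistribution(dist.label, np.minimum(dist.values + constant, 1.0))


def effective_genic_b(genic_mean: float, nongenic_mean: float) -> float:
    """Ratio of mean genic to mean non-genic B: the diversity reduction of
    genic relative to non-genic regions (e.g. 0.75 / 0.85 ~ 0.88)."""
    return genic_mean / nongenic_mean


def apply_b(model: DemographicModel, b) -> DemographicModel:
    """Scale every epoch size by a B value (uniform float, or per-population
    dict). B must lie in (0, 1]."""
    if not isinstance(b, dict):
        b = {p: float(b) for p in model.populations}
    for p, v in b.items():
        if not (0 < v <= 1):
            raise ValueError(f"B for {p} must be in (0, 1], got {v}")
    out = model.copy()
    for p, v in b.items():
        if p not in model.populations:
            raise KeyError(f"unknown population {p!r}")
        out.initial_sizes[p] *= v
        out.events = [
            replace(e, size=e.size * v)
            if isinstance(e, SizeChange) and e.population == p else e
            for e in out.events
        ]
    return out


# ---------------------------------------------------------------------------
# locus simulation


@dataclass
class SimulatedLocusSet:
    """Independent simulated loci with per-SNP per-population derived counts.

    ``snps`` has one row per segregating site: locus id, genic flag, B used,
    and ``der_<pop>``/``called_<pop>`` columns. Loci are independent given
    the seed, so each locus is its own jackknife block.
    """

    populations: tuple[str, ...]
    snps: pd.DataFrame
    n_loci: int
    locus_length: int

    def to_snp_table(self, loci_per_block: int = 1):
        """View as a SnpTable on a synthetic coordinate system (one locus
        after another on chromosome "sim"), for the enrichment machinery."""
        from diffsel.variant_io import SnpTable
        df = self.snps.copy()
        df["chrom"] = "sim"
        df["pos"] = df["locus"] * self.locus_length + df["offset"] + 1
        df["anc"] = "A"
        df["der"] = "G"
        df["block"] = df["locus"] // loci_per_block
        df["rate"] = np.nan
        df = df.sort_values("pos", kind="stable")
        cols = ["chrom", "pos", "anc", "der"] + [
            c for c in df.columns if c.startswith(("der_", "called_"))
        ] + ["genic", "block", "rate"]
        return SnpTable(df[cols], self.populations, validate=False)


def _sample_b(rng, n, spec):
    """B values for n loci from a class spec: float, BDistribution, or None (B=1)."""
    if spec is None:
        return np.ones(n)
    if isinstance(spec, BDistribution):
        return spec.sample(n, rng)
    return np.full(n, float(spec))


def simulate_loci(model: DemographicModel, n_loci: int, locus_length: int = 2000,
                  genic_b=None, nongenic_b=None, genic_fraction: float = 0.5,
                  seed: int = 1, b_grid_step: float = 0.005,
                  b_per_population: dict | None = None) -> SimulatedLocusSet:
    """Simulate independent neutral loci under the model, with per-locus B.

    Each locus is genic with probability ``genic_fraction``; its B is drawn
    from ``genic_b`` / ``nongenic_b`` (a float, a BDistribution, or None for
    B = 1) and applied by scaling every population size. B values are
    rounded to ``b_grid_step`` so loci can be simulated in batches.

    ``b_per_population`` (dict pop -> B) overrides the genic-locus B with a
    heterogeneous-across-populations scaling (the unequal-BGS scenario);
    non-genic loci then use ``nongenic_b`` as usual.
    """
    if n_loci == 0:
        cols = ["locus", "offset", "genic", "b"]
        for p in model.populations:
            cols += [f"der_{p}", f"called_{p}"]
        return SimulatedLocusSet(model.populations, pd.DataFrame(columns=cols),
                                 0, locus_length)
    rng = np.random.default_rng(seed)
    genic = rng.random(n_loci) < genic_fraction
    b = np.ones(n_loci)
    b[genic] = _sample_b(rng, int(genic.sum()), genic_b)
    b[~genic] = _sample_b(rng, int((~genic).sum()), nongenic_b)
    b = np.clip(np.round(b / b_grid_step) * b_grid_step, b_grid_step, 1.0)

    sample_sets = {p: model.sample_sizes[p] // 2 for p in model.populations
                   if model.sample_sizes.get(p, 0) > 0}
    called = {p: 2 * sample_sets[p] for p in sample_sets}

    records = []
    group_keys = sorted(set(zip(genic, b)))
    for is_genic, b_val in group_keys:
        idx = np.flatnonzero(genic == is_genic)
        idx = idx[np.isclose(b[idx], b_val)]
        if is_genic and b_per_population is not None:
            scaled = apply_b(model, b_per_population)
        else:
            scaled = apply_b(model, b_val)
        dem = scaled.to_demography()
        anc_seed = int(rng.integers(1, 2**31 - 1))
        mut_rng = np.random.default_rng(rng.integers(1, 2**31 - 1))
        reps = msprime.sim_ancestry(
            samples=sample_sets, demography=dem,
            sequence_length=locus_length,
            recombination_rate=model.recombination_rate,
            num_replicates=len(idx), random_seed=anc_seed,
        )
        for locus_id, ts in zip(idx, reps):
            mts = msprime.sim_mutations(
                ts, rate=model.mutation_rate, discrete_genome=False,
                random_seed=int(mut_rng.integers(1, 2**31 - 1)),
            )
            if mts.num_sites == 0:
                continue
            derived = mts.genotype_matrix() != 0   # (sites, sample nodes)
            block = {
                "locus": np.full(mts.num_sites, locus_id, dtype=int),
                "offset": np.array(mts.tables.sites.position),  # copy: avoid holding the tables alive
                "genic": np.full(mts.num_sites, is_genic, dtype=bool),
                "b": np.full(mts.num_sites, b_val),
            }
            for k, p in enumerate(model.populations):
                if p not in sample_sets:
                    continue
                nodes = mts.samples(population=k)
                block[f"der_{p}"] = derived[:, nodes].sum(axis=1)
                block[f"called_{p}"] = np.full(mts.num_sites, called[p], dtype=int)
            records.append(block)
    pops = tuple(p for p in model.populations if p in sample_sets)
    if records:
        df = pd.DataFrame({k: np.concatenate([r[k] for r in records])
                           for k in records[0]})
    else:
        cols = ["locus", "offset", "genic", "b"]
        for p in pops:
            cols += [f"der_{p}", f"called_{p}"]
        df = pd.DataFrame(columns=cols)
    return SimulatedLocusSet(pops, df, n_loci, locus_length)


def model_fst_check(sim: SimulatedLocusSet) -> pd.DataFrame:
    """Ratio-of-averages Hudson F_ST per population pair across all SNPs."""
    from diffsel.pbsnj import hudson_fst_components
    pops = sim.populations
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    rows = []
    for p1, p2 in itertools.combinations(pops, 2):
        num, den = hudson_fst_components(
            sim.snps[f"der_{p1}"], sim.snps[f"called_{p1}"],
            sim.snps[f"der_{p2}"], sim.snps[f"called_{p2}"],
        )
        ok = den > 0
        rows.append((p1, p2, float(num[ok].sum() / den[ok].sum())))
    return pd.DataFrame(rows, columns=["pop1", "pop2", "fst"])


def sfs(derived_counts, n_haploids: int) -> np.ndarray:
    """Site frequency spectrum: proportions over derived counts 1..n-1."""
    d = np.asarray(derived_counts, int)
    d = d[(d > 0) & (d < n_haploids)]
    if len(d) == 0:
        raise ValueError("no segregating sites in the requested range")
    counts = np.bincount(d, minlength=n_haploids)[1:n_haploids]
    return counts / counts.sum()


def fit_b(observed: dict, library: dict, bins: str = "all",
          tail_bins=(1, 10)) -> tuple[float, pd.DataFrame]:
    """Best-fitting B by sum of squared enrichment differences.

    ``observed`` maps pair -> per-bin enrichment array; ``library`` maps
    B -> {pair -> per-bin enrichment array} with the same binning. SSD is
    summed over population pairs and the chosen bin subset (``all``,
    ``no-tails`` or ``tails``); bins missing (NaN) in either spectrum are
    skipped symmetrically. Returns (argmin B, SSD table).
    """
    if len(library) == 0:
        raise ValueError("empty simulation library")
    if len(library) == 1:
        warnings.warn("library holds a single B value; returning it")
    rows = []
    for b_val, spectra in sorted(library.items()):
        ssd = 0.0
        n_used = 0
        for pair, e_obs in observed.items():
            e_obs = np.asarray(e_obs, float)
            e_sim = np.asarray(spectra[pair], float)
            nb = len(e_obs)
            idx = np.arange(1, nb + 1)
            if bins == "all":
                sel = np.ones(nb, bool)
            elif bins == "no-tails":
                sel = ~np.isin(idx, tail_bins)
            elif bins == "tails":
                sel = np.isin(idx, tail_bins)
            else:
                raise ValueError(f"unknown bin subset {bins!r}")
            sel &= ~np.isnan(e_obs) & ~np.isnan(e_sim)
            if not sel.any():
                continue
            ssd += float(np.sum((e_obs[sel] - e_sim[sel]) ** 2))
            n_used += int(sel.sum())
        if n_used == 0:
            raise ValueError("empty bin subset after NaN masking")
        rows.append((b_val, ssd, n_used))
    table = pd.DataFrame(rows, columns=["b", "ssd", "n_bins"])
    best = float(table.loc[table["ssd"].idxmin(), "b"])
    return best, table
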