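"""Demographic models, B scaling, coalescent simulation, SSD fitting."""

import numpy as np
import pandas as pd
import pytest

from diffsel.bgs_sim import (
    BDistribution, DemographicModel, MassMigration, MigrationChange, SizeChange,
    adjust_split_time, apply_b, effective_genic_b, fit_b, model_fst_check,
    parse_msms, rescale_population, sfs, shift_b, simulate_loci,
)

MSMS_PATH = "src/diffsel/data/chimp_demography.msms"


def single_pop(mu=1.2e-8):
    return DemographicModel(
        populations=("p1",), initial_sizes={"p1": 10_000},
        sample_sizes={"p1": 20}, mutation_rate=mu)


def two_pop(t_split, mig=0.0, mu=1.2e-8):
    m = DemographicModel(
        populations=("A", "B"), initial_sizes={"A": 10_000, "B": 10_000},
        sample_sizes={"A": 20, "B": 20},
        events=[MassMigration(time=t_split, source="B", dest="A")],
        mutation_rate=mu)
    if mig:
        m.migration = {("A", "B"): mig, ("B", "A"): mig}
    return m


class TestModelEdits:
    def test_rescale_population_printed_ratios(self):
        m = single_pop()
        out = rescale_population(m, "p1", 3.66914400056, 4.3158739382)
        assert out.initial_sizes["p1"] == pytest.approx(8501.5, abs=0.1)
        out2 = rescale_population(m, "p1", 0.3092, 0.30865)
        assert out2.initial_sizes["p1"] == pytest.approx(10017.8, abs=0.1)
        assert rescale_population(m, "p1", 2.0, 2.0).initial_sizes["p1"] == 10_000

    def test_rescale_covers_epoch_events(self):
        m = single_pop()
        m.events.append(SizeChange(1000.0, "p1", 5000.0))
        out = rescale_population(m, "p1", 1.0, 2.0)
        assert out.events[0].size == 2500.0
        with pytest.raises(KeyError):
            rescale_population(m, "ghost", 1, 1)

    @pytest.mark.parametrize("obs,model,base,corr,expected", [
        (0.258, 0.250, 250.0, -0.008, 250.0),     # identity when obs+corr = model
        (0.300, 0.250, 250.0, -0.008, 292.0),
        (0.500, 0.250, 300.0, 0.0, 600.0),
    ])
    def test_adjust_split_time(self, obs, model, base, corr, expected):
        assert adjust_split_time(obs, model, base, corr) == pytest.approx(expected)

    def test_adjust_split_time_validation(self):
        with pytest.raises(ValueError):
            adjust_split_time(0.3, 0.0, 250)
        with pytest.raises(ValueError):
            adjust_split_time(0.001, 0.25, 250, correction=-0.008)


class TestBValues:
    def test_shift_caps_at_one(self):
        d = shift_b(BDistribution("genic", np.array([0.7, 0.95])), 0.1)
        np.testing.assert_allclose(d.values, [0.8, 1.0])
        unchanged = shift_b(BDistribution("genic", np.array([0.4, 0.6])), 0.0)
        np.testing.assert_allclose(unchanged.values, [0.4, 0.6])

    def test_effective_genic_b(self):
        # mean genic B 0.75 over mean non-genic 0.85: an effective genic B ~0.88
        assert round(effective_genic_b(0.75, 0.85), 2) == 0.88

    def test_apply_b_rules(self):
        m = two_pop(4000)
        m.events.append(SizeChange(2000.0, "A", 8000.0))
        ident = apply_b(m, 1.0)
        assert ident.initial_sizes == m.initial_sizes
        vec = apply_b(m, {"A": 0.825, "B": 0.9})
        assert vec.initial_sizes["A"] == pytest.approx(8250)
        assert vec.initial_sizes["B"] == pytest.approx(9000)
        sc = [e for e in vec.events if isinstance(e, SizeChange)][0]
        assert sc.size == pytest.approx(8000 * 0.825)
        with pytest.raises(ValueError):
            apply_b(m, 0.0)
        with pytest.raises(ValueError):
            apply_b(m, 1.1)

    def test_bdistribution_validation(self):
        with pytest.raises(ValueError):
            BDistribution("x", np.array([0.0, 0.5]))


class TestParseMsms:
    def test_reference_command(self):
        cmd = open(MSMS_PATH).read().strip()
        model, n0, L = parse_msms(cmd)
        assert n0 == pytest.approx(10_000.0)    # theta = 4*N0*mu*L with the printed -t
        assert L == 2001
        assert model.sample_sizes == {"pop1": 0, "pop2": 38, "pop3": 36,
                                      "pop4": 20, "pop5": 22}
        assert model.initial_sizes["pop2"] == pytest.approx(3181.0)
        assert model.initial_sizes["pop3"] == pytest.approx(3092.0)
        # migration entries are M/(4 N0)
        assert model.migration[("pop2", "pop3")] == pytest.approx(
            1.8181960943074 / 40_000)
        joins = [e for e in model.events if isinstance(e, MassMigration)]
        assert len(joins) == 4
        # the first join (eastern into central) at 0.106325 * 4 N0 generations
        assert joins[0].time == pytest.approx(0.106325 * 40_000)
        assert (joins[0].source, joins[0].dest) == ("pop2", "pop3")
        # size-change events carry sizes in diploids
        en = [e for e in model.events if isinstance(e, SizeChange)]
        assert any(e.size == pytest.approx(1.83290809268 * 10_000) for e in en)

    def test_event_times_sorted(self):
        cmd = open(MSMS_PATH).read().strip()
        model, _, _ = parse_msms(cmd)
        times = [e.time for e in model.events]
        assert times == sorted(times)


class TestSimulateLoci:
    def test_zero_loci(self):
        out = simulate_loci(single_pop(), 0, seed=1)
        assert len(out.snps) == 0

    def test_seeded_determinism(self):
        a = simulate_loci(single_pop(), 50, seed=9)
        b = simulate_loci(single_pop(), 50, seed=9)
        pd.testing.assert_frame_equal(a.snps, b.snps)
        c = simulate_loci(single_pop(), 50, seed=10)
        assert not a.snps.equals(c.snps)

    def test_watterson_expectation_small(self):
        # theta = 4*N*mu*L = 0.96 per locus; E[S] = theta * a_{n-1}
        sim = simulate_loci(single_pop(), 2000, locus_length=2000, seed=5)
        S = sim.snps.groupby("locus").size().reindex(range(2000), fill_value=0)
        a19 = sum(1 / i for i in range(1, 20))
        exp = 0.96 * a19
        se = S.std() / np.sqrt(len(S))
        assert abs(S.mean() - exp) < 4 * se

    def test_heterogeneous_b_scales_only_genic_loci(self):
        m = single_pop()
        sim = simulate_loci(m, 1500, genic_b=0.5, nongenic_b=None,
                            genic_fraction=0.5, seed=3)
        S = sim.snps.groupby(["locus", "genic"]).size().reset_index(name="s")
        genic_mean = S[S["genic"]]["s"].sum() / sim.snps.groupby("locus")["genic"].first().sum()
        # genic loci should segregate roughly half as much as non-genic
        nongenic_loci = (~sim.snps.groupby("locus")["genic"].first()).sum()
        nongenic_mean = S[~S["genic"]]["s"].sum() / nongenic_loci
        assert genic_mean / nongenic_mean == pytest.approx(0.5, abs=0.12)

    def test_locus_set_to_snp_table_roundtrip(self):
        sim = simulate_loci(two_pop(4000), 100, seed=2)
        table = sim.to_snp_table()
        assert len(table) == len(sim.snps)
        assert set(table.populations) == {"A", "B"}
        assert (np.diff(table.df["pos"]) > 0).all()


class TestModelFst:
    def test_panmictic_is_near_zero(self):
        m = two_pop(t_split=1.0)   # effectively one population
        sim = simulate_loci(m, 2000, seed=4)
        fst = model_fst_check(sim)["fst"][0]
        assert abs(fst) < 0.02

    def test_two_deme_island_closed_form(self):
        # symmetric 2-island model at migration M = 4*N*m. For Hudson's
        # F_ST = 1 - Tw/Tb the structured-coalescent expectation is
        # Tw = 4N, Tb = 4N + 1/(2m), hence F_ST = 1/(1 + 8Nm) = 1/(1 + 2M)
        # (Wright's island formula 1/(1 + M (d/(d-1))^2) refers instead to
        # the pooled-total variant and does not apply to this estimator)
        n0, M = 10_000, 1.0
        m = DemographicModel(
            populations=("A", "B"), initial_sizes={"A": n0, "B": n0},
            sample_sizes={"A": 20, "B": 20},
            migration={("A", "B"): M / (4 * n0), ("B", "A"): M / (4 * n0)},
            mutation_rate=6e-8)
        sim = simulate_loci(m, 3000, seed=8)
        fst = model_fst_check(sim)["fst"][0]
        assert fst == pytest.approx(1 / (1 + 2 * M), abs=0.03)

    def test_long_divergence_approaches_one(self):
        m = two_pop(t_split=400_000, mu=6e-8)
        sim = simulate_loci(m, 400, seed=6)
        assert model_fst_check(sim)["fst"][0] > 0.9


class TestSfs:
    def test_neutral_shape(self):
        sim = simulate_loci(single_pop(mu=6e-8), 3000, seed=12)
        spec = sfs(sim.snps["der_p1"], 20)
        expected = (1 / np.arange(1, 20))
        expected /= expected.sum()
        assert np.abs(spec - expected).max() < 0.02

    def test_indicator_and_empty(self):
        spec = sfs([3], 20)
        assert spec[2] == 1.0 and spec.sum() == 1.0
        with pytest.raises(ValueError):
            sfs([], 20)
        with pytest.raises(ValueError):
            sfs([0, 20], 20)   # only fixed classes


class TestFitB:
    def fake_spectra(self, offset):
        base = np.ones(10)
        base[0] += offset
        base[9] += offset
        return {"AB": base, "AC": base * 1.0}

    def test_argmin_and_invariance_to_order(self):
        obs = self.fake_spectra(0.21)
        lib = {0.85: self.fake_spectra(0.3), 0.90: self.fake_spectra(0.2),
               0.95: self.fake_spectra(0.1)}
        best, table = fit_b(obs, lib)
        assert best == 0.90
        lib_rev = dict(reversed(list(lib.items())))
        obs_rev = dict(reversed(list(obs.items())))
        best2, table2 = fit_b(obs_rev, lib_rev)
        assert best2 == best
        pd.testing.assert_frame_equal(
            table.sort_values("b").reset_index(drop=True),
            table2.sort_values("b").reset_index(drop=True))

    def test_tails_subset_uses_two_bins_per_pair(self):
        obs = self.fake_spectra(0.2)
        lib = {0.9: self.fake_spectra(0.2)}
        with pytest.warns(UserWarning):
            best, table = fit_b(obs, lib, bins="tails")
        assert best == 0.9
        assert table["n_bins"][0] == 4   # 2 tail bins x 2 pairs

    def test_nan_bins_skipped_symmetrically(self):
        obs = self.fake_spectra(0.2)
        obs["AB"][3] = np.nan
        lib = {0.9: self.fake_spectra(0.2), 0.95: self.fake_spectra(0.1)}
        best, table = fit_b(obs, lib)
        assert table["n_bins"].tolist() == [19, 19]

    def test_empty_library_errors(self):
        with pytest.raises(ValueError):
            fit_b({"AB": np.ones(10)}, {})
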