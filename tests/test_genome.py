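"""Founder-genome simulation and meiosis."""

import numpy as np
import pytest

from gsvcbias.config import GenomeConfig, HistoricalConfig
from gsvcbias.genome import (
    GeneticMap,
    HaplotypePopulation,
    assign_qtl_effects,
    drop_gamete,
    make_gametes,
    run_historical,
    select_loci,
)


def small_map(n_chr=1, length=100.0, n_markers=50, n_qtl=5) -> GeneticMap:
    return GeneticMap.uniform(n_chr, length, n_markers, n_qtl)


class TestHistorical:
    def test_no_mutation_monomorphic_start_stays_monomorphic(self):
        gen = GenomeConfig(n_chromosomes=1, markers_per_chrom=30, qtl_per_chrom=3)
        hist = HistoricalConfig(
            n_generations=1, pop_size=20, mutation_rate=0.0, initial_frequency=0.0
        )
        pop = run_historical(gen, hist, 1)
        assert not pop.haplo.any()

    def test_zero_population_rejected(self):
        gen = GenomeConfig(n_chromosomes=1, markers_per_chrom=10, qtl_per_chrom=1)
        with pytest.raises(ValueError):
            run_historical(gen, HistoricalConfig(n_generations=1, pop_size=0), 1)

    def test_seeded_runs_bit_reproducible(self):
        gen = GenomeConfig(n_chromosomes=1, markers_per_chrom=60, qtl_per_chrom=6)
        hist = HistoricalConfig(n_generations=20, pop_size=30)
        a = run_historical(gen, hist, 7)
        b = run_historical(gen, hist, 7)
        assert np.array_equal(a.haplo, b.haplo)

    def test_ld_decays_with_map_distance(self):
        # adjacent markers must carry more r^2 than markers > 50 cM apart
        gen = GenomeConfig(n_chromosomes=2, markers_per_chrom=300, qtl_per_chrom=30)
        hist = HistoricalConfig(n_generations=150, pop_size=80)
        pop = run_historical(gen, hist, 11)
        geno = pop.genotypes().astype(float)
        mi = pop.gmap.marker_idx
        keep = geno[:, mi].std(axis=0) > 0
        G = geno[:, mi[keep]]
        pos, chrom = pop.gmap.pos_cm[mi[keep]], pop.gmap.chrom[mi[keep]]
        r2 = np.corrcoef(G.T) ** 2
        adj, far = [], []
        for c in range(2):
            idx = np.flatnonzero(chrom == c)
            adj.extend(r2[idx[k], idx[k + 1]] for k in range(idx.size - 1))
            d = np.abs(pos[idx][:, None] - pos[idx][None, :])
            far.extend(r2[np.ix_(idx, idx)][d > 50].ravel())
        assert np.mean(adj) > np.mean(far)


@pytest.fixture(scope="module")
def pop():
    gen = GenomeConfig(n_chromosomes=2, markers_per_chrom=200, qtl_per_chrom=40)
    return run_historical(gen, HistoricalConfig(n_generations=60, pop_size=50), 3)


class TestPanelSelection:
    def test_request_all_segregating_is_identity(self, pop):
        seg = pop.segregating()
        nm = int((seg & ~pop.gmap.is_qtl).sum())
        nq = int((seg & pop.gmap.is_qtl).sum())
        sub = select_loci(pop, nm, nq, 5)
        assert sub.gmap.n_loci == nm + nq
        assert sub.segregating().all()

    def test_positions_preserved_and_sampling_seeded(self, pop):
        a = select_loci(pop, 50, 10, 9)
        b = select_loci(pop, 50, 10, 9)
        assert np.array_equal(a.gmap.pos_cm, b.gmap.pos_cm)
        assert np.array_equal(a.haplo, b.haplo)
        assert set(a.gmap.pos_cm).issubset(set(pop.gmap.pos_cm))

    def test_deficit_error_names_the_shortfall(self, pop):
        with pytest.raises(ValueError, match="markers"):
            select_loci(pop, 10**6, 1, 1)


class TestQtlEffects:
    def _founders(self, n=500, n_qtl=40, seed=0):
        gmap = small_map(n_markers=10, n_qtl=n_qtl)
        rng = np.random.default_rng(seed)
        haplo = (rng.random((n, 2, gmap.n_loci)) < 0.5).astype(np.uint8)
        return HaplotypePopulation(haplo=haplo, gmap=gmap)

    def test_variance_scaled_exactly_to_target(self):
        pop = self._founders()
        eff = assign_qtl_effects(pop, 3.59, 1)
        assert eff.breeding_values(pop).var(ddof=1) == pytest.approx(3.59, abs=1e-9)

    def test_zero_target_gives_zero_effects(self):
        pop = self._founders()
        eff = assign_qtl_effects(pop, 0.0, 1)
        assert not eff.effects.any()

    def test_monomorphic_qtl_rejected(self):
        pop = self._founders()
        pop.haplo[:, :, pop.gmap.qtl_idx] = 0
        with pytest.raises(ValueError, match="monomorphic"):
            assign_qtl_effects(pop, 1.0, 1)

    def test_single_qtl_matches_hwe_closed_form(self):
        # 2 p (1-p) a^2 at p = 0.5 for one segregating QTL
        gmap = small_map(n_markers=5, n_qtl=1)
        rng = np.random.default_rng(4)
        haplo = (rng.random((4000, 2, gmap.n_loci)) < 0.5).astype(np.uint8)
        pop = HaplotypePopulation(haplo=haplo, gmap=gmap)
        eff = assign_qtl_effects(pop, 2.0, 2)
        a = eff.effects[0]
        p = pop.allele_frequencies()[gmap.qtl_idx[0]]
        assert 2 * p * (1 - p) * a**2 == pytest.approx(2.0, rel=0.05)


class TestMeiosis:
    def test_homozygous_parent_transmits_exactly(self):
        gmap = small_map()
        parent = np.ones((2, gmap.n_loci), np.uint8)
        gam = drop_gamete(parent, gmap, 3)
        assert np.array_equal(gam, parent[0])

    def test_zero_length_chromosome_transmits_whole_haplotypes(self):
        gmap = GeneticMap.uniform(1, 0.0, 20, 2)
        parent = np.zeros((2, 22), np.uint8)
        parent[1] = 1
        for seed in range(20):
            gam = drop_gamete(parent, gmap, seed)
            assert gam.min() == gam.max()  # no recombinant mosaic

    def test_crossover_count_is_poisson_with_map_length_mean(self):
        # distinguishable haplotypes make crossovers directly observable
        gmap = small_map(length=100.0, n_markers=400, n_qtl=0)
        parent = np.zeros((1, 2, gmap.n_loci), np.uint8)
        parent[0, 1] = 1
        n = 100_000
        gam = make_gametes(parent, np.zeros(n, np.int64), gmap, 17)
        switches = (np.diff(gam.astype(np.int8), axis=1) != 0).sum(axis=1)
        se = np.sqrt(1.0 / n)  # Poisson(1) variance 1
        assert abs(switches.mean() - 1.0) < 3 * se + 0.02  # small loss to double-crossovers

    def test_recombination_fraction_matches_haldane(self):
        gmap = small_map(length=100.0, n_markers=100, n_qtl=0)
        parent = np.zeros((1, 2, gmap.n_loci), np.uint8)
        parent[0, 1] = 1
        n = 10_000
        gam = make_gametes(parent, np.zeros(n, np.int64), gmap, 23)
        pos = gmap.pos_cm
        for j in (3, 20, 60, 99):
            d = (pos[j] - pos[0]) / 100.0
            expect = 0.5 * (1 - np.exp(-2 * d))
            obs = np.mean(gam[:, 0] != gam[:, j])
            se = np.sqrt(expect * (1 - expect) / n)
            assert abs(obs - expect) < 3 * se

    def test_gamete_alleles_come_from_parent(self):
        gmap = small_map()
        rng = np.random.default_rng(8)
        parent = (rng.random((2, gmap.n_loci)) < 0.5).astype(np.uint8)
        gam = drop_gamete(parent, gmap, 5)
        assert np.all((gam == parent[0]) | (gam == parent[1]))

    def test_midparent_regression_of_offspring_tbv_is_unity(self):
        gmap = small_map(n_markers=50, n_qtl=30)
        rng = np.random.default_rng(10)
        haplo = (rng.random((400, 2, gmap.n_loci)) < 0.5).astype(np.uint8)
        pop = HaplotypePopulation(haplo=haplo, gmap=gmap)
        eff = assign_qtl_effects(pop, 3.0, 6)
        sires = rng.integers(0, 200, 2000)
        dams = rng.integers(200, 400, 2000)
        gs = make_gametes(pop.haplo, sires, gmap, 31)
        gd = make_gametes(pop.haplo, dams, gmap, 32)
        off = np.stack([gs, gd], axis=1)
        tbv_off = eff.breeding_values(off)
        tbv = eff.breeding_values(pop)
        mid = 0.5 * (tbv[sires] + tbv[dams])
        slope = np.polyfit(mid, tbv_off, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)
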