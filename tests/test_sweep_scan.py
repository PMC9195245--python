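import math

import numpy as np
import pytest

from oracles import (
    hudson_fst_per_site,
    pi_pairwise,
    random_window,
    tajimas_d_textbook,
)
from peachscan.sweep_scan import (
    GenotypeMatrix,
    GroupAssignment,
    SweepRegion,
    WindowStats,
    hudson_fst,
    merge_and_annotate,
    scan_windows,
    select_sweep_windows,
    site_allele_freq,
    tajima_constants,
    tajimas_d,
    window_pi,
)
from peachscan.variant_io import GeneModel, GenomeInterval


def make_matrix(dosages, positions=None, chrom="chr1"):
    dosages = np.asarray(dosages, dtype=np.int8)
    n_sites, n_samples = dosages.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1)
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n_samples)],
        chroms=np.array([chrom] * n_sites, dtype=object),
        positions=np.asarray(positions),
        dosages=dosages,
    )


class TestSiteAlleleFreq:
    def test_arithmetic(self):
        p, n = site_allele_freq(np.array([0, 1, 2]), np.arange(3))
        assert (p, n) == (0.5, 6)

    def test_all_missing_undefined(self):
        p, n = site_allele_freq(np.array([-1, -1]), np.arange(2))
        assert n == 0 and math.isnan(p)

    def test_matches_brute_force_allele_count(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            col = rng.integers(-1, 3, size=12).astype(np.int8)
            idx = rng.choice(12, size=6, replace=False)
            p, n = site_allele_freq(col, idx)
            sub = col[idx]
            alleles = []
            for d in sub:
                if d >= 0:
                    alleles += [1] * d + [0] * (2 - d)
            assert n == len(alleles)
            if n:
                assert p == pytest.approx(sum(alleles) / n)


class TestWindowPi:
    def test_no_segregating_sites_zero(self):
        m = make_matrix(np.ones((5, 4)) * 2)
        assert window_pi(m, m.samples, GenomeInterval("chr1", 1, 100)) == 0.0

    def test_single_site_closed_form(self):
        # p = 0.5, n = 20 -> 2 * 0.25 * 20/19 per site over 50 kb
        d = np.array([[1] * 10])
        m = make_matrix(d)
        pi = window_pi(m, m.samples, GenomeInterval("chr1", 1, 50_000))
        assert pi == pytest.approx((2 * 0.25 * 20 / 19) / 50_000, abs=1e-15)

    def test_matches_pairwise_difference_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            d = random_window(rng, n_samples=20, max_sites=100, missing_rate=0.1)
            m = make_matrix(d)
            window = GenomeInterval("chr1", 1, len(d))
            assert window_pi(m, m.samples, window) == pytest.approx(
                pi_pairwise(d, window.length), abs=1e-10
            )

    def test_invariant_under_sample_reordering_and_allele_relabeling(self):
        rng = np.random.default_rng(5)
        d = random_window(rng, n_samples=10, max_sites=60)
        m = make_matrix(d)
        w = GenomeInterval("chr1", 1, 100)
        base = window_pi(m, m.samples, w)
        perm = rng.permutation(10)
        m2 = make_matrix(d[:, perm])
        assert window_pi(m2, m2.samples, w) == pytest.approx(base, abs=1e-12)
        m3 = make_matrix(2 - d)  # swap ref/alt
        assert window_pi(m3, m3.samples, w) == pytest.approx(base, abs=1e-12)


class TestTajimasD:
    def test_constants_positive_and_textbook_n4(self):
        c = tajima_constants(4)
        assert c.a1 == pytest.approx(1 + 1 / 2 + 1 / 3)
        for fieldname in ("a1", "a2", "b1", "b2", "c1", "c2", "e1", "e2"):
            assert getattr(c, fieldname) > 0

    def test_matches_independent_implementation(self):
        rng = np.random.default_rng(6)
        for n_samples in (4, 10, 27):
            for _ in range(20):
                d = random_window(rng, n_samples=n_samples, max_sites=80)
                m = make_matrix(d)
                w = GenomeInterval("chr1", 1, len(d))
                ours = tajimas_d(m, m.samples, w)
                oracle = tajimas_d_textbook(d)
                if math.isnan(oracle):
                    assert math.isnan(ours)
                else:
                    assert ours == pytest.approx(oracle, abs=1e-10)

    def test_no_segregating_sites_undefined(self):
        m = make_matrix(np.zeros((5, 6)))
        assert math.isnan(tajimas_d(m, m.samples, GenomeInterval("chr1", 1, 10)))

    def test_excess_rare_variants_negative(self):
        # many singletons: pi small relative to S
        rng = np.random.default_rng(7)
        n_samples, n_sites = 20, 60
        d = np.zeros((n_sites, n_samples), dtype=np.int8)
        for i in range(n_sites):
            d[i, rng.integers(n_samples)] = 1  # one singleton per site
        m = make_matrix(d)
        assert tajimas_d(m, m.samples, GenomeInterval("chr1", 1, n_sites)) < 0


class TestHudsonFst:
    def test_fixed_difference_is_one(self):
        d = np.array([[2] * 5 + [0] * 5])
        m = make_matrix(d)
        fst = hudson_fst(m, m.samples[:5], m.samples[5:], GenomeInterval("chr1", 1, 10))
        assert fst == pytest.approx(1.0)

    def test_matches_per_site_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            d = random_window(rng, n_samples=15, max_sites=100, missing_rate=0.05)
            m = make_matrix(d)
            w = GenomeInterval("chr1", 1, len(d))
            ours = hudson_fst(m, m.samples[:5], m.samples[5:], w)
            oracle = hudson_fst_per_site(d[:, :5], d[:, 5:])
            if math.isnan(oracle):
                assert math.isnan(ours)
            else:
                assert ours == pytest.approx(oracle, abs=1e-10)

    def test_same_group_split_near_zero(self):
        rng = np.random.default_rng(9)
        p = rng.beta(2, 2, size=400)
        d = rng.binomial(2, p[:, None], size=(400, 60)).astype(np.int8)
        m = make_matrix(d)
        w = GenomeInterval("chr1", 1, 400)
        fst = hudson_fst(m, m.samples[:30], m.samples[30:], w)
        assert abs(fst) < 0.02


class TestScanWindows:
    @staticmethod
    def _groups(matrix, n_high):
        return GroupAssignment(
            {
                s: ("high" if i < n_high else "low")
                for i, s in enumerate(matrix.samples)
            }
        )

    def test_grid_definition(self):
        rng = np.random.default_rng(10)
        d = rng.integers(0, 3, size=(50, 8)).astype(np.int8)
        positions = np.sort(rng.choice(np.arange(1, 100_001), 50, replace=False))
        m = make_matrix(d, positions)
        stats = scan_windows(
            m, self._groups(m, 4), window_size=50_000, step=10_000,
            chrom_lengths={"chr1": 100_000},
        )
        starts = [w.interval.start for w in stats]
        assert starts == [1, 10_001, 20_001, 30_001, 40_001, 50_001]
        assert all(w.interval.length == 50_000 for w in stats)

    def test_equals_single_window_recomputation(self):
        rng = np.random.default_rng(11)
        d = rng.integers(0, 3, size=(300, 12)).astype(np.int8)
        positions = np.sort(rng.choice(np.arange(1, 60_001), 300, replace=False))
        m = make_matrix(d, positions)
        groups = self._groups(m, 5)
        high, low = groups.members("high"), groups.members("low")
        stats = scan_windows(m, groups, window_size=10_000, step=5_000)
        assert len(stats) > 5
        for w in stats:
            assert w.pi_high == pytest.approx(
                window_pi(m, high, w.interval), abs=1e-12
            )
            assert w.pi_low == pytest.approx(
                window_pi(m, low, w.interval), abs=1e-12
            )
            ours_d = tajimas_d(m, high, w.interval)
            if math.isnan(w.d_high):
                assert math.isnan(ours_d)
            else:
                assert w.d_high == pytest.approx(ours_d, abs=1e-12)
            f = hudson_fst(m, high, low, w.interval)
            if math.isnan(w.fst):
                assert math.isnan(f)
            else:
                assert w.fst == pytest.approx(f, abs=1e-12)

    def test_uniform_data_identical_full_windows(self):
        d = np.tile(np.array([0, 1, 2, 1, 0, 1], dtype=np.int8), (1000, 1))
        positions = np.arange(1, 100_000, 100)[:1000]
        m = make_matrix(d, positions)
        stats = scan_windows(
            m, self._groups(m, 3), window_size=10_000, step=10_000,
            chrom_lengths={"chr1": 90_000},
        )
        pis = {round(w.pi_high, 15) for w in stats[:-1]}
        assert len(pis) == 1


def _fake_stats(n, rng, chrom="chr1"):
    stats = []
    for i in range(n):
        start = 1 + i * 10_000
        stats.append(
            WindowStats(
                interval=GenomeInterval(chrom, start, start + 49_999),
                n_sites=50,
                pi_high=rng.uniform(0.001, 0.01),
                pi_low=rng.uniform(0.001, 0.01),
                d_high=rng.normal(),
                d_low=rng.normal(),
                fst=rng.uniform(0, 0.2),
            )
        )
    return stats


class TestSelectSweepWindows:
    def test_planted_extreme_window_selected_under_intersection(self):
        rng = np.random.default_rng(12)
        stats = _fake_stats(100, rng)
        w = stats[50]
        w.pi_high = 1e-6
        w.d_high = -3.0
        w.d_low = 1.0
        w.fst = 0.9
        selected = select_sweep_windows(stats, q=0.05, mode="intersection")
        assert w in selected

    def test_q_one_selects_all_defined(self):
        rng = np.random.default_rng(13)
        stats = _fake_stats(50, rng)
        assert len(select_sweep_windows(stats, q=1.0, mode="union")) == 50

    def test_union_superset_of_intersection(self):
        rng = np.random.default_rng(14)
        stats = _fake_stats(200, rng)
        inter = set(map(id, select_sweep_windows(stats, mode="intersection")))
        union = set(map(id, select_sweep_windows(stats, mode="union")))
        any_two = set(map(id, select_sweep_windows(stats, mode="any-two")))
        assert inter <= any_two <= union

    def test_too_few_windows_raises(self):
        rng = np.random.default_rng(15)
        with pytest.raises(ValueError):
            select_sweep_windows(_fake_stats(10, rng))


class TestMergeAndAnnotate:
    def test_overlapping_windows_merged(self):
        rng = np.random.default_rng(16)
        stats = _fake_stats(2, rng)
        # starts 1 and 10001, both 50 kb -> overlap -> [1, 60000]
        regions = merge_and_annotate(stats)
        assert len(regions) == 1
        assert (regions[0].interval.start, regions[0].interval.end) == (1, 60_000)

    def test_disjoint_windows_not_merged(self):
        rng = np.random.default_rng(17)
        a, b = _fake_stats(1, rng)[0], _fake_stats(1, rng, chrom="chr2")[0]
        regions = merge_and_annotate([a, b])
        assert len(regions) == 2

    def test_no_overlapping_genes_empty_list(self):
        rng = np.random.default_rng(18)
        stats = _fake_stats(1, rng)
        genes = [GeneModel("g1", GenomeInterval("chr9", 1, 100))]
        (region,) = merge_and_annotate(stats, genes)
        assert region.gene_ids == []

    def test_gene_overlap_matches_brute_force(self):
        rng = np.random.default_rng(19)
        stats = _fake_stats(30, rng)
        selected = [stats[i] for i in (0, 1, 5, 6, 7, 20)]
        genes = []
        for i in range(100):
            s = int(rng.integers(1, 400_000))
            genes.append(
                GeneModel(f"g{i}", GenomeInterval("chr1", s, s + int(rng.integers(100, 20_000))))
            )
        regions = merge_and_annotate(selected, genes)
        for region in regions:
            brute = sorted(
                g.gene_id for g in genes if g.interval.overlaps(region.interval)
            )
            assert region.gene_ids == brute

    def test_span_and_gene_count_reported(self):
        rng = np.random.default_rng(20)
        stats = _fake_stats(3, rng)
        regions = merge_and_annotate(stats)
        assert sum(r.span for r in regions) == 70_000
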