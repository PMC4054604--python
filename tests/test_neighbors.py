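import numpy as np
import pytest
from helpers import brute_mannwhitney_p, brute_territory_owner

from tircat.core import GenomeModel, GenomicInterval
from tircat.neighbors import (
    compare_delta_distributions,
    delta,
    foldchange_correlation,
    gene_territories,
    intergenic_segments,
    overlap_enrichment,
    pair_loci,
    territory_enrichment,
)


def gene(chrom, start, end, name):
    return GenomicInterval(chrom, start, end, "+", name)


class TestGeneTerritories:
    def test_midpoint_split(self):
        genome = GenomeModel({"chr1": 1_000})
        genes = [gene("chr1", 100, 200, "A"), gene("chr1", 600, 700, "B")]
        terrs = gene_territories(genes, genome)
        assert [(t.gene_id, t.interval.start, t.interval.end) for t in terrs] == [
            ("A", 0, 400), ("B", 400, 1_000)
        ]

    def test_single_gene_takes_chromosome(self):
        genome = GenomeModel({"chr1": 1_000})
        (t,) = gene_territories([gene("chr1", 100, 200, "A")], genome)
        assert (t.interval.start, t.interval.end) == (0, 1_000)

    def test_geneless_chromosome_has_no_territory(self):
        genome = GenomeModel({"chr1": 1_000, "chr2": 500})
        terrs = gene_territories([gene("chr1", 100, 200, "A")], genome)
        assert all(t.interval.chrom == "chr1" for t in terrs)

    def test_overlapping_genes_merged(self):
        genome = GenomeModel({"chr1": 1_000})
        genes = [gene("chr1", 100, 300, "A"), gene("chr1", 200, 400, "B")]
        (t,) = gene_territories(genes, genome)
        assert t.gene_id == "A|B"

    def test_tiling_invariant(self, rng):
        genome = GenomeModel({"chr1": 10_000})
        starts = np.sort(rng.choice(9_000, size=8, replace=False))
        genes = [gene("chr1", int(s), int(s) + 50, f"g{i}")
                 for i, s in enumerate(starts)]
        terrs = gene_territories(genes, genome)
        assert sum(t.interval.length for t in terrs) == 10_000
        for a, b in zip(terrs, terrs[1:]):
            assert a.interval.end == b.interval.start

    def test_per_base_oracle(self, rng):
        genome = GenomeModel({"chr1": 10_000})
        starts = np.sort(rng.choice(9_500, size=6, replace=False))
        bodies = [(int(s), int(s) + int(rng.integers(20, 200))) for s in starts]
        # avoid overlaps so holder indices map 1:1 to gene indices
        bodies = [b for i, b in enumerate(bodies)
                  if i == 0 or b[0] >= bodies[i - 1][1]]
        genes = [gene("chr1", s, e, f"g{i}") for i, (s, e) in enumerate(bodies)]
        terrs = gene_territories(genes, genome)
        owner_of = {t.gene_id: t.interval for t in terrs}
        for base in rng.integers(0, 10_000, size=300):
            idx = brute_territory_owner(int(base), bodies)
            iv = owner_of[f"g{idx}"]
            # bases equidistant to two genes may fall on either side of the
            # integer midpoint; accept 1-bp slack at boundaries only
            assert iv.start - 1 <= base < iv.end + 1


def make_space(genome):
    return [GenomicInterval("chr1", 0, genome.length("chr1"))]


class TestEnrichment:
    def test_planted_queries_enriched(self):
        genome = GenomeModel({"chr1": 100_000})
        genes = [gene("chr1", i * 10_000, i * 10_000 + 100, f"g{i}")
                 for i in range(10)]
        terrs = gene_territories(genes, genome)
        selected = terrs[:1]  # territory of g0 = [0, 5050) ~ 5% of the genome
        queries = [GenomicInterval("chr1", 2_000 + i * 200, 2_050 + i * 200)
                   for i in range(10)]  # all inside territory of g0
        res = territory_enrichment(queries, selected, make_space(genome),
                                   n_perm=999, seed=3)
        assert res.observed == 10
        assert res.p_value == pytest.approx(1 / 1_000)
        assert 14 < res.fold < 28  # expectation ~ 10 / (10 * 0.0505) = 19.8

    def test_saturation_fold_one(self):
        genome = GenomeModel({"chr1": 100_000})
        terrs = gene_territories([gene("chr1", 50_000, 50_100, "g")], genome)
        queries = [GenomicInterval("chr1", i * 1_000, i * 1_000 + 50)
                   for i in range(20)]
        res = territory_enrichment(queries, terrs, make_space(genome),
                                   n_perm=99, seed=1)
        assert res.fold == pytest.approx(1.0, abs=0.01)

    def test_identical_sets_maximal_overlap(self):
        genome = GenomeModel({"chr1": 100_000})
        a = [GenomicInterval("chr1", i * 5_000, i * 5_000 + 100) for i in range(5)]
        res = overlap_enrichment(a, a, make_space(genome), n_perm=199, seed=2)
        assert res.observed == 5
        assert res.fold > 3
        assert res.p_value == pytest.approx(1 / 200)

    def test_oversized_query_errors(self):
        genome = GenomeModel({"chr1": 1_000})
        q = [GenomicInterval("chr1", 0, 999)]
        space = [GenomicInterval("chr1", 0, 500)]
        with pytest.raises(ValueError):
            overlap_enrichment(q, q, space, n_perm=9, seed=0)

    def test_seed_reproducibility(self):
        genome = GenomeModel({"chr1": 100_000})
        terrs = gene_territories([gene("chr1", 50_000, 50_100, "g")], genome)
        q = [GenomicInterval("chr1", 100, 200)]
        r1 = territory_enrichment(q, terrs, make_space(genome), n_perm=99, seed=9)
        r2 = territory_enrichment(q, terrs, make_space(genome), n_perm=99, seed=9)
        assert (r1.permuted_mean, r1.p_value) == (r2.permuted_mean, r2.p_value)


class TestPairLoci:
    GENES = [gene("chr1", 10_000, 11_000, "near"),
             gene("chr1", 40_000, 41_000, "far"),
             gene("chr1", 2_000, 2_500, "beyond")]

    def test_nearest_and_next_but_one(self):
        lnc = GenomicInterval("chr1", 20_000, 20_500, "+", "lnc")
        ((_, g, d),) = pair_loci([lnc], self.GENES, order="nearest")
        assert g.name == "near" and d == 9_000
        ((_, g2, _),) = pair_loci([lnc], self.GENES, order="next_but_one")
        assert g2.name == "beyond"  # far side of the nearest gene

    def test_chromosome_end_na(self):
        lnc = GenomicInterval("chr1", 20_000, 20_500)
        genes = [gene("chr1", 10_000, 11_000, "only")]
        ((_, g, d),) = pair_loci([lnc], genes, order="next_but_one")
        assert g is None and d is None

    def test_no_gene_on_chrom(self):
        lnc = GenomicInterval("chr2", 100, 200)
        ((_, g, d),) = pair_loci([lnc], self.GENES)
        assert g is None

    def test_adjacent_coding_control_same_rule(self):
        query = self.GENES[0]
        ((_, g, _),) = pair_loci([query], self.GENES[1:], order="nearest")
        assert g.name == "beyond"


class TestDelta:
    def test_formula_example(self):
        res = delta([1, 5, 2], [2, 3, 2])
        assert (res.stage_min, res.stage_max) == (0, 1)
        assert res.delta == pytest.approx(0.5)

    def test_constant_neighbor_zero(self):
        assert delta([1, 5, 2], [4, 4, 4]).delta == 0.0

    def test_epsilon_guard(self):
        res = delta([1, 5, 2], [0, 1, 0], epsilon=0.01)
        assert res.delta == pytest.approx(99.0)

    def test_constant_reference_nan(self):
        with pytest.warns(UserWarning):
            res = delta([3, 3, 3], [1, 2, 3])
        assert np.isnan(res.delta)

    def test_tie_broken_to_earliest_stage(self):
        res = delta([5, 1, 5], [1, 2, 3])
        assert res.stage_max == 0 and res.stage_min == 1

    def test_rescaling_invariance(self):
        base = delta([1, 5, 2], [2, 3, 2]).delta
        scaled = delta([1, 5, 2], [20, 30, 20]).delta
        assert base == pytest.approx(scaled)

    def test_lower_bound(self, rng):
        for _ in range(100):
            ref = rng.random(3) * 10 + 0.1
            nb = rng.random(3) * 10
            d = delta(ref, nb).delta
            if np.isfinite(d):
                assert d >= -1.0


class TestCompareDelta:
    def test_identical_distributions(self):
        a = [0.1, 0.5, 1.0, 2.0]
        med_a, med_b, p = compare_delta_distributions(a, a)
        assert med_a == med_b and p > 0.9

    def test_exact_enumeration_oracle(self):
        a = [0.1, 0.7, 2.5]
        b = [0.3, 1.4, 3.9]
        _, _, p = compare_delta_distributions(a, b)
        assert p == pytest.approx(brute_mannwhitney_p(a, b), abs=1e-9)

    def test_planted_shift_power(self):
        rejections = 0
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = rng.normal(0.5, 0.3, size=50)
            b = rng.normal(0.0, 0.3, size=50)
            _, _, p = compare_delta_distributions(a, b)
            rejections += p < 0.05
        assert rejections >= 45

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            compare_delta_distributions([], [1.0, 2.0, 3.0])


class TestFoldchangeCorrelation:
    def test_proportional(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert foldchange_correlation(x, 3 * x) == pytest.approx(1.0)

    def test_anti_proportional(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert foldchange_correlation(x, -2 * x) == pytest.approx(-1.0)

    def test_planted_rho(self, rng):
        z = rng.normal(size=200)
        y = 0.8 * z + np.sqrt(1 - 0.64) * rng.normal(size=200)
        assert abs(foldchange_correlation(z, y) - 0.8) < 0.1

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            foldchange_correlation([1, 1, 1], [1, 2, 3])


def test_intergenic_segments_complement():
    genome = GenomeModel({"chr1": 1_000})
    genes = [gene("chr1", 100, 200, "A"), gene("chr1", 600, 700, "B")]
    segs = intergenic_segments(genes, genome)
    assert [(s.start, s.end) for s in segs] == [(0, 100), (200, 600), (700, 1_000)]
    total = sum(s.length for s in segs) + sum(g.length for g in genes)
    assert total == 1_000
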