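import numpy as np
import pytest
from helpers import ml_grid_distance, random_gtr

from tircat.core import GenomicInterval
from tircat.evolution import (
    AlignedPair,
    SaturationError,
    constraint_test,
    count_site_patterns,
    estimate_distance,
    gc_content,
    match_ancestral_repeats,
    read_pair_fasta,
    write_pair_fasta,
)
from tircat.simulate import evolve_pair, random_sequence


def pair(a, b, id="p", kind="locus", anchor=None):
    return AlignedPair(id, a, b, kind=kind, anchor=anchor)


class TestCountSitePatterns:
    def test_identical(self):
        counts, n = count_site_patterns(pair("ACGT", "ACGT"))
        assert n == 4
        assert np.trace(counts) == 4

    def test_single_substitution(self):
        counts, n = count_site_patterns(pair("ACGT", "ACGA"))
        assert n == 4
        assert np.trace(counts) == 3
        assert counts[3, 0] == 1  # T -> A

    def test_gap_exclusion(self):
        counts, n = count_site_patterns(pair("A-GT", "ACGT"))
        assert n == 3

    def test_n_exclusion(self):
        counts, n = count_site_patterns(pair("ANGT", "ACGT"))
        assert n == 3

    def test_all_gaps_errors(self):
        with pytest.raises(ValueError):
            count_site_patterns(pair("----", "ACGT"))

    def test_matrix_sums_to_used_sites(self, rng):
        a = random_sequence(500, 0.5, rng)
        b = random_sequence(500, 0.5, rng)
        counts, n = count_site_patterns(pair(a, b))
        assert counts.sum() == n == 500


class TestEstimateDistance:
    def test_identical_gives_zero(self):
        counts, _ = count_site_patterns(pair("ACGT" * 100, "ACGT" * 100))
        for model in ("JC69", "K80", "GTR"):
            assert estimate_distance(counts, model).d == pytest.approx(0.0, abs=1e-9)

    def test_jc_closed_form_at_p_010(self):
        counts = np.diag([225, 225, 225, 225]).astype(np.int64)
        counts[0, 1] = 100  # 100 mismatches over 1,000 sites -> p = 0.10
        est = estimate_distance(counts, "JC69")
        assert est.d == pytest.approx(0.1073256, abs=1e-6)
        assert est.p_distance == pytest.approx(0.10)

    def test_d_at_least_p_distance(self, rng):
        for _ in range(20):
            seq = random_sequence(2_000, 0.5, rng)
            p = evolve_pair(seq, float(rng.uniform(0.01, 0.4)), rng)
            counts, _ = count_site_patterns(p)
            for model in ("JC69", "K80", "GTR"):
                est = estimate_distance(counts, model)
                assert est.d >= est.p_distance - 1e-12

    def test_jc_saturation(self):
        counts = np.zeros((4, 4), dtype=np.int64)
        counts[0, 1] = 80
        counts[0, 0] = 20
        with pytest.raises(SaturationError):
            estimate_distance(counts, "JC69")

    def test_gtr_equals_jc_under_uniform_composition(self):
        p = 0.10
        n = 1_000_000
        counts = np.full((4, 4), p / 12 * n)
        np.fill_diagonal(counts, (1 - p) / 4 * n)
        est_gtr = estimate_distance(counts.astype(np.int64), "GTR")
        est_jc = estimate_distance(counts.astype(np.int64), "JC69")
        assert est_gtr.d == pytest.approx(est_jc.d, abs=1e-9)

    def test_monotone_in_p_distance(self):
        ds = []
        for mismatches in (10, 50, 100, 200, 400):
            counts = np.diag([(1_000 - mismatches) // 4] * 4).astype(np.int64)
            counts[0, 1] = mismatches
            ds.append(estimate_distance(counts, "JC69").d)
        assert ds == sorted(ds)

    def test_planted_distance_recovered(self, rng):
        seq = random_sequence(50_000, 0.5, rng)
        p = evolve_pair(seq, 0.16, rng)
        counts, _ = count_site_patterns(p)
        assert estimate_distance(counts, "JC69").d == pytest.approx(0.16, abs=0.01)
        assert estimate_distance(counts, "GTR").d == pytest.approx(0.16, abs=0.01)

    def test_gtr_agrees_with_ml_grid(self, rng):
        Q, pi = random_gtr(rng)
        # draw ancestral states from the stationary distribution
        seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=30_000, p=pi)])
        d_true = 0.2
        p = evolve_pair(seq, d_true, rng, model="GTR", Q=Q)
        counts, _ = count_site_patterns(p)
        d_hat = estimate_distance(counts, "GTR").d
        d_ml = ml_grid_distance(counts, Q, pi, np.arange(0.05, 0.4, 1e-4))
        assert abs(d_hat - d_ml) < 1e-2

    def test_fallback_chain_recorded(self):
        # saturated for JC, so every model in the chain fails -> error
        counts = np.zeros((4, 4), dtype=np.int64)
        counts[0, 1] = counts[1, 2] = counts[2, 3] = counts[3, 0] = 250
        with pytest.raises(SaturationError):
            estimate_distance(counts, "GTR")


class TestGcContent:
    def test_all_gc(self):
        assert gc_content("GGCC") == 1.0

    def test_half(self):
        assert gc_content("ATGC") == 0.5

    def test_n_exclusion(self):
        assert gc_content("AANN") == 0.0

    def test_no_bases_errors(self):
        with pytest.raises(ValueError):
            gc_content("NNN-")


def anchored_pair(id, gc, chrom, start, end, d, rng, kind="AR"):
    seq = random_sequence(end - start, gc, rng)
    return evolve_pair(seq, d, rng, element_id=id, kind=kind,
                       anchor=GenomicInterval(chrom, start, end))


class TestMatchAncestralRepeats:
    def test_gc_tolerance_rule(self, rng):
        el = anchored_pair("el", 0.45, "chr1", 100_000, 101_000, 0.1, rng, "TIR")
        close = anchored_pair("ar1", 0.44, "chr1", 110_000, 111_000, 0.16, rng)
        far_gc = anchored_pair("ar2", 0.62, "chr1", 120_000, 121_000, 0.16, rng)
        counts, ids = match_ancestral_repeats(el, [close, far_gc])
        assert ids == ["ar1"]

    def test_distance_bound(self, rng):
        el = anchored_pair("el", 0.45, "chr1", 0, 1_000, 0.1, rng, "TIR")
        ar = anchored_pair("ar", 0.45, "chr1", 601_000, 602_000, 0.16, rng)
        with pytest.raises(ValueError):
            match_ancestral_repeats(el, [ar])

    def test_gc_fallback_with_warning(self, rng):
        el = anchored_pair("el", 0.45, "chr1", 0, 1_000, 0.1, rng, "TIR")
        ar = anchored_pair("ar", 0.62, "chr1", 10_000, 11_000, 0.16, rng)
        with pytest.warns(UserWarning, match="nearest-GC"):
            counts, ids = match_ancestral_repeats(el, [ar])
        assert ids == ["ar"]

    def test_overlapping_ar_excluded(self, rng):
        el = anchored_pair("el", 0.45, "chr1", 0, 1_000, 0.1, rng, "TIR")
        ar = anchored_pair("ar", 0.45, "chr1", 500, 1_500, 0.16, rng)
        with pytest.raises(ValueError):
            match_ancestral_repeats(el, [ar])


class TestConstraintTest:
    def _simulate(self, rng, factor, n=20, length=2_000):
        elements, ars = [], []
        for i in range(n):
            base = i * 50_000
            gc = 0.45
            elements.append(anchored_pair(f"el{i}", gc, "chr1", base,
                                          base + length, 0.165 * factor, rng, "TIR"))
            ars.append(anchored_pair(f"el{i}_ar", gc, "chr1", base + 10_000,
                                     base + 10_000 + length, 0.165, rng))
        return elements, ars

    def test_constrained_elements_detected(self, rng):
        elements, ars = self._simulate(rng, factor=0.8, n=40)
        results, summary = constraint_test(elements, ars, model="JC69")
        assert summary["median_relative_rate"] < 0.9
        assert summary["p_value"] < 0.05

    def test_neutral_relative_rate_near_one(self, rng):
        elements, ars = self._simulate(rng, factor=1.0, n=40, length=5_000)
        _, summary = constraint_test(elements, ars, model="JC69")
        assert summary["median_relative_rate"] == pytest.approx(1.0, abs=0.05)

    def test_identical_element_rate_zero(self, rng):
        el = anchored_pair("el", 0.45, "chr1", 0, 2_000, 0.0, rng, "TIR")
        ars = [anchored_pair(f"ar{i}", 0.45, "chr1", 10_000 + 5_000 * i,
                             12_000 + 5_000 * i, 0.165, rng) for i in range(3)]
        spare = [anchored_pair(f"el{i}", 0.45, "chr1", 0, 2_000, 0.1, rng, "TIR")
                 for i in range(1, 3)]
        results, _ = constraint_test([el] + spare, ars, model="JC69")
        assert results[0].relative_rate == 0.0

    def test_all_skipped_errors(self, rng):
        el = anchored_pair("el", 0.45, "chr1", 0, 1_000, 0.1, rng, "TIR")
        with pytest.raises(ValueError):
            constraint_test([el], [], model="JC69")


class TestEvolvePair:
    def test_zero_distance_identity(self, rng):
        seq = random_sequence(1_000, 0.5, rng)
        p = evolve_pair(seq, 0.0, rng)
        assert p.seq_a == p.seq_b

    def test_expected_mismatch_fraction(self, rng):
        seq = random_sequence(10_000, 0.5, rng)
        p = evolve_pair(seq, 0.1, rng)
        mismatch = sum(a != b for a, b in zip(p.seq_a, p.seq_b)) / 10_000
        expected = 0.75 * (1 - np.exp(-4 * 0.1 / 3))  # 0.0936
        se = np.sqrt(expected * (1 - expected) / 10_000)
        assert abs(mismatch - expected) < 3 * se

    def test_seed_determinism(self):
        seq = random_sequence(500, 0.5, np.random.default_rng(3))
        a = evolve_pair(seq, 0.2, np.random.default_rng(4))
        b = evolve_pair(seq, 0.2, np.random.default_rng(4))
        assert a.seq_b == b.seq_b

    def test_negative_distance_rejected(self, rng):
        with pytest.raises(ValueError):
            evolve_pair("ACGT", -0.1, rng)

    def test_indel_mode_produces_gaps_handled_downstream(self, rng):
        seq = random_sequence(2_000, 0.5, rng)
        p = evolve_pair(seq, 0.1, rng, indel_rate=0.01)
        assert "-" in p.seq_b
        counts, n = count_site_patterns(p)
        assert n == 2_000 - p.seq_b.count("-")


class TestPairFastaIO:
    def test_round_trip(self, tmp_path, rng):
        p = anchored_pair("el1", 0.5, "chr1", 0, 500, 0.1, rng, "TIR")
        path = tmp_path / "el1.fa"
        write_pair_fasta(p, path)
        back = read_pair_fasta(path, element_id="el1", kind="TIR", anchor=p.anchor)
        assert back.seq_a == p.seq_a and back.seq_b == p.seq_b

    def test_wrong_record_count(self, tmp_path):
        path = tmp_path / "bad.fa"
        path.write_text(">a\nACGT\n")
        with pytest.raises(ValueError):
            read_pair_fasta(path)
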