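import numpy as np
import pytest
from scipy import stats

from difftf.io_formats import GenomicInterval
from difftf.peak_selection import (
    CountedPeak,
    DifferentialResult,
    Label,
    Split,
    Thresholds,
    benjamini_hochberg,
    classify_peak,
    count_reads,
    differential_test,
    merge_peaks,
    normalize_count,
    select_peaks,
    split_by_chromosome,
    trim_peak,
    LabeledPeak,
)


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


def brute_force_union(intervals, chrom_len=1000):
    """Oracle: base-level membership set."""
    covered = np.zeros(chrom_len, dtype=bool)
    for i in intervals:
        covered[i.start : i.end] = True
    return covered


class TestMergePeaks:
    def test_disjoint_unchanged(self):
        merged = merge_peaks([iv("chr1", 100, 200)], [iv("chr1", 300, 400)])
        assert [(m.start, m.end) for m in merged] == [(100, 200), (300, 400)]

    def test_overlapping_merged(self):
        merged = merge_peaks([iv("chr1", 100, 250)], [iv("chr1", 200, 400)])
        assert [(m.start, m.end) for m in merged] == [(100, 400)]
        oracle = brute_force_union([iv("chr1", 100, 250), iv("chr1", 200, 400)])
        got = brute_force_union(merged)
        assert np.array_equal(oracle, got)

    def test_empty(self):
        assert merge_peaks([], []) == []

    def test_random_against_base_set_oracle(self, rng):
        ivs_a = [iv("chr1", s, s + rng.integers(10, 80))
                 for s in rng.integers(0, 900, 20)]
        ivs_b = [iv("chr1", s, s + rng.integers(10, 80))
                 for s in rng.integers(0, 900, 20)]
        merged = merge_peaks(ivs_a, ivs_b)
        assert np.array_equal(
            brute_force_union(ivs_a + ivs_b), brute_force_union(merged)
        )
        # disjoint and sorted
        for a, b in zip(merged, merged[1:]):
            assert a.end < b.start


class TestCountReads:
    def test_basic(self):
        merged = [iv("chr1", 100, 200)]
        reads_a = [iv("chr1", 120, 160), iv("chr1", 90, 130), iv("chr1", 150, 210)]
        counted = count_reads(merged, reads_a, [])
        assert counted[0].counts_A == 3
        assert counted[0].counts_B == 0

    def test_half_open_midpoint_convention(self):
        merged = [iv("chr1", 100, 200)]
        at_start = [iv("chr1", 90, 110)]  # midpoint 100 -> counted
        at_end = [iv("chr1", 190, 210)]  # midpoint 200 -> not counted
        assert count_reads(merged, at_start, [])[0].counts_A == 1
        assert count_reads(merged, at_end, [])[0].counts_A == 0

    def test_random_against_membership_oracle(self, rng):
        merged = merge_peaks(
            [iv("chr1", int(s), int(s) + 50) for s in rng.integers(0, 900, 8)], []
        )
        reads = [iv("chr1", int(s), int(s) + 20) for s in rng.integers(0, 950, 200)]
        counted = count_reads(merged, reads, [])
        for peak, c in zip(merged, counted):
            expected = sum(
                1 for r in reads if peak.start <= (r.start + r.end) // 2 < peak.end
            )
            assert c.counts_A == expected


class TestNormalizeCount:
    def test_direct_evaluation(self):
        # 10 / (1e6 * 1000) * 1e9 = 10.0
        assert normalize_count(10, 1e6, 1000) == pytest.approx(10.0)

    def test_zero_reads(self):
        assert normalize_count(0, 100, 10) == 0.0

    def test_ratio_invariance(self):
        assert normalize_count(20, 2e6, 1000) == pytest.approx(
            normalize_count(10, 1e6, 1000)
        )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            normalize_count(1, 0, 10)
        with pytest.raises(ValueError):
            normalize_count(1, 10, 0)


class TestBenjaminiHochberg:
    def test_against_direct_computation(self, rng):
        p = rng.random(50)
        q = benjamini_hochberg(p)
        # independent oracle: direct step-up definition
        n = len(p)
        order = np.argsort(p)
        expected = np.empty(n)
        running_min = 1.0
        for rank_idx in range(n - 1, -1, -1):
            i = order[rank_idx]
            running_min = min(running_min, p[i] * n / (rank_idx + 1))
            expected[i] = running_min
        assert np.allclose(q, expected)

    def test_monotone_in_rank(self, rng):
        p = rng.random(30)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(40)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(benjamini_hochberg(p), q_sm)


def _nb_counts(rng, mean, dispersion, size):
    n = 1.0 / dispersion
    return rng.negative_binomial(n, n / (n + mean), size)


class TestDifferentialTest:
    def test_null_case(self):
        counted = [
            CountedPeak(iv("chr1", i * 1000, i * 1000 + 600), 50 + i, 50 + i)
            for i in range(20)
        ]
        results = differential_test(counted, size_factors=(1.0, 1.0))
        assert all(abs(r.log2fc) < 0.1 for r in results)
        assert all(r.qvalue > 0.9 for r in results)

    def test_planted_fold_change_recovered(self):
        rng = np.random.default_rng(1)
        base = _nb_counts(rng, 200, 0.05, 200)
        up = _nb_counts(rng, 1600, 0.05, 200)  # 8-fold, log2fc = 3
        counted = [
            CountedPeak(iv("chr1", i * 1000, i * 1000 + 600), int(a), int(b))
            for i, (a, b) in enumerate(zip(base, up))
        ]
        results = differential_test(counted, size_factors=(1.0, 1.0))
        median_lfc = np.median([r.log2fc for r in results])
        assert abs(median_lfc - 3.0) < 0.3

    def test_all_zero_peak_flagged(self):
        counted = [
            CountedPeak(iv("chr1", 0, 600), 0, 0),
            CountedPeak(iv("chr1", 1000, 1600), 50, 50),
            CountedPeak(iv("chr1", 2000, 2600), 60, 55),
        ]
        results = differential_test(counted, size_factors=(1.0, 1.0))
        assert results[0].flagged
        assert results[0].pvalue == 1.0
        assert results[0].log2fc == 0.0

    def test_too_few_peaks(self):
        with pytest.raises(ValueError):
            differential_test([CountedPeak(iv("chr1", 0, 600), 1, 1)])


class TestClassifyPeak:
    @pytest.mark.parametrize(
        "q,lfc,expected",
        [
            (0.01, -3.0, Label.A_SPECIFIC),
            (0.01, 3.0, Label.B_SPECIFIC),
            (0.2, 0.5, Label.SHARED),
            (0.07, 0.0, Label.ABANDONED),
            (0.01, 1.5, Label.ABANDONED),  # significant but small effect
            (0.5, 2.5, Label.ABANDONED),  # big effect, not significant
        ],
    )
    def test_threshold_rules(self, q, lfc, expected):
        assert classify_peak(DifferentialResult(lfc, q / 2, q)) == expected

    def test_swap_symmetry(self, rng):
        """Swapping cell types (negating log2fc) swaps the specific labels
        and fixes SHARED/ABANDONED."""
        swap = {
            Label.A_SPECIFIC: Label.B_SPECIFIC,
            Label.B_SPECIFIC: Label.A_SPECIFIC,
            Label.SHARED: Label.SHARED,
            Label.ABANDONED: Label.ABANDONED,
        }
        for _ in range(200):
            q = rng.random()
            lfc = rng.normal(0, 3)
            direct = classify_peak(DifferentialResult(lfc, q / 2, q))
            mirrored = classify_peak(DifferentialResult(-lfc, q / 2, q))
            assert mirrored == swap[direct]

    def test_configurable_thresholds(self):
        loose = Thresholds(q_specific=0.2, lfc_specific=1.0)
        result = DifferentialResult(-1.5, 0.05, 0.1)
        assert classify_peak(result) == Label.ABANDONED
        assert classify_peak(result, loose) == Label.A_SPECIFIC


class TestTrimPeak:
    def test_centered_window(self):
        trimmed = trim_peak(iv("chr1", 100, 1100), 600)
        assert (trimmed.start, trimmed.end) == (300, 900)

    def test_already_target_length(self):
        trimmed = trim_peak(iv("chr1", 0, 600), 600)
        assert (trimmed.start, trimmed.end) == (0, 600)

    def test_odd_length_input(self):
        trimmed = trim_peak(iv("chr1", 0, 601), 600)
        assert trimmed.length == 600

    def test_short_input_extended(self):
        trimmed = trim_peak(iv("chr1", 1000, 1100), 600)
        assert trimmed.length == 600
        assert trimmed.start <= 1000 and trimmed.end >= 1100

    def test_clipped_at_chromosome_start(self):
        trimmed = trim_peak(iv("chr1", 0, 100), 600)
        assert (trimmed.start, trimmed.end) == (0, 600)

    def test_shifted_at_chromosome_end(self):
        trimmed = trim_peak(iv("chr1", 900, 1000), 600, chrom_size=1000)
        assert (trimmed.start, trimmed.end) == (400, 1000)

    def test_chromosome_too_short(self):
        with pytest.raises(ValueError, match="shorter"):
            trim_peak(iv("chr1", 0, 100), 600, chrom_size=500)

    def test_summit_anchor(self):
        peak = GenomicInterval("chr1", 1000, 2000, summit=100)
        trimmed = trim_peak(peak, 600, use_summit=True)
        assert (trimmed.start, trimmed.end) == (800, 1400)


class TestSplitByChromosome:
    @pytest.mark.parametrize(
        "chrom,expected",
        [
            ("chr8", Split.TEST),
            ("chr16", Split.TEST),
            ("chr18", Split.VAL),
            ("chrY", Split.EXCLUDED),
            ("chr1", Split.TRAIN),
            ("chr22", Split.TRAIN),
            ("chrX", Split.TRAIN),
        ],
    )
    def test_rules(self, chrom, expected):
        peak = LabeledPeak(iv(chrom, 0, 600), Label.SHARED)
        (out,) = split_by_chromosome([peak])
        assert out.split == expected

    def test_unprefixed_chromosome_warns_and_trains(self, caplog):
        peak = LabeledPeak(iv("8", 0, 600), Label.SHARED)
        with caplog.at_level("WARNING"):
            (out,) = split_by_chromosome([peak])
        assert out.split == Split.TRAIN
        assert "8" in caplog.text

    def test_partition_exhaustive(self, rng):
        chroms = [f"chr{c}" for c in list(range(1, 23)) + ["X", "Y"]]
        peaks = [
            LabeledPeak(iv(str(rng.choice(chroms)), 0, 600), Label.SHARED)
            for _ in range(100)
        ]
        out = split_by_chromosome(peaks)
        assert len(out) == len(peaks)
        assert all(p.split in Split for p in out)


class TestPipelineInvariants:
    def test_labels_partition_merged_peaks(self, bundle_default):
        b = bundle_default
        labeled = select_peaks(
            b.peak_calls("cellA"), b.peak_calls("cellB"),
            b.reads["cellA"], b.reads["cellB"],
        )
        assert len(labeled) == len(b.peaks)
        assert all(p.label in Label and p.split in Split for p in labeled)

    def test_planted_specific_recovery(self, bundle_default):
        """>=90% of planted A/B-specific peaks get the correct specific label."""
        b = bundle_default
        labeled = select_peaks(
            b.peak_calls("cellA"), b.peak_calls("cellB"),
            b.reads["cellA"], b.reads["cellB"],
        )
        truth = {(p.chrom, p.start): l for p, l in zip(b.peaks, b.labels)}
        specific = [
            lp for lp in labeled
            if truth.get((lp.interval.chrom, lp.interval.start))
            in (Label.A_SPECIFIC, Label.B_SPECIFIC)
        ]
        correct = sum(
            1 for lp in specific
            if lp.label == truth[(lp.interval.chrom, lp.interval.start)]
        )
        assert correct / len(specific) >= 0.90

    def test_trimmed_to_600(self, bundle_default):
        b = bundle_default
        labeled = select_peaks(
            b.peak_calls("cellA"), b.peak_calls("cellB"),
            b.reads["cellA"], b.reads["cellB"],
        )
        assert all(p.interval.length == 600 for p in labeled)
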