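import math

import numpy as np
import pytest

from epitet.core_model import CoverageTrack, GenomicInterval, Peak, ValidationError
from epitet.chip_peaks import (
    FilterCriteria,
    LARVA_CONFIG,
    PeakCallConfig,
    apply_peak_filters,
    call_peaks,
    multi_replicate_consensus,
    overlap_at_window,
    poisson_enrichment_pvalue,
    saturation_analysis,
)


def poisson_tail_by_summation(k: int, lam: float) -> float:
    """Independent oracle: P(X >= k) = 1 - sum_{i<k} e^-lam lam^i / i!
    computed term by term in log space."""
    if k == 0:
        return 1.0
    total = 0.0
    logterm = -lam  # log P(X=0)
    total += math.exp(logterm)
    for i in range(1, k):
        logterm += math.log(lam) - math.log(i)
        total += math.exp(logterm)
    return max(1.0 - total, 0.0)


def peak_at(summit, chrom="chr1", width=200, **kw):
    return Peak(
        interval=GenomicInterval(chrom, summit - width // 2, summit + width // 2),
        summit=summit,
        **kw,
    )


class TestPoissonPvalue:
    def test_k_zero_is_one(self):
        assert poisson_enrichment_pvalue(0, 0.1) == 1.0
        assert poisson_enrichment_pvalue(0, 100.0) == 1.0

    def test_closed_form_k1_lam1(self):
        assert poisson_enrichment_pvalue(1, 1.0) == pytest.approx(
            1 - math.exp(-1), abs=1e-12
        )

    def test_matches_summation_oracle(self, rng):
        """1000 random (k, lam) agree with term-by-term summation to 1e-12."""
        for _ in range(1000):
            k = int(rng.integers(0, 60))
            lam = float(rng.uniform(0.05, 40.0))
            assert poisson_enrichment_pvalue(k, lam) == pytest.approx(
                poisson_tail_by_summation(k, lam), abs=1e-12
            )

    def test_monotonicity(self):
        assert poisson_enrichment_pvalue(10, 2.0) < poisson_enrichment_pvalue(9, 2.0)
        assert poisson_enrichment_pvalue(10, 2.0) < poisson_enrichment_pvalue(10, 3.0)

    def test_domain_error(self):
        with pytest.raises(ValidationError):
            poisson_enrichment_pvalue(1, 0.0)


class TestFilters:
    @pytest.mark.parametrize(
        "p,fe,reads,kept",
        [
            (1e-6, 12, 60, True),   # all criteria strictly satisfied
            (1e-6, 10, 60, False),  # fold enrichment must exceed 10
            (1e-6, 12, 50, False),  # reads must exceed 50
            (1e-5, 12, 60, False),  # p must be below 1e-5
        ],
    )
    def test_selection_rule_boundaries(self, p, fe, reads, kept):
        peak = peak_at(100, pvalue=p, fold_enrichment=fe, reads=reads)
        out = apply_peak_filters([peak], FilterCriteria())
        assert (len(out) == 1) is kept

    def test_missing_field_names_peak(self):
        peak = peak_at(100, pvalue=1e-6, fold_enrichment=None, reads=60)
        with pytest.raises(ValidationError, match="fold_enrichment"):
            apply_peak_filters([peak])

    def test_relaxing_criteria_is_monotone(self, rng):
        peaks = [
            peak_at(
                int(s),
                pvalue=float(rng.uniform(1e-9, 1e-2)),
                fold_enrichment=float(rng.uniform(0, 30)),
                reads=float(rng.integers(0, 200)),
            )
            for s in rng.integers(200, 100_000, 100)
        ]
        strict = apply_peak_filters(peaks, FilterCriteria(1e-5, 10, 50))
        relaxed = apply_peak_filters(peaks, FilterCriteria(1e-4, 5, 20))
        assert set(id(p) for p in strict) <= set(id(p) for p in relaxed)


def brute_force_reproducible(peaks_a, peaks_b, w):
    """Independent all-pairs oracle for the greedy nearest-summit matching."""
    pairs = sorted(
        (abs(a.summit - b.summit), a.summit, b.summit, i, j)
        for i, a in enumerate(peaks_a)
        for j, b in enumerate(peaks_b)
        if a.chrom == b.chrom and abs(a.summit - b.summit) <= w
    )
    used_a, used_b = set(), set()
    for _, _, _, i, j in pairs:
        if i not in used_a and j not in used_b:
            used_a.add(i)
            used_b.add(j)
    return used_a


class TestOverlapWindows:
    def test_identical_sets_all_reproducible_at_zero(self):
        peaks = [peak_at(s) for s in (500, 1500, 2500)]
        assert len(overlap_at_window(peaks, list(peaks), 0)) == 3

    def test_window_is_max_summit_distance(self):
        a = [peak_at(1000)]
        b = [peak_at(1240)]
        assert overlap_at_window(a, b, 200) == []
        assert len(overlap_at_window(a, b, 250)) == 1

    def test_matches_brute_force_oracle(self, rng):
        for w in (0, 50, 250):
            a = [peak_at(int(s)) for s in rng.integers(200, 20_000, 40)]
            b = [peak_at(int(s)) for s in rng.integers(200, 20_000, 40)]
            got = {i for i, p in enumerate(a) if p in overlap_at_window(a, b, w)}
            assert got == brute_force_reproducible(a, b, w)

    def test_counts_non_decreasing_in_window(self, rng):
        a = [peak_at(int(s)) for s in rng.integers(200, 50_000, 60)]
        b = [peak_at(int(s)) for s in rng.integers(200, 50_000, 60)]
        counts = [len(overlap_at_window(a, b, w)) for w in (0, 50, 100, 200, 400)]
        assert counts == sorted(counts)


class TestSaturation:
    def test_identical_sets_flat_curve_selects_smallest(self):
        peaks = [peak_at(s) for s in (500, 1500, 2500)]
        sat = saturation_analysis(peaks, list(peaks))
        assert len(set(sat.counts)) == 1
        assert sat.selected == 50

    def test_disjoint_chromosomes_all_zero(self):
        a = [peak_at(500, chrom="chr1")]
        b = [peak_at(500, chrom="chr2")]
        sat = saturation_analysis(a, b)
        assert sat.counts == [0] * 6
        assert sat.selected == 50

    def test_needs_two_windows(self):
        with pytest.raises(ValidationError):
            saturation_analysis([], [], windows=[100])


class TestConsensus:
    def test_triplicate_identical_returns_first_set(self):
        peaks = [peak_at(s) for s in (500, 1500)]
        out = multi_replicate_consensus([peaks, list(peaks), list(peaks)], 250)
        assert out == peaks

    def test_one_empty_replicate_gives_empty_consensus(self):
        peaks = [peak_at(500)]
        assert multi_replicate_consensus([peaks, []], 250) == []

    def test_needs_two_sets(self):
        with pytest.raises(ValidationError):
            multi_replicate_consensus([[peak_at(500)]], 250)


def triangular_bump(length, summit, height, half_width):
    x = np.arange(length, dtype=float)
    return np.maximum(0.0, height * (1 - np.abs(x - summit) / half_width))


class TestCallPeaks:
    def test_ip_equal_input_gives_nothing_significant(self):
        v = np.full(50_000, 10.0)
        ip = CoverageTrack({"chr1": v.copy()})
        inp = CoverageTrack({"chr1": v.copy()})
        peaks = call_peaks(ip, inp)
        assert [p for p in peaks if p.pvalue < 1e-5] == []

    def test_larva_dialect_resizes_to_summit_plus_minus_100(self):
        """A strong deterministic peak at 10,000 is reported as [9900, 10100)."""
        base = np.full(50_000, 10.0)
        ip = base + triangular_bump(50_000, 10_000, 200.0, 147)
        peaks = call_peaks(
            CoverageTrack({"chr1": ip}),
            CoverageTrack({"chr1": base.copy()}),
            LARVA_CONFIG,
        )
        assert len(peaks) == 1
        (p,) = peaks
        assert p.summit == 10_000
        assert (p.interval.start, p.interval.end) == (9900, 10100)

    def test_zero_input_library_is_an_error(self):
        ip = CoverageTrack({"chr1": np.full(1000, 5.0)})
        inp = CoverageTrack({"chr1": np.zeros(1000)})
        with pytest.raises(ValidationError):
            call_peaks(ip, inp)

    def test_mismatched_chrom_sizes_rejected(self):
        ip = CoverageTrack({"chr1": np.full(100, 5.0)})
        inp = CoverageTrack({"chr1": np.full(200, 5.0)})
        with pytest.raises(ValidationError):
            call_peaks(ip, inp)
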