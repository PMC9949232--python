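import numpy as np
import pytest

from epitet.core_model import CoverageTrack, GenomicInterval, Peak, ValidationError
from epitet.hmerip import (
    ReductionConfig,
    abundance_stratification,
    call_rna_peaks,
    classify_reduced,
    element_distribution,
    expected_element_distribution,
    peak_element,
    transcript_reduction_summary,
)
from epitet.synthetic_data import SimulationConfig, simulate_genome, simulate_hmerip


@pytest.fixture(scope="module")
def hmerip_run():
    cfg = SimulationConfig(seed=21, genome_length=600_000, n_genes=90,
                           n_planted_rna_peaks=90, hmerip_replicates=2)
    genome, ts = simulate_genome(cfg)
    return cfg, ts, simulate_hmerip(cfg, ts, genome)


class TestCallRnaPeaks:
    def test_ip_equal_input_yields_nothing(self, five_gene_transcripts):
        v = np.full(30_000, 20.0)
        ip = CoverageTrack({"chr1": v.copy()})
        inp = CoverageTrack({"chr1": v.copy()})
        peaks, _ = call_rna_peaks(ip, inp, five_gene_transcripts)
        assert peaks == []

    def test_planted_peaks_recovered_and_assigned(self, hmerip_run):
        cfg, ts, h = hmerip_run
        peaks, assignment = call_rna_peaks(h.wt_ip[0], h.wt_input[0], ts)
        called = [(p.summit, assignment[p.name]) for p in peaks]
        hits = 0
        correct = 0
        for r in h.truth:
            match = [(abs(s - r.summit), tid) for s, tid in called]
            if match and min(match)[0] <= 250:
                hits += 1
                if min(match)[1] == r.transcript_id:
                    correct += 1
        assert hits / len(h.truth) >= 0.9
        assert correct == hits  # every recovered peak on its true transcript

    def test_unmodified_transcripts_stay_clean(self, hmerip_run):
        cfg, ts, h = hmerip_run
        peaks, assignment = call_rna_peaks(h.wt_ip[0], h.wt_input[0], ts)
        modified = {r.transcript_id for r in h.truth}
        called_tids = {assignment[p.name] for p in peaks}
        spurious = called_tids - modified
        assert len(spurious) <= 2


class TestElementDistribution:
    def test_peak_element_uses_cds_boundaries(self, five_gene_transcripts):
        tA = five_gene_transcripts[0]
        assert peak_element(2050, tA) == "5UTR"
        assert peak_element(2200, tA) == "CDS"
        assert peak_element(3000, tA) == "intron"
        assert peak_element(4900, tA) == "3UTR"

    def test_all_intron_planting(self):
        cfg = SimulationConfig(
            seed=4, genome_length=400_000, n_genes=60, n_planted_rna_peaks=50,
            element_weights={"5UTR": 0.0, "CDS": 0.0, "intron": 1.0, "3UTR": 0.0},
        )
        genome, ts = simulate_genome(cfg)
        h = simulate_hmerip(cfg, ts, genome)
        peaks, assignment = [], {}
        for i, r in enumerate(h.truth):
            p = Peak(
                interval=GenomicInterval(r.chrom, r.summit - 50, r.summit + 50),
                summit=r.summit, name=f"p{i}",
            )
            peaks.append(p)
            assignment[p.name] = r.transcript_id
        dist = element_distribution(peaks, assignment, ts)
        assert dist.fractions["intron"] == 1.0

    def test_fractions_sum_to_one_and_permutation_invariant(self, hmerip_run, rng):
        cfg, ts, h = hmerip_run
        peaks, assignment = [], {}
        for i, r in enumerate(h.truth):
            p = Peak(
                interval=GenomicInterval(r.chrom, r.summit - 50, r.summit + 50),
                summit=r.summit, name=f"p{i}",
            )
            peaks.append(p)
            assignment[p.name] = r.transcript_id
        d1 = element_distribution(peaks, assignment, ts)
        assert d1.fractions.sum() == pytest.approx(1.0, abs=1e-12)
        perm = [peaks[i] for i in rng.permutation(len(peaks))]
        d2 = element_distribution(perm, assignment, ts)
        assert d1.fractions.equals(d2.fractions)


class TestExpectedDistribution:
    def test_single_all_cds_transcript(self):
        from epitet.core_model import Transcript

        iv = GenomicInterval("chr1", 0, 3000, "+")
        t = Transcript(id="t", gene_id="g", interval=iv, exons=(iv,), cds=(iv,))
        for model in ("length_proportional", "monte_carlo_uniform"):
            e = expected_element_distribution([t], model, n_iter=2000, seed=0)
            assert e["CDS"] == 1.0

    def test_mc_converges_to_length_proportional(self, five_gene_transcripts):
        lp = expected_element_distribution(five_gene_transcripts, "length_proportional")
        mc = expected_element_distribution(
            five_gene_transcripts, "monte_carlo_uniform", n_iter=100_000, seed=1
        )
        assert np.abs(mc - lp).max() < 0.01

    def test_mc_deterministic_under_seed(self, five_gene_transcripts):
        a = expected_element_distribution(
            five_gene_transcripts, "monte_carlo_uniform", n_iter=5000, seed=7
        )
        b = expected_element_distribution(
            five_gene_transcripts, "monte_carlo_uniform", n_iter=5000, seed=7
        )
        assert a.equals(b)

    def test_expected_fractions_sum_to_one(self, five_gene_transcripts):
        for model in ("length_proportional", "monte_carlo_uniform"):
            e = expected_element_distribution(five_gene_transcripts, model, 5000, 0)
            assert e.sum() == pytest.approx(1.0, abs=1e-12)


class TestAbundanceStratification:
    def test_modification_in_top_decile(self):
        expr = {f"t{i}": float(i + 1) for i in range(100)}
        modified = {f"t{i}" for i in range(90, 100)}
        out = abundance_stratification(modified, expr, n_bins=10)
        assert out["table"]["modified"].iloc[-1] == 10
        assert out["table"]["modified"].iloc[:-1].sum() == 0

    def test_single_bin(self):
        expr = {f"t{i}": float(i) for i in range(10)}
        out = abundance_stratification({"t1"}, expr, n_bins=1)
        assert out["table"]["all"].tolist() == [10]

    def test_independent_planting_gives_small_correlation(self, rng):
        expr = {f"t{i}": float(v) for i, v in enumerate(np.exp(rng.normal(0, 1, 500)))}
        modified = {t for t in expr if rng.random() < 0.3}
        out = abundance_stratification(modified, expr)
        assert abs(out["rank_correlation"]) < 0.12


def flat_tracks(depth, n=2, length=10_000, lib_equalize=True):
    return [CoverageTrack({"chr1": np.full(length, float(depth))}) for _ in range(n)]


class TestClassifyReduced:
    def test_boundary_fold_1p4_is_reduced(self):
        """wt/ko = 1.4 exactly (per-million units) -> flagged (inclusive)."""
        peak = Peak(interval=GenomicInterval("chr1", 100, 300), summit=200, name="p1")
        L = 10_000
        wt = np.full(L, 100.0)
        wt[100:300] = 140.0 * (np.sum(wt) - 200 * 140.0 + 200 * 100.0) / np.sum(wt)
        # simpler: equalize library sizes so per-million scaling is equal
        wt = np.full(L, 100.0)
        ko = np.full(L, 100.0)
        wt[100:300] = 140.0
        ko[100:300] = 100.0
        extra = (140.0 - 100.0) * 200 / (L - 200)
        ko[np.r_[0:100, 300:L]] += extra  # equal totals -> equal per-million scale
        calls = classify_reduced(
            [peak],
            [CoverageTrack({"chr1": wt})],
            [CoverageTrack({"chr1": ko})],
            ReductionConfig(composition_normalize=False),
        )
        assert calls[0].fold_change == pytest.approx(1.4, rel=1e-9)
        assert calls[0].is_reduced

    def test_equal_signal_not_reduced(self):
        peak = Peak(interval=GenomicInterval("chr1", 100, 300), summit=200, name="p1")
        wt = flat_tracks(100)
        ko = flat_tracks(100)
        calls = classify_reduced([peak], wt, ko, ReductionConfig(composition_normalize=False))
        assert calls[0].fold_change == pytest.approx(1.0)
        assert not calls[0].is_reduced

    def test_scale_invariance(self, rng):
        peaks = [
            Peak(interval=GenomicInterval("chr1", s, s + 200), summit=s + 100, name=f"p{s}")
            for s in range(100, 8000, 400)
        ]
        base = rng.poisson(50.0, 10_000).astype(float) + 1
        wt = [CoverageTrack({"chr1": base * rng.uniform(0.9, 1.1, 10_000)}) for _ in range(2)]
        ko = [CoverageTrack({"chr1": base * rng.uniform(0.9, 1.1, 10_000)}) for _ in range(2)]
        c1 = classify_reduced(peaks, wt, ko)
        wt3 = [CoverageTrack({"chr1": t.depths["chr1"] * 3.0}) for t in wt]
        ko3 = [CoverageTrack({"chr1": t.depths["chr1"] * 3.0}) for t in ko]
        c2 = classify_reduced(peaks, wt3, ko3)
        for x, y in zip(c1, c2):
            assert x.fold_change == pytest.approx(y.fold_change, rel=1e-9)
            assert x.is_reduced == y.is_reduced

    def test_no_replicates_is_error(self):
        peak = Peak(interval=GenomicInterval("chr1", 0, 10), summit=5)
        with pytest.raises(ValidationError):
            classify_reduced([peak], [], flat_tracks(10))

    def test_null_reduction_flags_below_nominal_rate(self):
        """With reduction_factor = 1 the flagged fraction stays below the
        nominal false-positive rate."""
        cfg = SimulationConfig(seed=33, genome_length=600_000, n_genes=90,
                               n_planted_rna_peaks=90, reduction_factor=1.0)
        genome, ts = simulate_genome(cfg)
        h = simulate_hmerip(cfg, ts, genome)
        peaks, assignment = [], {}
        for i, r in enumerate(h.truth):
            p = Peak(
                interval=GenomicInterval(r.chrom, r.summit - 147, r.summit + 147),
                summit=r.summit, name=f"p{i}",
            )
            peaks.append(p)
            assignment[p.name] = r.transcript_id
        calls = classify_reduced(peaks, h.wt_ip, h.ko_ip, assignment=assignment)
        summary = transcript_reduction_summary(calls)
        assert summary["reduced_fraction"] <= 0.05


class TestTranscriptSummary:
    def make_call(self, tid, reduced, pid="p"):
        from epitet.hmerip import ReducedPeakCall

        return ReducedPeakCall(
            peak_id=pid, transcript_id=tid, wt_signal=1.0, ko_signal=1.0,
            fold_change=2.0 if reduced else 1.0, is_reduced=reduced, pvalue=0.5,
        )

    def test_no_reduced_peaks(self):
        calls = [self.make_call(f"t{i}", False, f"p{i}") for i in range(5)]
        assert transcript_reduction_summary(calls)["reduced_fraction"] == 0.0

    def test_every_transcript_reduced(self):
        calls = [self.make_call(f"t{i}", True, f"p{i}") for i in range(5)]
        assert transcript_reduction_summary(calls)["reduced_fraction"] == 1.0

    def test_any_reduced_peak_flags_transcript(self):
        calls = [
            self.make_call("t1", False, "a"),
            self.make_call("t1", True, "b"),
            self.make_call("t2", False, "c"),
        ]
        out = transcript_reduction_summary(calls)
        assert out["per_transcript"] == {"t1": True, "t2": False}
        assert out["reduced_fraction"] == 0.5

    def test_element_fractions_reported(self):
        calls = [
            self.make_call("t1", True, "a"),
            self.make_call("t2", False, "b"),
        ]
        out = transcript_reduction_summary(calls, {"a": "CDS", "b": "CDS"})
        assert out["element_reduction_fraction"]["CDS"] == 0.5
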