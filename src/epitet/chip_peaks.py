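"""Poisson local-background peak calling and replicate reproducibility.

The caller compares, at every position, the IP read count within an
extension-size window against the expected count under a local Poisson
background estimated from the input track (the larger of the genome-wide
rate and 1 kb / 10 kb local window rates, MACS-style "local lambda").
Candidate positions below a permissive p-value threshold are merged into
regions; each region yields one peak with its summit (argmax of raw IP
depth, leftmost on ties), a summit p-value, fold enrichment over the
local background at the summit, and the peak's whole-interval read count.

Two filter/selection dialects are provided:

* ``embryo`` — candidate p < 1e-2, effective genome size 1.2e8; peaks are
  then filtered downstream by (p < 1e-5, fold enrichment > 10, reads > 50).
* ``larva``  — Benjamini-Hochberg q < 0.05 over candidate peaks and each
  peak resized to summit +/- 100 bp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core_model import CoverageTrack, GenomicInterval, Peak, ValidationError


@dataclass
class PeakCallConfig:
    dialect: str = "embryo"
    candidate_pvalue: float = 1e-2
    effective_genome_size: float = 1.2e8  # larva: 142_573_024
    ext_size: int = 147
    local_windows: tuple[int, ...] = (1000, 10000)
    larva_q_threshold: float = 0.05
    summit_flank: int = 100  # larva resize: summit +/- 100 bp

    def __post_init__(self):
        if self.dialect not in ("embryo", "larva"):
            raise ValidationError(f"unknown dialect {self.dialect!r}")
        if not 0 < self.candidate_pvalue < 1:
            raise ValidationError("candidate_pvalue must be in (0, 1)")
        if self.ext_size <= 0:
            raise ValidationError("ext_size must be > 0")


EMBRYO_CONFIG = PeakCallConfig(dialect="embryo", effective_genome_size=1.2e8)
LARVA_CONFIG = PeakCallConfig(dialect="larva", effective_genome_size=142_573_024)


@dataclass
class FilterCriteria:
    """Peak selection thresholds; fold-enrichment and read comparisons are
    strict (greater-than)."""

    max_pvalue: float = 1e-5
    min_fold_enrichment: float = 10.0
    min_reads: float = 50.0

    def __post_init__(self):
        if not 0 < self.max_pvalue < 1:
            raise ValidationError("max_pvalue must be in (0, 1)")
        if self.min_fold_enrichment <= 0 or self.min_reads <= 0:
            raise ValidationError("thresholds must be > 0")


@dataclass
class SaturationCurve:
    windows: list[int]
    counts: list[int]
    selected: int
    rel_tolerance: float = 0.02


def poisson_enrichment_pvalue(k, lam) -> float:
    """Upper-tail Poisson probability P(X >= k) for X ~ Poisson(lam).

    Monotone decreasing in k and increasing in lam. Vectorized.
    """
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr <= 0):
        raise ValidationError("lam must be > 0")
    k_arr = np.asarray(k)
    if np.any(k_arr < 0):
        raise ValidationError("k must be >= 0")
    out = stats.poisson.sf(np.asarray(k_arr, dtype=float) - 1.0, lam_arr)
    if np.isscalar(k) and np.isscalar(lam):
        return float(out)
    return out


def _rolling_sum(v: np.ndarray, w: int) -> np.ndarray:
    """Centered rolling sum with zero padding outside the array."""
    cum = np.concatenate([[0.0], np.cumsum(v)])
    idx = np.arange(len(v))
    lo = np.clip(idx - w // 2, 0, len(v))
    hi = np.clip(idx + (w - w // 2), 0, len(v))
    return cum[hi] - cum[lo]


def _rolling_mean(v: np.ndarray, w: int) -> np.ndarray:
    cum = np.concatenate([[0.0], np.cumsum(v)])
    idx = np.arange(len(v))
    lo = np.clip(idx - w // 2, 0, len(v))
    hi = np.clip(idx + (w - w // 2), 0, len(v))
    return (cum[hi] - cum[lo]) / np.maximum(hi - lo, 1)


def _background_scale(ip: CoverageTrack, input_track: CoverageTrack, bin_size: int = 1000) -> float:
    """Input-to-IP scaling factor from the ratio of median binned counts.

    Total-count scaling overestimates the background when a substantial
    fraction of the IP library sits in enriched regions; the median bin
    is background-dominated (SES-style scaling to background)."""
    ip_meds, in_meds = [], []
    for chrom in ip.depths:
        v, w = ip.depths[chrom], input_track.depths[chrom]
        n = (len(v) // bin_size) * bin_size
        if n >= bin_size:
            ip_meds.append(np.median(v[:n].reshape(-1, bin_size).sum(axis=1)))
            in_meds.append(np.median(w[:n].reshape(-1, bin_size).sum(axis=1)))
    ip_med, in_med = float(np.sum(ip_meds)), float(np.sum(in_meds))
    if ip_med > 0 and in_med > 0:
        return ip_med / in_med
    return ip.library_size / input_track.library_size


def call_peaks(
    ip: CoverageTrack,
    input_track: CoverageTrack,
    config: Optional[PeakCallConfig] = None,
    sample_id: Optional[str] = None,
) -> list[Peak]:
    """Call enriched regions of ``ip`` over ``input_track``.

    Returns candidate peaks (embryo dialect: everything below the
    permissive candidate p-value — apply :func:`apply_peak_filters` for
    the final selection; larva dialect: BH q < threshold, resized to
    summit +/- summit_flank).
    """
    config = config or PeakCallConfig()
    if ip.chrom_sizes != input_track.chrom_sizes:
        raise ValidationError("IP and input chromosome sizes differ")
    if input_track.library_size <= 0:
        raise ValidationError("input library size is zero")
    if ip.library_size <= 0:
        warnings.warn("empty IP coverage; returning no peaks")
        return []

    scale = _background_scale(ip, input_track)
    rl = ip.read_length
    ext = config.ext_size
    peaks: list[Peak] = []

    for chrom in sorted(ip.depths):
        ipv = ip.depths[chrom]
        inv = input_track.depths[chrom] * scale
        if len(ipv) == 0:
            continue
        # expected background rate per base: max of genome-wide and local
        # window estimates from the scaled input
        rate = np.full(len(inv), float(inv.mean()))
        for w in config.local_windows:
            rate = np.maximum(rate, _rolling_mean(inv, w))
        rate = np.maximum(rate, 1e-9)

        # window-integrated counts in read units
        k = _rolling_sum(ipv, ext) / rl
        lam = rate * ext / rl
        pvals = stats.poisson.sf(np.round(k) - 1.0, lam)

        cand = pvals < config.candidate_pvalue
        if not cand.any():
            continue
        # merge candidate positions closer than ext into regions
        pos = np.flatnonzero(cand)
        breaks = np.flatnonzero(np.diff(pos) >= ext)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for si, ei in zip(starts, ends):
            a, b = int(pos[si]), int(pos[ei]) + 1
            region = ipv[a:b]
            summit = a + int(np.argmax(region))  # argmax is leftmost tie
            pvalue = float(min(max(pvals[summit], 5e-324), 1.0))
            fe = float(ipv[summit] / rate[summit])
            reads = float(ipv[a:b].sum() / rl)
            score = float(min(-10.0 * np.log10(pvalue), 3230.0))
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, a, b),
                    summit=summit,
                    score=score,
                    pvalue=pvalue,
                    fold_enrichment=fe,
                    reads=reads,
                    sample_id=sample_id or ip.sample_id,
                )
            )

    if config.dialect == "larva" and peaks:
        pv = np.array([p.pvalue for p in peaks])
        qv = stats.false_discovery_control(pv, method="bh")
        kept = []
        for p, q in zip(peaks, qv):
            if q < config.larva_q_threshold:
                size = len(ip.depths[p.chrom])
                s = max(0, p.summit - config.summit_flank)
                e = min(size, p.summit + config.summit_flank)
                kept.append(
                    Peak(
                        interval=GenomicInterval(p.chrom, s, e),
                        summit=p.summit,
                        score=p.score,
                        pvalue=p.pvalue,
                        fold_enrichment=p.fold_enrichment,
                        reads=p.reads,
                        sample_id=p.sample_id,
                    )
                )
        peaks = kept
    return peaks


def apply_peak_filters(
    peaks: Sequence[Peak], criteria: Optional[FilterCriteria] = None
) -> list[Peak]:
    """Retain peaks with pvalue < max_pvalue AND fold_enrichment >
    min_fold_enrichment AND reads > min_reads (both strict)."""
    criteria = criteria or FilterCriteria()
    out = []
    for i, p in enumerate(peaks):
        for f in ("pvalue", "fold_enrichment", "reads"):
            if getattr(p, f) is None:
                raise ValidationError(
                    f"peak #{i} ({p.chrom}:{p.interval.start}-{p.interval.end}) "
                    f"is missing {f}"
                )
        if (
            p.pvalue < criteria.max_pvalue
            and p.fold_enrichment > criteria.min_fold_enrichment
            and p.reads > criteria.min_reads
        ):
            out.append(p)
    return out


def _match_pairs(
    peaks_a: Sequence[Peak], peaks_b: Sequence[Peak], w: int
) -> list[tuple[int, int]]:
    """Greedy one-to-one summit matching: all A-B same-chromosome pairs
    with |summit distance| <= w, taken in ascending distance (ties by
    leftmost A then leftmost B), each peak used at most once.

    Because increasing w only appends farther pairs to the candidate
    list, the matching size is non-decreasing in w.
    """
    pairs = []
    for i, a in enumerate(peaks_a):
        for j, b in enumerate(peaks_b):
            if a.chrom != b.chrom:
                continue
            d = abs(a.summit - b.summit)
            if d <= w:
                pairs.append((d, a.summit, b.summit, i, j))
    pairs.sort()
    used_a, used_b, out = set(), set(), []
    for _, _, _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        out.append((i, j))
    return out


def overlap_at_window(
    peaks_a: Sequence[Peak], peaks_b: Sequence[Peak], w: int
) -> list[Peak]:
    """Peaks of A reproducible in B: matched one-to-one to a B peak whose
    summit lies within ``w`` bp (w = maximum summit-to-summit distance)."""
    if w < 0:
        raise ValidationError("window must be >= 0")
    matched = {i for i, _ in _match_pairs(peaks_a, peaks_b, w)}
    return [p for i, p in enumerate(peaks_a) if i in matched]


def saturation_analysis(
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    windows: Sequence[int] = (50, 100, 150, 200, 250, 300),
    rel_tolerance: float = 0.02,
) -> SaturationCurve:
    """Reproducible-peak count per window; the selected window is the
    smallest whose count is within ``rel_tolerance`` of the count at the
    largest window."""
    windows = sorted(windows)
    if len(windows) < 2:
        raise ValidationError("need >= 2 windows")
    counts = [len(overlap_at_window(peaks_a, peaks_b, w)) for w in windows]
    for c0, c1 in zip(counts, counts[1:]):
        assert c1 >= c0, "overlap counts must be non-decreasing in window size"
    final = counts[-1]
    selected = windows[-1]
    for w, c in zip(windows, counts):
        if final == 0 or (final - c) / final <= rel_tolerance:
            selected = w
            break
    return SaturationCurve(
        windows=list(windows), counts=counts, selected=selected,
        rel_tolerance=rel_tolerance,
    )


def multi_replicate_consensus(
    peaksets: Sequence[Sequence[Peak]], w: int = 250
) -> list[Peak]:
    """Peaks of the first replicate reproducible against every other
    replicate at window ``w``; consensus summit = first-replicate summit."""
    if len(peaksets) < 2:
        raise ValidationError("need >= 2 peak sets for a consensus")
    keep = list(peaksets[0])
    for other in peaksets[1:]:
        keep = overlap_at_window(keep, other, w)
        if not keep:
            break
    return keep
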