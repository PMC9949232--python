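"""Peak annotation, feature distributions and metagene profiles.

Peaks are assigned to exactly one genomic feature class by their summit
position, with the priority

    promoter-TSS > TTS > 5'UTR > 3'UTR > exon > intron > intergenic

(a base that is both exonic and UTR is the UTR). The promoter window
defaults to TSS -1000..+100 bp and the TTS window to +/-100 bp, both
strand-aware and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core_model import (
    CoverageTrack,
    GenomicInterval,
    Peak,
    Transcript,
    ValidationError,
    interval_overlap,
)

FEATURE_CLASSES = (
    "promoter-TSS",
    "TTS",
    "5UTR",
    "3UTR",
    "exon",
    "intron",
    "intergenic",
)


def promoter_interval(t: Transcript, upstream: int = 1000, downstream: int = 100) -> GenomicInterval:
    """Strand-aware promoter window around the TSS."""
    if t.strand != "-":
        s, e = t.tss - upstream, t.tss + downstream
    else:
        s, e = t.tss - downstream + 1, t.tss + upstream + 1
    return GenomicInterval(t.interval.chrom, max(0, s), max(1, e), t.strand)


def tts_interval(t: Transcript, flank: int = 100) -> GenomicInterval:
    return GenomicInterval(
        t.interval.chrom, max(0, t.tts - flank), t.tts + flank + 1, t.strand
    )


def transcript_elements(t: Transcript) -> dict[str, list[GenomicInterval]]:
    """Partition a transcript span into 5'UTR / CDS / intron / 3'UTR.

    Introns are the non-exonic gaps. Exonic bases 5' of the CDS are the
    5'UTR, 3' of it the 3'UTR (strand-aware). For transcripts without a
    CDS the exonic bases 5' of the span midpoint are treated as 5'UTR and
    the rest as 3'UTR.
    """
    chrom = t.interval.chrom
    out: dict[str, list[GenomicInterval]] = {"5UTR": [], "CDS": [], "intron": [], "3UTR": []}
    for a, b in zip(t.exons, t.exons[1:]):
        if a.end < b.start:
            out["intron"].append(GenomicInterval(chrom, a.end, b.start, t.strand))
    span = t.cds_span
    if span is None:
        mid = (t.interval.start + t.interval.end) // 2
        lo_label, hi_label = ("5UTR", "3UTR") if t.strand != "-" else ("3UTR", "5UTR")
        for e in t.exons:
            if e.end <= mid:
                out[lo_label].append(e)
            elif e.start >= mid:
                out[hi_label].append(e)
            else:
                out[lo_label].append(GenomicInterval(chrom, e.start, mid, t.strand))
                out[hi_label].append(GenomicInterval(chrom, mid, e.end, t.strand))
        return out
    lo_label, hi_label = ("5UTR", "3UTR") if t.strand != "-" else ("3UTR", "5UTR")
    for e in t.exons:
        lo, hi = max(e.start, span.start), min(e.end, span.end)
        if lo < hi:
            out["CDS"].append(GenomicInterval(chrom, lo, hi, t.strand))
        if e.start < span.start:
            out[lo_label].append(
                GenomicInterval(chrom, e.start, min(e.end, span.start), t.strand)
            )
        if e.end > span.end:
            out[hi_label].append(
                GenomicInterval(chrom, max(e.start, span.end), e.end, t.strand)
            )
    return out


class FeatureIndex:
    """Interval trees per feature class plus a TSS index for nearest-gene
    lookup. Intergenic is the implicit complement of all other classes."""

    def __init__(
        self,
        transcripts: Sequence[Transcript],
        promoter_upstream: int = 1000,
        promoter_downstream: int = 100,
        tts_flank: int = 100,
    ):
        if not transcripts:
            raise ValidationError("FeatureIndex needs >= 1 transcript")
        self.promoter_upstream = promoter_upstream
        self.promoter_downstream = promoter_downstream
        self.tts_flank = tts_flank
        self.trees: dict[str, dict[str, IntervalTree]] = {
            c: {} for c in FEATURE_CLASSES if c != "intergenic"
        }
        self._tss: dict[str, tuple[np.ndarray, list[str]]] = {}
        tss_rows: dict[str, list[tuple[int, str]]] = {}
        for t in transcripts:
            chrom = t.interval.chrom
            self._add(chrom, "promoter-TSS", promoter_interval(t, promoter_upstream, promoter_downstream), t)
            self._add(chrom, "TTS", tts_interval(t, tts_flank), t)
            elems = transcript_elements(t)
            for name in ("5UTR", "3UTR"):
                for iv in elems[name]:
                    self._add(chrom, name, iv, t)
            for e in t.exons:
                self._add(chrom, "exon", e, t)
            for iv in elems["intron"]:
                self._add(chrom, "intron", iv, t)
            tss_rows.setdefault(chrom, []).append((t.tss, t.gene_id))
        for chrom, rows in tss_rows.items():
            rows.sort()
            self._tss[chrom] = (
                np.array([p for p, _ in rows]),
                [g for _, g in rows],
            )

    def _add(self, chrom: str, cls: str, iv: GenomicInterval, t: Transcript) -> None:
        self.trees[cls].setdefault(chrom, IntervalTree()).addi(iv.start, iv.end, t.id)

    def class_at(self, chrom: str, pos: int) -> str:
        for cls in FEATURE_CLASSES[:-1]:
            tree = self.trees[cls].get(chrom)
            if tree is not None and tree.overlaps(pos):
                return cls
        return "intergenic"

    def nearest_gene(self, chrom: str, pos: int) -> Optional[str]:
        if chrom not in self._tss:
            return None
        positions, genes = self._tss[chrom]
        i = int(np.searchsorted(positions, pos))
        best, best_d = None, None
        for j in (i - 1, i):
            if 0 <= j < len(positions):
                d = abs(int(positions[j]) - pos)
                if best_d is None or d < best_d:
                    best, best_d = genes[j], d
        return best


def annotate_peak(peak: Peak, index: FeatureIndex) -> tuple[str, Optional[str]]:
    """Feature class of the summit plus the gene with the nearest TSS."""
    if peak.summit < 0:
        raise ValidationError(f"summit {peak.summit} outside genome")
    cls = index.class_at(peak.chrom, peak.summit)
    return cls, index.nearest_gene(peak.chrom, peak.summit)


def feature_distribution(peaks: Sequence[Peak], index: FeatureIndex) -> pd.Series:
    """Fraction of peaks per feature class (sums to 1)."""
    if not peaks:
        raise ValidationError("feature_distribution needs >= 1 peak")
    counts = {c: 0 for c in FEATURE_CLASSES}
    for p in peaks:
        counts[annotate_peak(p, index)[0]] += 1
    s = pd.Series(counts, dtype=float)
    return s / s.sum()


def score_by_region(peaks: Sequence[Peak], index: FeatureIndex) -> pd.DataFrame:
    """Per-feature-class summary (count, mean, quartiles) of peak scores."""
    rows = []
    for p in peaks:
        if p.score is None:
            continue
        rows.append({"feature": annotate_peak(p, index)[0], "score": p.score})
    if not rows:
        return pd.DataFrame(
            columns=["count", "mean", "q25", "median", "q75"]
        ).rename_axis("feature")
    df = pd.DataFrame(rows)
    g = df.groupby("feature")["score"]
    out = pd.DataFrame(
        {
            "count": g.count(),
            "mean": g.mean(),
            "q25": g.quantile(0.25),
            "median": g.median(),
            "q75": g.quantile(0.75),
        }
    )
    return out


def colocalization_fraction(
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    min_overlap: int = 1,
    index: Optional[FeatureIndex] = None,
) -> dict[str, float]:
    """Fraction of A peaks overlapping any B peak by >= min_overlap bases.

    With a FeatureIndex, also reports the fraction among the
    promoter-annotated subset of A (the promoter-restricted readout).
    """
    if not peaks_a:
        raise ValidationError("colocalization_fraction needs >= 1 A peak")
    trees: dict[str, IntervalTree] = {}
    for b in peaks_b:
        trees.setdefault(b.chrom, IntervalTree()).addi(b.interval.start, b.interval.end)

    def hits(p: Peak) -> bool:
        tree = trees.get(p.chrom)
        if tree is None:
            return False
        for h in tree.overlap(p.interval.start, p.interval.end):
            if min(h.end, p.interval.end) - max(h.begin, p.interval.start) >= min_overlap:
                return True
        return False

    flags = [hits(p) for p in peaks_a]
    out = {"fraction": float(np.mean(flags)), "n": len(peaks_a)}
    if index is not None:
        prom = [
            f for p, f in zip(peaks_a, flags)
            if annotate_peak(p, index)[0] == "promoter-TSS"
        ]
        out["promoter_fraction"] = float(np.mean(prom)) if prom else float("nan")
        out["n_promoter"] = len(prom)
    return out


# ---------------------------------------------------------------------------
# metagene
# ---------------------------------------------------------------------------

@dataclass
class MetageneMatrix:
    matrix: np.ndarray  # transcripts x (flank_bins + body_bins + flank_bins)
    transcript_ids: list[str]
    flank: int
    flank_bin: int
    body_bins: int

    @property
    def flank_bins(self) -> int:
        return self.flank // self.flank_bin

    def mean_profile(self) -> np.ndarray:
        # bins entirely outside the genome (flanks running off a
        # chromosome end) are missing, not zero
        return np.nanmean(self.matrix, axis=0)


def _integral(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    cum = np.concatenate([[0.0], np.cumsum(values)])
    x = np.arange(len(cum), dtype=float)
    return np.diff(np.interp(edges, x, cum))


def _bin_means(values: np.ndarray, weights: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Weighted mean of a per-base step function between fractional edges,
    from exact integrals (linear interpolation of cumulative sums).
    ``weights`` is 1 over real genome bases and 0 over padding, so bases
    outside the chromosome do not dilute the mean; a bin with zero weight
    is NaN. Regions shorter than the number of bins are handled by
    construction (fractional edges interpolate)."""
    num = _integral(values, edges)
    den = _integral(weights, edges)
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)


def metagene_profile(
    track: CoverageTrack,
    transcripts: Sequence[Transcript],
    flank: int = 5000,
    flank_bin: int = 100,
    body_bins: int = 100,
) -> MetageneMatrix:
    """Library-normalized coverage over scaled gene bodies +/- fixed flanks.

    Each row is one transcript: upstream flank (fixed-size bins), body
    rescaled to ``body_bins``, downstream flank. Minus-strand rows are
    reversed so the axis always runs 5' -> 3'. Coverage is scaled to
    per-million mapped reads; flank positions beyond chromosome ends are
    treated as missing (excluded from bin means), not as zero coverage.
    """
    if not transcripts:
        raise ValidationError("metagene_profile needs transcripts")
    if flank < 0 or flank_bin <= 0 or body_bins <= 0:
        raise ValidationError("flank, flank_bin and body_bins must be positive")
    norm = track.per_million()
    fb = flank // flank_bin
    rows, ids = [], []
    for t in sorted(transcripts, key=lambda t: (t.interval.chrom, t.interval.start, t.id)):
        v = norm.depths.get(t.interval.chrom)
        if v is None:
            continue
        s, e = t.interval.start, t.interval.end
        padded = np.concatenate([np.zeros(flank), v, np.zeros(flank)])
        weights = np.concatenate([np.zeros(flank), np.ones(len(v)), np.zeros(flank)])
        off = flank  # index of chromosome base 0 in `padded`
        up = _bin_means(
            padded, weights, np.linspace(off + s - flank, off + s, fb + 1)
        ) if fb else np.empty(0)
        body = _bin_means(padded, weights, np.linspace(off + s, off + e, body_bins + 1))
        down = _bin_means(
            padded, weights, np.linspace(off + e, off + e + flank, fb + 1)
        ) if fb else np.empty(0)
        row = np.concatenate([up, body, down])
        if t.strand == "-":
            row = row[::-1]
        rows.append(row)
        ids.append(t.id)
    return MetageneMatrix(
        matrix=np.vstack(rows), transcript_ids=ids,
        flank=flank, flank_bin=flank_bin, body_bins=body_bins,
    )
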