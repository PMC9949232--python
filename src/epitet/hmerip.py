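"""5hmrC RNA-modification peak analysis.

Peak calling reuses the Poisson window machinery of :mod:`.chip_peaks`,
restricted to transcript footprints and with the background additionally
floored at each transcript's own mean input rate — this controls for
expression level, so a highly expressed transcript is not called
"modified" merely for being abundant.

Wild-type vs Tet-null reduction is classified per peak on normalized
per-million coverage, with a composition-robust median-ratio correction
(see :func:`classify_reduced`), and a transcript is "reduced" when at
least one of its peaks is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chip_peaks import PeakCallConfig, call_peaks
from .core_model import CoverageTrack, GenomicInterval, Peak, Transcript, ValidationError
from .genomic_context import transcript_elements

RNA_ELEMENTS = ("5UTR", "CDS", "intron", "3UTR")


@dataclass
class ReductionConfig:
    fold_threshold: float = 1.4  # inclusive: fold >= threshold is reduced
    ko_pseudocount: float = 0.5  # per-million floor on the Tet-null signal
    composition_normalize: bool = True

    def __post_init__(self):
        if self.fold_threshold <= 1.0:
            raise ValidationError("fold_threshold must be > 1")


@dataclass
class ReducedPeakCall:
    peak_id: str
    transcript_id: Optional[str]
    wt_signal: float
    ko_signal: float
    fold_change: float
    is_reduced: bool
    pvalue: float


@dataclass
class ElementDistribution:
    counts: pd.Series
    fractions: pd.Series
    expected: Optional[pd.Series] = None
    chi2: Optional[float] = None
    pvalue: Optional[float] = None


def _transcript_lookup(transcripts: Sequence[Transcript]):
    spans = sorted(transcripts, key=lambda t: (t.interval.chrom, t.interval.start))
    return spans


def _host_transcript(
    summit: int, chrom: str, transcripts: Sequence[Transcript]
) -> Optional[Transcript]:
    for t in transcripts:
        if t.interval.chrom == chrom and t.interval.contains(summit):
            return t
    return None


def call_rna_peaks(
    ip: CoverageTrack,
    input_track: CoverageTrack,
    transcripts: Sequence[Transcript],
    p_threshold: float = 1e-5,
    config: Optional[PeakCallConfig] = None,
) -> tuple[list[Peak], dict[str, str]]:
    """Poisson IP-vs-input peaks restricted to transcript footprints.

    Returns (peaks, assignment) where assignment maps a peak name to its
    host transcript id. Peaks whose summit falls outside every transcript
    are excluded (they cannot enter element analysis) and counted under
    the ``"unassigned"`` key of the assignment map.
    """
    config = config or PeakCallConfig()
    if not transcripts:
        raise ValidationError("call_rna_peaks needs transcripts")

    # mask IP coverage to transcript footprints and floor the input rate
    # at each transcript's own mean (expression control); scaling to the
    # IP library size happens once, inside call_peaks
    ip_masked: dict[str, np.ndarray] = {}
    in_floored: dict[str, np.ndarray] = {}
    for chrom, v in ip.depths.items():
        mask = np.zeros(len(v), dtype=bool)
        inv = input_track.depths[chrom]
        floored = inv.copy()
        for t in transcripts:
            if t.interval.chrom != chrom:
                continue
            s, e = t.interval.start, t.interval.end
            mask[s:e] = True
            floored[s:e] = np.maximum(floored[s:e], inv[s:e].mean())
        ip_masked[chrom] = np.where(mask, v, 0.0)
        in_floored[chrom] = np.where(mask, floored, inv)

    ip2 = CoverageTrack(ip_masked, ip.read_length, ip.sample_id)
    in2 = CoverageTrack(in_floored, input_track.read_length, input_track.sample_id)
    candidates = call_peaks(ip2, in2, config, sample_id=ip.sample_id)

    peaks, assignment = [], {}
    n_unassigned = 0
    spans = _transcript_lookup(transcripts)
    for i, p in enumerate(candidates):
        if p.pvalue >= p_threshold:
            continue
        host = _host_transcript(p.summit, p.chrom, spans)
        if host is None:
            n_unassigned += 1
            continue
        named = Peak(
            interval=p.interval, summit=p.summit, score=p.score,
            pvalue=p.pvalue, fold_enrichment=p.fold_enrichment,
            reads=p.reads, sample_id=p.sample_id,
            name=f"rna_peak_{len(peaks) + 1}",
        )
        peaks.append(named)
        assignment[named.name] = host.id
    if n_unassigned:
        assignment["unassigned"] = str(n_unassigned)
    return peaks, assignment


def peak_element(
    summit: int, t: Transcript
) -> str:
    """Element class of a summit within its transcript: CDS/UTRs by exact
    CDS boundaries, intron = non-exonic transcript span."""
    elems = transcript_elements(t)
    for name in ("CDS", "5UTR", "3UTR"):
        for iv in elems[name]:
            if iv.contains(summit):
                return name
    return "intron"


def element_distribution(
    peaks: Sequence[Peak],
    assignment: Mapping[str, str],
    transcripts: Sequence[Transcript],
    expected: Optional[pd.Series] = None,
) -> ElementDistribution:
    """Observed element fractions of transcript-assigned peaks, with an
    optional chi-square comparison against expected fractions."""
    tmap = {t.id: t for t in transcripts}
    counts = {e: 0 for e in RNA_ELEMENTS}
    for p in peaks:
        tid = assignment.get(p.name)
        if tid is None or tid not in tmap:
            continue
        counts[peak_element(p.summit, tmap[tid])] += 1
    cs = pd.Series(counts, dtype=float)
    total = cs.sum()
    if total == 0:
        raise ValidationError("no assigned peaks")
    fr = cs / total
    chi2 = pv = None
    if expected is not None:
        expected = expected.reindex(list(RNA_ELEMENTS)).fillna(0.0)
        keep = expected > 0
        chi2_stat, pv = stats.chisquare(
            cs[keep], f_exp=expected[keep] / expected[keep].sum() * cs[keep].sum()
        )
        chi2 = float(chi2_stat)
        pv = float(pv)
    return ElementDistribution(counts=cs.astype(int), fractions=fr, expected=expected, chi2=chi2, pvalue=pv)


def expected_element_distribution(
    transcripts: Sequence[Transcript],
    model: str = "monte_carlo_uniform",
    n_iter: int = 10_000,
    seed: int = 0,
) -> pd.Series:
    """Expected element fractions under uniform peak placement.

    ``length_proportional`` is the closed form (element length totals over
    transcript length totals); ``monte_carlo_uniform`` places ``n_iter``
    pseudo-peaks uniformly over concatenated transcript bases and tallies.
    """
    if model not in ("length_proportional", "monte_carlo_uniform"):
        raise ValidationError(f"unknown model {model!r}")
    if not transcripts:
        raise ValidationError("needs transcripts")
    lens = {e: 0 for e in RNA_ELEMENTS}
    per_t = []
    for t in transcripts:
        elems = transcript_elements(t)
        row = {e: sum(len(iv) for iv in elems[e]) for e in RNA_ELEMENTS}
        per_t.append((t, row))
        for e in RNA_ELEMENTS:
            lens[e] += row[e]
    total = sum(lens.values())
    if model == "length_proportional":
        return pd.Series({e: lens[e] / total for e in RNA_ELEMENTS})
    if n_iter < 1000:
        import warnings

        warnings.warn("n_iter < 1000 gives a noisy Monte-Carlo expectation")
    rng = np.random.default_rng(seed)
    t_lens = np.array([sum(r.values()) for _, r in per_t], dtype=float)
    counts = {e: 0 for e in RNA_ELEMENTS}
    choices = rng.choice(len(per_t), size=n_iter, p=t_lens / t_lens.sum())
    for i in choices:
        _, row = per_t[i]
        # position uniform within the transcript: element by cumulative length
        u = rng.integers(0, int(t_lens[i]))
        acc = 0
        for e in RNA_ELEMENTS:
            acc += row[e]
            if u < acc:
                counts[e] += 1
                break
    s = pd.Series(counts, dtype=float)
    return s / s.sum()


def abundance_stratification(
    modified_transcripts: set[str],
    expression: Mapping[str, float],
    n_bins: int = 10,
) -> dict:
    """Transcript counts per expression bin (quantile bins), overall and
    modified-only, plus the rank correlation between modification status
    and expression."""
    tids = sorted(expression)
    levels = np.array([expression[t] for t in tids])
    flags = np.array([t in modified_transcripts for t in tids])
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    qs = np.quantile(levels, np.linspace(0, 1, n_bins + 1))
    qs[0], qs[-1] = -np.inf, np.inf
    bins = np.clip(np.searchsorted(qs, levels, side="right") - 1, 0, n_bins - 1)
    table = pd.DataFrame(
        {
            "bin": range(n_bins),
            "all": [int((bins == b).sum()) for b in range(n_bins)],
            "modified": [int(((bins == b) & flags).sum()) for b in range(n_bins)],
        }
    )
    if flags.all() or not flags.any():
        rho, pv = 0.0, 1.0
    else:
        rho, pv = stats.spearmanr(flags.astype(float), levels)
    return {"table": table, "rank_correlation": float(rho), "pvalue": float(pv)}


def _peak_signal(peak: Peak, track: CoverageTrack, lib: float) -> float:
    """Mean per-million coverage over the peak interval."""
    v = track.depths[peak.chrom]
    s, e = peak.interval.start, peak.interval.end
    return float(v[s:e].mean() * 1e6 / lib)


def _mode_correction(folds: np.ndarray) -> float:
    """Compositional correction factor: the mode of the log2 fold-change
    distribution (Gaussian KDE), i.e. the most common fold, which under
    the usual "the typical peak is unchanged" assumption estimates the
    library-composition bias. More robust than the median when a large
    minority of peaks genuinely changes in one direction."""
    lf = np.log2(folds[np.isfinite(folds) & (folds > 0)])
    if len(lf) < 20 or np.allclose(lf.std(), 0):
        return float(np.median(folds)) if len(lf) else 1.0
    kde = stats.gaussian_kde(lf)
    grid = np.linspace(lf.min(), lf.max(), 512)
    return float(2.0 ** grid[int(np.argmax(kde(grid)))])


def classify_reduced(
    peaks: Sequence[Peak],
    wt_tracks: Sequence[CoverageTrack],
    ko_tracks: Sequence[CoverageTrack],
    config: Optional[ReductionConfig] = None,
    assignment: Optional[Mapping[str, str]] = None,
) -> list[ReducedPeakCall]:
    """Per-peak wild-type vs Tet-null reduction calls.

    Signal = mean per-million coverage over the peak interval, averaged
    across replicates. When ``composition_normalize`` is on, fold changes
    are divided by the mode of the fold distribution across peaks before
    thresholding: global library scaling assumes equal total signal, which
    is violated when a large fraction of peaks genuinely loses signal in
    the Tet-null sample; anchoring on the most common fold (the unchanged
    component) removes that compositional bias. A peak is reduced when
    the corrected wt/ko fold change is >= the threshold (inclusive,
    default 1.4). The p-value is a two-sample t on replicate-level signals
    with the variance shrunk toward the mean variance across peaks
    (moderated-t style).
    """
    config = config or ReductionConfig()
    if not wt_tracks or not ko_tracks:
        raise ValidationError("need >= 1 replicate per genotype")
    if not peaks:
        return []
    wt_libs = [tr.library_size for tr in wt_tracks]
    ko_libs = [tr.library_size for tr in ko_tracks]
    wt = np.array(
        [[_peak_signal(p, tr, lib) for tr, lib in zip(wt_tracks, wt_libs)] for p in peaks]
    )
    ko = np.array(
        [[_peak_signal(p, tr, lib) for tr, lib in zip(ko_tracks, ko_libs)] for p in peaks]
    )
    wt_mean = wt.mean(axis=1)
    ko_mean = np.maximum(ko.mean(axis=1), config.ko_pseudocount)
    folds = wt_mean / ko_mean
    correction = _mode_correction(folds) if config.composition_normalize else 1.0
    if correction <= 0:
        correction = 1.0
    folds_adj = folds / correction

    # moderated two-sample t on log signals
    n1, n2 = wt.shape[1], ko.shape[1]
    lw = np.log2(np.maximum(wt, config.ko_pseudocount))
    lk = np.log2(np.maximum(ko, config.ko_pseudocount))
    if n1 > 1 and n2 > 1:
        v1 = lw.var(axis=1, ddof=1)
        v2 = lk.var(axis=1, ddof=1)
        pooled = (v1 * (n1 - 1) + v2 * (n2 - 1)) / (n1 + n2 - 2)
        prior = float(np.mean(pooled))
        d0 = 4.0  # prior degrees of freedom for the shrinkage
        mod = (d0 * prior + (n1 + n2 - 2) * pooled) / (d0 + n1 + n2 - 2)
        se = np.sqrt(np.maximum(mod, 1e-12) * (1.0 / n1 + 1.0 / n2))
        tstat = (lw.mean(axis=1) - lk.mean(axis=1)) / se
        df = d0 + n1 + n2 - 2
        pv = stats.t.sf(np.abs(tstat), df) * 2.0
    else:
        pv = np.ones(len(peaks))

    out = []
    for i, p in enumerate(peaks):
        name = p.name or f"peak_{i + 1}"
        out.append(
            ReducedPeakCall(
                peak_id=name,
                transcript_id=assignment.get(name) if assignment else None,
                wt_signal=float(wt_mean[i]),
                ko_signal=float(ko_mean[i]),
                fold_change=float(folds_adj[i]),
                is_reduced=bool(folds_adj[i] >= config.fold_threshold),
                pvalue=float(min(pv[i], 1.0)),
            )
        )
    return out


def transcript_reduction_summary(
    calls: Sequence[ReducedPeakCall],
    elements: Optional[Mapping[str, str]] = None,
) -> dict:
    """Per-transcript reduced flag (>= 1 reduced peak) and the overall
    reduced fraction; optionally per-element reduction fractions when a
    peak_id -> element map is given."""
    by_t: dict[str, bool] = {}
    for c in calls:
        if c.transcript_id is None:
            continue
        by_t[c.transcript_id] = by_t.get(c.transcript_id, False) or c.is_reduced
    n = len(by_t)
    frac = (sum(by_t.values()) / n) if n else 0.0
    out = {
        "per_transcript": by_t,
        "n_transcripts": n,
        "reduced_fraction": float(frac),
    }
    if elements is not None:
        per_elem: dict[str, list[bool]] = {}
        for c in calls:
            e = elements.get(c.peak_id)
            if e is not None:
                per_elem.setdefault(e, []).append(c.is_reduced)
        out["element_reduction_fraction"] = {
            e: float(np.mean(v)) for e, v in sorted(per_elem.items())
        }
    return out
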