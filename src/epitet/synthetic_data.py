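"""Synthetic genome, coverage, peak-truth and count generation.

Every downstream stage of the pipeline (DNA peak calling, annotation,
RNA-modification peak calling, reduction classification, differential
expression, integration) can be exercised on data from this module with a
known ground truth, fully deterministic under a seed.

Coverage is simulated at the read level: read counts are Poisson, read
start positions are placed uniformly (background) or under a triangular
kernel around a planted summit (enrichment), and each read contributes a
``read_length``-long footprint of depth. This yields the autocorrelated
pileup that a window-based Poisson caller assumes, and makes
``CoverageTrack.library_size`` (coverage integral / read length) the exact
number of simulated reads in expectation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_model import (
    CountMatrix,
    CoverageTrack,
    GenomicInterval,
    Peak,
    Transcript,
    ValidationError,
    write_bedgraph,
    write_counts,
    write_fasta,
    write_gtf,
    write_peaks,
)
from .genomic_context import transcript_elements

BASES = np.frombuffer(b"ACGT", dtype="S1")

ELEMENT_ORDER = ("5UTR", "CDS", "intron", "3UTR")


class SizingError(ValueError):
    """The requested genes do not fit in the requested genome."""


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the study's default design.

    Defaults describe a desk-scale two-genotype experiment: a compact
    genome with non-overlapping protein-coding genes, promoter-biased
    Tet ChIP enrichment carrying a CG-rich motif, hydroxymethyl-RNA
    (5hmrC) peaks placed across transcript elements carrying a UC-rich
    motif and partially lost in the Tet-null genotype, plus a
    negative-binomial expression matrix with a small differential
    fraction.
    """

    seed: int = 0
    # genome / annotation
    genome_length: int = 1_000_000
    n_genes: int = 150  # enough promoters to realize promoter_peak_fraction
    exons_per_gene: tuple[int, int] = (2, 5)
    read_length: int = 50
    # Tet ChIP
    chip_depth: float = 10.0
    n_planted_chip_peaks: int = 200
    promoter_peak_fraction: float = 0.6
    chip_fold_enrichment: tuple[float, float] = (10.0, 20.0)
    chip_replicates: int = 3
    summit_jitter_sd: float = 40.0
    ext_size: int = 147  # kernel half-width (fragment size)
    min_peak_separation: int = 600
    h3k4me3_cooccurrence_prob: float = 0.4
    n_h3k4me3_decoys: int = 20
    # motifs
    motif_fg_fraction: float = 0.6
    chip_motif: str = "CGCCGC"  # CG-rich 6-mer
    rna_motif: str = "TCCTTC"  # UC-rich 6-mer (DNA alphabet)
    # hMeRIP
    hmerip_depth: float = 30.0
    n_planted_rna_peaks: int = 100  # ~2 per transcript, as in real hMeRIP
    rna_fold_enrichment: tuple[float, float] = (15.0, 25.0)
    element_weights: dict = field(
        default_factory=lambda: {"5UTR": 0.1, "CDS": 0.5, "intron": 0.3, "3UTR": 0.1}
    )
    reduced_transcript_fraction: float = 0.45
    reduction_factor: float = 1.5
    hmerip_replicates: int = 2
    expression_sigma: float = 0.5  # lognormal sd of transcript abundance
    # RNA-seq counts
    nb_dispersion: float = 0.05
    de_fraction: float = 0.1
    de_fold_change: float = 4.0
    count_replicates: int = 3
    mean_count: float = 200.0

    def __post_init__(self):
        for name in (
            "promoter_peak_fraction",
            "h3k4me3_cooccurrence_prob",
            "motif_fg_fraction",
            "reduced_transcript_fraction",
            "de_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} not in [0, 1]")
        if self.reduction_factor < 1.0:
            raise ValidationError("reduction_factor must be >= 1")
        if self.chip_depth <= 0 or self.hmerip_depth <= 0:
            raise ValidationError("depths must be > 0")
        w = self.element_weights
        if abs(sum(w.values()) - 1.0) > 1e-9:
            raise ValidationError("element_weights must sum to 1")


@dataclass
class ChipTruth:
    """Planted ChIP peak: where it is and what co-occurs with it.

    ``rep_summits`` are the realized (jittered) summit positions actually
    deposited in each replicate's coverage."""

    chrom: str
    summit: int
    fold_enrichment: float
    at_promoter: bool
    gene_id: Optional[str]
    h3k4me3: bool
    rep_summits: list = field(default_factory=list)


@dataclass
class RnaTruth:
    """Planted RNA-modification peak."""

    transcript_id: str
    gene_id: str
    chrom: str
    summit: int
    element: str
    fold_enrichment: float
    reduced: bool


@dataclass
class TruthBundle:
    chip_peaks: list[ChipTruth] = field(default_factory=list)
    rna_peaks: list[RnaTruth] = field(default_factory=list)
    reduced_transcripts: set[str] = field(default_factory=set)
    modified_transcripts: set[str] = field(default_factory=set)
    de_genes: dict[str, str] = field(default_factory=dict)  # gene -> up/down
    expression_levels: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

MIN_EXON = 200
MIN_INTRON = 100
UTR5_LEN = 100
UTR3_LEN = 150
GENE_MARGIN = 1200  # leaves room for a promoter window upstream


def _gene_structure(
    chrom: str, start: int, length: int, strand: str, n_exons: int, rng
) -> tuple[GenomicInterval, list[GenomicInterval], list[GenomicInterval]]:
    """Split a gene span into exons/introns and carve UTRs out of the
    terminal exons; returns (span, exons, cds)."""
    n_seg = 2 * n_exons - 1
    mins = np.array([MIN_EXON if i % 2 == 0 else MIN_INTRON for i in range(n_seg)])
    extra = length - mins.sum()
    if extra < 0:
        raise SizingError(f"gene of {length} bp cannot hold {n_exons} exons")
    props = rng.dirichlet(np.ones(n_seg))
    sizes = mins + np.floor(props * extra).astype(int)
    sizes[-1] += length - sizes.sum()
    bounds = start + np.concatenate([[0], np.cumsum(sizes)])
    exons = [
        GenomicInterval(chrom, int(bounds[i]), int(bounds[i + 1]), strand)
        for i in range(0, n_seg, 2)
    ]
    span = GenomicInterval(chrom, start, start + length, strand)
    # UTRs live in the terminal exons (strand-aware); the rest of the
    # exonic span is CDS.
    if strand == "+":
        cds_start = exons[0].start + UTR5_LEN
        cds_end = exons[-1].end - UTR3_LEN
    else:
        cds_start = exons[0].start + UTR3_LEN
        cds_end = exons[-1].end - UTR5_LEN
    cds = []
    for e in exons:
        s, t = max(e.start, cds_start), min(e.end, cds_end)
        if s < t:
            cds.append(GenomicInterval(chrom, s, t, strand))
    return span, exons, cds


def simulate_genome(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[dict[str, bytearray], list[Transcript]]:
    """Random genome sequence plus non-overlapping gene models.

    Returns the sequence as mutable bytearrays (so that peak simulation
    can plant motifs) and one transcript per gene.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    chrom = "chr1"
    L = config.genome_length
    seq = bytearray(BASES[rng.integers(0, 4, L)].tobytes())
    transcripts: list[Transcript] = []
    if config.n_genes > 0:
        lengths = rng.integers(1500, 3001, config.n_genes)
        needed = int(lengths.sum()) + GENE_MARGIN * (config.n_genes + 1)
        if needed > L:
            raise SizingError(
                f"{config.n_genes} genes need >= {needed} bp; genome_length is "
                f"{L}. Increase genome_length or reduce n_genes."
            )
        free = L - needed
        gaps = GENE_MARGIN + rng.multinomial(free, np.ones(config.n_genes + 1) / (config.n_genes + 1))
        pos = 0
        for i in range(config.n_genes):
            pos += int(gaps[i])
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            span, exons, cds = _gene_structure(
                chrom, pos, int(lengths[i]), strand, n_ex, rng
            )
            gid = f"gene{i + 1:04d}"
            transcripts.append(
                Transcript(
                    id=f"{gid}.t1",
                    gene_id=gid,
                    interval=span,
                    exons=tuple(exons),
                    cds=tuple(cds) if cds else None,
                )
            )
            pos += int(lengths[i])
    return {chrom: seq}, transcripts


def plant_motif(genome: dict[str, bytearray], chrom: str, pos: int, motif: str) -> None:
    """Overwrite the genome with ``motif`` starting at ``pos`` (clipped)."""
    seq = genome[chrom]
    pos = max(0, min(pos, len(seq) - len(motif)))
    seq[pos : pos + len(motif)] = motif.encode()


# ---------------------------------------------------------------------------
# read-level coverage
# ---------------------------------------------------------------------------

def _deposit_reads(cov: np.ndarray, starts: np.ndarray, read_length: int) -> None:
    """Add one read_length footprint per start position (single pass)."""
    starts = np.clip(starts.astype(int), 0, max(len(cov) - read_length, 0))
    diff = np.zeros(len(cov) + 1)
    np.add.at(diff, starts, 1.0)
    np.add.at(diff, starts + read_length, -1.0)
    cov += np.cumsum(diff[:-1])


def _background_reads(length: int, rate: float, read_length: int, rng) -> np.ndarray:
    """Read starts for a uniform background at ``rate`` depth per base."""
    n = rng.poisson(rate * length / read_length)
    return rng.integers(0, max(length - read_length, 1), n)


def _region_reads(
    start: int, end: int, rate: float, read_length: int, rng
) -> np.ndarray:
    """Read starts for uniform coverage over [start, end)."""
    span = end - start
    n = rng.poisson(rate * span / read_length)
    return start + rng.integers(-read_length + 1, span, n)


def _peak_reads(
    summit: int, height: float, half_width: int, read_length: int, rng
) -> np.ndarray:
    """Read starts for a triangular enrichment kernel: expected added depth
    at the summit is exactly ``height``, falling off to zero at
    ``summit ± half_width``.

    A read covers the summit iff its triangularly distributed center
    offset is within read_length/2, which happens with probability
    1 - (1 - a/hw)^2 for a = read_length/2; the read count is normalized
    by that coverage probability so the summit depth is unbiased."""
    if height <= 0:
        return np.empty(0, dtype=int)
    a = min(read_length / 2.0, half_width)
    p_cover = 1.0 - (1.0 - a / half_width) ** 2
    n = rng.poisson(height / p_cover)
    offsets = (rng.triangular(-half_width, 0, half_width, n)).astype(int)
    return summit + offsets - read_length // 2


# ---------------------------------------------------------------------------
# ChIP simulation
# ---------------------------------------------------------------------------

@dataclass
class ChipSim:
    ip: list[CoverageTrack]
    input: list[CoverageTrack]
    h3k4me3: list[Peak]
    truth: list[ChipTruth]


def _promoter_positions(t: Transcript, rng) -> int:
    """A summit inside the promoter window (TSS -1000..+100, strand-aware)."""
    off = int(rng.integers(-800, 100))
    return t.tss + off if t.strand != "-" else t.tss - off


def simulate_chip(
    config: SimulationConfig,
    transcripts: Sequence[Transcript],
    genome: Optional[dict[str, bytearray]] = None,
    rng: Optional[np.random.Generator] = None,
) -> ChipSim:
    """IP/input coverage per replicate with planted promoter-biased peaks,
    an H3K4me3 peak set with the configured co-occurrence probability, and
    the truth records."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    chrom = "chr1"
    L = config.genome_length
    rl = config.read_length

    # --- choose summits -----------------------------------------------------
    # Branch (promoter vs background) is decided per peak up front so the
    # realized promoter fraction is Bernoulli(promoter_peak_fraction);
    # placement retries stay within the chosen branch.
    summits: list[tuple[int, bool, Optional[str]]] = []
    taken: list[int] = []
    genic = list(transcripts)
    for _ in range(config.n_planted_chip_peaks):
        prom = bool(genic) and rng.random() < config.promoter_peak_fraction
        for attempt in range(200):
            if prom:
                t = genic[int(rng.integers(0, len(genic)))]
                s, gid = _promoter_positions(t, rng), t.gene_id
            else:
                s, gid = int(rng.integers(config.ext_size, L - config.ext_size)), None
            if s < config.ext_size or s >= L - config.ext_size:
                continue
            if any(abs(s - u) < config.min_peak_separation for u in taken):
                continue
            break
        else:
            raise SizingError("cannot place the requested peaks; genome too small")
        taken.append(s)
        summits.append((s, prom, gid))

    fes = rng.uniform(*config.chip_fold_enrichment, size=len(summits))
    cooc = rng.random(len(summits)) < config.h3k4me3_cooccurrence_prob
    truth = [
        ChipTruth(chrom, s, float(fe), prom, gid, bool(h))
        for (s, prom, gid), fe, h in zip(summits, fes, cooc)
    ]

    # --- motifs -------------------------------------------------------------
    if genome is not None:
        with_motif = rng.random(len(truth)) < config.motif_fg_fraction
        for rec, m in zip(truth, with_motif):
            if m:
                plant_motif(genome, chrom, rec.summit - len(config.chip_motif) // 2, config.chip_motif)

    # --- coverage -----------------------------------------------------------
    for rec in truth:
        for _ in range(config.chip_replicates):
            s = int(round(rec.summit + rng.normal(0, config.summit_jitter_sd)))
            rec.rep_summits.append(int(np.clip(s, 0, L - 1)))
    ip_tracks, input_tracks = [], []
    for rep in range(config.chip_replicates):
        starts = [_background_reads(L, config.chip_depth, rl, rng)]
        for rec in truth:
            starts.append(
                _peak_reads(
                    rec.rep_summits[rep],
                    (rec.fold_enrichment - 1.0) * config.chip_depth,
                    config.ext_size, rl, rng,
                )
            )
        ipv = np.zeros(L)
        _deposit_reads(ipv, np.concatenate(starts), rl)
        inv = np.zeros(L)
        _deposit_reads(inv, _background_reads(L, config.chip_depth, rl, rng), rl)
        ip_tracks.append(CoverageTrack({chrom: ipv}, rl, f"chip_ip_rep{rep + 1}"))
        input_tracks.append(CoverageTrack({chrom: inv}, rl, f"chip_input_rep{rep + 1}"))

    # --- H3K4me3 ------------------------------------------------------------
    k4: list[Peak] = []
    for rec in truth:
        if rec.h3k4me3:
            s = rec.summit
            iv = GenomicInterval(chrom, max(0, s - 300), min(L, s + 300))
            k4.append(Peak(interval=iv, summit=s, sample_id="h3k4me3"))
    for _ in range(config.n_h3k4me3_decoys):
        s = int(rng.integers(300, L - 300))
        if any(abs(s - u) < 2 * config.min_peak_separation for u in taken):
            continue
        k4.append(
            Peak(
                interval=GenomicInterval(chrom, s - 300, s + 300),
                summit=s,
                sample_id="h3k4me3",
            )
        )
    k4.sort(key=lambda p: p.interval.start)
    return ChipSim(ip=ip_tracks, input=input_tracks, h3k4me3=k4, truth=truth)


# ---------------------------------------------------------------------------
# hMeRIP simulation
# ---------------------------------------------------------------------------

@dataclass
class HmeripSim:
    wt_ip: list[CoverageTrack]
    wt_input: list[CoverageTrack]
    ko_ip: list[CoverageTrack]
    ko_input: list[CoverageTrack]
    truth: list[RnaTruth]
    reduced_transcripts: set[str]
    expression_levels: dict[str, float]


def _sample_element_position(
    t: Transcript, weights: dict[str, float], ext: int, rng
) -> Optional[tuple[str, int]]:
    """Pick an element class by weight (renormalized over the elements the
    transcript actually has) and a summit uniform within that element."""
    elems = transcript_elements(t)
    avail = {e: ivs for e, ivs in elems.items() if ivs and sum(len(i) for i in ivs) >= 20}
    if not avail:
        return None
    ws = np.array([weights.get(e, 0.0) for e in ELEMENT_ORDER if e in avail])
    names = [e for e in ELEMENT_ORDER if e in avail]
    if ws.sum() <= 0:
        ws = np.ones(len(names))
    ws = ws / ws.sum()
    elem = names[int(rng.choice(len(names), p=ws))]
    ivs = avail[elem]
    lens = np.array([len(i) for i in ivs], dtype=float)
    iv = ivs[int(rng.choice(len(ivs), p=lens / lens.sum()))]
    pad = min(10, (len(iv) - 1) // 2)
    return elem, int(rng.integers(iv.start + pad, iv.end - pad))


def simulate_hmerip(
    config: SimulationConfig,
    transcripts: Sequence[Transcript],
    genome: Optional[dict[str, bytearray]] = None,
    rng: Optional[np.random.Generator] = None,
) -> HmeripSim:
    """Wild-type and Tet-null IP/input coverage over transcript footprints.

    Each planted peak sits on one transcript; peaks are assigned to
    distinct transcripts first (a random permutation is consumed before
    any transcript receives a second peak). In the Tet-null genotype, for
    a ``reduced_transcript_fraction`` Bernoulli draw per modified
    transcript, one of its peaks has its observed IP signal over the
    kernel footprint reduced by ``reduction_factor``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    chrom = "chr1"
    L = config.genome_length
    rl = config.read_length
    if not transcripts:
        raise ValidationError("hMeRIP simulation needs transcripts")

    # transcript abundances (shared by genotypes; modification independent
    # of abundance by construction)
    expr = {
        t.id: float(np.exp(rng.normal(0.0, config.expression_sigma)))
        for t in transcripts
    }

    # --- assign peaks to transcripts ---------------------------------------
    order = rng.permutation(len(transcripts))
    truth: list[RnaTruth] = []
    i = 0
    while len(truth) < config.n_planted_rna_peaks:
        t = transcripts[int(order[i % len(order)])]
        i += 1
        picked = _sample_element_position(t, config.element_weights, config.ext_size, rng)
        if picked is None:
            continue
        elem, summit = picked
        fe = float(rng.uniform(*config.rna_fold_enrichment))
        truth.append(RnaTruth(t.id, t.gene_id, chrom, summit, elem, fe, False))

    by_tid: dict[str, list[RnaTruth]] = {}
    for rec in truth:
        by_tid.setdefault(rec.transcript_id, []).append(rec)
    modified = set(by_tid)

    reduced: set[str] = set()
    for tid in sorted(by_tid):
        if rng.random() < config.reduced_transcript_fraction:
            reduced.add(tid)
            recs = by_tid[tid]
            recs[int(rng.integers(0, len(recs)))].reduced = True

    if genome is not None:
        with_motif = rng.random(len(truth)) < config.motif_fg_fraction
        for rec, m in zip(truth, with_motif):
            if m:
                plant_motif(genome, chrom, rec.summit - len(config.rna_motif) // 2, config.rna_motif)

    # --- coverage -----------------------------------------------------------
    tmap = {t.id: t for t in transcripts}
    r = config.reduction_factor

    def make_ip(genotype: str, rep: int) -> CoverageTrack:
        starts = [
            _region_reads(
                t.interval.start, t.interval.end,
                config.hmerip_depth * expr[t.id], rl, rng,
            )
            for t in transcripts
        ]
        for rec in truth:
            bg = config.hmerip_depth * expr[rec.transcript_id]
            h = (rec.fold_enrichment - 1.0) * bg
            if genotype == "ko" and rec.reduced:
                # reduce the *observed* mean IP signal over the kernel
                # footprint by exactly reduction_factor: the footprint mean
                # is bg + h/2, so solve bg + h'/2 = (bg + h/2)/r.
                h = max(0.0, 2.0 * bg * (1.0 / r - 1.0) + h / r)
            starts.append(_peak_reads(rec.summit, h, config.ext_size, rl, rng))
        cov = np.zeros(L)
        _deposit_reads(cov, np.concatenate(starts), rl)
        return CoverageTrack({chrom: cov}, rl, f"hmerip_{genotype}_ip_rep{rep}")

    def make_input(genotype: str, rep: int) -> CoverageTrack:
        starts = [
            _region_reads(
                t.interval.start, t.interval.end,
                config.hmerip_depth * expr[t.id], rl, rng,
            )
            for t in transcripts
        ]
        cov = np.zeros(L)
        _deposit_reads(cov, np.concatenate(starts), rl)
        return CoverageTrack({chrom: cov}, rl, f"hmerip_{genotype}_input_rep{rep}")

    wt_ip = [make_ip("wt", i + 1) for i in range(config.hmerip_replicates)]
    wt_in = [make_input("wt", i + 1) for i in range(config.hmerip_replicates)]
    ko_ip = [make_ip("ko", i + 1) for i in range(config.hmerip_replicates)]
    ko_in = [make_input("ko", i + 1) for i in range(config.hmerip_replicates)]
    return HmeripSim(
        wt_ip=wt_ip, wt_input=wt_in, ko_ip=ko_ip, ko_input=ko_in,
        truth=truth, reduced_transcripts=reduced, expression_levels=expr,
    )


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

def simulate_counts(
    config: SimulationConfig,
    transcripts: Sequence[Transcript],
    rng: Optional[np.random.Generator] = None,
) -> tuple[CountMatrix, dict[str, str]]:
    """Negative-binomial gene counts for wt vs tetnull with a planted
    differential fraction; returns the matrix and gene -> up/down truth."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    if config.count_replicates < 2:
        raise ValidationError("need >= 2 replicates per condition")
    genes = [t.gene_id for t in transcripts]
    n = len(genes)
    base = config.mean_count * np.exp(rng.normal(0.0, 1.0, n))
    de_truth: dict[str, str] = {}
    fc = np.ones(n)
    is_de = rng.random(n) < config.de_fraction
    up = rng.random(n) < 0.5
    for i in range(n):
        if is_de[i]:
            if up[i]:
                fc[i] = config.de_fold_change
                de_truth[genes[i]] = "up"
            else:
                fc[i] = 1.0 / config.de_fold_change
                de_truth[genes[i]] = "down"

    def nb(mean: np.ndarray) -> np.ndarray:
        a = config.nb_dispersion
        if a <= 1e-12:
            return rng.poisson(mean)
        # NB with mean m, variance m + a m^2: gamma-poisson mixture
        shape = 1.0 / a
        lam = rng.gamma(shape, mean * a)
        return rng.poisson(lam)

    cols, conds, mats = [], [], []
    for rep in range(config.count_replicates):
        cols.append(f"wt_{rep + 1}")
        conds.append("wt")
        mats.append(nb(base))
    for rep in range(config.count_replicates):
        cols.append(f"tetnull_{rep + 1}")
        conds.append("tetnull")
        mats.append(nb(base * fc))
    m = CountMatrix(
        gene_ids=genes, sample_ids=cols, conditions=conds,
        counts=np.column_stack(mats).astype(int),
    )
    return m, de_truth


# ---------------------------------------------------------------------------
# full run + serialization
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genome: dict[str, bytearray]
    transcripts: list[Transcript]
    chip: ChipSim
    hmerip: HmeripSim
    counts: CountMatrix
    truth: TruthBundle


def simulate_study(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> SimulatedStudy:
    """Run all generators off one seeded stream, in a fixed order."""
    root = rng if rng is not None else np.random.default_rng(config.seed)
    genome, transcripts = simulate_genome(config, root)
    chip = simulate_chip(config, transcripts, genome, root)
    hmerip = simulate_hmerip(config, transcripts, genome, root)
    counts, de_truth = simulate_counts(config, transcripts, root)
    truth = TruthBundle(
        chip_peaks=chip.truth,
        rna_peaks=hmerip.truth,
        reduced_transcripts=hmerip.reduced_transcripts,
        modified_transcripts={r.transcript_id for r in hmerip.truth},
        de_genes=de_truth,
        expression_levels=hmerip.expression_levels,
    )
    return SimulatedStudy(config, genome, transcripts, chip, hmerip, counts, truth)


def write_study(study: SimulatedStudy, outdir) -> dict[str, str]:
    """Write a simulated study to a run directory; returns a manifest of
    relative path -> role."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    manifest: dict[str, str] = {}

    write_fasta({c: s.decode() for c, s in study.genome.items()}, outdir / "genome.fa")
    manifest["genome.fa"] = "genome sequence"
    write_gtf(study.transcripts, outdir / "genes.gtf")
    manifest["genes.gtf"] = "annotation"

    for tracks, stem in [
        (study.chip.ip, "chip_ip"),
        (study.chip.input, "chip_input"),
        (study.hmerip.wt_ip, "hmerip_wt_ip"),
        (study.hmerip.wt_input, "hmerip_wt_input"),
        (study.hmerip.ko_ip, "hmerip_ko_ip"),
        (study.hmerip.ko_input, "hmerip_ko_input"),
    ]:
        for i, tr in enumerate(tracks, start=1):
            name = f"{stem}_rep{i}.bedgraph"
            write_bedgraph(tr, outdir / name)
            manifest[name] = "coverage"

    write_peaks(study.chip.h3k4me3, outdir / "h3k4me3.bed")
    manifest["h3k4me3.bed"] = "H3K4me3 peaks"
    write_counts(study.counts, outdir / "counts.tsv")
    manifest["counts.tsv"] = "RNA-seq counts"

    pd.DataFrame(
        [dataclasses.asdict(r) for r in study.truth.chip_peaks]
    ).to_csv(outdir / "truth" / "chip_peaks.tsv", sep="\t", index=False)
    pd.DataFrame(
        [dataclasses.asdict(r) for r in study.truth.rna_peaks]
    ).to_csv(outdir / "truth" / "rna_peaks.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"gene_id": list(study.truth.de_genes), "direction": list(study.truth.de_genes.values())}
    ).to_csv(outdir / "truth" / "de_genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"transcript_id": sorted(study.truth.reduced_transcripts)}
    ).to_csv(outdir / "truth" / "reduced_transcripts.tsv", sep="\t", index=False)
    manifest["truth/"] = "ground truth tables"
    return manifest
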