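"""Domain types, interval algebra and text-format I/O.

Coordinate convention: everything in memory is 0-based, half-open
(BED-native). GTF is 1-based inclusive and is converted on read/write.

Formats handled here: GTF, BED / narrowPeak-like peak tables, bedGraph,
and TSV count tables. All are plain text; none require an index.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

PathLike = Union[str, Path]

STRANDS = ("+", "-", ".")

#: bases of aligned sequence contributed by one read; used to convert a
#: coverage integral into a mapped-read equivalent.
READ_LENGTH = 50


class FormatError(ValueError):
    """A text input did not parse as the expected format."""


class ValidationError(ValueError):
    """A parsed record violated a domain invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def interval_overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 if different chrom)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class Transcript:
    """A transcript model: span, ordered exons, optional CDS, TSS/TTS.

    ``tss`` and ``tts`` are single base positions derived from strand:
    for ``+`` the TSS is ``interval.start``; for ``-`` it is
    ``interval.end - 1`` (last covered base).
    """

    id: str
    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    cds: Optional[tuple[GenomicInterval, ...]] = None

    def __post_init__(self):
        ex = sorted(self.exons, key=lambda e: e.start)
        object.__setattr__(self, "exons", tuple(ex))
        for e in self.exons:
            if e.start < self.interval.start or e.end > self.interval.end:
                raise ValidationError(
                    f"exon {e} outside transcript span of {self.id}"
                )
            if e.chrom != self.interval.chrom:
                raise ValidationError(f"exon chrom mismatch in {self.id}")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValidationError(f"overlapping exons in {self.id}")
        if self.cds is not None:
            cds = tuple(sorted(self.cds, key=lambda c: c.start))
            object.__setattr__(self, "cds", cds)
            for c in cds:
                if not any(
                    c.start >= e.start and c.end <= e.end for e in self.exons
                ):
                    raise ValidationError(
                        f"CDS segment {c} not contained in an exon of {self.id}"
                    )

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand != "-" else self.interval.end - 1

    @property
    def tts(self) -> int:
        return self.interval.end - 1 if self.strand != "-" else self.interval.start

    @property
    def cds_span(self) -> Optional[GenomicInterval]:
        if not self.cds:
            return None
        return GenomicInterval(
            self.interval.chrom,
            self.cds[0].start,
            self.cds[-1].end,
            self.strand,
        )

    def length(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class Peak:
    """An enriched region with its summit and calling statistics.

    Optional statistics are ``None`` when absent (e.g. read from a plain
    3-column BED); they are never silently zero.
    """

    interval: GenomicInterval
    summit: int
    score: Optional[float] = None
    pvalue: Optional[float] = None
    fold_enrichment: Optional[float] = None
    reads: Optional[float] = None
    sample_id: Optional[str] = None
    name: Optional[str] = None

    def __post_init__(self):
        if not self.interval.contains(self.summit):
            raise ValidationError(
                f"summit {self.summit} outside {self.interval}"
            )
        if self.pvalue is not None and not (0.0 < self.pvalue <= 1.0):
            raise ValidationError(f"pvalue {self.pvalue} not in (0, 1]")
        if self.fold_enrichment is not None and self.fold_enrichment < 0:
            raise ValidationError("fold_enrichment must be >= 0")
        if self.reads is not None and self.reads < 0:
            raise ValidationError("reads must be >= 0")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


class CoverageTrack:
    """Per-base read coverage for one sample over a set of chromosomes.

    ``library_size`` is the mapped-read equivalent of the track,
    ``sum(depth) / READ_LENGTH`` (each read contributes READ_LENGTH bases
    of coverage).
    """

    def __init__(
        self,
        depths: Mapping[str, np.ndarray],
        read_length: int = READ_LENGTH,
        sample_id: Optional[str] = None,
    ):
        self.depths: dict[str, np.ndarray] = {}
        for chrom, v in depths.items():
            arr = np.asarray(v, dtype=float)
            if arr.ndim != 1:
                raise ValidationError("depth vectors must be 1-D")
            if np.any(arr < 0):
                raise ValidationError(f"negative depth on {chrom}")
            self.depths[chrom] = arr
        self.read_length = int(read_length)
        self.sample_id = sample_id

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.depths.items()}

    @property
    def library_size(self) -> float:
        return float(sum(v.sum() for v in self.depths.values())) / self.read_length

    def per_million(self) -> "CoverageTrack":
        """Depths scaled to a per-million-mapped-reads library."""
        lib = self.library_size
        if lib <= 0:
            raise ValidationError("cannot normalize an empty track")
        f = 1e6 / lib
        return CoverageTrack(
            {c: v * f for c, v in self.depths.items()},
            read_length=self.read_length,
            sample_id=self.sample_id,
        )


@dataclass
class CountMatrix:
    """Gene x sample integer read counts with per-sample condition labels."""

    gene_ids: list[str]
    sample_ids: list[str]
    conditions: list[str]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.conditions) != len(self.sample_ids):
            raise ValidationError("one condition label per sample required")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.gene_ids, columns=self.sample_ids
        )


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(s: str) -> dict[str, str]:
    out = {}
    for part in s.strip().rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gtf(path: PathLike) -> list[Transcript]:
    """Parse a GTF file into Transcript objects (coordinates converted
    from 1-based inclusive to 0-based half-open).

    Uses ``transcript``/``exon``/``CDS`` features; transcripts lacking an
    explicit ``transcript`` line get a span inferred from their exons.
    """
    spans: dict[str, GenomicInterval] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    genes: dict[str, str] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            chrom, _src, feat, start_s, end_s, _score, strand, _frame, attrs = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start1 < 1 or end1 < start1:
                raise FormatError(
                    f"{path}: line {lineno}: bad 1-based range {start1}..{end1}"
                )
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            a = _parse_gtf_attributes(attrs)
            tid = a.get("transcript_id")
            gid = a.get("gene_id", tid)
            if feat == "transcript":
                if tid is None:
                    raise FormatError(
                        f"{path}: line {lineno}: transcript without transcript_id"
                    )
                spans[tid] = iv
                genes[tid] = gid
                if tid not in order:
                    order.append(tid)
            elif feat == "exon":
                if tid is None:
                    raise FormatError(
                        f"{path}: line {lineno}: exon without transcript_id"
                    )
                exons.setdefault(tid, []).append(iv)
                genes.setdefault(tid, gid)
                if tid not in order:
                    order.append(tid)
            elif feat == "CDS":
                if tid is None:
                    raise FormatError(
                        f"{path}: line {lineno}: CDS without transcript_id"
                    )
                cds.setdefault(tid, []).append(iv)

    out = []
    for tid in order:
        ex = exons.get(tid, [])
        if tid in spans:
            span = spans[tid]
        elif ex:
            span = GenomicInterval(
                ex[0].chrom,
                min(e.start for e in ex),
                max(e.end for e in ex),
                ex[0].strand,
            )
        else:
            continue
        if not ex:
            ex = [replace(span)]
        for e in ex:
            if e.start < span.start or e.end > span.end:
                raise ValidationError(
                    f"exon {e} outside transcript {tid} span {span}"
                )
        out.append(
            Transcript(
                id=tid,
                gene_id=genes[tid],
                interval=span,
                exons=tuple(ex),
                cds=tuple(cds[tid]) if tid in cds else None,
            )
        )
    return out


def write_gtf(transcripts: Sequence[Transcript], path: PathLike) -> None:
    """Write transcripts as GTF (converting back to 1-based inclusive)."""
    def line(iv: GenomicInterval, feat: str, t: Transcript) -> str:
        attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.id}";'
        return (
            f"{iv.chrom}\tepitet\t{feat}\t{iv.start + 1}\t{iv.end}\t.\t"
            f"{iv.strand}\t.\t{attrs}"
        )

    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(line(t.interval, "transcript", t) + "\n")
            for e in t.exons:
                fh.write(line(e, "exon", t) + "\n")
            for c in t.cds or ():
                fh.write(line(c, "CDS", t) + "\n")


# ---------------------------------------------------------------------------
# Peaks (BED / narrowPeak-like)
# ---------------------------------------------------------------------------
#
# 10-column narrowPeak-like dialect, 0-based half-open:
#   chrom start end name score strand fold_enrichment -log10(p) reads summit
# where summit is an offset from start (as in ENCODE narrowPeak) and
# missing optional statistics are written as ".".

_NA = "."


def _fmt(x, spec="%.6g") -> str:
    return _NA if x is None else (spec % x)


def write_peaks(peaks: Iterable[Peak], path: PathLike) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            iv = p.interval
            neglogp = None if p.pvalue is None else -np.log10(p.pvalue)
            name = p.name or f"peak_{i + 1}"
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        name,
                        _fmt(p.score),
                        iv.strand,
                        _fmt(p.fold_enrichment),
                        _fmt(neglogp),
                        _fmt(p.reads),
                        str(p.summit - iv.start),
                    ]
                )
                + "\n"
            )


def read_peaks(path: PathLike, sample_id: Optional[str] = None) -> list[Peak]:
    """Read a BED-like peak table (>= 3 columns; 10-column dialect above).

    For plain BED (< 10 columns) the summit defaults to the interval
    midpoint and all statistics are absent.
    """
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: need >= 3 columns, got {len(f)}"
                )
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if start >= end:
                raise ValidationError(
                    f"{path}: line {lineno}: start >= end ({start} >= {end})"
                )
            strand = f[5] if len(f) > 5 and f[5] in STRANDS else "."
            iv = GenomicInterval(chrom, start, end, strand)

            def opt(i: int) -> Optional[float]:
                if len(f) <= i or f[i] == _NA or f[i] == "":
                    return None
                return float(f[i])

            name = f[3] if len(f) > 3 and f[3] != _NA else None
            score = opt(4)
            fe = opt(6)
            neglogp = opt(7)
            reads = opt(8)
            if len(f) > 9 and f[9] != _NA:
                summit = start + int(f[9])
            else:
                summit = (start + end) // 2
            peaks.append(
                Peak(
                    interval=iv,
                    summit=summit,
                    score=score,
                    pvalue=None if neglogp is None else float(10.0 ** -neglogp),
                    fold_enrichment=fe,
                    reads=reads,
                    sample_id=sample_id,
                    name=name,
                )
            )
    return peaks


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(track: CoverageTrack, path: PathLike) -> None:
    """Write a coverage track as bedGraph, run-length collapsing equal
    consecutive depths. Zero-depth runs are written too, so that the
    chromosome length round-trips."""
    with open(path, "w") as fh:
        for chrom in sorted(track.depths):
            v = track.depths[chrom]
            if len(v) == 0:
                continue
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(v)]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:.6g}\n")


def read_bedgraph(
    path: PathLike,
    chrom_sizes: Optional[Mapping[str, int]] = None,
    read_length: int = READ_LENGTH,
    sample_id: Optional[str] = None,
) -> CoverageTrack:
    """Read a bedGraph into dense per-base vectors.

    If ``chrom_sizes`` is omitted, each chromosome's size is the largest
    end coordinate seen.
    """
    raw: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) != 4:
                raise FormatError(
                    f"{path}: line {lineno}: bedGraph needs 4 columns"
                )
            raw.setdefault(f[0], []).append((int(f[1]), int(f[2]), float(f[3])))
    depths = {}
    for chrom, rows in raw.items():
        size = (
            chrom_sizes[chrom]
            if chrom_sizes is not None
            else max(e for _, e, _ in rows)
        )
        v = np.zeros(size)
        for s, e, d in rows:
            v[s:e] = d
        depths[chrom] = v
    if chrom_sizes is not None:
        for chrom, size in chrom_sizes.items():
            depths.setdefault(chrom, np.zeros(size))
    return CoverageTrack(depths, read_length=read_length, sample_id=sample_id)


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

def write_counts(m: CountMatrix, path: PathLike) -> None:
    """TSV with a header row; first column ``gene_id``, then one column
    per sample named ``<sample>:<condition>``."""
    cols = [f"{s}:{c}" for s, c in zip(m.sample_ids, m.conditions)]
    df = pd.DataFrame(m.counts, index=m.gene_ids, columns=cols)
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path: PathLike) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    samples, conditions = [], []
    for col in df.columns:
        s, _, c = col.partition(":")
        samples.append(s)
        conditions.append(c or s)
    return CountMatrix(
        gene_ids=list(df.index.astype(str)),
        sample_ids=samples,
        conditions=conditions,
        counts=df.to_numpy(),
    )


# ---------------------------------------------------------------------------
# FASTA (toy genomes only; sequences fit in memory)
# ---------------------------------------------------------------------------

def write_fasta(seqs: Mapping[str, str], path: PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_fasta(path: PathLike) -> dict[str, str]:
    seqs: dict[str, io.StringIO] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = io.StringIO()
            elif name is not None:
                seqs[name].write(line)
    return {k: v.getvalue() for k, v in seqs.items()}
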