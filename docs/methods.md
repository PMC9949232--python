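# Methods

This note documents the models, defaults and design choices behind
`epitet`, and what the synthetic-data tests do and do not demonstrate.

## Coordinates and formats

All in-memory coordinates are 0-based, half-open (BED-native); GTF is
converted on read/write (an exact bijection, tested at both interval
ends). Coverage is strandless — ChIP and hMeRIP libraries are analyzed
unstranded — and strand is used only for annotation and metagene
orientation. Peak tables use a 10-column narrowPeak-like dialect with the
summit stored as an offset from the interval start; optional statistics
absent from an input file stay `None`, never a silent zero.
`CoverageTrack.library_size` is the coverage integral divided by the read
length (default 50 bp), i.e. a mapped-read equivalent.

## Peak calling

The caller tests, at every base, the IP read count within an
extension-size window (`ext_size` = 147 bp, the fragment size the
coverage kernel also uses) against a Poisson expectation from the input
track:

* **Input scaling.** The input is scaled to the IP *background*, not the
  IP library total: the factor is the ratio of median 1 kb bin counts
  (SES-style). Total-count scaling inflates the background whenever a
  substantial fraction of the IP library sits in true peaks — on the
  synthetic data (200 strong peaks per Mb) that inflation reaches ~40%
  and halves sensitivity at the fold-enrichment filter.
* **Local lambda.** Expected rate at x = max(genome-wide input rate,
  1 kb and 10 kb window rates), floored at a tiny positive constant.
* **Candidates and regions.** Positions with Poisson upper-tail
  p < 1e-2 are merged when closer than `ext_size`; each region yields one
  peak: summit = argmax of raw IP depth (leftmost tie), p-value = window
  p at the summit, fold enrichment = raw IP depth at summit / local rate,
  reads = coverage integral over the region / read length (the ≥ reads
  criterion counts whole-peak reads, a documented choice).
* **Dialects.** *embryo*: candidates are filtered downstream by
  p < 1e-5 (the "10e-5" threshold is read as 1 × 10⁻⁵), fold
  enrichment > 10 (strict) and reads > 50 (strict). *larva*:
  Benjamini–Hochberg over candidate peaks at q < 0.05, then each peak is
  resized to summit ± 100 bp; effective genome size 142,573,024 bp is
  carried in the config for reference.

Replicate reproducibility: a peak is reproducible at window `w` when a
one-to-one greedy nearest-summit matching (ascending distance, leftmost
ties, each peak used once) pairs it with a peak of the other replicate
within `w` bp. `w` is the maximum summit-to-summit distance; because
growing `w` only appends farther candidate pairs, the matched count is
non-decreasing in `w` (asserted on every saturation run). The saturation
procedure evaluates windows {50…300} and selects the smallest window
whose count is within 2% (configurable) of the count at the largest.
Multi-replicate consensus keeps first-replicate peaks reproducible
against every other replicate (all-vs-first, configurable in scope),
with the first replicate's summit as the consensus summit.

## Annotation and metagene

Feature classes are assigned by summit position with priority
promoter-TSS > TTS > 5′UTR > 3′UTR > exon > intron > intergenic.
The promoter window is TSS −1000..+100 bp and the TTS window ± 100 bp
(both strand-aware and configurable; the upstream span follows common
annotation practice). Nearest gene = gene with the closest TSS.

Metagene rows are per-transcript: fixed 100 bp bins over ± 5 kb flanks
and a body rescaled to 100 bins. Bin values are exact integral means of
the per-base step function between fractional edges, so constant coverage
is exactly flat and transcripts shorter than the bin count are
interpolated, not dropped. Coverage is normalized to per-million mapped
reads. Flank positions beyond a chromosome end are *missing* (excluded
from the bin mean, NaN when a bin is entirely outside), not zero — zeros
would fabricate signal loss at genome edges. Minus-strand rows are
reversed so the axis runs 5′→3′.

## hMeRIP analysis

RNA peak calling reuses the Poisson machinery restricted to transcript
footprints, with the input rate floored at each transcript's own mean
input rate: this is the expression control — an abundant transcript needs
enrichment *above its own level* to yield a peak. Peaks are assigned to
the transcript containing their summit; summits outside every transcript
are excluded from element analysis and counted.

Element classes (5′UTR / CDS / intron / 3′UTR) come from exact CDS
boundaries; introns are the non-exonic transcript span. Transcripts
without a CDS split their exonic span at the midpoint into 5′/3′ UTR
(documented convention; the synthetic genes are always coding). The
"predicted" element distribution defaults to seeded Monte-Carlo uniform
placement within transcripts, with the analytic length-proportional form
as a cross-check (they agree within Monte-Carlo error; tested at 10⁵
draws to 1%).

**Reduction classification.** Per peak: signal = mean per-million
coverage over the peak interval, averaged over replicates per genotype;
Tet-null signal floored at a 0.5 per-million pseudocount; fold
change = wt/ko. Fold changes are divided by the **mode** of the fold
distribution across peaks (Gaussian KDE on log₂ folds) before
thresholding: per-million scaling assumes equal total signal, which fails
when ~45% of peaks genuinely lose signal in the Tet-null sample (the
Tet-null library is then ~10% "smaller" in peak content and every fold is
biased low by that factor). The mode targets the unchanged component and
is robust as long as unchanged peaks are the single most common fold —
if *every* peak were reduced by the same factor the correction would
erase the signal entirely; that regime is outside this design and the
correction is switchable (`composition_normalize=False`). The threshold
is inclusive (fold ≥ 1.4). The per-peak p-value is a two-sample t on
log₂ replicate signals with the pooled variance shrunk toward the
cross-peak mean variance (prior df = 4), a moderated-t-style test; the
reduced *call* is defined by the threshold rule, not the p-value.

A transcript is reduced when ≥ 1 of its peaks is; the summary also
reports reduction fractions per element class.

## Motif stand-in

Instead of PWM discovery, an exhaustive k-mer (default k = 6) enrichment:
foreground counts (reverse-complement-collapsed in DNA mode; sense-only
in RNA mode, since the modification sits on the transcript) against the
mean/sd over seeded dinucleotide shuffles (random Eulerian walk on the
order-1 de Bruijn multigraph; dinucleotide counts preserved exactly and
asserted per shuffle). Ranking is by z-score. The p-value is the Poisson
upper tail at an *upper confidence bound* of the estimated background
mean (mean + 2 SE): with 4^k simultaneous tests, using the point estimate
selects k-mers whose background happened to be underestimated by shuffle
noise and is anticonservative under the null; the bound restores
conservativeness (shuffle counts are also under-dispersed relative to
Poisson, adding slack) without touching the ranking of real signals.
BH adjustment runs across all 4^k k-mers.

## Expression and integration

Counts are scaled so every sample totals the mean library size (size
factor = mean total / sample total). The NB Wald test uses
method-of-moments dispersion from within-condition variances, a fitted
`a₀ + a₁/μ` trend, and a 25/75 raw/trend shrinkage blend; the log₂ fold
change SE comes from the delta method, `Var(log₂ μ̂) = (1/μ + α)/(n ln²2)`.
Direction labels reproduce exactly the |FC| ≥ 2 & BH-adjusted p < 0.05
rule applied to the emitted columns. "Expression-unchanged" for target
genes means not passing that rule. Integration reports all pairwise set
intersection fractions at the gene level (transcript ids resolve through
the gene map; both denominators are available from the emitted sets) and
the target list bound ∩ modified ∩ reduced ∩ unchanged, with per-gene
evidence columns.

## Synthetic data

The generator emulates the study design: a single-chromosome genome
(default 1 Mb, 150 non-overlapping coding genes on both strands with
2–5 exons, 100/150 bp terminal UTRs), read-level coverage (Poisson read
counts, 50 bp footprints — so pileup is autocorrelated the way real
coverage is, and `library_size` is the true read count in expectation),
and:

* **ChIP**: 200 planted peaks, fold enrichment uniform 10–20 over a
  background depth of 10, triangular kernel with half-width 147 bp whose
  read count is normalized so the *summit* depth is exactly the planted
  height; 60% of peaks promoter-placed (branch decided per peak up
  front, so the realized fraction is Bernoulli); per-replicate summit
  jitter sd 40 bp; an H3K4me3 peak set co-occurring with probability 0.4
  plus decoys.
* **hMeRIP**: transcript abundances lognormal (σ = 0.5) shared across
  genotypes; ~2 peaks per modified transcript (peaks fill distinct
  transcripts first), element placement by configurable weights
  (default 0.1/0.5/0.3/0.1 over 5′UTR/CDS/intron/3′UTR), fold
  enrichment 15–25 over the transcript's own background — the
  signal-to-noise a MeRIP pulldown yields over ~300 bp peaks at depth 30.
  45% of modified transcripts have one peak reduced 1.5×; reduction is
  applied to the *observed* mean IP signal over the kernel footprint
  (solve bg + h′/2 = (bg + h/2)/r), so the generator's reduction factor
  is exactly the quantity the classifier thresholds.
* **Counts**: NB via gamma-Poisson (dispersion 0.05), lognormal gene
  means around 200, 10% of genes shifted 4-fold in the Tet-null
  condition, 3 replicates per condition.

Everything is deterministic under the seed; the pipeline forks one child
random stream per named stage so stage order changes cannot silently
shift another stage's results, and run manifests carry no timestamps
(same-seed runs are byte-identical).

**What the tests do not show.** The generator omits mappability and GC
bias, fragment-length variation, duplicate reads, antibody off-target
pulldown, isoform structure (one transcript per gene; intron coverage is
flat pre-mRNA), and batch effects. Passing recovery/calibration tests
therefore demonstrates correctness of the statistics under the stated
model, not performance on real libraries, where thresholds (particularly
the fold-enrichment filter and the 1.4 reduction cut) interact with
biases the model lacks.

## Problem sizes

Tests and the acceptance script run at desk scale: 1 Mb genomes for ChIP
properties (200 planted peaks), 5.5 Mb / 1000 genes for the
reduced-fraction calibration, 2000 genes for DE calibration, 300
sequences for motif recovery, and a 300 kb demo for the end-to-end run —
sizes at which every Monte-Carlo check has enough resolution for its
stated tolerance.
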