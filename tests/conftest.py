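import numpy as np
import pytest

from epitet.core_model import GenomicInterval, Transcript


@pytest.fixture(scope="session")
def five_gene_transcripts():
    """Hand-built 5-gene annotation with known element boundaries.

    Gene A (+): [2000, 5000), exons [2000,2600)+[3400,5000),
        CDS [2100,2600)+[3400,4850); TSS 2000, TTS 4999.
    Gene B (-): [8000, 10000), single exon, CDS [8150,9900);
        TSS 9999, TTS 8000.
    Gene C (+): [15000, 18000), exons [15000,15500)+[16000,18000),
        CDS [15100,15500)+[16000,17800).
    Gene D (-): [20000, 22500), single exon, no CDS (noncoding).
    Gene E (+): [25000, 27000), single exon, CDS [25200,26800).
    """
    c = "chr1"

    def t(tid, gid, span, strand, exons, cds):
        return Transcript(
            id=tid,
            gene_id=gid,
            interval=GenomicInterval(c, *span, strand),
            exons=tuple(GenomicInterval(c, a, b, strand) for a, b in exons),
            cds=tuple(GenomicInterval(c, a, b, strand) for a, b in cds) if cds else None,
        )

    return [
        t("tA", "geneA", (2000, 5000), "+", [(2000, 2600), (3400, 5000)],
          [(2100, 2600), (3400, 4850)]),
        t("tB", "geneB", (8000, 10000), "-", [(8000, 10000)], [(8150, 9900)]),
        t("tC", "geneC", (15000, 18000), "+", [(15000, 15500), (16000, 18000)],
          [(15100, 15500), (16000, 17800)]),
        t("tD", "geneD", (20000, 22500), "-", [(20000, 22500)], None),
        t("tE", "geneE", (25000, 27000), "+", [(25000, 27000)], [(25200, 26800)]),
    ]


#: (summit, expected feature class) for the five-gene annotation under the
#: default promoter (TSS -1000..+100) and TTS (+/-100) windows, including
#: boundary cases at the promoter-window edges.
ANNOTATION_CASES = [
    (1500, "promoter-TSS"),   # geneA TSS-500
    (1000, "promoter-TSS"),   # exact upstream edge of geneA promoter
    (999, "intergenic"),      # one base outside the promoter window
    (2050, "promoter-TSS"),   # inside 5'UTR but promoter wins
    (2100, "exon"),           # first CDS base: past the promoter window
    (3000, "intron"),         # geneA intron
    (4900, "TTS"),            # in TTS window and in 3'UTR: TTS wins
    (4860, "3UTR"),           # 3'UTR outside the TTS window
    (10500, "promoter-TSS"),  # upstream of minus-strand geneB
    (9950, "promoter-TSS"),   # geneB 5'UTR inside the promoter window
    (8100, "TTS"),            # geneB TTS (minus strand: left end)
    (12000, "intergenic"),    # > promoter window from every gene
]


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
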