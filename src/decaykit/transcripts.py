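"""Representative transcript models from GTF annotations and FASTA sequence.

Every gene is reduced to a single representative mRNA: among its annotated
coding transcripts, the one with the longest ORF, then the longest 5'UTR,
then the longest 3'UTR.  The representative is stored as a
:class:`TranscriptModel` -- the spliced mRNA sequence (5'->3', RNA alphabet)
plus the 5'UTR/ORF/3'UTR partition, exon-junction positions on the spliced
sequence, and the total intron length.

Coordinates are 0-based half-open internally; GTF input (1-based closed) is
converted at ingestion, and minus-strand genes are reverse-complemented so
spliced coordinates always run in mRNA sense.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import gffutils
from pyfaidx import Fasta

__all__ = [
    "TranscriptModel",
    "select_representative_transcript",
    "load_transcript_models",
    "rna",
    "revcomp_dna",
]

STOP_CODONS = ("UAA", "UAG", "UGA")

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")
_VALID_RNA = set("ACGUN")


def rna(seq: str) -> str:
    """Normalize a DNA/RNA string to the RNA alphabet (T->U, uppercase)."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - _VALID_RNA
    if bad:
        raise ValueError(f"unsupported sequence characters: {sorted(bad)}")
    return s


def revcomp_dna(seq: str) -> str:
    return seq.upper().translate(_DNA_COMP)[::-1]


@dataclass(frozen=True)
class TranscriptModel:
    """One representative mRNA for a gene.

    ``exon_junctions`` lists, in ascending spliced coordinates, the 0-based
    position of the first nucleotide of each downstream exon (so a
    single-exon transcript has none).
    """

    gene_id: str
    transcript_id: str
    spliced_seq: str
    utr5_len: int
    orf_len: int
    utr3_len: int
    exon_junctions: tuple[int, ...] = ()
    intron_len_total: int = 0

    def __post_init__(self):
        n = len(self.spliced_seq)
        if self.utr5_len + self.orf_len + self.utr3_len != n:
            raise ValueError(
                f"{self.transcript_id}: region lengths "
                f"{self.utr5_len}+{self.orf_len}+{self.utr3_len} != {n}"
            )
        if self.orf_len % 3 != 0 or self.orf_len < 3:
            raise ValueError(
                f"{self.transcript_id}: ORF length {self.orf_len} not a "
                f"positive multiple of 3"
            )
        for j in self.exon_junctions:
            if not 0 < j < n:
                raise ValueError(f"{self.transcript_id}: junction {j} outside (0,{n})")
        bad = set(self.spliced_seq) - _VALID_RNA
        if bad:
            raise ValueError(f"{self.transcript_id}: non-RNA characters {sorted(bad)}")

    # -- region accessors -----------------------------------------------
    @property
    def length(self) -> int:
        return len(self.spliced_seq)

    @property
    def utr5_seq(self) -> str:
        return self.spliced_seq[: self.utr5_len]

    @property
    def orf_seq(self) -> str:
        return self.spliced_seq[self.utr5_len : self.utr5_len + self.orf_len]

    @property
    def utr3_seq(self) -> str:
        return self.spliced_seq[self.utr5_len + self.orf_len :]

    def region_bounds(self, region: str) -> tuple[int, int]:
        """Half-open spliced-coordinate bounds of ``utr5 | orf | utr3``."""
        if region == "utr5":
            return 0, self.utr5_len
        if region == "orf":
            return self.utr5_len, self.utr5_len + self.orf_len
        if region == "utr3":
            return self.utr5_len + self.orf_len, self.length
        raise ValueError(f"unknown region {region!r}")


def select_representative_transcript(
    candidates: list[TranscriptModel],
) -> TranscriptModel:
    """Pick the representative: longest ORF, then 5'UTR, then 3'UTR.

    Residual ties are broken by the lexicographically smallest transcript ID
    for reproducibility.
    """
    if not candidates:
        raise ValueError("no candidate transcripts")
    return min(
        candidates,
        key=lambda t: (-t.orf_len, -t.utr5_len, -t.utr3_len, t.transcript_id),
    )


# ---------------------------------------------------------------------------
# GTF + FASTA ingestion
# ---------------------------------------------------------------------------

def _spliced_offset(exons: list[tuple[int, int]], strand: str, g: int) -> int:
    """Map genomic coordinate ``g`` (0-based) to its spliced position."""
    pos = 0
    if strand == "+":
        for s, e in exons:
            if s <= g < e:
                return pos + (g - s)
            pos += e - s
    else:
        for s, e in exons:  # exons ordered 3'->5' genomically descending
            if s <= g < e:
                return pos + (e - 1 - g)
            pos += e - s
    raise ValueError(f"genomic position {g} not exonic")


def _build_model(
    gene_id: str,
    tx_id: str,
    chrom_seq,
    strand: str,
    exons: list[tuple[int, int]],
    cds: list[tuple[int, int]],
) -> TranscriptModel | None:
    # transcription order
    exons = sorted(exons)
    if strand == "-":
        exons = exons[::-1]
    pieces = []
    for s, e in exons:
        frag = str(chrom_seq[s:e])
        pieces.append(revcomp_dna(frag) if strand == "-" else frag.upper())
    spliced = rna("".join(pieces))
    n = len(spliced)

    cds = sorted(cds)
    cds_len = sum(e - s for s, e in cds)
    if cds_len % 3 != 0 or cds_len < 3:
        warnings.warn(f"{tx_id}: CDS length {cds_len} not a multiple of 3; skipped")
        return None
    if strand == "+":
        cds_start_g = cds[0][0]
    else:
        cds_start_g = cds[-1][1] - 1
    utr5_len = _spliced_offset(exons, strand, cds_start_g)
    orf_len = cds_len
    # Ensembl-style CDS excludes the stop codon; absorb it into the ORF when
    # the next in-frame triplet is a stop.
    nxt = spliced[utr5_len + orf_len : utr5_len + orf_len + 3]
    if nxt in STOP_CODONS:
        orf_len += 3
    utr3_len = n - utr5_len - orf_len

    junctions = []
    acc = 0
    for s, e in exons[:-1]:
        acc += e - s
        junctions.append(acc)
    intron_total = 0
    gen_sorted = sorted(exons)
    for (s1, e1), (s2, e2) in zip(gen_sorted, gen_sorted[1:]):
        intron_total += s2 - e1
    try:
        return TranscriptModel(
            gene_id=gene_id,
            transcript_id=tx_id,
            spliced_seq=spliced,
            utr5_len=utr5_len,
            orf_len=orf_len,
            utr3_len=utr3_len,
            exon_junctions=tuple(junctions),
            intron_len_total=intron_total,
        )
    except ValueError as exc:
        warnings.warn(f"{tx_id}: {exc}; skipped")
        return None


def load_transcript_models(
    gtf_path: str, fasta_path: str, representative: bool = True
) -> dict[str, TranscriptModel]:
    """Load transcript models from an Ensembl-dialect GTF and genome FASTA.

    Returns a mapping keyed by gene ID when ``representative`` is true
    (one model per gene), otherwise by transcript ID (all coding
    transcripts).  Non-coding transcripts and malformed CDSs are skipped
    with a warning.
    """
    db = gffutils.create_db(
        gtf_path,
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    genome = Fasta(fasta_path, as_raw=True, sequence_always_upper=True)
    out: dict[str, TranscriptModel] = {}
    for gene in db.features_of_type("gene"):
        gene_id = gene.attributes["gene_id"][0]
        models = []
        for tx in db.children(gene, featuretype="transcript"):
            tx_id = tx.attributes["transcript_id"][0]
            exons = [
                (f.start - 1, f.end)
                for f in db.children(tx, featuretype="exon")
            ]
            cds = [
                (f.start - 1, f.end)
                for f in db.children(tx, featuretype="CDS")
            ]
            if not cds:
                warnings.warn(f"{tx_id}: no annotated CDS; skipped")
                continue
            model = _build_model(
                gene_id, tx_id, genome[gene.seqid], tx.strand, exons, cds
            )
            if model is not None:
                models.append(model)
        if not models:
            warnings.warn(f"gene {gene_id}: no usable coding transcript; skipped")
            continue
        if representative:
            out[gene_id] = select_representative_transcript(models)
        else:
            for mdl in models:
                out[mdl.transcript_id] = mdl
    return out
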