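"""Synthetic transcriptomes and half-life compendia with planted truth.

The transcriptome generator emits random annotated mRNAs whose latent
(log-scale) half-life is an additive function of known stability
determinants -- ORF exon-junction density (stabilizing), codon composition
(a fixed 61-weight vector), and destabilizing 3'UTR motifs with
position-dependent weight (an AU-rich element peaking at the 3'UTR termini
and a Pumilio-like element) -- plus Gaussian noise.  Every contribution is
recorded in an effect ledger so downstream models can be scored against
ground truth.  Matching FASTA/GTF fixtures are emitted so the real
annotation-ingestion path is exercised end to end.

The compendium generator turns latent half-lives into a multi-study
gene x sample matrix with the pathologies the harmonization pipeline is
built to remove: per-study offsets, a shared gene-wise bias between pulse
labeling and transcriptional shutoff protocols, cell-type effects,
per-sample monotone (cubic) distortions, mixed units (hours / minutes /
degradation rates), sampling noise, and missingness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compendium import HalfLifeMatrix, SampleMeta
from .features import CODONS61, codon_frequencies
from .transcripts import STOP_CODONS, TranscriptModel, revcomp_dna

__all__ = [
    "MotifEffect",
    "GenerativeSpec",
    "CompendiumSpec",
    "SyntheticTranscriptome",
    "gen_transcriptome",
    "gen_latent_halflives",
    "gen_compendium_matrix",
    "default_codon_weights",
]

_BASES = np.array(list("ACGU"))
SENSE_CODONS = CODONS61


def default_codon_weights(scale: float = 4.0, seed: int = 2718) -> pd.Series:
    """A fixed random codon-weight vector (mean 0) used as generator default.

    The scale is chosen so the across-gene spread of the codon contribution
    is comparable to the motif and junction terms.
    """
    rng = np.random.default_rng(seed)
    w = rng.normal(0.0, scale, size=len(SENSE_CODONS))
    return pd.Series(w - w.mean(), index=SENSE_CODONS)


def _pos_weight(name: str, pct: float) -> float:
    if name == "u_shaped":
        return (2.0 * pct - 1.0) ** 2
    if name == "flat":
        return 1.0
    raise ValueError(f"unknown positional weight {name!r}")


@dataclass(frozen=True)
class MotifEffect:
    """A k-mer with a base effect and positional weight over its region."""

    kmer: str
    effect: float
    region: str = "utr3"
    pos_weight: str = "u_shaped"
    plant_rate: float = 0.8  # expected planted occurrences per gene

    def weight_at(self, pct: float) -> float:
        return _pos_weight(self.pos_weight, pct)


DEFAULT_MOTIFS = (
    MotifEffect("UAUUUAU", -0.5, "utr3", "u_shaped", plant_rate=0.8),
    MotifEffect("UGUAAAUA", -0.4, "utr3", "flat", plant_rate=0.5),
)


@dataclass(frozen=True)
class GenerativeSpec:
    """Transcriptome generator settings (lengths in nt, effects on log scale)."""

    n_genes: int = 3000
    utr5_lognorm: tuple[float, float] = (math.log(110.0), 0.40)
    orf_codons_lognorm: tuple[float, float] = (math.log(170.0), 0.35)
    utr3_lognorm: tuple[float, float] = (math.log(260.0), 0.50)
    min_utr: int = 20
    min_codons: int = 40
    exon_rate: float = 4.0            # extra exons ~ Poisson(rate)
    intron_lognorm: tuple[float, float] = (math.log(200.0), 0.6)
    gc: float = 0.45
    junction_coef: float = 0.12       # per ORF junction per kb of ORF
    codon_weights: tuple[float, ...] = tuple(default_codon_weights())
    motif_effects: tuple[MotifEffect, ...] = DEFAULT_MOTIFS
    noise_sd: float = 0.1
    minus_strand_frac: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.codon_weights) != len(SENSE_CODONS):
            raise ValueError("codon_weights must have 61 entries")


@dataclass
class GeneLayout:
    """Genomic placement of one synthetic gene on its own contig."""

    chrom: str
    strand: str
    contig_dna: str
    exons: list[tuple[int, int]]       # genomic, 0-based half-open
    cds: list[tuple[int, int]]         # genomic, stop codon excluded


@dataclass
class SyntheticTranscriptome:
    spec: GenerativeSpec
    transcripts: dict[str, TranscriptModel]
    layouts: dict[str, GeneLayout]

    def write_fasta(self, path: str, width: int = 60) -> None:
        with open(path, "w") as fh:
            for gene in self.transcripts:
                lay = self.layouts[gene]
                fh.write(f">{lay.chrom}\n")
                s = lay.contig_dna
                for i in range(0, len(s), width):
                    fh.write(s[i : i + width] + "\n")

    def write_gtf(self, path: str, source: str = "decaykit_synth") -> None:
        def attr(gene, tx=None):
            a = f'gene_id "{gene}";'
            if tx:
                a += f' transcript_id "{tx}";'
            return a

        with open(path, "w") as fh:
            for gene, lay in self.layouts.items():
                tx = f"{gene}.t1"
                g_lo = min(s for s, _ in lay.exons)
                g_hi = max(e for _, e in lay.exons)
                rows = [
                    (lay.chrom, source, "gene", g_lo + 1, g_hi, ".", lay.strand,
                     ".", attr(gene)),
                    (lay.chrom, source, "transcript", g_lo + 1, g_hi, ".",
                     lay.strand, ".", attr(gene, tx)),
                ]
                for s, e in sorted(lay.exons):
                    rows.append((lay.chrom, source, "exon", s + 1, e, ".",
                                 lay.strand, ".", attr(gene, tx)))
                pieces = sorted(lay.cds)
                if lay.strand == "-":
                    pieces = pieces[::-1]
                phase, acc = 0, 0
                framed = []
                for s, e in pieces:
                    framed.append((s, e, (3 - acc % 3) % 3))
                    acc += e - s
                for s, e, frame in sorted(framed):
                    rows.append((lay.chrom, source, "CDS", s + 1, e, ".",
                                 lay.strand, str(frame), attr(gene, tx)))
                for row in rows:
                    fh.write("\t".join(str(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# transcriptome generation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _random_orf(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    body = []
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    while len(body) < n_codons - 2:
        cod = "".join(rng.choice(_BASES, size=3, p=p))
        if cod not in STOP_CODONS and cod != "AUG":
            body.append(cod)
    stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    return "AUG" + "".join(body) + stop


def gen_transcriptome(spec: GenerativeSpec) -> SyntheticTranscriptome:
    """Generate transcripts plus genomic layouts for FASTA/GTF fixtures."""
    rng = np.random.default_rng(spec.seed)
    transcripts: dict[str, TranscriptModel] = {}
    layouts: dict[str, GeneLayout] = {}
    for gi in range(spec.n_genes):
        gene = f"G{gi:05d}"
        u5 = max(spec.min_utr, int(rng.lognormal(*spec.utr5_lognorm)))
        nc = max(spec.min_codons, int(rng.lognormal(*spec.orf_codons_lognorm)))
        u3 = max(spec.min_utr, int(rng.lognormal(*spec.utr3_lognorm)))
        utr5 = _random_seq(rng, u5, spec.gc)
        orf = _random_orf(rng, nc, spec.gc)
        utr3 = list(_random_seq(rng, u3, spec.gc))
        # plant destabilizing motifs at random positions of their region
        for m in spec.motif_effects:
            if m.region != "utr3":
                continue
            for _ in range(rng.poisson(m.plant_rate)):
                if u3 <= len(m.kmer):
                    break
                p = int(rng.integers(0, u3 - len(m.kmer)))
                utr3[p : p + len(m.kmer)] = list(m.kmer)
        utr3 = "".join(utr3)
        spliced = utr5 + orf + utr3
        n = len(spliced)

        n_exons = 1 + int(rng.poisson(spec.exon_rate))
        n_exons = min(n_exons, n - 1)
        junctions = tuple(
            sorted(rng.choice(np.arange(1, n), size=n_exons - 1, replace=False))
        ) if n_exons > 1 else ()
        intron_lens = [
            max(30, int(rng.lognormal(*spec.intron_lognorm)))
            for _ in junctions
        ]
        strand = "-" if rng.random() < spec.minus_strand_frac else "+"

        t = TranscriptModel(
            gene_id=gene,
            transcript_id=f"{gene}.t1",
            spliced_seq=spliced,
            utr5_len=u5,
            orf_len=3 * nc,
            utr3_len=u3,
            exon_junctions=junctions,
            intron_len_total=int(sum(intron_lens)),
        )
        transcripts[gene] = t
        layouts[gene] = _layout(gene, t, intron_lens, strand, rng)
    return SyntheticTranscriptome(spec=spec, transcripts=transcripts,
                                  layouts=layouts)


def _to_genomic(iv: tuple[int, int], gmap: list[tuple[int, int, int]]
                ) -> list[tuple[int, int]]:
    """Split a spliced half-open interval across plus-strand exon pieces."""
    out = []
    lo, hi = iv
    for s_lo, s_hi, g_lo in gmap:
        a, b = max(lo, s_lo), min(hi, s_hi)
        if a < b:
            out.append((g_lo + (a - s_lo), g_lo + (b - s_lo)))
    return out


def _layout(gene: str, t: TranscriptModel, intron_lens: list[int],
            strand: str, rng: np.random.Generator) -> GeneLayout:
    bounds = [0, *t.exon_junctions, t.length]
    exon_spans = list(zip(bounds[:-1], bounds[1:]))
    gmap = []  # (spliced_lo, spliced_hi, genomic_lo) on the plus pre-mRNA
    g = 0
    pre = []
    for i, (lo, hi) in enumerate(exon_spans):
        gmap.append((lo, hi, g))
        pre.append(t.spliced_seq[lo:hi])
        g += hi - lo
        if i < len(intron_lens):
            intron = "GU" + "".join(
                rng.choice(_BASES, size=max(0, intron_lens[i] - 4))
            ) + "AG"
            pre.append(intron)
            g += len(intron)
    pre_rna = "".join(pre)
    contig_plus = pre_rna.replace("U", "T")
    exons_g = _to_genomic((0, t.length), gmap)
    cds_g = _to_genomic(
        (t.utr5_len, t.utr5_len + t.orf_len - 3), gmap  # GTF CDS excludes stop
    )
    if strand == "-":
        L = len(contig_plus)
        flip = lambda iv: (L - iv[1], L - iv[0])
        exons_g = sorted(flip(iv) for iv in exons_g)
        cds_g = sorted(flip(iv) for iv in cds_g)
        contig = revcomp_dna(contig_plus)
    else:
        contig = contig_plus
    return GeneLayout(chrom=f"chr_{gene}", strand=strand, contig_dna=contig,
                      exons=sorted(exons_g), cds=sorted(cds_g))


# ---------------------------------------------------------------------------
# latent half-lives
# ---------------------------------------------------------------------------

def _motif_term(t: TranscriptModel, m: MotifEffect) -> float:
    lo, hi = t.region_bounds(m.region)
    seq = t.spliced_seq[lo:hi]
    total, start = 0.0, 0
    L = hi - lo
    while True:
        p = seq.find(m.kmer, start)
        if p < 0:
            break
        center = (p + len(m.kmer) / 2.0) / max(1, L)
        total += m.effect * m.weight_at(center)
        start = p + 1
    return total


def gen_latent_halflives(
    transcripts: dict[str, TranscriptModel], spec: GenerativeSpec
) -> tuple[pd.Series, pd.DataFrame]:
    """Latent log-scale half-life per gene plus the full effect ledger.

    latent = junction_coef * ORF-junction density
             + sum_c w_c * codon frequency_c
             + sum over motif occurrences of effect * pos_weight
             + Gaussian noise.

    Motif terms scan the *final* sequence, so chance occurrences count
    exactly like planted ones and the latent is a true function of the
    emitted sequence.
    """
    rng = np.random.default_rng([spec.seed, 7777])
    w = pd.Series(spec.codon_weights, index=SENSE_CODONS)
    rows = {}
    for gene, t in transcripts.items():
        orf_lo, orf_hi = t.region_bounds("orf")
        n_j = sum(1 for j in t.exon_junctions if orf_lo < j < orf_hi)
        density = n_j / (t.orf_len / 1000.0)
        freqs = codon_frequencies(t)
        freqs.index = [c.replace("codon_", "") for c in freqs.index]
        row = {"junction": spec.junction_coef * density,
               "codon": float((w * freqs).sum())}
        for m in spec.motif_effects:
            row[f"motif_{m.kmer}"] = _motif_term(t, m)
        row["noise"] = float(rng.normal(0.0, spec.noise_sd))
        rows[gene] = row
    ledger = pd.DataFrame(rows).T
    ledger["latent"] = ledger.sum(axis=1)
    return ledger["latent"].rename("latent"), ledger


# ---------------------------------------------------------------------------
# compendium generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompendiumSpec:
    """Multi-study compendium settings.

    ``class_bias_sd`` scales a gene-wise bias vector shared by all
    transcriptional-shutoff samples -- the systematic disagreement between
    method classes that shows up on sample PC2.
    """

    n_samples: int = 20
    n_studies: int = 10
    species: str = "human"
    noise_sd: float = 0.5
    missing_rate: float = 0.3
    class_bias_sd: float = 0.4
    celltype_sd: float = 0.3
    study_offset_sd: float = 0.2
    distortion_cubic_max: float = 0.1
    length_missing_bias: float = 0.0
    minutes_frac: float = 0.3
    rate_frac: float = 0.1
    cell_types: tuple[str, ...] = ("HeLa", "K562", "HEK293", "MCF7")
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0,1)")
        if self.n_studies > self.n_samples:
            raise ValueError("need at least one sample per study")


def gen_compendium_matrix(
    latents: pd.Series,
    cspec: CompendiumSpec,
    lengths: pd.Series | None = None,
) -> tuple[HalfLifeMatrix, dict]:
    """Simulate a raw multi-study half-life matrix from latent values.

    Each sample observes ``monotone distortion(latent-z + study offset +
    class bias + cell-type effect + noise)`` mapped onto its unit scale
    (hours, minutes, or a degradation rate); cells are dropped at the
    missingness rate, optionally biased by mRNA length.
    """
    rng = np.random.default_rng(cspec.seed)
    genes = list(latents.index)
    z = (latents - latents.mean()) / latents.std(ddof=1)
    zv = z.to_numpy()
    n_g, n_s = len(genes), cspec.n_samples

    class_bias = rng.normal(0.0, cspec.class_bias_sd, size=n_g)
    ct_effects = {
        ct: rng.normal(0.0, cspec.celltype_sd, size=n_g)
        for ct in cspec.cell_types
    }
    study_offsets = rng.normal(0.0, cspec.study_offset_sd, size=cspec.n_studies)

    n_rate = int(round(cspec.rate_frac * n_s))
    rate_idx = set(rng.choice(n_s, size=n_rate, replace=False).tolist())

    cols, metas = {}, []
    truth_signal = {}
    for i in range(n_s):
        study_i = i * cspec.n_studies // n_s
        shutoff = study_i % 2 == 1
        method = "ActD" if shutoff else "4sU"
        ct = cspec.cell_types[study_i % len(cspec.cell_types)]
        sig = zv + study_offsets[study_i] + ct_effects[ct]
        if shutoff:
            sig = sig + class_bias
        sig = sig + rng.normal(0.0, cspec.noise_sd, size=n_g)
        b = rng.uniform(0.0, cspec.distortion_cubic_max)
        sig = sig + b * sig**3
        truth_signal[f"S{i:02d}"] = sig.copy()

        hours = 10.0 ** (0.35 * sig + 0.6)
        sid = f"S{i:02d}"
        if i in rate_idx:
            vals = np.log(2.0) / hours
            meta = SampleMeta(sid, f"study{study_i}", cspec.species, ct, method,
                              unit=None, is_degradation_rate=True)
        elif rng.random() < cspec.minutes_frac:
            vals = hours * 60.0
            meta = SampleMeta(sid, f"study{study_i}", cspec.species, ct, method,
                              unit="minutes")
        else:
            vals = hours
            meta = SampleMeta(sid, f"study{study_i}", cspec.species, ct, method,
                              unit="hours")
        p_miss = np.full(n_g, cspec.missing_rate)
        if cspec.length_missing_bias and lengths is not None:
            lz = (lengths.loc[genes] - lengths.mean()) / lengths.std(ddof=1)
            p_miss = np.clip(
                p_miss + cspec.length_missing_bias * lz.to_numpy(), 0.02, 0.95
            )
        miss = rng.random(n_g) < p_miss
        vals = vals.astype(float)
        vals[miss] = np.nan
        cols[sid] = vals
        metas.append(meta)

    table = pd.DataFrame(cols, index=genes)
    truth = {
        "latent_z": z,
        "class_bias": pd.Series(class_bias, index=genes),
        "celltype_effects": {k: pd.Series(v, index=genes)
                             for k, v in ct_effects.items()},
        "study_offsets": study_offsets,
        "signals": pd.DataFrame(truth_signal, index=genes),
    }
    return HalfLifeMatrix(values=table, samples=metas, stage="raw"), truth
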