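"""Sequence-derived and biochemical feature groups for half-life modeling.

Features live in a :class:`FeatureTable` (gene x feature matrix) where every
feature carries a single-letter group label used to assemble model codes
("BC3MS" = basic + codons + 3'UTR k-mers + miRNA + SeqWeaver-style scores):

====== =========================================================
letter group
====== =========================================================
B      basic mRNA properties (8 features)
C      codon frequencies, stop codons excluded (61)
5/O/3  1..7-mer frequencies of the 5'UTR / ORF / 3'UTR (21,844 each)
M      miRNA repression scores (negated context++ scores)
S/D    windowed RBP-binding predictions (two external predictors)
E/e/m  CLIP / eCLIP / m6A-pathway peak counts
P      PAR-CLIP peak counts
R      RIP-seq enrichments and translational efficiency
====== =========================================================
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .transcripts import STOP_CODONS, TranscriptModel

__all__ = [
    "FeatureTable",
    "PeakSet",
    "CODONS61",
    "ALL_CODONS",
    "basic_features",
    "codon_frequencies",
    "kmer_frequencies",
    "kmer_feature_names",
    "window_average_scores",
    "peak_count_features",
    "ingest_score_table",
    "impute_feature_missing",
    "build_feature_table",
]

_BASES = "ACGU"
ALL_CODONS = tuple("".join(c) for c in itertools.product(_BASES, repeat=3))
CODONS61 = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

REGIONS = ("utr5", "orf", "utr3")
_REGION_GROUP = {"utr5": "5", "orf": "O", "utr3": "3"}


@dataclass
class FeatureTable:
    """Gene x feature matrix; ``groups`` maps each feature to its group letter."""

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self):
        if list(self.values.columns) != list(self.groups.index):
            raise ValueError("groups index must match feature columns")
        if self.groups.isna().any():
            raise ValueError("every feature needs a group")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def group_sizes(self) -> dict[str, int]:
        return self.groups.value_counts().to_dict()

    def select_groups(self, letters: str) -> "FeatureTable":
        seen = set()
        for ch in letters:
            if ch in seen:
                raise ValueError(f"duplicate group letter {ch!r} in {letters!r}")
            seen.add(ch)
        missing = seen - set(self.groups.unique())
        if missing:
            raise KeyError(f"groups not present in table: {sorted(missing)}")
        keep = self.groups.isin(seen)
        return FeatureTable(self.values.loc[:, keep.values], self.groups[keep])

    def join(self, other: "FeatureTable") -> "FeatureTable":
        if not self.values.index.equals(other.values.index):
            other_vals = other.values.reindex(self.values.index)
        else:
            other_vals = other.values
        return FeatureTable(
            pd.concat([self.values, other_vals], axis=1),
            pd.concat([self.groups, other.groups]),
        )

    def to_tsv(self, path: str, manifest_path: str | None = None) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")
        if manifest_path:
            self.groups.rename("group").to_csv(
                manifest_path, sep="\t", index_label="feature"
            )

    @classmethod
    def from_tsv(cls, path: str, manifest_path: str) -> "FeatureTable":
        vals = pd.read_csv(path, sep="\t", index_col="gene_id")
        groups = pd.read_csv(manifest_path, sep="\t", index_col="feature")["group"]
        return cls(vals, groups)


@dataclass(frozen=True)
class PeakSet:
    """Genomic peak calls for one factor: (chrom, start, end, strand) tuples."""

    factor: str
    intervals: tuple[tuple[str, int, int, str], ...]

    def __post_init__(self):
        for chrom, start, end, strand in self.intervals:
            if start >= end:
                raise ValueError(
                    f"{self.factor}: malformed interval {chrom}:{start}-{end}"
                )
            if strand not in "+-":
                raise ValueError(f"{self.factor}: bad strand {strand!r}")


# ---------------------------------------------------------------------------
# sequence features
# ---------------------------------------------------------------------------

def _gc_fraction(seq: str) -> float:
    informative = len(seq) - seq.count("N")
    if informative == 0:
        return np.nan
    return (seq.count("G") + seq.count("C")) / informative


def _loglen(x: int) -> float:
    return float(np.log10(x + 0.1))


def basic_features(t: TranscriptModel) -> dict[str, float]:
    """Eight basic mRNA properties.

    Region lengths and total intron length are log10(x+0.1)-transformed to
    reduce right skew; junction density counts exon junctions strictly
    inside the ORF per kilobase of ORF.
    """
    orf_lo, orf_hi = t.region_bounds("orf")
    n_orf_junc = sum(1 for j in t.exon_junctions if orf_lo < j < orf_hi)
    return {
        "utr5_gc": _gc_fraction(t.utr5_seq),
        "orf_gc": _gc_fraction(t.orf_seq),
        "utr3_gc": _gc_fraction(t.utr3_seq),
        "utr5_len": _loglen(t.utr5_len),
        "orf_len": _loglen(t.orf_len),
        "utr3_len": _loglen(t.utr3_len),
        "intron_len": _loglen(t.intron_len_total),
        "orf_junction_density": n_orf_junc / (t.orf_len / 1000.0),
    }


def codon_frequencies(t: TranscriptModel) -> pd.Series:
    """Frequencies of the 61 sense codons over the ORF.

    Codons are read non-overlapping; the denominator is the total codon
    count including stop codons, whose own frequencies are then dropped.
    Codons containing N are excluded from numerator and denominator.
    """
    orf = t.orf_seq
    if len(orf) < 3:
        raise ValueError(f"{t.transcript_id}: ORF shorter than one codon")
    counts: dict[str, int] = {}
    total = 0
    for i in range(0, len(orf) - len(orf) % 3, 3):
        codon = orf[i : i + 3]
        if "N" in codon:
            continue
        counts[codon] = counts.get(codon, 0) + 1
        total += 1
    if total == 0:
        return pd.Series(np.nan, index=[f"codon_{c}" for c in CODONS61])
    freqs = {f"codon_{c}": counts.get(c, 0) / total for c in CODONS61}
    return pd.Series(freqs)


def kmer_feature_names(region: str, k_range=range(1, 8)) -> list[str]:
    names = []
    for k in k_range:
        for mer in itertools.product(_BASES, repeat=k):
            names.append(f"{region}_{''.join(mer)}")
    return names


def _kmer_counts_one_k(codes: np.ndarray, k: int) -> np.ndarray:
    """Counts of all 4^k overlapping k-mers; N-containing windows excluded."""
    n = len(codes)
    out = np.zeros(4**k, dtype=np.int64)
    if n < k:
        return out
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return out
    weights = 4 ** np.arange(k - 1, -1, -1)
    idx = windows[valid] @ weights
    np.add.at(out, idx, 1)
    return out


def kmer_frequencies(
    t: TranscriptModel, region: str, k_range=range(1, 8)
) -> pd.Series:
    """Overlapping k-mer frequencies of one functional region.

    Within each k, counts are normalized by the total valid window count of
    that k, so each k forms a proper distribution (zeros when the region is
    shorter than k).  The default k=1..7 yields 21,844 features.
    """
    seq = {"utr5": t.utr5_seq, "orf": t.orf_seq, "utr3": t.utr3_seq}[region]
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        lut[ord(b)] = i
    codes = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    parts = []
    for k in k_range:
        counts = _kmer_counts_one_k(codes, k)
        total = counts.sum()
        parts.append(counts / total if total > 0 else counts.astype(float))
    vals = np.concatenate(parts)
    return pd.Series(vals, index=kmer_feature_names(region, k_range))


def window_average_scores(
    t: TranscriptModel,
    region: str,
    predictor,
    window: int = 50,
    flank: int = 475,
) -> pd.Series:
    """Average windowed predictor scores over one functional region.

    The region is tiled in ``window``-nt steps; each window is padded with
    ``flank`` nt of neighboring *transcript* sequence on both sides (N where
    the transcript ends) and passed to ``predictor``, which returns a
    mapping of factor name to score for that padded window.  Per-factor
    sums are normalized by the region length.
    """
    lo, hi = t.region_bounds(region)
    region_len = hi - lo
    if region_len < 1:
        return pd.Series(dtype=float)
    totals: dict[str, float] = {}
    seq = t.spliced_seq
    for start in range(lo, hi, window):
        pad_lo = start - flank
        pad_hi = start + window + flank
        left_n = max(0, -pad_lo)
        right_n = max(0, pad_hi - len(seq))
        core = seq[max(0, pad_lo) : min(len(seq), pad_hi)]
        padded = "N" * left_n + core + "N" * right_n
        scores = predictor(padded)
        for factor, val in scores.items():
            totals[factor] = totals.get(factor, 0.0) + float(val)
    return pd.Series({f: v / region_len for f, v in totals.items()})


# ---------------------------------------------------------------------------
# biochemical features
# ---------------------------------------------------------------------------

def peak_count_features(
    gene_bodies: dict[str, tuple[str, int, int, str]],
    peaks: list[PeakSet],
    group: str = "E",
) -> FeatureTable:
    """Strand-aware peak counts per gene body, log10(x+1)-transformed.

    ``gene_bodies`` maps gene ID to its (chrom, start, end, strand) span
    (0-based half-open).  A peak counts toward a gene when they share the
    chromosome and strand and overlap by at least 1 bp.
    """
    from intervaltree import IntervalTree

    trees: dict[tuple[str, str], IntervalTree] = {}
    for ps in peaks:
        for chrom, start, end, strand in ps.intervals:
            trees.setdefault((chrom, strand, ps.factor), IntervalTree()).addi(
                start, end
            )
    genes = list(gene_bodies)
    data = {}
    for ps in peaks:
        counts = []
        for g in genes:
            chrom, start, end, strand = gene_bodies[g]
            tree = trees.get((chrom, strand, ps.factor))
            counts.append(len(tree.overlap(start, end)) if tree else 0)
        data[f"peaks_{ps.factor}"] = np.log10(np.asarray(counts) + 1.0)
    vals = pd.DataFrame(data, index=genes)
    groups = pd.Series(group, index=vals.columns)
    return FeatureTable(vals, groups)


def ingest_score_table(
    table: pd.DataFrame,
    gene_universe: list[str],
    group: str,
    transform: str = "identity",
) -> FeatureTable:
    """Attach an external per-gene score table as feature columns.

    ``transform`` is one of ``identity``, ``negate`` (used for miRNA
    cumulative context++ scores, where more negative means more repression)
    or ``log10p1``.  Duplicate gene rows are averaged with a warning;
    genes of the universe absent from the table become NaN.
    """
    if table.index.has_duplicates:
        warnings.warn("duplicate gene rows in score table; averaging")
        table = table.groupby(level=0, sort=False).mean()
    vals = table.reindex(gene_universe).astype(float)
    if transform == "negate":
        vals = -vals
    elif transform == "log10p1":
        vals = np.log10(vals + 1.0)
    elif transform != "identity":
        raise ValueError(f"unknown transform {transform!r}")
    groups = pd.Series(group, index=vals.columns)
    return FeatureTable(vals, groups)


def impute_feature_missing(
    f: FeatureTable, anchor_features: list[str]
) -> FeatureTable:
    """Impute missing feature cells from complete anchor columns.

    Each incomplete column is regressed on the anchors (partial-least-
    squares linear predictor fit on its observed rows) and missing cells
    are filled with the fitted values; observed cells are unchanged.
    Columns missing everywhere are dropped with a warning.
    """
    from sklearn.cross_decomposition import PLSRegression

    vals = f.values.copy()
    groups = f.groups.copy()
    anchors = vals[anchor_features]
    if anchors.isna().any().any():
        raise ValueError("anchor features must be complete")
    A = anchors.to_numpy(dtype=float)
    drop = []
    for col in vals.columns:
        if col in anchor_features:
            continue
        y = vals[col].to_numpy(dtype=float)
        miss = np.isnan(y)
        if not miss.any():
            continue
        if miss.all():
            warnings.warn(f"feature {col!r} missing everywhere; dropped")
            drop.append(col)
            continue
        n_comp = min(len(anchor_features), int((~miss).sum()) - 1)
        if n_comp < 1:
            warnings.warn(f"feature {col!r}: too few observed rows; dropped")
            drop.append(col)
            continue
        pls = PLSRegression(n_components=n_comp, scale=True)
        pls.fit(A[~miss], y[~miss])
        y[miss] = pls.predict(A[miss]).ravel()
        vals[col] = y
    if drop:
        vals = vals.drop(columns=drop)
        groups = groups.drop(index=drop)
    return FeatureTable(vals, groups)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def build_feature_table(
    transcripts: dict[str, TranscriptModel],
    groups: str = "BC",
    k_range=range(1, 8),
) -> FeatureTable:
    """Compute sequence-derived groups (any of B, C, 5, O, 3) for all genes."""
    parts: list[FeatureTable] = []
    genes = list(transcripts)
    if "B" in groups:
        vals = pd.DataFrame(
            {g: basic_features(transcripts[g]) for g in genes}
        ).T.loc[genes]
        parts.append(FeatureTable(vals, pd.Series("B", index=vals.columns)))
    if "C" in groups:
        vals = pd.DataFrame(
            {g: codon_frequencies(transcripts[g]) for g in genes}
        ).T.loc[genes]
        parts.append(FeatureTable(vals, pd.Series("C", index=vals.columns)))
    for region, letter in _REGION_GROUP.items():
        if letter in groups:
            rows = [
                kmer_frequencies(transcripts[g], region, k_range).to_numpy()
                for g in genes
            ]
            vals = pd.DataFrame(
                np.vstack(rows),
                index=genes,
                columns=kmer_feature_names(region, k_range),
            )
            parts.append(FeatureTable(vals, pd.Series(letter, index=vals.columns)))
    if not parts:
        raise ValueError(f"no computable groups among {groups!r}")
    table = parts[0]
    for p in parts[1:]:
        table = table.join(p)
    return table
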