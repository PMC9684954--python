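"""Probing a trained half-life model: ISM, insertions, variants, reporters.

All probes share one discipline: the mutant transcript has *exactly* the
same length as the reference (substitution, never indel, except for
reporter-fragment insertion which builds a new construct), and the splice
and codon-frame tracks are held fixed even when a substitution would in
reality create or destroy a stop codon.  Effects are always reported as
``delta = prediction(alt) - prediction(ref)``, so negative means
destabilizing.

A "predictor" here is any callable mapping a batch tensor ``(B, L, 6)``
to predictions ``(B,)``; :func:`make_predictor` adapts a single model or a
trained ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .encoding import BASE_CHANNEL, encode_mrna
from .features import CODONS61
from .transcripts import TranscriptModel

__all__ = [
    "make_predictor",
    "IsmTrack",
    "ism",
    "ism_metagene",
    "InsertionProfile",
    "insert_motif_scan",
    "insert_codon_scan",
    "splice_mark_effect",
    "variant_effect",
    "smooth_track",
    "ReporterConstruct",
    "build_chimera",
    "reporter_effect",
    "matched_variant_benchmark",
]

_BASES = "ACGU"


def make_predictor(model, species: str, mode: str = "external", **kw):
    """Adapt a SalukiModel or TrainedEnsemble into a batch predictor."""
    if hasattr(model, "members"):
        return lambda X: model.predict(X, species, mode=mode, **kw)
    return lambda X: model.predict(X, species)


def _window_offset(t: TranscriptModel, l_max: int) -> int:
    return max(0, t.length - l_max)


def _set_base(tensor: np.ndarray, row: int, base: str) -> None:
    tensor[row, :4] = 0.0
    if base != "N":
        tensor[row, BASE_CHANNEL[base]] = 1.0


def _batched(predict, tensors: list[np.ndarray], batch: int) -> np.ndarray:
    out = []
    for i in range(0, len(tensors), batch):
        out.append(predict(np.stack(tensors[i : i + batch])))
    return np.concatenate(out) if out else np.empty(0)


# ---------------------------------------------------------------------------
# in silico saturation mutagenesis
# ---------------------------------------------------------------------------

@dataclass
class IsmTrack:
    """Per-position substitution effects for one transcript.

    ``deltas[i, j]`` is prediction(alt_j) - prediction(ref) at
    ``positions[i]``; rows for reference N are NaN.
    """

    gene_id: str
    positions: np.ndarray
    alts: np.ndarray            # (n, 3) alternative bases
    deltas: np.ndarray          # (n, 3)
    ref_prediction: float

    @property
    def mean_effect(self) -> np.ndarray:
        return np.nanmean(self.deltas, axis=1)

    @property
    def abs_mean_effect(self) -> np.ndarray:
        return np.abs(self.mean_effect)


def ism(
    predict,
    t: TranscriptModel,
    l_max: int,
    positions=None,
    batch: int = 512,
) -> IsmTrack:
    """Mutate each position to its three alternative bases and score deltas.

    Auxiliary tracks are held fixed (a stop-gain substitution does not blank
    the downstream codon track).  Positions must lie inside the encoded
    window; the 3' zero padding is not mutable.
    """
    offset = _window_offset(t, l_max)
    if positions is None:
        positions = np.arange(offset, t.length)
    positions = np.asarray(positions, dtype=int)
    if (positions >= t.length).any():
        bad = positions[positions >= t.length][0]
        raise ValueError(f"position {bad} is beyond the mRNA (3' padding)")
    if (positions < offset).any():
        bad = positions[positions < offset][0]
        raise ValueError(
            f"position {bad} was 5'-truncated out of the {l_max}-nt window"
        )
    wt = encode_mrna(t, l_max)
    ref_pred = float(predict(wt.tensor[None])[0])
    alts = np.empty((len(positions), 3), dtype="<U1")
    deltas = np.full((len(positions), 3), np.nan)
    tensors, where = [], []
    for i, pos in enumerate(positions):
        ref = t.spliced_seq[pos]
        if ref == "N":
            alts[i] = "N"
            continue
        row = pos - offset
        alt3 = [b for b in _BASES if b != ref]
        alts[i] = alt3
        for j, alt in enumerate(alt3):
            mut = wt.tensor.copy()
            _set_base(mut, row, alt)
            tensors.append(mut)
            where.append((i, j))
    preds = _batched(predict, tensors, batch)
    for (i, j), p in zip(where, preds):
        deltas[i, j] = p - ref_pred
    return IsmTrack(
        gene_id=t.gene_id,
        positions=positions,
        alts=alts,
        deltas=deltas,
        ref_prediction=ref_pred,
    )


def ism_metagene(
    tracks: dict[str, IsmTrack],
    transcripts: dict[str, TranscriptModel],
    predicted_halflife: pd.Series,
    n_quartiles: int = 4,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Aggregate |mean ISM effect| into (half-life quartile, region, bin).

    Positions map to percentile bins within their own functional region;
    transcripts are grouped into ``n_quartiles`` bins of their predicted
    half-life, and all positional values within a cell are averaged.
    """
    quart = pd.qcut(
        predicted_halflife.loc[list(tracks)], n_quartiles,
        labels=range(1, n_quartiles + 1),
    )
    rows = []
    for gene, track in tracks.items():
        t = transcripts[gene]
        q = int(quart[gene])
        vals = track.abs_mean_effect
        for region in ("utr5", "orf", "utr3"):
            lo, hi = t.region_bounds(region)
            if hi == lo:
                continue
            sel = (track.positions >= lo) & (track.positions < hi)
            if not sel.any():
                continue
            pct = (track.positions[sel] - lo) / (hi - lo)
            bins = np.minimum((pct * n_bins).astype(int), n_bins - 1)
            for b, v in zip(bins, vals[sel]):
                if np.isfinite(v):
                    rows.append((q, region, int(b), float(v)))
    df = pd.DataFrame(rows, columns=["quartile", "region", "bin", "value"])
    return df.groupby(["quartile", "region", "bin"], observed=True)["value"].mean()


# ---------------------------------------------------------------------------
# insertional analysis
# ---------------------------------------------------------------------------

@dataclass
class InsertionProfile:
    """Mean predicted change per positional bin for one inserted element."""

    element: str
    table: pd.DataFrame          # index (region, bin); columns mean_delta, n
    n_transcripts: int


def _valid_transcripts(
    transcripts: dict[str, TranscriptModel],
    min_utr5: int, min_orf: int, min_utr3: int,
) -> dict[str, TranscriptModel]:
    return {
        g: t for g, t in transcripts.items()
        if t.utr5_len >= min_utr5 and t.orf_len >= min_orf
        and t.utr3_len >= min_utr3
    }


def insert_motif_scan(
    predict,
    transcripts: dict[str, TranscriptModel],
    kmer: str,
    l_max: int,
    bins: int = 50,
    min_utr5: int = 100,
    min_orf: int = 500,
    min_utr3: int = 500,
    regions: tuple[str, ...] = ("utr5", "orf", "utr3"),
    batch: int = 512,
) -> InsertionProfile:
    """Overwrite the reference with ``kmer`` at each positional bin.

    The insertion replaces the reference sequence in place (length
    preserved); the anchor is the first position of each of ``bins``
    equal spans of the region, and anchors whose k-mer would overrun the
    region are skipped.  Deltas are averaged per (region, bin) across all
    valid mRNAs.
    """
    if set(kmer) - set(_BASES):
        raise ValueError(f"k-mer must be over ACGU, got {kmer!r}")
    valid = _valid_transcripts(transcripts, min_utr5, min_orf, min_utr3)
    if not valid:
        raise ValueError("no transcript passes the length validity filter")
    sums: dict[tuple[str, int], float] = {}
    counts: dict[tuple[str, int], int] = {}
    for t in valid.values():
        offset = _window_offset(t, l_max)
        wt = encode_mrna(t, l_max)
        wt_pred = float(predict(wt.tensor[None])[0])
        tensors, keys = [], []
        for region in regions:
            lo, hi = t.region_bounds(region)
            span = hi - lo
            for b in range(bins):
                anchor = lo + (b * span) // bins
                if anchor + len(kmer) > hi or anchor < offset:
                    continue
                mut = wt.tensor.copy()
                for i, base in enumerate(kmer):
                    _set_base(mut, anchor + i - offset, base)
                tensors.append(mut)
                keys.append((region, b))
        preds = _batched(predict, tensors, batch)
        for key, p in zip(keys, preds):
            sums[key] = sums.get(key, 0.0) + (p - wt_pred)
            counts[key] = counts.get(key, 0) + 1
    idx = pd.MultiIndex.from_tuples(sorted(sums), names=["region", "bin"])
    table = pd.DataFrame(
        {
            "mean_delta": [sums[k] / counts[k] for k in idx],
            "n": [counts[k] for k in idx],
        },
        index=idx,
    )
    return InsertionProfile(element=kmer, table=table, n_transcripts=len(valid))


def insert_codon_scan(
    predict,
    transcripts: dict[str, TranscriptModel],
    l_max: int,
    codons: tuple[str, ...] = CODONS61,
    bins: int = 50,
    min_utr5: int = 100,
    min_orf: int = 500,
    min_utr3: int = 500,
    batch: int = 512,
) -> tuple[pd.DataFrame, pd.Series]:
    """Insert each codon in-frame at each ORF bin; per-codon positional means.

    The replacement is anchored at the first in-frame codon start inside
    each bin's span.  Returns the (codon, bin) mean-delta table and the
    per-codon mean over all ORF bins -- the quantity comparable to codon
    stability coefficients.
    """
    valid = _valid_transcripts(transcripts, min_utr5, min_orf, min_utr3)
    if not valid:
        raise ValueError("no transcript passes the length validity filter")
    sums = np.zeros((len(codons), bins))
    counts = np.zeros((len(codons), bins), dtype=int)
    for t in valid.values():
        offset = _window_offset(t, l_max)
        lo, hi = t.region_bounds("orf")
        wt = encode_mrna(t, l_max)
        wt_pred = float(predict(wt.tensor[None])[0])
        anchors = []
        for b in range(bins):
            start = lo + (b * (hi - lo)) // bins
            inframe = lo + 3 * ((start - lo + 2) // 3)
            if inframe + 3 > hi or inframe < offset:
                continue
            anchors.append((b, inframe))
        tensors, keys = [], []
        for ci, codon in enumerate(codons):
            for b, pos in anchors:
                mut = wt.tensor.copy()
                for i, base in enumerate(codon):
                    _set_base(mut, pos + i - offset, base)
                tensors.append(mut)
                keys.append((ci, b))
        preds = _batched(predict, tensors, batch)
        for (ci, b), p in zip(keys, preds):
            sums[ci, b] += p - wt_pred
            counts[ci, b] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    table = pd.DataFrame(means, index=list(codons),
                         columns=pd.RangeIndex(bins, name="bin"))
    per_codon = pd.Series(np.nanmean(means, axis=1), index=list(codons),
                          name="mean_delta")
    return table, per_codon


def splice_mark_effect(
    predict,
    t: TranscriptModel,
    l_max: int,
    orf_only: bool = True,
) -> pd.Series:
    """Predicted change from erasing each splice-track mark.

    A stabilizing junction yields a negative removal delta.  ``orf_only``
    restricts to junctions strictly inside the ORF (the strongest known
    junction effect).
    """
    offset = _window_offset(t, l_max)
    lo, hi = t.region_bounds("orf")
    juncs = [
        j for j in t.exon_junctions
        if j >= offset and (not orf_only or lo < j < hi)
    ]
    if not juncs:
        return pd.Series(dtype=float)
    wt = encode_mrna(t, l_max)
    ref = float(predict(wt.tensor[None])[0])
    tensors = []
    for j in juncs:
        mut = wt.tensor.copy()
        mut[j - offset, 4] = 0.0
        tensors.append(mut)
    preds = predict(np.stack(tensors))
    return pd.Series(preds - ref, index=pd.Index(juncs, name="junction"))


# ---------------------------------------------------------------------------
# variants and reporters
# ---------------------------------------------------------------------------

def variant_effect(
    predict,
    t: TranscriptModel,
    pos: int,
    ref: str,
    alt: str,
    l_max: int,
) -> float:
    """delta = prediction(alt transcript) - prediction(ref transcript)."""
    if not 0 <= pos < t.length:
        raise ValueError(f"position {pos} outside transcript of length {t.length}")
    observed = t.spliced_seq[pos]
    if observed != ref:
        raise ValueError(
            f"{t.transcript_id}:{pos} reference mismatch: spec says {ref!r}, "
            f"transcript has {observed!r}"
        )
    offset = _window_offset(t, l_max)
    if pos < offset:
        raise ValueError(f"position {pos} was 5'-truncated out of the window")
    wt = encode_mrna(t, l_max)
    mut = wt.tensor.copy()
    _set_base(mut, pos - offset, alt)
    preds = predict(np.stack([wt.tensor, mut]))
    return float(preds[1] - preds[0])


def smooth_track(x: np.ndarray, window: int = 8) -> np.ndarray:
    """Centered moving average with a shrinking window at the edges."""
    x = np.asarray(x, dtype=float)
    left = window // 2
    right = window - left - 1
    csum = np.concatenate([[0.0], np.nancumsum(x)])
    cnt = np.concatenate([[0], np.cumsum(np.isfinite(x))])
    n = len(x)
    lo = np.maximum(0, np.arange(n) - left)
    hi = np.minimum(n, np.arange(n) + right + 1)
    tot = csum[hi] - csum[lo]
    m = cnt[hi] - cnt[lo]
    with np.errstate(invalid="ignore"):
        return np.where(m > 0, tot / m, np.nan)


@dataclass(frozen=True)
class ReporterConstruct:
    """A reporter scaffold (fixed 5'UTR/ORF) with a 3'UTR insertion site."""

    scaffold: TranscriptModel
    insert_site: int  # spliced coordinate inside the 3'UTR

    def __post_init__(self):
        lo, hi = self.scaffold.region_bounds("utr3")
        if not lo <= self.insert_site <= hi:
            raise ValueError(
                f"insert_site {self.insert_site} outside the scaffold 3'UTR "
                f"[{lo},{hi}]"
            )


def build_chimera(construct: ReporterConstruct, fragment: str) -> TranscriptModel:
    """Splice a fragment into the scaffold 3'UTR at the declared site."""
    s = construct.scaffold
    site = construct.insert_site
    seq = s.spliced_seq[:site] + fragment + s.spliced_seq[site:]
    junctions = tuple(
        j + len(fragment) if j >= site else j for j in s.exon_junctions
    )
    return TranscriptModel(
        gene_id=s.gene_id,
        transcript_id=f"{s.transcript_id}|frag{len(fragment)}",
        spliced_seq=seq,
        utr5_len=s.utr5_len,
        orf_len=s.orf_len,
        utr3_len=s.utr3_len + len(fragment),
        exon_junctions=junctions,
        intron_len_total=s.intron_len_total,
    )


def reporter_effect(
    predict,
    construct: ReporterConstruct,
    fragment: str,
    l_max: int,
) -> float:
    """Predicted half-life of the scaffold carrying ``fragment`` in its 3'UTR."""
    chim = build_chimera(construct, fragment) if fragment else construct.scaffold
    x = encode_mrna(chim, l_max).tensor
    return float(predict(x[None])[0])


# ---------------------------------------------------------------------------
# matched variant benchmarking
# ---------------------------------------------------------------------------

def _auroc_midrank(pos: np.ndarray, neg: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    n_pos, n_neg = len(pos), len(neg)
    r_pos = ranks[:n_pos].sum()
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def matched_variant_benchmark(
    variants: pd.DataFrame,
    score_col: str = "abs_delta",
    pip_hi: float = 0.9,
    pip_lo: float = 0.01,
) -> dict:
    """Causal-vs-matched-negative variant classification by |predicted delta|.

    Positives are variants with fine-mapping PIP > ``pip_hi``.  Each is
    matched (without replacement) to a negative with PIP < ``pip_lo`` from
    the same transcript region but a different gene, minimizing the gene-
    expression difference.  Returns the matched pairs and the midrank
    AUROC of the ``score_col`` ranking.
    """
    required = {"pip", "region", "expression", "gene", score_col}
    missing = required - set(variants.columns)
    if missing:
        raise ValueError(f"variants table lacks columns: {sorted(missing)}")
    pos = variants[variants["pip"] > pip_hi]
    cand = variants[variants["pip"] < pip_lo]
    used: set = set()
    pairs, unmatched = [], []
    for idx, row in pos.iterrows():
        pool = cand[
            (cand["region"] == row["region"])
            & (cand["gene"] != row["gene"])
            & (~cand.index.isin(used))
        ]
        if pool.empty:
            unmatched.append(idx)
            continue
        best = (pool["expression"] - row["expression"]).abs().idxmin()
        used.add(best)
        pairs.append((idx, best))
    if unmatched:
        raise ValueError(f"insufficient negatives for positives: {unmatched}")
    pos_scores = variants.loc[[a for a, _ in pairs], score_col].to_numpy(float)
    neg_scores = variants.loc[[b for _, b in pairs], score_col].to_numpy(float)
    return {
        "pairs": pd.DataFrame(pairs, columns=["positive", "negative"]),
        "auroc": _auroc_midrank(pos_scores, neg_scores),
        "n_pairs": len(pairs),
    }
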