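"""Fixed-width 6-track tensor encoding of spliced mRNAs.

Channels 0-3 one-hot encode A, C, G, U (N and 3' padding are all-zero);
channel 4 marks exon junctions (the 5'-most nucleotide of every non-first
exon); channel 5 marks the first nucleotide of every codon, which
implicitly delimits the ORF.  Sequences longer than ``l_max`` keep their
3'-most ``l_max`` nucleotides (the tracks shift with the sequence);
shorter sequences are zero-padded at the 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transcripts import TranscriptModel

__all__ = ["EncodedRNA", "encode_mrna", "decode_sequence", "encode_dataset"]

BASE_CHANNEL = {"A": 0, "C": 1, "G": 2, "U": 3}
_CHANNEL_BASE = "ACGU"


@dataclass
class EncodedRNA:
    """L_max x 6 tensor with the pre-padding length and species tag."""

    tensor: np.ndarray
    true_length: int
    species: str | None = None
    gene_id: str | None = None

    def __post_init__(self):
        if self.tensor.ndim != 2 or self.tensor.shape[1] != 6:
            raise ValueError("tensor must be (L_max, 6)")
        if not 0 < self.true_length <= self.tensor.shape[0]:
            raise ValueError("true_length out of range")


def encode_mrna(
    t: TranscriptModel, l_max: int, species: str | None = None
) -> EncodedRNA:
    """Encode one transcript; 5'-truncates to the 3'-most ``l_max`` nt."""
    seq = t.spliced_seq
    offset = max(0, len(seq) - l_max)
    window = seq[offset:]
    L = len(window)
    x = np.zeros((l_max, 6), dtype=np.float32)
    codes = np.frombuffer(window.encode(), dtype=np.uint8)
    for base, ch in BASE_CHANNEL.items():
        x[:L, ch][codes == ord(base)] = 1.0
    for j in t.exon_junctions:
        jj = j - offset
        if 0 <= jj < l_max:
            x[jj, 4] = 1.0
    for start in range(t.utr5_len, t.utr5_len + t.orf_len, 3):
        ss = start - offset
        if 0 <= ss < l_max:
            x[ss, 5] = 1.0
    return EncodedRNA(tensor=x, true_length=L, species=species, gene_id=t.gene_id)


def decode_sequence(e: EncodedRNA) -> str:
    """Invert the one-hot channels back to sequence (padding/N become N)."""
    L = e.true_length
    nt = e.tensor[:L, :4]
    out = np.full(L, "N", dtype="<U1")
    hot = nt.sum(axis=1) > 0
    out[hot] = np.array(list(_CHANNEL_BASE))[nt[hot].argmax(axis=1)]
    return "".join(out)


def encode_dataset(
    transcripts: dict[str, TranscriptModel],
    l_max: int,
    species: str | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Stack encodings for a transcript set; returns (n, l_max, 6) and gene order."""
    genes = list(transcripts)
    X = np.stack([encode_mrna(transcripts[g], l_max, species).tensor for g in genes])
    return X, genes
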