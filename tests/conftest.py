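"""Shared fixtures: small synthetic transcriptomes and transcript models."""

import numpy as np
import pytest

from decaykit import synth
from decaykit.transcripts import TranscriptModel


@pytest.fixture(scope="session")
def small_tome():
    """A 40-gene synthetic transcriptome with both strands represented."""
    spec = synth.GenerativeSpec(n_genes=40, seed=101)
    return synth.gen_transcriptome(spec)


@pytest.fixture(scope="session")
def small_spec(small_tome):
    return small_tome.spec


def make_transcript(
    utr5="ACGUACGUAC",
    orf="AUGAAACCCGGGUUUUAG",
    utr3="ACGUACGUACGUACGUACGU",
    junctions=(),
    intron_total=0,
    gene="gX",
):
    return TranscriptModel(
        gene_id=gene,
        transcript_id=f"{gene}.t1",
        spliced_seq=utr5 + orf + utr3,
        utr5_len=len(utr5),
        orf_len=len(orf),
        utr3_len=len(utr3),
        exon_junctions=tuple(junctions),
        intron_len_total=intron_total,
    )


@pytest.fixture
def toy_transcript():
    return make_transcript()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
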