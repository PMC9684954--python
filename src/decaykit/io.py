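"""TSV and checkpoint serialization helpers."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .compendium import SampleMeta
from .saluki import SalukiHyperparams, TrainedMember

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_meta_tsv",
    "write_meta_tsv",
    "write_consensus_tsv",
    "read_consensus_tsv",
    "save_member",
    "load_member",
]


def read_matrix_tsv(path: str) -> pd.DataFrame:
    """Sparse gene x sample matrix; empty cells are missing."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id", na_rep="")


_META_COLS = [
    "sample_id", "study", "species", "cell_type", "method", "unit",
    "is_degradation_rate",
]


def read_meta_tsv(path: str) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"is_degradation_rate": bool})
    metas = []
    for _, row in df.iterrows():
        unit = row.get("unit")
        if pd.isna(unit):
            unit = None
        metas.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                study=str(row["study"]),
                species=str(row["species"]),
                cell_type=str(row["cell_type"]),
                method=str(row["method"]),
                unit=unit,
                is_degradation_rate=bool(row.get("is_degradation_rate", False)),
            )
        )
    return metas


def write_meta_tsv(samples: list[SampleMeta], path: str) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "study": s.study,
                "species": s.species,
                "cell_type": s.cell_type,
                "method": s.method,
                "unit": s.unit,
                "is_degradation_rate": s.is_degradation_rate,
            }
            for s in samples
        ]
    ).to_csv(path, sep="\t", index=False)


def write_consensus_tsv(scores: pd.Series, path: str) -> None:
    scores.rename("pc1_score").to_csv(path, sep="\t", index_label="gene_id")


def read_consensus_tsv(path: str) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col="gene_id")["pc1_score"]


def save_member(member: TrainedMember, path: str) -> None:
    """One trained network as npz (arrays) + embedded JSON metadata."""
    meta = {
        "hyperparams": member.hyperparams.__dict__,
        "test_fold": member.test_fold,
        "replicate": member.replicate,
        "val_r": member.val_r,
    }
    np.savez_compressed(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **member.state,
    )


def load_member(path: str) -> TrainedMember:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    hp = dict(meta["hyperparams"])
    hp["heads"] = tuple(hp["heads"])
    return TrainedMember(
        state=state,
        hyperparams=SalukiHyperparams(**hp),
        test_fold=meta["test_fold"],
        replicate=meta["replicate"],
        val_r=meta["val_r"],
    )
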