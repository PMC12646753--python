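"""Reading and writing the pipeline's on-disk formats.

FASTA via Biopython, tab-separated tables via pandas, Newick trees via
dendropy.  The taxonomy/trait sidecar has the fixed header
``record_id order family subfamily bin reproduction lifestyle locomotion``.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable

import dendropy
import pandas as pd
from Bio import SeqIO

from .qc import SequenceRecord

TAXONOMY_COLUMNS = [
    "record_id",
    "order",
    "family",
    "subfamily",
    "bin",
    "reproduction",
    "lifestyle",
    "locomotion",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, seqs: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(TAXONOMY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"taxonomy table lacks columns: {sorted(missing)}")
    return df


def load_records(fasta: str | Path, taxonomy: str | Path) -> list[SequenceRecord]:
    """Join aligned sequences with their taxonomy/trait rows into records."""
    seqs = read_fasta(fasta)
    tax = read_taxonomy(taxonomy)
    records = []
    for row in tax.itertuples(index=False):
        if row.record_id not in seqs:
            raise KeyError(f"record {row.record_id} present in taxonomy but not FASTA")
        records.append(
            SequenceRecord(
                record_id=row.record_id,
                bin_id=row.bin,
                family=row.family,
                order=row.order,
                subfamily=row.subfamily,
                nt=seqs[row.record_id],
                traits={
                    "reproduction": row.reproduction,
                    "lifestyle": row.lifestyle,
                    "locomotion": row.locomotion,
                },
            )
        )
    return records


def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", extract_comment_metadata=True
    )


def write_tsv(path: str | Path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def records_to_frame(records: Iterable[SequenceRecord]) -> pd.DataFrame:
    rows = [
        {
            "record_id": r.record_id,
            "order": r.order,
            "family": r.family,
            "subfamily": r.subfamily,
            "bin": r.bin_id,
            "reproduction": r.traits.get("reproduction", ""),
            "lifestyle": r.traits.get("lifestyle", ""),
            "locomotion": r.traits.get("locomotion", ""),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=TAXONOMY_COLUMNS)
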