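"""Reading and writing the interchange formats (FASTA/FASTQ/TSV/YAML).

Thin wrappers over Biopython's SeqIO and pandas, so format handling stays
in one place.  All coordinates written by this package are 0-based
half-open on the sense strand.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file."""
    try:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot read FASTA {path}: {exc}") from exc


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path: str | Path) -> list[str]:
    """Read sequences (only) from a FASTQ file."""
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Write (id, sequence, quality-string) triples as Sanger FASTQ."""
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def write_collapsed_tags(tags, path: str | Path) -> None:
    """Collapsed-tag FASTA with headers ``tag{serial}_x{count}``."""
    write_fasta(
        ((f"tag{i}_x{t.count}", t.sequence) for i, t in enumerate(tags)), path
    )


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_count_table(path: str | Path):
    """Count TSV (gene_id, count_s1, count_s2, length_nt) -> CountRecords."""
    from .expression import CountRecord

    df = read_tsv(path)
    required = {"gene_id", "count_s1", "count_s2", "length_nt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"count table {path} lacks columns {sorted(missing)}")
    return [
        CountRecord(str(r.gene_id), int(r.count_s1), int(r.count_s2), int(r.length_nt))
        for r in df.itertuples(index=False)
    ]
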