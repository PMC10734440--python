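"""FASTA/FASTQ/TSV input-output helpers.

All sequence IO goes through Biopython; tables through pandas. FASTQ
qualities are Phred+33 throughout.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMMENT_CHAR = "#"


def reverse_complement(seq: str) -> str:
    """Reverse complement, IUPAC-aware (M -> K etc.)."""
    return str(Seq(seq).reverse_complement())


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[tuple[str, str, list[int]]]:
    """Read FASTQ (Phred+33) as (read_id, seq, quals) tuples."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append((rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]))
    return out


def write_fastq(reads: Iterable[tuple[str, str, list[int]]], path: str | Path) -> None:
    records = []
    for read_id, seq, quals in reads:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = list(quals)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_tsv(df: pd.DataFrame, path: str | Path, header_comment: str | None = None, **kwargs) -> None:
    """Write a TSV, optionally prefixed with '#'-comment provenance lines."""
    path = Path(path)
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", **kwargs)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"{COMMENT_CHAR} {line}\n")
        fh.write(buf.getvalue())


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment=COMMENT_CHAR, **kwargs)
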