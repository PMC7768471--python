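"""Readers and writers for the formats the pipeline exchanges.

FASTA/FASTQ go through Bio.SeqIO; tabular data through pandas TSV with an
optional ``# config=<hash>`` comment stamped in the first line; gene sets
through GMT.  All id-keyed readers reject duplicate identifiers and report
the offending line number.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class DuplicateIdError(ValueError):
    pass


# -- FASTA / FASTQ --------------------------------------------------------

def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if rec.id in out:
            raise DuplicateIdError(f"{path}: duplicate sequence id {rec.id!r} (record {i + 1})")
        out[rec.id] = str(rec.seq)
    return out


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]], quality: int = 40) -> None:
    """Write reads as FASTQ with a constant per-base quality."""
    records = []
    for name, seq in reads:
        rec = SeqRecord(Seq(seq), id=name, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


# -- TSV -------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | Path, config_hash: str | None = None,
              index: bool = True) -> None:
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config={config_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
    if index_col is not None and df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        # +2: header line and 1-based counting; comment lines shift this
        line = int(df.index.get_loc(dup).nonzero()[0][-1]) + 2 if hasattr(
            df.index.get_loc(dup), "nonzero") else 0
        raise DuplicateIdError(f"{path}: duplicate row id {dup!r} (near line {line})")
    return df


def read_config_hash(path: str | Path) -> str | None:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# config="):
        return first.strip().split("=", 1)[1]
    return None


# -- GMT -------------------------------------------------------------------

def write_gmt(path: str | Path, genesets: Mapping[str, Iterable[str]],
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in genesets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed GMT line {lineno}")
            name = parts[0]
            if name in out:
                raise DuplicateIdError(f"{path}: duplicate gene set {name!r} (line {lineno})")
            out[name] = parts[2:]
    return out


def gmt_from_string(text: str) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for line in _io.StringIO(text):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        out[parts[0]] = parts[2:]
    return out
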