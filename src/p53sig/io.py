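"""Readers and writers for the pipeline's external file formats.

Supported formats: genome FASTA, 7-column gene-model TSV, narrowPeak-extended
peak TSV (narrowPeak's first six columns plus four count columns), BED3
fragment files, gene x sample count TSV, and the sample sheet TSV.  All TSVs
are tab-delimited with a single header line, UTF-8, no quoting.  Readers
reject schema violations with a :class:`~p53sig.types.FormatError` naming the
first offending line.
"""
from __future__ import annotations

import os
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .types import (
    CountMatrix,
    FormatError,
    GeneModel,
    GenomicInterval,
    PeakCall,
    SampleSheet,
)

_FASTA_ALPHABET = set("ACGTN")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str) -> Dict[str, str]:
    """Read a genome FASTA into ``{chrom: uppercase sequence}``.

    Rejects sequences containing characters outside A/C/G/T/N, naming the
    offending line number.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    records: Dict[str, str] = {}
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in records:
                raise FormatError(f"{path}: duplicate FASTA header {rec.id!r}")
            records[rec.id] = str(rec.seq).upper()
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    # locate invalid characters with their line numbers for the error message
    bad = {
        chrom for chrom, seq in records.items() if set(seq) - _FASTA_ALPHABET
    }
    if bad:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if line.startswith(">") or not line:
                    continue
                if set(line.upper()) - _FASTA_ALPHABET:
                    raise FormatError(
                        f"{path}:{lineno}: non-ACGTN character in sequence"
                    )
    return records


def write_fasta(records: Dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in records.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width])
                fh.write("\n")


# ---------------------------------------------------------------------------
# generic TSV helpers

def _read_tsv(path: str, required: Sequence[str]) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}:1: missing columns {missing}")
    return df


def _to_int(df: pd.DataFrame, col: str, path: str) -> pd.Series:
    raw = df[col]
    try:
        as_float = raw.astype(float)
    except ValueError as exc:
        bad = raw[pd.to_numeric(raw, errors="coerce").isna()].index[0]
        raise FormatError(
            f"{path}:{bad + 2}: non-numeric value {raw[bad]!r} in column {col!r}"
        ) from exc
    as_int = as_float.astype(np.int64)
    if not np.allclose(as_float, as_int):
        bad = raw[(as_float != as_int)].index[0]
        raise FormatError(
            f"{path}:{bad + 2}: non-integer value {raw[bad]!r} in column {col!r}"
        )
    return as_int


# ---------------------------------------------------------------------------
# gene models (flat 7-column TSV)

GENE_MODEL_COLUMNS = ["chrom", "start", "end", "gene_id", "name", "strand", "biotype"]


def read_gene_models(path: str) -> List[GeneModel]:
    df = _read_tsv(path, GENE_MODEL_COLUMNS)
    for col in ("start", "end"):
        df[col] = _to_int(df, col, path)
    genes: List[GeneModel] = []
    seen = set()
    for i, row in df.iterrows():
        lineno = i + 2
        if row.gene_id in seen:
            raise FormatError(f"{path}:{lineno}: duplicate gene_id {row.gene_id!r}")
        seen.add(row.gene_id)
        try:
            interval = GenomicInterval(row.chrom, int(row.start), int(row.end))
            gene = GeneModel(row.gene_id, row["name"], interval, row.strand, row.biotype)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        genes.append(gene)
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str) -> None:
    rows = [
        (
            g.interval.chrom,
            g.interval.start,
            g.interval.end,
            g.gene_id,
            g.name,
            g.strand,
            g.biotype,
        )
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_MODEL_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# peak calls (narrowPeak-extended)

PEAK_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "ip_count",
    "control_count",
    "ip_libsize",
    "control_libsize",
]


def read_peak_calls(path: str, sample_sheet: SampleSheet, sample_id: str) -> List[PeakCall]:
    """Read one sample's candidate peaks; ``sample_id`` must be in the sheet."""
    if sample_id not in sample_sheet:
        raise FormatError(f"{path}: sample {sample_id!r} not in sample sheet")
    df = _read_tsv(path, PEAK_COLUMNS)
    for col in ("start", "end", "ip_count", "control_count", "ip_libsize", "control_libsize"):
        df[col] = _to_int(df, col, path)
    peaks: List[PeakCall] = []
    for i, row in df.iterrows():
        lineno = i + 2
        try:
            interval = GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand)
            peak = PeakCall(
                interval=interval,
                sample_id=sample_id,
                ip_count=int(row.ip_count),
                control_count=int(row.control_count),
                ip_libsize=int(row.ip_libsize),
                control_libsize=int(row.control_libsize),
                name=row["name"],
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        peaks.append(peak)
    return peaks


def write_peak_calls(peaks: Iterable[PeakCall], path: str) -> None:
    rows = [
        (
            p.interval.chrom,
            p.interval.start,
            p.interval.end,
            p.name or f"peak_{i}",
            0,
            p.interval.strand,
            p.ip_count,
            p.control_count,
            p.ip_libsize,
            p.control_libsize,
        )
        for i, p in enumerate(peaks)
    ]
    pd.DataFrame(rows, columns=PEAK_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED3 fragments

def read_fragments_bed(path: str) -> List[GenomicInterval]:
    """Read a header-less BED3 file of sequenced fragments."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_fragments_bed(fragments: Iterable[GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for frag in fragments:
            fh.write(f"{frag.chrom}\t{frag.start}\t{frag.end}\n")


# ---------------------------------------------------------------------------
# count matrix

def read_counts_tsv(path: str) -> CountMatrix:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(set(header)) != len(header):
        # checked on the raw header: pandas would silently mangle duplicates
        raise FormatError(f"{path}:1: duplicated sample column name")
    df = _read_tsv(path, ["gene_id"])
    if list(df.columns)[0] != "gene_id":
        raise FormatError(f"{path}:1: first column must be gene_id")
    sample_cols = list(df.columns[1:])
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"{path}: duplicate gene_id {dup!r}")
    for col in sample_cols:
        df[col] = _to_int(df, col, path)
    counts = df.set_index("gene_id")[sample_cols]
    try:
        return CountMatrix(counts)
    except FormatError:
        raise
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_counts_tsv(matrix: CountMatrix, path: str) -> None:
    out = matrix.df.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# sample sheet

def read_sample_sheet(path: str) -> SampleSheet:
    df = _read_tsv(path, SampleSheet.COLUMNS)
    df["timepoint_h"] = _to_int(df, "timepoint_h", path)
    df["path"] = df["path"].fillna("")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str) -> None:
    sheet.df.to_csv(path, sep="\t", index=False)
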