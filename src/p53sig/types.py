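"""Domain types shared across the pipeline.

All genomic coordinates in this package are 0-based, half-open (BED
convention).  ``GenomicInterval.display()`` renders the 1-based closed
form used in logs; the conversion is lossless.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

VALID_STRANDS = {"+", "-", "."}
VALID_BIOTYPES = {"PCG", "lncRNA"}
TUMOR_TYPES = ("LA", "SA", "LY")
CELL_LINES = ("LA1", "LA2", "SA1", "SA2", "LY1", "LY2")
ASSAYS = {"RNA", "CHIP_IP", "CHIP_CONTROL"}
CONDITIONS = {"mock", "tam"}
RNA_TIMEPOINTS = (0, 8, 24)


class FormatError(ValueError):
    """Raised when an input file violates its declared schema."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open overlap: at least one shared base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Distance in bases between intervals; 0 if they overlap."""
        if self.chrom != other.chrom:
            raise ValueError("gap between intervals on different chromosomes")
        if self.overlaps(other):
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end

    def display(self) -> str:
        """1-based closed display string, e.g. ``chr1:101-200``."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"

    @classmethod
    def from_display(cls, text: str, strand: str = ".") -> "GenomicInterval":
        chrom, _, span = text.rpartition(":")
        lo, _, hi = span.partition("-")
        return cls(chrom, int(lo) - 1, int(hi), strand)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    name: str
    interval: GenomicInterval
    strand: str
    biotype: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be +/-, got {self.strand!r}")
        if self.biotype not in VALID_BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")

    @property
    def tss(self) -> int:
        """Transcription start: interval start on +, end-1 on -."""
        if self.strand == "+":
            return self.interval.start
        return self.interval.end - 1


@dataclass
class PeakCall:
    interval: GenomicInterval
    sample_id: str
    ip_count: int
    control_count: int
    ip_libsize: int
    control_libsize: int
    name: str = ""
    pvalue: Optional[float] = None
    qvalue: Optional[float] = None
    enrichment: Optional[float] = None
    significant: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.ip_count < 0 or self.control_count < 0:
            raise ValueError("counts must be non-negative")
        if self.ip_libsize <= 0 or self.control_libsize <= 0:
            raise ValueError("library sizes must be positive")
        for attr in ("pvalue", "qvalue"):
            v = getattr(self, attr)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{attr} must lie in [0, 1]")


@dataclass
class MergedRegion:
    """Union interval of significant peaks, the unit of signature calling."""

    region_id: str
    interval: GenomicInterval
    raw_counts: dict = field(default_factory=dict)
    norm_density: dict = field(default_factory=dict)
    significant_in: set = field(default_factory=set)
    has_motif: Optional[bool] = None
    motif_score: Optional[float] = None

    def __post_init__(self) -> None:
        bad = set(self.significant_in) - set(TUMOR_TYPES)
        if bad:
            raise ValueError(f"unknown tumor types in significant_in: {bad}")


@dataclass
class SignatureCall:
    region_id: str
    gene_id: str
    locality: str  # intragenic | intergenic
    klass: str  # core | senescence_specific | LY_specific | other


class SampleSheet:
    """Validated table of samples (RNA and ChIP) with metadata."""

    COLUMNS = [
        "sample_id",
        "cell_line",
        "tumor_type",
        "assay",
        "condition",
        "timepoint_h",
        "path",
    ]

    def __init__(self, df: pd.DataFrame) -> None:
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        df = df[self.COLUMNS].copy()
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample_id {dup!r}")
        for i, row in df.iterrows():
            line_no = f"sample {row.sample_id!r}"
            if row.cell_line not in CELL_LINES:
                raise FormatError(f"{line_no}: unknown cell line {row.cell_line!r}")
            if row.tumor_type not in TUMOR_TYPES:
                raise FormatError(f"{line_no}: unknown tumor type {row.tumor_type!r}")
            if not row.cell_line.startswith(row.tumor_type):
                raise FormatError(
                    f"{line_no}: tumor type {row.tumor_type!r} inconsistent "
                    f"with cell line {row.cell_line!r}"
                )
            if row.assay not in ASSAYS:
                raise FormatError(f"{line_no}: unknown assay {row.assay!r}")
            if row.condition not in CONDITIONS:
                raise FormatError(f"{line_no}: unknown condition {row.condition!r}")
            tp = int(row.timepoint_h)
            if row.assay == "RNA" and tp not in RNA_TIMEPOINTS:
                raise FormatError(f"{line_no}: RNA timepoint must be 0/8/24, got {tp}")
            if row.assay != "RNA" and tp != 24:
                raise FormatError(f"{line_no}: ChIP samples are profiled at 24 h only")
        df["timepoint_h"] = df["timepoint_h"].astype(int)
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in set(self.df["sample_id"])

    def row(self, sample_id: str) -> pd.Series:
        hits = self.df[self.df["sample_id"] == sample_id]
        if hits.empty:
            raise KeyError(f"sample {sample_id!r} not in sheet")
        return hits.iloc[0]

    def select(self, **filters) -> pd.DataFrame:
        out = self.df
        for key, val in filters.items():
            out = out[out[key] == val]
        return out


class CountMatrix:
    """Gene x sample integer count matrix."""

    def __init__(self, counts: pd.DataFrame) -> None:
        if counts.index.duplicated().any():
            raise FormatError("duplicate gene_ids in count matrix")
        if counts.columns.duplicated().any():
            raise FormatError("duplicate sample ids in count matrix")
        arr = counts.to_numpy()
        if (arr < 0).any():
            raise FormatError("negative counts in count matrix")
        self.df = counts.astype(int)

    @property
    def gene_ids(self) -> list:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list:
        return list(self.df.columns)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountMatrix) and self.df.equals(other.df)
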