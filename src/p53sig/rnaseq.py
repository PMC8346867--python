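"""Expression-side operations: median-of-ratios normalization, fold changes,
induction/repression calls, PCA coordinates, and the early-response statistic.

Normalization follows the DESeq2 median-of-ratios scheme: size factors are
medians, over genes with all-positive counts, of each sample's ratio to the
per-gene geometric mean.  Fold changes are computed per cell line against
that line's 0-h (mock) sample with a +1 pseudocount on normalized counts;
with a single library per line and time point there is no per-gene variance
estimate, so induction calls use an effect-size threshold with a
sign-consistency requirement across the tumor type's two cell lines instead
of a p-value.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .types import CountMatrix, SampleSheet, TUMOR_TYPES, CELL_LINES

DEFAULT_LFC_MIN = math.log2(1.5)  # ~0.585
DEFAULT_PSEUDOCOUNT = 1.0

LINES_BY_TYPE = {
    "LA": ("LA1", "LA2"),
    "SA": ("SA1", "SA2"),
    "LY": ("LY1", "LY2"),
}


class SizeFactors(dict):
    """Map sample_id -> positive size factor."""


@dataclass
class ExprSummary:
    """Per-gene expression summary across the cell-line panel.

    ``lfc8``/``lfc24`` are gene x cell-line log2 fold changes versus the
    line's 0-h sample; ``induced8``/``induced24``/``repressed24`` are
    gene x tumor-type booleans.
    """

    lfc8: pd.DataFrame
    lfc24: pd.DataFrame
    induced8: pd.DataFrame
    induced24: pd.DataFrame
    repressed24: pd.DataFrame


def size_factors_median_of_ratios(counts: CountMatrix) -> SizeFactors:
    """DESeq2-style median-of-ratios size factors."""
    mat = counts.df.to_numpy(dtype=float)
    all_positive = (mat > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("no gene has positive counts in every sample")
    sub = mat[all_positive]
    geomean = np.exp(np.log(sub).mean(axis=1))
    factors = np.median(sub / geomean[:, None], axis=0)
    return SizeFactors(zip(counts.sample_ids, factors))


def normalized_counts(counts: CountMatrix, size_factors: SizeFactors) -> pd.DataFrame:
    sf = pd.Series(size_factors).reindex(counts.sample_ids)
    if sf.isna().any():
        missing = list(sf[sf.isna()].index)
        raise KeyError(f"size factors missing for samples {missing}")
    return counts.df / sf


def lfc(
    counts: CountMatrix,
    size_factors: SizeFactors,
    gene: str,
    sample_a: str,
    sample_b: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """log2 fold change of ``sample_a`` over ``sample_b`` for one gene."""
    norm = normalized_counts(counts, size_factors)
    a = norm.at[gene, sample_a] + pseudocount
    b = norm.at[gene, sample_b] + pseudocount
    return float(np.log2(a / b))


def _rna_sample_map(sheet: SampleSheet) -> Dict[Tuple[str, int], str]:
    """(cell_line, timepoint) -> sample_id for RNA samples."""
    rna = sheet.select(assay="RNA")
    out: Dict[Tuple[str, int], str] = {}
    for _, row in rna.iterrows():
        key = (row.cell_line, int(row.timepoint_h))
        if key in out:
            raise ValueError(f"duplicate RNA sample for {key}")
        out[key] = row.sample_id
    return out


def lfc_tables(
    counts: CountMatrix,
    size_factors: SizeFactors,
    sheet: SampleSheet,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x cell-line lfc8 and lfc24 tables versus each line's 0-h sample."""
    norm = normalized_counts(counts, size_factors)
    smap = _rna_sample_map(sheet)
    lines = [ln for ln in CELL_LINES if (ln, 0) in smap]
    if not lines:
        raise ValueError("no RNA baseline (0 h) samples in sheet")
    tables = {}
    for tp in (8, 24):
        cols = {}
        for line in lines:
            if (line, tp) not in smap:
                raise ValueError(f"missing RNA sample for {line} at {tp} h")
            a = norm[smap[(line, tp)]] + pseudocount
            b = norm[smap[(line, 0)]] + pseudocount
            cols[line] = np.log2(a / b)
        tables[tp] = pd.DataFrame(cols)
    return tables[8], tables[24]


def induction_calls(
    lfc8: pd.DataFrame,
    lfc24: pd.DataFrame,
    lfc_min: float = DEFAULT_LFC_MIN,
) -> ExprSummary:
    """Call per-type induction/repression from per-line fold changes.

    A gene is induced at 24 h in a tumor type iff the mean lfc24 across the
    type's two lines is >= ``lfc_min`` and both lines' lfc24 are > 0;
    induced8 is the analogous call on lfc8; repressed24 mirrors induced24
    with both signs flipped.
    """
    def per_type(table: pd.DataFrame, sign: int) -> pd.DataFrame:
        cols = {}
        for ttype, (l1, l2) in LINES_BY_TYPE.items():
            for line in (l1, l2):
                if line not in table.columns:
                    raise ValueError(f"missing cell line {line} in lfc table")
            vals = sign * table[[l1, l2]]
            cols[ttype] = (vals.mean(axis=1) >= lfc_min) & (vals.min(axis=1) > 0)
        return pd.DataFrame(cols)

    return ExprSummary(
        lfc8=lfc8,
        lfc24=lfc24,
        induced8=per_type(lfc8, +1),
        induced24=per_type(lfc24, +1),
        repressed24=per_type(lfc24, -1),
    )


def compute_expr_summary(
    counts: CountMatrix,
    sheet: SampleSheet,
    lfc_min: float = DEFAULT_LFC_MIN,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ExprSummary:
    sf = size_factors_median_of_ratios(counts)
    lfc8, lfc24 = lfc_tables(counts, sf, sheet, pseudocount)
    return induction_calls(lfc8, lfc24, lfc_min)


def early_response_fraction(
    counts: CountMatrix,
    size_factors: SizeFactors,
    sheet: SampleSheet,
    gene_set: Sequence[str],
) -> float:
    """Mean 8-h change as a fraction of the 24-h change, reported in %.

    Per gene, compute d8 = E8 - E0 and d24 = E24 - E0 on normalized linear
    expression averaged across the panel's cell lines; the statistic is the
    mean of d8/d24 over genes with positive averaged 24-h change, times 100.
    Averaging across lines before taking the ratio keeps single-library
    noise in the denominator from producing unstable near-zero divisors.
    """
    genes = [g for g in gene_set if g in counts.df.index]
    if not genes:
        raise ValueError("empty gene set for early-response fraction")
    norm = normalized_counts(counts, size_factors)
    smap = _rna_sample_map(sheet)
    lines = sorted({ln for (ln, _tp) in smap})
    e_mean = {
        tp: norm.loc[genes, [smap[(line, tp)] for line in lines]].mean(axis=1)
        for tp in (0, 8, 24)
    }
    d8 = e_mean[8] - e_mean[0]
    d24 = e_mean[24] - e_mean[0]
    keep = d24 > 0
    if not keep.any():
        raise ValueError("no gene with positive averaged 24-h change")
    return 100.0 * float((d8[keep] / d24[keep]).mean())


def module_mean_lfc(
    expr: ExprSummary, gene_set: Sequence[str], tumor_type: str
) -> float:
    """Mean lfc24 of a gene module across the tumor type's two lines."""
    genes = [g for g in gene_set if g in expr.lfc24.index]
    if not genes:
        raise ValueError("empty gene set")
    lines = list(LINES_BY_TYPE[tumor_type])
    return float(expr.lfc24.loc[genes, lines].to_numpy().mean())


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # sample x component
    variance_fraction: np.ndarray
    degenerate: bool = False


def pca_coordinates(
    counts: CountMatrix,
    size_factors: Optional[SizeFactors] = None,
    n_components: int = 2,
) -> PCAResult:
    """PCA of samples on log2(normalized count + 1), genes centered.

    Sign convention: the first nonzero loading of each component is made
    positive, so coordinates are reproducible across runs.  With zero total
    variance the result is flagged degenerate and all coordinates are 0.
    """
    if len(counts.sample_ids) < n_components:
        raise ValueError("fewer samples than requested components")
    if size_factors is None:
        size_factors = size_factors_median_of_ratios(counts)
    norm = normalized_counts(counts, size_factors)
    x = np.log2(norm.to_numpy(dtype=float).T + 1.0)  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    if not np.any(np.abs(x) > 1e-12):
        coords = pd.DataFrame(
            np.zeros((x.shape[0], n_components)),
            index=counts.sample_ids,
            columns=[f"PC{i+1}" for i in range(n_components)],
        )
        return PCAResult(coords, np.full(n_components, np.nan), degenerate=True)
    model = PCA(n_components=n_components, svd_solver="full")
    coords = model.fit_transform(x)
    for j in range(n_components):
        loading = model.components_[j]
        nz = np.nonzero(np.abs(loading) > 1e-12)[0]
        if nz.size and loading[nz[0]] < 0:
            coords[:, j] *= -1
    frame = pd.DataFrame(
        coords,
        index=counts.sample_ids,
        columns=[f"PC{i+1}" for i in range(n_components)],
    )
    return PCAResult(frame, model.explained_variance_ratio_.copy())


def write_expr_summary_tsv(expr: ExprSummary, path: str) -> None:
    out = pd.DataFrame(index=expr.lfc24.index)
    for line in expr.lfc8.columns:
        out[f"lfc8_{line}"] = expr.lfc8[line].round(4)
        out[f"lfc24_{line}"] = expr.lfc24[line].round(4)
    for ttype in TUMOR_TYPES:
        out[f"induced8_{ttype}"] = expr.induced8[ttype].astype(int)
        out[f"induced24_{ttype}"] = expr.induced24[ttype].astype(int)
        out[f"repressed24_{ttype}"] = expr.repressed24[ttype].astype(int)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
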