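"""Stage orchestration: chip -> rnaseq -> signatures -> cisreg -> summary.

Stages communicate through files in the output directory, so running the
individual stage commands in sequence is identical to one end-to-end run.
All outputs are written atomically (temp file + rename).  Input bundles use
the standard layout emitted by :mod:`p53sig.simulate`:

    genome.fa  genes.tsv  sample_sheet.tsv  rna_counts.tsv
    peaks_{LA,SA,LY}.tsv  fragments_{type}_{mock,tam}.bed
    perturbation_counts.tsv  perturbation_design.tsv   (optional)
"""
from __future__ import annotations

import json
import os
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import chip as pchip
from . import cisreg as pcis
from . import io as pio
from . import rnaseq as prna
from . import signatures as psig
from .rnaseq import ExprSummary
from .types import GenomicInterval, MergedRegion, TUMOR_TYPES

MOCK, TAM = "mock", "tam"


class EmptyResultError(RuntimeError):
    """A stage produced an empty result where a nonempty one is required."""


def _atomic_write(path: str, writer) -> None:
    tmp = path + ".tmp"
    writer(tmp)
    os.replace(tmp, path)


def _require(path: str) -> str:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    return path


# ---------------------------------------------------------------------------
# chip stage

def stage_chip(
    indir: str,
    outdir: str,
    fdr_max: float = pchip.DEFAULT_FDR_MAX,
    min_fold: float = pchip.DEFAULT_MIN_FOLD,
    top_fraction: float = pchip.DEFAULT_TOP_FRACTION,
    motif_threshold: Optional[float] = None,
) -> List[MergedRegion]:
    """Call significant peaks per type, merge, count, normalize, annotate."""
    os.makedirs(outdir, exist_ok=True)
    sheet = pio.read_sample_sheet(_require(os.path.join(indir, "sample_sheet.tsv")))

    sig_by_type: Dict[str, List[GenomicInterval]] = {}
    for t in TUMOR_TYPES:
        rows = sheet.select(assay="CHIP_IP", tumor_type=t, condition=TAM)
        if rows.empty:
            raise FileNotFoundError(f"no Tam ChIP IP sample for tumor type {t}")
        row = rows.iloc[0]
        peaks_path = _require(os.path.join(indir, row.path))
        peaks = pio.read_peak_calls(peaks_path, sheet, row.sample_id)
        peaks = pchip.call_significant_peaks(peaks, fdr_max, min_fold)
        sig_by_type[t] = [p.interval for p in peaks if p.significant]

    all_sig = [iv for ivs in sig_by_type.values() for iv in ivs]
    if not all_sig:
        raise EmptyResultError("no significant peaks in any tumor type")
    regions = pchip.merge_regions(all_sig)

    # membership: a type is significant in a region iff one of its significant
    # peaks overlaps it (overlap counting reuses the fragment counter)
    for t in TUMOR_TYPES:
        hits = pchip.count_fragments(sig_by_type[t], regions)
        for reg, h in zip(regions, hits):
            if h > 0:
                reg.significant_in.add(t)

    # raw fragment counts per condition
    for t in TUMOR_TYPES:
        for cond in (MOCK, TAM):
            path = _require(os.path.join(indir, f"fragments_{t}_{cond}.bed"))
            frags = pio.read_fragments_bed(path)
            counts = pchip.count_fragments(frags, regions)
            for reg, c in zip(regions, counts):
                reg.raw_counts[f"{t}:{cond}"] = int(c)

    # top-30% normalization, separately over the Tam trio and the mock trio
    # (the comparable enrichment structure lives within a treatment arm)
    raw = pd.DataFrame(
        {f"{t}:{c}": [r.raw_counts[f"{t}:{c}"] for r in regions]
         for t in TUMOR_TYPES for c in (MOCK, TAM)},
        index=[r.region_id for r in regions],
    )
    for cols in ([f"{t}:{TAM}" for t in TUMOR_TYPES], [f"{t}:{MOCK}" for t in TUMOR_TYPES]):
        norm = None
        for fraction in (top_fraction, 0.5, 0.75, 1.0):
            if fraction < top_fraction:
                continue
            try:
                norm = pchip.normalize_top30(raw[cols], fraction)
                break
            except ValueError:
                # shared top set empty at this fraction (flat profiles, e.g.
                # the mock trio at small scale): escalate deterministically
                continue
        if norm is None:
            raise EmptyResultError(f"no shared top regions across {cols}")
        for reg in regions:
            for c in cols:
                reg.norm_density[c] = float(norm.at[reg.region_id, c])

    genome = pio.read_fasta(_require(os.path.join(indir, "genome.fa")))
    pwm = pchip.build_pwm_from_consensus()
    pchip.annotate_motifs(regions, genome, pwm, motif_threshold)

    _atomic_write(
        os.path.join(outdir, "merged_regions.tsv"),
        lambda p: pchip.write_merged_regions_tsv(regions, p),
    )
    venn = psig.venn_partition(regions)
    _atomic_write(
        os.path.join(outdir, "venn.tsv"),
        lambda p: venn.to_frame().to_csv(p, sep="\t", index=False),
    )
    return regions


def read_merged_regions(path: str) -> List[MergedRegion]:
    df = pd.read_csv(_require(path), sep="\t")
    regions: List[MergedRegion] = []
    raw_cols = [c for c in df.columns if c.startswith("raw_")]
    norm_cols = [c for c in df.columns if c.startswith("norm_")]
    for _, row in df.iterrows():
        sig = row["significant_in"]
        reg = MergedRegion(
            region_id=row.region_id,
            interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
            raw_counts={c[4:]: int(row[c]) for c in raw_cols},
            norm_density={
                c[5:]: float(row[c]) for c in norm_cols if pd.notna(row[c])
            },
            significant_in=set(str(sig).split(",")) if pd.notna(sig) and sig else set(),
            has_motif=bool(row.has_motif),
            motif_score=float(row.motif_score) if pd.notna(row.motif_score) else None,
        )
        regions.append(reg)
    return regions


# ---------------------------------------------------------------------------
# rnaseq stage

def stage_rnaseq(
    indir: str,
    outdir: str,
    lfc_min: float = prna.DEFAULT_LFC_MIN,
) -> ExprSummary:
    os.makedirs(outdir, exist_ok=True)
    sheet = pio.read_sample_sheet(_require(os.path.join(indir, "sample_sheet.tsv")))
    counts = pio.read_counts_tsv(_require(os.path.join(indir, "rna_counts.tsv")))
    sf = prna.size_factors_median_of_ratios(counts)
    lfc8, lfc24 = prna.lfc_tables(counts, sf, sheet)
    expr = prna.induction_calls(lfc8, lfc24, lfc_min)
    _atomic_write(
        os.path.join(outdir, "expr_summary.tsv"),
        lambda p: prna.write_expr_summary_tsv(expr, p),
    )
    pca = prna.pca_coordinates(counts, sf)
    out = pca.coordinates.round(4).copy()
    out.index.name = "sample_id"
    _atomic_write(
        os.path.join(outdir, "pca.tsv"), lambda p: out.to_csv(p, sep="\t")
    )
    with open(os.path.join(outdir, "pca_variance.json"), "w") as fh:
        json.dump(
            {
                "variance_fraction": [round(float(v), 6) for v in pca.variance_fraction],
                "degenerate": pca.degenerate,
            },
            fh,
            indent=2,
        )
        fh.write("\n")
    _atomic_write(
        os.path.join(outdir, "size_factors.tsv"),
        lambda p: pd.Series(sf, name="size_factor")
        .rename_axis("sample_id")
        .round(6)
        .to_csv(p, sep="\t"),
    )
    return expr


def read_expr_summary(path: str) -> ExprSummary:
    df = pd.read_csv(_require(path), sep="\t", index_col="gene_id")
    lines = [c[len("lfc24_"):] for c in df.columns if c.startswith("lfc24_")]
    lfc8 = pd.DataFrame({ln: df[f"lfc8_{ln}"] for ln in lines})
    lfc24 = pd.DataFrame({ln: df[f"lfc24_{ln}"] for ln in lines})
    def flags(prefix: str) -> pd.DataFrame:
        return pd.DataFrame(
            {t: df[f"{prefix}_{t}"].astype(bool) for t in TUMOR_TYPES}
        )
    return ExprSummary(
        lfc8=lfc8,
        lfc24=lfc24,
        induced8=flags("induced8"),
        induced24=flags("induced24"),
        repressed24=flags("repressed24"),
    )


# ---------------------------------------------------------------------------
# signatures stage

def stage_signatures(indir: str, outdir: str) -> Tuple[List[psig.SignatureCall], dict]:
    os.makedirs(outdir, exist_ok=True)
    regions = read_merged_regions(os.path.join(outdir, "merged_regions.tsv"))
    expr = read_expr_summary(os.path.join(outdir, "expr_summary.tsv"))
    genes = pio.read_gene_models(_require(os.path.join(indir, "genes.tsv")))
    gene_map = {g.gene_id: g for g in genes}

    assignment = psig.assign_regions(regions, genes)
    calls = psig.call_signatures(regions, assignment, expr)
    _atomic_write(
        os.path.join(outdir, "signature_calls.tsv"),
        lambda p: psig.write_signature_calls_tsv(calls, gene_map, p),
    )

    by_region = {c.region_id: c for c in calls}
    sen_regions = [r for r in regions if by_region[r.region_id].klass == "senescence_specific"]
    summary: dict = {
        "n_merged_regions": len(regions),
        "n_core_regions": sum(1 for c in calls if c.klass == "core"),
        "n_senescence_regions": len(sen_regions),
        "n_ly_regions": sum(1 for c in calls if c.klass == "LY_specific"),
    }
    for klass, key in [("core", "core"), ("senescence_specific", "senescence")]:
        try:
            n_lnc, n_pcg, pct = psig.biotype_fraction(calls, gene_map, klass)
        except ValueError:
            n_lnc = n_pcg = 0
            pct = None
        summary[f"{key}_genes_lnc"] = n_lnc
        summary[f"{key}_genes_pcg"] = n_pcg
        summary[f"{key}_genes_total"] = n_lnc + n_pcg
        summary[f"{key}_lnc_percent"] = pct
    if sen_regions:
        summary["density_fold_reduction"] = round(
            psig.density_fold_reduction(sen_regions), 4
        )
    else:
        summary["density_fold_reduction"] = None

    # early-response fraction over the recovered core genes
    sheet = pio.read_sample_sheet(_require(os.path.join(indir, "sample_sheet.tsv")))
    counts = pio.read_counts_tsv(_require(os.path.join(indir, "rna_counts.tsv")))
    sf = prna.size_factors_median_of_ratios(counts)
    gclasses = psig.gene_classes(calls)
    core_genes = sorted(g for g, k in gclasses.items() if k == "core")
    if core_genes:
        summary["early_response_percent"] = round(
            prna.early_response_fraction(counts, sf, sheet, core_genes), 4
        )
    else:
        summary["early_response_percent"] = None

    _atomic_write(
        os.path.join(outdir, "signature_summary.json"),
        lambda p: psig.write_summary_json(summary, p),
    )
    return calls, summary


# ---------------------------------------------------------------------------
# cisreg stage

def stage_cisreg(indir: str, outdir: str) -> dict:
    os.makedirs(outdir, exist_ok=True)
    genes = pio.read_gene_models(_require(os.path.join(indir, "genes.tsv")))
    gene_map = {g.gene_id: g for g in genes}
    calls_df = pd.read_csv(
        _require(os.path.join(outdir, "signature_calls.tsv")), sep="\t"
    )
    expr = read_expr_summary(os.path.join(outdir, "expr_summary.tsv"))

    sig_lnc = sorted(
        set(
            calls_df.loc[
                calls_df.klass.isin(["core", "senescence_specific"])
                & (calls_df.biotype == "lncRNA"),
                "gene_id",
            ]
        )
    )
    pairs = [pcis.find_neighbor(gene_map[g], genes) for g in sig_lnc]
    _atomic_write(
        os.path.join(outdir, "neighbor_pairs.tsv"),
        lambda p: pcis.write_neighbor_pairs_tsv(pairs, p),
    )
    out: dict = {"n_pairs": len(pairs)}
    if len(pairs) >= 3:
        r, points = pcis.pair_lfc_correlation(pairs, expr.lfc24["LA1"])
        out["pair_lfc_correlation_LA1"] = None if np.isnan(r) else round(float(r), 4)
        _atomic_write(
            os.path.join(outdir, "pair_lfc_points.tsv"),
            lambda p: points.round(4).to_csv(p, sep="\t", index=False),
        )
    else:
        out["pair_lfc_correlation_LA1"] = None

    design_path = os.path.join(indir, "perturbation_design.tsv")
    counts_path = os.path.join(indir, "perturbation_counts.tsv")
    effects = []
    if os.path.exists(design_path) and os.path.exists(counts_path):
        design = pd.read_csv(design_path, sep="\t")
        pcounts = pio.read_counts_tsv(counts_path)
        sf = prna.size_factors_median_of_ratios(pcounts)
        norm = prna.normalized_counts(pcounts, sf)
        for _, row in design.iterrows():
            pair = pcis.find_neighbor(gene_map[row.lnc_gene_id], genes)
            ctrl = norm[str(row.control_samples).split(";")].mean(axis=1)
            pert = norm[str(row.perturbed_samples).split(";")].mean(axis=1)
            effects.append(pcis.classify_perturbation(pair, ctrl, pert))
        _atomic_write(
            os.path.join(outdir, "perturbation_effects.tsv"),
            lambda p: pcis.write_perturbation_effects_tsv(effects, p),
        )
        out["perturbation_directions"] = {
            e.pair.lnc_gene_id: (e.direction or "perturbation_failed")
            for e in effects
        }
    return out


# ---------------------------------------------------------------------------
# end-to-end

def run_all(
    indir: str,
    outdir: str,
    fdr_max: float = pchip.DEFAULT_FDR_MAX,
    min_fold: float = pchip.DEFAULT_MIN_FOLD,
    top_fraction: float = pchip.DEFAULT_TOP_FRACTION,
    lfc_min: float = prna.DEFAULT_LFC_MIN,
    motif_threshold: Optional[float] = None,
) -> dict:
    """Run every stage in sequence and write ``summary.json``."""
    stage_chip(indir, outdir, fdr_max, min_fold, top_fraction, motif_threshold)
    stage_rnaseq(indir, outdir, lfc_min)
    _calls, summary = stage_signatures(indir, outdir)
    cis = stage_cisreg(indir, outdir)
    venn = pd.read_csv(os.path.join(outdir, "venn.tsv"), sep="\t")
    summary["venn_with_motif"] = dict(
        zip(venn["subset"], venn["with_motif"].astype(int))
    )
    summary["venn_without_motif"] = dict(
        zip(venn["subset"], venn["without_motif"].astype(int))
    )
    summary.update(cis)
    _atomic_write(
        os.path.join(outdir, "summary.json"),
        lambda p: psig.write_summary_json(summary, p),
    )
    return summary
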