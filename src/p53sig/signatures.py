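"""Peak-to-gene assignment and core / context-specific signature calling.

A merged region is assigned to its closest gene (gap distance, 0 on
overlap; ties broken by the lexicographically smaller gene_id) and termed
intragenic if it overlaps the gene or lies within 2 kb upstream of its TSS,
else intergenic.  Signature classes combine three layers of evidence:

* core              -- p53 motif present, significantly bound in all three
                       tumor types, assigned gene induced at 24 h in all three;
* senescence_specific -- motif present, bound in LA and SA but not LY,
                       gene induced in LA and SA but not LY;
* LY_specific       -- motif present, bound in LY only, gene induced in LY only;
* other             -- everything else.

The classes are mutually exclusive and exhaustive by construction.
"""
from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .rnaseq import ExprSummary
from .types import GeneModel, MergedRegion, SignatureCall, TUMOR_TYPES

UPSTREAM_WINDOW = 2_000  # bp upstream of the TSS counted as promoter-proximal
CLASS_PRECEDENCE = ("core", "senescence_specific", "LY_specific", "other")


def assign_region_to_gene(
    region: MergedRegion, genes: Sequence[GeneModel]
) -> Tuple[str, str]:
    """Closest gene and locality (intragenic/intergenic) for one region."""
    if not genes:
        raise ValueError("gene list is empty")
    best: Tuple[int, str] = None  # (distance, gene_id)
    best_gene: GeneModel = None
    for gene in genes:
        if gene.interval.chrom != region.interval.chrom:
            continue
        dist = region.interval.gap_to(gene.interval)
        key = (dist, gene.gene_id)
        if best is None or key < best:
            best, best_gene = key, gene
    if best_gene is None:
        # no gene on this chromosome: fall back to global closest by id
        best_gene = min(genes, key=lambda g: g.gene_id)
        return best_gene.gene_id, "intergenic"
    locality = "intergenic"
    if region.interval.overlaps(best_gene.interval):
        locality = "intragenic"
    else:
        if best_gene.strand == "+":
            gap = best_gene.interval.start - region.interval.end
            upstream = gap >= 0
        else:
            gap = region.interval.start - best_gene.interval.end
            upstream = gap >= 0
        if upstream and gap <= UPSTREAM_WINDOW:
            locality = "intragenic"
    return best_gene.gene_id, locality


def assign_regions(
    regions: Iterable[MergedRegion], genes: Sequence[GeneModel]
) -> Dict[str, Tuple[str, str]]:
    """region_id -> (gene_id, locality) for all regions.

    Genes are bucketed per chromosome and pre-sorted so the scan per region
    only touches a local window.
    """
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.interval.start)
    out: Dict[str, Tuple[str, str]] = {}
    for region in regions:
        cands = by_chrom.get(region.interval.chrom)
        if not cands:
            out[region.region_id] = assign_region_to_gene(region, list(genes))
            continue
        starts = [g.interval.start for g in cands]
        i = int(np.searchsorted(starts, region.interval.start))
        lo, hi = max(0, i - 40), min(len(cands), i + 40)
        out[region.region_id] = assign_region_to_gene(region, cands[lo:hi])
    return out


@dataclass
class VennPartition:
    """Counts of significant regions per tumor-type subset, split by motif."""

    with_motif: Dict[FrozenSet[str], int]
    without_motif: Dict[FrozenSet[str], int]

    @staticmethod
    def subsets() -> List[FrozenSet[str]]:
        out = []
        for mask in range(1, 8):
            out.append(
                frozenset(t for i, t in enumerate(TUMOR_TYPES) if mask >> i & 1)
            )
        return out

    def total(self) -> int:
        return sum(self.with_motif.values()) + sum(self.without_motif.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for subset in sorted(self.subsets(), key=lambda s: (len(s), sorted(s))):
            label = "+".join(t for t in TUMOR_TYPES if t in subset)
            rows.append(
                {
                    "subset": label,
                    "with_motif": self.with_motif.get(subset, 0),
                    "without_motif": self.without_motif.get(subset, 0),
                }
            )
        return pd.DataFrame(rows)


def venn_partition(regions: Iterable[MergedRegion]) -> VennPartition:
    """Tally significant regions into the 7 nonempty tumor-type subsets."""
    with_m: Counter = Counter()
    without_m: Counter = Counter()
    for reg in regions:
        subset = frozenset(reg.significant_in)
        if not subset:
            warnings.warn(
                f"region {reg.region_id} significant in no tumor type; excluded"
            )
            continue
        (with_m if reg.has_motif else without_m)[subset] += 1
    empty = {s: 0 for s in VennPartition.subsets()}
    return VennPartition({**empty, **with_m}, {**empty, **without_m})


def call_signatures(
    regions: Sequence[MergedRegion],
    assignment: Dict[str, Tuple[str, str]],
    expr: ExprSummary,
) -> List[SignatureCall]:
    """Classify each merged region as core / senescence_specific / LY_specific / other."""
    calls: List[SignatureCall] = []
    for reg in regions:
        gene_id, locality = assignment[reg.region_id]
        klass = "other"
        if reg.has_motif and gene_id in expr.induced24.index:
            ind = expr.induced24.loc[gene_id]
            bound = set(reg.significant_in)
            if bound == {"LA", "SA", "LY"} and ind.all():
                klass = "core"
            elif bound == {"LA", "SA"} and ind["LA"] and ind["SA"] and not ind["LY"]:
                klass = "senescence_specific"
            elif bound == {"LY"} and ind["LY"] and not ind["LA"] and not ind["SA"]:
                klass = "LY_specific"
        calls.append(SignatureCall(reg.region_id, gene_id, locality, klass))
    return calls


def gene_classes(calls: Iterable[SignatureCall]) -> Dict[str, str]:
    """Gene-level class: union of the gene's region classes with precedence
    core > senescence_specific > LY_specific > other."""
    rank = {k: i for i, k in enumerate(CLASS_PRECEDENCE)}
    out: Dict[str, str] = {}
    for call in calls:
        prev = out.get(call.gene_id)
        if prev is None or rank[call.klass] < rank[prev]:
            out[call.gene_id] = call.klass
    return out


def density_fold_reduction(
    regions: Sequence[MergedRegion],
    tam_conditions: Dict[str, str] = None,
    eps: float = 1e-6,
) -> float:
    """Mean over regions of mean(LA, SA) / LY normalized Tam densities.

    ``tam_conditions`` maps tumor type to the condition key used in
    ``norm_density`` (default ``{T}:tam``).  LY densities are floored at
    ``eps`` to guard division by zero.
    """
    if not regions:
        raise ValueError("empty region set")
    if tam_conditions is None:
        tam_conditions = {t: f"{t}:tam" for t in TUMOR_TYPES}
    ratios = []
    for reg in regions:
        la = reg.norm_density[tam_conditions["LA"]]
        sa = reg.norm_density[tam_conditions["SA"]]
        ly = max(reg.norm_density[tam_conditions["LY"]], eps)
        ratios.append(0.5 * (la + sa) / ly)
    return float(np.mean(ratios))


def biotype_fraction(
    calls: Iterable[SignatureCall],
    genes: Dict[str, GeneModel],
    klass: str,
) -> Tuple[int, int, int]:
    """(n_lncRNA, n_PCG, rounded % lncRNA) among genes of one class.

    Genes are deduplicated (a gene with several regions counts once); the
    gene's class is its precedence-resolved class across all its regions.
    """
    classes = gene_classes(calls)
    members = [g for g, k in classes.items() if k == klass]
    if not members:
        raise ValueError(f"no genes in class {klass!r}")
    n_lnc = sum(1 for g in members if genes[g].biotype == "lncRNA")
    n_pcg = sum(1 for g in members if genes[g].biotype == "PCG")
    percent = int(round(100.0 * n_lnc / (n_lnc + n_pcg)))
    return n_lnc, n_pcg, percent


def write_signature_calls_tsv(
    calls: Sequence[SignatureCall], genes: Dict[str, GeneModel], path: str
) -> None:
    rows = [
        {
            "region_id": c.region_id,
            "gene_id": c.gene_id,
            "biotype": genes[c.gene_id].biotype,
            "locality": c.locality,
            "klass": c.klass,
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_summary_json(summary: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
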