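"""lncRNA-neighbor pairing and cis-regulatory direction calling.

Each p53-regulated lncRNA is paired with its nearest protein-coding gene
and the pair is labelled by genomic relation: ``antisense_overlap`` (the
two genes overlap on opposite strands), ``divergent`` (head-to-head TSSs
within 2 kb), or ``intergenic``.  The direction of cis regulation is read
out from a response-element perturbation contrast: in the activated (Tam)
state, cells whose lncRNA-associated p53 response element was mutagenized
(dRE) are compared to control cells.  If the lncRNA itself dropped (the
perturbation worked), the neighbor's fold change classifies the pair as
cis_activator (neighbor falls with the lncRNA), cis_repressor (neighbor
rises -- the Pvt1b/Myc pattern), or uncoupled.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .rnaseq import DEFAULT_LFC_MIN, DEFAULT_PSEUDOCOUNT
from .types import GeneModel

DIVERGENT_WINDOW = 2_000  # bp between head-to-head TSSs


@dataclass(frozen=True)
class NeighborPair:
    lnc_gene_id: str
    pcg_gene_id: str
    distance: int  # bases, 0 if overlapping
    relation: str  # antisense_overlap | divergent | intergenic


@dataclass
class PerturbationEffect:
    pair: NeighborPair
    lnc_lfc: float
    pcg_lfc: float
    direction: Optional[str]  # cis_activator | cis_repressor | uncoupled | None
    perturbation_failed: bool = False


def _is_divergent(lnc: GeneModel, pcg: GeneModel) -> bool:
    """Head-to-head promoters within the divergent window, no overlap."""
    if lnc.strand == pcg.strand or lnc.interval.overlaps(pcg.interval):
        return False
    if abs(lnc.tss - pcg.tss) > DIVERGENT_WINDOW:
        return False
    # each gene must transcribe away from the other
    left, right = (lnc, pcg) if lnc.tss <= pcg.tss else (pcg, lnc)
    return left.strand == "-" and right.strand == "+"


def find_neighbor(lnc: GeneModel, genes: Sequence[GeneModel]) -> NeighborPair:
    """Nearest protein-coding gene of a lncRNA, with the pair relation."""
    pcgs = [
        g
        for g in genes
        if g.biotype == "PCG" and g.interval.chrom == lnc.interval.chrom
    ]
    if not pcgs:
        pcgs = [g for g in genes if g.biotype == "PCG"]
        if not pcgs:
            raise ValueError("no protein-coding gene available")
        best = min(pcgs, key=lambda g: g.gene_id)
        return NeighborPair(lnc.gene_id, best.gene_id, -1, "intergenic")
    best = min(pcgs, key=lambda g: (lnc.interval.gap_to(g.interval), g.gene_id))
    distance = lnc.interval.gap_to(best.interval)
    if distance == 0 and lnc.strand != best.strand:
        relation = "antisense_overlap"
    elif _is_divergent(lnc, best):
        relation = "divergent"
    else:
        relation = "intergenic"
    return NeighborPair(lnc.gene_id, best.gene_id, distance, relation)


def pair_lfc_correlation(
    pairs: Sequence[NeighborPair], lfc24: pd.Series
) -> Tuple[float, pd.DataFrame]:
    """Pearson r between lncRNA and neighbor-PCG log2 fold changes.

    ``lfc24`` is a per-gene series for one cell line.  Returns (r, points);
    r is NaN (flagged undefined) when either vector has zero variance.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    x = np.array([lfc24[p.lnc_gene_id] for p in pairs], dtype=float)
    y = np.array([lfc24[p.pcg_gene_id] for p in pairs], dtype=float)
    points = pd.DataFrame(
        {
            "lnc_gene_id": [p.lnc_gene_id for p in pairs],
            "pcg_gene_id": [p.pcg_gene_id for p in pairs],
            "lnc_lfc24": x,
            "pcg_lfc24": y,
        }
    )
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), points
    r = float(stats.pearsonr(x, y).statistic)
    return r, points


def classify_perturbation(
    pair: NeighborPair,
    expr_control: pd.Series,
    expr_perturbed: pd.Series,
    lfc_thresh: float = DEFAULT_LFC_MIN,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> PerturbationEffect:
    """Classify cis-regulatory direction from a dRE-vs-control contrast.

    ``expr_control``/``expr_perturbed`` are per-gene normalized linear
    expression in the activated (Tam) state.  The perturbation is deemed to
    have worked iff the lncRNA's log2 fold change (perturbed vs control) is
    <= -``lfc_thresh``; otherwise the effect is flagged and no direction is
    assigned.
    """
    def _lfc(gene: str) -> float:
        a = expr_perturbed[gene] + pseudocount
        b = expr_control[gene] + pseudocount
        return float(np.log2(a / b))

    lnc_lfc = _lfc(pair.lnc_gene_id)
    pcg_lfc = _lfc(pair.pcg_gene_id)
    if lnc_lfc > -lfc_thresh:
        return PerturbationEffect(pair, lnc_lfc, pcg_lfc, None, True)
    if pcg_lfc <= -lfc_thresh:
        direction = "cis_activator"
    elif pcg_lfc >= lfc_thresh:
        direction = "cis_repressor"
    else:
        direction = "uncoupled"
    return PerturbationEffect(pair, lnc_lfc, pcg_lfc, direction)


def write_neighbor_pairs_tsv(pairs: Sequence[NeighborPair], path: str) -> None:
    pd.DataFrame([p.__dict__ for p in pairs]).to_csv(path, sep="\t", index=False)


def write_perturbation_effects_tsv(
    effects: Sequence[PerturbationEffect], path: str
) -> None:
    rows = [
        {
            "lnc_gene_id": e.pair.lnc_gene_id,
            "pcg_gene_id": e.pair.pcg_gene_id,
            "relation": e.pair.relation,
            "lnc_lfc": round(e.lnc_lfc, 4),
            "pcg_lfc": round(e.pcg_lfc, 4),
            "direction": e.direction or "",
            "perturbation_failed": int(e.perturbation_failed),
        }
        for e in effects
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
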