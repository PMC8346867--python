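"""Synthetic-data generator planting the study's signature structure.

The generator emits a complete desk-scale file bundle -- genome FASTA, gene
models, candidate ChIP peak files with IP/pooled-control counts, per-condition
fragment BEDs, RNA count matrix, perturbation count matrix, sample sheet --
together with ground-truth tables sufficient to score recovery.

Planted structure (defaults):

* 276 motif-containing regions bound in all three tumor types, of which 102
  (on 87 genes: 56 PCG + 31 lncRNA) have their assigned gene induced in all
  types -> the core signature;
* 174 motif-containing regions bound in LA and SA only, of which 103 (on 64
  genes: 45 PCG + 19 lncRNA) have genes induced in LA/SA only -> the
  senescence-specific signature, with LY read density planted at 1/3.3 of
  the LA/SA level;
* 12 LY-only regions with LY-only induced genes;
* per tumor type, motif-free bound peaks at half the motif-positive density
  and motif-free background peaks at ~2-fold enrichment over the pooled
  control (below the fold-5 significance filter);
* a repressed proliferation module (down in LA/SA at 24 h only), an 8-h
  early response equal to a fixed fraction (12%) of the 24-h linear change,
  and 8 lncRNA-neighbor pairs (6 cis-activators, 1 cis-repressor, 1
  uncoupled) including one pair exactly 125 kb apart.

Counts are negative-binomial; sequences are i.i.d. background with one
consensus p53 response element embedded at the center of every
motif-positive region (verified post hoc with the scanner and regenerated
from an incremented sub-seed on the rare accidental hit).
"""
from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as pio
from .chip import P53_CONSENSUS, IUPAC, build_pwm_from_consensus, scan_pwm
from .types import (
    CountMatrix,
    GeneModel,
    GenomicInterval,
    PeakCall,
    SampleSheet,
    TUMOR_TYPES,
)

REPRESENTATIVE_LINES = {"LA": "LA2", "SA": "SA1", "LY": "LY1"}
RNA_LINES = ("LA1", "LA2", "SA1", "SA2", "LY1", "LY2")
CONDITIONS = [f"{t}:{c}" for t in TUMOR_TYPES for c in ("mock", "tam")]
DISTAL_PAIR_GAP = 125_000  # bp, the lincRNA/Gadd45g-like geometry


@dataclass
class SimConfig:
    seed: int = 0
    # genome / gene layout
    n_chrom: int = 6
    chrom_len: int = 2_000_000
    slot_len: int = 3_900
    n_genes: int = 3_000
    lnc_fraction: float = 0.2
    region_len: int = 200
    fragment_len: int = 100
    # planted region / gene composition
    n_shared_bound_motif: int = 276
    n_core_regions: int = 102
    n_core_pcg: int = 56
    n_core_lnc: int = 31
    n_lasa_bound_motif: int = 174
    n_sen_regions: int = 103
    n_sen_pcg: int = 45
    n_sen_lnc: int = 19
    n_ly_regions: int = 12
    n_nonmotif_bound_per_type: int = 150
    n_background_peaks_per_type: int = 600
    # ChIP count model
    chip_mean_reads: float = 120.0  # per bound peak (motif-free level)
    control_mean_reads: float = 8.0  # per control library
    motif_density_boost: float = 2.0
    ly_density_factor: float = 1.0 / 3.3
    background_fold: float = 2.0
    nb_dispersion: float = 0.05
    ip_libsize: int = 1_000_000
    control_libsize: int = 2_000_000  # pooled control = two merged libraries
    # RNA model
    rna_baseline_median: float = 200.0
    rna_baseline_sigma: float = 1.0
    rna_depth_range: Tuple[float, float] = (0.7, 1.4)
    core_lfc24_range: Tuple[float, float] = (1.0, 3.0)
    early_fraction: float = 0.12
    repressed_module_size: int = 100
    repressed_lfc24: float = -1.0
    # lncRNA-neighbor pairs
    n_pairs: int = 8
    n_activator_pairs: int = 6
    include_distal_pair: bool = True
    pair_pcg_coupling: float = 0.8
    repressor_pcg_lfc24: float = -0.8
    n_perturbed_pairs: int = 3
    n_perturb_replicates: int = 5  # RT-qPCR-style biological replicates
    perturb_lnc_lfc: float = -2.0
    perturb_activator_pcg_lfc: float = -1.5
    perturb_repressor_pcg_lfc: float = 1.5

    @property
    def n_core_genes(self) -> int:
        return self.n_core_pcg + self.n_core_lnc

    @property
    def n_sen_genes(self) -> int:
        return self.n_sen_pcg + self.n_sen_lnc

    def validate(self) -> None:
        if self.n_core_regions < self.n_core_genes or self.n_core_regions > 2 * self.n_core_genes:
            raise ValueError("core regions must map 1-2 per core gene")
        if self.n_sen_regions < self.n_sen_genes or self.n_sen_regions > 2 * self.n_sen_genes:
            raise ValueError("senescence regions must map 1-2 per gene")
        if self.n_shared_bound_motif < self.n_core_regions:
            raise ValueError("core regions must be a subset of shared bound regions")
        if self.n_lasa_bound_motif < self.n_sen_regions:
            raise ValueError("senescence regions must be a subset of LA/SA-bound regions")
        if self.n_pairs < 2 or self.n_activator_pairs != self.n_pairs - 2:
            raise ValueError("pairs = activators + 1 repressor + 1 uncoupled")
        if self.n_pairs > self.n_core_lnc:
            raise ValueError("pair lncRNAs are drawn from the core lncRNAs")
        if self.n_perturbed_pairs < 2 or self.n_perturbed_pairs > self.n_pairs:
            raise ValueError("need at least the repressor and one activator perturbed")
        if not (0 < self.early_fraction < 1):
            raise ValueError("early_fraction must lie in (0, 1)")
        for n in (
            self.n_genes, self.chrom_len, self.slot_len, self.region_len,
            self.fragment_len, self.n_ly_regions, self.repressed_module_size,
        ):
            if n <= 0:
                raise ValueError("all sizes must be positive")
        if self.fragment_len > self.region_len:
            raise ValueError("fragments must fit inside a region")
        n_lnc = round(self.lnc_fraction * self.n_genes)
        if n_lnc < self.n_core_lnc + self.n_sen_lnc + 2:
            raise ValueError("lncRNA fraction too small for the planted lncRNAs")
        # slot budget (gene zone [600, 2800), peak zone [3000, 3200))
        if self.slot_len < 3_700:
            raise ValueError("slot_len must be >= 3700")
        self._slot_budget()

    def _slot_budget(self) -> Tuple[int, int, int]:
        slots_per_chrom = self.chrom_len // self.slot_len
        total = slots_per_chrom * self.n_chrom
        desert = (
            math.ceil((DISTAL_PAIR_GAP + 2 * self.slot_len) / self.slot_len) + 1
            if self.include_distal_pair
            else 0
        )
        n_act = self.n_activator_pairs
        n_distal = 1 if self.include_distal_pair else 0
        n_antisense, n_divergent, n_plain_act = _activator_relations(n_act, n_distal)
        # slot consumption: antisense/divergent share one slot, plain pairs
        # (incl. repressor and uncoupled) take a triple, distal lives in desert
        pair_slots = n_antisense + n_divergent + 3 * (n_plain_act + 2)
        genes_in_pair_slots = (
            2 * (n_antisense + n_divergent) + 3 * (n_plain_act + 2) + 2 * n_distal
        )
        single_slots = self.n_genes - genes_in_pair_slots
        needed = desert + pair_slots + single_slots
        if needed > total:
            raise ValueError(
                f"gene layout needs {needed} slots but only {total} available; "
                "increase chrom_len/n_chrom or reduce n_genes"
            )
        n_gap_loci = 3 * (self.n_nonmotif_bound_per_type + self.n_background_peaks_per_type)
        if n_gap_loci > single_slots:
            raise ValueError("not enough slots for background/nonmotif peak loci")
        return total, desert, pair_slots


def _activator_relations(n_act: int, n_distal: int) -> Tuple[int, int, int]:
    """Split activator pairs into (antisense, divergent, plain intergenic)."""
    rest = n_act - n_distal
    n_antisense = (rest + 1) // 2
    n_divergent = rest - n_antisense
    return n_antisense, n_divergent, 0 if rest >= 0 else 0


def default_config(seed: int = 0) -> SimConfig:
    return SimConfig(seed=seed)


def mini_config(seed: int = 0) -> SimConfig:
    """A seconds-scale configuration exercising every planted class."""
    return SimConfig(
        seed=seed,
        n_chrom=2,
        chrom_len=80_000,
        n_genes=30,
        n_shared_bound_motif=9,
        n_core_regions=7,
        n_core_pcg=3,
        n_core_lnc=3,
        n_lasa_bound_motif=6,
        n_sen_regions=4,
        n_sen_pcg=2,
        n_sen_lnc=1,
        n_ly_regions=1,
        n_nonmotif_bound_per_type=2,
        n_background_peaks_per_type=4,
        repressed_module_size=4,
        n_pairs=3,
        n_activator_pairs=1,
        include_distal_pair=False,
        n_perturbed_pairs=3,
    )


# ---------------------------------------------------------------------------
# truth containers

@dataclass
class SimTruth:
    regions: pd.DataFrame      # locus_id, coords, class, motif, gene_id, planted densities
    genes: pd.DataFrame        # gene_id, biotype, class, planted lfc24 per line
    pairs: pd.DataFrame        # pair composition, relation, planted direction
    chip_counts: pd.DataFrame  # locus x condition realized counts (+ inputs)
    seed: int = 0


@dataclass
class SimBundle:
    outdir: str
    files: Dict[str, str] = field(default_factory=dict)

    def path(self, key: str) -> str:
        return self.files[key]


# ---------------------------------------------------------------------------
# internal layout records

@dataclass
class _Gene:
    gene_id: str
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str
    klass: str
    lfc24: Dict[str, float] = field(default_factory=dict)  # per cell line
    early: bool = False

    def to_model(self) -> GeneModel:
        return GeneModel(
            self.gene_id,
            self.name,
            GenomicInterval(self.chrom, self.start, self.end),
            self.strand,
            self.biotype,
        )


@dataclass
class _Locus:
    locus_id: str
    chrom: str
    start: int
    end: int
    klass: str      # shared | lasa | ly | nonmotif_<T> | background_<T>
    subclass: str   # core | shared_other | senescence | lasa_other | ly | nonmotif | background
    motif: bool
    gene_id: str = ""


def _nb_draw(rng: np.random.Generator, mean, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, np.clip(p, 1e-12, 1.0))


def _realize_motif(rng: np.random.Generator, consensus: str = P53_CONSENSUS) -> str:
    return "".join(rng.choice(list(IUPAC[c])) for c in consensus.upper())


# ---------------------------------------------------------------------------
# layout

def _build_layout(cfg: SimConfig, rng: np.random.Generator):
    """Place genes and peak loci on the slotted genome grid."""
    slot = cfg.slot_len
    chroms = [f"chr{i+1}" for i in range(cfg.n_chrom)]
    slots_per_chrom = cfg.chrom_len // slot
    desert_n = (
        math.ceil((DISTAL_PAIR_GAP + 2 * slot) / slot) + 1
        if cfg.include_distal_pair
        else 0
    )
    # free slots: (chrom, base); desert occupies the start of the last chrom
    free: List[Tuple[str, int]] = []
    for ci, chrom in enumerate(chroms):
        first = desert_n if ci == cfg.n_chrom - 1 else 0
        for si in range(first, slots_per_chrom):
            free.append((chrom, si * slot))
    free_iter = iter(free)
    gap_slots: List[Tuple[str, int]] = []  # slots whose peak zone is usable

    genes: List[_Gene] = []
    loci: List[_Locus] = []
    gid = iter(f"G{i:05d}" for i in range(1, cfg.n_genes + 1))

    def glen() -> int:
        return int(rng.integers(1200, 1601))

    def add_gene(chrom, start, end, strand, biotype, klass, name=None) -> _Gene:
        g = _Gene(next(gid), name or "", chrom, start, end, strand, biotype, klass)
        g.name = name or g.gene_id
        genes.append(g)
        return g

    def add_promoter_locus(g: _Gene, klass, subclass, motif) -> _Locus:
        if g.strand == "+":
            start = g.start - 600
        else:
            start = g.end + 400
        loc = _Locus(
            f"L{len(loci):05d}", g.chrom, start, start + cfg.region_len,
            klass, subclass, motif, g.gene_id,
        )
        loci.append(loc)
        return loc

    def add_internal_locus(g: _Gene, klass, subclass, motif) -> _Locus:
        start = g.start + 300
        loc = _Locus(
            f"L{len(loci):05d}", g.chrom, start, start + cfg.region_len,
            klass, subclass, motif, g.gene_id,
        )
        loci.append(loc)
        return loc

    # ---------------- pairs -------------------------------------------------
    n_distal = 1 if cfg.include_distal_pair else 0
    n_antisense, n_divergent, _ = _activator_relations(cfg.n_activator_pairs, n_distal)
    n_plain_act = cfg.n_activator_pairs - n_distal - n_antisense - n_divergent

    pair_specs: List[dict] = []

    def pair_names(idx: int, direction: str, relation: str) -> Tuple[str, str]:
        if direction == "cis_repressor":
            return "Pvt1b_like", "Myc_like"
        if relation == "divergent" and not any(
            p["lnc_name"] == "lincRNA_p21_like" for p in pair_specs
        ):
            return "lincRNA_p21_like", "Cdkn1a_like"
        if relation == "distal":
            return "lincRNA_Gadd45g_like", "Gadd45g_like"
        return f"lnc_pair{idx}", f"pcg_pair{idx}"

    relations: List[Tuple[str, str]] = [("cis_repressor", "plain")]
    relations += [("cis_activator", "antisense")] * n_antisense
    relations += [("cis_activator", "divergent")] * n_divergent
    relations += [("cis_activator", "plain")] * n_plain_act
    if cfg.include_distal_pair:
        relations += [("cis_activator", "distal")]
    relations += [("uncoupled", "plain")]
    assert len(relations) == cfg.n_pairs

    for idx, (direction, geometry) in enumerate(relations):
        lnc_name, pcg_name = pair_names(idx, direction, geometry)
        if geometry == "antisense":
            chrom, base = next(free_iter)
            pcg = add_gene(chrom, base + 600, base + 2200, "+", "PCG",
                           "pair_pcg", pcg_name)
            lnc = add_gene(chrom, base + 1900, base + 3100, "-", "lncRNA",
                           "core", lnc_name)
            relation = "antisense_overlap"
        elif geometry == "divergent":
            chrom, base = next(free_iter)
            lnc = add_gene(chrom, base + 600, base + 1200, "-", "lncRNA",
                           "core", lnc_name)
            pcg = add_gene(chrom, base + 2400, base + 3600, "+", "PCG",
                           "pair_pcg", pcg_name)
            relation = "divergent"
        elif geometry == "distal":
            chrom = chroms[-1]
            lnc = add_gene(chrom, 600, 2100, "+", "lncRNA", "core", lnc_name)
            pcg_start = lnc.end + DISTAL_PAIR_GAP
            pcg = add_gene(chrom, pcg_start, pcg_start + 1500, "+", "PCG",
                           "pair_pcg", pcg_name)
            relation = "intergenic"
        else:  # plain intergenic triple: lnc filler, pair lnc, pair pcg
            chrom, base = next(free_iter)
            add_gene(chrom, base + 600, base + 600 + glen(),
                     rng.choice(["+", "-"]), "lncRNA", "filler")
            chrom2, base2 = next(free_iter)
            lnc = add_gene(chrom2, base2 + 600, base2 + 2000, "+", "lncRNA",
                           "core", lnc_name)
            chrom3, base3 = next(free_iter)
            pcg = add_gene(chrom3, base3 + 600, base3 + 2000, "+", "PCG",
                           "pair_pcg", pcg_name)
            relation = "intergenic"
        add_promoter_locus(lnc, "shared", "core", True)
        pair_specs.append(
            dict(
                pair_id=f"pair{idx}",
                lnc_name=lnc_name,
                pcg_name=pcg_name,
                lnc_gene_id=lnc.gene_id,
                pcg_gene_id=pcg.gene_id,
                relation=relation,
                direction=direction,
            )
        )

    # mark the perturbed pairs: repressor, first activator (divergent if any),
    # then the uncoupled pair
    perturbed = [0]
    act_order = sorted(
        range(1, cfg.n_pairs - 1),
        key=lambda i: (pair_specs[i]["relation"] != "divergent", i),
    )
    for i in act_order:
        if len(perturbed) < cfg.n_perturbed_pairs - 1:
            perturbed.append(i)
    perturbed.append(cfg.n_pairs - 1)
    for i, spec in enumerate(pair_specs):
        spec["perturbed"] = i in perturbed[: cfg.n_perturbed_pairs + 1]

    # ---------------- remaining genes --------------------------------------
    n_lnc_total = round(cfg.lnc_fraction * cfg.n_genes)
    n_named_lnc = cfg.n_core_lnc + cfg.n_sen_lnc
    n_filler_lnc = n_lnc_total - n_named_lnc - n_plain_act - 2  # triples placed
    n_filler_lnc = max(n_filler_lnc, 0)
    specs: List[Tuple[str, str]] = []  # (biotype, class)
    specs += [("PCG", "core")] * cfg.n_core_pcg
    specs += [("lncRNA", "core")] * (cfg.n_core_lnc - cfg.n_pairs)
    specs += [("PCG", "senescence")] * cfg.n_sen_pcg
    specs += [("lncRNA", "senescence")] * cfg.n_sen_lnc
    specs += [("PCG", "ly")] * cfg.n_ly_regions
    specs += [("PCG", "shared_other")] * (cfg.n_shared_bound_motif - cfg.n_core_regions)
    specs += [("PCG", "lasa_other")] * (cfg.n_lasa_bound_motif - cfg.n_sen_regions)
    specs += [("PCG", "repressed_module")] * cfg.repressed_module_size
    specs += [("lncRNA", "filler")] * n_filler_lnc
    n_so_far = len(genes) + len(specs)
    specs += [("PCG", "filler")] * (cfg.n_genes - n_so_far)
    order = rng.permutation(len(specs))
    for i in order:
        biotype, klass = specs[i]
        chrom, base = next(free_iter)
        strand = str(rng.choice(["+", "-"]))
        start = base + 600
        add_gene(chrom, start, start + glen(), strand, biotype, klass)
        gap_slots.append((chrom, base))

    # ---------------- target-gene loci -------------------------------------
    by_class: Dict[str, List[_Gene]] = {}
    for g in genes:
        by_class.setdefault(g.klass, []).append(g)

    core_genes = by_class["core"]
    sen_genes = by_class["senescence"]
    assert len(core_genes) == cfg.n_core_genes
    assert len(sen_genes) == cfg.n_sen_genes

    pair_ids = {s["lnc_gene_id"] for s in pair_specs}
    for g in core_genes:
        if g.gene_id not in pair_ids:
            add_promoter_locus(g, "shared", "core", True)
    doubled = rng.choice(
        [g.gene_id for g in core_genes if g.gene_id not in pair_ids],
        size=cfg.n_core_regions - cfg.n_core_genes,
        replace=False,
    )
    for g in core_genes:
        if g.gene_id in set(doubled):
            add_internal_locus(g, "shared", "core", True)

    for g in sen_genes:
        add_promoter_locus(g, "lasa", "senescence", True)
    doubled_sen = rng.choice(
        [g.gene_id for g in sen_genes],
        size=cfg.n_sen_regions - cfg.n_sen_genes,
        replace=False,
    )
    for g in sen_genes:
        if g.gene_id in set(doubled_sen):
            add_internal_locus(g, "lasa", "senescence", True)

    for g in by_class.get("ly", []):
        add_promoter_locus(g, "ly", "ly", True)
    for g in by_class.get("shared_other", []):
        add_promoter_locus(g, "shared", "shared_other", True)
    for g in by_class.get("lasa_other", []):
        add_promoter_locus(g, "lasa", "lasa_other", True)

    # ---------------- gap loci (non-motif bound + background) --------------
    gap_order = rng.permutation(len(gap_slots))
    gap_iter = iter(gap_order)

    def add_gap_locus(klass: str, subclass: str) -> None:
        chrom, base = gap_slots[next(gap_iter)]
        start = base + 3000
        loci.append(
            _Locus(
                f"L{len(loci):05d}", chrom, start, start + cfg.region_len,
                klass, subclass, False,
            )
        )

    for t in TUMOR_TYPES:
        for _ in range(cfg.n_nonmotif_bound_per_type):
            add_gap_locus(f"nonmotif_{t}", "nonmotif")
    for t in TUMOR_TYPES:
        for _ in range(cfg.n_background_peaks_per_type):
            add_gap_locus(f"background_{t}", "background")

    return chroms, genes, loci, pair_specs


# ---------------------------------------------------------------------------
# planted expression

def _plant_expression(cfg: SimConfig, rng: np.random.Generator,
                      genes: List[_Gene], pair_specs: List[dict]) -> None:
    def u_lfc() -> float:
        lo, hi = cfg.core_lfc24_range
        return float(rng.uniform(lo, hi))

    by_id = {g.gene_id: g for g in genes}
    for g in genes:
        g.lfc24 = {line: 0.0 for line in RNA_LINES}
        if g.klass == "core":
            l = u_lfc()
            g.lfc24 = {line: l for line in RNA_LINES}
            g.early = True
        elif g.klass == "senescence":
            l = u_lfc()
            g.lfc24 = {line: (l if line[:2] in ("LA", "SA") else 0.0) for line in RNA_LINES}
            g.early = True
        elif g.klass == "ly":
            l = u_lfc()
            g.lfc24 = {line: (l if line.startswith("LY") else 0.0) for line in RNA_LINES}
            g.early = True
        elif g.klass == "repressed_module":
            g.lfc24 = {
                line: (cfg.repressed_lfc24 if line[:2] in ("LA", "SA") else 0.0)
                for line in RNA_LINES
            }
    for spec in pair_specs:
        lnc = by_id[spec["lnc_gene_id"]]
        pcg = by_id[spec["pcg_gene_id"]]
        if spec["direction"] == "cis_activator":
            pcg.lfc24 = {
                line: cfg.pair_pcg_coupling * lnc.lfc24[line] for line in RNA_LINES
            }
            pcg.early = True
        elif spec["direction"] == "cis_repressor":
            pcg.lfc24 = {
                line: (cfg.repressor_pcg_lfc24 if line[:2] in ("LA", "SA") else 0.0)
                for line in RNA_LINES
            }


# ---------------------------------------------------------------------------
# genome synthesis

_BASES = np.array(list("ACGT"))


def _synthesize_genome(cfg: SimConfig, seed_seq: np.random.SeedSequence,
                       chroms: List[str], loci: List[_Locus]) -> Dict[str, str]:
    rng = np.random.default_rng(seed_seq)
    genome: Dict[str, np.ndarray] = {
        chrom: rng.choice(4, size=cfg.chrom_len).astype(np.int8) for chrom in chroms
    }
    pwm = build_pwm_from_consensus()
    L = pwm.length
    base_codes = {b: i for i, b in enumerate("ACGT")}

    def locus_seq(loc: _Locus) -> str:
        arr = genome[loc.chrom][loc.start : loc.end]
        return "".join(_BASES[arr])

    for li, loc in enumerate(loci):
        for attempt in range(20):
            sub = np.random.default_rng([cfg.seed, 104729, li, attempt])
            if attempt > 0:
                genome[loc.chrom][loc.start : loc.end] = sub.choice(
                    4, size=loc.end - loc.start
                ).astype(np.int8)
            if loc.motif:
                word = _realize_motif(sub)
                mid = loc.start + (loc.end - loc.start - L) // 2
                genome[loc.chrom][mid : mid + L] = [base_codes[b] for b in word]
            hits = scan_pwm(locus_seq(loc), pwm)
            offsets = {off for off, _, _ in hits}
            ok = (len(offsets) == 1) if loc.motif else (len(offsets) == 0)
            if ok:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError(f"could not realize sequence for locus {loc.locus_id}")
    return {chrom: "".join(_BASES[arr]) for chrom, arr in genome.items()}


# ---------------------------------------------------------------------------
# count channels

def _chip_mean(cfg: SimConfig, loc: _Locus, condition: str) -> float:
    ttype, state = condition.split(":")
    base = cfg.control_mean_reads
    if state == "mock":
        return base
    bound_motif = cfg.chip_mean_reads * cfg.motif_density_boost
    if loc.klass == "shared":
        return bound_motif
    if loc.klass == "lasa":
        if ttype in ("LA", "SA"):
            return bound_motif
        return bound_motif * cfg.ly_density_factor
    if loc.klass == "ly":
        return bound_motif if ttype == "LY" else base
    if loc.klass == f"nonmotif_{ttype}":
        return cfg.chip_mean_reads
    if loc.klass == f"background_{ttype}":
        scale = cfg.ip_libsize / cfg.control_libsize
        return cfg.background_fold * (2 * cfg.control_mean_reads + 1) * scale
    return base


def _candidate_in_type(loc: _Locus, ttype: str) -> bool:
    """Whether the upstream caller proposes this locus in the type's Tam IP.

    Senescence-prone (lasa) loci are not proposed in LY: their residual LY
    density is planted in the fragment channel but sits below the caller's
    local background, mirroring how the weak LY signal escapes peak calling.
    """
    if loc.klass == "shared":
        return True
    if loc.klass == "lasa":
        return ttype in ("LA", "SA")
    if loc.klass == "ly":
        return ttype == "LY"
    return loc.klass in (f"nonmotif_{ttype}", f"background_{ttype}")


def _draw_chip_counts(cfg: SimConfig, seed_seq, loci: List[_Locus]) -> pd.DataFrame:
    rng = np.random.default_rng(seed_seq)
    data = {}
    for cond in CONDITIONS:
        means = [_chip_mean(cfg, loc, cond) for loc in loci]
        data[cond] = _nb_draw(rng, means, cfg.nb_dispersion)
    for t in TUMOR_TYPES:
        data[f"input_{t}"] = _nb_draw(
            rng, np.full(len(loci), cfg.control_mean_reads), cfg.nb_dispersion
        )
    return pd.DataFrame(data, index=[loc.locus_id for loc in loci])


def _write_fragments(cfg: SimConfig, seed_seq, loci: List[_Locus],
                     chip_counts: pd.DataFrame, outdir: str) -> Dict[str, str]:
    rng = np.random.default_rng(seed_seq)
    files = {}
    span = cfg.region_len - cfg.fragment_len
    for cond in CONDITIONS:
        frags: List[Tuple[str, int, int]] = []
        counts = chip_counts[cond].to_numpy()
        for loc, k in zip(loci, counts):
            if k <= 0:
                continue
            starts = loc.start + rng.integers(0, span + 1, size=int(k))
            frags.extend((loc.chrom, int(s), int(s) + cfg.fragment_len) for s in starts)
        frags.sort()
        name = f"fragments_{cond.replace(':', '_')}.bed"
        path = os.path.join(outdir, name)
        with open(path, "w") as fh:
            for chrom, s, e in frags:
                fh.write(f"{chrom}\t{s}\t{e}\n")
        files[name] = path
    return files


def _write_peaks(cfg: SimConfig, loci: List[_Locus], chip_counts: pd.DataFrame,
                 outdir: str) -> Dict[str, str]:
    files = {}
    for t in TUMOR_TYPES:
        sample_id = f"CHIP_{REPRESENTATIVE_LINES[t]}_tam"
        peaks = []
        for loc in loci:
            if not _candidate_in_type(loc, t):
                continue
            ip = int(chip_counts.at[loc.locus_id, f"{t}:tam"])
            pooled = int(
                chip_counts.at[loc.locus_id, f"input_{t}"]
                + chip_counts.at[loc.locus_id, f"{t}:mock"]
            )
            peaks.append(
                PeakCall(
                    interval=GenomicInterval(loc.chrom, loc.start, loc.end),
                    sample_id=sample_id,
                    ip_count=ip,
                    control_count=pooled,
                    ip_libsize=cfg.ip_libsize,
                    control_libsize=cfg.control_libsize,
                    name=loc.locus_id,
                )
            )
        name = f"peaks_{t}.tsv"
        path = os.path.join(outdir, name)
        pio.write_peak_calls(peaks, path)
        files[name] = path
    return files


def _rna_mean(cfg: SimConfig, g: _Gene, baseline: float, line: str, tp: int) -> float:
    l24 = g.lfc24[line]
    if tp == 0 or l24 == 0.0:
        return baseline
    full = baseline * 2.0 ** l24
    if tp == 24:
        return full
    if not g.early or l24 < 0:
        return baseline  # late responders are flat at 8 h
    return baseline + cfg.early_fraction * (full - baseline)


def _write_rna(cfg: SimConfig, seed_seq, genes: List[_Gene], outdir: str):
    rng = np.random.default_rng(seed_seq)
    baselines = cfg.rna_baseline_median * np.exp(
        rng.normal(0.0, cfg.rna_baseline_sigma, size=len(genes))
    )
    sample_ids, depths, means = [], [], []
    for line in RNA_LINES:
        for tp in (0, 8, 24):
            sample_ids.append(f"RNA_{line}_{tp}h")
            depths.append(rng.uniform(*cfg.rna_depth_range))
            means.append(
                [_rna_mean(cfg, g, b, line, tp) for g, b in zip(genes, baselines)]
            )
    mean_mat = np.array(means).T * np.array(depths)[None, :]
    counts = _nb_draw(rng, mean_mat, cfg.nb_dispersion)
    df = pd.DataFrame(counts, index=[g.gene_id for g in genes], columns=sample_ids)
    cm = CountMatrix(df)
    path = os.path.join(outdir, "rna_counts.tsv")
    pio.write_counts_tsv(cm, path)
    return path, baselines, sample_ids


def _write_perturbation(cfg: SimConfig, seed_seq, genes: List[_Gene],
                        baselines: np.ndarray, pair_specs: List[dict], outdir: str):
    rng = np.random.default_rng(seed_seq)
    by_id = {g.gene_id: i for i, g in enumerate(genes)}
    base_line = "LA1"  # perturbation experiments run in an LA background
    tam_mean = np.array(
        [b * 2.0 ** g.lfc24[base_line] for g, b in zip(genes, baselines)]
    )
    perturbed = [s for s in pair_specs if s["perturbed"]][: cfg.n_perturbed_pairs]
    n_rep = cfg.n_perturb_replicates
    ctrl_cols = [f"ctrl_tam_r{r+1}" for r in range(n_rep)]
    cols = {c: tam_mean.copy() for c in ctrl_cols}
    design_rows = []
    for spec in perturbed:
        mean = tam_mean.copy()
        mean[by_id[spec["lnc_gene_id"]]] *= 2.0 ** cfg.perturb_lnc_lfc
        if spec["direction"] == "cis_activator":
            shift = cfg.perturb_activator_pcg_lfc
        elif spec["direction"] == "cis_repressor":
            shift = cfg.perturb_repressor_pcg_lfc
        else:
            shift = 0.0
        mean[by_id[spec["pcg_gene_id"]]] *= 2.0 ** shift
        rep_cols = [f"dre_{spec['lnc_name']}_tam_r{r+1}" for r in range(n_rep)]
        for c in rep_cols:
            cols[c] = mean
        design_rows.append(
            dict(
                pair_id=spec["pair_id"],
                lnc_gene_id=spec["lnc_gene_id"],
                pcg_gene_id=spec["pcg_gene_id"],
                control_samples=";".join(ctrl_cols),
                perturbed_samples=";".join(rep_cols),
            )
        )
    counts = {c: _nb_draw(rng, m, cfg.nb_dispersion) for c, m in cols.items()}
    df = pd.DataFrame(counts, index=[g.gene_id for g in genes])
    cpath = os.path.join(outdir, "perturbation_counts.tsv")
    pio.write_counts_tsv(CountMatrix(df), cpath)
    dpath = os.path.join(outdir, "perturbation_design.tsv")
    pd.DataFrame(design_rows).to_csv(dpath, sep="\t", index=False)
    return cpath, dpath


# ---------------------------------------------------------------------------
# top-level entry points

def simulate_dataset(cfg: SimConfig, outdir: str) -> Tuple[SimBundle, SimTruth]:
    """Write the full synthetic bundle into ``outdir``; return paths + truth."""
    cfg.validate()
    os.makedirs(outdir, exist_ok=True)
    root = np.random.SeedSequence(cfg.seed)
    s_layout, s_genome, s_chip, s_frag, s_rna, s_pert = root.spawn(6)

    layout_rng = np.random.default_rng(s_layout)
    chroms, genes, loci, pair_specs = _build_layout(cfg, layout_rng)
    _plant_expression(cfg, layout_rng, genes, pair_specs)
    genome = _synthesize_genome(cfg, s_genome, chroms, loci)
    chip_counts = _draw_chip_counts(cfg, s_chip, loci)

    files: Dict[str, str] = {}

    gpath = os.path.join(outdir, "genome.fa")
    pio.write_fasta(genome, gpath)
    files["genome.fa"] = gpath

    genes_path = os.path.join(outdir, "genes.tsv")
    pio.write_gene_models([g.to_model() for g in genes], genes_path)
    files["genes.tsv"] = genes_path

    files.update(_write_peaks(cfg, loci, chip_counts, outdir))
    files.update(_write_fragments(cfg, s_frag, loci, chip_counts, outdir))

    rna_path, baselines, rna_samples = _write_rna(cfg, s_rna, genes, outdir)
    files["rna_counts.tsv"] = rna_path

    cpath, dpath = _write_perturbation(cfg, s_pert, genes, baselines, pair_specs, outdir)
    files["perturbation_counts.tsv"] = cpath
    files["perturbation_design.tsv"] = dpath

    # sample sheet
    rows = []
    for line in RNA_LINES:
        for tp in (0, 8, 24):
            rows.append(
                dict(
                    sample_id=f"RNA_{line}_{tp}h",
                    cell_line=line,
                    tumor_type=line[:2],
                    assay="RNA",
                    condition="mock" if tp == 0 else "tam",
                    timepoint_h=tp,
                    path="rna_counts.tsv",
                )
            )
    for t in TUMOR_TYPES:
        line = REPRESENTATIVE_LINES[t]
        rows.append(
            dict(
                sample_id=f"CHIP_{line}_tam", cell_line=line, tumor_type=t,
                assay="CHIP_IP", condition="tam", timepoint_h=24,
                path=f"peaks_{t}.tsv",
            )
        )
        rows.append(
            dict(
                sample_id=f"CHIP_{line}_mock", cell_line=line, tumor_type=t,
                assay="CHIP_IP", condition="mock", timepoint_h=24,
                path=f"fragments_{t}_mock.bed",
            )
        )
        rows.append(
            dict(
                sample_id=f"CHIP_{line}_input", cell_line=line, tumor_type=t,
                assay="CHIP_CONTROL", condition="mock", timepoint_h=24,
                path="",
            )
        )
    sheet = SampleSheet(pd.DataFrame(rows))
    sheet_path = os.path.join(outdir, "sample_sheet.tsv")
    pio.write_sample_sheet(sheet, sheet_path)
    files["sample_sheet.tsv"] = sheet_path

    # truth tables
    bound_motif_mean = cfg.chip_mean_reads * cfg.motif_density_boost
    region_rows = []
    for loc in loci:
        region_rows.append(
            dict(
                locus_id=loc.locus_id,
                chrom=loc.chrom,
                start=loc.start,
                end=loc.end,
                klass=loc.subclass,
                bound_in=";".join(
                    t for t in TUMOR_TYPES if _candidate_in_type(loc, t)
                    and loc.subclass != "background"
                ),
                has_motif=int(loc.motif),
                gene_id=loc.gene_id,
                planted_tam_LA=_chip_mean(cfg, loc, "LA:tam"),
                planted_tam_SA=_chip_mean(cfg, loc, "SA:tam"),
                planted_tam_LY=_chip_mean(cfg, loc, "LY:tam"),
            )
        )
    truth_regions = pd.DataFrame(region_rows)

    gene_rows = []
    for g, b in zip(genes, baselines):
        row = dict(
            gene_id=g.gene_id, name=g.name, biotype=g.biotype, klass=g.klass,
            baseline=round(float(b), 3), early=int(g.early),
        )
        for line in RNA_LINES:
            row[f"lfc24_{line}"] = round(g.lfc24[line], 4)
        gene_rows.append(row)
    truth_genes = pd.DataFrame(gene_rows)

    truth_pairs = pd.DataFrame(pair_specs)

    for name, frame in [
        ("truth_regions.tsv", truth_regions),
        ("truth_genes.tsv", truth_genes),
        ("truth_pairs.tsv", truth_pairs),
    ]:
        path = os.path.join(outdir, name)
        frame.to_csv(path, sep="\t", index=False)
        files[name] = path
    cc_path = os.path.join(outdir, "truth_chip_counts.tsv")
    out_cc = chip_counts.copy()
    out_cc.index.name = "locus_id"
    out_cc.to_csv(cc_path, sep="\t")
    files["truth_chip_counts.tsv"] = cc_path

    manifest = {
        "seed": cfg.seed,
        "files": {
            name: hashlib.sha256(open(path, "rb").read()).hexdigest()
            for name, path in sorted(files.items())
        },
    }
    mpath = os.path.join(outdir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    files["manifest.json"] = mpath

    truth = SimTruth(
        regions=truth_regions,
        genes=truth_genes,
        pairs=truth_pairs,
        chip_counts=chip_counts,
        seed=cfg.seed,
    )
    return SimBundle(outdir=outdir, files=files), truth


def make_mini_fixture(outdir: str, seed: int = 0,
                      cfg: Optional[SimConfig] = None) -> Tuple[SimBundle, SimTruth]:
    """Seconds-scale bundle (<= 50 regions) with explicit fragment BEDs."""
    cfg = cfg or mini_config(seed)
    return simulate_dataset(cfg, outdir)
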