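"""Classifying cis-regulatory direction from response-element perturbation.

Mutagenizing a lncRNA-associated p53 response element (dRE) knocks the
lncRNA down in the p53-activated state; the neighboring gene's response
then reveals the pair's direction: a cis-activator's neighbor falls with
the lncRNA (the lincRNA-p21/p21 pattern), a cis-repressor's neighbor rises
(the Pvt1b/Myc pattern), and an uncoupled neighbor does not move.
"""
import pandas as pd

from p53sig.cisreg import NeighborPair, classify_perturbation

control = pd.Series({"Pvt1b": 400.0, "Myc": 600.0,
                     "lincRNA_p21": 300.0, "Cdkn1a": 900.0})
perturbed = pd.Series({"Pvt1b": 95.0, "Myc": 1750.0,      # lnc down, Myc up
                       "lincRNA_p21": 70.0, "Cdkn1a": 310.0})  # both down

pairs = [
    NeighborPair("Pvt1b", "Myc", 50_000, "intergenic"),
    NeighborPair("lincRNA_p21", "Cdkn1a", 15_000, "divergent"),
]
for pair in pairs:
    effect = classify_perturbation(pair, control, perturbed)
    print(
        f"{pair.lnc_gene_id:>12} -> {pair.pcg_gene_id:<7} "
        f"lnc log2FC {effect.lnc_lfc:+.2f}, neighbor {effect.pcg_lfc:+.2f} "
        f"=> {effect.direction}"
    )
print()
print("Directions use symmetric log2FC thresholds (default log2 1.5) after")
print("requiring that the perturbation actually reduced the lncRNA.")
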