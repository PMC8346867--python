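"""Median-of-ratios normalization and fold changes.

Size factors make RNA-seq counts comparable across libraries of different
depth; fold changes are then computed on normalized counts with a +1
pseudocount.
"""
import pandas as pd

from p53sig.rnaseq import lfc, size_factors_median_of_ratios
from p53sig.types import CountMatrix

counts = CountMatrix(
    pd.DataFrame(
        {
            "mock": [100, 200, 50, 400],
            "tam_shallow": [55, 95, 110, 210],   # half-depth library
            "tam_deep": [220, 380, 440, 840],    # 2x-depth replicate of it
        },
        index=["Cdkn1a", "Mdm2", "Bax", "Actb"],
    )
)
sf = size_factors_median_of_ratios(counts)
print("size factors:", {k: round(float(v), 3) for k, v in sf.items()})
for gene in ("Cdkn1a", "Bax"):
    a = lfc(counts, sf, gene, "tam_deep", "mock")
    b = lfc(counts, sf, gene, "tam_shallow", "mock")
    print(f"{gene}: log2FC deep vs mock = {a:.3f}, shallow vs mock = {b:.3f}")
print()
print("The two treated libraries differ 4-fold in depth but give matching")
print("fold changes once the size factors absorb the depth difference.")
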