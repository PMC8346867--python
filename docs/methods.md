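# Methods

This note documents the models and procedures implemented in `p53sig`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Coordinates and formats

All genomic coordinates are 0-based half-open (BED convention); display
strings in logs are 1-based closed and the conversion is lossless. Gene
models use a flat 7-column TSV (span, strand, biotype ∈ {PCG, lncRNA})
rather than GTF: the pipeline's logic needs nothing finer than the gene
span and TSS, and exon/intron structure is deliberately out of scope.
Candidate ChIP peaks arrive as narrowPeak-style TSV extended with four
count columns (IP count, pooled-control count, and the two library sizes),
which keeps the pipeline alignment-free. Readers reject schema violations
naming the first offending line; unknown chromosomes are hard errors.

## Peak significance

The peak *caller* is upstream of this package; what is implemented is the
significance filtering of candidate peaks. For a peak with IP count `k`,
pooled-control count `c`, and library sizes `N_ip`, `N_ctl`:

* enrichment = `(k / N_ip) / ((c + 1) / N_ctl)` — the +1 pseudocount keeps
  the ratio finite on empty controls;
* p-value = `P(Poisson(λ) ≥ k)` with `λ = (c + 1) · N_ip / N_ctl`, a
  deterministic, desk-scale stand-in for a full peak-caller enrichment
  test (computed with the stable scipy survival function);
* q-values are Benjamini–Hochberg across the sample's candidate peaks.

A peak is significant iff `q < 0.01` and `enrichment ≥ 5`. A fold filter
stated in log2 units could also be read as ≥ 2⁵-fold; this package uses
plain fold enrichment ≥ 5 and exposes `min_fold` as a configuration knob
for the stricter reading. The pooled negative control for a tumor type is the
type's input plus mock-IP library, so its library size is naturally about
twice the IP's — the enrichment definition scales accordingly.

## Merging, counting, normalization

Significant peak positions from any tumor type are merged into the minimal
disjoint cover; intervals merge only when they share at least one base —
adjacent (touching) intervals stay separate, and region ids are the
deterministic `chrom:start-end` strings. A tumor type is recorded as bound
in a merged region iff one of its significant peaks overlaps it. Fragments
are counted per region per condition by half-open overlap; a fragment
spanning two regions increments both.

Cross-condition normalization follows the top-30% rule: per condition,
regions are ranked by count (descending, ties broken by region id,
`ceil` for the 30% cutoff); the scaling denominator is the summed counts of
regions ranking in the top 30% in *every* condition, and columns are
rescaled by the mean denominator so magnitudes remain read-like.
Normalization is applied to the three Tam IP conditions jointly and to the
three mock conditions jointly: the rule presupposes a shared enrichment
structure, and a mock (background-only) profile ranks regions essentially
at random, so a six-way intersection is empty with high probability. When
the shared top set is empty at the configured fraction (possible for the
mock trio at small scale), the pipeline escalates the fraction
deterministically (0.5, 0.75, 1.0) rather than aborting; at the default
scale the Tam trio never escalates.

## Motif model

The p53 response element is two adjacent RRRCWWGYYY half-sites with zero
spacer (L = 20); spaced or dimeric variants are out of scope. The PWM
distributes probability uniformly over each IUPAC code's bases, mixed with
pseudocount 0.01 × uniform, and scores are log₂-odds against a uniform
background; N bases contribute 0 bits. The default hit threshold is the
consensus score minus the largest single-position drop — i.e. the score of
the worst single-base mismatch to the consensus (15.21 bits for the
default element; consensus scores 23.84). A random 20-mer reaches this
threshold with probability ≈ 2⁻²⁴ per offset, so background hits are
negligible at the scales scanned. Scanning is restricted to the region
sequence: a motif straddling the region edge does not count. Because the
consensus is reverse-complement symmetric, a planted element scores on
both strands at the same forward-coordinate offset.

## Expression summaries

Size factors are textbook median-of-ratios: per gene with all-positive
counts, the geometric mean across samples; per sample, the median of
count/geometric-mean ratios, with the median taken on the ratio scale.
(pydeseq2 medians the log-ratios; the two coincide whenever the
all-positive gene count is odd, and the test suite pins the agreement.)
Two near-invariances are worth stating precisely: scaling one sample's
counts by `c` scales its factor by `c` *relative to the others* — all
factors also pick up a common `c^(−1/n)` from the shifted geometric-mean
reference — and log fold changes are exactly invariant under such
rescaling only without the pseudocount, since a common scale cancels in
the pure count ratio.

Fold changes per cell line are `log2((norm_t + 1)/(norm_0 + 1))` against
the line's 0-h sample. The induction criteria are this package's own
convention: a type calls a gene induced at 24 h
iff the mean lfc24 of its two lines is ≥ log₂ 1.5 ≈ 0.585 and both lines
are positive; `induced8` and `repressed24` are the obvious analogues. With
one library per line and time point there is no per-gene variance
estimate, hence an effect-size-plus-sign-consistency rule rather than a
p-value; the threshold is a config knob (`lfc_min`).

The early-response fraction is computed on linear normalized expression:
per gene, expression is averaged across the six cell lines at each time
point, and the statistic is the mean over genes (with positive averaged
24-h change) of `(E8 − E0)/(E24 − E0)`, reported in percent. Averaging
across lines before forming the ratio is a deliberate design choice:
per-(gene, line) ratios have single-library denominators that can land
near zero and make the estimator's tails heavy enough to dominate the
mean (observed swings of ±2 percentage points at the default scale),
whereas the line-averaged form recovers a planted 12% early response to
within ±1.3 points across seeds.

PCA operates on log₂(normalized count + 1) with genes centered (the
transform is unspecified upstream; log stabilizes the NB variance); the
first nonzero loading of each component is made positive so coordinates
are reproducible, and an all-identical input is flagged degenerate rather
than erroring.

## Signature calling

Regions are assigned to the closest gene by gap distance (0 on overlap),
ties broken by the lexicographically smaller gene id; locality is
intragenic iff the region overlaps the gene or lies within 2,000 bp
upstream of its TSS on the gene's strand. Binding per tumor type is
assessed in the type's single profiled representative line (LA2, SA1,
LY1). Classes are assigned per region (core / senescence_specific /
LY_specific / other as defined in the README) and are mutually exclusive
and exhaustive by construction; the gene-level class is the union of the
gene's region classes with precedence core > senescence_specific >
LY_specific > other. Biotype percentages round to the nearest integer.
The LY fold-reduction over the called senescence-specific regions is the
mean over regions of `mean(norm_LA, norm_SA)/norm_LY` on Tam densities,
with LY floored at 10⁻⁶ to guard empty denominators; the mean-of-ratios
form carries a small Jensen bias upward that the top-set selection effect
in the normalization largely offsets at the default scale.

## lncRNA cis-regulation

Each signature lncRNA is paired with its nearest protein-coding gene:
`antisense_overlap` when the two overlap on opposite strands, `divergent`
when non-overlapping head-to-head TSSs sit within 2 kb (the window is this
package's choice), else `intergenic`. The pair
correlation is Pearson's r between lncRNA and neighbor lfc24 across pairs
in one cell line (LA1), undefined (flagged) under zero variance.
Perturbation contrasts compare mean normalized expression between control
and response-element-mutagenized (dRE) libraries in the activated state:
the contrast is valid only if the lncRNA fell by ≥ log₂ 1.5, after which
the neighbor's fold change classifies the pair as cis_activator (≤ −log₂
1.5), cis_repressor (≥ +log₂ 1.5), or uncoupled. Thresholds rather than
p-values are used deliberately: the replicate structure emulated here is
too small for stable per-gene tests, and the planted effects are large.

## The synthetic-data generator

The generator emulates the study design — six cell lines in three tumor
types, RNA at 0/8/24 h (0 h mock, later points Tam), ChIP at 24 h in one
representative line per type with input and mock-IP controls — on a
6 × 2 Mb genome with ~3,000 genes (20% lncRNA) laid out on a regular slot
grid. Its defaults *are* the study conditions: 276 motif-containing
regions bound in all types containing the 102 core regions (87 genes:
56 PCG + 31 lncRNA), 174 LA/SA-only regions containing the 103
senescence-specific regions (64 genes: 45 + 19), 12 LY-only regions,
negative-binomial counts with dispersion 0.05 for both assays, bound-peak
density 240 reads (120 × the twofold motif boost) against mean-8 control
libraries, LY residual density 1/3.3 at senescence loci, RNA baselines
lognormal with median 200, planted induction log₂FC uniform in [1, 3], an
8-h linear change equal to 12% of the 24-h change for induced genes, a
100-gene proliferation module at log₂FC −1 in LA/SA only, and 8
lncRNA–neighbor pairs (6 cis-activators, 1 cis-repressor, 1 uncoupled),
one placed exactly 125 kb from its neighbor. Per-type motif-free classes
complete the picture: 150 bound peaks at half the motif-positive density
(the ~twofold motif effect on binding strength) and 600 background peaks at ~2-fold
enrichment, below the fold-5 filter by design so that planted-count
recovery is sharp. Perturbation data are emitted as 5 replicate libraries
per state (control and three dRE lines) with the lncRNA knocked down
4-fold and neighbors shifted ±log₂FC 1.5 per the planted direction.

Sequences are i.i.d. uniform ACGT with exactly one consensus realization
embedded at the center of every motif-positive region; after synthesis
every region is re-scanned and any region violating the exactly-one (or
exactly-zero) hit property is regenerated from an incremented sub-seed.
Senescence loci are absent from LY's candidate peak list — their residual
LY enrichment (~8-fold over a naive global control) is exactly the kind of
weak signal a local-background-aware caller drops, and their density
remains planted in the fragment channel where the fold-reduction statistic
measures it. Bundles are byte-reproducible from the seed (a manifest of
content hashes is emitted), and a mini configuration (~34 regions, < 1 s)
exercises every planted class including fragment-level counting.

What the generator does **not** emulate, and hence what passing tests do
not show about real data: mappability and GC bias, read-level sequence
(FASTQ), peak-width variation and summit structure, exon/intron structure
and isoform-level counting, replicate-level biological variability beyond
a single NB dispersion, batch effects, tumor-type-specific baseline
expression differences (real PCA separates tumor types; here the dominant
variance is the treatment response), and chromatin fractionation.

## Recovery behaviour and known limitations

ChIP-side recovery is essentially exact: bound peaks clear the fold-5
filter with ≈3.4σ margin, so the motif-stratified Venn cells reproduce
276/174 exactly across seeds. RNA-side recovery is sharp but not exact by
construction: planted effects at the low end of [1, 3] sit ≈1.2σ from the
induction threshold given the single-library lfc noise (sd ≈ 0.47 at
dispersion 0.05), so a few percent of signature genes can miss, and a
similar fraction of senescence genes draw a spurious LY induction; called
counts across seeds range roughly 92–102 core and 94–102
senescence-specific regions against the planted 102/103, while the
biotype percentages are robust (lncRNAs and PCGs miss at the same rate).
The fold-reduction estimate lands in 3.0–3.5 and the early-response
fraction in 11.1–13.3% across seeds. Default problem sizes (a 12-Mb
genome, ~2,700 peak loci, ~470k fragments, 3,000 × 22 counts) were chosen
so a full simulate-plus-pipeline run completes in ~10 s on one CPU.
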