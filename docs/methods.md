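# Methods

This note documents the models, statistical procedures, numerical choices and
known limitations of `methbrain`. It is the package's own account of what it
computes; every empirical number mentioned here is produced by the test suite
or by `scripts/acceptance.py`, not asserted from elsewhere.

## Coordinate and data conventions

All in-memory coordinates are 0-based half-open. Cytosine reports (1-based)
and RepeatMasker `.out` rows (1-based inclusive) are converted at the parse
boundary; BED and UCSC-table inputs pass through unchanged. A methylation
level β is `n_meth / (n_meth + n_unmeth)` and is undefined (NaN) at zero
depth. Sites with depth below 10 are discarded before every analysis — the
filter's boundary (depth 9 removed, depth 10 kept) is pinned by tests.

CpG sites on the two strands of a dyad are kept separate by default;
`merge_dyads` sums the strand counts onto the plus-strand coordinate. The
merged ("destranded") representation is the unit we use for differential
calling benchmarks, because a CpG's methylation state is a property of the
dyad and merging doubles the effective depth behind each test — the same
convention methylKit applies with `destrand=TRUE`.

## Per-sample quantification

Promoters are the 2,000 bp immediately upstream of the TSS, strand-aware and
clipped at position 0 (and at the chromosome end when lengths are known).
Features are assigned with the priority promoter > gene body > intergenic;
gene body is the full transcript span including introns. Methylation-level
bins are the quartiles `[0,.25) [.25,.5) [.5,.75) [.75,1]` — half-open except
the last, so β = 0.25 falls in the second bin and no site is double-counted.

## Differential methylation

Each CpG shared by a sample pair contributes a 2x2 table (methylated /
unmethylated counts in the two samples) to a two-sided Fisher's exact test
under the probability-mass rule: the p-value sums the hypergeometric
probabilities of every table with the observed margins whose probability does
not exceed the observed table's (relative tie slack 1e-7, absorbing
floating-point noise on symmetric tables). The implementation is vectorised
over all sites of a scan with log-gamma arithmetic; agreement with an exact
rational-arithmetic enumeration oracle over all 635,375 tables with total
count ≤ 60 is better than 1e-9 (measured ~1e-13).

p-values are Benjamini–Hochberg adjusted per sample pair; the family is
exactly the intersection of the two depth-filtered site sets. Sites with
q ≤ 0.05 are classified hyper- (level higher in sample B) or hypo-methylated
by the sign of the level difference. A minimum absolute difference filter is
available but defaults to 0. methylKit's SLIM q-values are deliberately not
re-implemented: BH is exactly specified, testable against its step-up
definition, and the choice is recorded in output headers.

DMGs (differentially methylated genes) are genes whose strand-aware first
exon overlaps (≥ 1 bp) a CpG island containing at least one significant DMS.
The DMG threshold defaults to q ≤ 0.01 in the pipeline, with the q ≤ 0.05
screen threshold exposed separately; both are configurable and neither is
hard-coded anywhere downstream.

### Calibration and power

On a null two-region simulation (no planted differences, ~10,000 CpG sites,
negative-binomial depth with mean 15) the raw p ≤ 0.05 fraction is ~0.02 —
Fisher is conservative on discrete tables — and BH yields zero calls at
q ≤ 0.05. For planted differences of Δβ = 0.5 at mean depth 30, exact power
enumeration shows a strand-level test cannot exceed ~0.81 sensitivity at the
BH-implied per-site α; on destranded sites (both strands' reads behind each
test) measured sensitivity is ~0.98 at empirical FDR ~0.03. This is why the
benchmark, and our recommendation for real CpG analyses, use the destranded
unit.

## Expression analysis

TMM scaling factors are computed on the expression values as given
(FPKM-scale), not raw counts: M = log2(x/x_ref) and A = log2(x·x_ref)/2 are
taken directly, with the library-size term dropped because FPKM is already
depth-scaled. Trimming removes the top/bottom 30% of M and 5% of A (the
edgeR defaults); the remaining M are averaged with inverse-asymptotic-
variance weights 1/(1/x + 1/x_ref) and factors are rescaled to geometric
mean 1. The reference sample is the one whose upper quartile is closest to
the mean upper quartile, or a caller-pinned column (edgeR's `refColumn`).
Scale equivariance — multiplying a column by s multiplies its factor ratio
by s — holds to within 0.2% on the synthetic study.

Genes are filtered to those with a ≥ 4-fold pseudocounted ratio between some
sample pair (pseudocount 1, consistent with the log2(FPKM+1) transform; the
filter is applied after TMM). log2(FPKM+1) values are standardised per gene
(sample standard deviation, ddof 1) and capped at ±2. With seven regions the
largest attainable raw z is (n−1)/√n ≈ 2.27, so the cap is active exactly
for genes whose signal concentrates in one region.

### PAM clustering

k-medoids with Euclidean distance on the capped z-matrix, k = number of
regions (7). When the medoid-set space C(n,k) is at most 5,000 the global
optimum is found by exact enumeration; larger instances use the classical
deterministic BUILD phase followed by best-improvement SWAP. The exact
small-instance branch exists because best-improvement local search
provably sticks in a local optimum on ~4–5% of random tiny instances,
whereas small instances are cheap to solve exactly; production-size inputs
(hundreds of genes, k = 7) always take the BUILD+SWAP path, whose cost never
exceeds the BUILD cost (tested). No randomness anywhere: ties break toward
the lower gene index and cluster labels are assigned in sorted order of
medoid gene ids, so results are bit-reproducible.

Each region is assigned the cluster with the highest mean z in that region;
the assignment need not be a bijection (a warning is raised when two regions
select the same cluster). The assigned cluster's genes form the region's
BRSG (brain-region-specific gene) set.

## Methylation–expression integration

Candidate pairs are CpG islands overlapping a promoter by ≥ 1 bp; an island
spanning two promoters yields two pairs. Each region contributes the median
β over the depth-filtered CpG sites inside the island (even-count median =
midpoint of the central order statistics); a pair missing any region's
median is dropped and counted. Pearson's r between the methylation vector
and the TMM-normalised expression vector is tested two-sided on n−2 degrees
of freedom; pairs with p ≤ 0.05 are kept and signed. Expression enters on
the normalised FPKM scale, not as capped z-scores, so the cap cannot distort
r. No multiple-testing correction is applied in the screen by default — the
screen is a deliberate raw-p filter — but `add_bh` attaches q-values for
users who want them. When one gene has several qualifying islands the
smallest-p pair represents the gene.

With seven regions the critical |r| at p = 0.05 is ≈ 0.755; planted
couplings with true |r| ≈ 0.95 are recovered at ≥ 80% (measured ~100% on a
1,000-gene screen simulation) while null genes pass at ≤ 7% (measured ~4%).

## Repeat-element methylation

Repeats are stratified by class and subtype and split by CpG-island content.
Metaprofiles scale each element body to 100 bins (a site at offset o in an
element of length L falls in bin ⌊100·o/L⌋), add 100-bp flanks in 20 fixed
5-bp bins, flip minus-strand elements into element orientation, and average
β per bin over all elements; bins without covered sites are missing, never
zero. The raw series is LOESS-smoothed (tricube weights, degree-1 local
fits, span 0.3 — a logged configuration value; the span choice only affects
presentation, not the raw series, and both are emitted). Elements shorter
than the bin count are dropped from profiles.

Inner/outer statistics pool site-level β inside elements of a class versus
sites within 100 bp outside element boundaries; flank sites falling inside
any annotated repeat are excluded from the outer pool so dense repeat
neighbourhoods cannot leak element signal into the flanks (a per-element-
mean mode and a same-class-only exclusion are available). Means and sample
standard deviations (ddof 1) are reported with the outer-minus-inner
difference. Subtypes are called hypo-methylated below median β 0.25 and
hyper-methylated at or above 0.75, mirroring the quartile bins.

## Synthetic data generator

The generator emulates the structure of a seven-region paired WGBS +
transcriptome study at desk scale: 2 chromosomes x 2 Mbp, 300 genes (each
with ≥ 2 exons), ~200 promoter CpG islands spanning TSSs, ~370 intergenic
repeats placed with ≥ 2 flank-widths of spacing, ~55,000 CpG strand-sites
(denser inside islands) plus sparse non-CpG sites, and 7 paired expression
columns. Compartment Beta distributions give the qualitative methylation
landscape: hypomethylated promoter islands (Beta(1,9)), hypermethylated
gene bodies, intergenic space and repeat interiors (Beta(8,2)), elevated
repeat flanks (Beta(9,1.5)), near-zero non-CpG methylation (Beta(0.5,20)).
LINE-like bodies are planted edge-high (outer thirds Beta(18,2), middle
Beta(6,4)) and SINE-like bodies centre-high, so both canonical metaprofile
shapes are recoverable. Depth is negative-binomial (mean 15, size 5) so the
depth-10 filter removes a realistic ~25% of sites; methylated counts are
binomial in the latent level.

Planted signals, all recorded in machine-readable truth tables:

* **DMSs** — latent dyad levels shifted by ±0.5 in exactly one region
  (clipped into [0.02, 0.98] with a warning), one third drawn from promoter
  islands so DMGs exist downstream.
* **DMGs** — derived: genes whose promoter island contains a planted DMS.
* **Clusters** — 30 genes per region gain +3 log2 units in that region.
* **Methylation-coupled genes** — 5 positive and 3 negative by default.
  Their promoter islands receive latent per-region mean levels
  Normal(0.4, 0.15) (mid-range, so clipping never distorts the pattern)
  with a small fixed per-dyad scatter; log2 expression is then a linear
  function of the island's measured depth-filtered median per region, with
  noise calibrated so the correlation target is ≈ 0.95. The coupling
  amplitude is 1 log2 unit per SD of methylation — large enough to matter,
  small enough that exponentiating to the FPKM scale (where the screen
  correlates) preserves the target correlation.

Everything is a pure function of (config, seed): identical configurations
produce byte-identical files, and the full pipeline on the default dataset
runs in well under a minute on one CPU, with two runs yielding identical
output digests.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: read-level artefacts (mapping bias,
bisulfite conversion error, PCR duplicates), spatial autocorrelation of
methylation beyond compartment membership, overdispersion of counts beyond
the binomial, realistic repeat sequence divergence, covariance between
expression noise and library composition, and genome-scale input sizes
(the design targets desk-scale inputs; scaling is an engineering concern).

## Problem sizes used in verification

The verification suite uses deliberately modest sizes chosen so every check
re-runs from scratch in a couple of minutes: the exact-test sweep covers
all 2x2 tables with total ≤ 60; BH is checked on 1,000 random vectors of
length ≤ 500; null calibration and planted-DMS recovery use single-
chromosome two-region methylomes of ~10,000 CpG units; the correlation
screen simulation uses 1,000 genes over 7 regions; cluster and repeat
recovery use the default synthetic study.

## Known limitations

* Fisher per-site testing ignores biological replication and
  overdispersion; with one sample per region (as in the source design) calls
  reflect sampling noise plus any real difference, not population-level
  variability.
* The BH family is per sample pair; no correction is applied across the 21
  pairs of a 7-region scan.
* The correlation screen's raw p ≤ 0.05 over thousands of pairs implies a
  non-trivial false-discovery burden by construction; `add_bh` exists for
  stricter use.
* TMM on FPKM is a fidelity choice, not the textbook count-based usage; the
  weights use the asymptotic 1/x approximation without library sizes.
* Transcript-to-gene collapsing of expression input is the caller's
  responsibility; duplicate gene ids are rejected rather than summed.
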