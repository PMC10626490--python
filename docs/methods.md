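# Methods

## Scope and data model

`waxgrn` infers a gene regulatory network (GRN) from cell-type-resolved
RNA-seq of plant stems and computes the organ-level morphometrics used in
cuticular-wax work. The in-memory containers are pandas objects: an
`ExpressionDataset` (counts + TPM, genes × cell-type/replicate samples, with
a sample sheet), a DE table, symmetric coexpression matrices, a binding-map
table, and a `networkx.DiGraph` wrapped by `RegulatoryNetwork`.

## Differential expression

Genes are kept when mean TPM over a cell type's replicates reaches 5 in at
least one cell type (boundary inclusive). On the retained genes:

* **TMM normalization.** The reference sample is the one whose
  upper-quartile count proportion is closest to the mean upper quartile.
  Per sample, M = log₂ of library-size-normalized proportions vs the
  reference and A = the average log abundance are computed over genes
  nonzero in both; genes outside the central 40% of M (30% trimmed each
  side) or the central 90% of A (5% each side) are discarded, and the factor
  is 2 to the precision-weighted mean of the retained M values
  (delta-method inverse-variance weights). Factors are rescaled to geometric
  mean 1. A consequence worth knowing: multiplying one sample's counts by a
  constant is absorbed by its library size, so its factor moves only through
  the precision weights (by at most a few percent).
* **Test.** Counts are scaled to a common effective library size
  (raw library size × TMM factor). The two groups are the epidermis samples
  and all other cell types pooled. A single common negative-binomial
  dispersion is estimated by the method of moments from within-group
  variability — per gene, pooled (variance − mean) over squared mean, then
  averaged across genes and floored at 0 (Poisson). The p-value is a
  conditional exact test: group sums of n iid NB(μ, φ) samples are
  NB(nμ, φ/n); conditional on the pooled sum S the two-sided p adds the
  probabilities of all splits no more likely than the observed one. Pooled
  sums above 2·10⁵ use a two-tailed marginal NB approximation instead of
  enumeration. FDR is Benjamini–Hochberg over the tested genes.
* **Selection.** Linear fold change (ratio of normalized group means, with a
  configurable pseudocount of 0.5 to guard empty groups) ≥ 5, inclusive, and
  FDR < 0.05, strict. Both thresholds and the direction (up/down/both) are
  configurable.

No tagwise or trended dispersion shrinkage is attempted, and no GLM designs
beyond the two-group contrast; the DE stage is validated by properties
(type-I error and power on planted effects), not by numeric parity with any
particular count-model package.

## Coexpression

Pearson correlation is computed across replicate-level TPM columns by
default; a cell-type-means mode is available (fewer, less noisy samples).
Constant genes are masked with a warning and excluded from ranking
denominators. Significance uses the exact t transform with n−2 degrees of
freedom; BH-FDR is applied to the upper triangle. Mutual Rank ranks each
gene's partners by descending PCC with average ranks for ties and the gene
itself excluded; MR is the geometric mean of the two reciprocal ranks, so
MR = 1 exactly for reciprocal best partners, and MR is invariant under any
strictly increasing transformation of the correlations.

## Promoters and motifs

Coordinates are 0-based, half-open throughout. For a + strand gene with TSS
at t the promoter is [t−1000, t); for a − strand gene, the reverse
complement of [t+1, t+1001). Promoters running off a contig are truncated
and flagged. PFMs (JASPAR format, read and written with Biopython) are
scored as log₂-odds with the pseudocount distributed by background
composition: score[b,k] = log₂(((f[b,k] + pc·bg[b]) / (colsum + pc)) /
bg[b]) — uniform columns against a uniform background score exactly 0. A
window is a hit when its score reaches `min_score_fraction` (default 0.85)
of the attainable range above the minimum; both strands are scanned, windows
containing N are skipped, and both-strand hits at one position keep the
higher score. Enrichment is a one-sided Fisher's exact test on promoter
presence/absence, DE-gene promoters as foreground against all promoters as
background (genome-wide background is the deliberate choice; it is what the
promoter library represents), BH across motifs, enriched at q < 0.05.

## Network assembly

An edge requires: both endpoints DE-selected; PCC ≥ `pcc_min` (0.9;
≤ −pcc_min in the negative mode); correlation-test FDR ≤ `edge_q_max`
(0.05) — the correlation FDR, not the DE FDR, is the default gate, with the
DE FDR already enforced upstream by gene selection; and an enriched motif of
the TF present in the partner's promoter. Boundaries follow the printed
inequalities (PCC inclusive, edge FDR inclusive, DE FDR strict). Direction
is TF → partner; mutual TF–TF binding yields two directed edges. Mutual
Rank is carried as an edge attribute with an optional cutoff that is off by
default, since the final edge rule is stated without an MR threshold.
Exports (edge TSV, node TSV, GraphML, summary JSON) are deterministically
ordered so identical runs are byte-identical.

## Synthetic study generator

The generator emulates the LCM stem study: six cell types (epidermis, pith
parenchyma, phloem, bundle sheath, xylem, vascular parenchyma) × 3
biological replicates. Expected counts are built on the log scale:

* per-gene baseline log-mean ~ N(log 150, 0.7²) — raw counts of tens to a
  few thousand at 30–50 M-read depths scaled to a 2000-gene universe;
* an 8-fold epidermis uplift for the 200-gene planted module (the 5-fold
  selection threshold sits well inside it);
* a per-cell-type signature ~ N(0, 0.8²) for each TF over the non-epidermis
  cell types, centred so the arithmetic-mean epidermis/other fold stays
  exactly 8 — this gives each TF a distinctive profile that its targets
  inherit, so TF–target correlation exceeds the generic module-pattern
  correlation;
* each target's log profile equals its TF's plus N(0, correlation_noise_sd²)
  per-sample noise;
* mild N(0, 0.2²) cell-type variation for background genes;
* per-sample depth factors ~ U(0.7, 1.3), which the TMM stage must undo.

Counts are negative-binomial with constant dispersion `nb_dispersion`
(the count-noise model of LCM RNA-seq is not established; NB is the standard
overdispersed-count assumption and is flagged as such). `nb_dispersion = 0`
is the deterministic limit — counts are the rounded expected means — used
for noise-free round-trip checks; the unrounded expected-mean matrix is
exposed on `PlantedTruth` because integer rounding alone perturbs
correlations at the ~10⁻⁷ level.

**Calibration of the noise defaults.** On the linear TPM scale the
correlation between two genes with proportional means and independent
multiplicative noise of variance v is bounded by 1/(1+v) regardless of
signal strength; v ≈ φ + 1/μ + ε² for NB dispersion φ, mean count μ and
coupling noise ε. For the planted edges to genuinely satisfy the PCC ≥ 0.9
definition of a network edge, the defaults are set to φ = 0.02 and ε = 0.05
(v ≈ 0.03, expected pair PCC ≈ 0.95); these are generator-design constants,
not tuning knobs. Planted truth must be consistent with the thresholds that
define an edge — a coupling whose noise pushes PCC below 0.9 is simply not
an edge under the method's own definition.

Promoters are uniform-random 1 kb sequences on one contig per gene
(alternating strands, so both TSS conventions are exercised). Each TF gets
an informative PWM (88/100 on the consensus base per column, motif length
10) and its consensus is written into each target's promoter at a random
offset and strand. Background promoters are made motif-free by construction:
any window within Hamming distance 1 of a consensus (either strand), other
than the planted placements, is re-randomized until none remain — at the
default scan threshold a single mismatch still scores as a hit, so cleaning
only exact matches would leave ~10⁻³ per-base spurious binding evidence.

What the generator does **not** emulate: compositional coupling beyond the
planted module, gene-length biases, GC effects, dispersion that varies with
expression, correlated replicates, chained or overlapping regulons
(each target has exactly one TF), and degenerate/low-information motifs.
Passing the planted-recovery tests therefore demonstrates correctness of the
machinery under the stated model, not performance on real LCM data.

## Morphometrics

Surface area treats the internode as two intersecting truncated cones whose
largest diameters sit at the internode ends, with the slant approximated by
h/2; with equal diameters this is the cylinder wall π·d·h (the closed-form
sanity check). Wax load is the summed wash mass per cm², invariant to how
the total is partitioned across washes. %TIC divides each wax class's peak
area by the sample's total (background subtraction is upstream of the peak
table, which is the input boundary). Group comparisons use Welch's t-test —
the comparison behind the published asterisks is not named, so the unequal-
variance default is the package's choice — with stars at p < 0.01 and
p < 0.001.

## Numerical conventions and problem sizes

All randomness flows from a single integer seed through
`numpy.random.SeedSequence`; same seed ⇒ bit-identical outputs, including
FASTA bytes and network exports. Ties in ranking take average ranks; exact
boundary comparisons use the stated inequality with a 10⁻¹² floating-point
guard in the scanner. Degenerate inputs (all-zero count columns, constant
genes, empty foregrounds, motifs longer than their sequence) warn or raise
as documented per function rather than producing NaN.

The default verification sizes — 2000 genes, 200-gene module, 10 TFs × 5
targets, 3 replicates, and a 2000-gene null simulation — were chosen so the
whole pipeline and the statistical checks each complete in seconds while
leaving hundreds of genes per category for rate estimates.
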