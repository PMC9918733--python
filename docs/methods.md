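# Methods

This note documents the statistical model behind each stage, the defaults
and why they hold, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Data model

A library is three aligned matrices: cell×variant total depth `DP`,
cell×variant alternate reads `AD` (`AD ≤ DP` elementwise), and
barcode×amplicon read counts, plus the amplicon panel (1-based inclusive
coordinates, MAF convention). Variant identity is the canonical string
`chrom:pos:ref/alt`; no indel normalization is attempted (the panels this
serves are SNV-centric). The HDF5 container is a functional named-matrix
layout, not a clone of any vendor schema; TSV import/export exists for
small text fixtures.

## Cell calling

Three passes, all with strict inequalities:

1. **Qualification**: total reads > `total_read_multiplier` (8) ×
   n_amplicons. At 186 amplicons this is ~1.5k reads — background barcodes
   at a few percent of cell depth fall far below it.
2. **Working amplicons**: per-amplicon mean over qualified barcodes >
   `working_amplicon_factor` (0.2) × the grand mean of those means. The
   two-pass structure (qualify first, then define working amplicons over
   qualified barcodes) resolves the circularity of defining each in terms
   of the other.
3. **Completeness**: fraction of working amplicons with ≥ 1 read >
   `completeness_fraction` (0.80). "Data completeness" is interpreted as
   nonzero coverage of an amplicon, the simplest reading; a depth-quantile
   reading would be stricter and is not implemented.

A consequence worth knowing: a clone with a large homozygous deletion loses
completeness on the deleted amplicons. On a 186-amplicon panel an 8-amplicon
deletion costs ~4 points of completeness and is harmless; on small panels
(tens of amplicons) a deletion spanning ≥ 20% of the panel would make the
clone uncallable.

## Genotyping

Order of operations: depth gate (DP < 5 → MISSING), VAF binning
(WT [0, 20], HET (20, 80], HOM (80, 100], percent scale, boundaries as the
interval notation prints them), then demotion of HET/HOM calls with AD < 3
to WT. The alt-read threshold is read as a minimum required count
(AD ≥ 3 retains). Demotion applies to HOM as well as HET: a HOM call with
AD < 3 has DP ≤ 3 at most, which can only arise below the depth gate in the
default configuration, but the rule is applied uniformly so non-default
parameterizations behave consistently. The 20% WT bin deliberately
tolerates low-level barcode contamination; the cost is reduced sensitivity
to genuinely low-VAF signal (see the doublet section).

The stringent de-novo filter re-genotypes at DP ≥ 10 / AD ≥ 5, discards
variants MISSING in strictly more than 75% of cells unless the gene is
whitelisted (genes prone to homozygous deletion — SMAD4, CDKN2A by default
— would otherwise be eliminated by their own biology), and keeps variants
carried by ≥ 0.5% of all cells (half-open boundary: exactly 0.5%
qualifies). Output is ordered by prevalence, ties broken by canonical
variant string for determinism.

Pseudobulk VAF is read-weighted (ΣAD/ΣDP), not a mean of per-cell VAFs,
matching what a bulk assay of the same material measures.

## Allelic dropout

Per germline SNP: denominator = nuclei with DP ≥ 5; numerator = nuclei with
exactly one allele at zero reads (AD = 0 xor AD = DP). Nuclei with both
alleles absent are unobservable (DP ≈ 0) and enter neither count; the
depth floor ensures a zero-read allele reflects dropout rather than shallow
sampling (at DP = 5 the binomial probability of sampling zero of one allele
at a true HET is 2⁻⁵ ≈ 3%, falling to ~10⁻¹⁵ at depth 50). `mean_ado` is the
unweighted mean over SNPs; per-SNP denominators are reported so a pooled
rate can be formed if preferred.

Under symmetric per-allele Bernoulli dropout with probability q, exactly
one allele drops with probability 2q(1−q) and both with q². Because the
both-dropped nuclei leave the denominator, the estimator converges to
2q(1−q)/(1−q²) = 2q/(1+q), slightly above 2q(1−q): at q = 0.1101 that is
19.8% versus 19.6%. The difference (0.2 points) is well inside the
estimator's practical tolerance and is a property of any denominator
restricted to observed nuclei.

SNP selection: bulk-normal VAF > 0.2 (artifact guard), then mean
single-nucleus VAF strictly in (0.2, 0.8) computed over nuclei with VAF > 0
— excluding zero-VAF nuclei keeps alt-allele dropout from dragging the mean
down, while the upper bound removes homozygous/mosaic sites. Copy-number
loss also produces allelic imbalance; this estimator does not separate
CNV-driven imbalance from technical dropout, so it is an upper bound on
technical ADO when aneuploid cells are included.

## Depth planning

Required read pairs X = nuclei × amplicons × depth / fraction-to-cells,
rounded up. Defaults: target depth 100 reads/cell/amplicon (the observed
elbow for cell recovery on panels of this size), fraction 0.5. Expected
nuclei called is the loading concentration × 1 µl.

## Doublet mixture model

With doublet rate d and population-A fraction p, and doublet constituents
drawn independently from the mixed suspension:

    P(A-only) = (1−d)p + dp²,  P(B-only) = (1−d)(1−p) + d(1−p)²,
    P(AB) = 2dp(1−p).

This is a reconstruction of the standard two-population multiplet model
(the original supplementary derivation is not public); same-population
doublets are genotypically invisible and are folded into the singlet
categories, so d is the *full* doublet rate. The multinomial likelihood has
two free parameters against two free frequencies, so the interior MLE is
closed-form: p̂ = (1 + f_A − f_B)/2, d̂ = f_AB/(2p̂(1−p̂)), clipped to
[0, 1]; an observed AB fraction above 2p̂(1−p̂) saturates at d̂ = 1 with a
warning. The 95% CI is a seeded nonparametric bootstrap (default 1000
multinomial resamples, percentile interval, widened if necessary to contain
the point estimate).

Known bias: a cross-population doublet's expected VAF at each driver is
0.25, only five points above the 20% WT bin, so read-count noise can push
one driver below the bin and reclassify the droplet as a singlet —
downward-biasing d̂. Allelic dropout does the same. Neither is corrected;
with deep, balanced coverage (see below) the residual bias is under 0.1
percentage points at d = 0.04.

## Ploidy

Normalization: (1) divide each cell's row by its mean across amplicons
(removes library size); (2) divide each amplicon's column by its median
over good-quality cells (removes amplicon efficiency). Good-quality cells
are those with ≥ 1/10 of the reads of the 10th-ranked cell by total count;
with fewer than 10 cells the rule keeps everything (warned). Ploidy is
2 × normalized / (per-amplicon median over the diploid baseline group), so
baseline cells read 2 by construction — the factor 2 converts the ratio
(centered at 1) to the conventional copy-number scale. Medians use the
standard midpoint convention; zero or undefined baseline medians mark the
amplicon undefined (NaN) rather than propagating infinities. Homdel is
called at median clone ploidy < 0.5 ("ploidy ≈ 0" with headroom for noise;
single-copy loss at ~1 is well separated).

Because step 1 divides by the within-cell mean, a clone with a large
deletion has its remaining amplicons inflated by n/(n−k); with 8 deleted
amplicons on a 186-amplicon panel this is a 4% upward shift in that
clone's non-deleted ploidy — visible but far from the homdel cutoff.

## Clonal analysis

Clone rules are evaluated in declared order, first match wins; carriage
means an explicit HET/HOM call, wildtype means an explicit WT call, and
MISSING satisfies neither, leaving the cell unassigned. Rules support
all-of (default) and any-of carrier semantics (for clones defined by
"at least one of" several drivers). Fractions are printed at one decimal,
except fractions under 2% which print as whole percent (matching
convention for small clones). Venn region counts exclude cells MISSING at
any queried variant and report them; region + neither + excluded counts
always sum to the cell total. The multi-layer feature matrix concatenates
4-state genotype columns with boolean homdel columns in declared order and
exports as TSV for downstream clustering; the clustering itself is out of
scope.

## Synthetic-data generator

Per real cell: clone drawn by proportion; per-amplicon reads negative
binomial with mean = mean_depth × efficiency × copy_number/2 and shape
`depth_dispersion` (variance m + m²/k; the read-depth law is not specified
by the workflow, and overdispersion is the norm for amplicon counts).
Each variant maps to exactly one covering amplicon and takes that
amplicon's reads as DP — amplicon reads are the physical unit, so no
per-variant resampling. AD is binomial in DP at alt fraction 0/0.5/1 by
genotype. At HET sites each allele drops independently with probability q:
ref-only dropout → alt fraction 1, alt-only → 0, both → DP forced to 0
(the site is unobservable). Dropout is not applied at homozygous sites —
losing one copy of the only allele type present leaves the read fraction
unchanged. Doublets (probability d) are the elementwise sum of two
independently drawn cells' count vectors, with constituent vectors retained
in the truth for conservation checks. Background barcodes carry depth
scaled by `background_depth_scale` (default 0.05) and genotype-free noise.
Everything is deterministic given the seed.

Defaults model a typical solid-tumor nuclei run: mean depth 100
reads/cell/amplicon, dispersion 10, doublet rate 0.04, per-allele dropout
0.1101 (so the measured one-allele loss is ~19.6%), background at 5% of
cell depth.

The **mixing-experiment** generator instead defaults to mean depth 300 and
dispersion 300. The genotype contrast that identifies cross-population
doublets rides on within-droplet allele fractions sitting five points above
the WT bin, so the classification step presumes deep, balanced coverage;
mixing runs are sequenced accordingly (deep targeted runs reach
~170–340 reads/cell/amplicon), and at these settings fewer than 1% of true
AB droplets are misclassified. With the heavier overdispersion of the
general defaults the threshold genotyper would lose a large share of AB
droplets and the inferred rate would be biased low — a genuine limitation
of threshold genotyping near a bin boundary, not of the mixture model.

What the generator does **not** emulate: sequencing error and base
substitution (reads are allele-perfect), ambient DNA beyond background
barcodes, GC/primer-specific efficiency drift (efficiency is a static
per-amplicon factor), doublets sharing one PCR reaction (constituents are
independent draws), and CNV breakpoints within an amplicon. Passing tests
therefore demonstrate correctness of the estimators under the stated
statistical model, not robustness to artifact classes the model omits.

## Problem sizes and statistical tolerances in the test suite

Validation experiments are sized so the checks are well-powered: ADO runs
at 10,000 nuclei × 20 SNPs (the mean-ADO sampling error is ~0.1 points,
against a ±1 point band); doublet recovery uses 4,000 droplets per
replicate and 200 replicates for the bias check (< 0.5 points, observed
~0.1); the diploid-baseline validation splits ~2,100 simulated normal cells
into thirds at depth 100 and dispersion 50, putting the per-amplicon median
sampling error near 0.01 against a ±0.1 band. Stochastic assertions use 3σ
binomial bands with fixed seeds. Rule-level stages (genotyper, cell
calling, filters) are checked exhaustively or against independent
nested-loop oracles rather than statistically.

## Known limitations

* The genotyper is for bulk-validated variants, not novel SNV discovery;
  no error model is fitted.
* ADO and CNV-driven allelic imbalance are confounded by design.
* The doublet model ignores triplets and ADO-induced misclassification.
* Ploidy is relative to the chosen baseline; a wrong baseline rescales
  every call. No segmentation or allele-specific copy number.
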