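# scamp — single-cell targeted amplicon DNA-seq analysis

`scamp` implements the downstream analysis for droplet-based,
high-throughput targeted single-nucleus DNA sequencing (snDNA-seq) of solid
tumors. The input is the standard output of such a pipeline — a cell×variant
total-depth matrix (DP), a cell×variant alternate-read matrix (AD), and a
barcode×amplicon read-count matrix over a targeted panel of a couple of
hundred amplicons — and the package provides:

* **Cell calling** — three-pass barcode QC: qualify barcodes with total
  reads > 8 × n_amplicons, detect *working amplicons*
  (mean reads > 0.2 × panel mean over qualified barcodes), and call cells
  with > 80% data completeness over working amplicons.
* **Genotyping** — per cell-variant pair: MISSING if DP < 5, else bin the
  percent VAF = 100·AD/DP into WT ∈ [0, 20], HET ∈ (20, 80],
  HOM ∈ (80, 100], then demote HET/HOM calls with AD < 3 back to WT.
  A stricter scheme (DP ≥ 10, AD ≥ 5, ≤ 75% missingness with a
  deletion-prone-gene whitelist, carrier prevalence ≥ 0.5%) derives de-novo
  high-quality variant lists; pseudobulk VAF (ΣAD/ΣDP) supports
  concordance checks against bulk sequencing.
* **Allelic dropout (ADO)** — from germline SNPs (bulk-normal VAF > 0.2,
  mean single-nucleus VAF in (0.2, 0.8) ignoring zero-VAF cells), per SNP:
  ADO = #nuclei with strictly 0 reads of exactly one allele / #nuclei
  measured, averaged over SNPs.
* **Doublet rate** — from a two-population mixing experiment, via the
  multinomial mixture P(A) = (1−d)p + dp², P(B) = (1−d)(1−p) + d(1−p)²,
  P(AB) = 2dp(1−p), maximum likelihood with a bootstrap CI.
* **Per-amplicon ploidy** — normalize counts within cell (by mean) then
  within amplicon (by median over good-quality cells), scale ×2 against a
  diploid baseline population; flag homozygous deletions at median
  ploidy < 0.5.
* **Clonal analysis** — rule-based clone assignment (carriers of clonal
  drivers vs all-wildtype "putative normal"), driver colocalization (Venn)
  counts, and the combined SNV-genotype + homdel feature matrix for
  multi-layer multi-state clustering.
* **Synthetic data** — a clone-structured generator with known truth
  (clone proportions, copy-number profiles, per-allele dropout,
  cross-population doublets, background barcodes) used to validate every
  stage end to end.

The package is a library: import it from Python. The `examples/` directory
holds one short narrative script per capability.

## Worked example: doublet rate from a mixing experiment

```python
from scamp import (assign_genotypes, classify_mixing_cells,
                   estimate_doublet_rate, simulate_mixing_experiment)
from scamp.simulate import MIXING_DRIVER_A, MIXING_DRIVER_B

data, truth = simulate_mixing_experiment(p=0.5, d=0.04, n_droplets=4000, seed=11)
g = assign_genotypes(data)
counts = classify_mixing_cells(g, MIXING_DRIVER_A, MIXING_DRIVER_B)
est = estimate_doublet_rate(counts, n_bootstrap=1000, seed=11)
print(counts.n_A, counts.n_B, counts.n_AB, round(est.d_hat, 4), est.ci_95)
```

Running `python examples/doublet_rate.py` prints:

```
category counts:   A-only=2006  B-only=1918  AB=76
true doublet rate: 4.0%
estimated rate:    3.80%  (95% CI 3.00-4.65%)
population A share: 0.511
```

76 of 4000 droplets carry both populations' private drivers; since only
cross-population doublets are visible (2·d·p·(1−p) = half of all doublets at
p = 0.5), the mixture MLE doubles the observed AB fraction to recover the
full rate, here 3.8% against a simulated truth of 4%.

Similarly, `python examples/ado_estimation.py` prints a mean ADO of 19.87%
on 10,000 simulated nuclei with per-allele dropout q = 0.1101
(2q(1−q) = 19.6%), and `python examples/ploidy_and_homdel.py` shows the
diploid-baseline validation (median ploidy 1.94–2.06 for held-out normal
groups) with all eight simulated SMAD4 homdel amplicons flagged.

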