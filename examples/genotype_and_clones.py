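"""Genotype a simulated library and measure the tumor-cell fraction.

Assigns per-cell genotypes with the standard thresholds (depth >= 5, VAF
bins [0,20]/(20,80]/(80,100], alternate reads >= 3), defines the tumor clone
as carriers of the clonal driver, and compares the called fraction and the
pseudobulk VAF with the simulation truth.
"""

from scamp import (
    CloneRule, CloneSpec, Genotype, SimConfig, VariantId,
    assign_clones, assign_genotypes, format_percent, pseudobulk_vaf, simulate_dataset,
)
from scamp.simulate import default_panel

panel = default_panel(60)
row = panel.table.iloc[20]
kras = VariantId(str(row["chrom"]), int(row["start"]) + 50, "C", "A")

clones = [CloneSpec("normal", 0.764), CloneSpec("tumor", 0.236, genotype={kras: Genotype.HET})]
config = SimConfig(panel=panel, variants=[kras], clones=clones,
                   n_cells=2000, doublet_rate=0.0, ado_prob=0.0,
                   n_background_barcodes=0, seed=3)
data, _, truth = simulate_dataset(config)

genotypes = assign_genotypes(data)
rules = [CloneRule("tumor", required_carriers=frozenset({kras})),
         CloneRule("putative_normal", required_wt=frozenset({kras}))]
assignment = assign_clones(genotypes, rules)

true_tumor = sum(lab == "tumor" for lab in truth.clone_labels)
print(f"true tumor cells:       {true_tumor} ({format_percent(true_tumor / len(truth.barcodes))})")
for clone, n in assignment.counts.items():
    print(f"called {clone:16s} {n:5d} ({format_percent(assignment.fractions[clone])})")
vaf = pseudobulk_vaf(data)[kras]
print(f"pseudobulk VAF:         {vaf:.3f}")
# The tumor fraction should match the simulated 23.6% prevalence, and the
# pseudobulk VAF ~ prevalence/2 since the driver is heterozygous.
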