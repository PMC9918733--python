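"""Driver colocalization (Venn) analysis and the multi-layer feature matrix.

Simulates two mutually exclusive SNV clones plus normals, counts the Venn
regions of the two drivers, and assembles the combined genotype + homdel
feature matrix used as input for multi-state clonal clustering.
"""

import pandas as pd

from scamp import (
    CloneSpec, Genotype, PloidyParams, SimConfig, VariantId,
    assign_genotypes, build_multilayer_features, clone_median_ploidy,
    colocalization_counts, compute_ploidy, normalize_counts, simulate_dataset,
)
from scamp.simulate import default_panel

panel = default_panel(40)
r1, r2 = panel.table.iloc[20], panel.table.iloc[25]
fgfr1 = VariantId(str(r1["chrom"]), int(r1["start"]) + 10, "C", "A")
tgfbr2 = VariantId(str(r2["chrom"]), int(r2["start"]) + 10, "G", "A")
smad4_amps = panel.amplicons_of_gene("SMAD4")

clones = [
    CloneSpec("normal", 0.5),
    CloneSpec("cloneF", 0.25, genotype={fgfr1: Genotype.HET}),
    CloneSpec("cloneT", 0.25, genotype={tgfbr2: Genotype.HET},
              copy_number={a: 0.0 for a in smad4_amps}),
]
config = SimConfig(panel=panel, variants=[fgfr1, tgfbr2], clones=clones,
                   n_cells=1500, doublet_rate=0.0, ado_prob=0.0,
                   n_background_barcodes=0, seed=5)
data, amplicon_matrix, truth = simulate_dataset(config)
genotypes = assign_genotypes(data)

venn = colocalization_counts(genotypes, [fgfr1, tgfbr2])
print("Venn regions (mutually exclusive clones => empty intersection):")
print(f"  {fgfr1} only: {venn.regions[frozenset({fgfr1})]}")
print(f"  {tgfbr2} only: {venn.regions[frozenset({tgfbr2})]}")
print(f"  both: {venn.regions[frozenset({fgfr1, tgfbr2})]}")
print(f"  neither: {venn.n_neither}, excluded (MISSING): {venn.n_excluded_missing}")

# per-cell homdel indicators from ploidy, then the combined feature matrix
normals = [b for b, z in zip(truth.barcodes, truth.clone_labels) if z == "normal"]
ploidy = compute_ploidy(normalize_counts(amplicon_matrix), baseline=set(normals))
cell_homdel = ploidy.to_frame() < PloidyParams().homdel_ploidy_max
features = build_multilayer_features(genotypes, [fgfr1, tgfbr2], cell_homdel, smad4_amps)
print(f"feature matrix: {len(features.cells)} cells x {len(features.columns)} columns "
      f"({features.provenance.count('genotype')} genotype + {features.provenance.count('homdel')} homdel)")
print(features.table.iloc[:3, :4].to_string())
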