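"""Plan the sequencing read budget for a targeted single-nucleus run.

Required read pairs = nuclei x amplicons x target depth / fraction of reads
assigned to cells. Defaults: depth 100 reads/cell/amplicon, half the reads
reaching called cells.
"""

from scamp import DepthPlanParams, expected_nuclei_called, required_read_pairs

nuclei = expected_nuclei_called(4000)  # 4000 nuclei/ul loading concentration
params = DepthPlanParams(expected_nuclei=nuclei, n_amplicons=186)
budget = required_read_pairs(params)

print(f"expected nuclei called:   {nuclei}")
print(f"amplicons:                {params.n_amplicons}")
print(f"target depth:             {params.target_depth:.0f} reads/cell/amplicon")
print(f"reads-to-cells fraction:  {params.frac_reads_to_cells}")
print(f"required read pairs:      {budget:,}")
# 4000 x 186 x 100 / 0.5 = 148.8 million read pairs for a full-size run.
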