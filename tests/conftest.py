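import numpy as np
import pandas as pd
import pytest

from scamp import (
    AmpliconMatrix,
    AmpliconPanel,
    CellVariantData,
    CloneSpec,
    Genotype,
    SimConfig,
    VariantId,
    simulate_dataset,
)


@pytest.fixture
def small_panel() -> AmpliconPanel:
    return AmpliconPanel(
        pd.DataFrame(
            [
                {"amplicon_id": "A1", "chrom": "12", "start": 100, "end": 299, "gene": "KRAS"},
                {"amplicon_id": "A2", "chrom": "17", "start": 100, "end": 299, "gene": "TP53"},
                {"amplicon_id": "A3", "chrom": "18", "start": 100, "end": 299, "gene": "SMAD4"},
            ]
        )
    )


@pytest.fixture
def small_variants() -> list[VariantId]:
    return [
        VariantId("12", 150, "G", "T"),
        VariantId("17", 200, "C", "A"),
        VariantId("18", 250, "G", "A"),
    ]


@pytest.fixture
def tiny_data(small_variants) -> CellVariantData:
    rng = np.random.default_rng(11)
    dp = rng.integers(0, 60, size=(8, 3))
    ad = rng.binomial(dp, 0.4)
    return CellVariantData(
        barcodes=[f"c{i}" for i in range(8)],
        variants=small_variants,
        DP=dp,
        AD=ad,
    )


@pytest.fixture(scope="session")
def tumor_sim():
    """A two-clone tumor + normal simulated library with truth, reused across tests."""
    from scamp.simulate import default_panel

    panel = default_panel(60)
    kras = VariantId("12", 25398284, "C", "A")
    tp53 = VariantId("17", 7578190, "G", "A")
    # place variants inside panel amplicons
    kras_amp = panel.table.iloc[20]
    tp53_amp = panel.table.iloc[25]
    kras = VariantId(str(kras_amp["chrom"]), int(kras_amp["start"]) + 50, "C", "A")
    tp53 = VariantId(str(tp53_amp["chrom"]), int(tp53_amp["start"]) + 60, "G", "A")
    smad4_amps = panel.amplicons_of_gene("SMAD4")
    clones = [
        CloneSpec("normal", 0.6, genotype={}),
        CloneSpec(
            "tumor",
            0.4,
            genotype={kras: Genotype.HET, tp53: Genotype.HET},
            copy_number={a: 0.0 for a in smad4_amps},
        ),
    ]
    config = SimConfig(
        panel=panel,
        variants=[kras, tp53],
        clones=clones,
        n_cells=600,
        doublet_rate=0.0,
        ado_prob=0.0,
        mean_depth_per_amplicon=80.0,
        depth_dispersion=20.0,
        n_background_barcodes=300,
        background_depth_scale=0.05,
        seed=42,
    )
    data, amp, truth = simulate_dataset(config)
    return {
        "config": config,
        "data": data,
        "amplicon_matrix": amp,
        "truth": truth,
        "kras": kras,
        "tp53": tp53,
        "panel": panel,
    }
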