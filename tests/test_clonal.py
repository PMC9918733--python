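import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scamp import (
    CloneRule,
    Genotype,
    GenotypeMatrix,
    ValidationError,
    VariantId,
    assign_clones,
    build_multilayer_features,
    colocalization_counts,
    format_percent,
)

KRAS = VariantId("12", 25398284, "C", "A")
TP53 = VariantId("17", 7578190, "G", "A")
SMAD4 = VariantId("18", 48581173, "C", "T")


def _gmatrix(calls, variants):
    calls = np.asarray(calls, dtype=np.int8)
    return GenotypeMatrix([f"c{i}" for i in range(calls.shape[0])], variants, calls)


def _carriers_matrix(n_cells, n_carriers, variant=KRAS):
    calls = np.full((n_cells, 1), int(Genotype.WT), dtype=np.int8)
    calls[:n_carriers, 0] = int(Genotype.HET)
    return _gmatrix(calls, [variant])


class TestAssignClones:
    def test_tumor_fraction_printed_as_one_decimal(self):
        g = _carriers_matrix(479, 113)
        result = assign_clones(g, [CloneRule("tumor", required_carriers=frozenset({KRAS}))])
        assert result.counts["tumor"] == 113
        assert format_percent(result.fractions["tumor"]) == "23.6%"

    def test_small_any_of_clone_printed_as_integer_percent(self):
        calls = np.full((3866, 3), int(Genotype.WT), dtype=np.int8)
        calls[:14, 0] = int(Genotype.HET)
        calls[14:27, 1] = int(Genotype.HET)
        calls[27:40, 2] = int(Genotype.HOM)
        g = _gmatrix(calls, [KRAS, TP53, SMAD4])
        rule = CloneRule(
            "tumor",
            required_carriers=frozenset({KRAS, TP53, SMAD4}),
            any_of_carriers=True,
        )
        result = assign_clones(g, [rule])
        assert result.counts["tumor"] == 40
        assert format_percent(result.fractions["tumor"]) == "1%"

    def test_all_wt_rule_defines_putative_normal(self):
        calls = np.array(
            [
                [Genotype.WT, Genotype.WT],
                [Genotype.HET, Genotype.WT],
                [Genotype.MISSING, Genotype.WT],
            ],
            dtype=np.int8,
        )
        g = _gmatrix(calls, [KRAS, TP53])
        rules = [
            CloneRule("tumor", required_carriers=frozenset({KRAS})),
            CloneRule("putative_normal", required_wt=frozenset({KRAS, TP53})),
        ]
        result = assign_clones(g, rules)
        assert result.assignments["c0"] == "putative_normal"
        assert result.assignments["c1"] == "tumor"
        # MISSING satisfies neither carriage nor wildtype
        assert result.assignments["c2"] == "unassigned"

    def test_first_matching_rule_wins(self):
        g = _carriers_matrix(4, 4)
        rules = [
            CloneRule("first", required_carriers=frozenset({KRAS})),
            CloneRule("second", required_carriers=frozenset({KRAS})),
        ]
        result = assign_clones(g, rules)
        assert all(z == "first" for z in result.assignments.values())

    def test_partition_property(self):
        rng = np.random.default_rng(6)
        calls = rng.integers(0, 4, size=(200, 2)).astype(np.int8)
        g = _gmatrix(calls, [KRAS, TP53])
        rules = [
            CloneRule("tumor", required_carriers=frozenset({KRAS})),
            CloneRule("normal", required_wt=frozenset({KRAS, TP53})),
        ]
        result = assign_clones(g, rules)
        assert sum(result.counts.values()) == g.n_cells
        assert sum(result.fractions.values()) == pytest.approx(1.0)

    def test_no_rules_rejected(self):
        with pytest.raises(ValidationError):
            assign_clones(_carriers_matrix(5, 1), [])


class TestColocalization:
    def test_two_variant_region_counts(self):
        calls = (
            [[Genotype.HET, Genotype.WT]] * 5
            + [[Genotype.WT, Genotype.HET]] * 3
            + [[Genotype.HOM, Genotype.HET]] * 2
        )
        g = _gmatrix(calls, [KRAS, TP53])
        venn = colocalization_counts(g, [KRAS, TP53])
        assert venn.regions[frozenset({KRAS})] == 5
        assert venn.regions[frozenset({TP53})] == 3
        assert venn.regions[frozenset({KRAS, TP53})] == 2
        assert venn.n_neither == 0

    def test_duplicate_variant_rejected(self):
        g = _carriers_matrix(5, 2)
        with pytest.raises(ValidationError, match="duplicate"):
            colocalization_counts(g, [KRAS, KRAS])

    def test_missing_cells_excluded_and_reported(self):
        calls = [
            [Genotype.HET, Genotype.MISSING],
            [Genotype.HET, Genotype.WT],
            [Genotype.WT, Genotype.WT],
        ]
        g = _gmatrix(calls, [KRAS, TP53])
        venn = colocalization_counts(g, [KRAS, TP53])
        assert venn.n_excluded_missing == 1
        assert venn.regions[frozenset({KRAS})] == 1
        assert venn.n_neither == 1

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 3**6 - 1), st.integers(2, 3))
    def test_conservation_law_on_random_matrices(self, state, k):
        rng = np.random.default_rng(state)
        variants = [KRAS, TP53, SMAD4][:k]
        calls = rng.integers(0, 4, size=(40, k)).astype(np.int8)
        g = _gmatrix(calls, variants)
        venn = colocalization_counts(g, variants)
        assert venn.n_cells == 40
        expected_regions = 2**k - 1
        assert len(venn.regions) == expected_regions

    def test_mutually_exclusive_clones_have_empty_intersection(self):
        calls = [[Genotype.HET, Genotype.WT]] * 6 + [[Genotype.WT, Genotype.HOM]] * 4
        g = _gmatrix(calls, [KRAS, TP53])
        venn = colocalization_counts(g, [KRAS, TP53])
        assert venn.regions[frozenset({KRAS, TP53})] == 0


class TestMultiLayerFeatures:
    def _inputs(self, n_cells=10):
        rng = np.random.default_rng(4)
        variants = [VariantId("1", 100 + i, "A", "G") for i in range(25)]
        calls = rng.integers(0, 4, size=(n_cells, 25)).astype(np.int8)
        g = GenotypeMatrix([f"c{i}" for i in range(n_cells)], variants, calls)
        amplicons = [f"AMPL_SMAD4_{k}" for k in range(1, 9)]
        homdel = pd.DataFrame(
            rng.random((n_cells, 8)) < 0.3, index=g.barcodes, columns=amplicons
        )
        return g, variants, homdel, amplicons

    def test_25_snvs_plus_8_amplicons_gives_33_columns(self):
        g, variants, homdel, amplicons = self._inputs()
        feats = build_multilayer_features(g, variants, homdel, amplicons)
        assert len(feats.columns) == 33
        assert feats.provenance.count("genotype") == 25
        assert feats.provenance.count("homdel") == 8

    def test_zero_amplicons_gives_genotype_only_matrix(self):
        g, variants, homdel, _ = self._inputs()
        feats = build_multilayer_features(g, variants, homdel, [])
        assert set(feats.provenance) == {"genotype"}

    def test_mismatched_cells_rejected(self):
        g, variants, homdel, amplicons = self._inputs()
        with pytest.raises(ValidationError, match="different cells"):
            build_multilayer_features(g, variants, homdel.iloc[:5], amplicons)

    def test_feature_matrix_separates_simulated_clones(self):
        """Hierarchical clustering on the combined feature matrix recovers a
        7-clone structure with adjusted Rand >= 0.9 at dropout q = 0.05."""
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import pdist
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(19)
        n_per, n_var = 60, 12
        true_labels = np.repeat(np.arange(7), n_per)
        # each clone carries a distinct subset of variants and homdels
        clone_gt = np.zeros((7, n_var), dtype=np.int8)
        for z in range(1, 7):
            clone_gt[z, 2 * (z - 1) : 2 * z] = int(Genotype.HET)
        clone_hd = np.zeros((7, 8), dtype=bool)
        clone_hd[3:, :4] = True
        clone_hd[5:, 4:] = True
        calls = clone_gt[true_labels]
        dropout = rng.random(calls.shape) < 0.05
        calls = calls.copy()
        calls[dropout & (calls == Genotype.HET)] = int(Genotype.WT)
        variants = [VariantId("1", 100 + i, "A", "G") for i in range(n_var)]
        g = GenotypeMatrix([f"c{i}" for i in range(len(calls))], variants, calls)
        amplicons = [f"AMPL_SMAD4_{k}" for k in range(1, 9)]
        homdel = pd.DataFrame(clone_hd[true_labels], index=g.barcodes, columns=amplicons)
        feats = build_multilayer_features(g, variants, homdel, amplicons)
        onehot = pd.get_dummies(feats.table.astype(str)).to_numpy(float)
        z = linkage(pdist(onehot, metric="hamming"), method="average")
        pred = fcluster(z, t=7, criterion="maxclust")
        assert adjusted_rand_score(true_labels, pred) >= 0.9
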