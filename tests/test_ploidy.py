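import numpy as np
import pytest

from scamp import (
    AmpliconMatrix,
    CloneSpec,
    Genotype,
    PloidyParams,
    SimConfig,
    ValidationError,
    clone_median_ploidy,
    compute_ploidy,
    detect_homdel,
    good_quality_cells,
    normalize_counts,
    simulate_dataset,
)
from scamp.simulate import default_panel


def _matrix(counts):
    counts = np.asarray(counts)
    return AmpliconMatrix(
        barcodes=[f"b{i}" for i in range(counts.shape[0])],
        amplicons=[f"a{k}" for k in range(counts.shape[1])],
        counts=counts,
    )


class TestGoodQualityCells:
    def test_tenth_rank_threshold_boundary(self):
        totals = [1000] * 9 + [1000, 100, 99]
        counts = np.array(totals)[:, None]
        m = _matrix(counts)
        good = good_quality_cells(m)
        # 10th-ranked total is 1000, threshold 100: the 99-read cell is out
        assert "b10" in good and "b11" not in good

    def test_uniform_cells_all_good(self):
        m = _matrix(np.full((15, 3), 7))
        assert good_quality_cells(m) == set(m.barcodes)

    def test_fewer_than_rank_cells_all_kept(self):
        m = _matrix(np.array([[100], [1]]))
        with pytest.warns(UserWarning, match="fewer"):
            good = good_quality_cells(m)
        assert good == {"b0", "b1"}

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_sort_and_threshold_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 200, size=(50, 6))
        m = _matrix(counts)
        p = PloidyParams()
        totals = counts.sum(axis=1)
        tenth = sorted(totals, reverse=True)[p.good_cell_rank - 1]
        expected = {b for b, t in zip(m.barcodes, totals) if t >= p.good_cell_fraction * tenth}
        assert good_quality_cells(m, p) == expected


class TestNormalize:
    def test_constant_matrix_normalizes_to_one(self):
        m = _matrix(np.full((12, 4), 33))
        norm = normalize_counts(m)
        np.testing.assert_allclose(norm.to_numpy(), 1.0)

    def test_scaled_cell_matches_others(self):
        base = np.array([[10, 20, 30]] * 11)
        base[0] = [20, 40, 60]  # doubled counts, same profile
        m = _matrix(base)
        norm = normalize_counts(m)
        np.testing.assert_allclose(norm.iloc[0], norm.iloc[1])

    def test_hand_computed_two_step_fixture(self):
        counts = np.array([[2, 4, 6], [1, 2, 3], [4, 4, 4], [8, 2, 2]])
        m = _matrix(counts)
        # step 1: divide rows by row means (4, 2, 4, 4)
        step1 = counts / counts.mean(axis=1, keepdims=True)
        # step 2: divide columns by medians over all cells (all good here)
        expected = step1 / np.median(step1, axis=0)
        norm = normalize_counts(m, good_cells=set(m.barcodes))
        np.testing.assert_allclose(norm.to_numpy(), expected)

    def test_zero_read_cell_flagged_nan(self):
        counts = np.array([[10, 10], [0, 0], [10, 10], [12, 8]])
        m = _matrix(counts)
        with pytest.warns(UserWarning, match="zero reads"):
            norm = normalize_counts(m, good_cells=set(m.barcodes))
        assert norm.iloc[1].isna().all()
        assert not norm.iloc[0].isna().any()


class TestComputePloidy:
    def test_baseline_reads_as_diploid(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(50, 150, size=(20, 5))
        m = _matrix(counts)
        norm = normalize_counts(m, good_cells=set(m.barcodes))
        baseline = set(m.barcodes[:10])
        pm = compute_ploidy(norm, baseline)
        base_median = pm.to_frame().loc[sorted(baseline)].median(axis=0)
        np.testing.assert_allclose(base_median.to_numpy(), 2.0, atol=1e-9)

    def test_half_signal_cell_reads_ploidy_one(self):
        counts = np.array([[100, 100], [100, 100], [100, 100], [100, 50]])
        m = _matrix(counts)
        norm = normalize_counts(m, good_cells=set(m.barcodes))
        pm = compute_ploidy(norm, {"b0", "b1", "b2"})
        # b3's second amplicon has half the within-cell relative signal of
        # baseline; ploidy ratio reflects the within-cell renormalization
        frame = pm.to_frame()
        assert frame.loc["b3", "a1"] < frame.loc["b3", "a0"]
        np.testing.assert_allclose(frame.loc["b0"], [2.0, 2.0])

    def test_scale_invariance_of_cell_row(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(50, 150, size=(15, 4))
        scaled = counts.copy()
        scaled[3] *= 7
        n1 = normalize_counts(_matrix(counts), good_cells={f"b{i}" for i in range(15) if i != 3})
        n2 = normalize_counts(_matrix(scaled), good_cells={f"b{i}" for i in range(15) if i != 3})
        p1 = compute_ploidy(n1, {"b0", "b1", "b2"})
        p2 = compute_ploidy(n2, {"b0", "b1", "b2"})
        np.testing.assert_allclose(p1.ploidy[3], p2.ploidy[3])

    def test_empty_baseline_rejected(self):
        norm = normalize_counts(_matrix(np.full((12, 3), 10)))
        with pytest.raises(ValidationError):
            compute_ploidy(norm, set())


class TestCloneMedianAndHomdel:
    def test_single_cell_clone_median_is_that_cell(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(80, 120, size=(12, 4))
        m = _matrix(counts)
        norm = normalize_counts(m, good_cells=set(m.barcodes))
        pm = compute_ploidy(norm, set(m.barcodes[:6]))
        med = clone_median_ploidy(pm, {"b11": "solo"})
        np.testing.assert_allclose(med.loc["solo"].to_numpy(), pm.ploidy[11])

    def test_homdel_threshold(self):
        import pandas as pd

        medians = pd.DataFrame({"a0": [0.0, 1.0], "a1": [2.0, 0.4]}, index=["c1", "c2"])
        calls = detect_homdel(medians)
        assert bool(calls.loc["c1", "a0"]) and not bool(calls.loc["c1", "a1"])
        assert not bool(calls.loc["c2", "a0"]) and bool(calls.loc["c2", "a1"])

    def test_norm_abc_split_validation_and_single_copy_loss(self):
        """Normal cells split into thirds read ploidy ~2 against the first
        third; an aneuploid clone with one-copy loss reads ~1 there."""
        panel = default_panel(30)
        loss_amps = panel.amplicon_ids[:5]
        clones = [
            CloneSpec("normal", 0.7),
            CloneSpec("aneuploid", 0.3, copy_number={a: 1.0 for a in loss_amps}),
        ]
        cfg = SimConfig(
            panel=panel,
            variants=[],
            clones=clones,
            n_cells=3000,
            doublet_rate=0.0,
            ado_prob=0.0,
            mean_depth_per_amplicon=100.0,
            depth_dispersion=50.0,
            n_background_barcodes=0,
            seed=13,
        )
        _, amp, truth = simulate_dataset(cfg)
        normals = [b for b, lab in zip(truth.barcodes, truth.clone_labels) if lab == "normal"]
        tumor = [b for b, lab in zip(truth.barcodes, truth.clone_labels) if lab == "aneuploid"]
        third = len(normals) // 3
        norm_a, norm_b, norm_c = normals[:third], normals[third : 2 * third], normals[2 * third :]
        norm = normalize_counts(amp)
        pm = compute_ploidy(norm, set(norm_a))
        assignment = {b: "norm_b" for b in norm_b}
        assignment.update({b: "norm_c" for b in norm_c})
        assignment.update({b: "tumor" for b in tumor})
        med = clone_median_ploidy(pm, assignment)
        assert ((med.loc["norm_b"] > 1.9) & (med.loc["norm_b"] < 2.1)).all()
        assert ((med.loc["norm_c"] > 1.9) & (med.loc["norm_c"] < 2.1)).all()
        lost = med.loc["tumor", loss_amps]
        assert (abs(lost - 1.0) < 0.15).all()

    def test_simulated_homdel_clone_detected_on_exact_amplicons(self, tumor_sim):
        amp = tumor_sim["amplicon_matrix"]
        truth = tumor_sim["truth"]
        smad4 = tumor_sim["panel"].amplicons_of_gene("SMAD4")
        cells = [b for b, bg in zip(truth.barcodes, truth.is_background) if not bg]
        sub = amp.subset_barcodes(cells)
        labels = {
            b: ("tumor" if lab == "tumor" else "normal")
            for b, lab in zip(truth.barcodes, truth.clone_labels)
            if lab is not None
        }
        normals = [b for b in cells if labels[b] == "normal"]
        norm = normalize_counts(sub)
        pm = compute_ploidy(norm, set(normals))
        med = clone_median_ploidy(pm, labels)
        calls = detect_homdel(med)
        assert calls.loc["tumor", smad4].all()
        others = [a for a in amp.amplicons if a not in smad4]
        assert not calls.loc["tumor", others].any()
        assert not calls.loc["normal"].any()
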