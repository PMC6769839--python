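import numpy as np
import pytest
from scipy import stats

from hsimargin.evaluation import roc_auc
from hsimargin.hypercube_io import (
    CalibrationFrames,
    ConfigurationError,
    Hypercube,
    NORMAL,
    SceneMeta,
    SpecimenScene,
    build_band_grid,
)
from hsimargin.patch_cnn import (
    CNNConfig,
    PatchSpec,
    SpectralInceptionNet,
    _softmax_ce_grad,
    assign_folds,
    extract_patches,
    reconstruct_heatmap,
    run_inter_patient_experiment,
    train_fold,
)
from hsimargin.synthetic_scene import SceneSpec, generate_cohort, generate_patient


def make_flat_scene(h, w, n_bands=3, label=NORMAL):
    """Fully-tissue scene with unit reflectance (dark=0, white=1)."""
    grid = build_band_grid(500, 500 + 10 * (n_bands - 1), 10)
    raw = Hypercube(np.ones((h, w, n_bands)), grid)
    frames = CalibrationFrames(np.zeros((h, w, n_bands)), np.ones((h, w, n_bands)))
    gt = np.full((h, w), label, np.uint8)
    return SpecimenScene(raw, frames, gt, SceneMeta("P0", "N"))


class TestPatchExtraction:
    def test_stride_is_size_minus_overlap(self):
        assert PatchSpec(25, 13).stride_px == 12
        with pytest.raises(ConfigurationError):
            PatchSpec(25, 25)

    def test_lattice_enumeration_49px(self):
        # floor((49-25)/12)+1 = 3 offsets per axis: {0, 12, 24}; the flush
        # window coincides with 24 = 49 - 25, so exactly 9 patches
        scene = make_flat_scene(49, 49)
        pset = extract_patches(scene, PatchSpec(25, 13), "inference")
        assert len(pset) == 9
        assert set(map(tuple, pset.coords)) == {
            (r, c) for r in (0, 12, 24) for c in (0, 12, 24)
        }

    def test_exact_fit_gives_single_patch(self):
        pset = extract_patches(make_flat_scene(25, 25), PatchSpec(25, 13))
        assert len(pset) == 1 and tuple(pset.coords[0]) == (0, 0)

    def test_flush_windows_cover_all_tissue(self, tiny_patient):
        scene = tiny_patient["TN"]
        spec = PatchSpec(25, 13)
        pset = extract_patches(scene, spec, "inference")
        heat = reconstruct_heatmap(
            np.ones(len(pset)), pset.coords, scene.gt_mask.shape, spec
        )
        assert np.all(heat.coverage[scene.tissue_mask] >= 1)

    def test_pure_normal_training_patches_all_negative(self):
        pset = extract_patches(make_flat_scene(40, 40), PatchSpec(25, 13), "training")
        assert len(pset) > 0 and np.all(pset.labels == 0)

    def test_image_smaller_than_patch_rejected(self):
        with pytest.raises(ConfigurationError):
            extract_patches(make_flat_scene(20, 30), PatchSpec(25, 13))


class TestFoldAssignment:
    def test_ten_patients_five_equal_folds(self):
        fa = assign_folds([f"P{i}" for i in range(10)], k=5, seed=0)
        sizes = [len(fa.patients_in_fold(f)) for f in range(5)]
        assert sizes == [2] * 5

    def test_deterministic_given_seed(self):
        pts = [f"P{i}" for i in range(9)]
        assert assign_folds(pts, seed=3).fold_of_patient == assign_folds(
            pts, seed=3
        ).fold_of_patient

    def test_folds_partition_patients_over_many_seeds(self):
        pts = [f"P{i}" for i in range(13)]
        for seed in range(30):
            fa = assign_folds(pts, k=5, seed=seed)
            seen = [p for f in range(5) for p in fa.patients_in_fold(f)]
            assert sorted(seen) == sorted(pts)  # each patient in exactly one fold
            sizes = [len(fa.patients_in_fold(f)) for f in range(5)]
            assert max(sizes) - min(sizes) <= 1

    def test_fewer_patients_than_folds_rejected(self):
        with pytest.raises(ConfigurationError):
            assign_folds(["P0", "P1"], k=5)


class TestHeatmapReconstruction:
    def test_single_patch_constant_block(self):
        heat = reconstruct_heatmap([0.7], [(2, 3)], (30, 30), PatchSpec(25, 13))
        assert np.allclose(heat.values[2:27, 3:28], 0.7)
        assert np.isnan(heat.values[0, 0])
        assert heat.coverage[2:27, 3:28].min() == 1

    def test_two_overlapping_patches_average(self):
        spec = PatchSpec(4, 2)
        heat = reconstruct_heatmap([0.2, 0.8], [(0, 0), (0, 2)], (4, 6), spec)
        assert np.allclose(heat.values[:, 2:4], 0.5)  # overlap zone
        assert np.allclose(heat.values[:, 0:2], 0.2)
        assert np.allclose(heat.values[:, 4:6], 0.8)

    def test_matches_brute_force_accumulation_exactly(self):
        rng = np.random.default_rng(7)
        spec = PatchSpec(5, 2)
        h, w = 20, 17
        coords = [
            (rng.integers(0, h - 5 + 1), rng.integers(0, w - 5 + 1)) for _ in range(30)
        ]
        scores = rng.random(30)
        heat = reconstruct_heatmap(scores, coords, (h, w), spec)
        total = np.zeros((h, w))
        count = np.zeros((h, w))
        for s, (r, c) in zip(scores, coords):
            total[r : r + 5, c : c + 5] += s
            count[r : r + 5, c : c + 5] += 1
        covered = count > 0
        assert np.array_equal(heat.coverage, count)
        assert np.array_equal(heat.values[covered], total[covered] / count[covered])

    def test_out_of_image_coordinate_rejected(self):
        with pytest.raises(ConfigurationError):
            reconstruct_heatmap([0.5], [(10, 10)], (20, 20), PatchSpec(25, 13))


class TestNetworkGradients:
    def test_backprop_matches_finite_differences(self):
        config = CNNConfig(stem_width=4, block_widths=(2, 2, 2), n_blocks=1, seed=0)
        net = SpectralInceptionNet(5, config)
        rng = np.random.default_rng(8)
        X = rng.random((3, 8, 8, 5)).astype(np.float32)
        y = np.array([0, 1, 1])

        def loss():
            logits, _ = net.forward(X)
            l, _ = _softmax_ce_grad(logits.astype(np.float64), y)
            return l

        logits, cache = net.forward(X)
        _, dlogits = _softmax_ce_grad(logits.astype(np.float64), y)
        grads, extras = net.backward(cache, dlogits.astype(np.float32),
                                     want_input_grad=True)
        eps = 1e-2
        for name in ("stem_W", "b0_k3_W", "fc_W", "fc_b", "b0_k5_b"):
            flat = net.params[name].ravel()
            for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss()
                flat[idx] = orig - eps
                down = loss()
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                analytic = grads[name].ravel()[idx]
                assert analytic == pytest.approx(numeric, abs=5e-4), name
        # input gradient (used by grad-CAM) via the same finite differences
        for _ in range(3):
            m, i, j, b = (rng.integers(s) for s in X.shape)
            orig = X[m, i, j, b]
            X[m, i, j, b] = orig + eps
            up = loss()
            X[m, i, j, b] = orig - eps
            down = loss()
            X[m, i, j, b] = orig
            numeric = (up - down) / (2 * eps)
            analytic = extras["input_grad"][m, i, j, b]
            assert analytic == pytest.approx(numeric, abs=5e-4)

    def test_forward_accepts_any_band_count(self):
        for c in (3, 23, 91):
            net = SpectralInceptionNet(c, CNNConfig(stem_width=4, block_widths=(2, 2, 2),
                                                    n_blocks=1, seed=1))
            logits, _ = net.forward(np.zeros((2, 25, 25, c), np.float32))
            assert logits.shape == (2, 2)


@pytest.fixture(scope="module")
def tiny_cohort():
    spec = SceneSpec(image_size=(40, 40), grid=build_band_grid(450, 530, 10),
                     class_separation=2.0)
    _, scenes = generate_cohort(6, spec, seed=13)
    return scenes


FAST_CNN = CNNConfig(stem_width=8, block_widths=(4, 4, 4), n_blocks=1,
                     epochs_max=6, patience=3, seed=0)


class TestTraining:
    def test_separable_phantom_reaches_high_validation_auc(self, tiny_cohort):
        from hsimargin.patch_cnn import concatenate_patchsets

        train = concatenate_patchsets(
            [extract_patches(tiny_cohort[(f"P00{i}", st)], PatchSpec(25, 13), "training")
             for i in range(4) for st in ("T", "N")]
        )
        val = concatenate_patchsets(
            [extract_patches(tiny_cohort[(f"P00{i}", st)], PatchSpec(25, 13), "training")
             for i in (4, 5) for st in ("T", "N")]
        )
        model = train_fold(train, val, FAST_CNN)
        assert model.best_val_auc >= 0.95
        # label swap: scores anti-correlate with the original ranking
        import dataclasses

        swapped = dataclasses.replace(train)
        swapped.labels = 1 - train.labels
        val_sw = dataclasses.replace(val)
        val_sw.labels = 1 - val.labels
        model_sw = train_fold(swapped, val_sw, FAST_CNN)
        s = model.net.predict_proba(val.patches)
        s_sw = model_sw.net.predict_proba(val.patches)
        rho = stats.spearmanr(s, s_sw).statistic
        assert rho < 0

    def test_single_class_training_rejected(self, tiny_cohort):
        pset = extract_patches(tiny_cohort[("P000", "N")], PatchSpec(25, 13), "training")
        with pytest.raises(ConfigurationError):
            train_fold(pset, pset, FAST_CNN)


class TestExperimentProtocol:
    @pytest.fixture(scope="class")
    def result(self, tiny_cohort):
        return run_inter_patient_experiment(
            tiny_cohort, "both", FAST_CNN, PatchSpec(25, 13), seed=3
        )

    def test_every_patient_tested_exactly_once(self, result, tiny_cohort):
        pids = {pid for pid, _ in tiny_cohort}
        tested = {pid for pid, _ in result.predictions}
        assert tested == pids
        for key in tiny_cohort:
            assert key in result.predictions  # 'both' predicts all scene types
        # a scene is scored by exactly one fold
        assert set(result.fold_of_scene) == set(result.predictions)

    def test_no_test_patient_in_its_training_set(self, result):
        """Leakage audit via recorded provenance."""
        for key, fold in result.fold_of_scene.items():
            pid = key[0]
            assert pid not in result.train_patients_of_fold[fold]
            assert pid not in result.models[fold].train_patient_ids
            assert pid not in result.models[fold].val_patient_ids

    def test_heatmaps_cover_tissue_with_unit_interval_scores(self, result, tiny_cohort):
        for key, pmap in result.predictions.items():
            tissue = tiny_cohort[key].tissue_mask
            vals = pmap.values[tissue & pmap.valid]
            assert np.all((vals >= 0) & (vals <= 1))

    def test_thresholds_come_from_validation_folds(self, result):
        for fold, thr in result.thresholds.items():
            assert np.isfinite(thr)
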