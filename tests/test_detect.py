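"""Patch CNN training, augmentation and sliding-window detection."""

import numpy as np
import pytest

from angiotrack import detect as dt
from angiotrack import evaluate as ev
from angiotrack import synthgen as sg
from angiotrack.cnn import CnnArchitecture, PatchCNN


TOY_ARCH = CnnArchitecture(input_size=28, conv1_size=3, conv1_filters=6,
                           conv2_size=5, conv2_filters=6, fc1_units=8,
                           dropout=0.25)


def _toy_bank(n=40, size=28, seed=0):
    """Bright vs dark patches: separable by mean intensity."""
    rng = np.random.default_rng(seed)
    bright = rng.normal(0.7, 0.05, (n, size, size)).astype(np.float32)
    dark = rng.normal(0.3, 0.05, (n, size, size)).astype(np.float32)
    return (np.concatenate([bright, dark]),
            np.array([1] * n + [0] * n))


class TestGradients:
    def test_backward_matches_numeric_gradient(self):
        arch = CnnArchitecture(input_size=12, conv1_size=3,
                               conv1_filters=3, conv2_size=3,
                               conv2_filters=4, fc1_units=5, dropout=0.0)
        m = PatchCNN(arch, rng=0)
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (4, 12, 12, 1)).astype(np.float32)
        y = np.array([0, 1, 1, 0])

        def loss():
            probs, _ = m._forward(X, train=False)
            return -np.log(probs[np.arange(4), y] + 1e-12).mean()

        probs, cache = m._forward(X, train=False)
        grads = m._backward(probs, y, cache)
        for name in ("w1", "b1", "w2", "b2", "w3", "b3", "w4", "b4"):
            w = getattr(m, name)
            idx = tuple(0 for _ in w.shape)
            orig = w[idx]
            w[idx] = orig + 1e-3
            lp = loss()
            w[idx] = orig - 1e-3
            lm = loss()
            w[idx] = orig
            num = (lp - lm) / 2e-3
            assert abs(num - grads[name][idx]) < 2e-3 * max(1, abs(num))


class TestAugmentation:
    def test_twelve_variants_per_patch(self, rng):
        patches = rng.random((3, 100, 100)).astype(np.float32)
        bank, labels = dt.augment_templates(patches, [1, 0, 1])
        assert bank.shape == (36, 100, 100)
        assert list(labels) == [1] * 12 + [0] * 12 + [1] * 12

    def test_symmetric_patch_geometric_variants_identical(self):
        # rotation/flip invariant patch: all six geometric variants equal
        x = np.arange(100)
        r = np.hypot(*np.meshgrid(x - 49.5, x - 49.5))
        patch = np.exp(-r / 30).astype(np.float32)
        bank, _ = dt.augment_templates(patch[None], [1], noise_sigma=0.0)
        for v in bank[1:6]:
            assert np.allclose(v, bank[0], atol=1e-6)

    def test_zero_sigma_noise_copies_equal_originals(self, rng):
        patches = rng.random((2, 100, 100)).astype(np.float32)
        bank, _ = dt.augment_templates(patches, [0, 1], noise_sigma=0.0)
        assert np.allclose(bank[6:12], bank[0:6])

    def test_wrong_shape_rejected(self, rng):
        with pytest.raises(ValueError):
            dt.augment_templates(rng.random((2, 50, 60)), [0, 1])


class TestTraining:
    def test_separable_toy_bank_cv_accuracy(self):
        patches, labels = _toy_bank()
        _, cv = dt.train_classifier(patches, labels, arch=TOY_ARCH,
                                    rng_seed=0, epochs=4, lr=0.01)
        assert cv >= 0.99

    def test_label_shuffled_bank_is_chance_level(self):
        patches, labels = _toy_bank()
        accs = []
        for seed in (0, 1, 2):
            shuffled = np.random.default_rng(seed).permutation(labels)
            _, cv = dt.train_classifier(patches, shuffled, arch=TOY_ARCH,
                                        rng_seed=seed, epochs=3, lr=0.01)
            accs.append(cv)
        assert 0.35 <= float(np.mean(accs)) <= 0.65

    def test_single_class_bank_rejected(self):
        patches, _ = _toy_bank(n=6)
        with pytest.raises(ValueError):
            dt.train_classifier(patches, np.ones(12, dtype=int),
                                arch=TOY_ARCH)

    def test_synthetic_template_bank_cv_accuracy(self, bench_config):
        """Five-fold CV on the rendered template bank."""
        patches, labels = sg.make_template_bank(bench_config, n_cell=16,
                                                n_noncell=16)
        bank, bl = dt.augment_templates(patches, labels, rng_seed=1)
        _, cv = dt.train_classifier(bank, bl, rng_seed=1, epochs=2)
        assert cv >= 0.90


class TestSlidingWindow:
    def test_score_map_equals_patch_evaluation(self, trained_detector,
                                               rng):
        img = rng.normal(0.5, 0.1, (160, 220)).astype(np.float32)
        probs, stride, off = trained_detector.score_map(img)
        assert stride == 4 and off == 50
        for i, j in [(0, 0), (3, 7), (10, 20), (14, 29)]:
            patch = img[4 * i:4 * i + 100, 4 * j:4 * j + 100]
            p = trained_detector.predict_proba(patch[None])[0, 1]
            assert abs(p - probs[i, j]) < 1e-5

    def test_blank_image_no_detections(self, trained_detector, rng):
        img = rng.normal(0.5, 0.02, (300, 300))
        det = dt.sliding_window_detect(img, trained_detector)
        assert len(det) == 0

    def test_single_cell_detected_and_out_of_vessel_discarded(
            self, trained_detector, bench_config):
        import dataclasses
        cfg = dataclasses.replace(bench_config, rng_seed=77,
                                  n_initial_cells=1,
                                  division_prob_per_day=0.0,
                                  monolayer_entry_rate=0.0,
                                  outoffocus_prob=0.0)
        ds = sg.simulate_dataset(cfg, render=False)
        scene = sg.render_scene(ds.truth, 0)
        _, pts = ds.truth.positions(0, include_oof=False)
        assert len(pts) == 1
        det = dt.sliding_window_detect(scene, trained_detector,
                                       vessel=ds.truth.vessel, frame=0)
        got = det[["x", "y"]].to_numpy()
        # the one rendered cell yields exactly one detection within 10 px
        d = np.hypot(got[:, 0] - pts[0, 0], got[:, 1] - pts[0, 1])
        assert (d <= 10).sum() == 1
        # a fake vessel far away discards everything
        far = np.zeros_like(ds.truth.vessel.mask)
        far[:40, :40] = True
        from angiotrack.vessel import VesselModel
        fake = VesselModel(mask=far,
                           branches=[np.array([[5.0, 5.0], [30.0, 30.0]])],
                           radii=[np.array([5.0, 5.0])])
        det2 = dt.sliding_window_detect(scene, trained_detector,
                                        vessel=fake, frame=0)
        assert len(det2) == 0

    def test_shift_invariance_by_stride(self, trained_detector,
                                        bench_config):
        import dataclasses
        cfg = dataclasses.replace(bench_config, rng_seed=78)
        ds = sg.simulate_dataset(cfg, render=False)
        scene = sg.render_scene(ds.truth, 0)
        _, pts = ds.truth.positions(0, include_oof=False)
        cx, cy = pts.mean(axis=0)
        r0 = int(np.clip(cy - 200, 0, scene.shape[0] - 400))
        c0 = int(np.clip(cx - 250, 0, scene.shape[1] - 500))
        region = scene[r0:r0 + 400, c0:c0 + 500]
        shifted = np.roll(region, 4, axis=1)
        d1 = dt.sliding_window_detect(region, trained_detector, frame=0)
        d2 = dt.sliding_window_detect(shifted, trained_detector, frame=0)
        a = np.sort(d1[["x", "y"]].to_numpy(), axis=0)
        b = np.sort(d2[["x", "y"]].to_numpy(), axis=0)
        b[:, 0] -= 4
        keep = min(len(a), len(b))
        assert keep > 0
        assert np.abs(a[:keep] - b[:keep]).max() <= 1.0 + 1e-9


class TestDetectorQuality:
    def test_precision_recall_on_synthetic_suite(self, trained_detector,
                                                 bench_config):
        """Aggregate precision and recall >= 0.85 on held-out scenes."""
        import dataclasses
        tp = fp = fn = 0
        for seed in (201, 202):
            cfg = dataclasses.replace(bench_config, rng_seed=seed)
            ds = sg.simulate_dataset(cfg, render=False)
            for k in range(cfg.n_frames):
                scene = sg.render_scene(ds.truth, k)
                det = dt.sliding_window_detect(scene, trained_detector,
                                               vessel=ds.truth.vessel,
                                               frame=k)
                _, pts = ds.truth.positions(k, include_oof=False)
                xy = det[["x", "y"]].to_numpy() if len(det) \
                    else np.empty((0, 2))
                c = ev.confusion_counts(xy, pts, 15.0)
                tp += c.TP
                fp += c.FP
                fn += c.FN
        precision, recall, _ = ev.precision_recall_f1(
            ev.ConfusionCounts(tp, fp, fn))
        assert precision >= 0.85
        assert recall >= 0.85
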