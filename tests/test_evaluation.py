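"""Accuracy metrics against hand-computed values and independent oracles."""

from collections import Counter
from dataclasses import replace

import numpy as np
import pytest

from conftest import FAST_TRAIN, TINY_MODEL, TINY_SCENE, scene_patches
from hybridcs.cube import LabelMap
from hybridcs.evaluate import (ConfusionMatrix, average_accuracy, confusion,
                               kappa, kernel_size_sweep, metrics_report,
                               overall_accuracy, render_map)
from hybridcs.preprocess import SplitSpec


WORKED = ConfusionMatrix(np.array([[3, 1], [1, 5]]))


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        y = np.array([1, 1, 1, 2, 2, 2, 2, 2, 1, 2])
        cm = confusion(y, y, 2)
        assert cm.total == 10
        np.testing.assert_array_equal(cm.counts, np.diag([4, 6]))

    def test_constant_prediction_fills_one_column(self, rng):
        t = rng.integers(1, 4, size=30)
        cm = confusion(t, np.ones(30, dtype=int), 3)
        assert cm.counts[:, 1:].sum() == 0
        assert cm.counts[:, 0].sum() == 30

    def test_matches_dictionary_tally_oracle(self, rng):
        t = rng.integers(1, 6, size=500)
        p = rng.integers(1, 6, size=500)
        cm = confusion(t, p, 5)
        tally = Counter(zip(t.tolist(), p.tolist()))
        for (i, j), n in tally.items():
            assert cm.counts[i - 1, j - 1] == n
        assert cm.total == 500

    def test_errors(self):
        with pytest.raises(ValueError, match="length"):
            confusion(np.array([1, 2]), np.array([1]), 2)
        with pytest.raises(ValueError, match="outside"):
            confusion(np.array([1, 3]), np.array([1, 1]), 2)


class TestMetrics:
    def test_worked_matrix_overall_accuracy(self):
        assert overall_accuracy(WORKED) == pytest.approx(0.8)

    def test_worked_matrix_average_accuracy(self):
        assert average_accuracy(WORKED) == pytest.approx(0.7917, abs=5e-5)

    def test_worked_matrix_kappa(self):
        # (10*8 - (4*4 + 6*6)) / (100 - 52) = 28/48
        assert kappa(WORKED) == pytest.approx(28 / 48)

    def test_diagonal_matrix_scores_perfectly(self):
        cm = ConfusionMatrix(np.diag([7, 2, 11]))
        assert overall_accuracy(cm) == 1.0
        assert average_accuracy(cm) == 1.0
        assert kappa(cm) == pytest.approx(1.0)

    def test_zero_diagonal_gives_zero_oa(self):
        cm = ConfusionMatrix(np.array([[0, 4], [6, 0]]))
        assert overall_accuracy(cm) == 0.0

    def test_half_right_average_accuracy(self):
        cm = ConfusionMatrix(np.array([[5, 0], [3, 0]]))
        assert average_accuracy(cm) == pytest.approx(0.5)

    def test_kappa_equals_standard_form_and_sklearn(self, rng):
        """Marginal-product kappa == (p_o - p_e)/(1 - p_e) == sklearn."""
        from sklearn.metrics import cohen_kappa_score

        for _ in range(100):
            k = int(rng.integers(2, 6))
            cm = ConfusionMatrix(rng.integers(0, 30, size=(k, k)))
            if cm.total == 0:
                continue
            p = cm.counts / cm.total
            po = np.trace(p)
            pe = p.sum(axis=1) @ p.sum(axis=0)
            if abs(1 - pe) < 1e-12:
                continue
            assert kappa(cm) == pytest.approx((po - pe) / (1 - pe), abs=1e-12)
        t = rng.integers(1, 5, size=300)
        p = rng.integers(1, 5, size=300)
        assert kappa(confusion(t, p, 4)) == pytest.approx(
            cohen_kappa_score(t, p), abs=1e-12)

    def test_independent_predictions_give_near_zero_kappa(self, rng):
        n = 100_000
        t = rng.choice([1, 2, 3], size=n, p=[0.6, 0.3, 0.1])
        p = rng.choice([1, 2, 3], size=n, p=[0.2, 0.5, 0.3])
        assert abs(kappa(confusion(t, p, 3))) < 0.02

    def test_permutation_equivariance(self, rng):
        t = rng.integers(1, 5, size=400)
        p = rng.integers(1, 5, size=400)
        cm = confusion(t, p, 4)
        perm = np.array([3, 1, 4, 2])
        cm_p = confusion(perm[t - 1], perm[p - 1], 4)
        assert overall_accuracy(cm) == pytest.approx(overall_accuracy(cm_p))
        assert average_accuracy(cm) == pytest.approx(average_accuracy(cm_p))
        assert kappa(cm) == pytest.approx(kappa(cm_p))

    def test_bounds_hold_on_random_matrices(self, rng):
        for _ in range(50):
            cm = ConfusionMatrix(rng.integers(0, 20, size=(3, 3)) + np.eye(3, dtype=int))
            assert 0.0 <= overall_accuracy(cm) <= 1.0
            assert 0.0 <= average_accuracy(cm) <= 1.0
            assert kappa(cm) <= 1.0

    def test_absent_class_excluded_with_warning(self):
        cm = ConfusionMatrix(np.array([[4, 0, 0], [1, 3, 0], [0, 0, 0]]))
        with pytest.warns(UserWarning, match="excluded"):
            aa = average_accuracy(cm)
        assert aa == pytest.approx((1.0 + 0.75) / 2)

    def test_degenerate_inputs_raise(self):
        empty = ConfusionMatrix(np.zeros((2, 2), dtype=int))
        with pytest.raises(ValueError):
            overall_accuracy(empty)
        with pytest.raises(ValueError):
            average_accuracy(empty)
        with pytest.raises(ValueError):
            kappa(empty)
        # all mass in one true/predicted pair: denominator M^2 - sum = 0
        with pytest.raises(ValueError, match="degenerate"):
            kappa(ConfusionMatrix(np.array([[5, 0], [0, 0]])))

    def test_report_percent_formatting(self):
        rep = metrics_report(WORKED)
        d = rep.to_dict()
        assert d["oa_percent"] == 80.0
        assert d["aa_percent"] == 79.17
        assert d["kappa_percent"] == 58.33
        assert "class_1" in d["per_class"]


class TestKernelSweep:
    def test_one_row_per_size_and_spatial_context_helps(self):
        """Patch size 1 (no spatial context) should not beat size 7."""
        from hybridcs.cube import HSICube
        from hybridcs.scene import make_scene

        aa1, aa7 = [], []
        for seed in range(3):
            cfg = replace(TINY_SCENE, seed=300 + seed)
            cube, labels, _ = make_scene(cfg)
            table = kernel_size_sweep(
                cube, labels, [1, 7], replace(TINY_MODEL, seed=seed),
                replace(FAST_TRAIN, epochs=4, seed=seed),
                SplitSpec(0.3, seed=seed), pca_components=8)
            assert list(table["size"]) == [1, 7]
            aa1.append(table["aa"].iloc[0])
            aa7.append(table["aa"].iloc[1])
        assert np.mean(aa1) <= np.mean(aa7) + 0.02

    def test_even_or_oversized_patch_rejected(self, small_scene):
        cube, labels, _ = small_scene
        with pytest.raises(ValueError, match="odd"):
            kernel_size_sweep(cube, labels, [4], TINY_MODEL, FAST_TRAIN,
                              SplitSpec(0.3, seed=0), pca_components=8)


class TestRenderMap:
    @pytest.fixture
    def label_map(self, rng):
        return LabelMap(rng.integers(0, 4, size=(20, 25)).astype(np.int64),
                        class_names=["birch", "larch", "spruce"])

    def test_png_round_trip_preserves_indices(self, tmp_path, label_map):
        from PIL import Image

        path = tmp_path / "map.png"
        render_map(label_map, path)
        back = np.asarray(Image.open(path))
        np.testing.assert_array_equal(back, label_map.labels)

    def test_background_uses_designated_color(self, tmp_path, label_map):
        from PIL import Image

        path = tmp_path / "map.png"
        render_map(label_map, path)
        img = Image.open(path).convert("RGB")
        rgb = np.asarray(img)
        assert np.all(rgb[label_map.labels == 0] == (0, 0, 0))

    def test_two_renders_byte_identical(self, tmp_path, label_map):
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        render_map(label_map, p1)
        render_map(label_map, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_short_palette_rejected(self, tmp_path, label_map):
        with pytest.raises(ValueError, match="palette"):
            render_map(label_map, tmp_path / "x.png",
                       palette=((0, 0, 0), (1, 1, 1)))

    def test_legend_sidecar_written(self, tmp_path, label_map):
        import json

        path = tmp_path / "map.png"
        render_map(label_map, path)
        legend = json.loads((tmp_path / "map.png.legend.json").read_text())
        assert legend["0"]["name"] == "background"
        assert legend["1"]["name"] == "birch"
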