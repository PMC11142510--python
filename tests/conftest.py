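"""Shared fixtures: small synthetic scenes and a reusable trained model."""

from dataclasses import replace

import numpy as np
import pytest

from hybridcs import (HybridCSModel, ModelConfig, SceneConfig, SplitSpec,
                      TrainConfig, extract_patches, make_scene, pca_apply,
                      pca_fit, standardize, stratified_split, train)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# desk-scale configs for tests that must train: a 48 x 48 scene keeps the
# forest-survey class imbalance while training in seconds
SMALL_SCENE = SceneConfig(n_rows=48, n_cols=48, seed=101)
TINY_SCENE = SceneConfig(n_rows=32, n_cols=32, region_scale=8.0, seed=202)

# small batches: tiny scenes have few training patches, and convergence
# needs enough SGD updates per epoch
FAST_TRAIN = TrainConfig(learning_rate=0.02, batch_size=32, epochs=6,
                         val_subsample=500, seed=0)

TINY_MODEL = ModelConfig(input_bands=8, n_classes=6, seed=0)


def scene_patches(scene_cfg: SceneConfig, n_components: int = 8,
                  patch_size: int = 7):
    """Scene -> PCA -> labeled patches (the shared pipeline front half)."""
    cube, labels, lib = make_scene(scene_cfg)
    reduced = pca_apply(cube, pca_fit(cube, n_components))
    return extract_patches(reduced, labels, patch_size), labels


def quick_fit(scene_cfg: SceneConfig, *, train_fraction=0.3, epochs=6,
              seed=0, use_sandglass=True, n_components=8, patch_size=7):
    """Train a small model on a scene; returns (model, test patches)."""
    ps, labels = scene_patches(scene_cfg, n_components, patch_size)
    tr, te = stratified_split(ps, SplitSpec(train_fraction, seed=seed))
    tr_s, te_s, sc = standardize(tr, te)
    cfg = replace(TINY_MODEL, input_bands=n_components,
                  patch_size=patch_size, use_sandglass=use_sandglass,
                  seed=seed)
    model = HybridCSModel(cfg)
    state = train(model, tr_s, te_s,
                  replace(FAST_TRAIN, epochs=epochs, seed=seed))
    return model, te_s, state


@pytest.fixture(scope="session")
def small_scene():
    """48 x 48 x 40 six-class scene with the default survey imbalance."""
    cube, labels, lib = make_scene(SMALL_SCENE)
    return cube, labels, lib
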