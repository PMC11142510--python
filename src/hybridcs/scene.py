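"""Synthetic labeled hyperspectral scenes for training and evaluation.

Real boreal-forest hyperspectral scenes with per-pixel species labels are
rarely redistributable, so this module generates scenes that carry the
statistical structure the classifier relies on:

* smooth, non-negative per-class reflectance endmembers with a configurable
  minimum inter-class separation;
* spatially contiguous class regions (species grow in stands, and the
  spatial branch of the network exploits exactly that neighborhood
  structure), built by seeded Voronoi growth;
* severe class imbalance mirroring a real forest survey — the default
  proportions follow the Tahe survey counts (birch dominating at ~52%,
  poplar and willow near 1%);
* per-pixel brightness jitter (within-class variability) and additive
  white sensor noise.

Everything is deterministic given ``SceneConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.spatial import cKDTree

from .cube import HSICube, LabelMap

__all__ = ["SceneConfig", "EndmemberLibrary", "make_endmembers",
           "make_label_map", "render_cube", "make_scene",
           "nearest_endmember_predict", "TAHE_PROPORTIONS", "TAHE_SPECIES"]

# Forest-survey sample counts for the six dominant species (pixels):
# birch 130124, larch 39216, mongolica 57620, poplar 3019, spruce 15330,
# willow 3492 — total 248801.  Normalized, these are the default class
# proportions; the ~43:1 ratio between the largest and smallest class is
# what makes average accuracy a much harsher metric than overall accuracy.
_TAHE_COUNTS = np.array([130124, 39216, 57620, 3019, 15330, 3492], dtype=float)
TAHE_PROPORTIONS = tuple(float(x) for x in _TAHE_COUNTS / _TAHE_COUNTS.sum())
TAHE_SPECIES = ("Birch", "Larch", "Mongolica", "Poplar", "Spruce", "Willow")


@dataclass
class SceneConfig:
    """Full recipe for one synthetic scene."""

    n_rows: int = 96
    n_cols: int = 96
    n_bands: int = 40
    n_classes: int = 6
    class_proportions: tuple[float, ...] = TAHE_PROPORTIONS
    class_names: tuple[str, ...] = TAHE_SPECIES
    region_scale: float = 12.0       # expected blob diameter, pixels
    spectral_separation: float = 0.5  # min inter-endmember L2 distance
    noise_sd: float = 0.2            # additive white noise, per band
    within_class_sd: float = 0.02    # per-pixel brightness jitter
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.class_proportions, dtype=float)
        if p.shape != (self.n_classes,):
            raise ValueError("class_proportions length must equal n_classes")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("class proportions must be non-negative and sum to 1")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.noise_sd < 0 or self.within_class_sd < 0:
            raise ValueError("noise levels must be non-negative")
        if len(self.class_names) != self.n_classes:
            self.class_names = tuple(f"class_{i + 1}"
                                     for i in range(self.n_classes))


@dataclass
class EndmemberLibrary:
    """Per-class pure reflectance spectra, [K x Q], values in [0, 1.5]."""

    spectra: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.min() < 0 or self.spectra.max() > 1.5:
            raise ValueError("endmember reflectance must lie in [0, 1.5]")
        if not self.class_names:
            self.class_names = [f"class_{i + 1}"
                                for i in range(self.spectra.shape[0])]

    def pairwise_distances(self) -> np.ndarray:
        d = self.spectra[:, None, :] - self.spectra[None, :, :]
        return np.sqrt((d ** 2).sum(axis=2))


def _draw_spectrum(rng: np.random.Generator, q: int) -> np.ndarray:
    """Baseline + 3..6 Gaussian bumps, lightly smoothed, clipped to [0, 1.5]."""
    grid = np.arange(q, dtype=float)
    baseline = rng.uniform(0.1, 0.6) + rng.uniform(-0.15, 0.15) * grid / max(q - 1, 1)
    s = baseline.copy()
    for _ in range(rng.integers(3, 7)):
        center = rng.uniform(0, q - 1)
        width = rng.uniform(2.5, 8.0)
        amp = rng.uniform(-0.25, 0.35)
        s += amp * np.exp(-0.5 * ((grid - center) / width) ** 2)
    s = gaussian_filter1d(s, sigma=1.0, mode="nearest")
    return np.clip(s, 0.0, 1.5)


def make_endmembers(config: SceneConfig, max_retries: int = 100) -> EndmemberLibrary:
    """Draw K smooth spectra with pairwise L2 distance >= the configured
    separation; redraws the whole library until the constraint holds."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xE17D]))
    k, q = config.n_classes, config.n_bands
    for _ in range(max_retries):
        spectra = np.stack([_draw_spectrum(rng, q) for _ in range(k)])
        if np.any(np.abs(np.diff(spectra, axis=1)) > 0.2):
            continue
        lib = EndmemberLibrary(spectra, list(config.class_names))
        d = lib.pairwise_distances()
        if k == 1 or d[np.triu_indices(k, 1)].min() >= config.spectral_separation:
            return lib
    raise ValueError(
        f"could not draw {k} endmembers with separation "
        f">= {config.spectral_separation} over {q} bands in {max_retries} "
        "tries; lower the separation or increase the band count")


def _largest_remainder(proportions: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``proportions``,
    guaranteeing at least one unit per class."""
    k = proportions.size
    if total < k:
        raise ValueError(f"{total} seeds cannot cover {k} classes; "
                         "decrease region_scale or the class count")
    raw = proportions * (total - k)
    counts = np.floor(raw).astype(int) + 1
    remainder = raw - np.floor(raw)
    short = total - counts.sum()
    for idx in np.argsort(-remainder)[:short]:
        counts[idx] += 1
    return counts


def make_label_map(config: SceneConfig, max_retries: int = 20) -> LabelMap:
    """Seeded Voronoi growth: one seed per jittered grid cell, classes
    allocated to seeds in proportion to the configured class shares, every
    pixel labeled by its nearest seed."""
    if config.region_scale < 2:
        raise ValueError("region_scale must be >= 2")
    m, n = config.n_rows, config.n_cols
    n_seeds = int(np.ceil(m * n / config.region_scale ** 2))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    grid_rows = max(1, int(round(np.sqrt(n_seeds * m / n))))
    grid_cols = int(np.ceil(n_seeds / grid_rows))
    props = np.asarray(config.class_proportions)
    pix_r, pix_c = np.meshgrid(np.arange(m), np.arange(n), indexing="ij")
    pixels = np.stack([pix_r.ravel(), pix_c.ravel()], axis=1).astype(float)
    # jitter seeds inside the central part of their grid cell: keeps the
    # Voronoi cells irregular but near-equal in area, so realized class
    # frequencies track the seed allocation closely
    for _ in range(max_retries):
        cells = rng.permutation(grid_rows * grid_cols)[:n_seeds]
        ci, cj = cells // grid_cols, cells % grid_cols
        seeds = np.stack([
            (ci + rng.uniform(0.2, 0.8, n_seeds)) * (m / grid_rows),
            (cj + rng.uniform(0.2, 0.8, n_seeds)) * (n / grid_cols),
        ], axis=1)
        seed_classes = np.repeat(np.arange(1, config.n_classes + 1),
                                 _largest_remainder(props, n_seeds))
        rng.shuffle(seed_classes)
        _, nearest = cKDTree(seeds).query(pixels)
        labels = seed_classes[nearest].reshape(m, n)
        if np.unique(labels).size != config.n_classes:
            continue
        if m * n >= 64 * 64:
            realized = np.bincount(labels.ravel(),
                                   minlength=config.n_classes + 1)[1:] / (m * n)
            if np.abs(realized - props).max() > 0.05:
                continue
        lm = LabelMap(labels.astype(np.int64),
                      class_names=list(config.class_names))
        lm.voronoi_seeds = seeds            # exposed for tests
        lm.voronoi_seed_classes = seed_classes
        return lm
    raise ValueError("could not realize the configured class proportions; "
                     "increase the scene size or adjust region_scale")


def render_cube(labels: LabelMap, lib: EndmemberLibrary,
                config: SceneConfig) -> HSICube:
    """Pixel spectrum = class endmember + brightness jitter + white noise."""
    m, n = labels.shape
    k, q = lib.spectra.shape
    if (m, n) != (config.n_rows, config.n_cols) or q != config.n_bands:
        raise ValueError("labels/library shapes do not match the scene config")
    if int(labels.labels.max()) > k:
        raise ValueError("label map references a class missing from the library")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0BE]))
    # index 0 (background) maps to a zero spectrum
    palette = np.vstack([np.zeros(q), lib.spectra])
    data = palette[labels.labels]
    if config.within_class_sd > 0:
        data = data + rng.normal(0.0, config.within_class_sd, (m, n, 1))
    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd, (m, n, q))
    return HSICube(data.astype(np.float32))


def make_scene(config: SceneConfig) -> tuple[HSICube, LabelMap, EndmemberLibrary]:
    """Endmembers + label map + rendered cube in one call."""
    lib = make_endmembers(config)
    labels = make_label_map(config)
    cube = render_cube(labels, lib, config)
    return cube, labels, lib


def nearest_endmember_predict(cube: HSICube, lib: EndmemberLibrary) -> np.ndarray:
    """Per-pixel nearest-endmember (minimum L2) classification, 1..K.

    A deliberately simple spectra-only baseline: on a noiseless scene it is
    exact, and tests use it as an independent reference for separability.
    """
    m, n, q = cube.shape
    flat = cube.data.reshape(-1, q)
    d2 = ((flat[:, None, :] - lib.spectra[None, :, :]) ** 2).sum(axis=2)
    return (d2.argmin(axis=1) + 1).reshape(m, n)
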