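"""PCA band reduction, patch extraction and stratified splitting.

The classifier never sees the full raster: training operates on C x C x P
patches cut around labeled pixels, where C is an odd window size (so the
center pixel — whose class labels the patch — is unique) and P is the
number of principal components kept after reducing the Q sensor bands.
A full-grid extraction over an M x N scene yields exactly
``(M - C + 1) * (N - C + 1)`` patches; pixels whose window would leave the
image are skipped rather than padded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
from sklearn.decomposition import PCA as _SkPCA

from .cube import HSICube, LabelMap

__all__ = ["PCAModel", "pca_fit", "pca_apply", "PatchSet", "extract_patches",
           "SplitSpec", "stratified_split", "Standardizer", "standardize"]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Fitted spectral PCA: ``components`` has orthonormal columns [Q x P]."""

    components: np.ndarray          # (Q, P)
    means: np.ndarray               # (Q,)
    explained_variance: np.ndarray  # (P,), non-increasing

    def __post_init__(self) -> None:
        q, p = self.components.shape
        if p > q:
            raise ValueError("more components than bands")
        gram = self.components.T @ self.components
        if not np.allclose(gram, np.eye(p), atol=1e-6):
            raise ValueError("component columns are not orthonormal")
        if np.any(np.diff(self.explained_variance) > 1e-9):
            raise ValueError("explained variance must be non-increasing")

    @property
    def n_bands(self) -> int:
        return self.components.shape[0]

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(components), axis=0)
    signs = np.sign(components[idx, np.arange(components.shape[1])])
    signs[signs == 0] = 1.0
    return components * signs


def pca_fit(cube: HSICube, n_components: int) -> PCAModel:
    """Fit spectral PCA on all pixels of ``cube``.

    Components are the leading eigenvectors of the across-pixel band
    covariance; the sign of each is fixed so that its largest-magnitude
    entry is positive, making the fit deterministic.
    """
    q = cube.n_bands
    if n_components > q:
        raise ValueError(f"n_components={n_components} exceeds band count {q}")
    pixels = cube.data.reshape(-1, q).astype(np.float64)
    if pixels.shape[0] < n_components:
        raise ValueError("fewer pixels than requested components")
    sk = _SkPCA(n_components=n_components, svd_solver="full")
    sk.fit(pixels)
    comps = _fix_signs(sk.components_.T.copy())
    return PCAModel(components=comps, means=sk.mean_.copy(),
                    explained_variance=sk.explained_variance_.copy())


def pca_apply(cube: HSICube, model: PCAModel) -> HSICube:
    """Project a cube onto the fitted components; spatial dims unchanged."""
    if cube.n_bands != model.n_bands:
        raise ValueError(f"cube has {cube.n_bands} bands but the PCA model "
                         f"was fitted on {model.n_bands}")
    m, n, q = cube.shape
    flat = cube.data.reshape(-1, q) - model.means
    reduced = flat @ model.components
    return HSICube(reduced.reshape(m, n, model.n_components),
                   geotransform=cube.geotransform)


# ---------------------------------------------------------------------------
# Patches
# ---------------------------------------------------------------------------

@dataclass
class PatchSet:
    """Labeled C x C x P patches; each label is the center pixel's class."""

    patches: np.ndarray            # (n, C, C, P)
    labels: np.ndarray             # (n,) ints; 0 only if unlabeled kept
    centers: np.ndarray            # (n, 2) 0-based (row, col)
    patch_size: int

    def __post_init__(self) -> None:
        if self.patch_size % 2 == 0:
            raise ValueError("patch size must be odd")
        self.labels = np.asarray(self.labels)
        self.centers = np.asarray(self.centers)
        n = self.patches.shape[0]
        if self.labels.shape != (n,) or self.centers.shape != (n, 2):
            raise ValueError("patches/labels/centers lengths disagree")

    def __len__(self) -> int:
        return self.patches.shape[0]

    @property
    def n_bands(self) -> int:
        return self.patches.shape[3]

    def subset(self, index: np.ndarray) -> "PatchSet":
        return PatchSet(self.patches[index], self.labels[index],
                        self.centers[index], self.patch_size)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("patches", data=self.patches, track_times=False)
            f.create_dataset("labels", data=self.labels, track_times=False)
            f.create_dataset("centers", data=self.centers, track_times=False)
            f.attrs["patch_size"] = self.patch_size

    @classmethod
    def load(cls, path) -> "PatchSet":
        with h5py.File(path, "r") as f:
            return cls(f["patches"][()], f["labels"][()], f["centers"][()],
                       int(f.attrs["patch_size"]))


def extract_patches(cube: HSICube, labels: LabelMap, patch_size: int,
                    keep_unlabeled: bool = False) -> PatchSet:
    """Cut one C x C x P patch around every eligible pixel.

    Eligible pixels are those whose full window fits inside the image and
    (unless ``keep_unlabeled``) whose label is nonzero.  Over a fully
    labeled scene with ``keep_unlabeled=True`` the count is exactly
    ``(M - C + 1) * (N - C + 1)``.
    """
    c = patch_size
    if c % 2 == 0:
        raise ValueError("patch size must be odd")
    m, n, _ = cube.shape
    if labels.shape != (m, n):
        raise ValueError(f"label map shape {labels.shape} does not match "
                         f"cube spatial shape {(m, n)}")
    if c > min(m, n):
        raise ValueError(f"patch size {c} exceeds scene extent {(m, n)}")
    r = (c - 1) // 2
    rows, cols = np.meshgrid(np.arange(r, m - r), np.arange(r, n - r),
                             indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    if not keep_unlabeled:
        lab = labels.labels[rows, cols]
        keep = lab > 0
        rows, cols = rows[keep], cols[keep]
    if rows.size == 0:
        raise ValueError("no eligible patch centers (is anything labeled "
                         "inside the valid window region?)")
    # gather all windows at once via a strided view
    from numpy.lib.stride_tricks import sliding_window_view
    windows = sliding_window_view(cube.data, (c, c), axis=(0, 1))
    patches = windows[rows - r, cols - r]          # (n, P, C, C)
    patches = np.ascontiguousarray(patches.transpose(0, 2, 3, 1))
    return PatchSet(patches=patches,
                    labels=labels.labels[rows, cols].astype(np.int64),
                    centers=np.stack([rows, cols], axis=1),
                    patch_size=c)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    train_fraction: float = 0.3
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train fraction must be in (0, 1)")


def stratified_split(patchset: PatchSet, spec: SplitSpec) -> tuple[PatchSet, PatchSet]:
    """Per-class random split: round(fraction * count) train, at least 1."""
    labels = patchset.labels
    if np.any(labels < 1):
        raise ValueError("split requires labeled patches only")
    rng = np.random.default_rng(spec.seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls} has {idx.size} patch(es); "
                             "need at least 2 to split")
        perm = rng.permutation(idx)
        if spec.stratified:
            n_train = int(np.floor(spec.train_fraction * idx.size + 0.5))
            n_train = min(max(n_train, 1), idx.size - 1)
        else:
            n_train = max(1, int(np.floor(spec.train_fraction * idx.size)))
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))
    return patchset.subset(tr), patchset.subset(te)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass
class Standardizer:
    """Zero-mean / unit-variance transform fitted on training patches only."""

    per_band: bool = True
    means: np.ndarray | None = field(default=None, repr=False)
    stds: np.ndarray | None = field(default=None, repr=False)

    def fit(self, train: PatchSet) -> "Standardizer":
        axis = (0, 1, 2) if self.per_band else None
        x = train.patches
        self.means = np.asarray(x.mean(axis=axis, dtype=np.float64))
        var = np.asarray(x.var(axis=axis, dtype=np.float64))
        if np.any(var < 1e-8):
            warnings.warn("zero-variance band(s) clamped during standardization")
            var = np.maximum(var, 1e-8)
        self.stds = np.sqrt(var)
        return self

    def transform(self, ps: PatchSet) -> PatchSet:
        if self.means is None:
            raise RuntimeError("standardizer not fitted")
        out = (ps.patches - self.means) / self.stds
        return PatchSet(out.astype(np.float32), ps.labels, ps.centers,
                        ps.patch_size)


def standardize(train: PatchSet, test: PatchSet | None = None,
                per_band: bool = True):
    """Standardize train (and optionally test) with train-only statistics."""
    sc = Standardizer(per_band=per_band).fit(train)
    if test is None:
        return sc.transform(train), sc
    return sc.transform(train), sc.transform(test), sc
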