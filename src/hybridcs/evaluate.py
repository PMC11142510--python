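"""Confusion-matrix accuracy metrics, the kernel-size sweep, and map output.

The three standard remote-sensing classification metrics are computed from
a K x K confusion matrix C (rows = true class, columns = predicted,
M = total samples):

* overall accuracy      OA = sum_i C(i,i) / M
* average accuracy      AA = (1/K) sum_i C(i,i) / C(i,+)   (mean producer
  accuracy — with heavy class imbalance this is the metric the rare
  species actually move)
* Cohen's kappa         kappa = (M sum_i C(i,i) - sum_i C(i,+) C(+,i))
                                / (M^2 - sum_i C(i,+) C(+,i))

where C(i,+) and C(+,i) are row and column marginals.  Classes with no
test samples are excluded from AA with a warning rather than scored 0.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion",
           "overall_accuracy", "average_accuracy", "kappa",
           "metrics_report", "kernel_size_sweep", "render_map",
           "DEFAULT_PALETTE"]

log = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """K x K counts, rows = true class (1..K), columns = predicted."""

    counts: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = self.counts.shape[0]
        if self.counts.shape != (k, k):
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")
        if not self.class_names:
            self.class_names = [f"class_{i + 1}" for i in range(k)]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_names,
                            columns=self.class_names)


def confusion(true_labels: np.ndarray, predicted: np.ndarray,
              n_classes: int, class_names: list[str] | None = None
              ) -> ConfusionMatrix:
    """Tally counts[i-1, j-1] = #{samples with true class i predicted j}."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted)
    if t.shape != p.shape:
        raise ValueError("true and predicted label arrays differ in length")
    for name, arr in (("true", t), ("predicted", p)):
        if arr.size and (arr.min() < 1 or arr.max() > n_classes):
            raise ValueError(f"{name} labels outside 1..{n_classes}")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (t - 1, p - 1), 1)
    return ConfusionMatrix(counts, class_names or [])


def overall_accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("overall accuracy undefined on an empty matrix")
    return float(np.trace(cm.counts) / cm.total)


def average_accuracy(cm: ConfusionMatrix) -> float:
    row_sums = cm.counts.sum(axis=1)
    present = row_sums > 0
    if not present.any():
        raise ValueError("average accuracy undefined: no test samples")
    if not present.all():
        missing = [cm.class_names[i] for i in np.flatnonzero(~present)]
        warnings.warn(f"classes absent from the test set excluded from AA: "
                      f"{missing}")
    per_class = np.diag(cm.counts)[present] / row_sums[present]
    return float(per_class.mean())


def kappa(cm: ConfusionMatrix) -> float:
    m = cm.total
    if m == 0:
        raise ValueError("kappa undefined on an empty matrix")
    diag = float(np.trace(cm.counts))
    chance = float(cm.counts.sum(axis=1) @ cm.counts.sum(axis=0))
    denom = m * m - chance
    if denom == 0:
        raise ValueError("kappa undefined: degenerate marginals")
    return float((m * diag - chance) / denom)


def per_class_accuracy(cm: ConfusionMatrix) -> np.ndarray:
    row_sums = cm.counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        acc = np.diag(cm.counts) / row_sums
    return acc


@dataclass
class MetricsReport:
    """OA/AA/kappa plus per-class producer accuracies."""

    oa: float
    aa: float
    kappa: float
    per_class: np.ndarray
    class_names: list[str]

    def to_dict(self) -> dict:
        return {
            "oa": self.oa, "aa": self.aa, "kappa": self.kappa,
            "oa_percent": round(100 * self.oa, 2),
            "aa_percent": round(100 * self.aa, 2),
            "kappa_percent": round(100 * self.kappa, 2),
            "per_class": {name: (None if np.isnan(a) else float(a))
                          for name, a in zip(self.class_names, self.per_class)},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def __str__(self) -> str:
        lines = [f"OA    = {100 * self.oa:6.2f}%",
                 f"AA    = {100 * self.aa:6.2f}%",
                 f"Kappa = {100 * self.kappa:6.2f}"]
        for name, a in zip(self.class_names, self.per_class):
            lines.append(f"  {name:<12s} {'--' if np.isnan(a) else f'{100 * a:6.2f}%'}")
        return "\n".join(lines)


def metrics_report(cm: ConfusionMatrix) -> MetricsReport:
    return MetricsReport(oa=overall_accuracy(cm), aa=average_accuracy(cm),
                         kappa=kappa(cm), per_class=per_class_accuracy(cm),
                         class_names=list(cm.class_names))


# ---------------------------------------------------------------------------
# Kernel-size (patch-size) sweep
# ---------------------------------------------------------------------------

def kernel_size_sweep(cube, labels, sizes, model_cfg, train_cfg, split,
                      pca_components: int | None = None) -> pd.DataFrame:
    """Train one model per patch size on identical splits/seeds; report AA.

    ``cube`` should already be PCA-reduced (or pass ``pca_components``).
    Returns a frame with one row per requested size (columns: size, oa, aa).
    """
    from .preprocess import extract_patches, pca_apply, pca_fit, \
        standardize, stratified_split
    from .model import HybridCSModel
    from .train import train as _train

    if pca_components is not None:
        cube = pca_apply(cube, pca_fit(cube, pca_components))
    rows = []
    for size in sizes:
        if size % 2 == 0 or size > min(cube.shape[:2]):
            raise ValueError(f"patch size {size} must be odd and fit the scene")
        ps = extract_patches(cube, labels, size)
        tr, te = stratified_split(ps, split)
        tr_s, te_s, _ = standardize(tr, te)
        cfg = replace(model_cfg, patch_size=size, input_bands=cube.shape[2])
        model = HybridCSModel(cfg)
        _train(model, tr_s, te_s, train_cfg)
        cm = confusion(te_s.labels, model.predict(te_s.patches),
                       cfg.n_classes, labels.class_names)
        rows.append({"size": size, "oa": overall_accuracy(cm),
                     "aa": average_accuracy(cm)})
        log.info("patch size %d: OA=%.4f AA=%.4f", size,
                 rows[-1]["oa"], rows[-1]["aa"])
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Map rendering
# ---------------------------------------------------------------------------

# background + up to 10 classes; colors fixed so renders are reproducible
DEFAULT_PALETTE = (
    (0, 0, 0),        # 0 background
    (31, 119, 180), (255, 127, 14), (44, 160, 44), (214, 39, 40),
    (148, 103, 189), (140, 86, 75), (227, 119, 194), (127, 127, 127),
    (188, 189, 34), (23, 190, 207),
)


def render_map(label_map, path, palette=DEFAULT_PALETTE,
               geotransform=None) -> None:
    """Write a paletted PNG of a label map (indices preserved exactly).

    The PNG stores the class index in the palette index, so reading the
    image back yields the label map unchanged; a JSON legend sidecar maps
    indices to class names and colors.  Rendering is deterministic.
    """
    from PIL import Image

    labels = np.asarray(label_map.labels)
    k = int(labels.max())
    if len(palette) < k + 1:
        raise ValueError(f"palette has {len(palette)} colors; need {k + 1}")
    img = Image.fromarray(labels.astype(np.uint8), mode="P")
    flat = [c for rgb in palette for c in rgb]
    img.putpalette(flat + [0] * (768 - len(flat)))
    img.save(path, format="PNG", optimize=False)
    legend = {"0": {"name": "background", "color": list(palette[0])}}
    for i, name in enumerate(label_map.class_names, start=1):
        legend[str(i)] = {"name": name, "color": list(palette[i])}
    with open(str(path) + ".legend.json", "w") as fh:
        json.dump(legend, fh, indent=2)
    if geotransform is not None:
        from .cube import HSICube, save_cube
        tif_path = str(path).rsplit(".", 1)[0] + ".tif"
        save_cube(HSICube(labels[:, :, None].astype(np.float32),
                          geotransform=tuple(geotransform)),
                  tif_path, format="geotiff")
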