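"""The two-branch hyperspectral classifier (spectral-spatial + sandglass).

Architecture, for a ``C x C x P`` input patch (defaults C=7, P=100, K=6):

Spectral-spatial (SS) branch
    3-D conv, kernel (1,1,7), 24 filters, spectral stride 2, valid
    spectral padding (P=100 -> depth 47) -> two same-padded (3,3,3) 3-D
    convs, 24 filters -> reshape spectral x filters into channels ->
    1x1 2-D conv to 60 -> global average pool -> 60-vector.

Sandglass branch
    The patch viewed as a P-channel 2-D image: C-B-M (3x3, 24) ->
    sandglass block -> C-B-M (3x3, 24) -> sandglass block -> 3x3 stride-1
    average pool -> global average pool -> linear expansion to 60.

Fusion and head
    The two 60-vectors are concatenated (120) and projected back to 60 by
    a learned 1x1 transform with batch norm and Smish; a final linear map
    yields K class scores.  There is no softmax: the head is trained with
    a maximum-margin (multiclass squared-hinge) objective and the
    prediction is the argmax of the raw scores, ties broken toward the
    lowest class index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import h5py
import numpy as np

from .autograd import Tensor, concat
from .layers import (AvgPool2d, BatchNorm, CBM, Conv2d, Conv3d, Linear,
                     SandglassBlock, global_avg_pool, smish)

__all__ = ["ModelConfig", "HybridCSModel", "FeaturePair"]


@dataclass
class ModelConfig:
    """Hyperparameters of the two-branch network (defaults = reference
    configuration: 7x7x100 input, 24-wide convolutions, 60-d features)."""

    patch_size: int = 7
    input_bands: int = 100
    n_classes: int = 6
    conv3d_filters: int = 24
    first_kernel: tuple[int, int, int] = (1, 1, 7)
    first_spectral_stride: int = 2
    follow_kernel: tuple[int, int, int] = (3, 3, 3)
    n_follow_convs: int = 2
    conv2d_out: int = 60
    sandglass_width: int = 24
    bottleneck_ratio: int = 4
    n_sandglass_blocks: int = 2
    fused_dim: int = 60
    use_sandglass: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_size % 2 == 0:
            raise ValueError("patch size must be odd")
        if self.sandglass_width % self.bottleneck_ratio != 0:
            raise ValueError("sandglass width must be divisible by the "
                             "bottleneck ratio")
        if self.input_bands < self.first_kernel[2]:
            raise ValueError(
                f"first spectral kernel ({self.first_kernel[2]}) cannot fit "
                f"{self.input_bands} input bands")
        if min(self.conv3d_filters, self.conv2d_out, self.fused_dim) < 1:
            raise ValueError("all widths must be >= 1")


@dataclass
class FeaturePair:
    """Per-branch 60-d features and their fused 60-d combination."""

    f_ss: np.ndarray
    f_sand: np.ndarray | None
    f_fused: np.ndarray


class HybridCSModel:
    """Two-branch network with concatenation fusion and a margin head."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x30DE]))
        c = config
        f = c.conv3d_filters

        # --- SS branch ---
        self.ss_conv1 = Conv3d("ss.conv1", 1, f, c.first_kernel, rng,
                               spectral_stride=c.first_spectral_stride,
                               spectral_padding="valid")
        self._ss_depth = (c.input_bands - c.first_kernel[2]) \
            // c.first_spectral_stride + 1
        self.ss_follow = [
            Conv3d(f"ss.conv{i + 2}", f, f, c.follow_kernel, rng,
                   spectral_stride=1, spectral_padding="same")
            for i in range(c.n_follow_convs)]
        self.ss_collapse = Conv2d("ss.collapse", self._ss_depth * f,
                                  c.conv2d_out, 1, rng)

        # --- sandglass branch ---
        self.sg_layers: list = []
        if c.use_sandglass:
            w = c.sandglass_width
            in_ch = c.input_bands
            for i in range(c.n_sandglass_blocks):
                self.sg_layers.append(CBM(f"sg.cbm{i + 1}", in_ch, w, 3, rng))
                self.sg_layers.append(
                    SandglassBlock(f"sg.block{i + 1}", w, c.bottleneck_ratio, rng))
                in_ch = w
            self.sg_pool = AvgPool2d("sg.pool", w, 3)
            self.sg_expand = Linear("sg.expand", w, c.conv2d_out, rng)

        # --- fusion + head ---
        fuse_in = 2 * c.conv2d_out if c.use_sandglass else c.conv2d_out
        self.fuse_proj = Linear("fuse.proj", fuse_in, c.fused_dim, rng)
        self.fuse_bn = BatchNorm("fuse.bn", c.fused_dim)
        self.head = Linear("head", c.fused_dim, c.n_classes, rng)

        self._layers = ([self.ss_conv1] + self.ss_follow + [self.ss_collapse]
                        + self.sg_layers
                        + ([self.sg_expand] if c.use_sandglass else [])
                        + [self.fuse_proj, self.fuse_bn, self.head])

    # ------------------------------------------------------------------
    def named_parameters(self) -> list[tuple[str, Tensor]]:
        return [p for layer in self._layers for p in layer.named_params()]

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    @property
    def n_parameters(self) -> int:
        return int(sum(t.data.size for t in self.parameters()))

    def zero_grad(self) -> None:
        for t in self.parameters():
            t.grad = None

    # ------------------------------------------------------------------
    def _check_input(self, x: np.ndarray | Tensor) -> Tensor:
        t = Tensor.as_tensor(x)
        if t.ndim == 3:
            t = t.reshape(1, *t.shape)
        c, p = self.config.patch_size, self.config.input_bands
        if t.shape[1:] != (c, c, p):
            raise ValueError(f"expected patches of shape ({c}, {c}, {p}); "
                             f"got {tuple(t.shape[1:])}")
        return t

    def ss_branch(self, x, training: bool = False,
                  intermediates: dict | None = None) -> Tensor:
        """Spectral-spatial branch: (n, C, C, P) -> (n, conv2d_out)."""
        t = self._check_input(x)
        n, c, _, p = t.shape
        h = t.reshape(n, c, c, p, 1)
        h = smish(self.ss_conv1.forward(h))
        if intermediates is not None:
            intermediates["ss_conv1"] = h.data
        for conv in self.ss_follow:
            h = smish(conv.forward(h))
        n_, hh, ww, dd, ff = h.shape
        h = h.reshape(n_, hh, ww, dd * ff)
        h = smish(self.ss_collapse.forward(h))
        if intermediates is not None:
            intermediates["ss_conv2d"] = h.data
        out = global_avg_pool(h)
        if intermediates is not None:
            intermediates["ss_pooled"] = out.data
        return out

    def sandglass_branch(self, x, training: bool = False,
                         intermediates: dict | None = None) -> Tensor:
        """Sandglass branch: (n, C, C, P) -> (n, conv2d_out)."""
        if not self.config.use_sandglass:
            raise RuntimeError("model was built without the sandglass branch")
        h = self._check_input(x)
        for layer in self.sg_layers:
            h = layer.forward(h, training)
        h = self.sg_pool.forward(h)
        if intermediates is not None:
            intermediates["sg_pooled_map"] = h.data
        h = global_avg_pool(h)
        out = self.sg_expand.forward(h)
        if intermediates is not None:
            intermediates["sg_feature"] = out.data
        return out

    def fuse(self, f_ss: Tensor, f_sand: Tensor | None,
             training: bool = False) -> Tensor:
        """Concatenate branch features and project back to ``fused_dim``."""
        if f_sand is not None:
            if f_ss.shape[-1] != f_sand.shape[-1]:
                raise ValueError("branch feature lengths disagree")
            joint = concat([f_ss, f_sand], axis=1)
        else:
            joint = f_ss
        h = self.fuse_proj.forward(joint)
        return smish(self.fuse_bn.forward(h, training))

    def head_scores(self, f_fused: Tensor) -> Tensor:
        """Linear maximum-margin head: (n, fused_dim) -> (n, K) raw scores."""
        return self.head.forward(f_fused)

    def forward(self, x, training: bool = False,
                intermediates: dict | None = None) -> Tensor:
        f_ss = self.ss_branch(x, training, intermediates)
        f_sand = (self.sandglass_branch(x, training, intermediates)
                  if self.config.use_sandglass else None)
        fused = self.fuse(f_ss, f_sand, training)
        if intermediates is not None:
            intermediates["fused"] = fused.data
        return self.head_scores(fused)

    def features(self, x, training: bool = False) -> FeaturePair:
        f_ss = self.ss_branch(x, training)
        f_sand = (self.sandglass_branch(x, training)
                  if self.config.use_sandglass else None)
        fused = self.fuse(f_ss, f_sand, training)
        return FeaturePair(f_ss.data, None if f_sand is None else f_sand.data,
                           fused.data)

    def predict(self, patches: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Class labels 1..K; argmax with ties to the lowest class index."""
        out = np.empty(patches.shape[0], dtype=np.int64)
        for lo in range(0, patches.shape[0], batch_size):
            scores = self.forward(patches[lo:lo + batch_size]).data
            out[lo:lo + batch_size] = scores.argmax(axis=1) + 1
        return out

    # ------------------------------------------------------------------
    def _bn_state(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for layer in self._layers:
            if hasattr(layer, "state"):
                state.update(layer.state())
        return state

    def save(self, path) -> None:
        """Weights + running stats to HDF5 with the config as a JSON attr."""
        with h5py.File(path, "w") as f:
            f.attrs["config"] = json.dumps(asdict(self.config))
            for name, t in self.named_parameters():
                f.create_dataset(f"params/{name}", data=t.data, track_times=False)
            for name, arr in self._bn_state().items():
                f.create_dataset(f"state/{name}", data=arr, track_times=False)

    @classmethod
    def load(cls, path) -> "HybridCSModel":
        with h5py.File(path, "r") as f:
            cfg_dict = json.loads(f.attrs["config"])
            for key in ("first_kernel", "follow_kernel", "class_names"):
                if key in cfg_dict and isinstance(cfg_dict[key], list):
                    cfg_dict[key] = tuple(cfg_dict[key])
            model = cls(ModelConfig(**cfg_dict))
            for name, t in model.named_parameters():
                stored = f[f"params/{name}"][()]
                if stored.shape != t.data.shape:
                    raise ValueError(
                        f"checkpoint/config mismatch for '{name}': stored "
                        f"{stored.shape}, model expects {t.data.shape}")
                t.data = stored.astype(np.float32)
            state: dict[str, np.ndarray] = {}
            if "state" in f:
                for key in f["state"]:
                    state[key] = f["state"][key][()]
            for layer in model._layers:
                if hasattr(layer, "load_state") and state:
                    layer.load_state(state)
        return model

    def set_weights_from(self, other: "HybridCSModel") -> None:
        for (_, a), (_, b) in zip(self.named_parameters(),
                                  other.named_parameters()):
            a.data = b.data.copy()
        state = other._bn_state()
        for layer in self._layers:
            if hasattr(layer, "load_state"):
                layer.load_state(state)
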