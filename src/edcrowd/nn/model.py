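"""Multi-fusion convolutional counting network (encoder-decoder).

The network regresses a density map from a grayscale waiting-room frame:

* an input block condenses each spatial dimension to a quarter;
* four downsampling stages of bottleneck residual blocks (channel-reduce,
  transform, channel-expand with an identity shortcut) halve the spatial
  size, with more blocks per stage as depth grows;
* the decoder upsamples deep feature maps and fuses each with the same-size
  shallower encoder map;
* a fine-grained regressor cuts the fused map into horizontal and vertical
  strips, enhances each strip with a shared bottleneck block per dimension,
  splices them back and fuses the two enhanced maps by addition;
* a regression head of global-average-pool channel gating plus 1x1
  convolutions (no fully connected layer, so any input size is accepted)
  emits a quarter-resolution map that is enlarged to the input size and
  refined by a dilated convolution; a final rectifier keeps it non-negative.

The predicted people count is the total mass of the output map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "NetworkConfig",
    "DensityPrediction",
    "MFCNN",
    "build_model",
    "fine_grained_regress",
    "split_strips",
    "splice_strips",
]

MIN_INPUT = 64


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters.

    ``blocks_per_stage`` must be non-decreasing (deeper stages gain blocks);
    ``input_reduction`` is the per-dimension shrink of the input block.
    """

    base_width: int = 32
    blocks_per_stage: tuple[int, int, int, int] = (1, 2, 3, 4)
    strip_count: int = 4
    upsample_mode: str = "nearest"
    input_reduction: int = 4
    in_channels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.blocks_per_stage) != 4:
            raise ValueError("exactly four encoder stages are required")
        if any(b < 1 for b in self.blocks_per_stage):
            raise ValueError("each stage needs at least one block")
        if list(self.blocks_per_stage) != sorted(self.blocks_per_stage):
            raise ValueError("blocks_per_stage must be non-decreasing")
        if self.strip_count < 1:
            raise ValueError("strip_count must be >= 1")
        if self.input_reduction not in (2, 4):
            raise ValueError("input_reduction must be 2 or 4")
        if self.upsample_mode != "nearest":
            raise ValueError(f"unsupported upsample mode {self.upsample_mode!r}")
        if self.base_width < 2 or self.base_width % 2:
            raise ValueError("base_width must be an even integer >= 2")


@dataclass
class DensityPrediction:
    """Predicted density map (input-sized) and its total count."""

    density: np.ndarray = field(repr=False)
    count: float = 0.0


def split_strips(x: np.ndarray, n: int, axis: int) -> list[np.ndarray]:
    """Cut an array into ``n`` equal strips along ``axis`` (zero-padded)."""
    size = x.shape[axis]
    if n < 1 or n > size:
        raise ValueError(f"cannot cut extent {size} into {n} strips")
    width = -(-size // n)
    pad = width * n - size
    if pad:
        spec = [(0, 0)] * x.ndim
        spec[axis] = (0, pad)
        x = np.pad(x, spec)
    return list(np.split(x, n, axis=axis))


def splice_strips(strips: list[np.ndarray], axis: int, size: int | None = None) -> np.ndarray:
    """Rejoin strips in order, cropping any split padding back off."""
    out = np.concatenate(strips, axis=axis)
    if size is not None:
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(0, size)
        out = out[tuple(sl)]
    return out


def fine_grained_regress(feature: np.ndarray, strip_count: int, block=None) -> np.ndarray:
    """Strip-wise feature enhancement, as plain arrays.

    ``feature`` is (C, H, W) or (N, C, H, W); ``block`` maps a strip to a
    same-shaped strip (identity when omitted) and is shared across strips
    within a dimension.  Width- and height-enhanced maps are fused by
    addition.
    """
    arr = np.asarray(feature, dtype=np.float32)
    squeeze = arr.ndim == 3
    if squeeze:
        arr = arr[None]
    block = block if block is not None else (lambda s: s)
    h, w = arr.shape[2], arr.shape[3]
    if strip_count > min(h, w):
        raise ValueError(f"strip_count {strip_count} exceeds spatial extent {h}x{w}")
    h_strips = [block(s) for s in split_strips(arr, strip_count, axis=2)]
    w_strips = [block(s) for s in split_strips(arr, strip_count, axis=3)]
    fused = splice_strips(h_strips, axis=2, size=h) + splice_strips(w_strips, axis=3, size=w)
    return fused[0] if squeeze else fused


class MFCNN:
    """Multi-fusion counting network with seeded NumPy parameters."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        self.params: dict[str, Tensor] = {}
        self._rng = np.random.default_rng(config.seed)
        self._build()

    # -- parameter plumbing -------------------------------------------------

    def _conv_param(self, name: str, cout: int, cin: int, k: int, bias: bool = True):
        fan_in = cin * k * k
        w = self._rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, cin, k, k))
        self.params[f"{name}.w"] = Tensor(w.astype(np.float32), requires_grad=True)
        if bias:
            self.params[f"{name}.b"] = Tensor(
                np.zeros(cout, dtype=np.float32), requires_grad=True
            )

    def _conv(self, name: str, x: Tensor, stride=1, padding=0, dilation=1) -> Tensor:
        return ag.conv2d(
            x,
            self.params[f"{name}.w"],
            self.params.get(f"{name}.b"),
            stride=stride,
            padding=padding,
            dilation=dilation,
        )

    def _build(self) -> None:
        cfg = self.config
        w = cfg.base_width
        cin = cfg.in_channels
        if cfg.input_reduction == 4:
            self._conv_param("input.0", w, cin, 3)
            self._conv_param("input.1", w, w, 3)
        else:
            self._conv_param("input.0", w, cin, 3)
        for s, n_blocks in enumerate(cfg.blocks_per_stage):
            self._conv_param(f"stage{s}.down", w, w, 3)
            for b in range(n_blocks):
                self._bottleneck_params(f"stage{s}.block{b}", w)
        for d in range(4):
            self._conv_param(f"decoder{d}.fuse", w, w, 1)
        self._bottleneck_params("strip_h", w)
        self._bottleneck_params("strip_w", w)
        self._conv_param("head.gate", w, w, 1)
        self._conv_param("head.out", 1, w, 1)
        self._conv_param("refine", 1, 1, 3)
        # start the output pathway near zero so initial density (and count)
        # predictions are small; the positive refine bias keeps the output
        # rectifier alive at init
        self.params["head.out.w"].data *= 0.05
        self.params["refine.w"].data *= 0.05
        self.params["refine.b"].data[:] = 1e-3

    def _bottleneck_params(self, name: str, ch: int) -> None:
        mid = ch // 2
        self._conv_param(f"{name}.reduce", mid, ch, 1)
        self._conv_param(f"{name}.conv", mid, mid, 3)
        self._conv_param(f"{name}.expand", ch, mid, 1)

    def _bottleneck(self, name: str, x: Tensor) -> Tensor:
        h = ag.relu(self._conv(f"{name}.reduce", x))
        h = ag.relu(self._conv(f"{name}.conv", h, padding=1))
        h = self._conv(f"{name}.expand", h)
        return ag.relu(ag.add(h, x))

    # -- forward ------------------------------------------------------------

    def forward_tensor(self, x: Tensor) -> Tensor:
        """Full forward pass on an NCHW tensor; returns the N1HW density map."""
        cfg = self.config
        n, c, h, w = x.data.shape
        if h < MIN_INPUT or w < MIN_INPUT:
            raise ValueError(f"input must be at least {MIN_INPUT}px per side, got {h}x{w}")

        feat = ag.relu(self._conv("input.0", x, stride=2, padding=1))
        if cfg.input_reduction == 4:
            feat = ag.relu(self._conv("input.1", feat, stride=2, padding=1))
        skips = [feat]
        for s, n_blocks in enumerate(cfg.blocks_per_stage):
            feat = ag.relu(self._conv(f"stage{s}.down", feat, stride=2, padding=1))
            for b in range(n_blocks):
                feat = self._bottleneck(f"stage{s}.block{b}", feat)
            skips.append(feat)
        self.last_encoder_shapes = [tuple(t.data.shape[2:]) for t in skips]

        deep = skips[-1]
        for d, skip in enumerate(reversed(skips[:-1])):
            up = ag.resize_nearest(deep, skip.data.shape[2:])
            deep = ag.relu(ag.add(self._conv(f"decoder{d}.fuse", up), skip))

        fused = self._fine_grained(deep)

        gate = ag.sigmoid(self._conv("head.gate", ag.global_avg_pool(fused)))
        gated = ag.mul(fused, gate)
        coarse = self._conv("head.out", gated)

        up = ag.resize_nearest(coarse, (h, w))
        refined = self._conv("refine", up, padding=2, dilation=2)
        return ag.relu(refined)

    def _fine_grained(self, feat: Tensor) -> Tensor:
        s = self.config.strip_count
        h, w = feat.data.shape[2], feat.data.shape[3]
        if s > min(h, w):
            raise ValueError(f"strip_count {s} exceeds feature extent {h}x{w}")
        fused = None
        for axis, name in ((2, "strip_h"), (3, "strip_w")):
            size = feat.data.shape[axis]
            width = -(-size // s)
            padded = ag.pad_hw(
                feat,
                width * s - size if axis == 2 else 0,
                width * s - size if axis == 3 else 0,
            )
            strips = []
            for i in range(s):
                lo, hi = i * width, (i + 1) * width
                strip = (
                    ag.slice_hw(padded, lo, hi, 0, padded.data.shape[3])
                    if axis == 2
                    else ag.slice_hw(padded, 0, padded.data.shape[2], lo, hi)
                )
                strips.append(self._bottleneck(name, strip))
            spliced = ag.concat(strips, axis=axis)
            spliced = ag.slice_hw(
                spliced,
                0,
                h if axis == 2 else spliced.data.shape[2],
                0,
                w if axis == 3 else spliced.data.shape[3],
            )
            fused = spliced if fused is None else ag.add(fused, spliced)
        return fused

    def forward(self, image: np.ndarray) -> DensityPrediction:
        """Predict a density map (and count) for one grayscale image."""
        x = Tensor(self._to_nchw(image))
        out = self.forward_tensor(x)
        density = out.data[0, 0]
        return DensityPrediction(density=density, count=float(density.sum()))

    def predict_count(self, image: np.ndarray) -> float:
        return self.forward(image).count

    @staticmethod
    def _to_nchw(image: np.ndarray) -> np.ndarray:
        arr = np.asarray(image, dtype=np.float32)
        if arr.ndim == 3:  # H x W x C -> mean to grayscale
            arr = arr.mean(axis=2)
        return arr[None, None]

    # -- bookkeeping --------------------------------------------------------

    def encoder_feature_sizes(self, height: int, width: int) -> list[tuple[int, int]]:
        """Spatial sizes of the input-block map and each stage output."""
        def shrink(v: int) -> int:
            return -(-v // 2)  # stride-2, pad-1, k=3 convolution: ceil(v/2)

        h, w = height, width
        for _ in range(2 if self.config.input_reduction == 4 else 1):
            h, w = shrink(h), shrink(w)
        sizes = [(h, w)]
        for _ in range(4):
            h, w = shrink(h), shrink(w)
            sizes.append((h, w))
        return sizes

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = np.asarray(v, dtype=np.float32)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def save(self, path) -> None:
        """Checkpoint: .npz weights plus a JSON config sidecar."""
        path = Path(path)
        np.savez(path, **self.state_dict())
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(self.config.__dict__, default=list, indent=2))

    @classmethod
    def load(cls, path) -> "MFCNN":
        path = Path(path)
        cfg_raw = json.loads(path.with_suffix(".json").read_text())
        cfg_raw["blocks_per_stage"] = tuple(cfg_raw["blocks_per_stage"])
        model = cls(NetworkConfig(**cfg_raw))
        with np.load(path if path.suffix else path.with_suffix(".npz")) as data:
            model.load_state_dict({k: data[k] for k in data.files})
        return model


def build_model(config: NetworkConfig | None = None) -> MFCNN:
    """Construct a seeded MFCNN from a :class:`NetworkConfig`."""
    return MFCNN(config or NetworkConfig())
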