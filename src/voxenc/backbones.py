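"""The two convolutional feature extractors of the mixed encoding model.

A small-kernel VGG16-style network and a large-kernel RepLKNet-style network,
each exposed as a :class:`BackboneGraph` — an ordered layer list with named
*tap points* at which multi-layer features are read out.  The RepLKNet-style
network carries parallel large+small depthwise kernel branches per block
(structural reparameterization); :func:`fuse_reparam_branch` folds the two
batch-normalized branches into one equivalent convolution for inference.

Both builders support the full-size configuration (224x224 input, the
channel ladders of the published architectures) and a topology-preserving
reduced variant for desk-scale experiments.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .nn import (
    DTYPE,
    BatchNorm2d,
    Conv2d,
    ConvSpec,
    Layer,
    MaxPool2d,
    ReLU,
    Residual,
    Sequential,
    he_conv,
)

# Per-channel standardization constants applied to RGB input in [0, 1].
# The customary ImageNet statistics; recorded here as the package-wide choice.
IMAGE_MEAN = np.array([0.485, 0.456, 0.406])
IMAGE_STD = np.array([0.229, 0.224, 0.225])

# Published training hyperparameters of the large-kernel backbone, kept as
# documentation constants only — this package never pretrains a backbone.
REPLKNET_PRETRAIN_SETTINGS = {
    "batch_size": 32,
    "drop_path": 0.1,
    "learning_rate": 4e-3,
    "warmup_epochs": 5,
    "epochs": 90,
}


# ---------------------------------------------------------------------------
# reparameterization


@dataclass
class ReparamBranch:
    """Parallel large + small depthwise-conv branches, each batch-normalized.

    Both branches see the same input and their outputs are summed; the small
    kernel rides inside the large kernel's padding so both produce identical
    output shapes.
    """

    large_spec: ConvSpec
    large_weight: np.ndarray
    small_spec: ConvSpec
    small_weight: np.ndarray
    large_bn: BatchNorm2d
    small_bn: BatchNorm2d

    def __post_init__(self) -> None:
        ls, ss = self.large_spec, self.small_spec
        if ls.kernel_size % 2 == 0 or ss.kernel_size % 2 == 0:
            raise ValueError("reparam kernels must be odd")
        if ss.kernel_size > ls.kernel_size:
            raise ValueError("small kernel must not exceed the large kernel")
        if (ls.stride, ls.groups) != (ss.stride, ss.groups):
            raise ValueError("branches must share stride and groups")
        if (ls.in_channels, ls.out_channels) != (ss.in_channels, ss.out_channels):
            raise ValueError("branches must share channel counts")
        if ls.padding != ls.kernel_size // 2 or ss.padding != ss.kernel_size // 2:
            raise ValueError("reparam branches assume same-padding")


class ReparamConv2d(Layer):
    """Two-branch large/small kernel convolution (training-time form)."""

    def __init__(self, branch: ReparamBranch):
        self.branch = branch
        b = branch
        self._large = Conv2d(b.large_spec, b.large_weight, None if not b.large_spec.has_bias else np.zeros(b.large_spec.out_channels))
        self._small = Conv2d(b.small_spec, b.small_weight, None if not b.small_spec.has_bias else np.zeros(b.small_spec.out_channels))

    def out_shape(self, shape):
        return self._large.out_shape(shape)

    def forward(self, x):
        yl, cl = self._large.forward(x)
        yl, cbl = self.branch.large_bn.forward(yl)
        ys, cs = self._small.forward(x)
        ys, cbs = self.branch.small_bn.forward(ys)
        return yl + ys, (cl, cs)

    def backward(self, gy, cache):
        cl, cs = cache
        gl = self._large.backward(self.branch.large_bn.backward(gy, None), cl)
        gs = self._small.backward(self.branch.small_bn.backward(gy, None), cs)
        return gl + gs

    def fuse(self) -> Conv2d:
        spec, weight, bias = fuse_reparam_branch(self.branch)
        return Conv2d(spec, weight, bias)


def _fold_bn(weight: np.ndarray, bn: BatchNorm2d) -> tuple[np.ndarray, np.ndarray]:
    g = bn.effective_scale
    return weight * g[:, None, None, None], bn.effective_shift.copy()


def fuse_reparam_branch(branch: ReparamBranch):
    """Fold BN into each branch and sum the kernels into one convolution.

    The small kernel is zero-padded symmetrically to the large kernel size.
    Returns ``(spec, weight, bias)`` of the equivalent single convolution.
    """
    wl, bl = _fold_bn(branch.large_weight, branch.large_bn)
    ws, bs = _fold_bn(branch.small_weight, branch.small_bn)
    pad = (branch.large_spec.kernel_size - branch.small_spec.kernel_size) // 2
    ws_padded = np.pad(ws, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ls = branch.large_spec
    spec = ConvSpec(
        kernel_size=ls.kernel_size,
        in_channels=ls.in_channels,
        out_channels=ls.out_channels,
        stride=ls.stride,
        padding=ls.padding,
        groups=ls.groups,
        has_bias=True,
    )
    return spec, wl + ws_padded, bl + bs


def make_reparam_branch(
    rng: np.random.Generator,
    channels: int,
    large_kernel: int,
    small_kernel: int,
    stride: int = 1,
) -> ReparamBranch:
    """Seeded random depthwise branch pair with near-identity BN statistics."""

    def spec(k: int) -> ConvSpec:
        return ConvSpec(k, channels, channels, stride=stride, padding=k // 2,
                        groups=channels, has_bias=False)

    def bn() -> BatchNorm2d:
        return BatchNorm2d(
            scale=rng.uniform(0.5, 1.5, channels),
            shift=rng.normal(0.0, 0.1, channels),
            mean=rng.normal(0.0, 0.1, channels),
            var=rng.uniform(0.5, 1.5, channels),
        )

    ls, ss = spec(large_kernel), spec(small_kernel)
    return ReparamBranch(ls, he_conv(rng, ls), ss, he_conv(rng, ss), bn(), bn())


# ---------------------------------------------------------------------------
# graphs


@dataclass
class BackboneGraph:
    """Ordered layer list with named feature tap points."""

    name: str
    layers: list[tuple[str, Layer]]
    taps: list[tuple[str, int]]
    input_shape: tuple[int, int, int]
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [t for t, _ in self.taps]
        if len(set(names)) != len(names):
            raise ValueError("tap names must be unique")
        idx = [i for _, i in self.taps]
        if idx != sorted(idx):
            raise ValueError("taps must be ordered shallow to deep")

    @property
    def tap_names(self) -> list[str]:
        return [t for t, _ in self.taps]

    def conv_layers(self) -> list[tuple[str, Conv2d]]:
        return [(n, l) for n, l in self.layers if isinstance(l, Conv2d)]

    def tap_shapes(self) -> dict[str, tuple[int, int, int]]:
        """Per-tap (channel, row, col) shapes by pure shape arithmetic."""
        out: dict[str, tuple[int, int, int]] = {}
        shape = self.input_shape
        tap_at = {i: t for t, i in self.taps}
        for i, (_, layer) in enumerate(self.layers):
            shape = layer.out_shape(shape)
            if i in tap_at:
                out[tap_at[i]] = shape
        return out

    def _check_input(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=DTYPE)
        if images.ndim == 3:
            images = images[None]
        if images.ndim != 4 or images.shape[1:] != self.input_shape:
            raise ValueError(
                f"expected input of shape (batch,) + {self.input_shape}, "
                f"received {images.shape}"
            )
        return images

    def forward(self, images: np.ndarray) -> dict[str, np.ndarray]:
        """One activation per tap; deterministic given weights and input."""
        images = self._check_input(images)
        tap_at = {i: t for t, i in self.taps}
        acts: dict[str, np.ndarray] = {}
        x = images
        for i, (_, layer) in enumerate(self.layers):
            x, _ = layer.forward(x)
            if i in tap_at:
                acts[tap_at[i]] = x
        return {t: acts[t] for t, _ in self.taps}

    def forward_with_cache(self, images: np.ndarray):
        """Forward through the last tap, keeping per-layer caches for VJP."""
        images = self._check_input(images)
        last = self.taps[-1][1]
        caches = []
        x = images
        for i, (_, layer) in enumerate(self.layers[: last + 1]):
            x, c = layer.forward(x)
            caches.append(c)
        return x, caches

    def backward_to_input(self, gy: np.ndarray, caches: list) -> np.ndarray:
        g = gy
        for (_, layer), c in zip(reversed(self.layers[: len(caches)]), reversed(caches)):
            g = layer.backward(g, c)
        return g

    def fingerprint(self) -> str:
        """Stable hash of the architecture and all parameters."""
        h = hashlib.sha256()
        h.update(repr((self.name, self.input_shape, self.taps)).encode())
        for name, layer in self.layers:
            h.update(name.encode())
            for arr in _layer_arrays(layer).values():
                h.update(np.ascontiguousarray(arr, dtype=np.float64).tobytes())
        return h.hexdigest()[:16]


def _layer_arrays(layer: Layer) -> dict[str, np.ndarray]:
    if isinstance(layer, Conv2d):
        out = {"weight": layer.weight}
        if layer.bias is not None:
            out["bias"] = layer.bias
        return out
    if isinstance(layer, BatchNorm2d):
        return {
            "bn_scale": layer.scale,
            "bn_shift": layer.shift,
            "bn_mean": layer.mean,
            "bn_var": layer.var,
        }
    if isinstance(layer, ReparamConv2d):
        b = layer.branch
        out = {"large_weight": b.large_weight, "small_weight": b.small_weight}
        for tag, bn in (("large", b.large_bn), ("small", b.small_bn)):
            out.update(
                {
                    f"{tag}_bn_scale": bn.scale,
                    f"{tag}_bn_shift": bn.shift,
                    f"{tag}_bn_mean": bn.mean,
                    f"{tag}_bn_var": bn.var,
                }
            )
        return out
    if isinstance(layer, (Residual, Sequential)):
        out = {}
        for j, sub in enumerate(layer.body):
            for k, v in _layer_arrays(sub).items():
                out[f"sub{j}/{k}"] = v
        return out
    return {}


# ---------------------------------------------------------------------------
# VGG16-style builder

VGG16_CHANNELS = ((64, 64), (128, 128), (256, 256, 256), (512, 512, 512), (512, 512, 512))
VGG16_REDUCED_CHANNELS = ((1, 1), (1, 1), (1, 1, 1), (1, 1, 1), (1, 1, 1))
VGG16_REDUCED_INPUT = 32


def build_vgg16(
    variant: str = "standard",
    seed: int = 0,
    weights_path: str | None = None,
    input_size: int | None = None,
    channels: tuple[tuple[int, ...], ...] | None = None,
) -> BackboneGraph:
    """Small-kernel backbone: 13 3x3 convolutions in five blocks (A-E).

    Six taps: the output of each block and the output of block E after the
    final max-pool.  The three fully connected layers of the classifier play
    no role in feature extraction and are omitted from the graph.
    """
    if variant == "standard":
        channels = channels or VGG16_CHANNELS
        input_size = input_size or 224
    elif variant == "reduced":
        channels = channels or VGG16_REDUCED_CHANNELS
        input_size = input_size or VGG16_REDUCED_INPUT
    else:
        raise ValueError(f"unknown vgg16 variant {variant!r}")
    if input_size < 2 ** len(channels):
        raise ValueError(f"input_size {input_size} too small for 5 poolings")

    rng = np.random.default_rng(seed)
    layers: list[tuple[str, Layer]] = []
    taps: list[tuple[str, int]] = []
    c_in = 3
    block_names = "ABCDE"
    for bi, block in enumerate(channels):
        for ci, c_out in enumerate(block):
            spec = ConvSpec(3, c_in, c_out, stride=1, padding=1)
            layers.append((f"conv{bi + 1}_{ci + 1}", Conv2d(spec, he_conv(rng, spec))))
            layers.append((f"relu{bi + 1}_{ci + 1}", ReLU()))
            c_in = c_out
        taps.append((f"block{block_names[bi]}", len(layers) - 1))
        layers.append((f"pool{bi + 1}", MaxPool2d(2)))
    taps.append((f"pool{len(channels)}", len(layers) - 1))

    graph = BackboneGraph(
        name="vgg16" if variant == "standard" else f"vgg16-{variant}",
        layers=layers,
        taps=taps,
        input_shape=(3, input_size, input_size),
        seed=seed,
        meta={"family": "vgg16", "variant": variant},
    )
    if weights_path is not None:
        load_weights(graph, weights_path)
    return graph


# ---------------------------------------------------------------------------
# RepLKNet-style builder

REPLKNET_CHANNELS = (128, 256, 512, 1024)  # 31B-style channel ladder
REPLKNET_KERNELS = (31, 29, 27, 13)
REPLKNET_SMALL_KERNEL = 5
REPLKNET_BLOCKS = (2, 2, 2, 2)
REPLKNET_REDUCED = {
    "channels": (2, 2, 2, 2),
    "kernels": (7, 7, 5, 3),
    "small_kernel": 3,
    "blocks": (1, 1, 1, 1),
    "input_size": 32,
}


def _bn_identity(channels: int) -> BatchNorm2d:
    return BatchNorm2d(
        np.ones(channels), np.zeros(channels), np.zeros(channels), np.ones(channels)
    )


def build_replknet(
    variant: str = "31B",
    seed: int = 0,
    weights_path: str | None = None,
    input_size: int | None = None,
    channels: tuple[int, ...] | None = None,
    kernels: tuple[int, ...] | None = None,
    small_kernel: int | None = None,
    blocks: tuple[int, ...] | None = None,
    fused: bool = False,
) -> BackboneGraph:
    """Large-kernel backbone: one stem, four stages, transition blocks.

    Each stage block carries a depthwise large-kernel convolution with a
    parallel small-kernel reparameterization branch (both batch-normalized)
    inside a residual unit, followed by a 1x1 channel mixer.  Taps sit at the
    four stage outputs; for a 224x224 input their spatial sizes are
    56/28/14/7 with channels 128/256/512/1024 in the 31B-style configuration.

    ``fused=True`` replaces every two-branch unit by its algebraically fused
    single convolution (inference deployment form).
    """
    if variant == "31B":
        channels = channels or REPLKNET_CHANNELS
        kernels = kernels or REPLKNET_KERNELS
        small_kernel = small_kernel or REPLKNET_SMALL_KERNEL
        blocks = blocks or REPLKNET_BLOCKS
        input_size = input_size or 224
    elif variant == "reduced":
        r = REPLKNET_REDUCED
        channels = channels or r["channels"]
        kernels = kernels or r["kernels"]
        small_kernel = small_kernel or r["small_kernel"]
        blocks = blocks or r["blocks"]
        input_size = input_size or r["input_size"]
    else:
        raise ValueError(f"unknown replknet variant {variant!r}")
    if not (len(channels) == len(kernels) == len(blocks) == 4):
        raise ValueError("replknet takes exactly four stages")
    if input_size % 32:
        raise ValueError("input_size must be a multiple of 32")

    rng = np.random.default_rng(seed)
    layers: list[tuple[str, Layer]] = []
    taps: list[tuple[str, int]] = []

    def conv(name: str, spec: ConvSpec, bn: bool = True, relu: bool = True) -> None:
        layers.append((name, Conv2d(spec, he_conv(rng, spec), None)))
        if bn:
            layers.append((f"{name}_bn", _bn_identity(spec.out_channels)))
        if relu:
            layers.append((f"{name}_relu", ReLU()))

    c0 = channels[0]
    # stem: /4 total downsampling
    conv("stem_conv1", ConvSpec(3, 3, c0, stride=2, padding=1))
    conv("stem_dw1", ConvSpec(3, c0, c0, stride=1, padding=1, groups=c0))
    conv("stem_pw", ConvSpec(1, c0, c0))
    conv("stem_dw2", ConvSpec(3, c0, c0, stride=2, padding=1, groups=c0))

    c_in = c0
    for si, (c, k, nb) in enumerate(zip(channels, kernels, blocks), start=1):
        if si > 1:
            conv(f"trans{si}_pw", ConvSpec(1, c_in, c))
            conv(f"trans{si}_dw", ConvSpec(3, c, c, stride=2, padding=1, groups=c))
            c_in = c
        for bi in range(1, nb + 1):
            branch = make_reparam_branch(rng, c, k, min(small_kernel, k))
            dw: Layer = ReparamConv2d(branch)
            if fused:
                dw = dw.fuse()
            pw_spec = ConvSpec(1, c, c)
            body: list[Layer] = [
                _bn_identity(c),
                dw,
                ReLU(),
                Conv2d(pw_spec, he_conv(rng, pw_spec), None),
            ]
            layers.append((f"stage{si}_block{bi}", Residual(body)))
            layers.append((f"stage{si}_block{bi}_relu", ReLU()))
        taps.append((f"stage{si}", len(layers) - 1))

    graph = BackboneGraph(
        name="replknet" if variant == "31B" else f"replknet-{variant}",
        layers=layers,
        taps=taps,
        input_shape=(3, input_size, input_size),
        seed=seed,
        meta={"family": "replknet", "variant": variant, "fused": fused},
    )
    if weights_path is not None:
        load_weights(graph, weights_path)
    return graph


# ---------------------------------------------------------------------------
# forward features


def forward_features(graph: BackboneGraph, images: np.ndarray):
    """Run a batch through a backbone and collect one activation per tap.

    Returns a :class:`~voxenc.feature_space.FeatureStack` tagged ``V`` for the
    VGG16-style graph (its six taps *are* the V features) and ``raw`` for any
    other graph.
    """
    from .feature_space import FeatureStack  # local import avoids a cycle

    acts = graph.forward(images)
    for name, a in acts.items():
        if not np.all(np.isfinite(a)):
            raise ValueError(f"non-finite activation at tap {name!r}")
    source = "V" if graph.meta.get("family") == "vgg16" else "raw"
    return FeatureStack(source=source, layers=acts, backbone=graph.name,
                        fingerprint=graph.fingerprint())


# ---------------------------------------------------------------------------
# weight files


def save_weights(graph: BackboneGraph, path: str) -> None:
    """Write all parameters to a flat hierarchical HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["name"] = graph.name
        for name, layer in graph.layers:
            for key, arr in _layer_arrays(layer).items():
                f.create_dataset(f"{name}/{key}", data=arr)


def load_weights(graph: BackboneGraph, path: str) -> None:
    """Assign parameters from a weight file, validating shapes first."""
    import h5py

    with h5py.File(path, "r") as f:
        # validate everything before assigning anything
        for name, layer in graph.layers:
            for key, arr in _layer_arrays(layer).items():
                ds = f.get(f"{name}/{key}")
                if ds is None:
                    raise ValueError(f"weight file missing {name}/{key}")
                if tuple(ds.shape) != arr.shape:
                    raise ValueError(
                        f"shape mismatch at {name}/{key}: file has "
                        f"{tuple(ds.shape)}, graph expects {arr.shape}"
                    )
        for name, layer in graph.layers:
            for key, arr in _layer_arrays(layer).items():
                arr[...] = f[f"{name}/{key}"][...]
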