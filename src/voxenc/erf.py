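"""Effective receptive field (ERF) quantification for backbone graphs.

The ERF of a deep unit is the input region that actually influences its
output — typically far smaller than the theoretical receptive field.  It is
measured here by a contribution-score heatmap: for seeded random probe
images, the sensitivity of the central spatial unit of the deepest feature
tap (summed over channels) to every input pixel is accumulated by a backward
pass, absolute values are summed over input channels and averaged over
probes, and the map is normalized to peak 1.  A scalar summary is the side
length of the smallest centered square window holding a given fraction
(default 95%) of the total score mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .backbones import BackboneGraph
from .nn import Conv2d, ConvSpec, ReLU, he_conv


@dataclass
class ERFMap:
    """Non-negative contribution-score grid over input pixels, peak 1."""

    scores: np.ndarray
    backbone: str
    n_probes: int
    normalized: bool = True

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("score grid must be 2-D")
        if np.any(self.scores < 0):
            raise ValueError("scores must be non-negative")
        if self.normalized and self.scores.size and self.scores.max() > 0:
            if not np.isclose(self.scores.max(), 1.0):
                raise ValueError("a normalized map must have peak 1")


def erf_heatmap(
    graph: BackboneGraph,
    n_probes: int = 32,
    seed: int = 0,
    linear_mode: bool = False,
) -> ERFMap:
    """Contribution scores of input pixels to the central unit of the last tap.

    Probe inputs are standard-normal random images.  ``linear_mode`` treats
    every ReLU as the identity, which makes the nonzero support exactly the
    theoretical receptive field of linear conv stacks (used by the analytic
    checks); by default nonlinearities stay active, matching the network as
    deployed.
    """
    if n_probes < 1:
        raise ValueError("need at least one probe")
    rng = np.random.default_rng(seed)
    c, h, w = graph.input_shape
    acc = np.zeros((h, w))

    relu_masks: list[tuple[int, ReLU]] = []
    if linear_mode:
        for i, (_, layer) in enumerate(graph.layers):
            if isinstance(layer, ReLU):
                relu_masks.append((i, layer))

    for _ in range(n_probes):
        x = rng.standard_normal((1, c, h, w))
        if linear_mode:
            y, caches = _forward_linear(graph, x)
        else:
            y, caches = graph.forward_with_cache(x)
        gy = np.zeros_like(y)
        gy[:, :, y.shape[2] // 2, y.shape[3] // 2] = 1.0  # all channels, center
        gx = graph.backward_to_input(gy, caches)
        acc += np.abs(gx[0]).sum(axis=0)

    acc /= n_probes
    peak = acc.max()
    if peak > 0:
        acc = acc / peak
    return ERFMap(acc, graph.name, n_probes)


def _forward_linear(graph: BackboneGraph, x: np.ndarray):
    """Forward through the last tap with every ReLU as identity."""
    last = graph.taps[-1][1]
    caches = []
    for _, layer in graph.layers[: last + 1]:
        if isinstance(layer, ReLU):
            caches.append(np.ones(x.shape, dtype=bool))
        else:
            x, c = layer.forward(x)
            caches.append(c)
            continue
    return x, caches


def erf_size(erf_map: ERFMap, mass_fraction: float = 0.95) -> int:
    """Side length of the smallest centered square holding the mass fraction.

    The window is centered on the pixel aligned with the probed output unit
    (index ``size // 2`` along each axis).
    """
    if not 0 < mass_fraction <= 1:
        raise ValueError("mass_fraction must lie in (0, 1]")
    s = erf_map.scores
    total = s.sum()
    if total == 0:
        raise ValueError("empty (all-zero) ERF map")
    h, w = s.shape
    cr, cc = h // 2, w // 2
    target = mass_fraction * total
    for side in range(1, max(h, w) * 2 + 2):
        lo = (side - 1) // 2
        hi = side // 2
        r0, r1 = max(0, cr - lo), min(h, cr + hi + 1)
        c0, c1 = max(0, cc - lo), min(w, cc + hi + 1)
        if s[r0:r1, c0:c1].sum() >= target - 1e-12 * total:
            return side
    return max(h, w)  # unreachable: the full map holds all mass


def compare_erf(
    graphs: list[BackboneGraph],
    n_probes: int = 32,
    seed: int = 0,
    mass_fraction: float = 0.95,
    linear_mode: bool = False,
) -> pd.DataFrame:
    """ERF size per backbone, one row each, deterministic given the seed."""
    rows = []
    for g in graphs:
        m = erf_heatmap(g, n_probes=n_probes, seed=seed, linear_mode=linear_mode)
        rows.append(
            {
                "backbone": g.name,
                "input_size": g.input_shape[1],
                "erf_size": erf_size(m, mass_fraction),
            }
        )
    return pd.DataFrame(rows)


def build_conv_stack(
    kernel_size: int,
    depth: int = 1,
    channels: int = 2,
    input_size: int | None = None,
    seed: int = 0,
    relu: bool = False,
    name: str | None = None,
) -> BackboneGraph:
    """Single-path conv stack (same-padding, stride 1) for ERF probing.

    Handy for analytic receptive-field checks and matched-depth kernel-size
    comparisons; the theoretical receptive field is depth*(k-1)+1 pixels.
    """
    if kernel_size % 2 == 0:
        raise ValueError("use odd kernels so the output center is well-defined")
    rf = depth * (kernel_size - 1) + 1
    if input_size is None:
        input_size = rf + (1 - rf % 2) + 8  # odd, comfortably larger than the RF
    rng = np.random.default_rng(seed)
    layers = []
    c_in = 3
    for d in range(depth):
        spec = ConvSpec(kernel_size, c_in, channels, stride=1, padding=kernel_size // 2)
        layers.append((f"conv{d + 1}", Conv2d(spec, he_conv(rng, spec))))
        if relu and d < depth - 1:
            layers.append((f"relu{d + 1}", ReLU()))
        c_in = channels
    return BackboneGraph(
        name=name or f"stack-k{kernel_size}-d{depth}",
        layers=layers,
        taps=[("out", len(layers) - 1)],
        input_shape=(3, input_size, input_size),
        seed=seed,
        meta={"family": "stack"},
    )


def save_heatmap(erf_map: ERFMap, array_path: str, image_path: str | None = None) -> None:
    """Persist a heatmap as a text array and optionally a rendered image."""
    np.savetxt(array_path, erf_map.scores)
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(erf_map.scores, cmap="viridis")
        ax.set_title(f"ERF: {erf_map.backbone}")
        ax.axis("off")
        fig.savefig(image_path, bbox_inches="tight", dpi=120)
        plt.close(fig)
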