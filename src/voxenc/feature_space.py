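"""Multi-layer feature stacks: R features, V features, and the merged M features.

The VGG16-style backbone contributes six layers of features (block outputs
plus the final pooled output, the *V features*); the RepLKNet-style backbone
contributes five (the four stage outputs plus an L2-normalized copy of the
deepest stage, the *R features*).  Merging flattens each stack per image and
concatenates V-first with equal weighting, giving the *M feature* vector that
the voxel-wise regression consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .backbones import BackboneGraph, forward_features


@dataclass
class FeatureStack:
    """Ordered named per-layer activations for a batch of images.

    ``source`` tags the stack as R, V, M (or ``raw`` for untagged taps);
    ``layers`` maps layer name to a ``(batch, ...)`` array in fixed
    shallow-to-deep order.
    """

    source: str
    layers: dict[str, np.ndarray]
    backbone: str = ""
    fingerprint: str = ""

    def __post_init__(self) -> None:
        sizes = {a.shape[0] for a in self.layers.values()}
        if len(sizes) > 1:
            raise ValueError(f"inconsistent batch sizes across layers: {sizes}")
        if self.source == "R" and len(self.layers) != 5:
            raise ValueError("an R stack has exactly 5 layers")
        if self.source == "V" and len(self.layers) != 6:
            raise ValueError("a V stack has exactly 6 layers")

    @property
    def batch_size(self) -> int:
        return next(iter(self.layers.values())).shape[0]

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def layer_shapes(self) -> dict[str, tuple[int, ...]]:
        return {k: v.shape[1:] for k, v in self.layers.items()}

    def width(self) -> int:
        """Flattened feature count per image."""
        return sum(int(np.prod(s)) for s in self.layer_shapes().values())


def normalize_layer(activation: np.ndarray) -> np.ndarray:
    """Per-image global L2 normalization over all channel x spatial elements.

    A zero activation maps to zero; any non-zero activation comes out with
    unit Euclidean norm.
    """
    activation = np.asarray(activation, dtype=float)
    if not np.all(np.isfinite(activation)):
        raise ValueError("normalize_layer requires finite input")
    flat = activation.reshape(activation.shape[0], -1)
    norms = np.linalg.norm(flat, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    return activation / safe.reshape((-1,) + (1,) * (activation.ndim - 1))


def extract_V(vgg_graph: BackboneGraph, images: np.ndarray) -> FeatureStack:
    """Six-layer V features: block A..E outputs plus the post-pool output."""
    if vgg_graph.meta.get("family") != "vgg16":
        raise ValueError("extract_V expects a vgg16-family graph")
    stack = forward_features(vgg_graph, images)
    return FeatureStack("V", stack.layers, stack.backbone, stack.fingerprint)


def extract_R(replk_graph: BackboneGraph, images: np.ndarray) -> FeatureStack:
    """Five-layer R features: stage 1..4 outputs plus normalized stage 4."""
    if replk_graph.meta.get("family") != "replknet":
        raise ValueError("extract_R expects a replknet-family graph")
    stack = forward_features(replk_graph, images)
    layers = dict(stack.layers)
    last = list(layers)[-1]
    layers[f"{last}_norm"] = normalize_layer(layers[last])
    return FeatureStack("R", layers, stack.backbone, stack.fingerprint)


def flatten_stack(stack: FeatureStack) -> tuple[np.ndarray, list[tuple[str, tuple[int, ...]]]]:
    """One row-major feature vector per image, layers concatenated in order.

    Returns the ``(batch, width)`` matrix and the shape metadata needed to
    invert the operation.
    """
    meta = [(name, arr.shape[1:]) for name, arr in stack.layers.items()]
    b = stack.batch_size
    X = np.concatenate([arr.reshape(b, -1) for arr in stack.layers.values()], axis=1)
    return X, meta


def unflatten_stack(
    X: np.ndarray, meta: list[tuple[str, tuple[int, ...]]], source: str = "raw"
) -> FeatureStack:
    widths = [int(np.prod(s)) for _, s in meta]
    if X.shape[1] != sum(widths):
        raise ValueError(f"width {X.shape[1]} does not match metadata {sum(widths)}")
    layers = {}
    at = 0
    for (name, shape), w in zip(meta, widths):
        layers[name] = X[:, at : at + w].reshape((X.shape[0],) + tuple(shape))
        at += w
    return FeatureStack(source, layers)


def merge_features(v_stack: FeatureStack, r_stack: FeatureStack) -> FeatureStack:
    """Concatenate V and R stacks per image (V first, equal weighting)."""
    if v_stack.batch_size != r_stack.batch_size:
        raise ValueError(
            f"batch mismatch: V has {v_stack.batch_size}, R has {r_stack.batch_size}"
        )
    layers = {f"V/{k}": v for k, v in v_stack.layers.items()}
    layers.update({f"R/{k}": v for k, v in r_stack.layers.items()})
    fp = f"{v_stack.fingerprint}+{r_stack.fingerprint}"
    return FeatureStack("M", layers, f"{v_stack.backbone}+{r_stack.backbone}", fp)


# ---------------------------------------------------------------------------
# on-disk container


def save_features(path: str, stacks: dict[str, FeatureStack]) -> None:
    """Write stacks to an HDF5 container, one group per source tag.

    Layout: ``/<tag>/<layer>`` datasets plus a ``/meta`` JSON attribute
    recording layer order, shapes and backbone fingerprints.
    """
    import h5py

    meta = {}
    with h5py.File(path, "w") as f:
        for tag, stack in stacks.items():
            grp = f.create_group(tag)
            for name, arr in stack.layers.items():
                grp.create_dataset(name.replace("/", "|"), data=np.asarray(arr, dtype=np.float32))
            meta[tag] = {
                "source": stack.source,
                "order": stack.layer_names,
                "shapes": {k: list(v) for k, v in stack.layer_shapes().items()},
                "backbone": stack.backbone,
                "fingerprint": stack.fingerprint,
            }
        f.attrs["meta"] = json.dumps(meta)


def load_features(path: str) -> dict[str, FeatureStack]:
    import h5py

    out = {}
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        for tag, m in meta.items():
            layers = {
                name: f[tag][name.replace("/", "|")][...].astype(float)
                for name in m["order"]
            }
            out[tag] = FeatureStack(m["source"], layers, m["backbone"], m["fingerprint"])
    return out
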