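"""Expansion ("granule") layers: Gaussian-kernel banks and random projections.

A kernel layer stores ``m`` centers, each an exact copy of a training sample,
and maps an input to the vector of Gaussian-kernel similarities

    k(x, x_j) = exp(-||x - x_j||^2 / (2 sigma_j^2)) / (sqrt(2 pi) sigma_j),

so the hidden unit ``j`` responds maximally when the input reproduces the
stored pattern ``x_j``.  The random-projection layer is the "lazy" control:
a fixed Gaussian weight matrix with an optional pointwise nonlinearity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from ._seeding import substream
from .errors import InvalidParameterError

__all__ = [
    "KernelLayer",
    "RandomProjectionLayer",
    "gaussian_kernel",
    "kernel_features",
    "random_projection_features",
    "sample_projection_layer",
    "layer_features",
    "ACTIVATIONS",
]

_SQRT_2PI = float(np.sqrt(2.0 * np.pi))

ACTIVATIONS = {
    "identity": lambda z: z,
    "relu": lambda z: np.maximum(z, 0.0),
    "tanh": np.tanh,
}


@dataclass
class KernelLayer:
    """Bank of Gaussian kernels centered on stored training samples."""

    centers: np.ndarray  # (m, p), every row a training sample
    widths: np.ndarray  # (m,) positive
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        widths = np.asarray(self.widths, dtype=float)
        if widths.ndim == 0:
            widths = np.full(len(self.centers), float(widths))
        self.widths = widths
        if len(self.widths) != len(self.centers):
            raise InvalidParameterError("one width per center required")
        if np.any(self.widths <= 0):
            raise InvalidParameterError("kernel widths must be positive")

    @property
    def m(self) -> int:
        return self.centers.shape[0]

    def to_json(self, path) -> None:
        payload = {
            "centers": self.centers.tolist(),
            "widths": self.widths.tolist(),
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "KernelLayer":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["centers"]), np.asarray(d["widths"]), d.get("provenance", {}))


@dataclass
class RandomProjectionLayer:
    """Fixed Gaussian random projection with a pointwise activation."""

    weights: np.ndarray  # (p, m)
    hidden_bias: np.ndarray  # (m,)
    activation: str = "relu"

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.hidden_bias = np.asarray(self.hidden_bias, dtype=float)
        if self.weights.ndim != 2:
            raise InvalidParameterError("weights must be a (p, m) matrix")
        if self.hidden_bias.shape != (self.weights.shape[1],):
            raise InvalidParameterError("hidden_bias length must equal hidden dim")
        if self.activation not in ACTIVATIONS:
            raise InvalidParameterError(f"unknown activation {self.activation!r}")

    @property
    def m(self) -> int:
        return self.weights.shape[1]


def gaussian_kernel(x: np.ndarray, center: np.ndarray, width: float = 1.0) -> float:
    """Evaluate one Gaussian kernel; peak value is ``1 / (sqrt(2 pi) width)``."""
    if width <= 0:
        raise InvalidParameterError("width must be positive")
    x = np.asarray(x, dtype=float)
    center = np.asarray(center, dtype=float)
    if x.shape != center.shape:
        raise InvalidParameterError(f"shape mismatch: {x.shape} vs {center.shape}")
    sq = float(np.sum((x - center) ** 2))
    return float(np.exp(-sq / (2.0 * width**2)) / (_SQRT_2PI * width))


def kernel_features(X: np.ndarray, layer: KernelLayer) -> np.ndarray:
    """Kernel similarity of every row of ``X`` to every stored center."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != layer.centers.shape[1]:
        raise InvalidParameterError(
            f"input dim {X.shape[1]} != center dim {layer.centers.shape[1]}"
        )
    sq = cdist(X, layer.centers, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * layer.widths**2)) / (_SQRT_2PI * layer.widths)


def random_projection_features(X: np.ndarray, layer: RandomProjectionLayer) -> np.ndarray:
    """Activation of the random-projection hidden layer for each input row."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != layer.weights.shape[0]:
        raise InvalidParameterError(
            f"input dim {X.shape[1]} != weight rows {layer.weights.shape[0]}"
        )
    return ACTIVATIONS[layer.activation](X @ layer.weights + layer.hidden_bias)


def sample_projection_layer(
    p: int,
    m: int,
    seed: int = 0,
    activation: str = "relu",
    weight_std: float = 3.0,
    bias_std: float = 3.0,
) -> RandomProjectionLayer:
    """Draw projection weights i.i.d. N(0, weight_std^2); seeded and repeatable.

    Biases are drawn from the same family so ReLU units hinge at diverse
    positions instead of all folding at the origin.
    """
    if p < 1 or m < 1:
        raise InvalidParameterError("p and m must be >= 1")
    rng = substream(seed, "projection")
    W = rng.normal(0.0, weight_std, size=(p, m))
    b = rng.normal(0.0, bias_std, size=m)
    return RandomProjectionLayer(W, b, activation)


def layer_features(X: np.ndarray, layer) -> np.ndarray:
    """Dispatch to the feature map matching the layer type."""
    if isinstance(layer, KernelLayer):
        return kernel_features(X, layer)
    if isinstance(layer, RandomProjectionLayer):
        return random_projection_features(X, layer)
    raise InvalidParameterError(f"unknown layer type {type(layer).__name__}")
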