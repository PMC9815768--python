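"""Synthetic entangled Gaussian-mixture classification tasks.

Two classes are generated as a mixture of ``2K`` isotropic Gaussian clusters
whose centers live in a bounded two-dimensional "relevant" subspace.  Each
sampled point is labelled by the class of its *nearest* cluster center (not
the class of the cluster that generated it), which entangles the classes
increasingly as ``K`` grows.  Labels are then corrupted with independent flip
noise, and task-irrelevant input dimensions — uniform draws spanning the same
range as the relevant dimensions — can be appended to emulate mossy-fiber
channels that carry no task information.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from ._seeding import substream
from .errors import InvalidParameterError, InvalidSpecError

__all__ = [
    "MixtureTaskSpec",
    "LabeledDataset",
    "build_task_spec",
    "sample_dataset",
    "nearest_center_labels",
    "corrupt_labels",
    "append_irrelevant_dims",
    "split_train_test",
    "write_dataset",
    "read_dataset",
]

LABELS = (-1, 1)


@dataclass(frozen=True)
class MixtureTaskSpec:
    """Generative description of one classification task.

    Parameters
    ----------
    K : int
        Clusters per class; the mixture has ``2K`` clusters in total.
    center_positions : ndarray of shape (2K, 2)
        Cluster centers in the relevant subspace.
    center_classes : ndarray of shape (2K,)
        Class label (−1 or +1) of each center; both classes must appear.
    cluster_sigma : float
        Isotropic within-cluster standard deviation, shared by all clusters.
    label_noise_rate : float
        Independent label-flip probability in ``[0, 1)``.
    n_irrelevant : int
        Number of uniform task-irrelevant dimensions appended after labelling.
    relevant_range : tuple of (low, high) pairs
        Bounding interval of each relevant dimension; irrelevant dimensions
        are drawn uniformly over the union of these intervals.
    seed : int
        Seed used to lay out centers (recorded so the spec is regenerable).
    """

    K: int
    center_positions: np.ndarray
    center_classes: np.ndarray
    cluster_sigma: float
    label_noise_rate: float = 0.05
    n_irrelevant: int = 0
    relevant_range: tuple = ((0.0, 1.0), (0.0, 1.0))
    seed: int = 0

    def __post_init__(self):
        pos = np.asarray(self.center_positions, dtype=float)
        cls = np.asarray(self.center_classes, dtype=int)
        object.__setattr__(self, "center_positions", pos)
        object.__setattr__(self, "center_classes", cls)
        if self.K < 1:
            raise InvalidSpecError("K must be >= 1")
        if pos.shape != (2 * self.K, 2):
            raise InvalidSpecError(f"expected {2 * self.K} centers in 2-D, got {pos.shape}")
        if cls.shape != (2 * self.K,):
            raise InvalidSpecError("center_classes length must equal 2K")
        if not set(np.unique(cls)) == set(LABELS):
            raise InvalidSpecError("both classes must appear among center_classes")
        if self.cluster_sigma <= 0:
            raise InvalidSpecError("cluster_sigma must be positive")
        if not 0.0 <= self.label_noise_rate < 1.0:
            raise InvalidSpecError("label_noise_rate must be in [0, 1)")
        if self.n_irrelevant < 0:
            raise InvalidSpecError("n_irrelevant must be >= 0")

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "center_positions": self.center_positions.tolist(),
            "center_classes": self.center_classes.tolist(),
            "cluster_sigma": self.cluster_sigma,
            "label_noise_rate": self.label_noise_rate,
            "n_irrelevant": self.n_irrelevant,
            "relevant_range": [list(r) for r in self.relevant_range],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureTaskSpec":
        d = dict(d)
        d["relevant_range"] = tuple(tuple(r) for r in d["relevant_range"])
        return cls(**d)


@dataclass
class LabeledDataset:
    """A feature matrix with binary labels and provenance metadata."""

    features: np.ndarray  # (n, p)
    labels: np.ndarray  # (n,) in {-1, +1}
    relevant_dims: tuple = (0, 1)
    role: str = "unsplit"
    relevant_range: tuple = ((0.0, 1.0), (0.0, 1.0))
    cluster_ids: np.ndarray | None = None  # generating cluster, diagnostics only

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise InvalidSpecError("features must be 2-D")
        if len(self.labels) != len(self.features):
            raise InvalidSpecError("labels length must match feature rows")
        bad = set(np.unique(self.labels)) - set(LABELS)
        if bad:
            raise InvalidSpecError(f"labels must be in {{-1, +1}}, found {bad}")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]


def build_task_spec(
    K: int,
    n_irrelevant: int = 0,
    seed: int = 0,
    extent: float = 1.0,
    cluster_sigma: float | None = None,
    label_noise_rate: float = 0.05,
) -> MixtureTaskSpec:
    """Lay out ``2K`` cluster centers uniformly inside ``[0, extent]^2``.

    Center classes are assigned uniformly at random, redrawn until both
    classes are represented.  The default spread ``sigma = 0.5 / sqrt(2K)``
    shrinks with the cluster count so that neighbouring clusters overlap
    moderately at every complexity level.
    """
    if K < 1:
        raise InvalidSpecError("K must be >= 1")
    rng = substream(seed, "task-layout")
    centers = rng.uniform(0.0, extent, size=(2 * K, 2))
    classes = rng.choice(LABELS, size=2 * K)
    while len(np.unique(classes)) < 2:
        classes = rng.choice(LABELS, size=2 * K)
    sigma = cluster_sigma if cluster_sigma is not None else 0.5 / np.sqrt(2 * K)
    return MixtureTaskSpec(
        K=K,
        center_positions=centers,
        center_classes=classes,
        cluster_sigma=sigma,
        label_noise_rate=label_noise_rate,
        n_irrelevant=n_irrelevant,
        relevant_range=((0.0, extent), (0.0, extent)),
        seed=seed,
    )


def nearest_center_labels(X_rel: np.ndarray, spec: MixtureTaskSpec) -> np.ndarray:
    """Class of the nearest cluster center (Euclidean, relevant subspace)."""
    d = cdist(np.asarray(X_rel, dtype=float), spec.center_positions)
    return spec.center_classes[np.argmin(d, axis=1)]


def sample_dataset(spec: MixtureTaskSpec, n: int, seed: int = 0) -> LabeledDataset:
    """Draw ``n`` points from the mixture and label them by nearest center.

    Each point picks a cluster uniformly over the ``2K`` clusters, then adds
    isotropic Gaussian noise with std ``cluster_sigma``.  The label is the
    class of the nearest center, which need not be the generating cluster.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = substream(seed, "sample")
    cluster = rng.integers(0, 2 * spec.K, size=n)
    X = spec.center_positions[cluster] + rng.normal(0.0, spec.cluster_sigma, size=(n, 2))
    y = nearest_center_labels(X, spec)
    return LabeledDataset(
        features=X,
        labels=y,
        relevant_dims=(0, 1),
        role="unsplit",
        relevant_range=spec.relevant_range,
        cluster_ids=cluster,
    )


def corrupt_labels(labels: np.ndarray, rate: float, seed: int = 0) -> np.ndarray:
    """Flip each label independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise InvalidParameterError("rate must be in [0, 1)")
    labels = np.asarray(labels)
    if rate == 0.0:
        return labels.copy()
    rng = substream(seed, "label-noise")
    flip = rng.random(len(labels)) < rate
    return np.where(flip, -labels, labels)


def append_irrelevant_dims(dataset: LabeledDataset, n_irrelevant: int, seed: int = 0) -> LabeledDataset:
    """Append uniform task-irrelevant columns spanning the relevant range."""
    if n_irrelevant < 0:
        raise InvalidParameterError("n_irrelevant must be >= 0")
    if n_irrelevant == 0:
        return dataset
    lo = min(r[0] for r in dataset.relevant_range)
    hi = max(r[1] for r in dataset.relevant_range)
    rng = substream(seed, "irrelevant")
    extra = rng.uniform(lo, hi, size=(dataset.n, n_irrelevant))
    return LabeledDataset(
        features=np.hstack([dataset.features, extra]),
        labels=dataset.labels.copy(),
        relevant_dims=dataset.relevant_dims,
        role=dataset.role,
        relevant_range=dataset.relevant_range,
        cluster_ids=dataset.cluster_ids,
    )


def split_train_test(
    dataset: LabeledDataset, train_fraction: float = 0.7, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Disjoint random partition into train and test subsets."""
    if not 0.0 < train_fraction < 1.0:
        raise InvalidParameterError("train_fraction must be in (0, 1)")
    rng = substream(seed, "split")
    perm = rng.permutation(dataset.n)
    n_train = int(round(train_fraction * dataset.n))
    n_train = min(max(n_train, 1), dataset.n - 1)
    parts = []
    for idx, role in ((perm[:n_train], "train"), (perm[n_train:], "test")):
        parts.append(
            LabeledDataset(
                features=dataset.features[idx],
                labels=dataset.labels[idx],
                relevant_dims=dataset.relevant_dims,
                role=role,
                relevant_range=dataset.relevant_range,
                cluster_ids=None if dataset.cluster_ids is None else dataset.cluster_ids[idx],
            )
        )
    return parts[0], parts[1]


def generate_task(
    K: int,
    n_samples: int,
    n_irrelevant: int = 0,
    label_noise_rate: float = 0.05,
    train_fraction: float = 0.7,
    seed: int = 0,
    cluster_sigma: float | None = None,
) -> tuple[LabeledDataset, LabeledDataset, MixtureTaskSpec]:
    """Full generation pipeline: layout, sample, label-noise, augment, split."""
    spec = build_task_spec(
        K,
        n_irrelevant=n_irrelevant,
        seed=seed,
        cluster_sigma=cluster_sigma,
        label_noise_rate=label_noise_rate,
    )
    ds = sample_dataset(spec, n_samples, seed=seed)
    ds.labels = corrupt_labels(ds.labels, label_noise_rate, seed=seed)
    ds = append_irrelevant_dims(ds, n_irrelevant, seed=seed)
    train, test = split_train_test(ds, train_fraction, seed=seed)
    return train, test, spec


def write_dataset(dataset: LabeledDataset, csv_path, spec: MixtureTaskSpec | None = None) -> None:
    """Write a headered CSV (x1..xp, label); optional spec sidecar JSON."""
    cols = {f"x{i + 1}": dataset.features[:, i] for i in range(dataset.p)}
    cols["label"] = dataset.labels
    pd.DataFrame(cols).to_csv(csv_path, index=False)
    if spec is not None:
        side = str(csv_path).rsplit(".", 1)[0] + ".spec.json"
        with open(side, "w") as fh:
            json.dump(spec.to_dict(), fh, indent=2)


def read_dataset(csv_path, role: str = "unsplit") -> LabeledDataset:
    df = pd.read_csv(csv_path)
    feat_cols = [c for c in df.columns if c != "label"]
    return LabeledDataset(
        features=df[feat_cols].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=int),
        role=role,
    )
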