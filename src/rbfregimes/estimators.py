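"""Scikit-learn style estimators wrapping the expansion + readout pipeline.

Both classifiers accept arbitrary binary label encodings; internally labels
are mapped to {-1, +1} so the least-squares readout's sign rule is symmetric.
"""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from ._seeding import child_seed
from .datasets import LabeledDataset
from .errors import InvalidTaskError
from .expansion import KernelLayer, kernel_features, layer_features, sample_projection_layer
from .readout import DEFAULT_RIDGE, decision_scores, scores_to_labels, solve_readout
from .regimes import RegimeSpec, resolve_spec, select_centers

__all__ = ["RandomProjectionClassifier", "KernelRegimeClassifier"]


def _encode_binary(y: np.ndarray):
    classes = np.unique(y)
    if len(classes) != 2:
        raise InvalidTaskError(f"expected exactly 2 classes, got {len(classes)}")
    signed = np.where(y == classes[1], 1, -1)
    return classes, signed


def _as_seed(random_state) -> int:
    if random_state is None:
        return 0
    if isinstance(random_state, numbers.Integral):
        return int(random_state)
    raise ValueError("random_state must be an int or None")


class _ExpansionReadoutBase(ClassifierMixin, BaseEstimator):
    """Shared predict path: expansion layer features -> linear readout."""

    def decision_function(self, X):
        check_is_fitted(self, "readout_")
        X = check_array(X)
        return decision_scores(layer_features(X, self.layer_), self.readout_)

    def predict(self, X):
        signed = scores_to_labels(self.decision_function(X))
        return self.classes_[(signed > 0).astype(int)]


class RandomProjectionClassifier(_ExpansionReadoutBase):
    """Fixed random projection ("lazy" expansion) with a least-squares readout.

    Parameters
    ----------
    n_hidden : int
        Hidden-layer dimension ``m``.
    activation : {"relu", "tanh", "identity"}
        Pointwise nonlinearity; ``"identity"`` is the linear control.
    weight_std, bias_std : float
        Std of the zero-mean Gaussian projection weights and hidden biases.
    ridge : float
        Ridge stabiliser of the closed-form readout.
    random_state : int or None
        Seed for the projection draw.
    """

    def __init__(
        self,
        n_hidden: int = 100,
        activation: str = "relu",
        weight_std: float = 3.0,
        bias_std: float = 3.0,
        ridge: float = DEFAULT_RIDGE,
        random_state=None,
    ):
        self.n_hidden = n_hidden
        self.activation = activation
        self.weight_std = weight_std
        self.bias_std = bias_std
        self.ridge = ridge
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, signed = _encode_binary(y)
        self.n_features_in_ = X.shape[1]
        self.layer_ = sample_projection_layer(
            X.shape[1],
            self.n_hidden,
            seed=_as_seed(self.random_state),
            activation=self.activation,
            weight_std=self.weight_std,
            bias_std=self.bias_std,
        )
        H = layer_features(X, self.layer_)
        self.readout_ = solve_readout(H, signed, self.ridge)
        return self


class KernelRegimeClassifier(_ExpansionReadoutBase):
    """Budgeted Gaussian-kernel expansion with regime-selected centers.

    ``fit`` selects ``n_centers`` training samples under the chosen regime,
    stores them as kernel centers, and solves the linear readout in closed
    form.  For the regular regime, whose published evaluation averages many
    random coordinate subsets, the fitted model uses the first subset; the
    subset-averaged evaluation lives in :mod:`rbfregimes.experiment`.

    Parameters
    ----------
    regime : str
        One of random, regular, frequency, kmeans, support_vector, novelty.
    n_centers : int
        Kernel budget ``m``.
    width : float
        Shared Gaussian kernel width sigma (field default 1.0).
    v, delta : int, float
        Frequency lattice resolution and novelty admission threshold; set
        ``tune_hyperparams=True`` to pick them on a validation split instead.
    lattice_range : tuple of (low, high) pairs or None
        Declared input range used by lattice-based regimes; the empirical
        range is used when None.
    """

    def __init__(
        self,
        regime: str = "random",
        n_centers: int = 20,
        width: float = 1.0,
        v: int = 8,
        delta: float = 0.5,
        n_subsets: int = 100,
        ridge: float = DEFAULT_RIDGE,
        svm_C: float = 1.0,
        svm_max_fit: int = 2000,
        novelty_rule: str = "sample_error",
        tune_hyperparams: bool = False,
        lattice_range=None,
        random_state=None,
    ):
        self.regime = regime
        self.n_centers = n_centers
        self.width = width
        self.v = v
        self.delta = delta
        self.n_subsets = n_subsets
        self.ridge = ridge
        self.svm_C = svm_C
        self.svm_max_fit = svm_max_fit
        self.novelty_rule = novelty_rule
        self.tune_hyperparams = tune_hyperparams
        self.lattice_range = lattice_range
        self.random_state = random_state

    def _regime_spec(self) -> RegimeSpec:
        return RegimeSpec(
            name=self.regime,
            m=self.n_centers,
            v=self.v,
            delta=self.delta,
            n_subsets=self.n_subsets,
            seed=child_seed(_as_seed(self.random_state), "estimator"),
            width=self.width,
            ridge=self.ridge,
            svm_C=self.svm_C,
            svm_max_fit=self.svm_max_fit,
            novelty_rule=self.novelty_rule,
        )

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, signed = _encode_binary(y)
        self.n_features_in_ = X.shape[1]
        train = LabeledDataset(
            features=X,
            labels=signed,
            relevant_dims=tuple(range(X.shape[1])),
            role="train",
            relevant_range=self.lattice_range,
        )
        spec = self._regime_spec()
        if self.tune_hyperparams:
            spec = resolve_spec(train, spec)
        self.selection_ = select_centers(train, spec)
        idx = self.selection_.primary()
        self.center_indices_ = idx
        self.layer_ = KernelLayer(
            X[idx].copy(),
            self.width,
            provenance={"regime": spec.name, "seed": spec.seed, "m": spec.m},
        )
        self.resolved_spec_ = spec
        H = kernel_features(X, self.layer_)
        self.readout_ = solve_readout(H, signed, self.ridge)
        return self
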