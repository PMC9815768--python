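"""Closed-form linear ("Purkinje") readout over hidden-layer features.

The readout weights solve the ridge-stabilised least-squares problem on
mean-centered hidden features,

    alpha = (Hc^T Hc + ridge I)^{-1} Hc^T y,      bias = mean(y),

solved by Cholesky factorisation of the normal equations rather than an
explicit inverse.  With labels in {-1, +1} classification is the sign of the
score; a score of exactly zero maps to +1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .errors import InvalidParameterError, RankDeficientError
from .expansion import layer_features

__all__ = ["ReadoutSolution", "solve_readout", "decision_scores", "predict", "accuracy"]

DEFAULT_RIDGE = 1e-8


@dataclass
class ReadoutSolution:
    alpha: np.ndarray  # (m,)
    bias: float
    feature_means: np.ndarray  # (m,) training column means used for centering
    ridge: float = DEFAULT_RIDGE

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha.tolist(),
            "bias": self.bias,
            "feature_means": self.feature_means.tolist(),
            "ridge": self.ridge,
        }


def _solve_spd(G: np.ndarray, b: np.ndarray, ridge: float) -> np.ndarray:
    A = G.copy()
    A[np.diag_indices_from(A)] += ridge
    try:
        return cho_solve(cho_factor(A, lower=True), b)
    except LinAlgError as exc:
        if ridge == 0.0:
            raise RankDeficientError(
                "normal equations are singular; supply ridge > 0"
            ) from exc
        # fall back to a least-squares solve for pathologically scaled inputs
        return np.linalg.lstsq(A, b, rcond=None)[0]


def solve_readout(H: np.ndarray, y: np.ndarray, ridge: float = DEFAULT_RIDGE) -> ReadoutSolution:
    """Fit the readout in closed form on raw hidden features ``H``."""
    H = np.atleast_2d(np.asarray(H, dtype=float))
    y = np.asarray(y, dtype=float)
    if H.shape[0] != len(y):
        raise InvalidParameterError("H rows must match y length")
    if ridge < 0:
        raise InvalidParameterError("ridge must be >= 0")
    mu = H.mean(axis=0)
    Hc = H - mu
    alpha = _solve_spd(Hc.T @ Hc, Hc.T @ y, ridge)
    return ReadoutSolution(alpha=alpha, bias=float(y.mean()), feature_means=mu, ridge=ridge)


def solve_readout_gram(
    G: np.ndarray,
    c: np.ndarray,
    colsum: np.ndarray,
    ysum: float,
    n: int,
    ridge: float = DEFAULT_RIDGE,
) -> ReadoutSolution:
    """Fit from running sufficient statistics of *raw* features.

    ``G = H^T H``, ``c = H^T y``, ``colsum = H^T 1``; centering is applied
    algebraically, so streaming callers never have to materialise ``H``.
    """
    mu = colsum / n
    Gc = G - n * np.outer(mu, mu)
    cc = c - mu * ysum
    alpha = _solve_spd(Gc, cc, ridge)
    return ReadoutSolution(alpha=alpha, bias=float(ysum / n), feature_means=mu, ridge=ridge)


def decision_scores(F: np.ndarray, solution: ReadoutSolution) -> np.ndarray:
    """Real-valued readout: centered features dotted with alpha, plus bias."""
    F = np.atleast_2d(np.asarray(F, dtype=float))
    if F.shape[1] != len(solution.alpha):
        raise InvalidParameterError("feature dim does not match alpha length")
    return (F - solution.feature_means) @ solution.alpha + solution.bias


def scores_to_labels(scores: np.ndarray) -> np.ndarray:
    """Sign decision rule with the tie broken toward +1."""
    return np.where(np.asarray(scores) >= 0.0, 1, -1)


def predict(X: np.ndarray, layer, solution: ReadoutSolution) -> tuple[np.ndarray, np.ndarray]:
    """Map raw inputs through the expansion layer and the fitted readout."""
    scores = decision_scores(layer_features(X, layer), solution)
    return scores, scores_to_labels(scores)


def accuracy(predicted: np.ndarray, actual: np.ndarray) -> float:
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.shape != actual.shape:
        raise InvalidParameterError("label vectors must have equal length")
    return float(np.mean(predicted == actual))
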