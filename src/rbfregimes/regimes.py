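"""Center-selection regimes for budgeted Gaussian-kernel expansion layers.

Given a training set and a kernel budget ``m``, each regime picks ``m``
training samples to serve as kernel centers ("which input patterns should a
limited pool of granule cells memorise?").  Four regimes are task-independent
(random, regular, frequency, k-means: they never read the labels) and two are
task-dependent (support-vector and novelty).  Every regime returns row
indices into the training matrix, so selected centers are always bit-exact
copies of training samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.svm import SVC

from ._seeding import child_seed, substream
from .datasets import LabeledDataset, split_train_test
from .errors import (
    DegenerateLatticeError,
    InsufficientDataError,
    InvalidParameterError,
    InvalidSpecError,
    InvalidTaskError,
)
from .expansion import KernelLayer, kernel_features
from .readout import (
    DEFAULT_RIDGE,
    accuracy,
    decision_scores,
    scores_to_labels,
    solve_readout,
    solve_readout_gram,
)

__all__ = [
    "REGIME_NAMES",
    "RegimeSpec",
    "CenterSelection",
    "select_centers",
    "select_random",
    "select_regular",
    "select_frequency",
    "select_kmeans",
    "select_support_vector",
    "select_novelty",
    "grid_search_hyperparams",
    "DEFAULT_V_GRID",
    "DEFAULT_DELTA_GRID",
]

REGIME_NAMES = ("random", "regular", "frequency", "kmeans", "support_vector", "novelty")

# Hyperparameter search grids for the frequency lattice resolution v and the
# novelty admission threshold delta.
DEFAULT_V_GRID = (4, 8, 16, 32)
DEFAULT_DELTA_GRID = (0.1, 0.25, 0.5, 1.0)


@dataclass(frozen=True)
class RegimeSpec:
    """Resolved configuration of one selection regime.

    Parameters
    ----------
    name : str
        One of :data:`REGIME_NAMES`.
    m : int
        Kernel budget (hidden-layer dimension).
    v : int
        Frequency regime: lattice bins per input dimension.
    delta : float
        Novelty regime: admission threshold on the prediction error.
    n_subsets : int
        Regular regime: number of random coordinate subsets evaluated.
    seed : int
        Master seed for the regime's randomness.
    width : float
        Gaussian kernel width used whenever a regime fits an internal model.
    ridge : float
        Ridge used by internal readout fits (novelty, grid search).
    svm_C : float
        Soft-margin cost of the support-vector selector.
    svm_max_fit : int
        Training-size cap for the support-vector selector fit; larger
        training sets are subsampled (seeded) before fitting the SVM.
    novelty_rule : str
        ``"sample_error"`` admits when the incoming sample's prediction error
        exceeds delta; ``"error_increase"`` admits when the error grew by
        more than delta since the previous streamed sample.
    novelty_max_stream : int or None
        Optional cap on the number of streamed samples.
    """

    name: str
    m: int
    v: int = 8
    delta: float = 0.5
    n_subsets: int = 1000
    seed: int = 0
    width: float = 1.0
    ridge: float = DEFAULT_RIDGE
    svm_C: float = 1.0
    svm_max_fit: int = 2000
    novelty_rule: str = "sample_error"
    novelty_max_stream: int | None = None

    def __post_init__(self):
        if self.name not in REGIME_NAMES:
            raise InvalidSpecError(f"unknown regime {self.name!r}")
        if self.m < 1:
            raise InvalidSpecError("m must be >= 1")
        if self.v < 1:
            raise InvalidSpecError("v must be >= 1")
        if self.delta <= 0:
            raise InvalidSpecError("delta must be > 0")
        if self.n_subsets < 1:
            raise InvalidSpecError("n_subsets must be >= 1")
        if self.novelty_rule not in ("sample_error", "error_increase"):
            raise InvalidSpecError(f"unknown novelty_rule {self.novelty_rule!r}")


@dataclass
class CenterSelection:
    """Indices of the chosen centers plus regime diagnostics.

    For the regular regime ``center_indices`` is a list of ``n_subsets``
    index arrays; for every other regime it is a single index array.
    """

    center_indices: object
    regime: RegimeSpec
    diagnostics: dict = field(default_factory=dict)

    def subsets(self) -> list[np.ndarray]:
        if self.regime.name == "regular":
            return list(self.center_indices)
        return [self.center_indices]

    def primary(self) -> np.ndarray:
        """A single representative center set (first subset for regular)."""
        return self.subsets()[0]


def _check_budget(train: LabeledDataset, spec: RegimeSpec) -> None:
    if spec.m > train.n:
        raise InsufficientDataError(f"m={spec.m} exceeds n_train={train.n}")


def _lattice_bounds(train: LabeledDataset) -> tuple[np.ndarray, np.ndarray]:
    """Per-dimension lattice bounds: the declared relevant range extended to
    every input dimension (irrelevant columns span the same range by
    construction), falling back to the empirical range when undeclared."""
    p = train.p
    if train.relevant_range is not None:
        lo = min(r[0] for r in train.relevant_range)
        hi = max(r[1] for r in train.relevant_range)
        return np.full(p, float(lo)), np.full(p, float(hi))
    return train.features.min(axis=0), train.features.max(axis=0)


def _snap_distinct(
    coords: np.ndarray, tree: cKDTree, n_train: int, X: np.ndarray
) -> np.ndarray:
    """Map each coordinate to its nearest training row, keeping rows distinct.

    Collisions are resolved greedily: a coordinate whose nearest rows are all
    taken falls through to its next-nearest unused row.
    """
    k = min(n_train, len(coords) + 8)
    _, nn = tree.query(coords, k=k)
    nn = np.asarray(nn)
    if nn.ndim == 1:
        nn = nn[:, None]
    used: set[int] = set()
    out = np.empty(len(coords), dtype=int)
    for i, row in enumerate(nn):
        choice = -1
        for j in np.atleast_1d(row):
            if int(j) not in used:
                choice = int(j)
                break
        if choice < 0:  # neighbour list exhausted; brute-force fallback
            d = cdist(coords[i : i + 1], X)[0]
            for j in np.argsort(d):
                if int(j) not in used:
                    choice = int(j)
                    break
        used.add(choice)
        out[i] = choice
    return out


def select_random(train: LabeledDataset, spec: RegimeSpec) -> CenterSelection:
    """Uniform sampling of ``m`` distinct training rows."""
    _check_budget(train, spec)
    rng = substream(spec.seed, "regime", "random")
    idx = np.sort(rng.choice(train.n, size=spec.m, replace=False))
    return CenterSelection(idx, spec)


def regular_coordinate_pool(train: LabeledDataset, spec: RegimeSpec) -> np.ndarray:
    """Cartesian grid of bin midpoints with ``ceil(m^(1/p))`` bins per dim."""
    p = train.p
    bins = int(np.ceil(spec.m ** (1.0 / p)))
    if bins**p > 2_000_000:
        raise InvalidParameterError("regular coordinate pool is too large")
    lo, hi = _lattice_bounds(train)
    mids = [lo[d] + (hi[d] - lo[d]) * (np.arange(bins) + 0.5) / bins for d in range(p)]
    grids = np.meshgrid(*mids, indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def select_regular(train: LabeledDataset, spec: RegimeSpec) -> CenterSelection:
    """Evenly spread coordinates snapped to training samples.

    Draws ``n_subsets`` random ``m``-subsets of the regular coordinate pool;
    each coordinate is replaced by its nearest training sample.  Downstream
    evaluation averages accuracy over the subsets.
    """
    _check_budget(train, spec)
    pool = regular_coordinate_pool(train, spec)
    n_pool = len(pool)
    if n_pool < spec.m:
        raise InsufficientDataError("coordinate pool smaller than m")
    rng = substream(spec.seed, "regime", "regular")
    tree = cKDTree(train.features)
    subsets = []
    for _ in range(spec.n_subsets):
        pick = np.sort(rng.choice(n_pool, size=spec.m, replace=False))
        subsets.append(_snap_distinct(pool[pick], tree, train.n, train.features))
    return CenterSelection(
        subsets, spec, diagnostics={"pool_size": n_pool, "bins_per_dim": int(round(n_pool ** (1 / train.p)))}
    )


def _cell_indices(X: np.ndarray, lo: np.ndarray, hi: np.ndarray, v: int) -> np.ndarray:
    """Half-open lattice cells [lo, hi) with the last cell closed; samples
    outside the declared range are clipped into the boundary cells."""
    width = (hi - lo) / v
    width = np.where(width > 0, width, 1.0)  # degenerate dims collapse to cell 0
    cells = np.floor((X - lo) / width).astype(int)
    return np.clip(cells, 0, v - 1)


def select_frequency(train: LabeledDataset, spec: RegimeSpec) -> CenterSelection:
    """Centers from the ``m`` most populous cells of a v-per-dim lattice."""
    _check_budget(train, spec)
    lo, hi = _lattice_bounds(train)
    cells = _cell_indices(train.features, lo, hi, spec.v)
    flat = np.ravel_multi_index(cells.T, (spec.v,) * train.p)
    occupied, inverse, counts = np.unique(flat, return_inverse=True, return_counts=True)
    if len(occupied) < spec.m:
        raise DegenerateLatticeError(
            f"only {len(occupied)} occupied cells for m={spec.m}; lower v"
        )
    # rank by count descending; ties broken by lexicographic cell index
    order = np.lexsort((occupied, -counts))[: spec.m]
    width = (hi - lo) / spec.v
    idx = np.empty(spec.m, dtype=int)
    for rank, cell_pos in enumerate(order):
        members = np.flatnonzero(inverse == cell_pos)
        cell = np.array(np.unravel_index(occupied[cell_pos], (spec.v,) * train.p))
        centroid = lo + (cell + 0.5) * width
        d = np.sum((train.features[members] - centroid) ** 2, axis=1)
        idx[rank] = members[np.argmin(d)]
    return CenterSelection(
        idx,
        spec,
        diagnostics={
            "occupied_cells": int(len(occupied)),
            "chosen_cell_counts": counts[order].tolist(),
        },
    )


def select_kmeans(train: LabeledDataset, spec: RegimeSpec) -> CenterSelection:
    """K-means centroids (labels unused) snapped to nearest training rows."""
    _check_budget(train, spec)
    km = KMeans(
        n_clusters=spec.m,
        init="k-means++",
        n_init=1,
        max_iter=300,
        tol=1e-4,
        random_state=child_seed(spec.seed, "regime", "kmeans"),
    ).fit(train.features)
    tree = cKDTree(train.features)
    idx = _snap_distinct(km.cluster_centers_, tree, train.n, train.features)
    return CenterSelection(idx, spec, diagnostics={"inertia": float(km.inertia_)})


def select_support_vector(train: LabeledDataset, spec: RegimeSpec) -> CenterSelection:
    """Top-``m`` support vectors of an RBF maximum-margin classifier.

    Support vectors are ranked by absolute dual coefficient; if fewer than
    ``m`` exist, the remainder is filled with the unchosen training samples
    nearest the decision surface.  Training sets larger than ``svm_max_fit``
    are subsampled (seeded) before the SVM fit to bound the quadratic cost.
    """
    _check_budget(train, spec)
    if len(np.unique(train.labels)) < 2:
        raise InvalidTaskError("support-vector regime needs both classes present")
    rng = substream(spec.seed, "regime", "support_vector")
    if train.n > spec.svm_max_fit:
        sub = np.sort(rng.choice(train.n, size=spec.svm_max_fit, replace=False))
        if len(np.unique(train.labels[sub])) < 2:  # pathological subsample
            sub = np.arange(train.n)
    else:
        sub = np.arange(train.n)
    gamma = 1.0 / (2.0 * spec.width**2)
    svc = SVC(C=spec.svm_C, kernel="rbf", gamma=gamma)
    svc.fit(train.features[sub], train.labels[sub])
    sv_global = sub[svc.support_]
    coef = np.abs(svc.dual_coef_[0])
    order = np.lexsort((sv_global, -coef))  # |coef| desc, index asc on ties
    chosen = list(sv_global[order][: spec.m])
    if len(chosen) < spec.m:
        df = np.abs(svc.decision_function(train.features))
        taken = set(chosen)
        for j in np.argsort(df, kind="stable"):
            if int(j) not in taken:
                chosen.append(int(j))
                taken.add(int(j))
            if len(chosen) == spec.m:
                break
    return CenterSelection(
        np.asarray(chosen, dtype=int),
        spec,
        diagnostics={"n_support_vectors": int(len(sv_global)), "svm_fit_size": int(len(sub))},
    )


def select_novelty(train: LabeledDataset, spec: RegimeSpec) -> CenterSelection:
    """Sequential novelty-criterion dictionary with least-weight pruning.

    The dictionary starts from a single random training sample.  Samples
    stream in random order; the current model (kernel layer on the dictionary
    plus a readout refit on all samples seen so far) predicts each incoming
    sample, and a sample whose prediction error exceeds ``delta`` is admitted
    as a new center.  Whenever the dictionary would exceed ``m``, the center
    with the smallest absolute readout weight is pruned.  The readout is
    refit whenever the dictionary changes, using running Gram statistics so
    the stream never rebuilds the full feature matrix.
    """
    _check_budget(train, spec)
    rng = substream(spec.seed, "regime", "novelty")
    X, y = train.features, train.labels.astype(float)
    order = rng.permutation(train.n)
    if spec.novelty_max_stream is not None:
        order = order[: max(2, min(len(order), spec.novelty_max_stream))]
    Xs, ys = X[order], y[order]
    inv_two_w2 = 1.0 / (2.0 * spec.width**2)
    peak = 1.0 / (np.sqrt(2.0 * np.pi) * spec.width)

    def kcol(center: np.ndarray, pts: np.ndarray) -> np.ndarray:
        sq = np.sum((pts - center) ** 2, axis=1)
        return peak * np.exp(-sq * inv_two_w2)

    # Dictionary state.  H_buf holds the kernel features of every seen sample
    # under the *current* dictionary; Gram statistics (G, c, colsum) of the
    # raw features are maintained incrementally in preallocated buffers so
    # each refit is a single d x d solve, never a pass over the stream.
    n_stream = len(order)
    d_max = spec.m + 1
    H_buf = np.empty((n_stream, d_max))
    G_buf = np.zeros((d_max, d_max))
    c_buf = np.zeros(d_max)
    colsum_buf = np.zeros(d_max)
    cen_buf = np.empty((d_max, X.shape[1]))

    def refit(d: int, t: int, ysum: float):
        """Centered ridge solve from the running Gram statistics."""
        mu = colsum_buf[:d] / t
        A = G_buf[:d, :d] - t * np.outer(mu, mu)
        A.flat[:: d + 1] += spec.ridge
        b = c_buf[:d] - mu * ysum
        try:
            alpha = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            alpha = np.linalg.lstsq(A, b, rcond=None)[0]
        return alpha, mu, ysum / t

    dict_pos = [0]
    d = 1
    h0 = kcol(Xs[0], Xs[:1])[0]
    H_buf[0, 0] = h0
    cen_buf[0] = Xs[0]
    G_buf[0, 0] = h0 * h0
    c_buf[0] = ys[0] * h0
    colsum_buf[0] = h0
    ysum = float(ys[0])
    t = 1  # samples seen

    alpha, mu, bias = refit(d, t, ysum)
    log: list[dict] = [{"step": 0, "event": "init", "size": 1}]
    prev_err = 0.0

    for pos in range(1, n_stream):
        x_i, y_i = Xs[pos], ys[pos]
        h = kcol(x_i, cen_buf[:d])  # feature row under current dictionary
        score = float((h - mu) @ alpha) + bias
        err = abs(score - y_i)
        admit = (err - prev_err > spec.delta) if spec.novelty_rule == "error_increase" else (err > spec.delta)
        prev_err = err
        # absorb the sample into the running statistics
        H_buf[pos, :d] = h
        G_buf[:d, :d] += np.outer(h, h)
        c_buf[:d] += y_i * h
        colsum_buf[:d] += h
        ysum += y_i
        t += 1
        if not admit:
            continue
        # admit: new kernel column against every seen sample
        k_new = kcol(x_i, Xs[:t])
        cross = H_buf[:t, :d].T @ k_new
        G_buf[:d, d] = cross
        G_buf[d, :d] = cross
        G_buf[d, d] = k_new @ k_new
        c_buf[d] = k_new @ ys[:t]
        colsum_buf[d] = k_new.sum()
        H_buf[:t, d] = k_new
        cen_buf[d] = x_i
        d += 1
        dict_pos.append(pos)
        log.append({"step": pos, "event": "admit", "size": d})
        alpha, mu, bias = refit(d, t, ysum)
        if d > spec.m:
            j = int(np.argmin(np.abs(alpha)))
            # compact the buffers in place
            G_buf[j : d - 1, :d] = G_buf[j + 1 : d, :d]
            G_buf[: d - 1, j : d - 1] = G_buf[: d - 1, j + 1 : d]
            c_buf[j : d - 1] = c_buf[j + 1 : d]
            colsum_buf[j : d - 1] = colsum_buf[j + 1 : d]
            H_buf[:t, j : d - 1] = H_buf[:t, j + 1 : d]
            cen_buf[j : d - 1] = cen_buf[j + 1 : d]
            d -= 1
            dict_pos.pop(j)
            log.append({"step": pos, "event": "prune", "size": d})
            alpha, mu, bias = refit(d, t, ysum)

    idx = np.asarray(order[dict_pos], dtype=int)
    return CenterSelection(
        idx,
        spec,
        diagnostics={
            "log": log,
            "n_admitted": sum(1 for e in log if e["event"] == "admit"),
            "n_pruned": sum(1 for e in log if e["event"] == "prune"),
            "stream_length": int(len(order)),
        },
    )


_SELECTORS = {
    "random": select_random,
    "regular": select_regular,
    "frequency": select_frequency,
    "kmeans": select_kmeans,
    "support_vector": select_support_vector,
    "novelty": select_novelty,
}


def select_centers(train: LabeledDataset, spec: RegimeSpec) -> CenterSelection:
    """Dispatch to the selector named by ``spec.name``."""
    return _SELECTORS[spec.name](train, spec)


def fit_and_score(
    train: LabeledDataset,
    test: LabeledDataset,
    center_indices: np.ndarray,
    spec: RegimeSpec,
) -> float:
    """Fit the kernel layer + readout on ``train`` and score on ``test``."""
    layer = KernelLayer(train.features[center_indices], spec.width)
    sol = solve_readout(kernel_features(train.features, layer), train.labels, spec.ridge)
    scores = decision_scores(kernel_features(test.features, layer), sol)
    return accuracy(scores_to_labels(scores), test.labels)


def grid_search_hyperparams(
    train: LabeledDataset,
    validation: LabeledDataset,
    spec_template: RegimeSpec,
    v_grid=None,
    delta_grid=None,
) -> RegimeSpec:
    """Pick v (frequency) or delta (novelty) by validation accuracy.

    Degenerate grid values (e.g. a lattice too coarse to supply ``m`` cells)
    are skipped; ties go to the smaller hyperparameter value.
    """
    name = spec_template.name
    if name == "frequency":
        grid = [("v", int(v)) for v in (v_grid if v_grid is not None else DEFAULT_V_GRID)]
    elif name == "novelty":
        grid = [("delta", float(d)) for d in (delta_grid if delta_grid is not None else DEFAULT_DELTA_GRID)]
    else:
        return spec_template
    if not grid:
        raise InvalidParameterError("hyperparameter grid must be non-empty")
    best: tuple[float, float, RegimeSpec] | None = None
    for key, value in grid:
        cand = replace(spec_template, **{key: value})
        try:
            sel = select_centers(train, cand)
            acc = np.mean([fit_and_score(train, validation, s, cand) for s in sel.subsets()])
        except (DegenerateLatticeError, InsufficientDataError):
            continue
        if best is None or acc > best[0] or (acc == best[0] and value < best[1]):
            best = (float(acc), value, cand)
    if best is None:
        raise InvalidParameterError("every grid value was degenerate for this task")
    return best[2]


def resolve_spec(
    train: LabeledDataset,
    spec: RegimeSpec,
    v_grid=None,
    delta_grid=None,
    val_fraction: float = 0.2,
    search_max_stream: int | None = 1000,
) -> RegimeSpec:
    """Resolve searched hyperparameters on a validation split of ``train``.

    The split is carved from the training set only (80/20 by default); the
    novelty search streams a capped number of samples to bound cost, while
    the final selection streams the full training set.
    """
    if spec.name not in ("frequency", "novelty"):
        return spec
    sub_train, validation = split_train_test(
        train, 1.0 - val_fraction, seed=child_seed(spec.seed, "hpsearch")
    )
    template = spec
    if spec.name == "novelty" and search_max_stream is not None:
        template = replace(spec, novelty_max_stream=search_max_stream)
    resolved = grid_search_hyperparams(sub_train, validation, template, v_grid, delta_grid)
    return replace(resolved, novelty_max_stream=spec.novelty_max_stream)
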