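"""Selection-regime contracts: membership, budget, determinism,
task-(in)dependence, and each regime's characteristic geometry."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.stats import chisquare

from rbfregimes.datasets import LabeledDataset
from rbfregimes.errors import (
    DegenerateLatticeError,
    InsufficientDataError,
    InvalidParameterError,
    InvalidSpecError,
    InvalidTaskError,
)
from rbfregimes.regimes import (
    REGIME_NAMES,
    RegimeSpec,
    grid_search_hyperparams,
    regular_coordinate_pool,
    select_centers,
    select_frequency,
    select_kmeans,
    select_novelty,
    select_random,
    select_regular,
    select_support_vector,
)
from conftest import make_blobs_dataset


def spec_for(name, m, **kw):
    kw.setdefault("n_subsets", 20)
    return RegimeSpec(name=name, m=m, seed=123, **kw)


def rows_as_set(X):
    return {tuple(row) for row in np.asarray(X)}


@pytest.mark.parametrize("name", REGIME_NAMES)
def test_membership_budget_determinism(name, tiny_train):
    spec = spec_for(name, 10)
    sel1 = select_centers(tiny_train, spec)
    sel2 = select_centers(tiny_train, spec)
    train_rows = rows_as_set(tiny_train.features)
    for sub1, sub2 in zip(sel1.subsets(), sel2.subsets()):
        assert len(sub1) == 10
        assert len(np.unique(sub1)) == 10  # distinct indices
        assert np.array_equal(sub1, sub2)  # deterministic under fixed seed
        # every center is bit-identical to a training row
        assert rows_as_set(tiny_train.features[sub1]) <= train_rows


@pytest.mark.parametrize("name", ["random", "regular", "frequency", "kmeans"])
def test_task_independent_regimes_ignore_labels(name, tiny_train):
    spec = spec_for(name, 8)
    sel = select_centers(tiny_train, spec)
    rng = np.random.default_rng(0)
    shuffled = LabeledDataset(
        tiny_train.features.copy(),
        tiny_train.labels[rng.permutation(tiny_train.n)],
        role="train",
        relevant_range=tiny_train.relevant_range,
    )
    sel_shuf = select_centers(shuffled, spec)
    for a, b in zip(sel.subsets(), sel_shuf.subsets()):
        assert np.array_equal(a, b)


@pytest.mark.parametrize("name", ["support_vector", "novelty"])
def test_task_dependent_regimes_react_to_label_permutation(name):
    # Full label inversion leaves both regimes invariant by sign symmetry
    # (the SVM dual and the readout error |score - y| negate consistently),
    # so task-dependence is demonstrated by permuting labels instead:
    # a different class geometry must move the selected centers.
    train = make_blobs_dataset(
        [(0, 0), (3, 0), (0, 3), (5, 5)], [-1, -1, -1, 1], 30, 0.4, seed=2
    )
    spec = spec_for(name, 6, delta=0.3)
    sel = select_centers(train, spec)
    rng = np.random.default_rng(1)
    shuffled = LabeledDataset(train.features.copy(),
                              train.labels[rng.permutation(train.n)],
                              role="train", relevant_range=None)
    sel_shuf = select_centers(shuffled, spec)
    assert not np.array_equal(np.sort(sel.primary()), np.sort(sel_shuf.primary()))


def test_random_exhaustive_when_m_equals_n(tiny_train):
    spec = spec_for("random", tiny_train.n)
    sel = select_random(tiny_train, spec)
    assert np.array_equal(np.sort(sel.center_indices), np.arange(tiny_train.n))


def test_random_rejects_oversized_budget(tiny_train):
    with pytest.raises(InsufficientDataError):
        select_random(tiny_train, spec_for("random", tiny_train.n + 1))


def test_random_selection_frequencies_uniform():
    ds = LabeledDataset(np.arange(20).reshape(10, 2).astype(float),
                        np.array([1, -1] * 5), role="train", relevant_range=None)
    counts = np.zeros(10)
    for s in range(10_000):
        sel = select_random(ds, RegimeSpec("random", m=1, seed=s))
        counts[sel.center_indices[0]] += 1
    assert chisquare(counts).pvalue > 0.01


def test_regular_pool_size_follows_ceiling_rule(tiny_train):
    # m=5, p=2 -> ceil(5^(1/2)) = 3 bins per dim -> 9 coordinates
    pool = regular_coordinate_pool(tiny_train, spec_for("regular", 5))
    assert pool.shape == (9, 2)
    # m=100, p=2 -> 10 bins -> pool of exactly 100: subsets use the whole pool
    pool100 = regular_coordinate_pool(tiny_train, spec_for("regular", 100))
    assert pool100.shape == (100, 2)


def test_regular_subsets_coincide_when_pool_equals_budget(tiny_train):
    sel = select_regular(tiny_train, spec_for("regular", 100, n_subsets=5))
    first = np.sort(sel.center_indices[0])
    for sub in sel.center_indices[1:]:
        assert np.array_equal(np.sort(sub), first)


def test_frequency_degenerate_inputs():
    X = np.tile([[0.5, 0.5]], (30, 1))
    ds = LabeledDataset(X, np.array([1, -1] * 15), role="train", relevant_range=None)
    sel = select_frequency(ds, spec_for("frequency", 1, v=4))
    assert len(sel.center_indices) == 1
    with pytest.raises(DegenerateLatticeError):
        select_frequency(ds, spec_for("frequency", 2, v=4))


def test_frequency_ranks_denser_blob_first():
    train = make_blobs_dataset([(0.1, 0.1), (0.9, 0.9)], [1, -1], 900, 0.02, seed=3)
    # shrink the denser blob to 900 vs 100 points
    keep = np.r_[np.arange(900), np.arange(900, 1000)]
    train = LabeledDataset(train.features[keep], train.labels[keep], role="train",
                           relevant_range=((0.0, 1.0), (0.0, 1.0)))
    sel = select_frequency(train, spec_for("frequency", 2, v=2))
    chosen = train.features[sel.center_indices]
    # one center per blob; the denser blob's cell ranked first
    assert np.all(np.abs(chosen[0] - [0.1, 0.1]) < 0.2)
    assert np.all(np.abs(chosen[1] - [0.9, 0.9]) < 0.2)
    assert sel.diagnostics["chosen_cell_counts"][0] >= sel.diagnostics["chosen_cell_counts"][1]


def test_kmeans_recovers_separated_blobs():
    centers = [(0, 0), (10, 0), (0, 10), (10, 10)]
    train = make_blobs_dataset(centers, [1, -1, 1, -1], 40, 0.3, seed=4)
    sel = select_kmeans(train, spec_for("kmeans", 4))
    chosen = train.features[sel.center_indices]
    for c in centers:
        assert np.min(np.linalg.norm(chosen - np.asarray(c, dtype=float), axis=1)) < 1.5


def test_kmeans_single_center_is_nearest_to_global_mean(tiny_train):
    sel = select_kmeans(tiny_train, spec_for("kmeans", 1))
    gm = tiny_train.features.mean(axis=0)
    nearest = np.argmin(np.linalg.norm(tiny_train.features - gm, axis=1))
    assert sel.center_indices[0] == nearest


def test_support_vector_picks_margin_defining_pair():
    rng = np.random.default_rng(0)
    Xm = np.column_stack([rng.uniform(-2.5, -1.0, 14), rng.uniform(-0.5, 0.5, 14)])
    Xp = np.column_stack([rng.uniform(1.0, 2.5, 14), rng.uniform(-0.5, 0.5, 14)])
    inner = np.array([[-0.5, 0.0], [0.5, 0.0]])  # closest pair to the midplane
    X = np.vstack([Xm, Xp, inner])
    y = np.array([-1] * 14 + [1] * 14 + [-1, 1])
    ds = LabeledDataset(X, y, role="train", relevant_range=None)
    sel = select_support_vector(ds, spec_for("support_vector", 2))
    assert set(sel.center_indices) == {28, 29}


def test_support_vector_centers_hug_the_boundary(tiny_train):
    from sklearn.svm import SVC

    sel = select_support_vector(tiny_train, spec_for("support_vector", 20))
    svc = SVC(C=1.0, kernel="rbf", gamma=0.5).fit(tiny_train.features, tiny_train.labels)
    dist = np.abs(svc.decision_function(tiny_train.features))
    assert dist[sel.center_indices].mean() < dist.mean()


def test_support_vector_requires_two_classes(tiny_train):
    one_class = LabeledDataset(tiny_train.features, np.abs(tiny_train.labels),
                               role="train", relevant_range=None)
    with pytest.raises(InvalidTaskError):
        select_support_vector(one_class, spec_for("support_vector", 5))


def test_novelty_huge_delta_keeps_single_center(tiny_train):
    sel = select_novelty(tiny_train, spec_for("novelty", 10, delta=1e9))
    assert len(sel.center_indices) == 1
    assert sel.diagnostics["n_admitted"] == 0


def test_novelty_tiny_delta_admits_everything_on_two_point_stream():
    ds = LabeledDataset(np.array([[0.0, 0.0], [1.0, 1.0]]), np.array([1, -1]),
                        role="train", relevant_range=None)
    sel = select_novelty(ds, spec_for("novelty", 2, delta=1e-9))
    assert len(sel.center_indices) == 2


def test_novelty_dictionary_never_exceeds_budget(tiny_train):
    spec = spec_for("novelty", 7, delta=0.2)
    sel = select_novelty(tiny_train, spec)
    sizes = [e["size"] for e in sel.diagnostics["log"]]
    # after every admit/prune event the dictionary holds at most m+1 centers
    # transiently and at most m at the end of each step
    final_sizes = {}
    for e in sel.diagnostics["log"]:
        final_sizes[e["step"]] = e["size"]
    assert all(s <= spec.m for s in final_sizes.values())
    assert len(sel.center_indices) <= spec.m


def test_novelty_alternative_admission_rule_runs(tiny_train):
    spec = spec_for("novelty", 5, delta=0.2, novelty_rule="error_increase")
    sel = select_novelty(tiny_train, spec)
    assert 1 <= len(sel.center_indices) <= 5


def test_regime_spec_validation():
    with pytest.raises(InvalidSpecError):
        RegimeSpec("no_such_regime", m=5)
    with pytest.raises(InvalidSpecError):
        RegimeSpec("random", m=0)
    with pytest.raises(InvalidSpecError):
        RegimeSpec("novelty", m=5, delta=0.0)


class TestGridSearch:
    def test_single_element_grid_returned(self, tiny_train):
        tr, val = tiny_train, tiny_train
        spec = grid_search_hyperparams(tr, val, spec_for("frequency", 4), v_grid=[6])
        assert spec.v == 6

    def test_degenerate_values_skipped(self):
        train = make_blobs_dataset([(0.2, 0.2), (0.8, 0.8)], [1, -1], 50, 0.03, seed=5)
        # v=1 yields a single occupied cell and cannot supply m=2 centers
        spec = grid_search_hyperparams(
            train, train, spec_for("frequency", 2), v_grid=[1, 4]
        )
        assert spec.v == 4

    def test_empty_grid_rejected(self, tiny_train):
        with pytest.raises(InvalidParameterError):
            grid_search_hyperparams(tiny_train, tiny_train,
                                    spec_for("frequency", 4), v_grid=[])

    def test_isolating_resolution_wins_on_constructed_task(self):
        # four tight corner clusters: v=2 isolates them; ties go to smaller v
        train = make_blobs_dataset(
            [(0.25, 0.25), (0.75, 0.25), (0.25, 0.75), (0.75, 0.75)],
            [1, -1, -1, 1], 60, 0.04, seed=6,
        )
        train = LabeledDataset(train.features, train.labels, role="train",
                               relevant_range=((0.0, 1.0), (0.0, 1.0)))
        val = LabeledDataset(train.features.copy(), train.labels.copy(), role="test",
                             relevant_range=train.relevant_range)
        spec = grid_search_hyperparams(train, val, spec_for("frequency", 4),
                                       v_grid=[2, 8])
        assert spec.v == 2
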