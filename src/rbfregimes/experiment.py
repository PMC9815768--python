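"""Condition-grid experiment runner.

One *condition* fixes the task (clusters per class ``K``, irrelevant-dimension
count, sample size, label noise, split fraction) and the resource constraint
(kernel budget ``m``).  For each condition, every selection regime plus the
two random-projection controls is trained end-to-end and scored on the held
out test set; replicate seeds give the stochastic spread.  Results are tidy
rows keyed by ``(K, m, n_irrelevant, regime, seed)``.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeding import child_seed
from .datasets import LabeledDataset, generate_task
from .expansion import KernelLayer, kernel_features, random_projection_features, sample_projection_layer
from .readout import (
    DEFAULT_RIDGE,
    accuracy,
    decision_scores,
    scores_to_labels,
    solve_readout,
    solve_readout_gram,
)
from .regimes import (
    DEFAULT_DELTA_GRID,
    DEFAULT_V_GRID,
    CenterSelection,
    RegimeSpec,
    fit_and_score,
    resolve_spec,
    select_centers,
)

logger = logging.getLogger("rbfregimes")

__all__ = [
    "Condition",
    "ResultRecord",
    "KERNEL_REGIMES",
    "CONTROL_REGIMES",
    "ALL_REGIMES",
    "run_condition",
    "run_grid",
    "rank_regimes",
    "grand_mean_ranks",
    "default_conditions",
    "noise_ceiling",
    "SCALES",
]

KERNEL_REGIMES = ("random", "regular", "frequency", "kmeans", "support_vector", "novelty")
CONTROL_REGIMES = ("rp_linear", "rp_nonlinear")
ALL_REGIMES = KERNEL_REGIMES + CONTROL_REGIMES

# Problem-size presets.  "paper" matches the published study conditions;
# "desk" is the scaled-down default used by the test-bench and preserves
# every qualitative contrast at workstation cost.
SCALES = {
    "paper": {"n_samples": 100_000, "n_subsets": 1000},
    "desk": {"n_samples": 5_000, "n_subsets": 200},
}


@dataclass(frozen=True)
class Condition:
    """One cell of the experiment grid."""

    K: int
    m: int
    n_irrelevant: int = 0
    n_samples: int = 5_000
    train_fraction: float = 0.7
    label_noise_rate: float = 0.05
    n_subsets: int = 200
    width: float = 1.0
    ridge: float = DEFAULT_RIDGE

    def __post_init__(self):
        if self.K < 1 or self.m < 1 or self.n_samples < 2 or self.n_irrelevant < 0:
            raise ValueError("grid values must be positive")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class ResultRecord:
    condition: Condition
    regime: str
    seed: int
    test_accuracy: float
    hyperparams: dict = field(default_factory=dict)
    status: str = "ok"

    def to_row(self) -> dict:
        row = {
            "K": self.condition.K,
            "m": self.condition.m,
            "n_irrelevant": self.condition.n_irrelevant,
            "n_samples": self.condition.n_samples,
            "regime": self.regime,
            "seed": self.seed,
            "test_accuracy": self.test_accuracy,
            "status": self.status,
        }
        row.update({f"hp_{k}": v for k, v in self.hyperparams.items()})
        return row


def noise_ceiling(label_noise_rate: float, n_test: int) -> float:
    """Upper bound on achievable test accuracy under symmetric label noise.

    Test labels are corrupted too, so Bayes-optimal accuracy is at most
    ``1 - r``; the bound adds four binomial standard errors of slack.
    """
    r = label_noise_rate
    return (1.0 - r) + 4.0 * np.sqrt(r * (1.0 - r) / n_test)


def _evaluate_regular(
    train: LabeledDataset, test: LabeledDataset, selection: CenterSelection, spec: RegimeSpec
) -> float:
    """Accuracy averaged over the regular regime's coordinate subsets.

    Kernel columns and their Gram matrix are shared across subsets: features
    are computed once for the union of selected training rows, and each
    subset solves its readout from the corresponding Gram submatrix.
    """
    subsets = selection.subsets()
    uniq = np.unique(np.concatenate(subsets))
    pos = {int(i): k for k, i in enumerate(uniq)}
    layer = KernelLayer(train.features[uniq], spec.width)
    H = kernel_features(train.features, layer)
    Ht = kernel_features(test.features, layer)
    y = train.labels.astype(float)
    G = H.T @ H
    c = H.T @ y
    colsum = H.sum(axis=0)
    n = train.n
    ysum = float(y.sum())
    accs = []
    for sub in subsets:
        cols = np.array([pos[int(i)] for i in sub])
        sol = solve_readout_gram(
            G[np.ix_(cols, cols)], c[cols], colsum[cols], ysum, n, spec.ridge
        )
        scores = (Ht[:, cols] - sol.feature_means) @ sol.alpha + sol.bias
        accs.append(accuracy(scores_to_labels(scores), test.labels))
    return float(np.mean(accs))


def run_condition(
    condition: Condition,
    regime: str,
    seed: int,
    v_grid=DEFAULT_V_GRID,
    delta_grid=DEFAULT_DELTA_GRID,
    dump_centers_dir=None,
) -> ResultRecord:
    """Execute the full pipeline for one (condition, regime, seed) cell.

    All randomness is derived from ``seed`` through named substreams, so the
    dataset draw is identical across regimes at the same seed.
    """
    if regime not in ALL_REGIMES:
        raise ValueError(f"unknown regime {regime!r}")
    t0 = time.perf_counter()
    data_seed = child_seed(seed, "data", condition.K, condition.n_irrelevant, condition.n_samples)
    train, test, task_spec = generate_task(
        K=condition.K,
        n_samples=condition.n_samples,
        n_irrelevant=condition.n_irrelevant,
        label_noise_rate=condition.label_noise_rate,
        train_fraction=condition.train_fraction,
        seed=data_seed,
    )
    hyper: dict = {"ridge": condition.ridge, "width": condition.width}
    if regime in CONTROL_REGIMES:
        activation = "identity" if regime == "rp_linear" else "relu"
        layer = sample_projection_layer(
            train.p,
            condition.m,
            seed=child_seed(seed, "layer", regime),
            activation=activation,
        )
        H = random_projection_features(train.features, layer)
        sol = solve_readout(H, train.labels.astype(float), condition.ridge)
        scores = decision_scores(random_projection_features(test.features, layer), sol)
        acc = accuracy(scores_to_labels(scores), test.labels)
        hyper["activation"] = activation
    else:
        spec = RegimeSpec(
            name=regime,
            m=condition.m,
            n_subsets=condition.n_subsets,
            seed=child_seed(seed, "regime", regime),
            width=condition.width,
            ridge=condition.ridge,
        )
        spec = resolve_spec(train, spec, v_grid=v_grid, delta_grid=delta_grid)
        selection = select_centers(train, spec)
        if regime == "regular":
            acc = _evaluate_regular(train, test, selection, spec)
            hyper["n_subsets"] = spec.n_subsets
        else:
            acc = fit_and_score(train, test, selection.center_indices, spec)
        if regime == "frequency":
            hyper["v"] = spec.v
        if regime == "novelty":
            hyper["delta"] = spec.delta
        if dump_centers_dir is not None:
            _dump_centers(dump_centers_dir, condition, regime, seed, train, selection)
    record = ResultRecord(condition, regime, seed, float(acc), hyper)
    logger.info(
        "K=%d m=%d irr=%d regime=%s seed=%d acc=%.4f (%.2fs)",
        condition.K,
        condition.m,
        condition.n_irrelevant,
        regime,
        seed,
        acc,
        time.perf_counter() - t0,
    )
    return record


def _dump_centers(out_dir, condition, regime, seed, train, selection) -> None:
    """Selected-centers artifact: indices, coordinates, hyperparameters."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    idx = selection.primary()
    payload = {
        "K": condition.K,
        "m": condition.m,
        "n_irrelevant": condition.n_irrelevant,
        "regime": regime,
        "seed": seed,
        "center_indices": np.asarray(idx).tolist(),
        "center_coordinates": train.features[idx].tolist(),
        "hyperparams": {
            "v": selection.regime.v,
            "delta": selection.regime.delta,
            "n_subsets": selection.regime.n_subsets,
            "width": selection.regime.width,
        },
        "diagnostics": {
            k: v for k, v in selection.diagnostics.items() if k != "log"
        },
    }
    name = f"K{condition.K}_m{condition.m}_irr{condition.n_irrelevant}_{regime}_s{seed}.json"
    with open(out_dir / name, "w") as fh:
        json.dump(payload, fh)


def default_conditions(
    scale: str = "desk",
    K_values=(2, 5, 25),
    m_values=(5, 20, 100),
    n_irrelevant_values=(0, 2, 6),
) -> list[Condition]:
    """Cross-product grid over data complexity, budget and irrelevant dims."""
    preset = SCALES[scale]
    return [
        Condition(
            K=K,
            m=m,
            n_irrelevant=d,
            n_samples=preset["n_samples"],
            n_subsets=preset["n_subsets"],
        )
        for K in K_values
        for m in m_values
        for d in n_irrelevant_values
    ]


_KEY_COLS = ["K", "m", "n_irrelevant", "regime", "seed"]


def run_grid(
    conditions,
    regimes=ALL_REGIMES,
    seeds=(0, 1, 2, 3, 4),
    out_csv=None,
    resume: bool = True,
    dump_centers_dir=None,
) -> pd.DataFrame:
    """Run the full cross-product; resumable against an existing CSV.

    Per-cell failures are recorded with ``status != "ok"`` and NaN accuracy
    rather than aborting the sweep.
    """
    existing = pd.DataFrame()
    if out_csv is not None and resume and Path(out_csv).exists():
        existing = pd.read_csv(out_csv)
    done = set()
    if len(existing):
        done = {tuple(r) for r in existing[_KEY_COLS].itertuples(index=False)}
    rows = []
    for cond in conditions:
        for regime in regimes:
            for seed in seeds:
                key = (cond.K, cond.m, cond.n_irrelevant, regime, seed)
                if key in done:
                    continue
                try:
                    rec = run_condition(cond, regime, seed, dump_centers_dir=dump_centers_dir)
                except Exception as exc:  # recorded, not fatal
                    logger.warning("cell %s failed: %s", key, exc)
                    rec = ResultRecord(cond, regime, seed, float("nan"), {}, status=f"error: {exc}")
                rows.append(rec.to_row())
                if out_csv is not None:
                    table = pd.concat([existing, pd.DataFrame(rows)], ignore_index=True)
                    table.to_csv(out_csv, index=False)
    return pd.concat([existing, pd.DataFrame(rows)], ignore_index=True) if rows or len(existing) else pd.DataFrame(columns=_KEY_COLS + ["test_accuracy", "status"])


def rank_regimes(results: pd.DataFrame, group_keys=("K", "m", "n_irrelevant")) -> pd.DataFrame:
    """Rank regimes by mean accuracy within each condition group.

    Ties on the mean are broken by the lower across-seed variance.  Returns a
    tidy table with mean, std-error, variance and rank per (group, regime).
    """
    ok = results[results["status"] == "ok"] if "status" in results else results
    group_keys = list(group_keys)
    agg = (
        ok.groupby(group_keys + ["regime"])["test_accuracy"]
        .agg(mean_accuracy="mean", variance="var", n_seeds="count")
        .reset_index()
    )
    agg["variance"] = agg["variance"].fillna(0.0)
    agg["sem"] = np.sqrt(agg["variance"] / agg["n_seeds"].clip(lower=1))
    out = []
    for _, grp in agg.groupby(group_keys):
        if len(grp) < 2:
            logger.warning("group with fewer than 2 regimes excluded from ranking")
            continue
        # round the primary key so float noise cannot defeat the tie rule
        grp = grp.assign(_mean_key=grp["mean_accuracy"].round(12))
        grp = grp.sort_values(["_mean_key", "variance"], ascending=[False, True], kind="stable")
        grp = grp.drop(columns="_mean_key").assign(rank=np.arange(1, len(grp) + 1))
        out.append(grp)
    return pd.concat(out, ignore_index=True) if out else agg.assign(rank=np.nan)


def grand_mean_ranks(ranking: pd.DataFrame) -> pd.Series:
    """Mean rank of each regime across all condition groups (lower = better)."""
    return ranking.groupby("regime")["rank"].mean().sort_values()
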