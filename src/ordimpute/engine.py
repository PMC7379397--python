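"""Greedy iterative imputation loop and baseline imputers.

The core procedure: starting from the 12 always-complete attention-test
indices as the feature set, every remaining item gets its own deep network
trained on the rows where that item was observed; the item whose network
achieves the highest held-out accuracy is selected, its missing cells are
filled with the network's predictions, and the now-complete column is
merged into the feature set for the next round.  The loop repeats until no
item remains, so iteration k trains networks with exactly 12 + (k - 1)
inputs.  The resulting selection sequence — the imputation order — doubles
as a discriminability ranking of the items and is cut into thirds
(top / intermediate / bottom tiers).

Baselines for comparison: per-item mean imputation, within-scale positional
interpolation, and a chained-equations multiple imputer.
"""

from __future__ import annotations

import enum
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import LinearRegression

from .network import HyperParams, TrainedItemModel, predict_item, train_item_model
from .registry import (
    N_CCPT_INDICES,
    CohortTable,
    ItemRegistry,
)

__all__ = [
    "Tier",
    "ImputeOptions",
    "IterationRecord",
    "ImputationResult",
    "run_iterative_imputation",
    "assign_tiers",
    "mean_impute",
    "interpolate_impute",
    "multiple_impute",
]


class Tier(str, enum.Enum):
    TOP = "TOP"
    INTERMEDIATE = "INTERMEDIATE"
    BOTTOM = "BOTTOM"


class InsufficientDataError(ValueError):
    """An item has too few observed responses to train its network."""


@dataclass
class ImputeOptions:
    """Switches for the iterative loop.

    ``min_observed`` rows are required to train an item's network; items
    below it either raise (``sparse_policy='error'``) or are deferred and
    imputed after every evaluable item, using the final feature set
    (``'skip_to_last'``, flagged in their record).  ``exclude_odd_items``
    drops oppositional-defiant items before the loop (sensitivity
    analysis).  ``track_classification`` runs the two-group classifier on
    the merged feature set after every iteration.
    """

    exclude_odd_items: bool = False
    track_classification: bool = False
    min_observed: int = 8
    sparse_policy: str = "skip_to_last"  # or "error"
    seed: int = 0


@dataclass
class IterationRecord:
    iteration: int
    selected_item: str
    candidate_accuracies: dict[str, float]
    selected_accuracy: float
    n_cells_imputed: int
    classification_accuracy: float | None = None
    elapsed_seconds: float = 0.0
    deferred: bool = False  # True when imputed under the sparse-item policy


@dataclass
class ImputationResult:
    completed_cohort: CohortTable
    imputation_order: list[str]
    records: list[IterationRecord]
    tiers: dict[str, Tier]
    models: dict[str, TrainedItemModel] = field(default_factory=dict, repr=False)


def _child_seed(base: int, *salt: int) -> int:
    return int(np.random.SeedSequence([base, *salt]).generate_state(1)[0] >> 1)


def run_iterative_imputation(
    cohort: CohortTable,
    registry: ItemRegistry,
    hyperparams: HyperParams,
    options: ImputeOptions | None = None,
) -> ImputationResult:
    """Run the greedy most-predictable-first imputation loop to completion.

    Candidate networks are retrained from scratch each iteration (the
    feature set has grown); the rows used for an item's network are those
    where the item was observed, with previously merged (possibly imputed)
    columns included as features.  Ties on accuracy break toward canonical
    registry order.  Deterministic given ``hyperparams.seed`` /
    ``options.seed``.
    """
    options = options or ImputeOptions()
    if cohort.item_ids != [d.item_id for d in registry]:
        raise ValueError("cohort item columns must match the registry (same ids, same order)")
    descs = [d for d in registry if not (options.exclude_odd_items and d.is_odd_item)]
    if not descs:
        raise ValueError("registry is empty after exclusions")
    item_ids = [d.item_id for d in descs]
    col_of = {d.item_id: j for j, d in enumerate(registry)}

    items = cohort.item_matrix().copy()
    ccpt = cohort.ccpt_matrix()
    labels = cohort.labels
    n = cohort.n_participants

    observed_counts = {iid: int((~np.isnan(items[:, col_of[iid]])).sum()) for iid in item_ids}
    sparse = [iid for iid in item_ids if observed_counts[iid] < options.min_observed]
    if sparse and options.sparse_policy == "error":
        raise InsufficientDataError(
            f"items with < {options.min_observed} observed responses: {sparse}"
        )
    evaluable = [iid for iid in item_ids if iid not in set(sparse)]

    # feature matrix starts as the attention indices; grows by one merged
    # item column per iteration.  The index block is standardized inside
    # each network fit (training-row statistics); item columns are raw 0-3.
    features = ccpt.copy()
    scale_mask = [True] * N_CCPT_INDICES

    remaining = list(evaluable)
    order: list[str] = []
    records: list[IterationRecord] = []
    models: dict[str, TrainedItemModel] = {}
    iteration = 0

    def fit_candidate(iid: str, it: int) -> TrainedItemModel:
        col = items[:, col_of[iid]]
        rows = ~np.isnan(col)
        hp = HyperParams(
            patience_epochs=hyperparams.patience_epochs,
            dropout_rate=hyperparams.dropout_rate,
            batch_mode=hyperparams.batch_mode,
            max_epochs=hyperparams.max_epochs,
            validation_fraction=hyperparams.validation_fraction,
            learning_rate=hyperparams.learning_rate,
            n_init_attempts=hyperparams.n_init_attempts,
            seed=_child_seed(hyperparams.seed, it, col_of[iid]),
        )
        return train_item_model(
            features[rows], col[rows].astype(int), hp, scale_cols=scale_mask
        )

    def merge(iid: str, model: TrainedItemModel) -> int:
        nonlocal features
        col = items[:, col_of[iid]]
        miss = np.isnan(col)
        if miss.any():
            col[miss] = predict_item(model, features[miss])
            items[:, col_of[iid]] = col
        features = np.column_stack([features, col])
        scale_mask.append(False)
        return int(miss.sum())

    while remaining:
        iteration += 1
        t0 = time.perf_counter()
        accs: dict[str, float] = {}
        cand_models: dict[str, TrainedItemModel] = {}
        for iid in remaining:
            m = fit_candidate(iid, iteration)
            cand_models[iid] = m
            accs[iid] = m.validation_accuracy
        best_acc = max(accs.values())
        selected = next(iid for iid in remaining if accs[iid] == best_acc)
        n_filled = merge(selected, cand_models[selected])
        remaining.remove(selected)
        order.append(selected)
        models[selected] = cand_models[selected]

        cls_acc = None
        if options.track_classification:
            from .evaluation import classify_groups

            run = classify_groups(
                features, labels, seed=_child_seed(options.seed, 1000 + iteration)
            )
            cls_acc = run.mean_accuracy
        records.append(
            IterationRecord(
                iteration=iteration,
                selected_item=selected,
                candidate_accuracies=accs,
                selected_accuracy=best_acc,
                n_cells_imputed=n_filled,
                classification_accuracy=cls_acc,
                elapsed_seconds=time.perf_counter() - t0,
            )
        )

    # deferred sparse items: imputed last, against the final feature set
    for iid in sparse:
        iteration += 1
        t0 = time.perf_counter()
        col = items[:, col_of[iid]]
        rows = ~np.isnan(col)
        if rows.sum() == 0:
            raise InsufficientDataError(f"item {iid} has no observed responses")
        # too few rows for a network: fall back to the observed mode
        vals, counts = np.unique(col[rows].astype(int), return_counts=True)
        fill = int(vals[np.argmax(counts)])
        miss = np.isnan(col)
        col[miss] = fill
        items[:, col_of[iid]] = col
        features = np.column_stack([features, col])
        scale_mask.append(False)
        order.append(iid)
        records.append(
            IterationRecord(
                iteration=iteration,
                selected_item=iid,
                candidate_accuracies={},
                selected_accuracy=float("nan"),
                n_cells_imputed=int(miss.sum()),
                elapsed_seconds=time.perf_counter() - t0,
                deferred=True,
            )
        )

    completed = cohort.with_items(items) if not options.exclude_odd_items else _completed_subset(
        cohort, items, registry, item_ids
    )
    return ImputationResult(
        completed_cohort=completed,
        imputation_order=order,
        records=records,
        tiers=assign_tiers(order),
        models=models,
    )


def _completed_subset(cohort, items, registry, kept_ids):
    """Completed table restricted to the non-excluded items."""
    frame = cohort.frame.copy()
    keep_cols = [c for c in frame.columns if c not in
                 {d.item_id for d in registry} - set(kept_ids)]
    frame = frame[keep_cols]
    sub = CohortTable(frame, kept_ids)
    col_of = {d.item_id: j for j, d in enumerate(registry)}
    return sub.with_items(items[:, [col_of[i] for i in kept_ids]])


def assign_tiers(imputation_order: Sequence[str]) -> dict[str, Tier]:
    """Cut the order into thirds: first ⌊N/3⌋ TOP, last ⌊N/3⌋ BOTTOM.

    The remainder (1–2 items when N is not divisible by 3) goes to
    INTERMEDIATE, giving the (35, 37, 35) split at N=107.
    """
    order = list(imputation_order)
    if not order:
        raise ValueError("imputation order is empty")
    third = len(order) // 3
    tiers: dict[str, Tier] = {}
    for rank, iid in enumerate(order):
        if rank < third:
            tiers[iid] = Tier.TOP
        elif rank >= len(order) - third:
            tiers[iid] = Tier.BOTTOM
        else:
            tiers[iid] = Tier.INTERMEDIATE
    return tiers


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.clip(np.floor(x + 0.5), 0, 3)


def mean_impute(cohort: CohortTable) -> CohortTable:
    """Fill each missing cell with the item's observed mean, rounded to 0–3.

    Halves round up (mean 1.5 -> 2).  Errors if an item has no observed
    value at all.
    """
    items = cohort.item_matrix().copy()
    for j, iid in enumerate(cohort.item_ids):
        col = items[:, j]
        obs = ~np.isnan(col)
        miss = ~obs
        if not miss.any():
            continue
        if not obs.any():
            raise ValueError(f"item {iid} has no observed values; cannot mean-impute")
        col[miss] = _round_half_up(np.full(miss.sum(), col[obs].mean()))
    return cohort.with_items(items)


def interpolate_impute(cohort: CohortTable, registry: ItemRegistry) -> CohortTable:
    """Linear interpolation over item position within each participant's scale.

    Missing cells between two observed items on the same scale take the
    linear interpolant over positions (rounded to 0–3, halves up); runs at
    either end copy the nearest observed value.  A scale with no observed
    item for a participant falls back to per-item mean imputation.
    """
    items = cohort.item_matrix().copy()
    col_of = {iid: j for j, iid in enumerate(cohort.item_ids)}
    scale_groups: dict = {}
    for d in registry:
        if d.item_id in col_of:
            scale_groups.setdefault(d.scale, []).append((d.position, col_of[d.item_id]))

    col_means = {}
    for j in range(items.shape[1]):
        obs = ~np.isnan(items[:, j])
        col_means[j] = items[obs, j].mean() if obs.any() else np.nan

    for cols in scale_groups.values():
        cols = sorted(cols)
        positions = np.array([p for p, _ in cols], dtype=float)
        idx = [j for _, j in cols]
        block = items[:, idx]
        for i in range(block.shape[0]):
            row = block[i]
            obs = ~np.isnan(row)
            if obs.all():
                continue
            if not obs.any():
                fill = np.array([col_means[j] for j in idx])
                if np.isnan(fill).any():
                    raise ValueError("scale entirely unobserved across the cohort")
                block[i] = _round_half_up(fill)
                continue
            interp = np.interp(positions, positions[obs], row[obs])
            row[~obs] = _round_half_up(interp[~obs])
        items[:, idx] = block
    return cohort.with_items(items)


def multiple_impute(
    cohort: CohortTable, m: int = 5, seed: int = 0, n_cycles: int = 10
) -> list[CohortTable]:
    """Chained-equations multiple imputation: ``m`` completed tables.

    Each chain initializes missing cells by mean imputation, then cycles
    through the items in canonical order for ``n_cycles`` rounds, refitting
    a linear regression of each item on all other columns (attention
    indices + items) over the rows where the item was observed, and
    redrawing its missing cells as prediction + Gaussian residual noise,
    rounded to the 0–3 range.  Chains are independent given ``seed``;
    observed cells are untouched in every table.
    """
    if m < 2:
        raise ValueError("m must be >= 2 for multiple imputation")
    orig_items = cohort.item_matrix()
    mask = np.isnan(orig_items)
    ccpt = cohort.ccpt_matrix()
    tables: list[CohortTable] = []
    for chain in range(m):
        rng = np.random.default_rng(_child_seed(seed, chain))
        items = mean_impute(cohort).item_matrix()
        if mask.any():
            for _ in range(n_cycles):
                for j in range(items.shape[1]):
                    miss = mask[:, j]
                    if not miss.any():
                        continue
                    others = np.delete(items, j, axis=1)
                    X = np.column_stack([ccpt, others])
                    reg = LinearRegression().fit(X[~miss], items[~miss, j])
                    pred_obs = reg.predict(X[~miss])
                    resid_sd = float(np.std(items[~miss, j] - pred_obs))
                    draw = reg.predict(X[miss]) + resid_sd * rng.standard_normal(miss.sum())
                    items[miss, j] = _round_half_up(draw)
        tables.append(cohort.with_items(items))
    return tables
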