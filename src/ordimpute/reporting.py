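"""Imputation-order reporting and order comparison.

The greedy loop's selection sequence is read as a discriminability
ranking: the tier report cross-tabulates the top / intermediate / bottom
thirds against scale, informant and symptom domain (the narrative being,
for the clinical cohort, that teacher-rated oppositional and
hyperactive-impulsive items surface early while inattention items sink).
``compare_orders`` supports sensitivity analyses — e.g. rerunning the loop
without the oppositional-defiant items and checking that the shared items
keep their relative order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .engine import ImputationResult, Tier, assign_tiers
from .registry import ItemRegistry

__all__ = ["TierReport", "build_tier_report", "compare_orders", "OrderComparison"]


@dataclass
class TierReport:
    tier_sizes: dict[Tier, int]
    composition: dict[Tier, dict[str, dict[str, int]]]  # tier -> facet -> value -> count
    item_rows: list[dict] = field(default_factory=list)  # rank, item_id, scale, ...

    def to_dict(self) -> dict:
        return {
            "tier_sizes": {t.value: n for t, n in self.tier_sizes.items()},
            "composition": {
                t.value: facets for t, facets in self.composition.items()
            },
            "items": self.item_rows,
        }


def build_tier_report(result: ImputationResult, registry: ItemRegistry) -> TierReport:
    """Cross-tabulate tiers × (scale, informant, domain) with per-item ranks."""
    desc_of = {d.item_id: d for d in registry}
    acc_of = {r.selected_item: r.selected_accuracy for r in result.records}
    tier_sizes = {t: 0 for t in Tier}
    composition: dict[Tier, dict[str, dict[str, int]]] = {
        t: {"scale": {}, "informant": {}, "domain": {}} for t in Tier
    }
    rows = []
    for rank, iid in enumerate(result.imputation_order, start=1):
        d = desc_of[iid]
        tier = result.tiers[iid]
        tier_sizes[tier] += 1
        for facet, value in (
            ("scale", d.scale.value),
            ("informant", d.informant.value),
            ("domain", d.domain.value),
        ):
            composition[tier][facet][value] = composition[tier][facet].get(value, 0) + 1
        rows.append(
            {
                "rank": rank,
                "item_id": iid,
                "scale": d.scale.value,
                "informant": d.informant.value,
                "domain": d.domain.value,
                "is_odd_item": d.is_odd_item,
                "tier": tier.value,
                "selected_accuracy": acc_of.get(iid, float("nan")),
            }
        )
    return TierReport(tier_sizes=tier_sizes, composition=composition, item_rows=rows)


@dataclass
class OrderComparison:
    n_shared: int
    spearman_rho: float
    p_value: float
    n_tier_changes: int


def compare_orders(order_a: Sequence[str], order_b: Sequence[str]) -> OrderComparison:
    """Rank agreement between two imputation orders on their shared items.

    Both orders are restricted to the shared item set and re-ranked; the
    summary reports the Spearman correlation of the restricted ranks and
    the number of shared items whose third-of-the-order tier differs.
    """
    shared = [iid for iid in order_a if iid in set(order_b)]
    if not shared:
        raise ValueError("orders have no items in common")
    sub_a = [iid for iid in order_a if iid in set(shared)]
    sub_b = [iid for iid in order_b if iid in set(shared)]
    rank_a = {iid: r for r, iid in enumerate(sub_a)}
    rank_b = {iid: r for r, iid in enumerate(sub_b)}
    ra = np.array([rank_a[iid] for iid in shared])
    rb = np.array([rank_b[iid] for iid in shared])
    if len(shared) < 2:
        rho, p = 1.0, 1.0
    else:
        rho, p = stats.spearmanr(ra, rb)
    tiers_a = assign_tiers(sub_a)
    tiers_b = assign_tiers(sub_b)
    changes = sum(1 for iid in shared if tiers_a[iid] != tiers_b[iid])
    return OrderComparison(
        n_shared=len(shared),
        spearman_rho=float(rho),
        p_value=float(p),
        n_tier_changes=changes,
    )
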