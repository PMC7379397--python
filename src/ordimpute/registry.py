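"""Item registry and cohort data model.

The cohort under study pairs a binary diagnostic label (ADHD case vs.
typically-developing control) with two kinds of measurements per
participant:

* 12 continuous indices from a continuous performance test (CPT) of
  sustained attention — always complete, the seed feature block for
  imputation;
* up to 107 ordinal item responses (4-point Likert, 0–3) spread over four
  rating scales: SNAP-IV parent and teacher forms (26 items each) and the
  Conners' short-form parent (27 items) and teacher (28 items) scales.
  Item responses may be missing, typically a whole scale at a time when an
  informant never returned the questionnaire.

This module defines the immutable item registry (scale, informant, symptom
domain, oppositional-defiant flag per item), the :class:`CohortTable`
wrapper around a pandas DataFrame, and CSV/JSON round-trip IO.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Scale",
    "Informant",
    "Domain",
    "ItemDescriptor",
    "ItemRegistry",
    "CohortTable",
    "build_default_registry",
    "subset_registry",
    "load_cohort",
    "write_cohort",
    "extract_reference_subset",
    "N_CCPT_INDICES",
    "CCPT_COLUMNS",
    "ORDINAL_LEVELS",
]

#: Number of continuous attention-test indices; always complete.
N_CCPT_INDICES = 12
CCPT_COLUMNS = tuple(f"ccpt_{i:02d}" for i in range(1, N_CCPT_INDICES + 1))
#: Admissible ordinal responses on the 4-point Likert scale.
ORDINAL_LEVELS = (0, 1, 2, 3)

GROUP_CASE = "CASE"
GROUP_CONTROL = "CONTROL"


class Scale(str, enum.Enum):
    """The four rating scales contributing items."""

    SNAP_P = "SNAP_P"
    SNAP_T = "SNAP_T"
    CPRS = "CPRS"
    CTRS = "CTRS"


class Informant(str, enum.Enum):
    PARENT = "parent"
    TEACHER = "teacher"


class Domain(str, enum.Enum):
    """Symptom domain an item loads on (used for reporting and simulation)."""

    INATTENTION = "inattention"
    HYPERACTIVITY_IMPULSIVITY = "hyperactivity_impulsivity"
    OPPOSITIONAL = "oppositional"
    COGNITIVE_INATTENTION = "cognitive_inattention"
    ADHD_INDEX = "adhd_index"


@dataclass(frozen=True)
class ItemDescriptor:
    """Metadata for one scale item."""

    item_id: str
    scale: Scale
    informant: Informant
    position: int  # 1-based within its scale
    domain: Domain
    is_odd_item: bool


ItemRegistry = list  # ordered list of ItemDescriptor; canonical order throughout

_SCALE_SIZES = {Scale.SNAP_P: 26, Scale.SNAP_T: 26, Scale.CPRS: 27, Scale.CTRS: 28}
_SCALE_INFORMANT = {
    Scale.SNAP_P: Informant.PARENT,
    Scale.SNAP_T: Informant.TEACHER,
    Scale.CPRS: Informant.PARENT,
    Scale.CTRS: Informant.TEACHER,
}

# Oppositional-defiant (ODD) item positions per scale.  SNAP forms devote
# items 19-26 to ODD symptoms; the Conners short forms embed them in an
# Oppositional subscale.
_ODD_POSITIONS = {
    Scale.SNAP_P: set(range(19, 27)),
    Scale.SNAP_T: set(range(19, 27)),
    Scale.CPRS: {2, 6, 11, 16, 20, 24},
    Scale.CTRS: {2, 6, 10, 15, 20},
}

# Conners short-form subscale membership by position (oppositional handled
# above): cognitive problems/inattention, hyperactivity-impulsivity, and the
# ADHD-index screening items.
_CONNERS_DOMAINS = {
    Scale.CPRS: {
        Domain.COGNITIVE_INATTENTION: {3, 8, 12, 17, 21, 25},
        Domain.HYPERACTIVITY_IMPULSIVITY: {4, 9, 14, 18, 22, 26},
    },
    Scale.CTRS: {
        Domain.COGNITIVE_INATTENTION: {4, 8, 13, 17, 22, 25},
        Domain.HYPERACTIVITY_IMPULSIVITY: {3, 7, 11, 16, 21, 26},
    },
}


def _snap_domain(position: int) -> Domain:
    if position <= 9:
        return Domain.INATTENTION
    if position <= 18:
        return Domain.HYPERACTIVITY_IMPULSIVITY
    return Domain.OPPOSITIONAL


def _conners_domain(scale: Scale, position: int) -> Domain:
    if position in _ODD_POSITIONS[scale]:
        return Domain.OPPOSITIONAL
    for domain, positions in _CONNERS_DOMAINS[scale].items():
        if position in positions:
            return domain
    return Domain.ADHD_INDEX


def build_default_registry() -> ItemRegistry:
    """Build the canonical 107-item registry.

    Canonical order is SNAP-IV parent 1–26, SNAP-IV teacher 1–26, Conners
    parent 1–27, Conners teacher 1–28; this order is the global tie-break
    used by the greedy imputation loop.
    """
    registry: ItemRegistry = []
    for scale in (Scale.SNAP_P, Scale.SNAP_T, Scale.CPRS, Scale.CTRS):
        for pos in range(1, _SCALE_SIZES[scale] + 1):
            if scale in (Scale.SNAP_P, Scale.SNAP_T):
                domain = _snap_domain(pos)
            else:
                domain = _conners_domain(scale, pos)
            registry.append(
                ItemDescriptor(
                    item_id=f"{scale.value}_{pos:02d}",
                    scale=scale,
                    informant=_SCALE_INFORMANT[scale],
                    position=pos,
                    domain=domain,
                    is_odd_item=pos in _ODD_POSITIONS[scale],
                )
            )
    return registry


def subset_registry(registry: ItemRegistry, item_ids: Iterable[str] | None = None,
                    n_items: int | None = None) -> ItemRegistry:
    """Restrict a registry to named items or its first ``n_items`` entries.

    Canonical order is preserved.  Useful for desk-scale runs where a full
    107-item greedy loop is unnecessarily heavy.
    """
    if (item_ids is None) == (n_items is None):
        raise ValueError("specify exactly one of item_ids or n_items")
    if n_items is not None:
        if not 1 <= n_items <= len(registry):
            raise ValueError(f"n_items must be in [1, {len(registry)}]")
        return registry[:n_items]
    wanted = set(item_ids)
    unknown = wanted - {d.item_id for d in registry}
    if unknown:
        raise ValueError(f"unknown item ids: {sorted(unknown)}")
    return [d for d in registry if d.item_id in wanted]


def registry_to_json(registry: ItemRegistry, path: str | Path) -> None:
    payload = [
        {
            "item_id": d.item_id,
            "scale": d.scale.value,
            "informant": d.informant.value,
            "position": d.position,
            "domain": d.domain.value,
            "is_odd_item": d.is_odd_item,
        }
        for d in registry
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def registry_from_json(path: str | Path) -> ItemRegistry:
    payload = json.loads(Path(path).read_text())
    return [
        ItemDescriptor(
            item_id=d["item_id"],
            scale=Scale(d["scale"]),
            informant=Informant(d["informant"]),
            position=int(d["position"]),
            domain=Domain(d["domain"]),
            is_odd_item=bool(d["is_odd_item"]),
        )
        for d in payload
    ]


class CohortValidationError(ValueError):
    """Raised when cohort data violate the data-model contract."""


class CohortTable:
    """Participants × (label, CPT indices, ordinal item responses).

    Backed by a pandas DataFrame with columns ``participant_id``, ``group``,
    the 12 ``ccpt_*`` float columns, and one float column per registry item
    (NaN encodes a missing response).  CPT indices must be complete; item
    values must be in {0,1,2,3} where observed.
    """

    def __init__(self, frame: pd.DataFrame, item_ids: Sequence[str]):
        self.frame = frame.reset_index(drop=True)
        self.item_ids = list(item_ids)
        self._validate()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        participant_ids: Sequence[str],
        groups: Sequence[str],
        ccpt: np.ndarray,
        items: np.ndarray,
        item_ids: Sequence[str],
    ) -> "CohortTable":
        """Assemble a table from raw arrays (items: float with NaN=missing)."""
        frame = pd.DataFrame({"participant_id": list(participant_ids), "group": list(groups)})
        for j, col in enumerate(CCPT_COLUMNS):
            frame[col] = np.asarray(ccpt, dtype=float)[:, j]
        items = np.asarray(items, dtype=float)
        for j, item_id in enumerate(item_ids):
            frame[item_id] = items[:, j]
        return cls(frame, item_ids)

    def _validate(self) -> None:
        f = self.frame
        required = ["participant_id", "group", *CCPT_COLUMNS, *self.item_ids]
        missing_cols = [c for c in required if c not in f.columns]
        if missing_cols:
            raise CohortValidationError(f"missing columns: {missing_cols}")
        if f["participant_id"].duplicated().any():
            dupes = f.loc[f["participant_id"].duplicated(), "participant_id"].tolist()
            raise CohortValidationError(f"duplicate participant ids: {dupes}")
        bad_group = set(f["group"]) - {GROUP_CASE, GROUP_CONTROL}
        if bad_group:
            raise CohortValidationError(f"invalid group labels: {sorted(bad_group)}")
        ccpt = f[list(CCPT_COLUMNS)].to_numpy(dtype=float)
        if np.isnan(ccpt).any():
            rows = f.loc[np.isnan(ccpt).any(axis=1), "participant_id"].tolist()
            raise CohortValidationError(
                f"CCPT indices must be complete; missing for participants {rows}"
            )
        if self.item_ids:
            items = f[self.item_ids].to_numpy(dtype=float)
            observed = items[~np.isnan(items)]
            if observed.size and not np.isin(observed, ORDINAL_LEVELS).all():
                bad = sorted(set(observed[~np.isin(observed, ORDINAL_LEVELS)]))
                raise CohortValidationError(
                    f"item responses must be in {{0,1,2,3}}; found {bad}"
                )

    # -- accessors --------------------------------------------------------
    @property
    def n_participants(self) -> int:
        return len(self.frame)

    @property
    def participant_ids(self) -> list[str]:
        return self.frame["participant_id"].tolist()

    @property
    def groups(self) -> np.ndarray:
        return self.frame["group"].to_numpy()

    @property
    def labels(self) -> np.ndarray:
        """Binary labels: 1 for CASE, 0 for CONTROL."""
        return (self.frame["group"] == GROUP_CASE).to_numpy(dtype=int)

    def ccpt_matrix(self) -> np.ndarray:
        return self.frame[list(CCPT_COLUMNS)].to_numpy(dtype=float)

    def item_matrix(self) -> np.ndarray:
        """Float matrix of item responses, NaN where missing."""
        if not self.item_ids:
            return np.empty((self.n_participants, 0))
        return self.frame[self.item_ids].to_numpy(dtype=float)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.item_matrix())

    def count_missing(self) -> int:
        return int(self.missing_mask().sum())

    def copy(self) -> "CohortTable":
        return CohortTable(self.frame.copy(), self.item_ids)

    def with_items(self, items: np.ndarray) -> "CohortTable":
        """Return a copy with the item matrix replaced."""
        frame = self.frame.copy()
        items = np.asarray(items, dtype=float)
        for j, item_id in enumerate(self.item_ids):
            frame[item_id] = items[:, j]
        return CohortTable(frame, self.item_ids)

    def equals(self, other: "CohortTable") -> bool:
        if self.item_ids != other.item_ids:
            return False
        return self.frame.reset_index(drop=True).equals(other.frame.reset_index(drop=True))


def load_cohort(path: str | Path, registry: ItemRegistry) -> CohortTable:
    """Read a cohort CSV (empty cell or ``NA`` = missing item response).

    Item columns must match registry ids; values outside {0,1,2,3} or any
    missing CPT-index cell raise :class:`CohortValidationError`.
    """
    item_ids = [d.item_id for d in registry]
    try:
        frame = pd.read_csv(
            path, na_values=["NA"], keep_default_na=False,
            dtype={"participant_id": str}, float_precision="round_trip",
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise CohortValidationError(f"malformed CSV {path}: {exc}") from exc
    for col in item_ids:
        if col not in frame.columns:
            raise CohortValidationError(f"missing item column {col!r}")
        vals = pd.to_numeric(frame[col], errors="coerce")
        newly_bad = vals.isna() & ~frame[col].astype(str).isin(["", "NA", "nan"])
        if newly_bad.any():
            row = int(np.flatnonzero(newly_bad)[0])
            raise CohortValidationError(
                f"non-numeric item value {frame[col].iloc[row]!r} at row {row}, column {col!r}"
            )
        frame[col] = vals
    for col in CCPT_COLUMNS:
        if col not in frame.columns:
            raise CohortValidationError(f"missing CCPT column {col!r}")
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    present = [c for c in ["participant_id", "group", *CCPT_COLUMNS, *item_ids] if c in frame.columns]
    return CohortTable(frame[present], item_ids)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write cohort CSV; missing item cells serialized as ``NA``.

    ``load_cohort`` on the result reproduces the table exactly, including
    the missingness mask (items are integer-formatted on disk).
    """
    frame = cohort.frame.copy()
    for col in cohort.item_ids:
        frame[col] = frame[col].astype("Int64")  # renders 2 not 2.0; <NA> handled below
    frame.to_csv(path, index=False, na_rep="NA")


def extract_reference_subset(cohort: CohortTable) -> list[str]:
    """Participant ids with zero missing item responses (complete cases).

    These form the reference dataset against which the imputed participants'
    downstream classification accuracy is compared.
    """
    if not cohort.item_ids:
        return cohort.participant_ids
    complete = ~cohort.missing_mask().any(axis=1)
    return [pid for pid, ok in zip(cohort.participant_ids, complete) if ok]
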