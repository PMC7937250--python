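"""Class construction: flexible rank-based sampling and fixed thresholds.

Bioactivity data for the carbonic anhydrase isoforms are heavily skewed
towards potent compounds, so fixed activity cutoffs (< 20 nM active,
>= 100 nM inactive) produce badly unbalanced classes.  The flexible
alternative sorts compounds by activity (ascending, nM) and takes the best
N as the active class and the worst N as the inactive class, yielding
perfectly balanced classes whose effective thresholds adapt to the data.
The boundary statistics — activity of the last active, of the first
inactive, and their ratio — quantify how well separated the two classes are
at each sampling size N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

#: Fixed activity thresholds (nM): active below, inactive at or above.
ACTIVE_LT_NM = 20.0
INACTIVE_GE_NM = 100.0

#: Sampling sizes investigated by default: 150..700 in steps of 50.
DEFAULT_N_GRID: Tuple[int, ...] = tuple(range(150, 701, 50))


@dataclass(frozen=True)
class SamplingStats:
    """Boundary statistics of a flexible-threshold sampling."""

    isoform: str
    n: int
    max_active_nM: float
    min_inactive_nM: float

    @property
    def closest_ratio(self) -> float:
        """Ratio between the first inactive and the last active compound."""
        return self.min_inactive_nM / self.max_active_nM


@dataclass
class LabeledDataset:
    """A binary-labelled dataset for one isoform.

    ``labels`` holds 1 for active and 0 for inactive, aligned with
    ``compound_ids``.  In flexible mode the middle (unsampled) compounds are
    kept in ``unsampled_ids`` for later validation-set construction; in fixed
    mode the intermediate band (20 <= activity < 100 nM) is excluded the same
    way.
    """

    compound_ids: List[str]
    labels: np.ndarray
    activities_nM: np.ndarray
    isoform: str
    labeling_mode: str  # "flexible" | "fixed"
    n: Optional[int] = None
    stats: Optional[SamplingStats] = None
    thresholds: Optional[Tuple[float, float]] = None
    unsampled_ids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.activities_nM = np.asarray(self.activities_nM, dtype=float)
        if not (len(self.compound_ids) == len(self.labels) == len(self.activities_nM)):
            raise ValueError("ids, labels and activities must align")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "compound_id": self.compound_ids,
            "isoform": self.isoform,
            "activity_nM": self.activities_nM,
            "label": self.labels,
            "labeling_mode": self.labeling_mode,
            "N": self.n if self.n is not None else pd.NA,
        })


def _sorted_items(activities: Mapping[str, float]) -> List[Tuple[str, float]]:
    # stable order: activity ascending, compound id as deterministic tie-break
    for cid, v in activities.items():
        if not v > 0:
            raise ValueError(f"non-positive activity {v} nM for {cid}")
    return sorted(activities.items(), key=lambda kv: (kv[1], kv[0]))


def flexible_sample(
    activities: Mapping[str, float], n: int, isoform: str = ""
) -> Tuple[LabeledDataset, SamplingStats]:
    """Sample the N most potent (active) and N least potent (inactive) compounds.

    Requires 2N <= number of compounds; raises otherwise, reporting the
    maximum feasible N.
    """
    items = _sorted_items(activities)
    size = len(items)
    if 2 * n > size:
        raise ValueError(
            f"2N = {2 * n} exceeds dataset size {size}; maximum feasible N "
            f"is {size // 2}"
        )
    actives = items[:n]
    inactives = items[size - n:]
    middle = items[n:size - n]
    stats = SamplingStats(
        isoform=isoform,
        n=n,
        max_active_nM=actives[-1][1],
        min_inactive_nM=inactives[0][1],
    )
    ids = [cid for cid, _ in actives] + [cid for cid, _ in inactives]
    values = np.array([v for _, v in actives] + [v for _, v in inactives])
    labels = np.array([1] * n + [0] * n)
    dataset = LabeledDataset(
        compound_ids=ids,
        labels=labels,
        activities_nM=values,
        isoform=isoform,
        labeling_mode="flexible",
        n=n,
        stats=stats,
        unsampled_ids=[cid for cid, _ in middle],
    )
    return dataset, stats


def fixed_label(
    activity_nM: float,
    active_lt: float = ACTIVE_LT_NM,
    inactive_ge: float = INACTIVE_GE_NM,
) -> str:
    """Fixed-threshold class of a single activity value.

    < 20 nM -> "active"; >= 100 nM -> "inactive"; the 20-100 nM band is
    "intermediate" and excluded from fixed-mode training.
    """
    if not activity_nM > 0:
        raise ValueError(f"non-positive activity {activity_nM} nM")
    if activity_nM < active_lt:
        return "active"
    if activity_nM >= inactive_ge:
        return "inactive"
    return "intermediate"


def fixed_dataset(
    activities: Mapping[str, float],
    isoform: str = "",
    active_lt: float = ACTIVE_LT_NM,
    inactive_ge: float = INACTIVE_GE_NM,
) -> LabeledDataset:
    """Label a whole activity map with the fixed thresholds.

    Intermediate compounds are excluded from the dataset (tracked in
    ``unsampled_ids``).
    """
    ids: List[str] = []
    labels: List[int] = []
    values: List[float] = []
    intermediate: List[str] = []
    for cid, v in _sorted_items(activities):
        cls = fixed_label(v, active_lt, inactive_ge)
        if cls == "intermediate":
            intermediate.append(cid)
        else:
            ids.append(cid)
            labels.append(1 if cls == "active" else 0)
            values.append(v)
    return LabeledDataset(
        compound_ids=ids,
        labels=np.array(labels, dtype=int),
        activities_nM=np.array(values),
        isoform=isoform,
        labeling_mode="fixed",
        thresholds=(active_lt, inactive_ge),
        unsampled_ids=intermediate,
    )


def sweep_sampling_sizes(
    activities: Mapping[str, float],
    n_grid: Sequence[int] = DEFAULT_N_GRID,
    isoform: str = "",
) -> List[SamplingStats]:
    """Boundary statistics for every feasible N in an ascending grid.

    Infeasible sizes (2N > dataset) are skipped — for data-poor isoforms the
    table simply ends early.
    """
    if not n_grid:
        raise ValueError("empty N grid")
    if list(n_grid) != sorted(n_grid):
        raise ValueError("N grid must be ascending")
    out: List[SamplingStats] = []
    for n in n_grid:
        try:
            _, stats = flexible_sample(activities, n, isoform=isoform)
        except ValueError:
            continue
        out.append(stats)
    return out


def stats_frame(stats: Sequence[SamplingStats]) -> pd.DataFrame:
    """Sampling statistics as a table (ratio reported to 2 decimals)."""
    return pd.DataFrame([{
        "isoform": s.isoform,
        "N": s.n,
        "max_active_nM": s.max_active_nM,
        "min_inactive_nM": s.min_inactive_nM,
        "closest_ratio": round(s.closest_ratio, 2),
    } for s in stats])


def class_counts_fixed(
    activities: Mapping[str, float],
    active_lt: float = ACTIVE_LT_NM,
    inactive_ge: float = INACTIVE_GE_NM,
) -> Dict[str, int]:
    """Counts of active / intermediate / inactive under the fixed thresholds."""
    counts = {"active": 0, "intermediate": 0, "inactive": 0}
    for v in activities.values():
        counts[fixed_label(v, active_lt, inactive_ge)] += 1
    return counts
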