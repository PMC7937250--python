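"""Selectivity profiling by combination of per-isoform binary labels.

A compound predicted active on the tumour-associated isoform (hCA IX or
hCA XII) but inactive on the homeostatic off-target hCA II is the
therapeutically interesting class.  The 2x2 label space maps bijectively
onto four selectivity classes per isoform pair:

    hCA II    other     class
    active    active    non-selective (active on both)
    inactive  active    selective for the other isoform over hCA II
    active    inactive  selective for hCA II over the other isoform
    inactive  inactive  non-selective (inactive on both)

Profiles are computed from validated consensus labels only; when one
isoform lacks a prediction (the compound was sampled into that isoform's
training set) the profile is flagged incomplete and carries no class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .learning import ConsensusPrediction

#: Isoform pairs profiled: hCA II against each tumour-associated isoform.
PAIRS: Tuple[str, ...] = ("II_vs_IX", "II_vs_XII")

_OFF_ISOFORM = {"II_vs_IX": "hCA_IX", "II_vs_XII": "hCA_XII"}

NON_SELECTIVE_ACTIVE = "non_selective_active"
SELECTIVE_OFF_OVER_II = "selective_off_isoform_over_II"
SELECTIVE_II_OVER_OFF = "selective_II_over_off_isoform"
NON_SELECTIVE_INACTIVE = "non_selective_inactive"

#: Human-readable report names per (pair, class).
def class_description(pair: str, cls: str) -> str:
    other = _OFF_ISOFORM[pair].replace("_", " ")
    return {
        NON_SELECTIVE_ACTIVE: "Non selective (active)",
        SELECTIVE_OFF_OVER_II: f"Selective for {other} over hCA II",
        SELECTIVE_II_OVER_OFF: f"Selective for hCA II over {other}",
        NON_SELECTIVE_INACTIVE: "Non selective (inactive)",
    }[cls]


@dataclass(frozen=True)
class SelectivityProfile:
    """Selectivity class of one compound for one isoform pair."""

    compound_id: str
    pair: str
    selectivity_class: Optional[str]
    label_II: Optional[int]
    label_other: Optional[int]
    min_confidence: Optional[float]
    complete: bool


def combine_labels(label_II: str | int, label_other: str | int, pair: str) -> str:
    """Map a pair of binary activity labels onto the selectivity class.

    Labels may be given as "active"/"inactive" or 1/0.  Total over the 2x2
    label space and bijective onto the four classes.
    """
    if pair not in PAIRS:
        raise ValueError(f"unknown pair {pair!r}; choose from {PAIRS}")
    a_II = _as_active(label_II)
    a_other = _as_active(label_other)
    if a_II and a_other:
        return NON_SELECTIVE_ACTIVE
    if not a_II and a_other:
        return SELECTIVE_OFF_OVER_II
    if a_II and not a_other:
        return SELECTIVE_II_OVER_OFF
    return NON_SELECTIVE_INACTIVE


def _as_active(label: str | int) -> bool:
    if label in (1, "active"):
        return True
    if label in (0, "inactive"):
        return False
    raise ValueError(f"label must be active/inactive or 1/0, got {label!r}")


def profile_compounds(
    predictions: Mapping[Tuple[str, str], ConsensusPrediction]
    | Sequence[ConsensusPrediction],
) -> List[SelectivityProfile]:
    """One profile per compound per isoform pair from consensus predictions.

    ``predictions`` is keyed by (compound_id, isoform), or given as a flat
    sequence of predictions carrying their isoform.  The combined confidence
    is the minimum of the two mean probability scores — the conservative
    extension of single-model confidence ranking.
    """
    if not isinstance(predictions, Mapping):
        predictions = {(p.compound_id, p.isoform): p for p in predictions}
    compounds = sorted({cid for cid, _ in predictions})
    out: List[SelectivityProfile] = []
    for cid in compounds:
        p_II = predictions.get((cid, "hCA_II"))
        for pair in PAIRS:
            p_other = predictions.get((cid, _OFF_ISOFORM[pair]))
            if p_II is None or p_other is None:
                out.append(SelectivityProfile(
                    compound_id=cid, pair=pair, selectivity_class=None,
                    label_II=None if p_II is None else p_II.final_label,
                    label_other=None if p_other is None else p_other.final_label,
                    min_confidence=None, complete=False,
                ))
                continue
            cls = combine_labels(p_II.final_label, p_other.final_label, pair)
            out.append(SelectivityProfile(
                compound_id=cid, pair=pair, selectivity_class=cls,
                label_II=p_II.final_label, label_other=p_other.final_label,
                min_confidence=min(p_II.mean_score, p_other.mean_score),
                complete=True,
            ))
    return out


def profiles_frame(profiles: Sequence[SelectivityProfile]) -> pd.DataFrame:
    """Selectivity profiles as a tidy report table."""
    return pd.DataFrame([{
        "compound_id": p.compound_id,
        "pair": p.pair,
        "selectivity_class": p.selectivity_class,
        "description": (
            class_description(p.pair, p.selectivity_class)
            if p.selectivity_class else None
        ),
        "label_II": p.label_II,
        "label_other": p.label_other,
        "min_confidence": p.min_confidence,
        "complete": p.complete,
    } for p in profiles])
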