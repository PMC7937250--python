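"""External validation under screening-like conditions.

The validation set for an isoform and sampling size N consists of the
compounds *not* drawn into the train/test sample whose curated activity is
below 20 nM (true actives) or above 100 nM (true inactives); the 20-100 nM
intermediate band has no defined truth and is excluded.  Models trained on
the full sampled dataset classify these unseen compounds; outcomes follow
the screening truth rule — a true active predicted active is a TP, predicted
inactive an FN; a true inactive predicted active is an FP, predicted
inactive a TN.  Results are stratified by consensus probability bin and,
separately, by structural similarity to the training set (mean atom-pair
fingerprint Tanimoto coefficient, "similar" at mean Tc >= 0.336).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .learning import ConsensusPrediction
from .metrics import (
    OVERALL,
    PROBABILITY_BINS,
    ConfusionCounts,
    MetricSet,
    compute_metrics,
    stratified_report_frame,
    stratify_by_probability,
)
from .sampling import ACTIVE_LT_NM, INACTIVE_GE_NM

#: Atom-pair Tanimoto threshold separating "similar" from "not similar".
TC_SIMILAR = 0.336


@dataclass(frozen=True)
class ValidationTruth:
    """Ground truth for one validation compound."""

    compound_id: str
    isoform: str
    activity_nM: float
    true_class: str  # "active" (< 20 nM) | "inactive" (> 100 nM)

    @property
    def true_label(self) -> int:
        return 1 if self.true_class == "active" else 0


def build_validation_set(
    activities: Mapping[str, float],
    sampled_ids: Iterable[str],
    isoform: str = "",
    active_lt: float = ACTIVE_LT_NM,
    inactive_gt: float = INACTIVE_GE_NM,
) -> List[ValidationTruth]:
    """Unsampled compounds with defined truth (< 20 nM or > 100 nM).

    ``sampled_ids`` are the compounds used in training or testing; they are
    excluded.  An empty result is legitimate (data-poor isoforms run out of
    inactives at large N) and simply yields an empty list.
    """
    sampled = set(sampled_ids)
    out: List[ValidationTruth] = []
    for cid, value in sorted(activities.items()):
        if cid in sampled:
            continue
        if value < active_lt:
            true_class = "active"
        elif value > inactive_gt:
            true_class = "inactive"
        else:
            continue  # intermediate band: truth undefined
        out.append(ValidationTruth(cid, isoform, float(value), true_class))
    return out


def outcome(true_label: int, predicted_label: int) -> str:
    """TP/FN/FP/TN assignment with active as the positive class."""
    if true_label == 1:
        return "TP" if predicted_label == 1 else "FN"
    return "FP" if predicted_label == 1 else "TN"


def score_validation(
    predictions: Sequence[ConsensusPrediction],
    truths: Sequence[ValidationTruth],
    mode: str = "consensus",
) -> Dict[object, Tuple[ConfusionCounts, Optional[MetricSet]]]:
    """Probability-stratified confusion counts and metrics on the validation set.

    ``mode="consensus"`` (default) assigns one outcome per compound from its
    final consensus label — per-bin counts then sum exactly to the overall
    counts.  ``mode="averaged"`` counts outcomes per repeat, averages the
    counts over the R repeats and rounds to the nearest integer, mirroring
    reports that average experiments before rounding; per-bin sums then
    match the overall counts only up to rounding.

    Every validation compound must carry a prediction.
    """
    pred_by_id = {p.compound_id: p for p in predictions}
    missing = [t.compound_id for t in truths if t.compound_id not in pred_by_id]
    if missing:
        raise ValueError(f"missing predictions for validation compounds: {missing[:5]}")
    if mode == "consensus":
        final = [pred_by_id[t.compound_id].final_label for t in truths]
        scores = [pred_by_id[t.compound_id].mean_score for t in truths]
        true = [t.true_label for t in truths]
        return stratify_by_probability(final, scores, true)
    if mode != "averaged":
        raise ValueError(f"unknown mode {mode!r}")

    keys = [OVERALL, *PROBABILITY_BINS]
    if not truths:
        empty = ConfusionCounts(0, 0, 0, 0)
        return {k: (empty, None) for k in keys}
    n_repeats = len(pred_by_id[truths[0].compound_id].repeat_labels)
    # accumulate per-repeat outcome counts per bin, then average and round
    acc: Dict[object, Dict[str, float]] = {
        k: {"TP": 0.0, "FN": 0.0, "FP": 0.0, "TN": 0.0} for k in keys
    }
    for t in truths:
        p = pred_by_id[t.compound_id]
        for r in range(n_repeats):
            o = outcome(t.true_label, int(p.repeat_labels[r]))
            acc[OVERALL][o] += 1.0
            acc[p.probability_bin][o] += 1.0
    out: Dict[object, Tuple[ConfusionCounts, Optional[MetricSet]]] = {}
    for k in keys:
        counts = ConfusionCounts(**{
            o.lower(): int(round(v / n_repeats)) for o, v in acc[k].items()
        })
        out[k] = (counts, compute_metrics(counts) if counts.total else None)
    return out


def validation_report_frame(
    stratified: Dict[object, Tuple[ConfusionCounts, Optional[MetricSet]]],
) -> pd.DataFrame:
    """Confusion/metric table with the overall column plus probability bins."""
    return stratified_report_frame(stratified)


_AP_GENERATOR = rdFingerprintGenerator.GetAtomPairGenerator()


def _fingerprints(smiles_list: Sequence[str]) -> List[Optional[object]]:
    fps: List[Optional[object]] = []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        fps.append(None if mol is None else _AP_GENERATOR.GetFingerprint(mol))
    return fps


def mean_training_similarity(
    validation_smiles: Mapping[str, str],
    training_smiles: Sequence[str],
    mode: str = "mean",
) -> Dict[str, float]:
    """Atom-pair Tanimoto similarity of each validation compound to training.

    ``mode="mean"`` (default) averages the Tanimoto coefficient over all
    training compounds; ``mode="max"`` takes the nearest neighbour instead.
    Unparseable SMILES are excluded with a warning.
    """
    if mode not in ("mean", "max"):
        raise ValueError(f"unknown similarity mode {mode!r}")
    train_fps = [fp for fp in _fingerprints(list(training_smiles)) if fp is not None]
    if not train_fps:
        raise ValueError("no parseable training SMILES for similarity")
    out: Dict[str, float] = {}
    for cid, smi in validation_smiles.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            import logging
            logging.getLogger(__name__).warning(
                "unparseable SMILES for %s; excluded from similarity", cid
            )
            continue
        fp = _AP_GENERATOR.GetFingerprint(mol)
        sims = DataStructs.BulkTanimotoSimilarity(fp, train_fps)
        out[cid] = float(np.mean(sims) if mode == "mean" else np.max(sims))
    return out


def similarity_subsets(
    mean_tc: Mapping[str, float], threshold: float = TC_SIMILAR
) -> Dict[str, List[str]]:
    """Partition compounds into "similar" (mean Tc >= threshold) and "not_similar"."""
    subsets: Dict[str, List[str]] = {"similar": [], "not_similar": []}
    for cid, tc in sorted(mean_tc.items()):
        subsets["similar" if tc >= threshold else "not_similar"].append(cid)
    return subsets


def score_similarity_subsets(
    predictions: Sequence[ConsensusPrediction],
    truths: Sequence[ValidationTruth],
    mean_tc: Mapping[str, float],
    threshold: float = TC_SIMILAR,
    probability_bin_filter: Optional[float] = None,
) -> Dict[str, Tuple[ConfusionCounts, Optional[MetricSet]]]:
    """Confusion counts and metrics per similarity subset.

    ``probability_bin_filter`` restricts the evaluation to predictions whose
    consensus bin equals the given value (e.g. 1.0 for the most confident
    calls).  Subset counts always sum to the corresponding all-validation
    counts.
    """
    pred_by_id = {p.compound_id: p for p in predictions}
    subsets = similarity_subsets(mean_tc, threshold)
    out: Dict[str, Tuple[ConfusionCounts, Optional[MetricSet]]] = {}
    for name, members in subsets.items():
        member_set = set(members)
        tally = {"TP": 0, "FN": 0, "FP": 0, "TN": 0}
        for t in truths:
            if t.compound_id not in member_set:
                continue
            p = pred_by_id[t.compound_id]
            if (probability_bin_filter is not None
                    and p.probability_bin != probability_bin_filter):
                continue
            tally[outcome(t.true_label, p.final_label)] += 1
        counts = ConfusionCounts(
            tp=tally["TP"], fn=tally["FN"], fp=tally["FP"], tn=tally["TN"]
        )
        out[name] = (counts, compute_metrics(counts) if counts.total else None)
    return out
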