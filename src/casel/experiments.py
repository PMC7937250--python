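"""End-to-end experiments on synthetic studies.

These functions wire the pipeline stages together in memory for the
benchmark questions the package answers:

* does flexible rank-based sampling beat fixed 20/100 nM thresholds on data
  with a populated intermediate band?
* does the consensus probability score stratify external-validation
  accuracy (most-confident bin at least as accurate as the overall set)?
* is performance on label-shuffled data at chance (permutation null)?
* can combined per-isoform models recover a truly selective subpopulation?
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .curation import (
    activities_frame,
    filter_primary_sulfonamide,
    filter_records,
    merge_replicates,
)
from .descriptors import compute_descriptors, drop_failed_compounds, filter_correlated
from .learning import (
    ConsensusPrediction,
    cross_validate,
    fit_predict,
    repeat_seeds,
    run_repeated,
    split_train_test,
)
from .metrics import OVERALL, compute_metrics, confusion_from_labels
from .sampling import fixed_dataset, flexible_sample
from .selectivity import SELECTIVE_OFF_OVER_II, profile_compounds
from .synth import SyntheticStudy, SyntheticStudyConfig, generate_study
from .validation import build_validation_set, score_validation


@dataclass
class StudyData:
    """A generated study, curated and featurised once."""

    study: SyntheticStudy
    curated: pd.DataFrame
    features: pd.DataFrame          # retained descriptors, indexed by compound
    descriptor_counts: Dict[str, int]

    def activities(self, isoform: str) -> Dict[str, float]:
        sub = self.curated[self.curated.isoform == isoform]
        return dict(zip(sub.compound_id, sub.activity_nM))

    def smiles(self) -> Dict[str, str]:
        return dict(zip(self.curated.compound_id, self.curated.smiles))

    def matrix(self, compound_ids: Sequence[str], labels: Sequence[int]):
        """Feature rows + aligned labels for compounds with descriptors."""
        keep = [c in self.features.index for c in compound_ids]
        ids = [c for c, k in zip(compound_ids, keep) if k]
        y = np.array([l for l, k in zip(labels, keep) if k], dtype=int)
        return self.features.loc[ids].to_numpy(), y, ids


def prepare_study(
    config: Optional[SyntheticStudyConfig] = None, pcc: Optional[float] = 0.95
) -> StudyData:
    """Generate, curate and featurise a synthetic study."""
    study = generate_study(config)
    with_zbg, _ = filter_primary_sulfonamide(filter_records(study.records))
    kept, _ = merge_replicates(with_zbg)
    curated = activities_frame(kept)
    unique = curated.drop_duplicates("compound_id")
    table = drop_failed_compounds(
        compute_descriptors(list(zip(unique.compound_id, unique.smiles)))
    )
    counts = {
        "baseline": len(filter_correlated(table, None).retained_names),
        "0.95": len(filter_correlated(table, 0.95).retained_names),
        "0.75": len(filter_correlated(table, 0.75).retained_names),
    }
    features = filter_correlated(table, pcc).to_frame(retained_only=True)
    return StudyData(study, curated, features, counts)


def _repeat_test_metrics(
    X, y, algorithm: str, test_fraction: float, repeats: int, seed: int
) -> Dict[str, float]:
    train_idx, test_idx, y_train, y_test = split_train_test(
        X, y, test_fraction, seed=seed
    )
    acc, mcc = [], []
    for s in repeat_seeds(seed, repeats):
        labels, _ = fit_predict(X[train_idx], y_train, X[test_idx], algorithm, seed=s)
        m = compute_metrics(confusion_from_labels(y_test, labels))
        acc.append(m.accuracy)
        if m.mcc is not None:
            mcc.append(m.mcc)
    return {
        "accuracy": float(np.mean(acc)),
        "mcc": float(np.mean(mcc)) if mcc else float("nan"),
        "n_test": len(y_test),
    }


def flexible_fixed_comparison(
    data: StudyData,
    isoform: str = "hCA_II",
    n: int = 150,
    algorithm: str = "ET",
    repeats: int = 10,
    test_fraction: float = 0.25,
    seed: int = 0,
) -> Dict[str, float]:
    """Repeat-averaged test metrics of the flexible vs the fixed labelling."""
    acts = data.activities(isoform)
    flex, _ = flexible_sample(acts, n, isoform)
    Xf, yf, _ = data.matrix(flex.compound_ids, flex.labels)
    flex_metrics = _repeat_test_metrics(Xf, yf, algorithm, test_fraction, repeats, seed)
    fixed = fixed_dataset(acts, isoform)
    Xx, yx, _ = data.matrix(fixed.compound_ids, fixed.labels)
    fixed_metrics = _repeat_test_metrics(Xx, yx, algorithm, test_fraction, repeats, seed)
    return {
        "flexible_mcc": flex_metrics["mcc"],
        "fixed_mcc": fixed_metrics["mcc"],
        "flexible_accuracy": flex_metrics["accuracy"],
        "fixed_accuracy": fixed_metrics["accuracy"],
        "n_flexible": 2 * n,
        "n_fixed": len(yx),
    }


def external_validation(
    data: StudyData,
    isoform: str = "hCA_II",
    n: int = 150,
    algorithm: str = "ET",
    repeats: int = 10,
    seed: int = 0,
):
    """Train on the full sampled dataset, score the unsampled validation set.

    Returns ``(predictions, truths, stratified)`` with the stratified map
    keyed by probability bin plus "overall".
    """
    acts = data.activities(isoform)
    dataset, _ = flexible_sample(acts, n, isoform)
    X, y, sampled_ids = data.matrix(dataset.compound_ids, dataset.labels)
    truths = build_validation_set(acts, sampled_ids, isoform)
    truths = [t for t in truths if t.compound_id in data.features.index]
    if not truths:
        return [], [], {}
    X_val = data.features.loc[[t.compound_id for t in truths]].to_numpy()
    preds = run_repeated(
        X, y, X_val, [t.compound_id for t in truths], algorithm,
        repeats=repeats, master_seed=seed, isoform=isoform,
    )
    return preds, truths, score_validation(preds, truths)


def permutation_null(
    data: StudyData,
    isoform: str = "hCA_II",
    n: int = 150,
    algorithm: str = "ET",
    n_shuffles: int = 10,
    k: int = 10,
    seed: int = 0,
) -> float:
    """Mean |MCC| over label shufflings — should sit at chance level."""
    acts = data.activities(isoform)
    dataset, _ = flexible_sample(acts, n, isoform)
    X, y, _ = data.matrix(dataset.compound_ids, dataset.labels)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_shuffles):
        shuffled = rng.permutation(y)
        cv = cross_validate(X, shuffled, algorithm, k=k,
                            seed=int(rng.integers(2**31 - 1)))
        if cv["mcc_mean"] is not None:
            out.append(abs(cv["mcc_mean"]))
    return float(np.mean(out))


def selectivity_recovery(
    data: StudyData,
    n: int = 150,
    algorithm: str = "ET",
    repeats: int = 10,
    seed: int = 0,
) -> Dict[str, float]:
    """Fraction of truly hCA IX-selective compounds recovered by combining
    the hCA II and hCA IX binary models on their validation sets."""
    preds: List[ConsensusPrediction] = []
    for isoform in ("hCA_II", "hCA_IX"):
        p, _, _ = external_validation(
            data, isoform=isoform, n=n, algorithm=algorithm,
            repeats=repeats, seed=seed,
        )
        preds.extend(p)
    profiles = profile_compounds(preds)
    truth = data.study.truth.set_index("compound_id")
    hits = total = 0
    for profile in profiles:
        if profile.pair != "II_vs_IX" or not profile.complete:
            continue
        if truth.loc[profile.compound_id, "true_class_II_vs_IX"] != SELECTIVE_OFF_OVER_II:
            continue
        total += 1
        hits += profile.selectivity_class == SELECTIVE_OFF_OVER_II
    return {
        "recovered_fraction": hits / total if total else float("nan"),
        "n_true_selective": total,
    }


def bin_accuracies(stratified) -> Tuple[Optional[float], Optional[float]]:
    """(overall accuracy, top-bin accuracy) from a stratified validation map."""
    overall = stratified[OVERALL][1]
    top = stratified[1.0][1]
    return (
        None if overall is None else overall.accuracy,
        None if top is None else top.accuracy,
    )
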