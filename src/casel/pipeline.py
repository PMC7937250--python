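"""Stage orchestration: simulate -> curate -> featurize -> sample -> train ->
test -> validate -> selectivity -> report.

Each stage reads the outputs of its upstream stages from the working
directory, writes flat CSV/JSON reports shaped like the study tables, and
stamps a ``manifest.json`` carrying the config (and its hash), the master
seed, package/library versions and the checksums of its inputs.  Stages are
pure with respect to upstream outputs: nothing is mutated, and a rerun with
identical config and seed reproduces the same files (manifests differ only
in their timestamp line).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__, curation, descriptors, sampling, selectivity, synth, validation
from .learning import (
    ALGORITHMS,
    DEFAULT_K,
    DEFAULT_REPEATS,
    DEFAULT_TEST_FRACTION,
    cross_validate,
    repeat_seeds,
    run_repeated,
    split_train_test,
)
from .metrics import OVERALL, round_half_away
from .validation import TC_SIMILAR

logger = logging.getLogger(__name__)

STAGES: Tuple[str, ...] = (
    "simulate", "curate", "featurize", "sample", "train", "test",
    "validate", "selectivity", "report",
)

#: Upstream artifact each stage needs: stage -> (producer stage, relative path)
_DEPENDENCIES: Dict[str, List[Tuple[str, str]]] = {
    "curate": [("simulate", "simulate/export.csv")],
    "featurize": [("curate", "curate/curated.csv")],
    "sample": [("curate", "curate/curated.csv")],
    "train": [("featurize", "featurize/descriptors.csv"),
              ("sample", "sample/labeled.csv")],
    "test": [("featurize", "featurize/descriptors.csv"),
             ("sample", "sample/labeled.csv")],
    "validate": [("featurize", "featurize/descriptors.csv"),
                 ("sample", "sample/labeled.csv")],
    "selectivity": [("validate", "validate/consensus.csv")],
    "report": [("validate", "validate/consensus.csv")],
}


@dataclass
class PipelineConfig:
    """All tunable constants of the pipeline, with study defaults.

    Every threshold is named and overridable; the config is echoed into each
    stage manifest.
    """

    workdir: Path = Path("casel_run")
    input_export: Optional[Path] = None  # None -> use the simulate stage
    active_lt: float = sampling.ACTIVE_LT_NM
    inactive_ge: float = sampling.INACTIVE_GE_NM
    n_grid: Tuple[int, ...] = sampling.DEFAULT_N_GRID
    pcc_options: Tuple[Optional[float], ...] = (None, 0.95, 0.75)
    algorithms: Tuple[str, ...] = ALGORITHMS
    validation_algorithm: str = "ET"
    k: int = DEFAULT_K
    repeats: int = DEFAULT_REPEATS
    test_fraction: float = DEFAULT_TEST_FRACTION
    tc_threshold: float = TC_SIMILAR
    isoforms: Tuple[str, ...] = curation.ISOFORMS
    seed: int = 0
    synth: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.workdir = Path(self.workdir)
        if self.input_export is not None:
            self.input_export = Path(self.input_export)
        self.n_grid = tuple(int(n) for n in self.n_grid)
        self.pcc_options = tuple(
            None if p in (None, "none", "None") else float(p)
            for p in self.pcc_options
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)

    def to_dict(self) -> Dict[str, object]:
        return {
            "workdir": str(self.workdir),
            "input_export": None if self.input_export is None else str(self.input_export),
            "active_lt": self.active_lt,
            "inactive_ge": self.inactive_ge,
            "n_grid": list(self.n_grid),
            "pcc_options": list(self.pcc_options),
            "algorithms": list(self.algorithms),
            "validation_algorithm": self.validation_algorithm,
            "k": self.k,
            "repeats": self.repeats,
            "test_fraction": self.test_fraction,
            "tc_threshold": self.tc_threshold,
            "isoforms": list(self.isoforms),
            "seed": self.seed,
            "synth": dict(self.synth),
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(
    stage_dir: Path, config: PipelineConfig, inputs: Sequence[Path]
) -> None:
    cfg = config.to_dict()
    manifest = {
        "stage": stage_dir.name,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "versions": _versions(),
        "input_checksums": {str(p): _sha256(Path(p)) for p in inputs},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _versions() -> Dict[str, str]:
    import rdkit
    import sklearn
    return {
        "casel": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "rdkit": rdkit.__version__,
        "scikit-learn": sklearn.__version__,
    }


def _check_dependencies(stage: str, config: PipelineConfig) -> List[Path]:
    needed = _DEPENDENCIES.get(stage, [])
    inputs: List[Path] = []
    for producer, rel in needed:
        if stage == "curate" and config.input_export is not None:
            inputs.append(config.input_export)
            continue
        path = config.workdir / rel
        if not path.exists():
            raise FileNotFoundError(
                f"stage {stage!r} needs {path} — run stage {producer!r} first"
            )
        inputs.append(path)
    return inputs


# --------------------------------------------------------------------------
# stages

def stage_simulate(config: PipelineConfig) -> Path:
    out = config.workdir / "simulate"
    study_config = synth.SyntheticStudyConfig(seed=config.seed, **config.synth)
    study = synth.generate_study(study_config)
    study.write(out)
    _write_manifest(out, config, [])
    logger.info("simulate: %d compounds, %d records", len(study.compounds),
                len(study.records))
    return out


def stage_curate(config: PipelineConfig) -> Path:
    inputs = _check_dependencies("curate", config)
    out = config.workdir / "curate"
    out.mkdir(parents=True, exist_ok=True)
    frame, report = curation.curate(inputs[0])
    frame.to_csv(out / "curated.csv", index=False)
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    _write_manifest(out, config, inputs)
    logger.info("curate: %d compound-isoform activities", len(frame))
    return out


def stage_featurize(config: PipelineConfig) -> Path:
    inputs = _check_dependencies("featurize", config)
    out = config.workdir / "featurize"
    out.mkdir(parents=True, exist_ok=True)
    curated = pd.read_csv(inputs[0])
    unique = curated.drop_duplicates("compound_id")[["compound_id", "smiles"]]
    table = descriptors.compute_descriptors(
        list(zip(unique.compound_id, unique.smiles))
    )
    table = descriptors.drop_failed_compounds(table)
    frame = table.to_frame()
    frame.index.name = "compound_id"
    frame.to_csv(out / "descriptors.csv")
    for pcc in config.pcc_options:
        pruned = descriptors.filter_correlated(table, pcc)
        tag = "baseline" if pcc is None else str(pcc)
        (out / f"manifest_pcc_{tag}.json").write_text(
            json.dumps(descriptors.manifest(pruned), indent=2)
        )
    _write_manifest(out, config, inputs)
    logger.info("featurize: %d compounds x %d descriptors", *table.values.shape)
    return out


def _activities_by_isoform(
    curated: pd.DataFrame, isoforms: Sequence[str]
) -> Dict[str, Dict[str, float]]:
    out: Dict[str, Dict[str, float]] = {}
    for isoform in isoforms:
        sub = curated[curated.isoform == isoform]
        out[isoform] = dict(zip(sub.compound_id, sub.activity_nM))
    return out


def stage_sample(config: PipelineConfig) -> Path:
    inputs = _check_dependencies("sample", config)
    out = config.workdir / "sample"
    out.mkdir(parents=True, exist_ok=True)
    curated = pd.read_csv(inputs[0])
    activities = _activities_by_isoform(curated, config.isoforms)

    stats_rows: List[sampling.SamplingStats] = []
    labeled_frames: List[pd.DataFrame] = []
    fixed_counts: Dict[str, Dict[str, int]] = {}
    for isoform, acts in activities.items():
        stats_rows.extend(sampling.sweep_sampling_sizes(acts, config.n_grid, isoform))
        for n in config.n_grid:
            try:
                dataset, _ = sampling.flexible_sample(acts, n, isoform)
            except ValueError:
                continue
            labeled_frames.append(dataset.to_frame())
        fixed = sampling.fixed_dataset(
            acts, isoform, config.active_lt, config.inactive_ge
        )
        labeled_frames.append(fixed.to_frame())
        fixed_counts[isoform] = sampling.class_counts_fixed(
            acts, config.active_lt, config.inactive_ge
        )
    sampling.stats_frame(stats_rows).to_csv(out / "stats.csv", index=False)
    pd.concat(labeled_frames, ignore_index=True).to_csv(out / "labeled.csv", index=False)
    (out / "fixed_class_counts.json").write_text(json.dumps(fixed_counts, indent=2))
    _write_manifest(out, config, inputs)
    return out


def _load_features(config: PipelineConfig, pcc: Optional[float]) -> pd.DataFrame:
    frame = pd.read_csv(
        config.workdir / "featurize" / "descriptors.csv", index_col="compound_id"
    )
    tag = "baseline" if pcc is None else str(pcc)
    manifest_path = config.workdir / "featurize" / f"manifest_pcc_{tag}.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        retained = [
            n for n in manifest["descriptor_names"]
            if n not in set(manifest["pruned_names"])
        ]
        return frame[retained]
    # pcc option not precomputed by featurize: prune on the fly
    table = descriptors.DescriptorTable(
        compound_ids=list(frame.index),
        descriptor_names=list(frame.columns),
        values=frame.to_numpy(),
    )
    return descriptors.filter_correlated(table, pcc).to_frame(retained_only=True)


def _load_labeled(config: PipelineConfig) -> pd.DataFrame:
    return pd.read_csv(config.workdir / "sample" / "labeled.csv")


def _dataset_matrix(
    features: pd.DataFrame, subset: pd.DataFrame
) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    ids = [c for c in subset.compound_id if c in features.index]
    sub = subset.set_index("compound_id").loc[ids]
    return features.loc[ids].to_numpy(), sub.label.to_numpy(int), ids


def stage_train(config: PipelineConfig) -> Path:
    """Training phase: stratified k-fold cross-validation on the 75% split."""
    inputs = _check_dependencies("train", config)
    out = config.workdir / "train"
    out.mkdir(parents=True, exist_ok=True)
    labeled = _load_labeled(config)
    rows = []
    for pcc in config.pcc_options:
        features = _load_features(config, pcc)
        for isoform in config.isoforms:
            flex = labeled[(labeled.isoform == isoform)
                           & (labeled.labeling_mode == "flexible")]
            for n in sorted(flex.N.dropna().unique()):
                subset = flex[flex.N == n]
                X, y, _ = _dataset_matrix(features, subset)
                train_idx, _, y_train, _ = split_train_test(
                    X, y, config.test_fraction, seed=config.seed
                )
                for algorithm in config.algorithms:
                    cv = cross_validate(
                        X[train_idx], y_train, algorithm, k=config.k,
                        seed=config.seed,
                    )
                    rows.append({
                        "phase": "train", "isoform": isoform, "N": int(n),
                        "pcc": pcc, "algorithm": algorithm,
                        **{key: cv[key] for key in (
                            "accuracy_mean", "accuracy_sd", "mcc_mean",
                            "mcc_sd", "precision_mean", "recall_mean",
                        )},
                    })
    pd.DataFrame(rows).to_csv(out / "cv_metrics.csv", index=False)
    _write_manifest(out, config, inputs)
    return out


def stage_test(config: PipelineConfig) -> Path:
    """Testing phase: fit on 75%, repeat-averaged metrics on the held-out 25%."""
    inputs = _check_dependencies("test", config)
    out = config.workdir / "test"
    out.mkdir(parents=True, exist_ok=True)
    labeled = _load_labeled(config)
    rows = []
    for pcc in config.pcc_options:
        features = _load_features(config, pcc)
        for isoform in config.isoforms:
            for mode in ("flexible", "fixed"):
                sub = labeled[(labeled.isoform == isoform)
                              & (labeled.labeling_mode == mode)]
                if mode == "flexible":
                    groups = [(int(n), sub[sub.N == n])
                              for n in sorted(sub.N.dropna().unique())]
                else:
                    groups = [(None, sub)] if len(sub) else []
                for n, subset in groups:
                    X, y, _ = _dataset_matrix(features, subset)
                    if len(np.unique(y)) < 2:
                        continue
                    train_idx, test_idx, y_train, y_test = split_train_test(
                        X, y, config.test_fraction, seed=config.seed
                    )
                    for algorithm in config.algorithms:
                        per_repeat = _test_metrics(
                            X[train_idx], y_train, X[test_idx], y_test,
                            algorithm, config,
                        )
                        rows.append({
                            "phase": "test", "isoform": isoform, "N": n,
                            "pcc": pcc, "algorithm": algorithm,
                            "labeling_mode": mode, **per_repeat,
                        })
    pd.DataFrame(rows).to_csv(out / "test_metrics.csv", index=False)
    _write_manifest(out, config, inputs)
    return out


def _test_metrics(X_train, y_train, X_test, y_test, algorithm, config):
    from .learning import fit_predict
    from .metrics import compute_metrics, confusion_from_labels
    values: Dict[str, List[float]] = {
        "accuracy": [], "mcc": [], "precision": [], "recall": [],
    }
    for seed in repeat_seeds(config.seed, config.repeats):
        labels, _ = fit_predict(X_train, y_train, X_test, algorithm, seed=seed)
        m = compute_metrics(confusion_from_labels(y_test, labels))
        for name in values:
            v = getattr(m, name)
            if v is not None:
                values[name].append(v)
    out: Dict[str, Optional[float]] = {}
    for name, vals in values.items():
        out[f"{name}_mean"] = float(np.mean(vals)) if vals else None
        out[f"{name}_sd"] = float(np.std(vals)) if vals else None
    return out


def stage_validate(config: PipelineConfig) -> Path:
    """External validation of the chosen algorithm, stratified by probability
    bin and by atom-pair Tanimoto similarity to the training set."""
    inputs = _check_dependencies("validate", config)
    out = config.workdir / "validate"
    out.mkdir(parents=True, exist_ok=True)
    curated = pd.read_csv(config.workdir / "curate" / "curated.csv")
    labeled = _load_labeled(config)
    activities = _activities_by_isoform(curated, config.isoforms)
    smiles = dict(zip(curated.compound_id, curated.smiles))

    consensus_rows = []
    report_rows = []
    similarity_rows = []
    for pcc in config.pcc_options:
        features = _load_features(config, pcc)
        for isoform in config.isoforms:
            flex = labeled[(labeled.isoform == isoform)
                           & (labeled.labeling_mode == "flexible")]
            for n in sorted(flex.N.dropna().unique()):
                subset = flex[flex.N == n]
                X, y, sampled_ids = _dataset_matrix(features, subset)
                truths = validation.build_validation_set(
                    activities[isoform], sampled_ids, isoform,
                    config.active_lt, config.inactive_ge,
                )
                truths = [t for t in truths if t.compound_id in features.index]
                if not truths:
                    continue
                X_val = features.loc[[t.compound_id for t in truths]].to_numpy()
                preds = run_repeated(
                    X, y, X_val, [t.compound_id for t in truths],
                    config.validation_algorithm, repeats=config.repeats,
                    master_seed=config.seed, isoform=isoform,
                )
                for p, t in zip(preds, truths):
                    consensus_rows.append({
                        "compound_id": p.compound_id, "isoform": isoform,
                        "N": int(n), "pcc": pcc,
                        "mean_label": p.mean_label, "sd_label": p.sd_label,
                        "mean_score": p.mean_score, "sd_score": p.sd_score,
                        "final_label": p.final_label,
                        "probability_bin": p.probability_bin,
                        "true_class": t.true_class,
                        "outcome": validation.outcome(t.true_label, p.final_label),
                    })
                strat = validation.score_validation(preds, truths)
                for key, (counts, m) in strat.items():
                    report_rows.append({
                        "isoform": isoform, "N": int(n), "pcc": pcc,
                        "bin": key, "TP": counts.tp, "FN": counts.fn,
                        "FP": counts.fp, "TN": counts.tn,
                        **{name: (None if m is None
                                  or getattr(m, name) is None
                                  else round_half_away(getattr(m, name)))
                           for name in ("accuracy", "mcc", "precision", "recall")},
                    })
                mean_tc = validation.mean_training_similarity(
                    {t.compound_id: smiles[t.compound_id] for t in truths},
                    [smiles[c] for c in sampled_ids],
                )
                by_subset = validation.score_similarity_subsets(
                    preds, truths, mean_tc, config.tc_threshold,
                    probability_bin_filter=1.0,
                )
                for name, (counts, m) in by_subset.items():
                    similarity_rows.append({
                        "isoform": isoform, "N": int(n), "pcc": pcc,
                        "subset": name, "TP": counts.tp, "FN": counts.fn,
                        "FP": counts.fp, "TN": counts.tn,
                        "mcc": None if m is None or m.mcc is None
                        else round_half_away(m.mcc),
                    })
    pd.DataFrame(consensus_rows).to_csv(out / "consensus.csv", index=False)
    pd.DataFrame(report_rows).to_csv(out / "stratified_metrics.csv", index=False)
    pd.DataFrame(similarity_rows).to_csv(out / "similarity_subsets.csv", index=False)
    _write_manifest(out, config, inputs)
    return out


def stage_selectivity(config: PipelineConfig) -> Path:
    inputs = _check_dependencies("selectivity", config)
    out = config.workdir / "selectivity"
    out.mkdir(parents=True, exist_ok=True)
    consensus = pd.read_csv(config.workdir / "validate" / "consensus.csv")
    # one prediction per compound x isoform: the most confident consensus call
    best = (consensus.sort_values("mean_score", ascending=False)
            .drop_duplicates(["compound_id", "isoform"]))
    from .learning import ConsensusPrediction
    preds = {}
    for row in best.itertuples(index=False):
        preds[(row.compound_id, row.isoform)] = ConsensusPrediction(
            compound_id=row.compound_id, isoform=row.isoform,
            repeat_labels=np.array([row.final_label]),
            repeat_scores=np.array([row.mean_score]),
            mean_label=row.mean_label, sd_label=row.sd_label,
            mean_score=row.mean_score, sd_score=row.sd_score,
            final_label=int(row.final_label),
            probability_bin=row.probability_bin,
        )
    profiles = selectivity.profile_compounds(preds)
    selectivity.profiles_frame(profiles).to_csv(out / "selectivity.csv", index=False)
    _write_manifest(out, config, inputs)
    return out


def stage_report(config: PipelineConfig) -> Path:
    inputs = _check_dependencies("report", config)
    out = config.workdir / "report"
    out.mkdir(parents=True, exist_ok=True)
    summary: Dict[str, object] = {}
    strat_path = config.workdir / "validate" / "stratified_metrics.csv"
    if strat_path.exists():
        strat = pd.read_csv(strat_path)
        overall = strat[strat["bin"] == OVERALL]
        top = strat[strat["bin"] == "1.0"]
        summary["validation_overall_accuracy_mean"] = (
            None if overall.accuracy.dropna().empty
            else float(overall.accuracy.dropna().mean())
        )
        summary["validation_top_bin_accuracy_mean"] = (
            None if top.accuracy.dropna().empty
            else float(top.accuracy.dropna().mean())
        )
    sel_path = config.workdir / "selectivity" / "selectivity.csv"
    if sel_path.exists():
        sel = pd.read_csv(sel_path)
        summary["selectivity_class_counts"] = (
            sel[sel.complete].selectivity_class.value_counts().to_dict()
        )
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    _write_manifest(out, config, inputs)
    return out


_STAGE_FUNCTIONS = {
    "simulate": stage_simulate,
    "curate": stage_curate,
    "featurize": stage_featurize,
    "sample": stage_sample,
    "train": stage_train,
    "test": stage_test,
    "validate": stage_validate,
    "selectivity": stage_selectivity,
    "report": stage_report,
}


def run_stage(stage: str, config: PipelineConfig) -> Path | List[Path]:
    """Run one pipeline stage (or "all") against the working directory."""
    if stage == "all":
        return [run_stage(s, config) for s in STAGES]
    if stage not in _STAGE_FUNCTIONS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES + ('all',)}")
    config.workdir.mkdir(parents=True, exist_ok=True)
    return _STAGE_FUNCTIONS[stage](config)
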