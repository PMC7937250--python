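"""Shared configuration of the analysis run.

One synthetic study (seed 42) flows through all numbered scripts.  The full
working tree (raw export, descriptor matrix, per-compound tables) lives
under scratch/run/; each script publishes its small summary tables into
results/.  The training/validation stages use the PCC = 0.95 feature set —
the best-performing option — while the featurize step records the pruning
manifests for all three options.
"""

import shutil
from pathlib import Path

from casel.pipeline import PipelineConfig

_ROOT = Path(__file__).resolve().parent.parent
RESULTS = _ROOT / "results"
SCRATCH = _ROOT / "scratch"


def config() -> PipelineConfig:
    return PipelineConfig(
        workdir=SCRATCH / "run",
        n_grid=(150, 250, 350),
        pcc_options=(0.95,),
        seed=42,
    )


def featurize_config() -> PipelineConfig:
    cfg = config()
    cfg.pcc_options = (None, 0.95, 0.75)
    return cfg


def publish(cfg: PipelineConfig, *relative_paths: str) -> None:
    """Copy small summary artifacts from the scratch workdir into results/."""
    for rel in relative_paths:
        src = cfg.workdir / rel
        dst = RESULTS / rel
        dst.parent.mkdir(parents=True, exist_ok=True)
        shutil.copyfile(src, dst)
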