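"""Train the ten classification algorithms and evaluate them.

Training phase: stratified tenfold cross-validation on the 75% split.
Testing phase: repeat-averaged metrics on the held-out 25%, for both the
flexible rank-sampled datasets and the fixed-threshold datasets.
"""

import pandas as pd

from common import config, publish
from casel.pipeline import run_stage

cfg = config()
run_stage("train", cfg)
run_stage("test", cfg)

cv = pd.read_csv(cfg.workdir / "train" / "cv_metrics.csv")
test = pd.read_csv(cfg.workdir / "test" / "test_metrics.csv")

print("cross-validation MCC by algorithm (mean over isoforms and N):")
ranking = cv.groupby("algorithm").mcc_mean.mean().sort_values(ascending=False)
print(ranking.round(3).to_string())
best = ranking.index[0]
print(f"\nbest algorithm by CV MCC: {best}")

flex = test[(test.labeling_mode == "flexible") & (test.algorithm == "ET")]
fixed = test[(test.labeling_mode == "fixed") & (test.algorithm == "ET")]
print("\nextra trees, testing phase (held-out 25%):")
for isoform in flex.isoform.unique():
    fmcc = flex[flex.isoform == isoform].mcc_mean.max()
    xmcc = fixed[fixed.isoform == isoform].mcc_mean.max()
    print(f"  {isoform}: flexible MCC (max over N) {fmcc:.2f} "
          f"vs fixed-threshold MCC {xmcc:.2f}")
publish(cfg, "train/cv_metrics.csv", "test/test_metrics.csv")
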