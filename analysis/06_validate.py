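"""External validation under screening-like conditions.

Extra-trees models trained on each full sampled dataset classify the
unsampled compounds with activity < 20 nM or > 100 nM.  Results are
stratified by consensus probability bin and by atom-pair Tanimoto
similarity to the training set (threshold 0.336).
"""

import pandas as pd

from common import config, publish
from casel.pipeline import run_stage

cfg = config()
run_stage("validate", cfg)

strat = pd.read_csv(cfg.workdir / "validate" / "stratified_metrics.csv")
print("validation accuracy: overall vs most-confident (1.0) probability bin")
for (isoform, n), group in strat.groupby(["isoform", "N"]):
    overall = group[group["bin"] == "overall"].accuracy.iloc[0]
    top = group[group["bin"] == "1.0"].accuracy.iloc[0]
    print(f"  {isoform}, N={n}: overall {overall:.2f} -> top bin {top:.2f}")

sim = pd.read_csv(cfg.workdir / "validate" / "similarity_subsets.csv")
print("\nMCC at probability 1.0 by training-set similarity subset:")
print(sim.pivot_table(index=["isoform", "N"], columns="subset", values="mcc")
      .round(2).to_string())
publish(cfg, "validate/stratified_metrics.csv", "validate/similarity_subsets.csv")
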