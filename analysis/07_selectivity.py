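"""Combine validated per-isoform activity labels into selectivity profiles
and summarise the run.

The therapeutically interesting class is "selective for hCA IX (or XII)
over hCA II": active on the tumour-associated isoform, inactive on the
homeostatic off-target.
"""

import json

import pandas as pd

from common import config, publish
from casel.pipeline import run_stage

cfg = config()
run_stage("selectivity", cfg)
run_stage("report", cfg)

sel = pd.read_csv(cfg.workdir / "selectivity" / "selectivity.csv")
complete = sel[sel.complete]
print(f"profiles: {len(sel)} ({len(complete)} complete; incomplete profiles "
      "lack a prediction on one isoform because the compound was sampled "
      "into that model's training set)")
print("\nselectivity classes among complete profiles:")
print(complete.groupby(["pair", "description"]).size().to_string())

interesting = complete[
    complete.selectivity_class == "selective_off_isoform_over_II"
].sort_values("min_confidence", ascending=False)
print("\ntop candidates selective over hCA II (by combined confidence):")
print(interesting.head(8)[
    ["compound_id", "pair", "min_confidence"]
].to_string(index=False))

summary = json.loads((cfg.workdir / "report" / "summary.json").read_text())
print("\nrun summary:", json.dumps(summary, indent=2))
publish(cfg, "selectivity/selectivity.csv", "report/summary.json")
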