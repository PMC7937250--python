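"""Build activity classes: flexible rank-based sampling at N = 150/250/350
per isoform, plus the fixed 20/100 nM labelling.

The boundary-statistics table shows how the effective class thresholds and
their separation (the "closest ratio" between the first inactive and the
last active) change with N, and where data-poor isoforms run out of
inactives.
"""

import json

import pandas as pd

from common import config, publish
from casel.pipeline import run_stage

cfg = config()
run_stage("sample", cfg)

stats = pd.read_csv(cfg.workdir / "sample" / "stats.csv")
print("flexible-sampling boundary statistics:")
print(stats.to_string(index=False))
counts = json.loads((cfg.workdir / "sample" / "fixed_class_counts.json").read_text())
print("\nfixed-threshold class counts (< 20 nM active, >= 100 nM inactive):")
for isoform, c in counts.items():
    print(f"  {isoform}: {c['active']} active / {c['intermediate']} intermediate "
          f"/ {c['inactive']} inactive  -> unbalanced classes")
publish(cfg, "sample/stats.csv", "sample/fixed_class_counts.json")
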