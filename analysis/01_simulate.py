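"""Generate the synthetic bioactivity study.

Writes a ChEMBL-export-shaped activity table for the three carbonic
anhydrase isoforms (with replicates, conflicting records, censored ">"
entries and a structurally selective subpopulation) plus the ground-truth
table, under scratch/run/simulate/; the config echo is published to
results/.
"""

import numpy as np
import pandas as pd

from common import config, publish
from casel.pipeline import run_stage

cfg = config()
run_stage("simulate", cfg)

export = pd.read_csv(cfg.workdir / "simulate" / "export.csv")
truth = pd.read_csv(cfg.workdir / "simulate" / "truth.csv")
print(f"records: {len(export)}, unique molecules: {export.molecule_chembl_id.nunique()}")
multi = export.groupby(["molecule_chembl_id", "target_chembl_id"]).size()
print(f"fraction of compound-target groups with replicates: {(multi > 1).mean():.3f}")
print(f"censored '>' records: {(export.standard_relation == '>').sum()}")
print(f"structurally selective compounds: {truth.is_selective.sum()} "
      f"({truth.is_selective.mean():.0%})")
for target, name in [("CHEMBL205", "hCA II"), ("CHEMBL3594", "hCA IX"),
                     ("CHEMBL3242", "hCA XII")]:
    sub = export[export.target_chembl_id == target]
    below = (sub.standard_value < 100).mean()
    print(f"{name}: {len(sub)} records, {below:.0%} below 100 nM "
          "(skewed towards potency, as in public bioactivity data)")
publish(cfg, "simulate/config.json")
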