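"""Curate the raw export: endpoint/unit/relation filters, the primary
sulfonamide zinc-binding-group filter, and replicate merging.

Writes one activity value per compound x isoform to scratch/run/curate/.
"""

import json

import pandas as pd

from common import config, publish
from casel.pipeline import run_stage

cfg = config()
run_stage("curate", cfg)

report = json.loads((cfg.workdir / "curate" / "report.json").read_text())
curated = pd.read_csv(cfg.workdir / "curate" / "curated.csv")
print(f"input records: {report['n_input']}")
print(f"removed by unit/endpoint/relation/target filters: {report['n_removed_filter']}")
print(f"removed by the primary-sulfonamide filter: {report['n_removed_zbg']}")
print(f"replicate groups discarded (noisy, n <= 5): {report['n_groups_discarded']}")
print(f"curated activities: {report['n_compound_activities']}")
print("\nper-isoform counts and merge provenance:")
print(curated.groupby(["isoform", "merge_rule"]).size().unstack(fill_value=0))
publish(cfg, "curate/report.json")
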