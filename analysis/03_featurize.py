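"""Compute the 118-descriptor baseline matrix and prune correlated features.

Records pruning manifests for no pruning, |PCC| < 0.95 and |PCC| < 0.75
under scratch/run/featurize/ and publishes them to results/.
"""

import json

from common import featurize_config, publish
from casel.pipeline import run_stage

cfg = featurize_config()
run_stage("featurize", cfg)

for tag in ("baseline", "0.95", "0.75"):
    manifest = json.loads(
        (cfg.workdir / "featurize" / f"manifest_pcc_{tag}.json").read_text()
    )
    print(f"PCC threshold {tag}: {manifest['n_retained']} of "
          f"{manifest['n_descriptors']} descriptors retained")
    if manifest["constant_columns"]:
        print(f"  constant columns (retained, uninformative): "
              f"{manifest['constant_columns']}")
publish(cfg, "featurize/manifest_pcc_baseline.json", "featurize/manifest_pcc_0.95.json", "featurize/manifest_pcc_0.75.json")
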