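"""Run the end-to-end pipeline from a YAML-style config and inspect the
provenance manifest.

The imaging branch (phantom -> parcellate -> track -> build-net) and the
cohort branch (simulate -> metrics -> stats) run in one invocation; every
output is a plain-text file and the manifest hash-stamps each one, so an
identical config always reproduces identical bytes.
"""

import json
from pathlib import Path

from hemiconn.pipeline import PipelineConfig, run_pipeline, save_config

out = Path("scratch/pipeline_demo")
config = PipelineConfig(
    seed=1,
    out_dir=str(out),
    stages=("simulate", "parcellate", "track", "build-net", "metrics", "stats"),
    n_rois=6,
    cohort=dict(n_per_group={"NC": 14, "MCI": 14, "AD": 10},
                n_nodes=16, density=0.5),
    phantom=dict(grid_shape=(23, 13, 9), voxel_size=(2.0, 2.0, 2.0),
                 bundles=[dict(points=[(4, -8, 0), (18, -8, 0)],
                               radius=2.5, fa=0.8),
                          dict(points=[(-4, -8, 0), (-18, -8, 0)],
                               radius=2.5, fa=0.8)]))
out.parent.mkdir(parents=True, exist_ok=True)
save_config(config, out.parent / "pipeline_demo.yaml")

manifest = run_pipeline(config)
print("stage row counts:", json.dumps(manifest["counts"], indent=1))
print("outputs:", ", ".join(sorted(manifest["outputs"])))
print("config hash:", manifest["config_sha256"][:16], "...")
print("re-running with the same config reproduces these hashes exactly.")
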