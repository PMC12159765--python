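"""One seeded end-to-end run of the full synthetic study.

Simulates a small three-group cohort, preprocesses every recording,
inverts to source space, computes band PAC / connectivity / power,
runs the group statistics and the BT-vs-NBT classifier, and writes all
result tables plus a manifest into a run directory.
"""

import pandas as pd

from crossfreq.pipeline import CohortConfig, PipelineConfig, run

config = PipelineConfig(
    cohort=CohortConfig(n_bt=5, n_nbt=5, n_hc=5, duration_s=16.0, n_rois=4),
    seed=7,
    out_dir="scratch/example_run",
)
out = run(config, force=True)

print(f"run directory: {out}")
print(pd.read_csv(out / "classification.tsv", sep="\t").to_string(index=False))
aov = pd.read_csv(out / "anova.tsv", sep="\t")
inter = aov[aov.effect == "ROI×Group"]
print(inter[["pair", "dv", "F", "p"]].to_string(index=False))
print("-> tables are bit-identical on re-run with the same seed; the")
print("   manifest records config, sub-seeds and table hashes.")
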