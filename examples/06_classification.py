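"""Feature ablation: what PAC features add to connectivity features.

Constructs a cohort where only the theta-gamma PAC features carry group
signal, then compares LOOCV KNN accuracy for connectivity-only (FC) vs
connectivity+PAC feature sets.
"""

import numpy as np
import pandas as pd

from crossfreq import assemble_features, feature_ablation

rng = np.random.default_rng(8)
subjects = [(f"s{i:02d}", "BT" if i < 12 else "NBT") for i in range(24)]

rows = []
for sid, grp in subjects:
    for roi in ("HES_L", "HES_R", "STG_L", "STG_R"):
        rows.append({
            "subject_id": sid, "group": grp, "roi": roi,
            "theta_beta_mi": rng.normal(0.10, 0.02),
            "theta_gamma_mi": rng.normal(0.10, 0.02)
            + (0.08 if grp == "BT" else 0.0),
        })
pac = pd.DataFrame(rows)
connectivity = {"wpli_gamma": {sid: np.abs(rng.random((6, 6)))
                               for sid, _ in subjects}}  # pure noise

tables = {combo: assemble_features(pac_table=pac, connectivity=connectivity,
                                   combo=combo)
          for combo in ("FC", "FC+PAC", "PAC")}
for rep in feature_ablation(tables, k=5, n_components=5):
    print(f"{rep.feature_set:8s} accuracy={rep.accuracy:.3f} "
          f"sensitivity={rep.sensitivity:.3f} specificity={rep.specificity:.3f}")
print("-> combinations containing the PAC block reach high accuracy; the")
print("   noise connectivity features alone stay near chance.")
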