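"""Minimum-norm source recovery through an abstract leadfield.

Simulates one subject (26 ROIs, 52 sources, 32 sensors, 20 dB SNR),
projects the sensors back to source space with the regularised
minimum-norm estimate, aggregates ROI series and compares them with the
ground truth.
"""

import numpy as np

from crossfreq import aggregate_rois, generate_leadfield, mne_inverse
from crossfreq.synthetic import RoiProfile, generate_subject

labels = [f"R{i:02d}" for i in range(26)]
leadfield = generate_leadfield(n_sensors=32, n_sources=52, roi_labels=labels,
                               seed=0)
profiles = [RoiProfile(r, theta_beta_depth=0.2, theta_gamma_depth=0.4)
            for r in labels]
sensors, truth = generate_subject(profiles, leadfield, duration_s=20.0,
                                  fs=500.0, seed=1, sensor_snr_db=20.0)

sources = mne_inverse(sensors, leadfield)
roi = aggregate_rois(sources, leadfield.roi_map, labels, fs=500.0)

cors = [np.corrcoef(truth[r], roi.data[0, r])[0, 1] for r in range(26)]
print(f"sensors: {sensors.shape}, sources: {sources.shape}")
print(f"true-vs-estimated ROI correlation: median {np.median(cors):.3f}, "
      f"min {min(cors):.3f}")
print("-> the linear inverse cannot undo all source mixing (32 sensors for")
print("   52 sources) but ROI time courses are recovered with high fidelity.")
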