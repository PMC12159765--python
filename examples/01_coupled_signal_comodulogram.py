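"""Plant a theta→gamma coupling and recover it from the comodulogram.

Generates 60 s of synthetic EEG in which the amplitude of a 40 Hz
carrier is modulated by the phase of a 6 Hz rhythm (depth 0.9) over a
1/f background, then scans the full KL-MI filter-bank grid.
"""

import numpy as np

from crossfreq import CouplingSpec, comodulogram, generate_coupled_signal

spec = CouplingSpec(phase_freq=6.0, amp_freq=40.0, modulation_depth=0.9)
signal = generate_coupled_signal(spec, duration_s=60.0, fs=500.0, seed=1)

com = comodulogram(signal, fs=500.0)
phase_hz, amp_hz = com.argmax()

print(f"planted coupling: phase {spec.phase_freq} Hz -> amplitude {spec.amp_freq} Hz")
print(f"comodulogram argmax: phase {phase_hz} Hz, amplitude {amp_hz} Hz")
print(f"peak KL-MI: {com.max_mi():.4f}")
print("-> the grid maximum sits on the planted pair; the MI value is the")
print("   normalized KL divergence of the phase-binned amplitude profile.")
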