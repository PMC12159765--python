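"""Coherence, PLV, PLI and wPLI on constructed signal pairs.

Three canonical cases: identical signals (zero lag), a constant
quarter-cycle lag, and independent noise.
"""

import numpy as np

from crossfreq import coherence, cross_spectra, pli, plv, wpli
from crossfreq.inverse import ROISeries

rng = np.random.default_rng(3)
fs, band = 500.0, (9.5, 10.5)
t = np.arange(1000) / fs


def report(name, data):
    cs = cross_spectra(ROISeries(data=data, fs=fs, roi_labels=("x", "y")),
                       band)
    vals = {m.__name__: m(cs).values[0, 1]
            for m in (coherence, plv, pli, wpli)}
    print(f"{name:16s} " + "  ".join(f"{k}={v:.3f}" for k, v in vals.items()))


x = rng.standard_normal((40, 1, 1000))
report("identical", np.concatenate([x, x], axis=1))

lagged = np.stack(
    [np.stack([np.sin(2 * np.pi * 10 * t) + 0.01 * rng.standard_normal(1000),
               np.sin(2 * np.pi * 10 * (t - 1 / 40))
               + 0.01 * rng.standard_normal(1000)])
     for _ in range(40)]
)
report("quarter-cycle", lagged)

report("independent", rng.standard_normal((40, 2, 1000)))

print("-> identical signals: full coherence/PLV but zero PLI/wPLI (the lag-")
print("   based metrics discount zero-lag, volume-conduction-like coupling);")
print("   a true constant lag drives all four up; noise leaves all low.")
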