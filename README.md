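# crossfreq

Source-level cross-frequency coupling analysis of resting-state EEG,
built for studies that ask whether theta-phase → beta/gamma-amplitude
coupling separates clinical groups — the motivating case being
bothersome tinnitus (BT), non-bothersome tinnitus (NBT, Tinnitus
Handicap Inventory ≤ 36) and healthy controls (HC), under the
thalamocortical-dysrhythmia picture in which deafferentation-driven
low-frequency rhythms drag high-frequency activity along with them.

The package covers the whole analysis chain as a library:

- **synthetic cohorts** with known, planted coupling structure
  (`crossfreq.synthetic`): 1/f background, narrowband oscillators,
  Tort-style amplitude modulation per ROI per group, leadfield mixing to
  sensors, THI scores drawn per group and thresholded at 36;
- **preprocessing** (`crossfreq.io`): EDF/delimited I/O, zero-phase
  0.5–150 Hz band-pass + 50 Hz notch, polyphase resampling to 500 Hz,
  2-s epoching, peak-to-peak epoch rejection;
- **source imaging** (`crossfreq.inverse`): minimum-norm estimate
  Ŝ = Lᵀ(LLᵀ + λI)⁻¹X with an SNR-based λ default, per-epoch detrending,
  signed-mean aggregation into 26 AAL-named ROIs;
- **the central statistic** (`crossfreq.pac`): the Kullback–Leibler
  modulation index. Amplitudes are sorted into 18 phase bins (20°) and
  the binned mean-amplitude distribution P is compared with uniform,

  MI = KL(P‖U)/log 18 = (log 18 − H(P))/log 18 ∈ [0, 1],

  evaluated over a (phase × amplitude) filter-bank grid (comodulogram)
  and averaged over a-priori boxes: theta–beta (4–8 × 13–30 Hz) and
  theta–gamma (4–8 × 30–70 Hz), one value per ROI per subject;
- **auxiliary coupling** (`crossfreq.spectral`): Hann/Welch PSD, relative
  band power, Spearman power–power coupling, amplitude–amplitude
  coupling (across-epoch power correlation, 2–70 Hz);
- **connectivity** (`crossfreq.connectivity`): coherence, PLV, PLI and
  wPLI from per-epoch cross-spectra, with edge-wise Welch-t group
  contrasts under Benjamini–Hochberg FDR;
- **group statistics** (`crossfreq.stats`): Shapiro–Wilk screening,
  ROI (within) × Group (between) mixed ANOVA, subject-level bootstrap
  post-hoc (1000 resamples, shift-method null) with FDR, PAC–THI
  correlation;
- **classification** (`crossfreq.classify`): Fisher-criterion feature
  reduction and k-nearest-neighbour classification under leave-one-out
  cross-validation, with systematic feature-set ablation (FC, FC+power,
  FC+PAC, PAC, all);
- **orchestration** (`crossfreq.pipeline` + the `crossfreq` CLI): one
  seeded, configured run from simulation to result tables with a
  hash-recording manifest.

Because every stage is validated against the generator's ground truth,
the package doubles as a test bench for PAC methodology: plant a
coupling, push it through sensors, the inverse and the estimator, and
check what survives.

## Worked example

```python
from crossfreq import CouplingSpec, comodulogram, generate_coupled_signal

spec = CouplingSpec(phase_freq=6.0, amp_freq=40.0, modulation_depth=0.9)
signal = generate_coupled_signal(spec, duration_s=60.0, fs=500.0, seed=1)
com = comodulogram(signal, fs=500.0)
print(com.argmax(), round(com.max_mi(), 4))
```

prints

```
(6.0, 40.0) 0.057
```

— the comodulogram's global maximum lands exactly on the planted
(6 Hz, 40 Hz) pair, and the peak MI of 0.057 is the normalized KL
divergence of the theta-binned 40 Hz amplitude profile (0 = amplitude
independent of phase, 1 = all amplitude in one 20° bin). The
`examples/` directory holds one short script per capability
(preprocessing, inverse recovery, connectivity contracts, group
statistics, classification, the full pipeline), each printing the
numbers it computes and what they mean.

A full end-to-end study runs from the shell:

```sh
crossfreq run --seed 7 --out my_run
```

and writes `pac_table.tsv`, per-band connectivity tables, `anova.tsv`,
`posthoc.tsv`, `pac_thi_correlation.tsv`, `classification.tsv` and a
`manifest.json` with config, sub-seeds and SHA-256 hashes; re-running
with the same seed reproduces every table bit-identically.

## Scope

The leadfield is an abstract full-rank mixing matrix — no electrode
geometry, BEM physics or MRI handling — and artifact handling is a
deterministic amplitude criterion, not ICA. Planted modulation depths
are calibration knobs for the estimation chain, not estimates of any
real clinical effect size. See `docs/methods.md` for the model, the
numerical choices and their rationale.
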