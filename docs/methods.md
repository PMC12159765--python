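# Methods

## The estimand

For a phase frequency f_p and amplitude frequency f_a, phase–amplitude
coupling (PAC) is quantified by the Kullback–Leibler modulation index.
The signal is band-passed around f_p and around f_a, the Hilbert
transform yields the instantaneous phase φ(t) of the low band and the
instantaneous amplitude A(t) of the high band, phases are sorted into
n = 18 bins of 20°, and the bin-wise mean amplitudes, normalized to sum
to one, form a distribution P. Then

    MI = KL(P ‖ U) / log n = (log n − H(P)) / log n,

so MI = 0 when amplitude is independent of phase and MI = 1 when all
amplitude mass falls in a single bin. MI is invariant to amplitude
rescaling and to circular relabeling of bins; both invariances are
tested. Tiny negative values from float round-off (≈ −1e-16 for exactly
uniform P) are clamped to 0.

A comodulogram evaluates MI on a grid: phase bands of 2 Hz bandwidth
with lower edges 1, 3, 5, 7 Hz (centers 2–8 Hz) and amplitude centers
8–148 Hz in 2 Hz steps. Band-level PAC averages MI over admissible grid
cells whose centers fall in the theta × beta (4–8 × 13–30 Hz) or
theta × gamma (4–8 × 30–70 Hz) box, giving one theta–beta and one
theta–gamma value per ROI per subject.

## Filter design — why the amplitude window adapts to the phase band

Amplitude modulation at f_p places side-bands at f_a ± f_p. A filter
around f_a narrower than 2·f_p removes those side-bands and is blind to
the very coupling being measured; conversely, very short (leaky)
filters let distant spectral structure into every band, and because MI
is amplitude-scale-invariant, cells containing only leakage can show
*higher* MI than the true cell (a weak leaked side-band beating against
a weak leaked carrier produces a deeply modulated envelope). Both
failure modes were confirmed numerically during development: with
either a literal 2 Hz amplitude bandwidth or an order tied to the
band's lower edge, the comodulogram maximum sits systematically 4–10 Hz
away from a planted pair.

The design adopted here follows the standard guidance that the
amplitude bandwidth must exceed twice the phase frequency:

- **phase filters**: 2 Hz bandwidth, windowed-sinc FIR with ≈ 1 Hz
  transition (order ≈ 3.3·fs), so a band's phase cannot be inherited
  from a strong neighbouring rhythm;
- **amplitude filters**: for each (f_p, f_a) cell, half-width
  1.5·f_p around f_a with transition ≈ f_p (order ≈ 3.3·fs/f_p), so
  both modulation side-bands pass while content one half-width further
  out is strongly attenuated;
- **admissibility**: a cell is evaluated only when the amplitude window
  lies strictly above the phase band and below Nyquist; inadmissible and
  degenerate cells (phase bins unpopulatable) are NaN.

All filters are applied zero-phase (forward–backward, implemented as a
single FFT convolution with the kernel's autocorrelation after odd edge
extension), which preserves phase estimates. With this design the
comodulogram argmax recovers a planted (6 Hz, 40 Hz) coupling of depth
0.9 exactly across seeds at the generator's default background noise.
At zero background noise the argmax is ill-posed for *any* banked
estimator — empty bands inherit leaked modulated structure at full
relative depth — so recovery is specified and tested under the
realistic 1/f background, not in the noiseless limit.

Epoched data are filtered as one concatenated record (epochs are
contiguous segments of one recording, so concatenation restores
continuity up to rejected-epoch seams); 0.25 s is trimmed from each
epoch edge before phase/amplitude samples are pooled across epochs into
a single binning. Pooling (rather than averaging per-epoch MI) uses all
samples in one distribution and keeps short epochs usable. Continuous
input is trimmed at both ends by the longer of the two filters'
lengths. Practical minimum: the sharp phase filters need roughly 10 s
of (kept) signal at 500 Hz.

Surrogate calibration uses random circular shifts of the amplitude
series (guarded away from the record ends), which preserve both
marginals while destroying alignment. For grid-level inference the
surrogate statistic is the *maximum* MI over all admissible cells under
one common shift, so the null accounts for the maximum over multiple
comparisons.

## Synthetic cohorts

Per ROI, the source signal is

    x(t) = a_θ sin(2π f_p t + ψ)
         + [1 + m_β cos(2π f_p t + ψ)] a_β sin(2π f_β t + ψ_β)
         + [1 + m_γ cos(2π f_p t + ψ)] a_γ sin(2π f_γ t + ψ_γ)
         + 1/f noise,

with f_p = 6 Hz, carriers f_β = 20 Hz and f_γ = 45 Hz inside the
analysis boxes, depths m ∈ [0, 1] set per ROI per group, band
amplitudes from a relative-power map (theta 1.0, beta 0.5, gamma 0.3),
and Gaussian background with power ∝ 1/f at unit variance — the
dominant structure of resting EEG spectra. Default group profiles plant
the qualitative pattern of interest: enhanced theta–beta/theta–gamma
depths in auditory/limbic ROIs for BT (0.65) over NBT (0.35) over
HC (0.15), and attenuated theta–gamma depth in orbitofrontal ROIs for
BT; per-subject depths get N(0, 0.05) jitter, clipped to [0, 1].

Sources (default two per ROI, sharing the ROI signal plus 10%-SD
independent 1/f noise) are mixed to sensors by an abstract full-rank
Gaussian leadfield (entries N(0, 1/n_sensors), round-robin ROI
ownership); white sensor noise is added at 20 dB SNR and the sensor
block is scaled to 7 µV RMS — a typical resting-EEG scale that keeps
clean epochs comfortably inside the ±100 µV rejection bound. The
ground truth returned alongside is the signed mean over each ROI's
sources under the identical scaling, i.e. exactly what a perfect
inverse-plus-aggregation would produce.

Cohort structure: group sizes default to 21 BT / 27 NBT / 21 HC. THI
scores are drawn from per-group normals (BT 44.43 ± 9.32,
NBT 18.52 ± 11.22), clipped to [0, 100] and rejection-sampled to the
36-point threshold (BT > 36, NBT ≤ 36; a draw of exactly 36 is NBT);
controls carry no THI. All randomness flows from one master seed
through `numpy` SeedSequence spawning: subject realisations are
independent streams, regenerated on demand so large cohorts never sit
in memory, and everything is bit-reproducible.

What the generator does *not* emulate: electrode geometry and head
physics (the leadfield is abstract), non-stationarity, eye/muscle/heart
artifacts beyond amplitude outliers, 50 Hz line noise (unless added by
hand), and realistic effect sizes — planted depths are calibration
knobs. Passing tests therefore demonstrate correctness of the
estimation chain, not clinical validity on real EEG.

## Preprocessing

Band-pass 0.5–150 Hz (zero-phase windowed-sinc FIR, order tied to the
0.5 Hz edge, capped at a third of the record) plus a second-order IIR
notch at 50 Hz (Q = 30, forward–backward). Resampling to 500 Hz by
polyphase rational resampling; segmentation into 2-s epochs with the
trailing partial epoch discarded (a sub-epoch recording yields zero
epochs with a warning). Artifact handling is a deterministic
peak-to-peak criterion: an epoch is kept only if every channel's
peak-to-peak lies within [flatline_threshold, abs_threshold]
(defaults 1e-3 and 100 µV); rejecting everything is an error that names
the remedy. Manual inspection and ICA are deliberately out of scope —
they are not reproducible operations.

## Source inverse

Ŝ = Lᵀ(LLᵀ + λI)⁻¹X with scalar (fixed-orientation) sources. λ defaults
to trace(LLᵀ)/(n_sensors·SNR²) with SNR = 3, standard minimum-norm
practice; λ = 0 is honoured only for full-row-rank leadfields and
otherwise raises with advice to regularise. "Noise regression in time"
is implemented as per-epoch, per-channel mean and linear-trend removal
(idempotent). ROI series are the signed mean over the ROI's sources —
the simplest faithful aggregation; it can cancel opposed sources, which
is documented and tested rather than hidden. The packaged registry
lists the 26 analysis ROIs (13 bilateral pairs: Heschl, superior/
middle/inferior temporal, superior/middle/inferior orbitofrontal,
anterior/dorsal/posterior cingulate, hippocampus, parahippocampus,
insula). At 20 dB sensor SNR with 32 sensors and 52 sources, the
median true-vs-estimated ROI-series correlation exceeds 0.8.

## Spectral measures

PSD is the mean over non-overlapping 2-s Hann-windowed epochs (Welch
with zero overlap), 0.5 Hz resolution, Parseval-consistent within 1%.
Band power integrates the PSD over theta/beta/gamma and normalizes by
broadband (0.5–150 Hz) power. Power–power coupling is Spearman's ρ;
the two-sided p-value is exact (full permutation enumeration) for
n ≤ 9 and the t-approximation above — the enumeration bound is set by
the factorial growth of the permutation set. AAC correlates squared
Hann-FFT moduli across epochs on a 2–70 Hz, 0.5 Hz grid (Pearson by
default, Spearman optional). Known and tested behaviour: a global
amplitude scale leaves AAC unchanged, while epoch-wise gain
fluctuations induce uniform positive AAC.

## Connectivity

From per-epoch Hann FFT coefficients, with expectations over epochs:
Coh = |⟨S_xy⟩|²/(⟨S_xx⟩⟨S_yy⟩), PLV = |⟨e^{i arg S_xy}⟩|,
PLI = |⟨sign Im S_xy⟩|, wPLI = |⟨Im S_xy⟩|/⟨|Im S_xy|⟩ (defined as 0
when the denominator vanishes, e.g. exactly zero-lag signals). Band
values are unweighted means over in-band FFT bins. Group contrasts:
two-sided Welch t per edge — on Fisher-z values for coherence/PLV
(variance stabilization for correlation-like quantities), raw for
PLI/wPLI — with BH-FDR across edges; zero-variance edges get p = 1 and
a degeneracy flag.

## Statistics

Shapiro–Wilk screens normality (3 ≤ n ≤ 5000) and provides the
normal/non-normal routing flag at p = 0.05. The group comparison is a
mixed-design ANOVA, ROI within × Group between, computed via pingouin,
run on one group pair at a time; all-equal input returns F = 0 for
every effect, and a Bonferroni-adjusted p is reported with family size
4 (two bands × two group pairs — the natural reading of the analysis
family). No sphericity correction by default. Post-hoc, each ROI's
group mean difference is tested by resampling subjects with replacement
within groups (n_boot = 1000): the null is the resampled difference
distribution re-centered on the observed difference (shift method), the
two-sided p is add-one corrected, and BH-FDR runs across ROIs. Under a
simulated null the interaction and the bootstrap p both hold their
nominal 5% level (measured in the acceptance suite), and a d = 2 shift
is detected with ≥ 90% power at n = 10 per group. PAC–THI correlation
is Pearson's r from the regression slope (Spearman optional), requiring
n ≥ 4 and variance in both variables; control subjects without THI are
dropped.

## Classification

Features per subject: band PAC per ROI (theta–beta and theta–gamma),
upper-triangle connectivity edges per metric/band, and per-ROI relative
band powers, joined by named blocks with strict subject alignment.
Evaluation is leave-one-out cross-validation with, inside every fold:
z-scoring fit on the training split, Fisher reduction fit on the
training split, then a KNN vote (Euclidean, default k = 5, odd to avoid
two-class ties). Fisher reduction defaults to per-feature discriminant
scoring (μ₁−μ₂)²/(s₁²+s₂²) keeping the top m = 10 features — for two
classes the canonical LDA projection yields a single component, so
scoring is the more useful default; the projection (ridge-regularised
when the within-class scatter is singular) remains available. BT is the
positive class: sensitivity is BT recall, specificity NBT recall.
Feature-set ablation runs identical folds across combinations and sorts
by accuracy. No leakage: the held-out subject never touches its fold's
scaler or reducer (tested by refitting a fold manually).

## Pipeline and problem sizes

`pipeline.run` validates a pydantic config, fans the master seed into
named sub-seeds (simulate / bootstrap / classifier), processes subjects
one at a time (constant memory), and writes TSV tables plus a manifest
of config, sub-seeds and SHA-256 table hashes; identical config and
seed reproduce every byte. The default configuration simulates
21/27/21 subjects, 8 ROIs, 60 s each; the test suite and the acceptance
script use scaled-down cohorts (5–12 subjects per group, 4–6 ROIs,
16–30 s) — the estimator properties under test are size-independent,
and these sizes keep a complete run in tens of seconds on one CPU.
Comodulograms in the per-subject pipeline are restricted to the two
analysis boxes; the full 2–148 Hz grid is available through
`comodulogram` directly.

## Known limitations

- The minimum-norm inverse leaves crosstalk between ROIs sharing
  leadfield structure; recovery is quantified by correlation with
  ground truth, not assumed.
- Signed-mean ROI aggregation can cancel opposed sources.
- The EDF writer covers the package's own recordings (16-bit, 1-s
  records, integer sampling rates); it is not a general EDF(+) library,
  and round-trips are verified against mne's independent reader.
- Band PAC values depend on the filter-bank geometry; comparisons are
  meaningful within one configuration, not across configurations.
- The exact-permutation Spearman p is limited to n ≤ 9.
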