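# Methods

This package quantifies residual signal quality in simultaneous EEG-fMRI:
after the conventional artifact corrections, how much does the EEG spectrum
and the fMRI temporal SNR still differ between recording separately and
recording simultaneously? Every stage is exercised on synthetic sessions with
known ground truth, so the whole chain is testable offline.

## Recording conditions

Four conditions are modeled, mirroring a typical quality-assessment protocol:

| tag | setting | artifacts present |
|---|---|---|
| `separate` | EEG lab, non-MR system | none |
| `outside` | MR-compatible system, control room | none |
| `pre_acquisition` | inside the bore, no scanning | pulse (BCG) |
| `simultaneous` | during image acquisition | gradient + pulse |

## EEG cleaning chain

Order: gradient correction → resample (500 Hz) → band-pass (0.5–30 Hz,
2nd-order Butterworth, zero-phase) → QRS detection → pulse-template
subtraction → bad-channel interpolation → average reference → epoching.
Stages whose artifact is absent are skipped.

**Gradient artifact (AAS).** The artifact repeats with the TR (clock
synchronization between scanner and amplifier is a precondition: TR onsets
must be equidistant to within one sample, no sub-sample realignment is
attempted). For each TR epoch the mean of the 25 nearest epochs — a centered
sliding window (12 before, current, 12 after), truncated at the recording
edges, shrinking with a warning below 25 and failing below 3 — is subtracted
per channel. A strictly periodic artifact is removed exactly; a slowly
drifting one is tracked by the sliding window (the tests verify both).

**QRS detection.** With a dedicated ECG channel, peaks are searched directly
on it. Without one, the EEG is decomposed with FastICA and each component is
scored by its cardiac periodicity — the maximum of the normalized
autocorrelation over lags 60/110 s to 1.5 s (heart rate assumed below
110 bpm, which also fixes the minimal peak distance) — and the top component
supplies the detection signal. The prominence threshold, a supervised
histogram choice in interactive pipelines, is automated as the two-class
(Otsu) split of the log-prominence histogram; the split is accepted only when
the two classes differ by at least one natural-log unit, because noise and
QRS prominences differ by orders of magnitude whereas beat-to-beat amplitude
jitter does not — without this guard Otsu bisects the unimodal beat
distribution whenever the min-distance filter has already removed all noise
candidates. A `prominence` argument preserves the supervised path.

**Pulse artifact.** For each beat, the epoch spans −0.25 to +0.75 of the
median RR interval around the R peak. Its template is the Gaussian-weighted
mean of the 20 nearest epochs (weights `exp(−(i−j)²/2·5²)` over epoch index
distance); overlapping epochs are corrected once, in peak order. The template
is not rescaled per epoch — plain weighted-mean subtraction.

**Noise floor of template subtraction.** Mean templates contain the
neighbors' neural EEG: subtracting them injects noise of roughly
`1/sqrt(n_eff)` of the neural RMS (≈20% for 25-epoch AAS, ≈24% inside pulse
windows for the Gaussian-weighted 20-beat template). End-to-end in-band
distortion of ~30–33% RMS is therefore inherent to these estimators, even
though artifact band power itself is suppressed by several orders of
magnitude; the end-to-end test asserts residual artifact power ≤5% of
pre-cleaning and distortion ≤35%.

**Interpolation and reference.** Bad channels are rebuilt by
inverse-distance-weighted (power 2, great-circle distance) means of good
channels — simpler than spherical splines and exact at coincident positions.
Average reference subtracts the mean over a channel subset from all channels;
changing the subset shifts every channel by a common per-sample constant, so
condition comparisons are unaffected (asserted as an algebraic identity).

## Spectral quality metrics

`A²(f)` is the single-sided squared FFT amplitude, normalized so a sinusoid
of amplitude *a* contributes *a²* at its bin; continuous data use 2-s Hann
windows at 50% overlap, epoched data are averaged per epoch. The range is
capped at 65 Hz. Band means average `A²(f)` over the half-open span
`[c−1, c+1)` around each integer center frequency `c` = 1…64 Hz — the
half-open convention resolves the endpoint ambiguity of a "2 Hz span"
deterministically. The **index of dispersion** at a band is the
across-electrode sample variance (n−1) divided by the across-electrode mean,
in μV²; it is zero for a perfectly homogeneous topography and scales linearly
with overall gain. The absolute scale of `A²` depends on the window
normalization; all condition comparisons are invariant to it.

## Statistics

Subjects enter the two-way condition × electrode ANOVAs as replicates (no
subject factor), giving error dfs 480 (60 electrodes), 208 (26 pairs) and 16
(single pair) at n=5 — this replicate convention is deliberate, not a
repeated-measures model. The ANOVA is the classical balanced closed-form SS
decomposition, cross-checked in the tests against an independent
projection-based fit. Multiple testing uses Benjamini-Hochberg FDR at
q = 0.05 (BH, not BY). Left-right asymmetry is assessed per symmetric pair as
|L−R| (two-way ANOVA over pairs), as a 2×2 condition × hemisphere ANOVA per
pair, and as one-sample t-tests of the signed L−R difference grouped by
amplifier. Tissue-level TSNR metrics are compared with a percentile bootstrap
on paired differences (mid-rank convention for ties at zero); at n=5 its
middle-95% interval undercovers (~84% in a calibration simulation), which is
a known property of the percentile bootstrap at small n, not a defect of the
implementation. Head movement is summarized as the mean volume-to-volume
Euclidean translation norm in mm; rotations are excluded because the metric
is defined in mm.

## fMRI

TSNR is the voxelwise temporal mean over the temporal sample standard
deviation (n−1); zero-variance voxels are invalid and excluded everywhere.
Smoothing uses a separable Gaussian with σ = FWHM/2.355 per axis in voxel
units and renormalized truncated kernels at the edges (constants are
preserved exactly). Paired condition contrasts compute a voxelwise paired t,
form clusters at one-sided voxel p < 0.001 under 18-connectivity, and assign
cluster-level FWE p by sign-flip permutation of the subject differences:
at n ≤ 12 all 2ⁿ flips are enumerated, making the p-values exact,
deterministic and order-invariant; the minimum attainable p at n=5 is
1/32 ≈ 0.031. Sign-flip permutation replaces random-field-theory cluster
inference deliberately: it is assumption-free and exactly enumerable at this
sample size, at the cost of a coarse p-value grid.

## Synthetic sessions

EEG = 1/f background (spectral shaping of white noise, exponent 1.0, flat
below 1 Hz, 10 μV RMS) + band-limited rhythms (alpha 10±1 Hz 3 μV with a
posterior topography; beta 20±5 Hz 1.5 μV with a central topography, both
left-right symmetric ±25%) + 50 Hz line noise + artifacts. The
condition-dependent inhomogeneity multiplies the 15–25 Hz component per
channel: gain = 1 + spread + asymmetry·(amp sign)·(side sign)·(polar angle /
90°), so amplifier-1 channels gain more power on the right, amplifier-2 on
the left, growing from vertex to periphery; spread/asymmetry are 0/0, 0.3/0.1,
1.0/0.5 and 2.5/1.5 for the four conditions — chosen once to reproduce the
qualitative ordering of the dispersion statistic across conditions, not
calibrated to any particular hardware. The gradient artifact is a sum of
1/k-weighted harmonics of the slice frequency (36 slices / 2.0 s TR = 18 Hz),
exactly TR-periodic on the sample grid, 1000 μV RMS with a 1%/min amplitude
drift — an order-of-magnitude choice, since gradient amplitude is
hardware-specific. The pulse artifact is a three-Gaussian template (R spike
at lag 0, T-like bump at +0.25 s, undershoot at +0.10 s), 30 μV typical peak
scaled by a smooth scalp gain (mean ≈ 1), amplitude-jittered 5% per beat, at
R times with RR ~ Normal(60/HR, sd) truncated at 60/110 s (HR 65 ± 3 bpm);
the first beat sits 0.35 s into the recording and beats within 50 ms of the
end are excluded from the ground truth as undetectable in principle. A
synthetic ECG channel (sharp QRS train, 800 μV, 20 μV noise) is generated
alongside and is never band-pass filtered with the EEG.

fMRI phantoms are concentric ellipsoids (CSF core < 0.25, WM to 0.62, GM
shell to 0.92 of the field of view) with per-tissue baselines/noise sds,
a ±10% anterior-posterior noise gradient, linear drift (1% per run), and an
optional condition effect multiplying the noise sd inside a posterior slab by
1.5 — the true TSNR field is recorded per voxel. Motion is a Gaussian random
walk whose step size is set from the target mean instantaneous movement
(E‖N(0, σI₃)‖ = 1.596 σ); the two conditions default to 0.092 mm and
0.0732 mm, the movement levels the method is meant to distinguish.

What the generator does **not** emulate: volume conduction and correlated
channel noise, non-stationary artifact morphology, helium-pump and
ventilation artifacts, susceptibility distortion of the fMRI by the EEG cap,
realistic anatomy. Passing recovery tests therefore demonstrate the
correctness and sensitivity of the estimators under the stated model, not
performance on any specific hardware.

## Problem sizes

The test suite and the acceptance script run the EEG study at 500 Hz × 64 s
(32 TR epochs, enough for the full 25-epoch AAS window) with 5 subjects × 4
conditions, and the fMRI study at 16×16×8 voxels (3 mm) × 150 volumes × 4
runs per subject-condition, smoothed at 8 mm FWHM. These sizes keep the full
study to seconds while leaving every statistic in its intended regime
(dfs 480/208/16, 2⁵ permutations). The generator defaults (5000 Hz, 120 s)
match the native acquisition rates and are used where timing precision
matters (QRS detection tests run at the native RR structure).

## Degenerate inputs and tie-breaks

Zero-variance voxels → invalid, excluded; zero-variance subject differences →
NaN t with a warning, never rejected by FDR; mean ≤ 0 → index of dispersion
undefined (error); all-zero bootstrap differences → percentile 50 by
mid-rank; two candidate R peaks closer than 60/110 s → the larger survives;
epochs exceeding recording bounds → skipped (pulse) or dropped with a count
(stimulus epochs); interpolation at a coincident electrode → exact copy.
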