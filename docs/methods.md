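# Methods

This note documents the models, algorithms and numerical choices behind
`sasskit`, what the synthetic data generator does and does not emulate, and
the known limitations.

## The SASS model

SASS assumes that, within a narrow analysis band, sensor data during
stimulation decompose as brain activity plus an artifact confined to a
low-dimensional spatial subspace, and that the *brain* signal statistics are
comparable between the stimulation and no-stimulation sessions. Under those
assumptions the generalized eigenproblem `A w = λ B w` of the band-limited
sensor covariances (`A` during stimulation, `B` without) orders components
by their stimulation/no-stimulation power ratio λ; artifact directions have
λ ≫ 1 while brain components have λ ≈ 1.

Implementation details:

- **Covariances** are unregularized sample covariances (per-channel mean
  removed, `n−1` denominator) of the *continuous* band-filtered session,
  not of epochs — nothing restricts the artifact statistics to trials.
- **Joint diagonalization** uses `scipy.linalg.eigh(A, B)`, which returns
  B-orthonormal eigenvectors (`W B Wᵀ = I`, `W A Wᵀ = diag λ`).
  Eigenvalues are sorted descending. Each eigenvector's sign is fixed by
  making its largest-magnitude entry positive, so filters and patterns are
  reproducible across runs and platforms.
- **Spatial patterns** are the columns of `W⁺` (the map from component
  space back to sensor space); a component's *filter* is the corresponding
  row of `W`. The pseudoinverse uses a relative cutoff of 1e-12.
- **Projection** `P = W⁺ S W` with `S` nulling the top-k components. `P` is
  idempotent with rank `n − k` and annihilates the rejected patterns.
- **Selection of k** scans k = 0…n. For each k the criterion is the mean
  over sensors of the squared difference between per-sensor band power
  (variance of the band-filtered signal) of `P_k`-cleaned stimulation data
  and of no-stimulation data; computed equivalently as
  `diag(P_k A P_kᵀ)` vs `diag(B)`. Ties break toward smaller k
  (reject less, preserve brain signal). Beyond the true artifact rank the
  criterion landscape is nearly flat — at ~2000 effective narrowband
  samples over 64 channels, sampling spread alone produces eigenvalues up
  to λ ≈ 2–3, so the argmin can legitimately include one or two noise
  directions on some realizations. This mirrors the method's behavior on
  real data and is harmless for recovery (see the no-artifact test: the
  projection then barely touches the SSVEP metrics).
- **Per-frequency fitting**: electrode nonlinearities give every artifact
  harmonic its own topography, so `sass_multiband` fits an independent
  model per band; broadband cleaning subtracts each band's rejected
  component (`x − Σ_b (I − P_b) filt_b(x)`), leaving out-of-band content
  untouched up to FIR transition effects (≤ ~5% RMS in practice).

## Signal processing

- **Band**: 10 ± 1 Hz by default. The half-width is a free choice; 1 Hz
  separates the SSVEP line from neighbors while fitting the transition
  width of the 1.65 s FIR.
- **FIR filters**: windowed linear-phase design (`scipy.signal.firwin`,
  Hamming), length `round(1.65 s × fs)` forced odd (825 taps at 500 Hz),
  applied centered (group delay compensated) so the net response is
  zero-phase and output length equals input length.
- **Single-trial metrics**: the continuous EEG is (optionally projected,
  then) band-filtered, averaged over the occipital set
  {O1, Oz, O2, PO3, POz, PO4, PO7, PO8} into a virtual channel, and
  Hilbert-transformed. Per trial, amplitude is the mean modulus over the
  2 s window and phase is the circular mean (argument of the mean unit
  phasor — arithmetic averaging of wrapped angles is ill-defined) of the
  instantaneous phase minus the flicker reference. The reference is a
  cosine at the flicker frequency with zero phase at trial onset; a source
  `A·cos(2πf(t − t_onset) + φ)` therefore has single-trial phase φ.
  Because the 2 Hz-wide filter's envelope rise time (~0.4 s) is not small
  against the 2 s trial, full-window trial amplitudes underestimate the
  plateau amplitude by a constant factor; this cancels in every comparison
  and correlation the pipeline computes. Exact plateau values can be read
  with an interior window (e.g. `tmin=0.5, tmax=1.5`).
- **Trigger detection**: the audio channel is z-scored over its whole
  length; an event is any sample where |z| rises above 3 from ≤ 3. Trial
  onsets are events with no predecessor within 400 ms (strictly smaller
  gaps suppress; a tie at exactly 400 ms is kept). Trials whose window
  exceeds the recording are dropped, not padded.
- **PSDs**: Welch with 2 s Hann segments and 50% overlap (matching the
  trial length); multitaper via full-length DPSS tapers (MNE) for
  high-resolution spectra.

## Statistics

- **Amplitude scheme**: no-stim vs stim-without-SASS is a one-sided
  independent t-test (the artifact inflates amplitudes); raw vs cleaned
  stimulation is a one-sided *paired* t-test (same trials); no-stim vs
  cleaned is two-sided (a residual could fall either way). Stars at
  0.05/0.01/0.001/0.0001. No multiplicity correction across the three
  comparisons.
- **Wallraff test**: angular distances `d_i = π − |π − |θ_i − median||` to
  each sample's own circular median (data-point minimizer of mean angular
  distance; ties broken toward the circular mean), compared with a Wilcoxon
  rank-sum test for independent samples. For *paired* samples a rank-sum
  test cannot respect the pairing, so the paired variant uses the Wilcoxon
  signed-rank test on paired distances. Exact rank distributions are used
  for n ≤ 25, the normal approximation above. With estimated medians the
  test is mildly conservative at small n (simulated type-I ≈ 0.03 at
  n = 20, ≈ 0.044 at n = 200).
- **Group level**: Wilcoxon rank-sum between conditions with one-sided
  alternatives where the artifact direction is known (uncleaned
  stimulation lowers PLV and inflates amplitude), two-sided for no-stim vs
  cleaned; exact at the N = 6 group size.
- **Power analysis**: smallest Cohen's d with two-sample noncentral-t power
  reaching the target (`df = 2n−2`, noncentrality `d√(n/2)`), solved by
  bisection to 1e-6 via the stable `scipy.special.nctdtr`; the far-left
  tail term is clamped to 0 where it underflows. Sidedness is exposed;
  two-sided is the default reporting convention. At n = 200/group,
  α = 0.05, power 0.80 this gives d = 0.281.
- **Heartbeat modulation**: 5–15 Hz filter, Hilbert envelope, 4 s windows
  centered on R-peaks, demeaned, averaged per channel. Significance per
  lag from 1000 random re-placements of the window centers (windows fully
  inside the recording, collisions allowed), corrected within channel by
  the max-statistic across lags (Westfall–Young style; Bonferroni is
  available as an option), with the add-one estimator so no p is below
  1/(n_perm+1). Deterministic given a seed. The permutation null is exact
  under exchangeability of window placements; when event windows overlap
  heavily (dense peaks relative to the recording) random centers cluster
  more than quasi-periodic ones and the test becomes conservative — the
  calibration simulation therefore uses windows sparse enough to satisfy
  exchangeability.
- **R-peak detection**: 5–30 Hz bandpass, squaring, 120 ms energy
  integration, threshold at median + 4×MAD of the integrated energy,
  refinement to the local band-signal maximum, 250 ms refractory period.
  The integration step is what makes a MAD-based threshold separate QRS
  energy from baseline noise; thresholding the raw squared signal does not.

## The synthetic data generator

The generator reproduces the structure of the two-session paradigm:
500 Hz sampling, 200 trials of 2 s 10-Hz flicker with 0.5–1 s inter-trial
intervals (~9–10 min per session), 64 EEG channels plus an audio trigger
row (one 6 ms pulse per flicker cycle) and optionally an ECG row.

Per-trial SSVEP amplitudes are lognormal (median 2 µV at the occipital
pattern peak, log-sd 0.4) and phases are a fixed lag plus von Mises jitter
with κ = 5, i.e. a single-trial PLV of ≈ 0.89 — the regime of a strong,
clearly unimodal SSVEP; neither distribution is prescribed by the paradigm,
so these are one-time realism choices. Background noise is rank-8
spatially mixed 1/f noise (3 µV per channel) plus 0.5 µV white sensor
noise (which also keeps the no-stimulation covariance positive definite).

The artifact is a unit AM carrier (220 Hz, 10 Hz envelope, envelope not
locked to trial onsets) scaled by `artifact_gain` (default 10³) times the
mean SSVEP amplitude, with a spatial footprint peaking over CPz and the
inion (the stimulation electrode positions). Each channel applies
`y = x + c₂x² + c_r·max(x,0)`; the default is a heterogeneous quadratic
term (c₂ ≈ 0.05, ±50% across channels) and no rectifier. Squaring the AM
carrier demodulates it: the envelope-squared term puts ~25 µV at 10 Hz at
the artifact-pattern peak — ≥ 20 dB above the SSVEP everywhere the brain
signal is weak — with topography ∝ pattern × c₂, i.e. spatial rank 1 per
nonlinearity profile (the generator records this planted rank).

A 125 Hz FIR low-pass emulating the recording amplifier's anti-alias
filter is applied by default, so the carrier and its 210/230 Hz sidebands
are absent from the generated sensors just as they are from the recorded
data, and only the demodulated envelope-frequency artifact survives;
disable it (`anti_alias=False`) to inspect the raw AM spectrum. Heartbeat
simulation multiplies the artifact by `1 + depth·Σ_k exp(−(t−t_k)²/2σ²)`
(σ = 80 ms) at quasi-periodic R-peaks (rate 1.1 Hz, 3% jitter) and adds an
ECG channel built from a spike template.

What the generator does **not** emulate: biophysical volume conduction
(patterns are parametric bumps, not head-model leadfields), non-stationary
brain rhythms, eye/muscle artifacts, electrode drift, line noise, or
realistic ECG morphology beyond the R-wave. Nonlinear demodulation is
computed on the 500 Hz sample grid, so carrier-squared terms around
430–450 Hz alias to 50–70 Hz instead of being removed in continuous time;
they lie outside every analysis band (9–11, 5–15 Hz). Passing tests on
synthetic sessions therefore demonstrate correctness of the algorithms
under the model's assumptions — rank-limited artifacts and comparable
brain statistics across sessions — not robustness to every real-world
nuisance.

## Problem sizes used in the validation suite

The end-to-end tests run the full default conditions (two 200-trial
sessions, 64 channels, ≈ 550 s at 500 Hz each). Statistical calibration
uses 1000 simulated repetitions per test, with the permutation test
evaluated on reduced recordings (one channel, 120 s at 50 Hz, 199
permutations per repetition); unit tests use 8–40-trial sessions.
The whole suite completes in about a minute on a single core.

## Known limitations

- `select_k` can overshoot the true artifact rank by a few components when
  the covariance pair is estimated from little data; the projection then
  removes noise directions, which is visible as mild amplitude shrinkage.
- The BrainVision writer emits multiplexed/vectorized INT_16 and
  IEEE_FLOAT_32 only; other encodings and formats (EDF, FIF) are out of
  scope. Reading assumes channel units of µV.
- The heartbeat permutation test assumes window-placement exchangeability;
  with heavily overlapping windows it is conservative, not anticonservative.
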