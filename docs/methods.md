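# Methods

This note documents the models, numerical choices and limitations of
the package, in the order data flows through the pipeline.

## Stimulus synthesis

Stimuli are spatiotemporally bandpass-filtered noise movies. White
Gaussian noise is shaped in the 3-D Fourier domain by a 1/f amplitude
envelope (over the joint spatiotemporal frequency magnitude, with the
DC bin removed) and a bandpass mask, then inverse-transformed and
normalised to 50% RMS contrast around a mean luminance of 1.

**Filter shape.** The bandpass is a Gaussian in log₂-frequency along
both the radial spatial-frequency axis and the temporal-frequency
axis, parameterised by its full width at half maximum (1 octave for
both, matching the tuning model's log-Gaussian structure). The
orientation band of anisotropic stimuli is a Gaussian over the
180-periodic spectral angle, parameterised by FWHM in degrees; its
centre rotates at 45 deg/s, so one 4-s epoch sweeps [0°, 180°) exactly
once. The roll-off family is a package choice — only the bandwidths
are fixed by the experimental design.

**Resolution.** Movies default to 64×64 pixels over 100°×80° at
30 fps. This keeps synthesis desk-scale but places the spatial Nyquist
limit at 0.32 cpd: conditions whose 1-octave upper band exceeds
Nyquist (0.32 cpd, and 16 Hz at 30 fps) raise a `NyquistWarning`, and
their spectral properties are validated on the analytic mask profile
(`bandpass_amplitude`) rather than on a rendered movie. Masks are
explicitly symmetrised on the FFT grid (`M(−f) = M(f)`); without this
the sampled orientation angle at the self-conjugate Nyquist bins
breaks evenness and the filtered movie acquires a spurious imaginary
part.

**Schedules.** Each of 4 trials presents every condition once in an
independent random order; every (trial, epoch) pair has its own noise
seed, so phases differ across trials while frequency content is fixed
by the condition — reproducible bit-for-bit from the schedule.

## Synthetic data generator

The generator emulates the *statistical* structure of a multi-area
calcium-imaging experiment; it does not model raw fluorescence movies,
neuropil, or spike inference. Traces are emitted directly as ΔF/F.

**Hierarchy.** Neurons nest in areas nest in mice. Area-level
distributions (means/SDs of log₂ sf₀, log₂ tf₀, ξ; cell-type mixture;
responsive fraction) are configurable; defaults encode qualitative
area biases (V1 slow/coarse and weakly speed-tuned; AL/RL/AM fast and
speed-tuned; PM/LI/POR slow and fine). Per-mouse offsets on
log₂ sf₀ (SD 0.3 oct), log₂ tf₀ (0.3 oct) and ξ (0.1) are shared by
all neurons of a mouse — this is the nested variability the
hierarchical bootstrap exists to respect, and shuffling mouse labels
destroys it (tested).

**Response model.** A neuron's noise-free epoch-mean response is the
2-D log-Gaussian tuning model evaluated at the condition's centre
frequencies, times an elongation gain for the condition's orientation
bandwidth. The gain 4-vector over (∞, 60°, 30°, 15°) bandwidths
defines the cell type: non-OS decreasing (default 1.0/0.75/0.5/0.3),
sharp-OS increasing (0.25/0.5/0.75/1.0), broad-OS flat (≈0.87), with
small per-neuron jitter that preserves monotonicity. Gains are defined
as *epoch means*: within an anisotropic epoch the response is
modulated by the neuron's orientation tuning curve along the 45 deg/s
sweep, normalised to mean 1 over the sweep, so the epoch-mean
amplitude is independent of the preferred orientation.

**Orientation tuning** is a wrapped Gaussian on the 180°-periodic
orientation circle, parameterised by FWHM (range 10–170°). A wrapped
Gaussian (rather than a von Mises matched at half maximum) keeps very
broad curves genuinely flat: a 170°-FWHM cell has true OSI near zero,
which is what an "untuned" cell should look like.

**Calcium dynamics.** Rates are convolved with a double-exponential
kernel (rise 200 ms, decay 560 ms — typical GCaMP6s transients),
normalised to unit sum so that sustained responses keep their mean.
Because the kernel delays mass past the 4-s epoch, measured epoch-mean
amplitudes are attenuated by a closed-form factor (the time-mean of
the kernel-convolved unit boxcar, ≈0.81 at 10 Hz). The factor is
identical for all conditions, so it rescales the fitted amplitude A
only and leaves sf₀, tf₀, σ and ξ unbiased; tests use the discrete
convolution as the oracle.

**Noise.** Per-epoch multiplicative gain (log-normal, CV 0.15) plus
per-frame additive Gaussian noise (SD 0.05 ΔF/F), with an optional
linear drift to exercise detrending. These defaults place the
reliability-index distribution astride the r = 0.3 selection
threshold, so QC is exercised in both directions. Traces run at 10 Hz
(typical multi-plane two-photon rates).

**Trace layout.** Each trial is a sequence of 8-s blocks, 4 s gray
then 4 s stimulus, one block per condition in schedule order. Every
epoch therefore has a pre-stimulus baseline; the post-offset window of
a trial's *last* epoch wraps circularly to the trace start. Only one
epoch per trial is affected and presentation order is randomised
across trials, so no condition is systematically distorted.

**Scale.** `PopulationConfig` defaults to 10 mice × 8 areas ×
150 neurons (a realistic study scale for the cheap table-sampling
step); trace simulation and fitting in the end-to-end pipeline default
to 4 mice × 4 areas × 30 neurons, and the test suite uses smoke scales
down to 2×2×20. Statistical conclusions in the tests are about the
procedures, not about any particular scale.

## QC

De-randomised epoch windows span 12 s (preceding gray, stimulus,
following gray). Responsiveness follows the 3×baseline-SD for >1 s
rule on the across-trial median time course, with the baseline taken
from the 4-s preceding gray; cells meeting the criterion only in the
2-s post-offset window are flagged offset-only and excluded (the 2-s
window is a package choice). Reliability is the 75th percentile
(linear interpolation between order statistics) of the 6 pairwise
Pearson correlations between concatenated stimulus+following-gray
trial courses; zero-variance trials contribute correlation 0 rather
than NaN so silent cells are defined (and fail). A shuffle control
permutes condition identity within trials and reports the 97.5/99.75
null percentiles. Slow drift is removed by subtracting a running
10th-percentile baseline (40-s window); on a clean trace the estimate
is identically the gray-screen baseline and the correction is a no-op.

## Tuning fits and indices

Fits use bounded multi-start least squares (`scipy.optimize.
least_squares`, trust-region reflective) on the 30 trial-averaged
amplitudes, with starts at the grid argmax crossed with slants
ξ₀ ∈ {−1, 0, 1} and widths σ₀ ∈ {1, 2.5}; bounds allow centre
frequencies 2 octaves beyond the tested range (sf₀ ∈ [0.005, 1.28]
cpd, tf₀ ∈ [0.125, 64] Hz), σ ∈ [0.3, 10] oct, ξ ∈ [−3, 3]. The
normalised RMS error uses the *fitted* peak amplitude as denominator
(more robust to single noisy bins than the raw maximum); the
acceptance gate is nRMSE < 0.1. A brute-force lattice search confirms
the optimizer finds the global optimum on noisy instances (tested).

Half-maximum cutoffs come from closed forms: along TF the half-width
is √(2 ln 2)·σ_tf; along SF the slant couples the two exponentials,
giving 1/σ²_eff = 1/σ²_sf + ξ²/σ²_tf. Shapes are classed against the
tested bounds (0.02/0.32 cpd, 0.5/16 Hz): lowpass, highpass, bandpass,
and "broadband" when both cutoffs fall outside (excluded from bandpass
fractions). Speed-tuned means strictly ξ > 0.5; preferred speed is
tf₀/sf₀.

API uses the raw peak trial-averaged amplitudes of the two batteries;
categories use strict inequalities at ±1/3 (the boundary value is
"mixed"). Orientation tuning curves are computed at the peak
anisotropic condition from 12 bins of 15°, after adding the 4-s
post-offset calcium back onto the sweep (wrap-around): cells preferring
orientations near the sweep's end would otherwise lose their response
mass into the gray epoch. Negative bin values are clipped to zero
before the circular-variance computation. The spike-vs-calcium
validation sweeps FWHM 10–170° × 4 preferred orientations with
Poisson spiking (zero spontaneous rate) and recovers a near-monotone
spike→calcium OSI mapping with Spearman ρ > 0.95.

## Statistics

The hierarchical bootstrap draws M animals with replacement then N
cells with replacement within each drawn animal, L times (default
150×5×1000). The bootstrap KS test computes D on each paired resample
and compares percentile CIs against the asymptotic critical values
D_α = c(α)√((n₁+n₂)/n₁n₂) with c = 1.36/1.63/1.95 at α =
0.05/0.01/0.001, reporting the most stringent α whose critical value
lies below the lower CI bound. n₁ = n₂ = N·M (the resampled sizes) —
using resampled rather than original sizes keeps the construction
internally consistent. The construction is conservative; calibration
on null two-level data shows ≤10% rejections at the 0.05 label
(tested, 100 replicates). The asymptotic critical values are inherited
as-is and not corrected for small resamples. Cohen's d on bootstrap
distributions uses closed category boundaries ([0.2, 2] is "median").
No multiple-testing correction is applied across area pairs. KDEs take
an absolute bandwidth in data units.

## Decoding

Linear SVM (C = 1), features z-scored with training-split statistics
only. Per iteration, 2 of the 4 trials train and 2 test (4 test
decisions); 100 iterations are averaged within each of 50 neuron
resamples; means and 95% CIs are taken over resamples. Pools are drawn
without replacement within a resample; sizes follow the logarithmic
2→512 ladder and are truncated with a warning when they exceed the
population. With only 4 trials, a single pair's chance-level accuracy
on one fixed dataset has an SD of several points (the finite noise
realisation can be persistently separable); chance calibration is
therefore assessed as the grand mean over speed pairs, which is stable
to about a point. Between-condition contrasts use two-sample t-tests
over the 50-resample accuracy sets.

## Clustering

Elongation typing: Ward linkage on the 4-point curves, cut at 3;
clusters are named by the slope rank of their peak-normalised mean
curves (most negative → non-OS, most positive → sharp-OS, middle →
broad-OS), so names are invariant to cluster indexing. Functional
clustering: per-neuron 60-vectors (30 ISO + 30 ANISO amplitudes)
min-max normalised to [0, 1] (constant rows dropped with a warning),
2000 rows per area sampled with replacement, PCA to 12 components
fitted after concatenating areas, k-means with 20 seeded restarts per
k, model selection by silhouette argmax with Davies-Bouldin and
Calinski-Harabasz curves reported alongside. Full-dataset assignment
is nearest centroid in PC space (ties to the lowest index).
Composition statistics bootstrap 150 neurons × 5 mice × 1000 per area,
compare 95% CIs of cluster proportions against the 1/k chance level,
and summarise between-area similarity as the bootstrap mean ± SEM of
Pearson correlations between proportion vectors, with Cohen's d for
similarity contrasts. t-SNE uses perplexity 120 and learning rate
n/10, seeded.

## Maps

Retinotopic phase maps average the movie across stimulus cycles and
take each pixel's phase as the argmax cycle time (a first-harmonic
Fourier mode is available for noisy data). The calcium kernel delays
all pixels equally, so phases carry a constant lag: pairwise phase
differences are unbiased (tested). Cortical parameter maps are
Nadaraya-Watson Gaussian-weighted averages on a regular grid;
"smoothing 400 µm" is interpreted as the kernel σ (an FWHM
interpretation would simply rescale by 2.355); empty cells are masked.

## What passing tests do and do not show

The generator shares its response model with the fitting code — by
design, since the purpose is verifying the *estimation machinery*
(fitting, QC, statistics, decoding, clustering) by parameter recovery.
Passing recovery tests therefore shows the pipeline is a consistent,
essentially unbiased estimator under the stated noise model; it does
not show that real neurons follow the model, that real noise is
log-normal-gain plus Gaussian, or that real areas differ as the
default configuration assumes. Features of real data the generator
omits: neuropil contamination, motion artefacts, non-Poisson spiking,
adaptation within and across epochs, eye movements, and correlated
(shared) noise between neurons — decoding results on synthetic data
are accordingly optimistic about pool-size scaling.
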