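# vistreams

Analysis pipeline for characterising visual-cortical neuron populations
with spatiotemporally bandpass-filtered noise stimuli, written for
calcium-imaging (ΔF/F) recordings of the mouse visual system and the
researchers who analyse them.

Large-scale imaging studies probe spatial-frequency (SF), temporal-
frequency (TF), speed and orientation tuning across the primary visual
cortex (V1) and higher visual areas (LM, AL, RL, AM, PM, LI, POR/P) by
presenting filtered-noise movies of controlled centre SF, centre TF and
orientation bandwidth. This package implements the full analysis chain
for such experiments, together with a hierarchical synthetic-data
generator so that every stage can be validated by parameter recovery —
no recordings are required to run, test or benchmark the pipeline.

## The model at the core

Single-neuron responses over the SF×TF stimulus grid are fitted with a
slanted two-dimensional Gaussian in log₂-frequency space:

    R(sf, tf) = A · exp(−(log₂sf − log₂sf₀)² / 2σ²_sf)
                  · exp(−(log₂tf − g(sf))² / 2σ²_tf)
    g(sf)     = ξ·(log₂sf − log₂sf₀) + log₂tf₀

where *A* is the peak ΔF/F, (sf₀, tf₀) the preferred frequencies,
(σ_sf, σ_tf) the tuning widths in octaves, and ξ the **speed-tuning
index**: ξ = 0 means separable SF×TF tuning, ξ = 1 means tuning for
speed tf/sf itself; cells with ξ > 0.5 are classed speed-tuned, with
preferred speed tf₀/sf₀ (deg/s). Fits with normalised RMS error < 10%
of the peak are accepted. Around this model the package provides:

- **stimuli** — the three condition batteries (30 SF×TF isotropic,
  30 SF×TF anisotropic with 15° FWHM orientation bandwidth rotating at
  45 deg/s, and 16 SF × orientation-bandwidth), synthesis of 1/f-noise
  movies at 50% RMS contrast, and randomised presentation schedules.
- **synthetic** — ground-truth populations (mouse → area → neuron) and
  simulated ΔF/F trial traces with GCaMP6s-like calcium dynamics
  (double-exponential kernel, 200 ms rise / 560 ms decay).
- **qc** — de-randomisation, drift correction, the 3·SD / >1 s
  responsiveness criterion and the cross-trial reliability index
  (75th percentile of pairwise trial correlations, selection at
  r > 0.3).
- **tuning** — model fits, half-maximum frequency cutoffs and
  lowpass/bandpass/highpass shapes, the anisotropy-preference index
  API = (R₁−R₀)/(R₁+R₀), elongation tuning curves, and orientation
  selectivity OSI = 1−CV from the response time course to the rotating
  stimulus (with wrap-around of post-offset calcium), validated by a
  spike-vs-calcium simulation.
- **stats** — hierarchical (N cells × M animals × L resamples)
  bootstrap, the bootstrap two-sample Kolmogorov–Smirnov test with
  critical values D_α = c(α)√((n₁+n₂)/n₁n₂), Cohen's d on bootstrap
  distributions and fixed-bandwidth KDEs.
- **decoding** — linear-SVM discrimination of speed pairs (4-fold speed
  difference) vs iso-speed pairs under the 50-resample ×
  100-iteration × pool-size protocol.
- **clustering** — Ward-linkage typing of elongation curves
  (non-OS / sharp-OS / broad-OS), PCA + k-means functional clustering
  with silhouette / Davies-Bouldin / Calinski-Harabasz validation,
  hierarchical-bootstrap area composition vs the 1/k chance level, and
  t-SNE embedding.
- **maps** — retinotopic phase maps from widefield movies and
  Gaussian-smoothed cortical parameter maps.

## Worked example

Run the full pipeline on synthetic data (about half a minute at the
smoke scale used here):

```python
from vistreams.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(root_seed=5, out_dir="demo_out", areas=("V1", "AL"),
                     n_mice=2, n_per_area_mouse=20,
                     cluster_n_per_area=120,
                     cluster_k_range=tuple(range(2, 9)),
                     decode_sizes=(2, 4, 8), decode_resamples=8,
                     decode_iterations=20, hb_resamples=100)
res = run_pipeline(cfg)
print(res["report"][:400])
```

The `demo_out/` directory then contains the QC table, the per-neuron
tuning table, the area KS matrix, decoding accuracies, cluster
composition and a markdown report. For this configuration the report
prints:

```
# Synthetic pipeline report

config hash: `5e825014` (root seed 5)

## Counts

- neurons simulated: 80
- responsive (dataset 1): 57
- selected (r > 0.3): 53
- tuning rows: 61

## Parameter recovery

- recovered-vs-true log2(sf0) slope: 0.967

## Area medians (fitted)

| area   |       sf0 |     tf0 |        xi |
|:-------|----------:|--------:|----------:|
| AL     | 0.0518141 | 9.21665 | 0.598765  |
| V1     | 0.0332879 | 1.59148 | 0.0403722 |
```

80 neurons were simulated for two mice in V1 and AL; 57 passed the
responsiveness criterion and 53 the reliability threshold on dataset 1
(61 neurons enter the tuning table because selection in either the
isotropic or the anisotropic battery suffices). The recovered-vs-true
slope of 0.967 means the fitted peak spatial frequencies track the
generator's ground truth essentially one-to-one, and the fitted area
medians reproduce the generator's built-in biases: AL prefers higher
temporal frequencies and is strongly speed-tuned (median ξ ≈ 0.6),
V1 prefers low frequencies and is not (ξ ≈ 0.04). Re-running with the
same config reproduces every output file byte for byte.

The same stages are available from the shell:

```sh
vistreams synth --out data.h5 --seed 1 --mice 2 --per-area 20
vistreams qc data.h5 --r-threshold 0.3 --out qc.csv
vistreams fit data.h5 qc.csv --out tuning.csv
vistreams validate-osi --fwhm 10:170:10 --out osi_val.csv
vistreams run --seed 1 --out pipeline_out
```

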