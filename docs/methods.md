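# Methods

## The measurement being modelled

Time-resolved Brillouin scattering (TRBS) records the interference between
a probe laser beam and the fraction of it scattered from a coherent phonon
wave packet travelling through a cell. The signal oscillates at the
Brillouin frequency shift

    f_B = 2 n ν / λ,

with `n` the refractive index of the probed volume, `ν` the sound velocity
(m/s) and `λ` the probe wavelength at normal incidence. Damping of the
phonon field by the medium's viscosity gives the trace an exponential
envelope, so a single-layer homogeneous medium reduces to the parametric
form

    s(t) = A sin(2π f_B t + φ) · exp(−α₀ ν t) + ε(t),

where `A` is the amplitude, `φ` the phase and `α₀` the sound attenuation
coefficient. `α₀` is carried in µm⁻¹ (the unit cell values are quoted in);
because it is a *spatial* decay rate, the temporal decay applied inside
the model is `α₀ · ν` (µm⁻¹ × µm/s after unit conversion). This
reparameterisation is exactly equivalent to fitting a purely temporal
decay rate and converting afterwards; we state ours explicitly because
the two conventions are easy to confuse.

Axial resolution of the frequency estimate is set by the phonon
wavelength, `z_min = λ_probe / 2n` (≈ 293 nm for a 780 nm probe in
water), independent of numerical aperture; lateral resolution follows the
Rayleigh criterion of the pump spot, `x_min = 0.61 λ_pump / NA`
(≈ 396 nm for a 390 nm pump at NA 0.6).

## Synthetic data generator

The experimental dataset this pipeline is designed for (per-pixel phonon
scans of normal and cancerous breast epithelial cells) is not publicly
downloadable, so the package ships a simulator that reproduces the
*statistical structure* the analysis depends on:

* **Traces.** 256 samples at 10 ps (a 2.56 ns window, matching a
  ~2.5 ns phonon time of flight and Nyquist-safe for the 4–7 GHz
  Brillouin band). Additive white Gaussian noise; the default
  `noise_sigma = 0.1` at unit amplitude (SNR 10) puts the scatter of
  fitted parameters well below the class separations, which is the
  regime the per-pixel classification task assumes.
* **Scans.** A 61 × 61 raster per cell (configurable; tests use smaller
  grids). The cell is a seeded random blob — smoothed Gaussian noise
  thresholded at a quantile drawn from 30–60 % coverage, largest
  connected component kept — over a saline-like background.
* **Classes.** Per-pixel labels are *normal*, *abnormal* (cancer) and
  *background*. Class parameters are Gaussian in the (ν, α₀) plane with
  the empirically observed ordering: cancer cells lie below normal cells
  in both sound velocity and attenuation, background lower still.
  Defaults (all configurable, none hard-coded in the algorithms):

  | class      | mean ν (m/s) | mean α₀ (µm⁻¹) | cell-to-cell sd | pixel sd |
  |------------|--------------|----------------|-----------------|----------|
  | background | 1490         | 0.15           | —               | 10 m/s, 0.05 |
  | normal     | 1700         | 1.8            | 25 m/s, 0.20    | 30 m/s, 0.28 |
  | abnormal   | 1640         | 1.2            | 25 m/s, 0.20    | 30 m/s, 0.28 |

  The population-level scatter of individual measurements per cell class
  is then ≈ (40 m/s, 0.34 µm⁻¹) in quadrature. Its decomposition into a
  cell-to-cell centroid spread plus within-cell pixel jitter is chosen
  so that (a) pooled scatter across cells overlaps broadly between the
  two cell classes, while (b) almost every individual cell's centroid
  (≈ 97 %) still falls on its own side of the class boundary — the
  regime in which aggregating measurements within a cell converges to
  the correct call, as observed experimentally. These numbers are
  plausible invented defaults honouring the published ordering, not
  measured values.
* **Batches.** Cells are split evenly over four acquisition batches.
  Optional per-batch offsets of the cell-class means (off by default)
  emulate session drift; the background distribution is always shared
  across batches, which is what makes batch-balanced splitting
  meaningful.
* **Structural events.** A single optional interface event (a phase jump
  at a configurable transit time, off by default) stands in for sharp
  structural transitions; no multilayer acoustic model is attempted.

What the simulator does **not** emulate: correlated (non-white) detector
noise, intra-cell spatial correlation of (ν, α₀) beyond the shared
centroid, organelle-scale structure, thermal background, transducer
response, and any morphology–class correlation. Passing tests therefore
demonstrate that the pipeline recovers what it is supposed to recover
*under the stated generative model*; they are not evidence about real
tissue.

## Signal processing

* **Frequency extraction:** Hann window, 8× zero-padded FFT, quadratic
  interpolation of the log-magnitude peak. The peak search is restricted
  to the band the acquisition is configured to resolve (with 25 %
  headroom) so an out-of-band noise spur cannot win; constant traces
  raise a no-peak error.
* **Segmentation:** cells are separated from background by thresholding
  the per-pixel frequency map. The default threshold is Otsu's two-class
  criterion on the map values rather than a magic number; an optional
  3 × 3 majority filter (off by default) cleans isolated pixels.
* **Fitting:** bounded trust-region nonlinear least squares
  (`scipy.optimize.least_squares`) of the decaying sinusoid, initialised
  by the FFT frequency, the log-envelope slope of the analytic signal
  (decay), and a linear quadrature projection (amplitude/phase).
  Bounds: `A ≥ 0`, `α₀ ≥ 0`, frequency within ±50 % of the FFT seed and
  under Nyquist. A fit whose frequency lands on a search bound is
  flagged non-converged; non-convergence never raises, it returns
  best-effort parameters with `converged=False`. Phase is reported in
  (−π, π]. Per-cell centroids average (ν, α₀) over converged cell-pixel
  fits.

## GASF encoding

A trace is min–max rescaled to [−1, 1] (a constant trace maps to zeros by
convention), each value mapped to an angle `θᵢ = arccos(xᵢ)` and the time
stamp to a radius `rᵢ = tᵢ/N` with `N` the series length (the radii are
provenance only; the image depends on the angles alone). The Gramian
angular summation field is `G_ij = cos(θᵢ + θⱼ)`: symmetric, entries in
[−1, 1], diagonal `G_ii = 2xᵢ² − 1`. Min–max normalisation makes the
encoding invariant to affine rescaling of the raw trace, so the
classifier cannot key on absolute signal amplitude.

Traces are shortened before encoding by piecewise aggregate approximation
(block means). The default image side is 64 (256-sample traces in blocks
of 4), which keeps the two-convolution network trainable on one CPU;
full-resolution 256 × 256 encoding is supported. Stored PNG previews use
a linear [−1, 1] → [0, 255] map, but the classifier always consumes the
float matrix, so 8-bit quantisation never becomes a hidden
hyperparameter.

## Classifier

A deliberately shallow LeNet-style CNN: two convolution + max-pool blocks
(6 then 16 filters of 5 × 5, 2 × 2 pooling), fully connected 120 → 84 → 3,
softmax output, Adam (default 1e-3), cross-entropy loss, minibatch 64,
up to 20 epochs with early stopping (patience 3) on a validation slice
carved *from training cells only*, stratified by cell class. The network
is implemented directly in NumPy with im2col convolutions; persistent
per-layer buffers avoid allocator churn, and training is bit-reproducible
under a seed because no threading or backend nondeterminism is involved.

Splitting is at the **cell** level, 70/30 by default, stratified so every
(class, batch) group contributes the same number of cells to each
partition; no pixel of a test cell is ever seen in training. Within the
training partition, images are subsampled balanced per class and spread
evenly over batches (`max_images_per_class`), mirroring batch-balanced
observation sampling.

## Evaluation conventions

* **Confusion/accuracy:** rows are true class, columns predicted, order
  (normal, abnormal, background); accuracy is the fraction of correct
  per-pixel predictions, optionally on a seeded random subsample of the
  test set.
* **Sensitivity/specificity:** positive = abnormal, computed at the
  measurement (pixel) level. A *background* prediction on a cell pixel
  counts as an error (false negative if the pixel is abnormal, false
  positive contribution if normal); true-background pixels are excluded
  entirely because a background call is diagnostically inconclusive.
  Zero denominators yield NaN rather than an exception.
* **Sweep maps:** a trained model classifies simulated traces on a
  Cartesian (ν, α₀) grid, majority-voted over replicates, giving the
  class-region map in elastic-parameter space.
* **Majority voting:** a cell is classified from k randomly drawn pixel
  predictions by the modal non-background class. Ties — including
  all-background draws — count as failures (conservative), and
  background predictions consume draws without voting, mirroring their
  "inconclusive" role. The curve averages per-cell success rates with
  equal cell weight over 250 repetitions by default; a pooled variant is
  available behind a flag. On iid synthetic cells the Monte-Carlo
  estimate converges to the binomial tail Σ_{j>k/2} C(k,j) p^j (1−p)^{k−j},
  which the tests verify.

## Problem sizes and numerical choices

The test suite and the acceptance script both train on a seeded
synthetic study of 20 cells per class on 31 × 31 grids with 64-px images
(≈ 38 000 traces), finishing on a single CPU in minutes. The quantities
being checked (parameter recovery, encoder exactness, chance-level
controls, binomial convergence) do not depend on raster size, and
classification accuracy at this scale is limited by the configured class
overlap and by cell-sampling noise in the small test partition (8 held-
out cells), not by pixel count — occasional low per-class rates reflect
a test cell whose centroid was drawn far into the other class's region,
the synthetic analogue of real inter-cell heterogeneity.

Other numerical choices: FFT peak interpolation is clipped to ±half a
bin; the Otsu threshold falls back to all-background on a flat map;
α₀ draws are clipped at zero; degenerate phantoms (cell distribution
identical to background) are permitted but logged as non-separable.

## Known limitations

* The simulator's Gaussian class model cannot exhibit the "unidentified
  biomarkers" phenomenon — waveform features beyond (ν, α₀) — because
  under the generative model the trace *is* fully described by
  (A, f_B, φ, α₀) plus white noise. The related property that is
  testable, and tested, is that the CNN beats any single-feature
  threshold rule on fitted ν or α₀ alone by combining both.
* Reported sensitivities/specificities are measurement-level; cell-level
  variants follow from the voting machinery but are not the default
  report.
* The CNN is intentionally shallow; no augmentation, transfer learning
  or deeper architectures are provided, since the scientific claim under
  test is that a shallow network on GASF images suffices.
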