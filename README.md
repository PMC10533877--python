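# phonocell

Classification of cancer cells at the sub-cellular level from
time-resolved Brillouin (phonon) signals.

Phonon microscopy records, for every pixel of a cell scan, a GHz
oscillation produced by interference between probe light and light
scattered from a laser-launched coherent phonon. The oscillation
frequency is the Brillouin shift `f_B = 2nν/λ` (sound velocity ν,
refractive index n, probe wavelength λ) and its exponential envelope
encodes the sound attenuation coefficient α₀ — together a per-voxel
elasticity fingerprint. Cancer cells are softer than their normal
counterparts: they sit at lower ν and lower α₀. This package implements
the full per-pixel analysis chain for such data and, because the
experimental datasets are not public, ships a physics-based simulator
that generates statistically faithful phantom scans for development and
validation:

1. **Simulation** — decaying-sinusoid traces
   `s(t) = A sin(2π f_B t + φ) e^{−α₀νt} + ε`, whole-cell phantom scans
   (default 61 × 61 pixels) with normal / abnormal / background labels,
   batch structure, and (ν, α₀) parameter sweeps.
2. **Signal processing** — FFT-based Brillouin frequency extraction,
   frequency-threshold cell/background segmentation (Otsu default),
   nonlinear least-squares recovery of (A, f_B, φ, α₀, ν), per-cell
   centroids in the (ν, α₀) plane.
3. **GASF encoding** — each raw trace becomes a Gramian angular
   summation field image `G_ij = cos(arccos xᵢ + arccos xⱼ)` of its
   min–max-normalised samples, the classifier's input representation.
4. **Classification** — a shallow LeNet-style CNN (two conv+pool blocks,
   FC 120–84–3, softmax, Adam), implemented in NumPy, trained with a
   strict cell-level 70/30 split balanced across classes and acquisition
   batches.
5. **Evaluation** — confusion tables; sensitivity/specificity with the
   background-aware convention (positive = abnormal; background calls on
   cell pixels count as errors, true background is excluded as
   inconclusive); reconstruction of per-cell class maps; CNN
   classification maps over (ν, α₀) sweeps; majority-vote accuracy
   versus number of measurements (250 repetitions).

See `docs/methods.md` for the model, parameter defaults and the
simulator's scope and limits.

## Worked example

```python
import numpy as np
from phonocell import *
from phonocell.dataset import build_image_set
from phonocell.cnn import ModelConfig, make_split, train, predict_proba
from phonocell.evaluate import confusion_and_accuracy

acq = AcquisitionParams()                      # 780 nm probe, 256 x 10 ps
tr  = simulate_trace(MaterialPoint(1600.0, 1.0), acq)
print(f"{extract_brillouin_frequency(tr)/1e9:.2f} GHz")   # 5.62 GHz

scans = generate_dataset(n_cells_per_class=12, n_batches=4,
                         grid_shape=(25, 25), rng_seed=1)
ds    = build_image_set(scans, image_size=64, rng_seed=2)
split = make_split(scans, 0.7, rng_seed=3)     # whole cells, never pixels
model, log = train(ds, split, ModelConfig(epochs=14,
                                          max_images_per_class=2500,
                                          rng_seed=4))
test = ds.for_cells(split.test_cell_ids)
pred = predict_proba(model, test.images).argmax(axis=1)
rep  = confusion_and_accuracy(pred, test.labels)
print(f"accuracy {rep.overall_accuracy:.3f}  "
      f"sensitivity {rep.sensitivity:.2f}  specificity {rep.specificity:.2f}")
```

This prints

```
5.62 GHz
accuracy 0.941  sensitivity 0.80  specificity 0.89
```

The first line is the Brillouin shift of a 1600 m/s medium under a
780 nm probe at n = 1.37 — `2·1.37·1600/780 nm = 5.62 GHz`. The second
line is per-pixel performance on the held-out cells of this seeded
synthetic study: background separates almost perfectly from cells, so
overall accuracy is high, while sensitivity and specificity (positive =
abnormal, with background calls on cell pixels counted as errors) are
limited by the configured overlap of the two cell classes in the
(ν, α₀) plane and move with the luck of the small test partition — the
synthetic counterpart of real inter-cell heterogeneity. Aggregating
multiple measurements per cell (`accuracy_vs_measurements`) pushes the
cell-level call into the mid-90s; larger runs tighten the per-class
rates.

The same stages are scriptable from the shell:

```bash
phonocell run --out runs/demo --seed 1        # simulate ... vote-curve
phonocell sweep --out runs/demo               # (nu, alpha0) class map
```

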