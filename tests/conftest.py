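"""Shared fixtures.

``e2e`` builds one full synthetic study — simulate, encode, split, train —
at a reduced but realistic scale (20 cells per class, 31 x 31 grids,
64-px GASF images) and is shared session-wide by the end-to-end tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from phonocell import (AcquisitionParams, generate_dataset)
from phonocell.cnn import ModelConfig, make_split, train, predict_proba
from phonocell.dataset import build_image_set

E2E_SEED = 11


@pytest.fixture(scope="session")
def acq() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture(scope="session")
def e2e():
    """Full seeded pipeline run: scans, images, split, trained model."""
    seed = E2E_SEED
    scans = generate_dataset(n_cells_per_class=20, n_batches=4,
                             grid_shape=(31, 31), noise_sigma=0.1,
                             rng_seed=seed)
    ds = build_image_set(scans, image_size=64, rng_seed=seed + 1)
    split = make_split(scans, 0.7, rng_seed=seed + 2)
    cfg = ModelConfig(epochs=20, max_images_per_class=3000, rng_seed=seed + 3)
    model, log = train(ds, split, cfg)
    test_ds = ds.for_cells(split.test_cell_ids)
    rng = np.random.default_rng(seed + 4)
    idx = rng.choice(len(test_ds), size=4000, replace=False)
    eval_ds = test_ds.subset(idx)
    eval_pred = predict_proba(model, eval_ds.images).argmax(axis=1)
    return {
        "seed": seed,
        "scans": scans,
        "dataset": ds,
        "split": split,
        "config": cfg,
        "model": model,
        "log": log,
        "eval_ds": eval_ds,
        "eval_pred": eval_pred,
    }
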