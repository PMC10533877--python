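"""Assembly of GASF image datasets from simulated or loaded scans."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .acquisition import ClassLabel
from .gasf import encode_traces_array
from .simulate import PhononScan

__all__ = ["GasfDataset", "build_image_set"]


@dataclass
class GasfDataset:
    """A stack of labelled GASF images with provenance.

    ``images`` is (N, side, side) float32 in [-1, 1]; ``labels`` the
    per-image ClassLabel values; ``cell_ids``/``batch_ids`` identify the
    source cell for cell-level splitting; ``pixels`` the (row, col)
    position of each image in its scan.
    """

    images: np.ndarray
    labels: np.ndarray
    cell_ids: np.ndarray
    batch_ids: np.ndarray
    pixels: np.ndarray  # (N, 2) row, col

    def __post_init__(self) -> None:
        n = self.images.shape[0]
        for name in ("labels", "cell_ids", "batch_ids", "pixels"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length must match images")

    def __len__(self) -> int:
        return self.images.shape[0]

    def subset(self, idx) -> "GasfDataset":
        return GasfDataset(self.images[idx], self.labels[idx],
                           self.cell_ids[idx], self.batch_ids[idx],
                           self.pixels[idx])

    def for_cells(self, cell_ids) -> "GasfDataset":
        return self.subset(np.isin(self.cell_ids, list(cell_ids)))

    def manifest(self) -> pd.DataFrame:
        """Per-image provenance table (label, cell_id, row, col, batch)."""
        return pd.DataFrame({
            "label": [ClassLabel(int(l)).name.lower() for l in self.labels],
            "cell_id": self.cell_ids,
            "row": self.pixels[:, 0],
            "col": self.pixels[:, 1],
            "batch": self.batch_ids,
        })


def build_image_set(scans: Sequence[PhononScan],
                    image_size: int = 64,
                    pixels_per_cell: int | None = None,
                    rng_seed: int | None = None) -> GasfDataset:
    """Encode scan pixels as GASF images.

    With ``pixels_per_cell`` set, a seeded random subset of that many
    pixels is encoded per scan (memory control for large grids);
    otherwise every pixel is encoded.
    """
    rng = np.random.default_rng(rng_seed)
    imgs, labels, cids, bids, pix = [], [], [], [], []
    for scan in scans:
        rows, cols = scan.grid_shape
        flat_traces = scan.traces.reshape(rows * cols, -1)
        flat_labels = scan.labels.reshape(-1)
        idx = np.arange(rows * cols)
        if pixels_per_cell is not None and pixels_per_cell < idx.size:
            idx = np.sort(rng.choice(idx, size=pixels_per_cell, replace=False))
        imgs.append(encode_traces_array(flat_traces[idx], target_size=image_size))
        labels.append(flat_labels[idx])
        cids.append(np.full(idx.size, scan.cell_id, dtype=object))
        bids.append(np.full(idx.size, scan.batch_id, dtype=int))
        pix.append(np.column_stack(np.unravel_index(idx, (rows, cols))))
    return GasfDataset(
        np.concatenate(imgs, axis=0),
        np.concatenate(labels).astype(np.int8),
        np.concatenate(cids),
        np.concatenate(bids),
        np.concatenate(pix, axis=0),
    )
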