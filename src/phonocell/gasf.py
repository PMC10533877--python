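"""Gramian angular summation field (GASF) encoding of time traces.

A real-valued series is min-max rescaled to [-1, 1], each value mapped to
an angle theta_i = arccos(x_i) and the time stamp to a radius r_i = t_i/N;
the summation-field image is

    G_ij = cos(theta_i + theta_j) = x_i x_j - sqrt(1-x_i^2) sqrt(1-x_j^2).

G is symmetric with entries in [-1, 1] and preserves temporal ordering
along its diagonal, turning a 1-D trace into an image a conventional CNN
can consume.  Longer traces may first be shortened by piecewise aggregate
approximation (block means).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import TimeTrace

__all__ = ["PolarSeries", "GasfImage", "normalize_series", "to_polar",
           "gasf_matrix", "encode_trace", "paa_downsample"]


@dataclass
class PolarSeries:
    """Polar-coordinate view of a normalized series.

    ``angles`` in [0, pi] (arccos of the normalized values), ``radii``
    t_i / N.  The radii are provenance for plotting only; the summation
    field depends on the angles alone.
    """

    angles: np.ndarray
    radii: np.ndarray
    n_reg: float

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.angles.shape != self.radii.shape:
            raise ValueError("angles and radii must have the same shape")
        if np.any(self.angles < -1e-12) or np.any(self.angles > np.pi + 1e-12):
            raise ValueError("angles must lie in [0, pi]")


@dataclass
class GasfImage:
    """One GASF-encoded trace: a symmetric n x n matrix in [-1, 1]."""

    matrix: np.ndarray
    label: int | None = None
    source: tuple = ()  # (cell_id, row, col)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("GASF matrix must be square")

    @property
    def side(self) -> int:
        return self.matrix.shape[0]


def normalize_series(samples) -> np.ndarray:
    """Min-max rescale to [-1, 1]; a constant series maps to all zeros."""
    x = np.asarray(samples, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    y = 2.0 * (x - lo) / (hi - lo) - 1.0
    return np.clip(y, -1.0, 1.0)


def to_polar(normalized: np.ndarray,
             timestamps: np.ndarray | None = None,
             n_reg: float | None = None) -> PolarSeries:
    """Angles theta_i = arccos(x_i), radii r_i = t_i / N.

    ``timestamps`` defaults to 1..n and the regularising constant N to
    the series length, so the last radius is 1.
    """
    x = np.asarray(normalized, dtype=float)
    if timestamps is None:
        timestamps = np.arange(1, x.size + 1, dtype=float)
    timestamps = np.asarray(timestamps, dtype=float)
    if n_reg is None:
        n_reg = float(x.size)
    angles = np.arccos(np.clip(x, -1.0, 1.0))
    return PolarSeries(angles, timestamps / n_reg, n_reg)


def gasf_matrix(polar: PolarSeries) -> np.ndarray:
    """Summation field G_ij = cos(theta_i + theta_j)."""
    th = polar.angles
    return np.cos(th[:, None] + th[None, :])


def paa_downsample(samples, target_size: int) -> np.ndarray:
    """Piecewise aggregate approximation: means over contiguous blocks."""
    x = np.asarray(samples, dtype=float)
    if target_size > x.size:
        raise ValueError(
            f"target_size {target_size} exceeds trace length {x.size}")
    if target_size == x.size:
        return x.copy()
    if x.size % target_size == 0:
        return x.reshape(target_size, -1).mean(axis=1)
    return np.array([seg.mean() for seg in np.array_split(x, target_size)])


def encode_trace(trace: TimeTrace | np.ndarray,
                 target_size: int | None = 64,
                 label: int | None = None,
                 source: tuple = ()) -> GasfImage:
    """Full GASF pipeline: (optional PAA) -> normalize -> polar -> G.

    ``target_size=None`` keeps the full trace length.
    """
    samples = trace.samples if isinstance(trace, TimeTrace) else np.asarray(trace)
    if target_size is not None:
        samples = paa_downsample(samples, target_size)
    x = normalize_series(samples)
    g = gasf_matrix(to_polar(x))
    return GasfImage(g, label=label, source=source)


def encode_traces_array(traces: np.ndarray, target_size: int | None = 64,
                        dtype=np.float32) -> np.ndarray:
    """Vectorised GASF encoding of a stack of traces.

    ``traces`` is (n, length); returns (n, side, side).  Equivalent to
    :func:`encode_trace` applied row-wise, kept separate for speed on
    large batches.
    """
    x = np.asarray(traces, dtype=float)
    if x.ndim != 2:
        raise ValueError("traces must be 2-D (n, length)")
    if target_size is not None and target_size != x.shape[1]:
        if target_size > x.shape[1]:
            raise ValueError("target_size exceeds trace length")
        if x.shape[1] % target_size == 0:
            x = x.reshape(x.shape[0], target_size, -1).mean(axis=2)
        else:
            bounds = np.linspace(0, x.shape[1], target_size + 1).astype(int)
            x = np.stack([x[:, a:b].mean(axis=1)
                          for a, b in zip(bounds[:-1], bounds[1:])], axis=1)
    lo = x.min(axis=1, keepdims=True)
    hi = x.max(axis=1, keepdims=True)
    span = hi - lo
    span[span == 0] = 1.0
    xn = np.clip(2.0 * (x - lo) / span - 1.0, -1.0, 1.0)
    # all-constant rows normalise to zero
    xn[(hi == lo).ravel()] = 0.0
    th = np.arccos(xn)
    g = np.cos(th[:, :, None] + th[:, None, :])
    return g.astype(dtype)
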