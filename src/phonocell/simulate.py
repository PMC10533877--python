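"""Synthetic time-resolved Brillouin signals, cell phantoms and datasets.

The simulator produces the signal form the physics reduces to for a single
homogeneous layer: a decaying sinusoid

    s(t) = A sin(2 pi f_B t + phi) exp(-alpha0 * nu * t) + noise,

with the Brillouin frequency f_B = 2 n nu / lambda set by the sound
velocity and the temporal decay rate given by the spatial attenuation
coefficient alpha0 (um^-1) multiplied by the sound velocity.  Additive
white Gaussian noise stands in for the photodetector/averaging noise of
the real instrument.

Whole-cell phantoms are lateral grids (default 61 x 61) of such traces: a
smooth random blob of "cell" pixels over a saline-like background, with
per-cell centroid parameters drawn from class-level hyper-distributions in
which abnormal (cancer) cells sit at lower sound velocity and attenuation
than normal cells, and per-pixel jitter around the centroid.  Datasets are
balanced across classes and acquisition batches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .acquisition import (
    AcquisitionParams,
    ClassLabel,
    MaterialPoint,
    NyquistError,
    UM_INV_TO_M_INV,
)

__all__ = [
    "TimeTrace", "ClassDistribution", "ClassParamModel", "CellPhantom",
    "PhononScan", "simulate_trace", "simulate_scan",
    "simulate_parameter_sweep", "generate_dataset", "random_cell_mask",
]


@dataclass
class TimeTrace:
    """One time-resolved phonon signal: amplitude samples vs time."""

    samples: np.ndarray
    sample_interval_ps: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.sample_interval_ps <= 0:
            raise ValueError("sample_interval_ps must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def sample_interval_s(self) -> float:
        return self.sample_interval_ps * 1e-12

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.samples.size) * self.sample_interval_s


@dataclass(frozen=True)
class ClassDistribution:
    """Gaussian model of one class in the (nu, alpha0) plane.

    ``cell_sd_*`` is the spread of per-cell centroids across the
    population (zero for the shared background buffer); ``pixel_sd_*`` the
    within-cell pixel jitter around a cell's centroid.  ``corr`` couples
    nu and alpha0 draws at both levels.
    """

    mean_nu: float
    mean_alpha0: float
    cell_sd_nu: float = 0.0
    cell_sd_alpha0: float = 0.0
    pixel_sd_nu: float = 15.0
    pixel_sd_alpha0: float = 0.10
    corr: float = 0.0

    def draw_centroid(self, rng: np.random.Generator) -> tuple[float, float]:
        z = _correlated_pair(rng, 1, self.corr)
        nu = self.mean_nu + self.cell_sd_nu * z[0, 0]
        a0 = self.mean_alpha0 + self.cell_sd_alpha0 * z[0, 1]
        return float(nu), float(max(a0, 0.0))

    def draw_pixels(self, center_nu: float, center_alpha0: float,
                    n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        z = _correlated_pair(rng, n, self.corr)
        nu = center_nu + self.pixel_sd_nu * z[:, 0]
        a0 = center_alpha0 + self.pixel_sd_alpha0 * z[:, 1]
        return np.maximum(nu, 1.0), np.maximum(a0, 0.0)


def _correlated_pair(rng: np.random.Generator, n: int, corr: float) -> np.ndarray:
    z = rng.standard_normal((n, 2))
    if corr:
        z[:, 1] = corr * z[:, 0] + math.sqrt(1.0 - corr**2) * z[:, 1]
    return z


# Default class models.  Means follow the observed ordering: saline
# background lowest, cancer (abnormal) below normal in both sound velocity
# and attenuation.  The population-level scatter of individual cell
# measurements (~40 m/s, ~0.35 um^-1 per class) decomposes into a
# cell-to-cell centroid spread and a within-cell pixel jitter; the
# decomposition keeps single-cell clusters visibly tighter than the
# population overlap while leaving almost every cell's centroid on its
# own side of the class boundary, so that aggregating measurements
# within a cell converges to the right call.
DEFAULT_CLASS_MODEL: dict[ClassLabel, ClassDistribution] = {
    ClassLabel.BACKGROUND: ClassDistribution(
        mean_nu=1490.0, mean_alpha0=0.15,
        cell_sd_nu=0.0, cell_sd_alpha0=0.0,
        pixel_sd_nu=10.0, pixel_sd_alpha0=0.05),
    ClassLabel.NORMAL: ClassDistribution(
        mean_nu=1700.0, mean_alpha0=1.8,
        cell_sd_nu=25.0, cell_sd_alpha0=0.20,
        pixel_sd_nu=30.0, pixel_sd_alpha0=0.28),
    ClassLabel.ABNORMAL: ClassDistribution(
        mean_nu=1640.0, mean_alpha0=1.2,
        cell_sd_nu=25.0, cell_sd_alpha0=0.20,
        pixel_sd_nu=30.0, pixel_sd_alpha0=0.28),
}


@dataclass
class ClassParamModel:
    """Per-class (nu, alpha0) distributions plus optional batch drift.

    ``batch_nu_drift`` / ``batch_alpha0_drift`` are standard deviations of
    a per-batch additive offset applied to cell classes only (the
    background buffer is shared across sessions); both default to zero.
    """

    classes: dict[ClassLabel, ClassDistribution] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MODEL))
    batch_nu_drift: float = 0.0
    batch_alpha0_drift: float = 0.0

    def __getitem__(self, label: ClassLabel) -> ClassDistribution:
        return self.classes[ClassLabel(label)]


@dataclass
class CellPhantom:
    """Ground truth for one synthetic cell scan."""

    grid_shape: tuple[int, int] = (61, 61)
    cell_mask: np.ndarray | None = None
    class_of_cell: ClassLabel = ClassLabel.NORMAL
    batch_id: int = 1
    class_param_model: ClassParamModel = field(default_factory=ClassParamModel)
    cell_id: str = "cell-0"
    centroid_nu: float | None = None
    centroid_alpha0: float | None = None

    def __post_init__(self) -> None:
        if self.class_of_cell not in (ClassLabel.NORMAL, ClassLabel.ABNORMAL):
            raise ValueError("class_of_cell must be normal or abnormal")
        if self.cell_mask is not None:
            self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
            if self.cell_mask.shape != tuple(self.grid_shape):
                raise ValueError("cell_mask shape must equal grid_shape")

    def labels(self) -> np.ndarray:
        """Per-pixel ClassLabel grid implied by the mask."""
        if self.cell_mask is None:
            raise ValueError("phantom has no mask")
        out = np.full(self.grid_shape, int(ClassLabel.BACKGROUND), dtype=np.int8)
        out[self.cell_mask] = int(self.class_of_cell)
        return out


@dataclass
class PhononScan:
    """A lateral grid of traces for one cell with per-pixel labels.

    ``traces`` is stored as a (rows, cols, n_samples) array; use
    :meth:`trace_at` for a single-pixel :class:`TimeTrace` view.
    """

    traces: np.ndarray
    labels: np.ndarray
    acquisition: AcquisitionParams
    phantom: CellPhantom | None = None
    nu_map: np.ndarray | None = None
    alpha0_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.traces.ndim != 3:
            raise ValueError("traces must be (rows, cols, n_samples)")
        if self.labels.shape != self.traces.shape[:2]:
            raise ValueError("labels grid must be congruent with traces")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.traces.shape[:2]

    @property
    def n_traces(self) -> int:
        return self.traces.shape[0] * self.traces.shape[1]

    @property
    def cell_id(self) -> str:
        return self.phantom.cell_id if self.phantom is not None else "unknown"

    @property
    def batch_id(self) -> int:
        return self.phantom.batch_id if self.phantom is not None else 0

    @property
    def cell_class(self) -> ClassLabel:
        if self.phantom is None:
            raise ValueError("scan has no phantom metadata")
        return self.phantom.class_of_cell

    def trace_at(self, row: int, col: int) -> TimeTrace:
        return TimeTrace(
            self.traces[row, col],
            self.acquisition.sample_interval_ps,
            meta={"cell_id": self.cell_id, "row": row, "col": col,
                  "label": int(self.labels[row, col])})


def _synth(times: np.ndarray, amplitude, f_b, phase, decay_rate) -> np.ndarray:
    """Closed-form decaying sinusoid; broadcasting over leading axes."""
    f_b = np.asarray(f_b)[..., None]
    phase = np.asarray(phase)[..., None]
    amplitude = np.asarray(amplitude)[..., None]
    decay_rate = np.asarray(decay_rate)[..., None]
    return amplitude * np.sin(2.0 * np.pi * f_b * times + phase) * np.exp(
        -decay_rate * times)


def simulate_trace(material: MaterialPoint,
                   acq: AcquisitionParams | None = None,
                   amplitude: float = 1.0,
                   phase: float = 0.0,
                   noise_sigma: float = 0.0,
                   rng_seed: int | np.random.Generator | None = None,
                   interface_time_s: float | None = None,
                   interface_phase_jump: float = math.pi / 2) -> TimeTrace:
    """Simulate one time-resolved Brillouin trace for ``material``.

    The sample values are A sin(2 pi f_B t + phi) exp(-alpha0 nu t) plus
    iid Gaussian noise of standard deviation ``noise_sigma``.  An optional
    single interface event adds a phase jump at ``interface_time_s``
    (off by default), mimicking a sharp structural transition.

    Deterministic given ``rng_seed``.
    """
    acq = acq or AcquisitionParams()
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    f_b = material.brillouin_frequency(acq)
    acq.check_nyquist(f_b)
    t = acq.times()
    phi = np.full(t.shape, float(phase))
    if interface_time_s is not None:
        phi = phi + np.where(t >= interface_time_s, interface_phase_jump, 0.0)
    samples = (amplitude * np.sin(2.0 * np.pi * f_b * t + phi)
               * np.exp(-material.temporal_decay_rate * t))
    if noise_sigma > 0:
        rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
               else np.random.default_rng(rng_seed))
        samples = samples + rng.normal(0.0, noise_sigma, size=t.size)
    meta = {
        "nu": material.sound_velocity,
        "alpha0": material.attenuation_coeff,
        "f_B": f_b,
        "amplitude": amplitude,
        "phase": phase,
        "noise_sigma": noise_sigma,
    }
    return TimeTrace(samples, acq.sample_interval_ps, meta=meta)


def random_cell_mask(grid_shape: tuple[int, int],
                     rng: np.random.Generator,
                     coverage_range: tuple[float, float] = (0.30, 0.60),
                     smooth_sigma: float | None = None) -> np.ndarray:
    """Seeded random blob mask: smoothed noise thresholded at a quantile.

    Produces a single connected cell-like region covering a fraction of
    the grid drawn uniformly from ``coverage_range``.
    """
    rows, cols = grid_shape
    if smooth_sigma is None:
        smooth_sigma = max(min(rows, cols) / 6.0, 1.0)
    coverage = rng.uniform(*coverage_range)
    noise = rng.standard_normal((rows, cols))
    smooth = ndimage.gaussian_filter(noise, sigma=smooth_sigma, mode="nearest")
    thresh = np.quantile(smooth, 1.0 - coverage)
    mask = smooth > thresh
    # keep the largest connected component so the "cell" is one blob
    labelled, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labelled, index=np.arange(1, n + 1))
        mask = labelled == (1 + int(np.argmax(sizes)))
    return mask


def simulate_scan(phantom: CellPhantom,
                  acq: AcquisitionParams | None = None,
                  noise_sigma: float = 0.1,
                  rng_seed: int | np.random.Generator | None = None,
                  amplitude: float = 1.0) -> PhononScan:
    """Simulate a full scan of one phantom.

    Each pixel draws (nu, alpha0) from its class distribution — cell
    pixels jitter around the phantom's per-cell centroid, background
    pixels around the shared buffer distribution — then synthesises the
    decaying sinusoid with a uniformly random phase and additive noise.
    Reproducible under ``rng_seed``.
    """
    acq = acq or AcquisitionParams()
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    model = phantom.class_param_model
    if phantom.cell_mask is None:
        phantom.cell_mask = random_cell_mask(tuple(phantom.grid_shape), rng)
    rows, cols = phantom.grid_shape
    labels = phantom.labels()
    mask = phantom.cell_mask

    cell_dist = model[phantom.class_of_cell]
    if phantom.centroid_nu is None or phantom.centroid_alpha0 is None:
        phantom.centroid_nu, phantom.centroid_alpha0 = cell_dist.draw_centroid(rng)
    if (cell_dist.pixel_sd_nu == 0 and cell_dist.pixel_sd_alpha0 == 0
            and phantom.centroid_nu == model[ClassLabel.BACKGROUND].mean_nu):
        import logging
        logging.getLogger(__name__).warning(
            "degenerate class distributions: cell and background coincide; "
            "classes are non-separable")

    nu_map = np.empty((rows, cols))
    a0_map = np.empty((rows, cols))
    n_cell = int(mask.sum())
    nu_c, a0_c = cell_dist.draw_pixels(
        phantom.centroid_nu, phantom.centroid_alpha0, n_cell, rng)
    nu_map[mask], a0_map[mask] = nu_c, a0_c
    bg = model[ClassLabel.BACKGROUND]
    n_bg = rows * cols - n_cell
    nu_b, a0_b = bg.draw_pixels(bg.mean_nu, bg.mean_alpha0, n_bg, rng)
    nu_map[~mask], a0_map[~mask] = nu_b, a0_b

    n = acq.refractive_index
    lam = acq.probe_wavelength_nm * 1e-9
    f_map = 2.0 * n * nu_map / lam
    acq.check_nyquist(float(f_map.max()))
    decay = a0_map * UM_INV_TO_M_INV * nu_map
    phases = rng.uniform(-np.pi, np.pi, size=(rows, cols))
    t = acq.times()
    traces = _synth(t, np.full((rows, cols), amplitude), f_map, phases, decay)
    if noise_sigma > 0:
        traces = traces + rng.normal(0.0, noise_sigma, size=traces.shape)
    return PhononScan(traces, labels, acq, phantom=phantom,
                      nu_map=nu_map, alpha0_map=a0_map)


def simulate_parameter_sweep(nu_grid: Sequence[float] | None = None,
                             alpha_grid: Sequence[float] | None = None,
                             acq: AcquisitionParams | None = None,
                             noise_sigma: float = 0.1,
                             rng_seed: int | None = None,
                             replicates: int = 1,
                             amplitude: float = 1.0,
                             ) -> list[tuple[MaterialPoint, TimeTrace]]:
    """Cartesian (nu, alpha0) sweep of simulated traces.

    Default grids span the single-layer cell model ranges, nu in
    [1550, 1850] m/s and alpha0 in [0.25, 3] um^-1.  Each grid point gets
    ``replicates`` traces with fresh noise and random phase (phase fixed
    at 0 when ``noise_sigma == 0`` so replicates are exact repeats).
    """
    acq = acq or AcquisitionParams()
    if nu_grid is None:
        nu_grid = np.linspace(1550.0, 1850.0, 7)
    if alpha_grid is None:
        alpha_grid = np.linspace(0.25, 3.0, 7)
    nu_grid = np.asarray(list(nu_grid), dtype=float)
    alpha_grid = np.asarray(list(alpha_grid), dtype=float)
    if nu_grid.size == 0 or alpha_grid.size == 0:
        raise ValueError("sweep grids must be non-empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(rng_seed)
    out: list[tuple[MaterialPoint, TimeTrace]] = []
    for nu in nu_grid:
        for a0 in alpha_grid:
            mat = MaterialPoint(float(nu), float(a0),
                                refractive_index=acq.refractive_index)
            for _ in range(replicates):
                phase = rng.uniform(-np.pi, np.pi) if noise_sigma > 0 else 0.0
                out.append((mat, simulate_trace(
                    mat, acq, amplitude=amplitude, phase=phase,
                    noise_sigma=noise_sigma, rng_seed=rng)))
    return out


def generate_dataset(n_cells_per_class: int = 40,
                     n_batches: int = 4,
                     grid_shape: tuple[int, int] = (61, 61),
                     class_param_model: ClassParamModel | None = None,
                     acq: AcquisitionParams | None = None,
                     noise_sigma: float = 0.1,
                     rng_seed: int | None = None) -> list[PhononScan]:
    """Generate a balanced multi-cell, multi-batch synthetic dataset.

    Cells are split evenly across ``n_batches`` acquisition sessions for
    both classes; per-cell centroids come from the class
    hyper-distributions, so abnormal cells have lower mean nu and alpha0
    than normal cells.  The background distribution is shared across
    batches; optional per-batch offsets (``ClassParamModel`` drift fields)
    emulate session-to-session drift of the cell signals.
    """
    if n_cells_per_class % n_batches != 0:
        raise ValueError(
            f"n_cells_per_class={n_cells_per_class} not divisible by "
            f"n_batches={n_batches}")
    acq = acq or AcquisitionParams()
    model = class_param_model or ClassParamModel()
    master = np.random.SeedSequence(rng_seed)
    batch_rng = np.random.default_rng(master.spawn(1)[0])
    offsets = {
        b: (batch_rng.normal(0.0, model.batch_nu_drift) if model.batch_nu_drift else 0.0,
            batch_rng.normal(0.0, model.batch_alpha0_drift) if model.batch_alpha0_drift else 0.0)
        for b in range(1, n_batches + 1)}

    scans: list[PhononScan] = []
    per_batch = n_cells_per_class // n_batches
    idx = 0
    for label in (ClassLabel.NORMAL, ClassLabel.ABNORMAL):
        for batch in range(1, n_batches + 1):
            for _ in range(per_batch):
                seed = master.spawn(1)[0]
                rng = np.random.default_rng(seed)
                d_nu, d_a0 = offsets[batch]
                cls = model[label]
                batch_model = model
                if d_nu or d_a0:
                    shifted = replace(cls, mean_nu=cls.mean_nu + d_nu,
                                      mean_alpha0=cls.mean_alpha0 + d_a0)
                    batch_model = ClassParamModel(
                        classes={**model.classes, label: shifted},
                        batch_nu_drift=model.batch_nu_drift,
                        batch_alpha0_drift=model.batch_alpha0_drift)
                phantom = CellPhantom(
                    grid_shape=tuple(grid_shape),
                    class_of_cell=label,
                    batch_id=batch,
                    class_param_model=batch_model,
                    cell_id=f"{label.name.lower()}-b{batch}-{idx:03d}")
                scans.append(simulate_scan(phantom, acq,
                                           noise_sigma=noise_sigma,
                                           rng_seed=rng))
                idx += 1
    return scans
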