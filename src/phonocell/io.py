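"""File formats: HDF5 scan containers, CSV trace tables, fit tables, PNGs.

HDF5 layout per scan::

    /traces   float32 (rows, cols, n_samples)
    /labels   int8    (rows, cols)
    /nu_map, /alpha0_map   float32 (rows, cols), optional ground truth
    attrs: sample_interval_ps, probe_wavelength_nm, refractive_index,
           cell_id, batch_id, cell_class, grid metadata

The CSV dialect (small fixtures) stores one trace per row with a header
comment carrying the sample interval.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .acquisition import AcquisitionParams, ClassLabel
from .simulate import CellPhantom, PhononScan

__all__ = ["save_scan_h5", "load_scan_h5", "save_scans_h5", "load_scans_h5",
           "traces_to_csv", "traces_from_csv", "fits_to_csv",
           "save_frequency_map_csv", "save_mask_png", "save_gasf_png"]


def _scan_to_group(scan: PhononScan, grp) -> None:
    grp.create_dataset("traces", data=scan.traces.astype(np.float32),
                       compression="gzip", compression_opts=4)
    grp.create_dataset("labels", data=scan.labels.astype(np.int8))
    if scan.nu_map is not None:
        grp.create_dataset("nu_map", data=scan.nu_map.astype(np.float32))
    if scan.alpha0_map is not None:
        grp.create_dataset("alpha0_map", data=scan.alpha0_map.astype(np.float32))
    acq = scan.acquisition
    grp.attrs["sample_interval_ps"] = acq.sample_interval_ps
    grp.attrs["probe_wavelength_nm"] = acq.probe_wavelength_nm
    grp.attrs["pump_wavelength_nm"] = acq.pump_wavelength_nm
    grp.attrs["refractive_index"] = acq.refractive_index
    grp.attrs["numerical_aperture_delivery"] = acq.numerical_aperture_delivery
    grp.attrs["cell_id"] = scan.cell_id
    grp.attrs["batch_id"] = scan.batch_id
    if scan.phantom is not None:
        grp.attrs["cell_class"] = scan.phantom.class_of_cell.name.lower()
        if scan.phantom.cell_mask is not None:
            grp.create_dataset("cell_mask", data=scan.phantom.cell_mask)


def _scan_from_group(grp) -> PhononScan:
    acq = AcquisitionParams(
        probe_wavelength_nm=float(grp.attrs["probe_wavelength_nm"]),
        pump_wavelength_nm=float(grp.attrs.get("pump_wavelength_nm", 390.0)),
        refractive_index=float(grp.attrs["refractive_index"]),
        numerical_aperture_delivery=float(
            grp.attrs.get("numerical_aperture_delivery", 0.6)),
        sample_interval_ps=float(grp.attrs["sample_interval_ps"]),
        n_samples=int(grp["traces"].shape[2]))
    phantom = None
    if "cell_class" in grp.attrs:
        mask = grp["cell_mask"][()] if "cell_mask" in grp else None
        phantom = CellPhantom(
            grid_shape=tuple(grp["traces"].shape[:2]),
            cell_mask=mask,
            class_of_cell=ClassLabel.from_name(str(grp.attrs["cell_class"])),
            batch_id=int(grp.attrs.get("batch_id", 1)),
            cell_id=str(grp.attrs.get("cell_id", "cell")))
    return PhononScan(
        grp["traces"][()].astype(float), grp["labels"][()], acq,
        phantom=phantom,
        nu_map=grp["nu_map"][()] if "nu_map" in grp else None,
        alpha0_map=grp["alpha0_map"][()] if "alpha0_map" in grp else None)


def save_scan_h5(scan: PhononScan, path) -> None:
    import h5py
    with h5py.File(path, "w") as f:
        _scan_to_group(scan, f)


def load_scan_h5(path) -> PhononScan:
    import h5py
    with h5py.File(path, "r") as f:
        return _scan_from_group(f)


def save_scans_h5(scans, path) -> None:
    """Store a whole dataset, one group per scan, keyed by cell_id."""
    import h5py
    with h5py.File(path, "w") as f:
        for scan in scans:
            _scan_to_group(scan, f.create_group(scan.cell_id))


def load_scans_h5(path) -> list[PhononScan]:
    import h5py
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            out.append(_scan_from_group(f[key]))
    return out


def traces_to_csv(traces: np.ndarray, sample_interval_ps: float, path) -> None:
    """One trace per row; the header comment carries the sample interval."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sample_interval_ps={sample_interval_ps}\n")
        np.savetxt(fh, np.atleast_2d(traces), delimiter=",")


def traces_from_csv(path) -> tuple[np.ndarray, float]:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("# sample_interval_ps="):
            raise ValueError("missing sample_interval_ps header")
        dt = float(header.split("=", 1)[1])
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    return data, dt


def fits_to_csv(fits: dict, cell_id: str, path) -> pd.DataFrame:
    """Export a {(row, col): SignalFit} mapping as the documented table."""
    rows = [{
        "cell_id": cell_id, "row": r, "col": c,
        "A": fit.amplitude,
        "f_B_GHz": fit.brillouin_frequency / 1e9,
        "phi_rad": fit.phase,
        "alpha_um^-1": fit.attenuation,
        "nu_m_s": fit.sound_velocity,
        "residual": fit.residual_norm,
        "converged": fit.converged,
    } for (r, c), fit in sorted(fits.items())]
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def save_frequency_map_csv(freq_map: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(freq_map), delimiter=",")


def save_mask_png(mask: np.ndarray, path) -> None:
    """Boolean mask as an 8-bit PNG (cell = 255)."""
    from PIL import Image
    Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8)).save(path)


def save_gasf_png(matrix: np.ndarray, path) -> None:
    """GASF matrix as grayscale PNG with the linear map [-1, 1] -> [0, 255].

    The stored file is for inspection; the classifier consumes the float
    matrix directly, so 8-bit quantisation never enters the model.
    """
    from PIL import Image
    g = np.clip(np.asarray(matrix, float), -1.0, 1.0)
    img = np.round((g + 1.0) * 127.5).astype(np.uint8)
    Image.fromarray(img).save(path)


def save_report_json(report, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))
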