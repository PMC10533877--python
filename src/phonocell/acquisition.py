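"""Acquisition geometry, material parameters and the Brillouin relation.

Time-resolved Brillouin scattering (TRBS) interferes probe light with light
scattered from a laser-launched coherent phonon wavefront.  The beat
frequency of the recorded signal is the Brillouin frequency shift

    f_B = 2 n nu / lambda,

where ``n`` is the refractive index of the probed volume, ``nu`` the sound
velocity and ``lambda`` the probe wavelength at normal incidence.  Axial
resolution is set by the phonon wavelength, z_min = lambda / (2 n), and
lateral resolution by the Rayleigh criterion of the pump spot.

Units are SI throughout the library: frequencies in Hz, times in seconds,
lengths in metres, sound velocity in m/s.  The sound attenuation
coefficient ``alpha0`` is carried in um^-1 (the unit in which cell values
are conventionally quoted) and converted where a temporal decay rate is
needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

__all__ = [
    "ClassLabel", "NyquistError", "AcquisitionParams", "MaterialPoint",
    "axial_resolution", "lateral_resolution", "brillouin_frequency",
    "frequency_to_velocity", "velocity_to_frequency",
]

NM = 1e-9
PS = 1e-12
UM_INV_TO_M_INV = 1e6  # um^-1 -> m^-1


class ClassLabel(IntEnum):
    """Three admissible per-pixel classes."""

    NORMAL = 0
    ABNORMAL = 1
    BACKGROUND = 2

    @classmethod
    def from_name(cls, name: str) -> "ClassLabel":
        return cls[name.upper()]


class NyquistError(ValueError):
    """Sampling too slow for the configured Brillouin frequency range."""


def velocity_to_frequency(nu: float, n: float, wavelength_m: float) -> float:
    """Brillouin shift f_B = 2 n nu / lambda, in Hz."""
    return 2.0 * n * nu / wavelength_m


def frequency_to_velocity(f_b: float, n: float, wavelength_m: float) -> float:
    """Invert the Brillouin relation: nu = f_B lambda / (2 n), in m/s."""
    return f_b * wavelength_m / (2.0 * n)


def brillouin_frequency(nu: float, n: float, wavelength_nm: float = 780.0) -> float:
    """Convenience wrapper taking the probe wavelength in nm."""
    return velocity_to_frequency(nu, n, wavelength_nm * NM)


def axial_resolution(wavelength_nm: float = 780.0, n: float = 1.33) -> float:
    """Axial resolution z_min = lambda_probe / (2 n), in metres.

    Defaults give the probe wavelength in water (~293 nm): resolution is
    set by the phonon wavelength and is independent of numerical aperture.
    """
    return wavelength_nm * NM / (2.0 * n)


def lateral_resolution(pump_wavelength_nm: float = 390.0, na: float = 0.6) -> float:
    """Rayleigh lateral resolution of the pump spot, 0.61 lambda / NA, metres."""
    return 0.61 * pump_wavelength_nm * NM / na


@dataclass(frozen=True)
class AcquisitionParams:
    """Optical and sampling configuration of the phonon microscope.

    Parameters
    ----------
    probe_wavelength_nm : probe laser wavelength (default 780 nm).
    pump_wavelength_nm : frequency-doubled pump wavelength (default 390 nm).
    refractive_index : index of the probed medium (1.37 cell, 1.33 water).
    numerical_aperture_delivery : NA of the delivery objective.
    sample_interval_ps : sampling step of the reconstructed trace.
    n_samples : samples per trace (default 256, a 2.56 ns window).
    repetition_rate_mhz : laser repetition rate (metadata only).
    max_sound_velocity : largest velocity the configuration must resolve;
        used for the Nyquist check at construction.
    """

    probe_wavelength_nm: float = 780.0
    pump_wavelength_nm: float = 390.0
    refractive_index: float = 1.37
    numerical_aperture_delivery: float = 0.6
    sample_interval_ps: float = 10.0
    n_samples: int = 256
    repetition_rate_mhz: float = 100.0
    max_sound_velocity: float = 1850.0

    def __post_init__(self) -> None:
        for name in ("probe_wavelength_nm", "pump_wavelength_nm",
                     "sample_interval_ps", "max_sound_velocity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.refractive_index <= 0 or self.numerical_aperture_delivery <= 0:
            raise ValueError("refractive_index and NA must be strictly positive")
        if self.n_samples < 16:
            raise ValueError("n_samples must be at least 16")
        f_max = velocity_to_frequency(
            self.max_sound_velocity, self.refractive_index,
            self.probe_wavelength_nm * NM)
        if self.sample_rate <= 2.0 * f_max:
            raise NyquistError(
                f"sample rate {self.sample_rate:.3g} Hz does not exceed twice "
                f"the maximum Brillouin frequency {f_max:.3g} Hz")

    @property
    def sample_interval_s(self) -> float:
        return self.sample_interval_ps * PS

    @property
    def sample_rate(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.sample_interval_s

    @property
    def window_s(self) -> float:
        """Trace duration in seconds."""
        return self.n_samples * self.sample_interval_s

    def times(self):
        import numpy as np
        return np.arange(self.n_samples) * self.sample_interval_s

    def check_nyquist(self, f_b: float) -> None:
        """Raise NyquistError if ``f_b`` (Hz) is not strictly resolvable."""
        if 2.0 * f_b >= self.sample_rate:
            raise NyquistError(
                f"Brillouin frequency {f_b:.4g} Hz violates Nyquist for "
                f"sample rate {self.sample_rate:.4g} Hz")

    def axial_resolution(self, n: float | None = None) -> float:
        """z_min = lambda_probe / 2n (metres); pass n=1.33 for water."""
        return axial_resolution(self.probe_wavelength_nm,
                                self.refractive_index if n is None else n)

    def lateral_resolution(self) -> float:
        """Rayleigh x_min of the pump generation spot (metres)."""
        return lateral_resolution(self.pump_wavelength_nm,
                                  self.numerical_aperture_delivery)


@dataclass(frozen=True)
class MaterialPoint:
    """Acoustic parameters of one probed volume.

    ``sound_velocity`` (nu) in m/s, ``attenuation_coeff`` (alpha0) in um^-1,
    density in kg/m^3.  Cancer cells sit at lower nu and alpha0 than normal
    cells; saline background lower still in both.
    """

    sound_velocity: float
    attenuation_coeff: float
    density: float = 1050.0
    refractive_index: float = 1.37

    def __post_init__(self) -> None:
        if self.sound_velocity <= 0:
            raise ValueError("sound_velocity must be positive")
        if self.attenuation_coeff < 0:
            raise ValueError("attenuation_coeff must be non-negative")
        if self.density <= 0:
            raise ValueError("density must be positive")

    def brillouin_frequency(self, acq: AcquisitionParams) -> float:
        """f_B (Hz) of this material under ``acq``."""
        return velocity_to_frequency(
            self.sound_velocity, self.refractive_index,
            acq.probe_wavelength_nm * NM)

    @property
    def temporal_decay_rate(self) -> float:
        """Decay rate alpha0 * nu in s^-1 (spatial attenuation x velocity)."""
        return self.attenuation_coeff * UM_INV_TO_M_INV * self.sound_velocity
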