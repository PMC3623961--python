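"""Steady-state spectroscopy: polarization, quantum yield and band metrics.

Covers the G-factor and steady-state anisotropy from the four polarized
intensities, relative quantum yields against a reference standard
(quinine sulfate, phi = 0.54 in 0.1 N H2SO4), and emission/phosphorescence
band metrics: peak position, integrated area, and the width at half
maximum expressed in wavenumbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DataQualityWarning, DomainError, GridError

__all__ = [
    "EmissionSpectrum",
    "PolarizedIntensities",
    "QuantumYieldInput",
    "BandMetrics",
    "g_factor",
    "steady_anisotropy",
    "relative_quantum_yield",
    "band_metrics",
]

QUININE_SULFATE_PHI = 0.54


@dataclass
class EmissionSpectrum:
    """Emission (or phosphorescence) spectrum on a wavelength grid."""

    wavelength: np.ndarray  # nm, strictly increasing
    intensity: np.ndarray  # arbitrary units, >= 0
    excitation_nm: float | None = None
    bandpass_ex_nm: float | None = None
    bandpass_em_nm: float | None = None

    def __post_init__(self):
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.wavelength) <= 0):
            raise GridError("wavelength grid must be strictly increasing")
        if len(self.wavelength) != len(self.intensity):
            raise GridError("wavelength and intensity must have equal length")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise DomainError("intensity must be finite and non-negative")

    def area(self) -> float:
        """Trapezoidal integral over the full recorded window."""
        return float(np.trapezoid(self.intensity, self.wavelength))


@dataclass
class PolarizedIntensities:
    """The four polarizer-combination intensities I_VV, I_VH, I_HV, I_HH."""

    i_vv: float
    i_vh: float
    i_hv: float = 0.0
    i_hh: float = 0.0

    def __post_init__(self):
        for name in ("i_vv", "i_vh", "i_hv", "i_hh"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")


@dataclass
class QuantumYieldInput:
    """Inputs for a relative quantum-yield determination."""

    sample_area: float
    ref_area: float
    sample_absorbance: float
    ref_absorbance: float
    ref_phi: float = QUININE_SULFATE_PHI

    def __post_init__(self):
        if self.sample_area <= 0 or self.ref_area <= 0:
            raise DomainError("integrated areas must be positive")
        if self.sample_absorbance <= 0 or self.ref_absorbance <= 0:
            raise DomainError("absorbances must be positive")
        if max(self.sample_absorbance, self.ref_absorbance) > 0.1:
            warnings.warn(
                "absorbance above 0.1: inner-filter effects may bias the "
                "relative quantum yield",
                DataQualityWarning,
                stacklevel=2,
            )


def g_factor(p: PolarizedIntensities) -> float:
    """Grating correction factor G = I_HV / I_HH."""
    if p.i_hh <= 0:
        raise DomainError("i_hh must be positive to define G")
    return p.i_hv / p.i_hh


def steady_anisotropy(p: PolarizedIntensities, g: float) -> float:
    """Steady-state anisotropy r = (I_VV - G I_VH) / (I_VV + 2 G I_VH)."""
    denom = p.i_vv + 2.0 * g * p.i_vh
    if denom <= 0:
        raise DomainError("I_VV + 2 G I_VH must be positive")
    return (p.i_vv - g * p.i_vh) / denom


def relative_quantum_yield(q: QuantumYieldInput) -> float:
    """Quantum yield relative to the reference standard.

    phi = phi_ref * (A_sample / A_ref) * (Abs_ref / Abs_sample)

    where A are integrated emission areas and Abs the absorbances at the
    excitation wavelength.  No refractive-index correction is applied
    (sample and reference both aqueous); correct externally by
    (n_sample / n_ref)^2 for non-aqueous work.
    """
    return (
        q.ref_phi
        * (q.sample_area / q.ref_area)
        * (q.ref_absorbance / q.sample_absorbance)
    )


@dataclass
class BandMetrics:
    lambda_max_nm: float
    area: float
    fwhm_cm1: float


def _half_crossing(wl, inten, i_peak, half, side):
    """Wavelength of the half-maximum crossing by linear interpolation."""
    if side == "lo":
        seg = range(i_peak, 0, -1)
        step = -1
    else:
        seg = range(i_peak, len(wl) - 1)
        step = 1
    for i in seg:
        j = i + step
        if (inten[i] - half) * (inten[j] - half) <= 0 and inten[i] != inten[j]:
            frac = (half - inten[i]) / (inten[j] - inten[i])
            return wl[i] + frac * (wl[j] - wl[i])
    raise DomainError(
        f"half-maximum not bracketed on the {side} side of the recorded grid"
    )


def band_metrics(s: EmissionSpectrum, smooth_window: int | None = None) -> BandMetrics:
    """Peak position (nm), trapezoidal area, and FWHM in wavenumbers.

    The width is measured where the band crosses half of its maximum on the
    wavelength axis; the two crossing wavelengths lambda_lo < lambda_hi are
    converted to wavenumbers, fwhm = 1e7 (1/lambda_lo - 1/lambda_hi) cm^-1.
    Optional boxcar smoothing (odd ``smooth_window`` channels) is applied
    before locating the maximum only.
    """
    wl, inten = s.wavelength, s.intensity
    work = inten
    if smooth_window and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        work = np.convolve(inten, kernel, mode="same")
    i_peak = int(np.argmax(work))
    lam_max = float(wl[i_peak])
    half = inten[i_peak] / 2.0
    lam_lo = _half_crossing(wl, inten, i_peak, half, "lo")
    lam_hi = _half_crossing(wl, inten, i_peak, half, "hi")
    fwhm_cm1 = 1e7 * (1.0 / lam_lo - 1.0 / lam_hi)
    return BandMetrics(lambda_max_nm=lam_max, area=s.area(), fwhm_cm1=float(fwhm_cm1))
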