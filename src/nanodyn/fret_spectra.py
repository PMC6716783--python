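"""Liquid-ordered / liquid-disordered spectral decomposition of
solvatochromic-probe TR-FRET emission scans.

A long-lifetime lanthanide donor on the receptor transfers energy to a
membrane probe (NR12S) whose emission blue-shifts in liquid-ordered
(Lo) relative to liquid-disordered (Ld) membrane phase. Each spectral
scan (460-650 nm, 5-nm steps) is ratiometrically normalized to its
490-nm donor signal; the normalized donor-only scan is subtracted to
isolate the probe-specific sensitized emission, which is then split at
590 nm into Lo-associated (530-590 nm) and Ld-associated (590-650 nm)
band areas expressed relative to the 530-650 nm total. A point-ratio
readout (increase at 570 nm over increase at 610 nm) and a kinetic
three-channel ratio readout are also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EMISSION_GRID_NM",
    "EmissionSpectrum",
    "SpectralBands",
    "nr12s_fret_spectrum",
    "lo_ld_fractions",
    "lo_ld_point_ratio",
    "kinetic_lo_ratio",
]

# native plate-reader emission grid: 460-650 nm in 5-nm steps (39 points)
EMISSION_GRID_NM = np.arange(460.0, 655.0, 5.0)


@dataclass
class EmissionSpectrum:
    """Wavelength-indexed plate-reader signal.

    Intensities may be negative after blank subtraction; they are kept,
    not clipped (clipping would bias band areas).
    """

    wavelengths: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelengths.shape != self.intensity.shape:
            raise ValueError("wavelengths and intensity must align")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")

    def subtract_blank(self, blank: "EmissionSpectrum | float") -> "EmissionSpectrum":
        if isinstance(blank, EmissionSpectrum):
            if not np.array_equal(blank.wavelengths, self.wavelengths):
                raise ValueError("blank spectrum must share the grid")
            corrected = self.intensity - blank.intensity
        else:
            corrected = self.intensity - float(blank)
        return EmissionSpectrum(self.wavelengths.copy(), corrected)

    def at(self, wavelength: float) -> float:
        idx = np.nonzero(np.isclose(self.wavelengths, wavelength))[0]
        if idx.size != 1:
            raise ValueError(f"{wavelength} nm is not on the grid")
        return float(self.intensity[idx[0]])


@dataclass
class SpectralBands:
    """Band definitions for the Lo/Ld split. The Lo and Ld bands share
    the 590-nm boundary; contiguous trapezoids count it once per band so
    lo + ld areas sum exactly to the 530-650 total."""

    ref_wavelength: float = 490.0
    lo_band: tuple[float, float] = (530.0, 590.0)
    ld_band: tuple[float, float] = (590.0, 650.0)
    lo_point: float = 570.0
    ld_point: float = 610.0

    def __post_init__(self) -> None:
        if self.lo_band[1] != self.ld_band[0]:
            raise ValueError("lo and ld bands must be contiguous")
        if not (self.lo_band[0] <= self.lo_point <= self.lo_band[1]):
            raise ValueError("lo_point must lie inside the lo band")
        if not (self.ld_band[0] <= self.ld_point <= self.ld_band[1]):
            raise ValueError("ld_point must lie inside the ld band")


def nr12s_fret_spectrum(
    donor_only: EmissionSpectrum,
    with_probe: EmissionSpectrum,
    bands: SpectralBands | None = None,
) -> EmissionSpectrum:
    """Probe-specific sensitized-emission difference spectrum.

    Both inputs (already blank-subtracted) are normalized to their own
    signal at the reference wavelength (490 nm); the normalized
    donor-only scan is subtracted from the normalized probe scan. The
    output is exactly zero at 490 nm by construction and invariant to
    rescaling either input.
    """
    bands = bands or SpectralBands()
    if not np.array_equal(donor_only.wavelengths, with_probe.wavelengths):
        raise ValueError("spectra must share the wavelength grid")
    ref_d = donor_only.at(bands.ref_wavelength)
    ref_p = with_probe.at(bands.ref_wavelength)
    if ref_d <= 0 or ref_p <= 0:
        raise ValueError(
            f"signal at {bands.ref_wavelength:g} nm must be positive to normalize"
        )
    diff = with_probe.intensity / ref_p - donor_only.intensity / ref_d
    return EmissionSpectrum(donor_only.wavelengths.copy(), diff)


def _band_auc(spectrum: EmissionSpectrum, lo: float, hi: float) -> float:
    wl, y = spectrum.wavelengths, spectrum.intensity
    mask = (wl >= lo) & (wl <= hi)
    if mask.sum() < 2:
        raise ValueError(f"grid does not cover the {lo}-{hi} nm band")
    return float(np.trapezoid(y[mask], wl[mask]))


def lo_ld_fractions(
    fret_spectrum: EmissionSpectrum, bands: SpectralBands | None = None
) -> tuple[float, float]:
    """Fraction of the total sensitized-emission area in each band.

    Trapezoidal areas on the native grid over the Lo and Ld bands,
    each divided by the area over their union; the two fractions sum to
    1 exactly because the bands share the 590-nm trapezoid endpoint.
    Fractions can fall outside [0, 1] when noise drives band areas
    negative; they are reported as computed.
    """
    bands = bands or SpectralBands()
    lo_auc = _band_auc(fret_spectrum, *bands.lo_band)
    ld_auc = _band_auc(fret_spectrum, *bands.ld_band)
    total = lo_auc + ld_auc
    if total <= 0:
        raise ValueError("total band area is non-positive; fractions undefined")
    return lo_auc / total, ld_auc / total


def lo_ld_point_ratio(
    before: EmissionSpectrum,
    after: EmissionSpectrum,
    bands: SpectralBands | None = None,
    denominator_floor: float = 0.0,
) -> float:
    """Ratio of the stimulus-induced increase at the Lo point wavelength
    (570 nm) to the increase at the Ld point wavelength (610 nm).

    Both inputs are probe-specific difference spectra (before/after
    stimulation). Raises if the Ld-point increase is zero (or below the
    optional floor), which makes the ratio undefined.
    """
    bands = bands or SpectralBands()
    d_lo = after.at(bands.lo_point) - before.at(bands.lo_point)
    d_ld = after.at(bands.ld_point) - before.at(bands.ld_point)
    if abs(d_ld) <= denominator_floor:
        raise ZeroDivisionError(
            f"increase at {bands.ld_point:g} nm is {d_ld:g}; ratio undefined"
        )
    return d_lo / d_ld


def kinetic_lo_ratio(
    trace,
    bands: SpectralBands | None = None,
) -> dict[str, np.ndarray]:
    """Baseline-normalized Lo and Ld ratio traces from a three-channel
    kinetic read (reference 490 nm, Lo 570 nm, Ld 610 nm).

    Each wavelength channel is blank-subtracted, the 570/490 and
    610/490 ratios formed, and each ratio divided by its own mean over
    the pre-stimulation baseline window, so responses are fold-change
    from baseline per well and invariant to common gain.
    """
    from .pharmacology import normalize_to_baseline, ratiometric_trace

    bands = bands or SpectralBands()
    out: dict[str, np.ndarray] = {"times": trace.times}
    for name, nm in (("lo", bands.lo_point), ("ld", bands.ld_point)):
        ratio = ratiometric_trace(trace, nm, bands.ref_wavelength)
        normalized, _ = normalize_to_baseline(
            ratio, trace.times, trace.baseline_window
        )
        out[f"{name}_ratio"] = normalized
    return out
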