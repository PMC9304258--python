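"""Radially averaged frequency spectra, frequency transfer and bandpass.

The spectral magnitude of a frame is summarised by averaging ``|F(u, v)|``
over integer annuli ``r <= sqrt(u**2 + v**2) < r + 1`` in DC-centered index
coordinates.  When the imaging geometry is known, annulus indices are
rescaled to cycles/mm via the Nyquist frequency of the *entrance-plane*
pixel spacing (detector element spacing corrected by the geometric
magnification sed/sid).  Ratios of two profiles characterise the frequency
transfer of a denoiser; a hard annular DFT mask implements the bandpass
filter used to locate the band of clinically useful content.

By default no apodization window is applied (an optional Hann flag exists
for leakage-sensitive use), and magnitudes — not squared magnitudes — are
averaged; ``power=True`` switches to ``|F|**2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .image_io import GeometrySpec, ImageFrame

__all__ = [
    "SpectrumProfile",
    "Band",
    "nyquist_cycles_per_mm",
    "radial_profile",
    "transfer_ratio",
    "average_transfer_ratio",
    "bandpass_filter",
    "band_consensus",
]


@dataclass
class SpectrumProfile:
    """Mean spectral magnitude per radial annulus.

    The conservation identity ``sum_r n(r) * S(r) == sum |F|`` holds over
    all covered bins by construction.
    """

    radii: np.ndarray  # integer annulus indices 0..r_max
    s_of_r: np.ndarray  # mean |F| per annulus
    n_of_r: np.ndarray  # element count per annulus
    nyquist_index: int = 0  # annulus index of the per-axis Nyquist frequency
    cycles_per_mm: np.ndarray | None = None
    nyquist_cpmm: float | None = None

    def total_magnitude(self) -> float:
        return float(np.sum(self.n_of_r * self.s_of_r))

    def up_to_nyquist(self) -> np.ndarray:
        """Boolean mask of annuli at or below the Nyquist frequency.

        Annuli beyond it (corner bins of the DFT) only sample diagonal
        directions and are kept in the profile solely for the conservation
        identity; frequency-transfer analysis uses this mask.
        """
        return self.radii <= self.nyquist_index


@dataclass(frozen=True)
class Band:
    """Spatial-frequency interval in cycles/mm."""

    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_lo < self.f_hi):
            raise ValueError("band must satisfy 0 <= f_lo < f_hi")


def nyquist_cycles_per_mm(geometry: GeometrySpec) -> float:
    """Nyquist frequency at the patient entrance plane.

    The effective pixel spacing is ``detector_spacing * sed / sid`` (the
    magnification correction); Nyquist is ``1 / (2 * effective spacing)``.
    """
    if geometry.sed_mm > geometry.sid_mm:
        raise ValueError("sed_mm must not exceed sid_mm")
    return 1.0 / (2.0 * geometry.effective_spacing_mm)


def _effective_spacing(frame, geometry: GeometrySpec | None) -> float | None:
    """Entrance-plane spacing in mm/pixel, or None if unknown.

    Prefers an explicit geometry; falls back to the frame's detector pixel
    spacing at magnification 1 (useful for phantoms).
    """
    if geometry is not None:
        return geometry.effective_spacing_mm
    if isinstance(frame, ImageFrame):
        if frame.geometry is not None:
            return frame.geometry.effective_spacing_mm
        if frame.pixel_spacing_mm is not None:
            return float(frame.pixel_spacing_mm)
    return None


def _radial_index(rows: int, cols: int) -> np.ndarray:
    """Integer annulus index per DC-centered DFT bin.

    For non-square frames both axes are rescaled so that the per-axis
    Nyquist falls at the same annulus (index ``min(rows, cols) // 2``),
    keeping annuli isotropic in physical frequency.
    """
    u = np.arange(rows) - rows // 2
    v = np.arange(cols) - cols // 2
    m = min(rows, cols)
    uu = u[:, None] * (m / rows)
    vv = v[None, :] * (m / cols)
    return np.floor(np.sqrt(uu**2 + vv**2)).astype(int)


def radial_profile(
    frame,
    geometry: GeometrySpec | None = None,
    window: bool = False,
    power: bool = False,
) -> SpectrumProfile:
    """Radially averaged DFT magnitude of a frame.

    ``window=True`` applies a Hann window before the transform;
    ``power=True`` averages ``|F|**2`` instead of ``|F|``.
    """
    arr = frame.pixels if isinstance(frame, ImageFrame) else np.asarray(frame, dtype=float)
    if arr.ndim != 2 or min(arr.shape) < 8:
        raise ValueError("radial_profile needs a 2D frame of at least 8x8")
    if window:
        arr = arr * np.outer(np.hanning(arr.shape[0]), np.hanning(arr.shape[1]))
    mag = np.abs(np.fft.fftshift(np.fft.fft2(arr)))
    if power:
        mag = mag**2
    idx = _radial_index(*arr.shape)
    counts = np.bincount(idx.ravel())
    sums = np.bincount(idx.ravel(), weights=mag.ravel())
    radii = np.arange(counts.size)
    s_of_r = sums / counts
    spacing = _effective_spacing(frame, geometry)
    cycles = None
    nyq = None
    if spacing is not None:
        nyq = 1.0 / (2.0 * spacing)
        # annulus r sits at physical frequency r / (min(M, N) * spacing)
        cycles = radii / (min(arr.shape) * spacing)
    return SpectrumProfile(
        radii=radii,
        s_of_r=s_of_r,
        n_of_r=counts,
        nyquist_index=min(arr.shape) // 2,
        cycles_per_mm=cycles,
        nyquist_cpmm=nyq,
    )


def transfer_ratio(numerator: SpectrumProfile, denominator: SpectrumProfile) -> np.ndarray:
    """Per-annulus ratio ``S_num(r) / S_den(r)``.

    Profiles must share the annulus grid (same frame size and geometry).
    Bins with zero denominator are marked NaN.
    """
    if numerator.radii.size != denominator.radii.size:
        raise ValueError("profiles have different annulus grids")
    if (numerator.nyquist_cpmm is None) != (denominator.nyquist_cpmm is None) or (
        numerator.nyquist_cpmm is not None
        and not math.isclose(numerator.nyquist_cpmm, denominator.nyquist_cpmm)
    ):
        raise ValueError("profiles have different frequency scaling")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = numerator.s_of_r / denominator.s_of_r
    ratio[denominator.s_of_r == 0] = np.nan
    return ratio


def average_transfer_ratio(
    numerators: list[SpectrumProfile], denominators: list[SpectrumProfile]
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SD over per-image ratio curves (ratio first, then average)."""
    if len(numerators) != len(denominators) or not numerators:
        raise ValueError("need equally many numerator and denominator profiles")
    curves = np.array([transfer_ratio(n, d) for n, d in zip(numerators, denominators)])
    return np.nanmean(curves, axis=0), np.nanstd(curves, axis=0)


def bandpass_filter(frame: ImageFrame, band: Band, geometry: GeometrySpec | None = None) -> ImageFrame:
    """Hard annular bandpass in the DFT domain.

    DFT coefficients whose radial frequency (cycles/mm) falls outside
    ``[f_lo, f_hi]`` are zeroed and the frame is rebuilt from the inverse
    transform's real part.  DC survives only when ``f_lo == 0``.  When
    ``f_hi`` reaches the Nyquist frequency the upper cut is disabled, since
    the diagonal bins beyond the per-axis Nyquist would otherwise be lost
    and a full-band filter must be the identity.
    """
    spacing = _effective_spacing(frame, geometry)
    if spacing is None:
        raise ValueError("bandpass_filter requires a geometry or a frame pixel spacing")
    nyq = 1.0 / (2.0 * spacing)
    if band.f_hi > nyq * (1 + 1e-9):
        raise ValueError(f"band upper edge {band.f_hi} exceeds Nyquist {nyq}")
    arr = frame.pixels
    rows, cols = arr.shape
    fu = (np.arange(rows) - rows // 2) / (rows * spacing)
    fv = (np.arange(cols) - cols // 2) / (cols * spacing)
    freq = np.sqrt(fu[:, None] ** 2 + fv[None, :] ** 2)
    mask = freq >= band.f_lo
    if band.f_hi < nyq * (1 - 1e-9):
        mask &= freq <= band.f_hi
    spec = np.fft.fftshift(np.fft.fft2(arr))
    out = np.fft.ifft2(np.fft.ifftshift(spec * mask)).real
    return frame.with_pixels(out)


def band_consensus(selections: list[tuple[float, float]]) -> tuple[Band, Band | None]:
    """Overall and consensus band from per-observer selections.

    The overall band spans the minimum lower to the maximum upper limit;
    the consensus band is the intersection of all selections, or None when
    the selections do not overlap.
    """
    if not selections:
        raise ValueError("no selections given")
    bands = [Band(lo, hi) for lo, hi in selections]
    overall = Band(min(b.f_lo for b in bands), max(b.f_hi for b in bands))
    lo = max(b.f_lo for b in bands)
    hi = min(b.f_hi for b in bands)
    consensus = Band(lo, hi) if lo < hi else None
    return overall, consensus
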