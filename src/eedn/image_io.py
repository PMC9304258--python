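"""Raster frame I/O and the shared image data model.

All processing in this package runs on :class:`ImageFrame`: a 2D array of
intensities together with the bit depth of the acquisition (intensities live
in ``[0, 2**n - 1]``), an optional physical pixel spacing at the detector
plane, and, for fluoroscopy frames read from DICOM, the imaging geometry
needed to rescale spatial frequencies to cycles/mm.

Pixels are kept in floating point during processing; quantisation (round,
then clip to the intensity range) happens only when a frame is written to an
integer format.  Pixel coordinates are row-major with the origin at the top
left, 0-based.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ImageFrame",
    "GeometrySpec",
    "FormatError",
    "read_frame",
    "read_dicom_frames",
    "write_frame",
]


class FormatError(ValueError):
    """Raised when a file cannot be interpreted as the named image format."""


@dataclass(frozen=True)
class GeometrySpec:
    """X-ray imaging geometry used for frequency rescaling.

    Parameters
    ----------
    detector_spacing_mm
        Detector element spacing in mm.
    sid_mm
        Source-to-image (detector) distance in mm.
    sed_mm
        Source-to-entrance distance in mm (distance from the focal spot to
        the patient entrance plane).  Must not exceed ``sid_mm``.
    """

    detector_spacing_mm: float
    sid_mm: float
    sed_mm: float

    def __post_init__(self) -> None:
        for name in ("detector_spacing_mm", "sid_mm", "sed_mm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.sed_mm > self.sid_mm:
            raise ValueError("sed_mm must not exceed sid_mm")

    @property
    def effective_spacing_mm(self) -> float:
        """Pixel spacing projected to the patient entrance plane (mm).

        The detector spacing is demagnified by ``sed / sid``, the standard
        geometric magnification correction.
        """
        return self.detector_spacing_mm * self.sed_mm / self.sid_mm


@dataclass
class ImageFrame:
    """A single 2D radiographic frame.

    ``pixels`` is stored as float64; values are expected to be non-negative
    and, when materialised to disk, within ``[0, 2**bit_depth - 1]``.
    """

    pixels: np.ndarray
    bit_depth: int
    pixel_spacing_mm: float | None = None
    frame_id: str | None = None
    geometry: GeometrySpec | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("frame must be at least 1x1")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")
        if int(self.bit_depth) < 1:
            raise ValueError("bit_depth must be a positive integer")
        self.bit_depth = int(self.bit_depth)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def max_value(self) -> float:
        """Largest representable intensity, ``2**bit_depth - 1``."""
        return float(2**self.bit_depth - 1)

    def with_pixels(self, pixels: np.ndarray, frame_id: str | None = None) -> "ImageFrame":
        """Copy of this frame with new pixel data and otherwise equal metadata."""
        out = replace(self, pixels=np.array(pixels, dtype=np.float64))
        if frame_id is not None:
            out.frame_id = frame_id
        return out

    def clipped(self) -> "ImageFrame":
        """Copy with intensities clipped to ``[0, 2**n - 1]``."""
        return self.with_pixels(np.clip(self.pixels, 0.0, self.max_value))


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower()
    if suffix == ".png":
        return "png"
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix in (".dcm", ".dicom", ".ima"):
        return "dicom"
    raise FormatError(f"cannot infer image format from {path.name!r}")


def _depth_from_dtype(arr: np.ndarray, path: Path) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    raise FormatError(f"{path}: unsupported dtype {arr.dtype} (expect 8/16-bit grayscale)")


def read_frame(path: str | Path, format: str | None = None, frame_index: int = 0) -> ImageFrame:
    """Read a single grayscale frame from PNG, TIFF or DICOM.

    Bit depth is inferred from the stored dtype (PNG/TIFF) or from the
    ``BitsStored`` header field (DICOM).  DICOM pixel data is rescaled by
    slope/intercept when present, and a :class:`GeometrySpec` is attached
    when the header carries the detector spacing, the source-to-image
    distance and the source-to-entrance distance.  ``frame_index`` selects a
    frame from multi-frame DICOM files.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = _infer_format(path, format)
    if fmt == "png":
        import imageio.v3 as iio

        try:
            arr = iio.imread(path)
        except Exception as exc:  # pragma: no cover - backend specific
            raise FormatError(f"unreadable PNG: {path}") from exc
        if arr.ndim != 2:
            raise FormatError(f"{path}: color images are not supported")
        return ImageFrame(arr, _depth_from_dtype(arr, path), frame_id=path.stem)
    if fmt == "tiff":
        import tifffile

        try:
            arr = tifffile.imread(path)
        except Exception as exc:
            raise FormatError(f"unreadable TIFF: {path}") from exc
        if arr.ndim != 2:
            raise FormatError(f"{path}: color/stacked TIFF is not supported")
        return ImageFrame(arr, _depth_from_dtype(arr, path), frame_id=path.stem)
    if fmt == "dicom":
        return _read_dicom(path, frame_index)
    raise FormatError(f"unknown format {fmt!r}")


# DICOM header mapping for the imaging geometry.  The detector element
# spacing is taken from ImagerPixelSpacing (0018,1164), falling back to
# PixelSpacing; the source-to-image distance from DistanceSourceToDetector
# (0018,1110); and the source-to-entrance distance from
# DistanceSourceToEntrance (0040,0306), falling back to
# DistanceSourceToPatient (0018,1111) when absent.
_GEOMETRY_TAGS = {
    "spacing": ("ImagerPixelSpacing", "PixelSpacing"),
    "sid": ("DistanceSourceToDetector",),
    "sed": ("DistanceSourceToEntrance", "DistanceSourceToPatient"),
}


def _dicom_geometry(ds) -> GeometrySpec | None:
    values = {}
    for key, names in _GEOMETRY_TAGS.items():
        value = None
        for name in names:
            raw = getattr(ds, name, None)
            if raw is None:
                continue
            if key == "spacing":
                try:
                    value = float(raw[0])
                except (TypeError, IndexError):
                    value = float(raw)
            else:
                value = float(raw)
            break
        if value is None:
            return None
        values[key] = value
    try:
        return GeometrySpec(values["spacing"], values["sid"], values["sed"])
    except ValueError:
        return None


def _read_dicom(path: Path, frame_index: int) -> ImageFrame:
    import pydicom

    try:
        ds = pydicom.dcmread(path)
    except Exception as exc:
        raise FormatError(f"unreadable DICOM: {path}") from exc
    if "PixelData" not in ds:
        raise FormatError(f"{path}: DICOM file has no pixel data")
    arr = ds.pixel_array
    if arr.ndim == 3:
        if not 0 <= frame_index < arr.shape[0]:
            raise FormatError(f"{path}: frame index {frame_index} out of range")
        arr = arr[frame_index]
    elif arr.ndim != 2:
        raise FormatError(f"{path}: unsupported pixel array shape {arr.shape}")
    pixels = arr.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
    intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
    pixels = pixels * slope + intercept
    bit_depth = int(getattr(ds, "BitsStored", 0) or 0)
    if bit_depth < 1:
        bit_depth = _depth_from_dtype(np.asarray(arr), path)
    geometry = _dicom_geometry(ds)
    spacing = geometry.detector_spacing_mm if geometry is not None else None
    if geometry is None:
        msg = f"{path.name}: DICOM geometry tags incomplete; frequencies will be in cycles/pixel"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=3)
    return ImageFrame(
        pixels,
        bit_depth,
        pixel_spacing_mm=spacing,
        frame_id=path.stem,
        geometry=geometry,
    )


def read_dicom_frames(path: str | Path):
    """Yield every frame of a (possibly multi-frame) DICOM file."""
    import pydicom

    path = Path(path)
    ds = pydicom.dcmread(path)
    if "PixelData" not in ds:
        raise FormatError(f"{path}: DICOM file has no pixel data")
    n = int(getattr(ds, "NumberOfFrames", 1) or 1)
    for i in range(n):
        yield read_frame(path, format="dicom", frame_index=i)


def write_frame(frame: ImageFrame, path: str | Path, format: str | None = None) -> None:
    """Write a frame to PNG or TIFF, losslessly for in-range integer data.

    Intensities are rounded to the nearest integer; rounded values outside
    ``[0, 2**n - 1]`` are a contract violation (clip first, e.g. with
    :meth:`ImageFrame.clipped`).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "dicom":
        raise FormatError("DICOM writing is not supported")
    quantised = np.rint(frame.pixels)
    if quantised.min() < 0 or quantised.max() > frame.max_value:
        raise ValueError(
            "intensities outside [0, 2**n - 1]; clip before writing "
            f"(range {quantised.min()}..{quantised.max()}, depth {frame.bit_depth})"
        )
    if frame.bit_depth <= 8:
        arr = quantised.astype(np.uint8)
    elif frame.bit_depth <= 16:
        arr = quantised.astype(np.uint16)
    else:
        raise ValueError("only bit depths up to 16 can be written")
    if fmt == "png":
        import imageio.v3 as iio

        iio.imwrite(path, arr)
    elif fmt == "tiff":
        import tifffile

        tifffile.imwrite(path, arr)
    else:  # pragma: no cover
        raise FormatError(f"unknown format {fmt!r}")
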