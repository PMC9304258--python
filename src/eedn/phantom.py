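"""Synthetic fluoroscopy-like phantoms.

A rendered phantom combines the three kinds of content that matter for
fluoroscopy denoising:

* a smooth, low-spatial-frequency anatomical background (broad Gaussian
  blobs on top of a base level plus a gentle linear gradient),
* dark curvilinear device tracks — catheter/guidewire-like structures
  rendered as smooth splines with a Gaussian cross profile, and
* sharp step edges (rib/heart-border-like transitions).

Rendering is a pure function of the spec, so identical specs give identical
frames; :func:`dataset_specs` derives randomised variants of a template
spec reproducibly from a seed.  No X-ray transport physics is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.interpolate import make_interp_spline

from .image_io import ImageFrame

__all__ = [
    "Blob",
    "Device",
    "StepEdge",
    "PhantomSpec",
    "generate_phantom",
    "dataset_specs",
    "generate_dataset",
]


@dataclass(frozen=True)
class Blob:
    """Smooth background blob: Gaussian bump of the given amplitude."""

    center: tuple[float, float]  # (row, col) in pixels
    radius: float  # Gaussian sigma in pixels
    amplitude: float


@dataclass(frozen=True)
class Device:
    """Curvilinear device track (catheter/wire-like intensity dip)."""

    control_points: tuple[tuple[float, float], ...]  # (row, col) points
    width_px: float = 2.0  # cross-sectional width; Gaussian sigma is width/2
    contrast: float = 40.0  # dip depth at the centerline


@dataclass(frozen=True)
class StepEdge:
    """Straight step edge through ``position`` with the given normal angle."""

    position: tuple[float, float]  # (row, col)
    orientation_deg: float  # direction of the step normal
    step_height: float


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom frame.

    Defaults follow typical fluoroscopy frames: 512x512, 8-bit, 0.5 mm
    detector spacing.  ``base_level`` defaults to 45% of the intensity
    range so that device dips and step edges stay in range.
    """

    size: tuple[int, int] = (512, 512)  # (rows, cols)
    bit_depth: int = 8
    pixel_spacing_mm: float = 0.5
    base_level: float | None = None
    gradient_amplitude: float | None = None
    background: tuple[Blob, ...] = ()
    devices: tuple[Device, ...] = ()
    edges: tuple[StepEdge, ...] = ()
    seed: int = 0

    @property
    def max_value(self) -> float:
        return float(2**self.bit_depth - 1)

    def resolved_base(self) -> float:
        return 0.45 * self.max_value if self.base_level is None else float(self.base_level)

    def resolved_gradient(self) -> float:
        return 0.05 * self.max_value if self.gradient_amplitude is None else float(self.gradient_amplitude)


def _device_dip(spec: PhantomSpec, device: Device) -> np.ndarray:
    pts = np.asarray(device.control_points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("a device needs at least 2 control points")
    if device.width_px < 1:
        raise ValueError("device width must be at least 1 pixel")
    # Interpolating spline through the control points, parameterised by
    # cumulative chord length and sampled densely enough that the rasterised
    # centerline is 8-connected.
    # collapse zero-length segments so the chord parameterisation is strict
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-9])
    pts = pts[keep]
    if pts.shape[0] < 2:
        raise ValueError("device control points are degenerate (zero length)")
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    k = min(3, pts.shape[0] - 1)
    spline = make_interp_spline(chord, pts, k=k)
    n_samples = max(int(4 * chord[-1]), 2)
    samples = spline(np.linspace(0.0, chord[-1], n_samples))
    rows, cols = spec.size
    mask = np.zeros(spec.size, dtype=bool)
    rr = np.clip(np.rint(samples[:, 0]).astype(int), 0, rows - 1)
    cc = np.clip(np.rint(samples[:, 1]).astype(int), 0, cols - 1)
    mask[rr, cc] = True
    dist = ndimage.distance_transform_edt(~mask)
    sigma = max(device.width_px, 1.0) / 2.0
    return device.contrast * np.exp(-(dist**2) / (2.0 * sigma**2))


def generate_phantom(spec: PhantomSpec) -> ImageFrame:
    """Render a phantom frame. Deterministic in the spec (no RNG at render)."""
    rows, cols = spec.size
    if rows < 1 or cols < 1:
        raise ValueError("phantom size must be positive")
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    img = np.full(spec.size, spec.resolved_base(), dtype=np.float64)
    denom = max(rows + cols - 2, 1)
    img += spec.resolved_gradient() * ((xx + yy) / denom - 0.5)
    for blob in spec.background:
        r0, c0 = blob.center
        d2 = (yy - r0) ** 2 + (xx - c0) ** 2
        img += blob.amplitude * np.exp(-d2 / (2.0 * blob.radius**2))
    for device in spec.devices:
        img -= _device_dip(spec, device)
    for edge in spec.edges:
        theta = np.deg2rad(edge.orientation_deg)
        nr, nc = np.sin(theta), np.cos(theta)
        side = (yy - edge.position[0]) * nr + (xx - edge.position[1]) * nc
        img += edge.step_height * (side > 0)
    np.clip(img, 0.0, spec.max_value, out=img)
    return ImageFrame(
        img,
        spec.bit_depth,
        pixel_spacing_mm=spec.pixel_spacing_mm,
        frame_id=f"phantom-{spec.seed}",
    )


def _random_point(rng: np.random.Generator, size: tuple[int, int], margin: float) -> tuple[float, float]:
    rows, cols = size
    return (
        float(rng.uniform(margin * rows, (1 - margin) * rows)),
        float(rng.uniform(margin * cols, (1 - margin) * cols)),
    )


def _randomize(template: PhantomSpec, rng: np.random.Generator, seed: int) -> PhantomSpec:
    rows, cols = template.size
    blobs = tuple(
        Blob(
            center=_random_point(rng, template.size, 0.1),
            radius=b.radius * float(rng.uniform(0.7, 1.3)),
            amplitude=b.amplitude * float(rng.uniform(0.8, 1.2)),
        )
        for b in template.background
    )
    devices = []
    for dev in template.devices:
        n_pts = len(dev.control_points)
        start = np.array(_random_point(rng, template.size, 0.15))
        heading = rng.uniform(0, 2 * np.pi)
        step = 0.6 * min(rows, cols) / max(n_pts - 1, 1)
        pts = [start]
        for _ in range(n_pts - 1):
            heading += rng.uniform(-0.5, 0.5)
            nxt = pts[-1] + step * np.array([np.sin(heading), np.cos(heading)])
            if not (2 <= nxt[0] <= rows - 3 and 2 <= nxt[1] <= cols - 3):
                # bounce back towards the interior instead of clipping, so
                # consecutive control points never collapse onto the border
                heading += np.pi
                nxt = pts[-1] + step * np.array([np.sin(heading), np.cos(heading)])
                nxt[0] = np.clip(nxt[0], 2, rows - 3)
                nxt[1] = np.clip(nxt[1], 2, cols - 3)
            pts.append(nxt)
        devices.append(
            Device(
                control_points=tuple((float(p[0]), float(p[1])) for p in pts),
                width_px=dev.width_px,
                contrast=dev.contrast * float(rng.uniform(0.85, 1.15)),
            )
        )
    edges = tuple(
        StepEdge(
            position=_random_point(rng, template.size, 0.2),
            orientation_deg=float(rng.uniform(0.0, 360.0)),
            step_height=e.step_height * float(rng.uniform(0.8, 1.2)),
        )
        for e in template.edges
    )
    return replace(template, background=blobs, devices=tuple(devices), edges=edges, seed=seed)


def dataset_specs(template: PhantomSpec, count: int, seed: int) -> list[PhantomSpec]:
    """Derive ``count`` randomised specs from a template, reproducibly."""
    if count < 1:
        raise ValueError("count must be >= 1")
    specs = []
    for i in range(count):
        rng = np.random.default_rng([seed, i])
        specs.append(_randomize(template, rng, seed=int(seed * 100_003 + i) % (2**31)))
    return specs


def generate_dataset(template: PhantomSpec, count: int, seed: int) -> list[ImageFrame]:
    """Render ``count`` randomised phantom frames derived from a template."""
    frames = [generate_phantom(s) for s in dataset_specs(template, count, seed)]
    for i, frame in enumerate(frames):
        frame.frame_id = f"phantom-{seed}-{i:04d}"
    return frames


def default_template(
    size: tuple[int, int] = (512, 512),
    bit_depth: int = 8,
    pixel_spacing_mm: float = 0.5,
) -> PhantomSpec:
    """Template with typical content: 3 background blobs, 2 devices, 2 edges."""
    rows, cols = size
    scale = min(rows, cols)
    maxv = float(2**bit_depth - 1)
    return PhantomSpec(
        size=size,
        bit_depth=bit_depth,
        pixel_spacing_mm=pixel_spacing_mm,
        background=tuple(
            Blob(center=(rows / 2, cols / 2), radius=0.22 * scale, amplitude=amp * maxv)
            for amp in (0.12, -0.08, 0.10)
        ),
        devices=(
            Device(control_points=((0.2 * rows, 0.2 * cols), (0.5 * rows, 0.45 * cols), (0.8 * rows, 0.5 * cols)), width_px=2.0, contrast=0.16 * maxv),
            Device(control_points=((0.7 * rows, 0.2 * cols), (0.55 * rows, 0.5 * cols), (0.75 * rows, 0.8 * cols)), width_px=3.0, contrast=0.12 * maxv),
        ),
        edges=(
            StepEdge(position=(0.35 * rows, 0.6 * cols), orientation_deg=25.0, step_height=0.08 * maxv),
            StepEdge(position=(0.65 * rows, 0.3 * cols), orientation_deg=115.0, step_height=-0.06 * maxv),
        ),
    )
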