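"""Quantum-noise degradation and training-corpus construction.

Low-dose fluoroscopy noise is quantum limited and Poisson distributed.  A
clean frame ``I'`` is degraded pixelwise as ``I_input = I' + Poisson(lam)``
with ``lam = mu * alpha / 100``, where ``mu`` is the percentage noise level
and ``alpha`` is the mean intensity of the whole clean frame.  Note that as
written this adds noise with positive mean ``lam`` (a brightness bias);
``mean_subtract=True`` subtracts ``lam`` afterwards for a zero-mean
variant, and the choice is logged.

Training corpora mix noise levels: the number of patches ``N_x`` degraded
at level ``x%`` follows a Gaussian over levels, centered by default on 60%
(the level matching the clinical fluoroscopy/acquisition dose gap) with a
20% standard deviation, integrated over level bins of width ``delta``.
Mass falling outside the simulated level range is renormalised into the
covered bins so the counts sum to the requested total.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .image_io import ImageFrame

logger = logging.getLogger(__name__)

__all__ = [
    "NoiseSpec",
    "PatchDataset",
    "add_poisson_noise",
    "noise_level_counts",
    "exact_level_counts",
    "build_training_set",
    "save_patch_dataset",
    "load_patch_dataset",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise level and level-distribution parameters (all in percent).

    ``mu_percent`` is the single-frame degradation level; the remaining
    fields describe the Gaussian distribution of levels used when building
    training corpora.  ``level_range`` gives the centers of the first and
    last level bins (inclusive), tiled in steps of ``delta_percent``.
    """

    mu_percent: float = 60.0
    mean_percent: float = 60.0
    sigma_percent: float = 20.0
    delta_percent: float = 10.0
    level_range: tuple[float, float] = (10.0, 100.0)
    seed: int = 0
    mean_subtract: bool = False

    def __post_init__(self) -> None:
        if self.mu_percent < 0:
            raise ValueError("mu_percent must be >= 0")
        if self.sigma_percent <= 0:
            raise ValueError("sigma_percent must be > 0")
        if self.delta_percent <= 0:
            raise ValueError("delta_percent must be > 0")
        if not self.level_range[0] < self.level_range[1]:
            raise ValueError("level_range must satisfy min < max")

    def bin_centers(self) -> np.ndarray:
        lo, hi = self.level_range
        n = int(round((hi - lo) / self.delta_percent))
        centers = lo + self.delta_percent * np.arange(n + 1)
        return centers[centers <= hi + 1e-9]


@dataclass
class PatchDataset:
    """Paired (noisy, clean) patches with their recorded noise levels."""

    noisy: np.ndarray  # (n, P, P) float32
    clean: np.ndarray  # (n, P, P) float32
    levels: np.ndarray  # (n,) percentage level used for each pair
    source_ids: list[str]
    seed: int
    bit_depth: int

    def __post_init__(self) -> None:
        if self.noisy.shape != self.clean.shape:
            raise ValueError("noisy and clean stacks must have identical shapes")
        if self.noisy.ndim != 3 or self.noisy.shape[1] != self.noisy.shape[2]:
            raise ValueError("patches must be square and stacked as (n, P, P)")
        if len(self.levels) != len(self.noisy) or len(self.source_ids) != len(self.noisy):
            raise ValueError("levels/source_ids must match the number of pairs")

    def __len__(self) -> int:
        return self.noisy.shape[0]

    @property
    def patch_size(self) -> int:
        return self.noisy.shape[1]


def add_poisson_noise(frame: ImageFrame, spec: NoiseSpec, rng: np.random.Generator | None = None) -> ImageFrame:
    """Degrade a clean frame with Poisson quantum noise at ``spec.mu_percent``.

    Each output pixel is the input pixel plus an independent draw from
    ``Poisson(lam)``, ``lam = mu * alpha / 100`` with ``alpha`` the mean
    intensity of the clean frame.  The result is kept in floating point and
    is *not* clipped; clipping happens at write time.
    """
    if np.any(frame.pixels < 0):
        raise ValueError("clean frame must be non-negative")
    alpha = float(frame.pixels.mean())
    lam = spec.mu_percent * alpha / 100.0
    if lam == 0.0:
        if spec.mu_percent > 0:
            msg = "all-zero frame: lam = 0, returning the input unchanged"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
        return frame.with_pixels(frame.pixels.copy())
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    noisy = frame.pixels + rng.poisson(lam, size=frame.pixels.shape)
    if spec.mean_subtract:
        logger.info("mean_subtract: removing the +lam brightness bias (lam=%.3f)", lam)
        noisy = noisy - lam
    return frame.with_pixels(noisy)


def _bin_masses(spec: NoiseSpec) -> tuple[np.ndarray, np.ndarray]:
    centers = spec.bin_centers()
    half = spec.delta_percent / 2.0
    masses = norm.cdf(centers + half, spec.mean_percent, spec.sigma_percent) - norm.cdf(
        centers - half, spec.mean_percent, spec.sigma_percent
    )
    total = masses.sum()
    if total <= 0:
        raise ValueError("level bins capture no probability mass")
    return centers, masses / total


def noise_level_counts(n_total: int, spec: NoiseSpec) -> list[tuple[float, int]]:
    """Per-level patch counts ``N_x`` from the Gaussian level distribution.

    ``N_x = round(n_total * mass_x)`` where ``mass_x`` is the normal
    probability mass of the bin ``[x - delta/2, x + delta/2]``, renormalised
    over the covered level range.  The rounded counts sum to ``n_total`` up
    to rounding (at most half a count per bin).
    """
    if n_total < 0:
        raise ValueError("n_total must be non-negative")
    centers, masses = _bin_masses(spec)
    if centers.size == 0:
        raise ValueError("empty level bin list")
    counts = np.rint(n_total * masses).astype(int)
    return [(float(c), int(k)) for c, k in zip(centers, counts)]


def exact_level_counts(n_total: int, spec: NoiseSpec) -> list[tuple[float, int]]:
    """Like :func:`noise_level_counts` but forced to sum exactly to ``n_total``.

    Uses the largest-remainder rule, so each count differs from the plain
    rounded value by at most one.
    """
    centers, masses = _bin_masses(spec)
    raw = n_total * masses
    counts = np.floor(raw).astype(int)
    short = n_total - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return [(float(c), int(k)) for c, k in zip(centers, counts)]


def build_training_set(
    clean_frames: list[ImageFrame],
    n_patches: int,
    patch_size: int,
    spec: NoiseSpec,
) -> PatchDataset:
    """Sample random patches and degrade them at Gaussian-distributed levels.

    Patch locations are drawn uniformly over the usable frames; each clean
    patch is paired with a Poisson-degraded copy whose level is assigned so
    that the empirical level histogram matches the analytic bin masses
    (largest-remainder rounding).  ``lam`` uses the *whole-frame* mean
    intensity, so patches inherit their source frame's photon scale.
    """
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    usable: list[ImageFrame] = []
    for f in clean_frames:
        if f.shape[0] < patch_size or f.shape[1] < patch_size:
            msg = f"frame {f.frame_id!r} smaller than patch size {patch_size}; skipped"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        usable.append(f)
    if not usable:
        raise ValueError("no usable frames: all smaller than the patch size")
    depths = {f.bit_depth for f in usable}
    if len(depths) != 1:
        raise ValueError("all frames must share one bit depth")
    rng = np.random.default_rng(spec.seed)
    levels = np.concatenate([np.full(k, c) for c, k in exact_level_counts(n_patches, spec)])
    rng.shuffle(levels)
    alphas = np.array([f.pixels.mean() for f in usable])
    frame_idx = rng.integers(0, len(usable), size=n_patches)
    clean = np.empty((n_patches, patch_size, patch_size), dtype=np.float32)
    noisy = np.empty_like(clean)
    source_ids = []
    for i in range(n_patches):
        f = usable[frame_idx[i]]
        top = int(rng.integers(0, f.shape[0] - patch_size + 1))
        left = int(rng.integers(0, f.shape[1] - patch_size + 1))
        patch = f.pixels[top : top + patch_size, left : left + patch_size]
        lam = levels[i] * alphas[frame_idx[i]] / 100.0
        noise = rng.poisson(lam, size=patch.shape) if lam > 0 else np.zeros_like(patch)
        out = patch + noise
        if spec.mean_subtract:
            out = out - lam
        clean[i] = patch
        noisy[i] = out
        source_ids.append(f.frame_id or f"frame-{frame_idx[i]}")
    return PatchDataset(
        noisy=noisy,
        clean=clean,
        levels=levels.astype(np.float64),
        source_ids=source_ids,
        seed=spec.seed,
        bit_depth=usable[0].bit_depth,
    )


def save_patch_dataset(dataset: PatchDataset, path: str | Path) -> None:
    """Write a patch dataset to HDF5 (datasets /clean, /noisy, /levels)."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("clean", data=dataset.clean, compression="gzip")
        h5.create_dataset("noisy", data=dataset.noisy, compression="gzip")
        h5.create_dataset("levels", data=dataset.levels)
        h5.create_dataset(
            "source_ids", data=np.array(dataset.source_ids, dtype=h5py.string_dtype())
        )
        h5.attrs["seed"] = dataset.seed
        h5.attrs["bit_depth"] = dataset.bit_depth


def load_patch_dataset(path: str | Path) -> PatchDataset:
    import h5py

    with h5py.File(path, "r") as h5:
        return PatchDataset(
            noisy=h5["noisy"][...],
            clean=h5["clean"][...],
            levels=h5["levels"][...],
            source_ids=[s.decode() if isinstance(s, bytes) else str(s) for s in h5["source_ids"][...]],
            seed=int(h5.attrs["seed"]),
            bit_depth=int(h5.attrs["bit_depth"]),
        )
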