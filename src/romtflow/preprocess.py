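"""Image-series preparation: % baseline conversion, intensity normalization,
smoothing, and analysis-window selection.

The transport solver interprets intensity as conserved mass, so every
operation here is mass-aware: only :func:`normalize_total_intensity` changes
frame sums, and it makes them equal — the precondition for solving
consecutive pairs under a mass-preserving constraint. Head-motion correction
is assumed done upstream by external tools; aligned input is a precondition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .grid import ImageGrid, ScalarField

__all__ = [
    "DensitySeries",
    "percent_baseline",
    "normalize_total_intensity",
    "gaussian_smooth",
    "crop_to_window",
]

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


@dataclass
class DensitySeries:
    """Ordered nonnegative intensity volumes with acquisition times.

    Parameters
    ----------
    frames : list of ScalarField
        The volumes, all on one grid.
    times : array of float
        Acquisition time per frame (minutes), strictly increasing.
    baseline_count : int
        Number of leading pre-contrast frames used as the baseline.
    units : {"raw", "percent_baseline", "normalized"}
    """

    frames: list[ScalarField]
    times: np.ndarray
    baseline_count: int = 1
    units: str = "raw"

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("series must contain at least one frame")
        grid = self.frames[0].grid
        if any(f.grid.dims != grid.dims for f in self.frames):
            raise ValueError("all frames must share one grid")
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (len(self.frames),):
            raise ValueError("times must have one entry per frame")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def grid(self) -> ImageGrid:
        return self.frames[0].grid

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def as_array(self) -> np.ndarray:
        """(T, m1, m2, m3) stack of the frames."""
        return np.stack([f.values for f in self.frames])

    def with_frames(self, arrays, **changes) -> "DensitySeries":
        frames = [ScalarField(self.grid, a) for a in arrays]
        return replace(self, frames=frames, **changes)


def percent_baseline(series: DensitySeries) -> DensitySeries:
    """Voxel-by-voxel conversion to percentage of the baseline signal.

    Each voxel is divided by its mean over the ``baseline_count`` leading
    frames and multiplied by 100; baseline frames are retained. Voxels with
    zero baseline are set to 0 (count logged).
    """
    if series.units != "raw":
        raise ValueError(f"percent_baseline expects raw units, got {series.units!r}")
    if series.baseline_count < 1:
        raise ValueError("baseline_count must be >= 1")
    stack = series.as_array()
    base = stack[: series.baseline_count].mean(axis=0)
    zero = base <= 0
    n_zero = int(zero.sum())
    if n_zero:
        logger.info("percent_baseline: %d zero-baseline voxels set to 0", n_zero)
    safe = np.where(zero, 1.0, base)
    out = np.where(zero, 0.0, 100.0 * stack / safe)
    return series.with_frames(out, units="percent_baseline")


def normalize_total_intensity(series: DensitySeries) -> DensitySeries:
    """Scale every frame so its voxel sum equals the first frame's sum.

    This enforces the mass-preservation premise of the transport model
    across the whole series. Scale factors are logged.
    """
    sums = np.array([float(f.values.sum()) for f in series.frames])
    if np.any(sums <= 0):
        bad = int(np.argmax(sums <= 0))
        raise ValueError(f"frame {bad} has non-positive total intensity; cannot normalize")
    if np.any([np.any(f.values < 0) for f in series.frames]):
        raise ValueError("normalize_total_intensity requires nonnegative frames")
    scales = sums[0] / sums
    logger.info("normalize_total_intensity: scale factors %s", np.round(scales, 6).tolist())
    out = [f.values * s for f, s in zip(series.frames, scales)]
    return series.with_frames(out, units="normalized")


def gaussian_smooth(series: DensitySeries, fwhm: float = 1.0) -> DensitySeries:
    """Per-frame isotropic Gaussian smoothing, mass-preserving.

    ``fwhm`` is in voxels. Half-sample-symmetric boundary reflection is the
    discrete zero-flux closure, so the frame sum is conserved exactly for
    the normalized symmetric kernel.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm == 0:
        return series.with_frames([f.values.copy() for f in series.frames])
    sigma = fwhm * FWHM_TO_SIGMA
    out = [
        ndimage.gaussian_filter(f.values, sigma=sigma, mode="reflect", truncate=6.0)
        for f in series.frames
    ]
    return series.with_frames(out)


def find_peak_frame(series: DensitySeries, mask: np.ndarray | None = None) -> int:
    """Index of the frame with maximal mean signal (over ``mask`` if given)."""
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        means = [float(f.values[mask].mean()) for f in series.frames]
    else:
        means = [float(f.values.mean()) for f in series.frames]
    return int(np.argmax(means))


def crop_to_window(
    series: DensitySeries,
    start_time: float | None = None,
    duration: float = 0.0,
    mask: np.ndarray | None = None,
) -> DensitySeries:
    """Frames covering ``[start, start + duration]`` minutes.

    If ``start_time`` is None the window starts at the peak-signal frame
    (whole-volume or mask mean), the interval that best represents tracer
    redistribution after arrival.
    """
    if start_time is None:
        start_time = float(series.times[find_peak_frame(series, mask)])
    end_time = start_time + duration
    eps = 1e-9
    if start_time < series.times[0] - eps or end_time > series.times[-1] + eps:
        raise ValueError(
            f"window [{start_time}, {end_time}] outside acquisition span "
            f"[{series.times[0]}, {series.times[-1]}]"
        )
    keep = (series.times >= start_time - eps) & (series.times <= end_time + eps)
    idx = np.nonzero(keep)[0]
    return replace(
        series,
        frames=[series.frames[i] for i in idx],
        times=series.times[idx],
        baseline_count=min(series.baseline_count, len(idx)),
    )


def clip_negative(series: DensitySeries) -> DensitySeries:
    """Clip negative voxels to 0 (required by the solver's density model)."""
    n_neg = int(sum((f.values < 0).sum() for f in series.frames))
    if n_neg:
        logger.info("clip_negative: %d negative voxels clipped to 0", n_neg)
    return series.with_frames([np.maximum(f.values, 0.0) for f in series.frames])
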