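"""Quantification of mask/intensity stacks from the activated-region assay.

Implements the standard processing applied to TIRF time-lapse data of an
optogenetically activated region: four-step biosensor normalization,
surface displacement (area of the cell inside the activated region), the
5-minute area-based phenotype call, and trajectory persistence.  Masks are
binary pixel grids with unit-square pixels, so area is a pixel count — the
convention of thresholded segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import GeometryError, NormalizationError, WindowError
from .stimulus import Trace

__all__ = [
    "RegionStack",
    "normalize_biosensor",
    "surface_displacement",
    "classify_from_area",
    "persistence",
    "read_stack_npz",
    "write_stack_npz",
    "read_stack_tiff",
    "synthetic_stack",
]


@dataclass
class RegionStack:
    """Per-frame cell masks and intensities plus the static activation region.

    cell_masks: (T, H, W) boolean; region_mask: (H, W) boolean (static);
    intensity: (T, H, W); frame_times in seconds; activation_start is the
    index of the first frame with light on (at least one frame precedes it).
    """

    cell_masks: np.ndarray
    region_mask: np.ndarray
    intensity: np.ndarray
    frame_times: np.ndarray
    activation_start: int

    def __post_init__(self):
        self.cell_masks = np.asarray(self.cell_masks, dtype=bool)
        self.region_mask = np.asarray(self.region_mask, dtype=bool)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.cell_masks.ndim != 3 or self.intensity.shape != self.cell_masks.shape:
            raise GeometryError("cell_masks and intensity must be (T, H, W) with equal shapes")
        if self.region_mask.shape != self.cell_masks.shape[1:]:
            raise GeometryError("region_mask must match the frame shape")
        if self.frame_times.size != self.cell_masks.shape[0]:
            raise GeometryError("frame_times length must match the frame count")
        if not self.region_mask.any():
            raise GeometryError("activation region is empty")
        if not 1 <= self.activation_start <= self.cell_masks.shape[0] - 1:
            raise GeometryError("need at least one pre-activation frame")

    @property
    def n_frames(self) -> int:
        return self.cell_masks.shape[0]


def normalize_biosensor(stack: RegionStack, background: float) -> Trace:
    """Four-step normalized biosensor intensity in the activated region.

    1. subtract background; 2. mean intensity over (cell mask intersected
    with activation region); 3. divide by the mean over the non-activated
    part of the cell; 4. divide by the pre-activation mean of that ratio.
    Pre-activation frames average to 1 by construction.
    """
    vals = np.empty(stack.n_frames)
    for i in range(stack.n_frames):
        img = stack.intensity[i] - background
        inside = stack.cell_masks[i] & stack.region_mask
        outside = stack.cell_masks[i] & ~stack.region_mask
        if not inside.any():
            raise GeometryError(f"empty cell/activation intersection at frame {i}")
        if not outside.any():
            raise GeometryError(f"empty non-activated cell region at frame {i}")
        mean_out = img[outside].mean()
        if mean_out <= 0:
            raise NormalizationError(
                f"non-positive reference intensity at frame {i}; background too high?"
            )
        vals[i] = img[inside].mean() / mean_out
    baseline = vals[: stack.activation_start].mean()
    if baseline <= 0:
        raise NormalizationError("non-positive pre-activation baseline")
    return Trace(stack.frame_times, vals / baseline, channel="b", meta={"normalized": True})


def surface_displacement(stack: RegionStack) -> Trace:
    """Cell area inside the activated region, normalized to its pre-activation mean."""
    areas = np.array(
        [(stack.cell_masks[i] & stack.region_mask).sum() for i in range(stack.n_frames)],
        dtype=float,
    )
    baseline = areas[: stack.activation_start].mean()
    if baseline <= 0:
        raise GeometryError("cell does not overlap the activation region before activation")
    return Trace(stack.frame_times, areas / baseline, channel="area", meta={"normalized": True})


def classify_from_area(area: Trace, t_eval: float = 300.0, delta: float = 0.05) -> str:
    """Phenotype call from the normalized area at ``t_eval`` (default 5 min)."""
    if area.times[-1] < t_eval - 1e-9 or area.times[0] > t_eval:
        raise WindowError(f"area trace does not cover t = {t_eval:g} s")
    a = float(area.value_at(t_eval))
    if a > 1.0 + delta:
        return "protrusion"
    if a < 1.0 - delta:
        return "retraction"
    return "mixed"


def persistence(path) -> float:
    """Net-over-total displacement ratio of a trajectory, in [0, 1].

    Returns nan (with no error) for a degenerate path with zero total
    displacement, where the ratio is undefined.
    """
    pts = np.asarray(path, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise GeometryError("need at least two positions")
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = steps.sum()
    if total == 0:
        return float("nan")
    return float(np.linalg.norm(pts[-1] - pts[0]) / total)


# ---------------------------------------------------------------------------
# stack I/O and the synthetic fixture generator


def write_stack_npz(stack: RegionStack, path) -> None:
    np.savez(
        path,
        cell_masks=stack.cell_masks,
        region_mask=stack.region_mask,
        intensity=stack.intensity,
        frame_times=stack.frame_times,
        activation_start=np.array(stack.activation_start),
    )


def read_stack_npz(path) -> RegionStack:
    with np.load(path) as data:
        return RegionStack(
            cell_masks=data["cell_masks"],
            region_mask=data["region_mask"],
            intensity=data["intensity"],
            frame_times=data["frame_times"],
            activation_start=int(data["activation_start"]),
        )


def read_stack_tiff(intensity_path, cellmask_path, region_path, activation_start: int, dt: float = 1.0) -> RegionStack:
    """Assemble a stack from multi-page TIFFs (intensity + masks)."""
    import tifffile

    intensity = tifffile.imread(intensity_path)
    cell = tifffile.imread(cellmask_path) > 0
    region = tifffile.imread(region_path) > 0
    if region.ndim == 3:
        region = region[0]
    times = np.arange(intensity.shape[0], dtype=float) * dt
    return RegionStack(cell, region, intensity, times, activation_start)


def write_stack_tiff(stack: RegionStack, intensity_path, cellmask_path, region_path) -> None:
    import tifffile

    tifffile.imwrite(intensity_path, stack.intensity.astype(np.float32))
    tifffile.imwrite(cellmask_path, stack.cell_masks.astype(np.uint8))
    tifffile.imwrite(region_path, stack.region_mask.astype(np.uint8))


def synthetic_stack(
    n_frames: int = 12,
    shape=(32, 32),
    activation_start: int = 3,
    dt: float = 30.0,
    intensity_fold: float = 2.0,
    shift_per_frame: int = 0,
    base_intensity: float = 100.0,
    background: float = 10.0,
) -> RegionStack:
    """Small synthetic mask/intensity stack (fixture generator).

    A rectangular cell occupies the left 3/4 of the frame and translates
    right-to-left by ``shift_per_frame`` pixels per post-activation frame;
    the activation region is the left third.  Intensity inside the region
    multiplies by ``intensity_fold`` after activation.
    """
    H, W = shape
    region = np.zeros(shape, dtype=bool)
    region[:, : W // 3] = True
    cells = np.zeros((n_frames, H, W), dtype=bool)
    intensity = np.full((n_frames, H, W), background, dtype=float)
    for i in range(n_frames):
        shift = shift_per_frame * max(0, i - activation_start + 1)
        left = min(shift, W - 1)
        cells[i, :, left : 3 * W // 4] = True
        intensity[i][cells[i]] = base_intensity
        if i >= activation_start:
            inside = cells[i] & region
            intensity[i][inside] = background + (base_intensity - background) * intensity_fold
    times = (np.arange(n_frames) - activation_start) * dt
    return RegionStack(cells, region, intensity, times, activation_start)
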