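"""Colocalization and axoneme intensity-profile quantification.

Two-channel confocal z-stacks of multiciliated-cell cytoplasm show
cytoplasmic foci (DynAPs).  Colocalization of two labelled proteins is
quantified as the sample Pearson correlation of pixel intensities inside a
focus ROI mask, computed per z-section and averaged per cell.  Separately,
axonemal signal is quantified as an intensity profile along the cilium,
rescaled to normalized length [0, 1] and ratioed against a co-expressed
membrane reference channel.

Coordinates are 0-based pixel centers throughout; profile sampling uses
bilinear interpolation at 1-pixel arc-length steps, averaged across a
perpendicular band (3 pixels by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "FociStackPair",
    "AxonemeProfile",
    "ThresholdError",
    "UndefinedCorrelationError",
    "roi_mask_from_reference",
    "pearson_in_mask",
    "cell_colocalization",
    "sample_profile",
    "normalize_profile",
]

logger = logging.getLogger(__name__)


class ThresholdError(ValueError):
    """Automatic thresholding is undefined (e.g. constant image)."""


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined (too few pixels or zero variance)."""


@dataclass
class FociStackPair:
    """Registered two-channel z-stack of cytoplasmic foci."""

    channel_a: np.ndarray  # (z, y, x)
    channel_b: np.ndarray  # (z, y, x)
    pixel_size: float = 1.0  # micrometers per pixel

    def __post_init__(self) -> None:
        self.channel_a = np.asarray(self.channel_a, dtype=np.float64)
        self.channel_b = np.asarray(self.channel_b, dtype=np.float64)
        if self.channel_a.shape != self.channel_b.shape:
            raise ValueError("channels must have identical shape")
        if self.channel_a.ndim != 3:
            raise ValueError("expected a (z, y, x) stack")


@dataclass
class AxonemeProfile:
    """Signal/reference intensity profile along normalized axoneme length."""

    normalized_position: np.ndarray  # strictly increasing, 0 to 1
    signal: np.ndarray
    reference: np.ndarray
    ratio: np.ndarray


def roi_mask_from_reference(
    section: np.ndarray, method: str = "otsu", threshold: float | None = None
) -> np.ndarray:
    """Boolean ROI mask of above-threshold pixels in a reference section.

    The reference is conventionally the red (mCherry) channel in which the
    foci are defined.  ``method`` is ``"otsu"`` or ``"fixed"`` (the latter
    requires ``threshold``).
    """
    section = np.asarray(section, dtype=np.float64)
    if method == "otsu":
        if np.ptp(section) == 0:
            raise ThresholdError("otsu threshold undefined on a constant image")
        thr = threshold_otsu(section)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed-threshold method requires a threshold")
        thr = threshold
    else:
        raise ValueError(f"unknown thresholding method {method!r}")
    return section > thr


def pearson_in_mask(
    ch_a: np.ndarray, ch_b: np.ndarray, mask: np.ndarray
) -> float:
    """Sample Pearson correlation of two channels over masked pixels."""
    a = np.asarray(ch_a, dtype=np.float64)[np.asarray(mask, dtype=bool)]
    b = np.asarray(ch_b, dtype=np.float64)[np.asarray(mask, dtype=bool)]
    if a.size < 2:
        raise UndefinedCorrelationError("need >=2 masked pixels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("zero variance within the mask")
    r = np.corrcoef(a, b)[0, 1]
    return float(np.clip(r, -1.0, 1.0))


def cell_colocalization(stack: FociStackPair, masks: np.ndarray) -> float:
    """Per-cell colocalization: unweighted mean of per-section Pearson R.

    Sections where the correlation is undefined (tiny or constant masks)
    are skipped; their count is logged.  Raises if no section is usable.
    """
    masks = np.asarray(masks, dtype=bool)
    if masks.shape != stack.channel_a.shape:
        raise ValueError("masks must match the stack shape (z, y, x)")
    values = []
    skipped = 0
    for z in range(stack.channel_a.shape[0]):
        try:
            values.append(
                pearson_in_mask(stack.channel_a[z], stack.channel_b[z], masks[z])
            )
        except UndefinedCorrelationError:
            skipped += 1
    if skipped:
        logger.info("cell_colocalization: skipped %d unusable section(s)", skipped)
    if not values:
        raise UndefinedCorrelationError("no usable sections in the stack")
    return float(np.mean(values))


def _profile_sample_points(
    polyline: np.ndarray, step: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Equal arc-length sample points along a polyline with unit normals."""
    pts = np.asarray(polyline, dtype=np.float64)  # columns x, y
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("polyline must be >=2 (x, y) points")
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    if (seg_len == 0).any():
        raise ValueError("polyline has zero-length segments")
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    arcs = np.append(np.arange(0.0, total, step), total)  # endpoint included
    x = np.interp(arcs, cum, pts[:, 0])
    y = np.interp(arcs, cum, pts[:, 1])
    # tangent of the segment each sample falls in, for the perpendicular band
    idx = np.clip(np.searchsorted(cum, arcs, side="right") - 1, 0, len(seg_len) - 1)
    tx = seg[idx, 0] / seg_len[idx]
    ty = seg[idx, 1] / seg_len[idx]
    normals = np.stack([-ty, tx], axis=1)
    return arcs / total, np.stack([x, y], axis=1), normals


def sample_profile(
    image: np.ndarray, polyline, width: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Intensity profile along a polyline at 1-pixel arc-length steps.

    Intensity at each step is the bilinear-interpolated mean across a
    perpendicular band of ``width`` pixels.  Returns (normalized_position,
    intensity); positions run from 0 to 1.  The whole sampled band must
    stay within the image bounds.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image section")
    if width < 1:
        raise ValueError("width must be >= 1")
    positions, centers, normals = _profile_sample_points(np.asarray(polyline))
    offsets = np.arange(width, dtype=np.float64) - (width - 1) / 2.0
    # (samples, width, 2) band coordinates
    band = centers[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    xs, ys = band[..., 0], band[..., 1]
    h, w = image.shape
    if (xs < 0).any() or (ys < 0).any() or (xs > w - 1).any() or (ys > h - 1).any():
        raise ValueError("sampled band falls outside the image bounds")
    vals = ndimage.map_coordinates(
        image, [ys.ravel(), xs.ravel()], order=1, mode="nearest"
    ).reshape(xs.shape)
    return positions, vals.mean(axis=1)


def normalize_profile(
    positions, signal, reference, reference_floor: float = 0.0
) -> AxonemeProfile:
    """Ratio a signal profile against a membrane-reference profile.

    ``reference_floor`` clips tiny reference values from below before the
    pointwise division; any reference value still <= 0 raises.
    """
    positions = np.asarray(positions, dtype=np.float64)
    signal = np.asarray(signal, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if not (positions.size == signal.size == reference.size):
        raise ValueError("positions, signal and reference must align")
    if not (np.diff(positions) > 0).all():
        raise ValueError("positions must be strictly increasing")
    ref = np.maximum(reference, reference_floor) if reference_floor > 0 else reference
    if (ref <= 0).any():
        raise ValueError("reference must be positive everywhere after flooring")
    return AxonemeProfile(
        normalized_position=positions,
        signal=signal,
        reference=ref,
        ratio=signal / ref,
    )
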