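"""Mask preparation: threshold resizing, small-mask filtering, slice stacking.

These steps mirror a common workflow for slice-wise tumor segmentation:
high-resolution 2-D masks (e.g. 512x512 transaxial slices) are downsampled
to the network's working resolution with a fractional-coverage threshold,
slices with too few positive pixels are excluded, and per-slice masks are
recombined into 3-D volumes for volumetric evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from .core_metrics import as_binary_mask

__all__ = ["SliceStackSpec", "resize_mask", "min_positive_filter", "stack_slices"]

DEFAULT_RESIZE_THRESHOLD = 0.25
DEFAULT_MIN_POSITIVE = 6


def resize_mask(
    mask: np.ndarray,
    target_shape: tuple[int, int],
    threshold: float = DEFAULT_RESIZE_THRESHOLD,
) -> np.ndarray:
    """Resize a 2-D binary mask and re-binarize at ``threshold``.

    The mask is interpolated to ``target_shape`` as a real-valued field and
    an output pixel is positive iff its interpolated value exceeds the
    threshold.  For integer downscale factors the interpolation is an exact
    block mean, so the threshold reads as a fractional-coverage rule: with
    the default 0.25, an output pixel is positive when more than a quarter
    of the source pixels it covers were positive.  Non-integer factors fall
    back to bilinear interpolation.
    """
    mask = as_binary_mask(mask, "mask")
    if mask.ndim != 2:
        raise ValueError("resize_mask operates on 2-D masks")
    th, tw = int(target_shape[0]), int(target_shape[1])
    if th <= 0 or tw <= 0:
        raise ValueError(f"target shape must be positive, got {(th, tw)}")
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    h, w = mask.shape
    if (th, tw) == (h, w):
        return mask.copy()
    if h % th == 0 and w % tw == 0:
        fh, fw = h // th, w // tw
        field = mask.reshape(th, fh, tw, fw).mean(axis=(1, 3))
    else:
        field = _sk_resize(
            mask.astype(np.float64), (th, tw), order=1, anti_aliasing=False
        )
    return field > threshold


def min_positive_filter(
    masks: list[np.ndarray], min_count: int = DEFAULT_MIN_POSITIVE
) -> tuple[list[np.ndarray], list[int]]:
    """Drop masks with fewer than ``min_count`` positive elements.

    Returns the retained masks (order preserved, contents untouched) and
    the indices of the excluded ones.
    """
    if min_count < 0:
        raise ValueError(f"min_count must be non-negative, got {min_count}")
    retained: list[np.ndarray] = []
    excluded: list[int] = []
    for i, m in enumerate(masks):
        m = as_binary_mask(m, f"masks[{i}]")
        if int(np.count_nonzero(m)) >= min_count:
            retained.append(m)
        else:
            excluded.append(i)
    return retained, excluded


@dataclass(frozen=True)
class SliceStackSpec:
    """An ordered set of 2-D slice masks belonging to one subject.

    Slice order is acquisition (transaxial) order; the stacked volume puts
    the slice index on axis 0.
    """

    slices: tuple[np.ndarray, ...]
    identifier: str = ""

    def __post_init__(self) -> None:
        if len(self.slices) == 0:
            raise ValueError("at least one slice required")
        shapes = {s.shape for s in self.slices}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent slice shapes: {sorted(shapes)}")


def stack_slices(spec: SliceStackSpec) -> np.ndarray:
    """Stack 2-D slices into a 3-D mask, slice index first."""
    slices = [as_binary_mask(s, "slice") for s in spec.slices]
    return np.stack(slices, axis=0)
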