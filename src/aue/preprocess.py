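"""ROI extraction from raw dual-panel ultrasound scans.

A raw strain-elastography screenshot holds a grayscale B-mode panel and
a color elastography panel with a clinician-drawn green ROI box.  The
paired training sample is recovered in two steps: a device-specific
fixed-location crop around the color panel, then color-gradient boundary
detection — count non-gray pixels per row, take the largest positive and
negative first differences as the upper/lower ROI boundaries, repeat on
columns of the vertically-cropped sub-image.

Conventions: 0-based coordinates, (left, top, right, bottom) half-open
crop rectangles, inclusive boundary pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import DeviceProfile, ImagePair, RawScan

__all__ = [
    "CountVector",
    "BoundaryPair",
    "fixed_location_crop",
    "count_nongray",
    "detect_color_boundaries",
    "extract_roi_pair",
]


@dataclass(frozen=True)
class CountVector:
    """Non-gray pixel counts along rows or columns of an RGB image."""

    counts: np.ndarray  # int, length = scanned dimension
    axis: str           # "rows" | "cols"
    gray_tol: int

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class BoundaryPair:
    """Inclusive (lo, hi) ROI boundary indices along one axis."""

    lo: int
    hi: int
    axis: str
    grad_lo: int  # first-difference value that selected lo
    grad_hi: int

    def __post_init__(self):
        if not 0 <= self.lo <= self.hi:
            raise ValueError(f"invalid boundary pair ({self.lo}, {self.hi})")


def fixed_location_crop(raw: RawScan | np.ndarray, profile: DeviceProfile) -> np.ndarray:
    """Device-specific crop of the raw canvas (no resampling)."""
    image = raw.image if isinstance(raw, RawScan) else np.asarray(raw)
    h, w = image.shape[:2]
    l, t, r, b = profile.crop_rect
    for name, bad in (
        ("left", l < 0),
        ("top", t < 0),
        ("right", r > w),
        ("bottom", b > h),
    ):
        if bad:
            raise ValueError(f"crop rectangle exceeds canvas at the {name} edge")
    return image[t:b, l:r]


def count_nongray(image: np.ndarray, axis: str = "rows", gray_tol: int = 16) -> CountVector:
    """Count, per row (or column), pixels whose channel spread exceeds ``gray_tol``.

    A pixel is gray iff max(R,G,B) - min(R,G,B) <= gray_tol, which is
    robust to overall brightness.
    """
    if not 0 <= gray_tol <= 255:
        raise ValueError("gray_tol must lie in [0, 255]")
    if axis not in ("rows", "cols"):
        raise ValueError("axis must be 'rows' or 'cols'")
    img = np.asarray(image, dtype=np.int16)
    spread = img.max(axis=2) - img.min(axis=2)
    nongray = spread > gray_tol
    counts = nongray.sum(axis=1 if axis == "rows" else 0)
    return CountVector(counts.astype(np.int64), axis, gray_tol)


def detect_color_boundaries(counts: CountVector) -> BoundaryPair:
    """Boundaries of the color block from the count profile's gradients.

    With forward differences d[i] = counts[i+1] - counts[i], the entering
    edge is the largest positive difference (boundary index argmax+1) and
    the leaving edge the largest negative one, searched at or after the
    entering edge so lo <= hi.  Ties break toward the widest ROI:
    earliest index for the entering edge, latest for the leaving edge.
    """
    c = np.asarray(counts.counts, dtype=np.int64)
    if len(c) < 2:
        raise ValueError("count vector must have length >= 2")
    if not c.any():
        raise ValueError("no color content")
    d = np.diff(c)
    if d.max() <= 0:
        raise ValueError("no rising color boundary found")
    i_max = int(d.argmax())  # earliest maximum
    lo = i_max + 1
    tail = d[lo:]
    if len(tail) == 0 or tail.min() >= 0:
        raise ValueError("no falling color boundary at or after the rising one")
    # latest index attaining the minimum
    i_min = lo + int(len(tail) - 1 - tail[::-1].argmin())
    hi = i_min
    return BoundaryPair(lo, hi, counts.axis, int(d[i_max]), int(d[i_min]))


def extract_roi_pair(
    raw: RawScan,
    profile: DeviceProfile | None = None,
    gray_tol: int | None = None,
    erode_px: int = 2,
) -> ImagePair:
    """Recover the aligned (B-mode, elastogram) ROI pair from a raw scan.

    Applies the fixed-location crop, detects the vertical color
    boundaries, then the horizontal ones on the vertically-cropped
    sub-image; erodes the detected rectangle by ``erode_px`` to discard
    the green ROI box (which itself counts as color); and crops the
    B-mode panel at the same rectangle translated by the profile's panel
    offset.
    """
    profile = profile or raw.layout
    tol = profile.gray_tol if gray_tol is None else gray_tol
    flc = fixed_location_crop(raw, profile)
    v = detect_color_boundaries(count_nongray(flc, "rows", tol))
    sub = flc[v.lo : v.hi + 1]
    hz = detect_color_boundaries(count_nongray(sub, "cols", tol))
    top, bottom = v.lo + erode_px, v.hi + 1 - erode_px
    left, right = hz.lo + erode_px, hz.hi + 1 - erode_px
    if bottom - top < 1 or right - left < 1:
        raise ValueError("detected ROI vanished after green-box erosion")
    l0, t0 = profile.crop_rect[0], profile.crop_rect[1]
    ex0, ey0 = l0 + left, t0 + top
    elasto = raw.image[ey0 : t0 + bottom, ex0 : l0 + right]
    dx, dy = profile.panel_offset
    bx0, by0 = ex0 + dx, ey0 + dy
    bh, bw = elasto.shape[:2]
    ih, iw = raw.image.shape[:2]
    if bx0 < 0 or by0 < 0 or bx0 + bw > iw or by0 + bh > ih:
        raise ValueError("mapped B-mode rectangle falls outside the canvas")
    bmode = raw.image[by0 : by0 + bh, bx0 : bx0 + bw, 0]
    return ImagePair(bmode.copy(), elasto.copy())
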