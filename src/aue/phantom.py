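"""Synthetic strain-phantom generator.

Strain elastography overlays a stiffness color map on B-mode ultrasound:
soft tissue renders red/yellow, intermediate green, hard tissue blue.
Clinical datasets of paired (B-mode, elastogram) scans are rarely
shareable, so this module builds fully synthetic pairs with known
per-pixel stiffness ground truth: an elliptical nodule of configurable
stiffness embedded in softer background, a speckled grayscale B-mode
rendering, a stiffness-to-hue elastogram, and optionally the raw
dual-panel scan layout (gray panel + color panel + clinician green ROI
box) that the preprocessing stage consumes.

Coordinates are 0-based; rectangles are (left, top, right, bottom) and
half-open; sizes are (width, height).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "StiffnessMap",
    "ImagePair",
    "RawScan",
    "DeviceProfile",
    "PhantomConfig",
    "Inclusion",
    "make_stiffness_map",
    "render_bmode",
    "render_elastogram",
    "stiffness_to_color",
    "color_to_stiffness",
    "compose_raw_scan",
    "default_profile",
    "generate_dataset",
]

GREEN = np.array([0, 255, 0], dtype=np.uint8)  # ROI box color in synthetic scans

# Stiffness -> RGB anchor table (linear interpolation in RGB between rows).
# 0 = softest = red, 1 = hardest = blue, following the strain-elastography
# convention that hard (suspicious) tissue renders blue.
COLORMAP_ANCHORS: dict[str, tuple[tuple[float, tuple[int, int, int]], ...]] = {
    "strain": (
        (0.00, (255, 0, 0)),     # red
        (0.25, (255, 255, 0)),   # yellow
        (0.50, (0, 255, 0)),     # green
        (0.75, (0, 255, 255)),   # cyan
        (1.00, (0, 0, 255)),     # blue
    ),
}


@dataclass(frozen=True)
class Inclusion:
    """Elliptical stiff (or soft) lesion: center/axes in pixels, angle in degrees."""

    center: tuple[float, float]  # (x, y)
    axes: tuple[float, float]    # semi-axes (a, b), pixels
    angle: float = 0.0
    stiffness: float = 0.9

    def to_json(self) -> dict:
        return {
            "center": list(self.center),
            "axes": list(self.axes),
            "angle": self.angle,
            "stiffness": self.stiffness,
        }


@dataclass
class StiffnessMap:
    """Per-pixel relative stiffness in [0, 1] (1 = hardest)."""

    values: np.ndarray  # float32, (height, width)
    inclusions: list[Inclusion] = field(default_factory=list)
    background: float = 0.3

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValueError("stiffness map must be 2-D")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("stiffness values must lie in [0, 1]")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass
class ImagePair:
    """Aligned (B-mode, elastogram) ROI pair — the training unit."""

    bmode: np.ndarray   # uint8, (H, W)
    elasto: np.ndarray  # uint8, (H, W, 3)
    mask: np.ndarray | None = None  # bool, (H, W): nodule support

    def __post_init__(self):
        self.bmode = np.asarray(self.bmode, dtype=np.uint8)
        self.elasto = np.asarray(self.elasto, dtype=np.uint8)
        if self.bmode.ndim != 2 or self.elasto.ndim != 3 or self.elasto.shape[2] != 3:
            raise ValueError("bmode must be (H,W) and elasto (H,W,3)")
        if self.bmode.shape != self.elasto.shape[:2]:
            raise ValueError(
                f"pair dimensions differ: bmode {self.bmode.shape}, "
                f"elasto {self.elasto.shape[:2]}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.bmode.shape


@dataclass(frozen=True)
class DeviceProfile:
    """Where a device draws its panels, and how they align.

    ``crop_rect`` is the fixed-location crop around the color
    (elastography) panel, (left, top, right, bottom), 0-based half-open.
    ``panel_offset`` (dx, dy) translates color-panel canvas coordinates
    onto the corresponding grayscale-panel coordinates.  ``gray_tol`` is
    the channel-spread threshold below which a pixel counts as gray.
    """

    crop_rect: tuple[int, int, int, int]
    panel_offset: tuple[int, int]
    gray_tol: int = 16
    canvas_size: tuple[int, int] = (800, 555)  # (width, height)

    def __post_init__(self):
        l, t, r, b = self.crop_rect
        if not (l < r and t < b):
            raise ValueError(f"empty crop rectangle {self.crop_rect}")
        w, h = self.canvas_size
        dx, dy = self.panel_offset
        if not (0 <= l + dx and r + dx <= w and 0 <= t + dy and b + dy <= h):
            raise ValueError("panel_offset maps crop rectangle outside canvas")


@dataclass
class RawScan:
    """Full dual-panel scan canvas plus the layout it was drawn with."""

    image: np.ndarray  # uint8, (H, W, 3)
    layout: DeviceProfile
    roi_rect: tuple[int, int, int, int] | None = None  # planted ROI (synthetic truth)


def default_profile(canvas_size: tuple[int, int] = (800, 555)) -> DeviceProfile:
    """Two side-by-side panels: B-mode left, elastography right."""
    w, h = canvas_size
    margin_x, margin_y = round(w * 0.02), round(h * 0.08)
    panel_w = (w - 3 * margin_x) // 2
    left_color = 2 * margin_x + panel_w
    crop = (left_color, margin_y, left_color + panel_w, h - margin_y)
    return DeviceProfile(
        crop_rect=crop,
        panel_offset=(margin_x - left_color, 0),
        canvas_size=canvas_size,
    )


# ---------------------------------------------------------------------------
# stiffness maps


def make_stiffness_map(
    width: int,
    height: int,
    inclusions: list[Inclusion],
    background_stiffness: float = 0.3,
    seed: int = 0,
    ramp_px: float = 2.0,
) -> StiffnessMap:
    """Background stiffness plus elliptical inclusions with a smooth edge.

    Each inclusion contributes a blending weight that is 1 in its
    interior, 0 outside, and ramps linearly over ~``ramp_px`` pixels at
    the boundary; inclusions are composited in order.  Deterministic for
    fixed arguments (``seed`` is accepted for interface symmetry with the
    stochastic renderers).
    """
    if width < 32 or height < 32:
        raise ValueError("canvas must be at least 32x32")
    if not 0.0 <= background_stiffness <= 1.0:
        raise ValueError("background stiffness must lie in [0, 1]")
    yy, xx = np.mgrid[0:height, 0:width].astype(np.float32)
    values = np.full((height, width), background_stiffness, dtype=np.float32)
    for k, inc in enumerate(inclusions):
        cx, cy = inc.center
        a, b = inc.axes
        th = np.deg2rad(inc.angle)
        hx = np.hypot(a * np.cos(th), b * np.sin(th))
        hy = np.hypot(a * np.sin(th), b * np.cos(th))
        if cx - hx < 0 or cx + hx > width - 1 or cy - hy < 0 or cy + hy > height - 1:
            raise ValueError(f"inclusion {k} does not fit inside the canvas")
        if not 0.0 <= inc.stiffness <= 1.0:
            raise ValueError(f"inclusion {k} stiffness outside [0, 1]")
        xr = (xx - cx) * np.cos(th) + (yy - cy) * np.sin(th)
        yr = -(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
        r = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)
        alpha = np.clip((1.0 - r) * min(a, b) / max(ramp_px, 1e-6), 0.0, 1.0)
        values = values * (1.0 - alpha) + inc.stiffness * alpha
    return StiffnessMap(values, list(inclusions), background_stiffness)


def inclusion_mask(smap: StiffnessMap) -> np.ndarray:
    """Boolean support of the inclusions (blend weight > 1/2)."""
    yy, xx = np.mgrid[0 : smap.height, 0 : smap.width].astype(np.float32)
    mask = np.zeros(smap.values.shape, dtype=bool)
    for inc in smap.inclusions:
        cx, cy = inc.center
        a, b = inc.axes
        th = np.deg2rad(inc.angle)
        xr = (xx - cx) * np.cos(th) + (yy - cy) * np.sin(th)
        yr = -(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
        mask |= (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    return mask


# ---------------------------------------------------------------------------
# rendering


def render_bmode(
    smap: StiffnessMap,
    speckle_sigma: float = 0.25,
    mean_level: float = 110.0,
    seed: int = 0,
    contrast: float = 80.0,
) -> np.ndarray:
    """Grayscale B-mode rendering: affine shading times log-normal speckle.

    Base intensity is ``mean_level + contrast * (0.5 - stiffness)``, so
    with the default positive contrast harder tissue is darker (set
    ``contrast=0`` for stiffness-blind texture).  Speckle is multiplicative
    unit-median log-normal noise, the standard coarse surrogate for
    ultrasound speckle statistics.
    """
    if speckle_sigma < 0:
        raise ValueError("speckle_sigma must be >= 0")
    base = mean_level + contrast * (0.5 - smap.values)
    if speckle_sigma > 0:
        rng = np.random.default_rng(seed)
        speckle = rng.lognormal(mean=0.0, sigma=speckle_sigma, size=smap.values.shape)
    else:
        speckle = 1.0
    return np.clip(base * speckle, 0, 255).astype(np.uint8)


def stiffness_to_color(values: np.ndarray, colormap: str = "strain") -> np.ndarray:
    """Map stiffness in [0,1] to uint8 RGB through the anchor table."""
    if colormap not in COLORMAP_ANCHORS:
        raise ValueError(f"unknown colormap {colormap!r}")
    anchors = COLORMAP_ANCHORS[colormap]
    pos = np.array([a[0] for a in anchors])
    cols = np.array([a[1] for a in anchors], dtype=np.float64)
    v = np.asarray(values, dtype=np.float64)
    out = np.stack(
        [np.interp(v, pos, cols[:, ch]) for ch in range(3)], axis=-1
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _colormap_lut(colormap: str, n: int = 1001) -> tuple[np.ndarray, np.ndarray]:
    s = np.linspace(0.0, 1.0, n)
    return s, stiffness_to_color(s, colormap).astype(np.int32)


def color_to_stiffness(rgb: np.ndarray, colormap: str = "strain") -> np.ndarray:
    """Invert the colormap by nearest-neighbor lookup on a dense ramp."""
    s, lut = _colormap_lut(colormap)
    flat = np.asarray(rgb, dtype=np.int32).reshape(-1, 3)
    d2 = ((flat[:, None, :] - lut[None, :, :]) ** 2).sum(axis=2)
    return s[d2.argmin(axis=1)].reshape(np.asarray(rgb).shape[:-1])


def render_elastogram(smap: StiffnessMap, colormap: str = "strain") -> np.ndarray:
    """Color elastogram of the stiffness map (uint8 RGB)."""
    return stiffness_to_color(smap.values, colormap)


# ---------------------------------------------------------------------------
# raw-scan composition


def compose_raw_scan(
    pair: ImagePair,
    profile: DeviceProfile | None = None,
    background_gray: int = 40,
    box_px: int = 2,
) -> RawScan:
    """Lay an image pair out as a dual-panel device screenshot.

    The elastogram is centered in the profile's fixed-crop rectangle, the
    B-mode at the same position shifted by ``panel_offset``; a ``box_px``
    pure-green ROI rectangle is drawn around both; the rest of the canvas
    is uniform gray.
    """
    profile = profile or default_profile()
    w, h = profile.canvas_size
    canvas = np.full((h, w, 3), background_gray, dtype=np.uint8)
    l, t, r, b = profile.crop_rect
    if not (0 <= l and r <= w and 0 <= t and b <= h):
        raise ValueError("crop rectangle outside canvas")
    ph, pw = pair.shape
    pad = box_px + 1  # green box plus one gray guard row inside the crop
    if pw + 2 * pad > r - l or ph + 2 * pad > b - t:
        raise ValueError(
            f"pair {pw}x{ph} too large for panel {(r - l)}x{(b - t)} "
            f"(needs {2 * pad} px margin)"
        )
    x0 = l + (r - l - pw) // 2
    y0 = t + (b - t - ph) // 2

    def paste(img3: np.ndarray, x: int, y: int) -> None:
        canvas[y : y + ph, x : x + pw] = img3
        canvas[y - box_px : y, x - box_px : x + pw + box_px] = GREEN
        canvas[y + ph : y + ph + box_px, x - box_px : x + pw + box_px] = GREEN
        canvas[y - box_px : y + ph + box_px, x - box_px : x] = GREEN
        canvas[y - box_px : y + ph + box_px, x + pw : x + pw + box_px] = GREEN

    paste(pair.elasto, x0, y0)
    dx, dy = profile.panel_offset
    paste(np.repeat(pair.bmode[:, :, None], 3, axis=2), x0 + dx, y0 + dy)
    return RawScan(canvas, profile, roi_rect=(x0, y0, x0 + pw, y0 + ph))


# ---------------------------------------------------------------------------
# dataset generation


@dataclass
class PhantomConfig:
    """Study conditions for a synthetic dataset.

    Defaults emulate a thyroid strain-elastography acquisition at desk
    scale: one nodule per image with semi-axes 10–30% of the frame
    (clinical nodules span roughly 5–30 mm inside an ROI of a few cm),
    background softer than any nodule, and nodule stiffness drawn wide
    enough to cover soft (red/green) through hard (blue) color grades.
    """

    width: int = 256
    height: int = 256
    background_range: tuple[float, float] = (0.2, 0.4)
    nodule_stiffness_range: tuple[float, float] = (0.45, 1.0)
    nodule_axes_frac: tuple[float, float] = (0.10, 0.30)
    speckle_sigma: float = 0.25
    mean_level: float = 110.0
    contrast: float = 80.0
    colormap: str = "strain"
    compose_raw: bool = False
    canvas_size: tuple[int, int] = (800, 555)

    def to_json(self) -> dict:
        return asdict(self)


def sample_pair(config: PhantomConfig, seed: int) -> tuple[ImagePair, StiffnessMap]:
    """One phantom pair drawn from the study conditions under ``seed``."""
    rng = np.random.default_rng(seed)
    w, h = config.width, config.height
    bg = rng.uniform(*config.background_range)
    a = rng.uniform(*config.nodule_axes_frac) * w
    b = rng.uniform(*config.nodule_axes_frac) * h
    angle = rng.uniform(0.0, 180.0)
    hx = max(np.hypot(a * np.cos(np.deg2rad(angle)), b * np.sin(np.deg2rad(angle))), a, b)
    cx = rng.uniform(hx + 1, w - hx - 2)
    cy = rng.uniform(hx + 1, h - hx - 2)
    stiff = rng.uniform(*config.nodule_stiffness_range)
    inc = Inclusion((cx, cy), (a, b), angle, stiff)
    smap = make_stiffness_map(w, h, [inc], background_stiffness=bg, seed=seed)
    bmode = render_bmode(
        smap, config.speckle_sigma, config.mean_level,
        seed=seed, contrast=config.contrast,
    )
    elasto = render_elastogram(smap, config.colormap)
    return ImagePair(bmode, elasto, inclusion_mask(smap)), smap


def generate_dataset(
    n: int,
    out_dir: str | Path,
    config: PhantomConfig | None = None,
    seed: int = 0,
) -> dict:
    """Write ``n`` phantom pairs plus a reproducibility manifest.

    Per-sample seeds are spawned from ``numpy.random.SeedSequence(seed)``,
    so (config, seed) fully determines every byte of the manifest.
    Returns the manifest dict; files are 8-bit PNGs (stiffness as 16-bit
    PNG scaled by 65535).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or PhantomConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   np.random.SeedSequence(seed).spawn(n)]
    samples = []
    profile = default_profile(config.canvas_size) if config.compose_raw else None
    for i, s in enumerate(child_seeds):
        pair, smap = sample_pair(config, s)
        stem = f"phantom_{i:04d}"
        files = {
            "bmode": f"{stem}_bmode.png",
            "elasto": f"{stem}_elasto.png",
            "mask": f"{stem}_mask.png",
            "stiffness": f"{stem}_stiffness.png",
        }
        iio.imwrite(out_dir / files["bmode"], pair.bmode)
        iio.imwrite(out_dir / files["elasto"], pair.elasto)
        iio.imwrite(out_dir / files["mask"], (pair.mask * 255).astype(np.uint8))
        iio.imwrite(
            out_dir / files["stiffness"],
            np.rint(smap.values * 65535).astype(np.uint16),
        )
        if profile is not None:
            scan = compose_raw_scan(pair, profile)
            files["raw"] = f"{stem}_raw.png"
            iio.imwrite(out_dir / files["raw"], scan.image)
        samples.append(
            {
                "index": i,
                "seed": s,
                "background": float(smap.background),
                "inclusions": [inc.to_json() for inc in smap.inclusions],
                "files": files,
            }
        )
    manifest = {
        "n": n,
        "seed": seed,
        "config": config.to_json(),
        "samples": samples,
    }
    with open(out_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return manifest


def load_dataset(manifest_path: str | Path) -> tuple[list[ImagePair], dict]:
    """Read pairs back from a manifest written by :func:`generate_dataset`."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as f:
        manifest = json.load(f)
    root = manifest_path.parent
    pairs = []
    for s in manifest["samples"]:
        bmode = iio.imread(root / s["files"]["bmode"])
        elasto = iio.imread(root / s["files"]["elasto"])
        mask = iio.imread(root / s["files"]["mask"]) > 127
        pairs.append(ImagePair(bmode, elasto, mask))
    return pairs, manifest
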