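"""Synthetic H&E-like histology generator.

Produces labeled pseudo-whole-slide images and individual tiles with a
controllable class signal and controllable contamination, standing in for
clinical slides that cannot be redistributed.  The class signal is nuclear
density: positive ("BL-like") slides carry a markedly higher area fraction
of hematoxylin-hued (purple) nucleus blobs on an eosin-hued (pink) stromal
field than negative ("control-like") slides.  Contamination mimics the
artifacts a tile-QC stage must remove: blank (glass) regions, pathologist
pen markings in green/blue/gray, and tiles with scant tissue.

Everything is deterministic in the supplied seeds; repeated calls are
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.color import hsv2rgb

ARTIFACT_CATEGORIES = ("clean", "blank", "pen_green", "pen_blue", "pen_gray", "low_tissue")

#: truth-mask category codes
MASK_BACKGROUND = 0
MASK_TISSUE = 1
MASK_PEN = 2
MASK_BLANK = 3

# Hue centers (degrees) straddle the QC purple band [250, 310) and pink band
# [310, 360); jitter is clipped so clean tissue never leaks into a pen band.
PURPLE_HUE_DEG = 270.0
PINK_HUE_DEG = 330.0

# Nuclear area fractions: the separable class signal.  Positive is chosen
# well above negative so the purple:pink ratio differs by > 1.5x, while the
# negative default still clears the QC purple-to-pink floor.
POSITIVE_NUCLEAR_DENSITY = 0.55
NEGATIVE_NUCLEAR_DENSITY = 0.25

_PEN_HSV = {
    # (hue deg, saturation, value) stroke centers, inside the QC pen masks
    "pen_green": (120.0, 0.75, 0.65),
    "pen_blue": (230.0, 0.75, 0.65),
    "pen_gray": (0.0, 0.04, 0.50),
}


@dataclasses.dataclass(frozen=True)
class SyntheticSlideSpec:
    """Recipe for one pseudo-WSI; fully determines the rendered raster."""

    slide_id: str
    label: int  # 1 = positive (BL-like), 0 = negative (control-like)
    width_px: int = 320
    height_px: int = 320
    nuclear_density: float | None = None  # default depends on label
    nucleus_radius_px: float = 4.0
    purple_hue_deg: float = PURPLE_HUE_DEG
    pink_hue_deg: float = PINK_HUE_DEG
    pen_mark_fraction: float = 0.03
    blank_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("slide dimensions must be positive")
        for name in ("pen_mark_fraction", "blank_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nuclear_density is not None and not 0.0 <= self.nuclear_density <= 1.0:
            raise ValueError("nuclear_density must be in [0, 1]")
        if self.nucleus_radius_px <= 0:
            raise ValueError("nucleus_radius_px must be positive")

    @property
    def effective_density(self) -> float:
        if self.nuclear_density is not None:
            return self.nuclear_density
        return POSITIVE_NUCLEAR_DENSITY if self.label else NEGATIVE_NUCLEAR_DENSITY


@dataclasses.dataclass
class SyntheticSlide:
    spec: SyntheticSlideSpec
    raster: np.ndarray  # H x W x 3 uint8
    truth_mask: np.ndarray  # H x W uint8, MASK_* codes


def _rng_for(seed: int, *context: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, context)]))


def _hsv_field(
    rng: np.random.Generator,
    shape: tuple[int, int],
    hue_deg: float,
    sat: float,
    val: float,
    hue_jitter: float = 4.0,
    sv_jitter: float = 0.04,
) -> np.ndarray:
    """Per-pixel jittered HSV field; jitter clipped to ±1.5 sigma so hues
    stay inside their nominal band."""
    h, w = shape
    dh = np.clip(rng.normal(0.0, hue_jitter, (h, w)), -1.5 * hue_jitter, 1.5 * hue_jitter)
    ds = np.clip(rng.normal(0.0, sv_jitter, (h, w)), -1.5 * sv_jitter, 1.5 * sv_jitter)
    dv = np.clip(rng.normal(0.0, sv_jitter, (h, w)), -1.5 * sv_jitter, 1.5 * sv_jitter)
    hsv = np.empty((h, w, 3), dtype=np.float64)
    hsv[..., 0] = ((hue_deg + dh) % 360.0) / 360.0
    hsv[..., 1] = np.clip(sat + ds, 0.0, 1.0)
    hsv[..., 2] = np.clip(val + dv, 0.0, 1.0)
    return hsv


def _hsv_to_uint8(hsv: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(hsv2rgb(hsv) * 255.0), 0, 255).astype(np.uint8)


def _ellipse_patch(
    shape: tuple[int, int],
    cy: float,
    cx: float,
    ry: float,
    rx: float,
    theta: float,
) -> tuple[tuple[slice, slice], np.ndarray]:
    """Rotated filled ellipse rasterized on the pixel grid, returned as a
    (bounding-box slices, boolean patch) pair to keep stamping cheap."""
    h, w = shape
    r = max(ry, rx)
    y0 = max(0, int(np.floor(cy - r - 1)))
    y1 = min(h, int(np.ceil(cy + r + 2)))
    x0 = max(0, int(np.floor(cx - r - 1)))
    x1 = min(w, int(np.ceil(cx + r + 2)))
    sl = (slice(y0, y1), slice(x0, x1))
    if y0 >= y1 or x0 >= x1:
        return sl, np.zeros((max(0, y1 - y0), max(0, x1 - x0)), dtype=bool)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy = yy - cy
    dx = xx - cx
    c, s = np.cos(theta), np.sin(theta)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    return sl, (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _ellipse_mask(
    shape: tuple[int, int],
    cy: float,
    cx: float,
    ry: float,
    rx: float,
    theta: float,
) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    sl, patch = _ellipse_patch(shape, cy, cx, ry, rx, theta)
    mask[sl] = patch
    return mask


def _scatter_nuclei(
    rng: np.random.Generator,
    shape: tuple[int, int],
    density: float,
    radius: float,
    region: np.ndarray | None = None,
) -> np.ndarray:
    """Drop jittered ellipses until the covered area fraction (within
    ``region`` if given) reaches ``density``."""
    h, w = shape
    covered = np.zeros(shape, dtype=bool)
    if density <= 0.0:
        return covered
    region_area = int(region.sum()) if region is not None else h * w
    if region_area == 0:
        return covered
    target = density * region_area
    max_draws = int(20 * target / max(radius * radius * np.pi, 1.0)) + 200
    if region is not None:
        ys, xs = np.nonzero(region)
    count = 0
    for _ in range(max_draws):
        if count >= target:
            break
        if region is not None:
            idx = rng.integers(0, region_area)
            cy, cx = float(ys[idx]), float(xs[idx])
        else:
            cy = rng.uniform(0, h)
            cx = rng.uniform(0, w)
        r = radius * rng.uniform(0.7, 1.3)
        ecc = rng.uniform(0.6, 1.0)
        theta = rng.uniform(0, np.pi)
        sl, patch = _ellipse_patch(shape, cy, cx, r, r * ecc, theta)
        if region is not None:
            patch = patch & region[sl]
        new = patch & ~covered[sl]
        count += int(new.sum())
        covered[sl] |= patch
    return covered


def _tissue_field(
    rng: np.random.Generator,
    shape: tuple[int, int],
    density: float,
    radius: float,
    purple_hue: float = PURPLE_HUE_DEG,
    pink_hue: float = PINK_HUE_DEG,
) -> np.ndarray:
    """Pink stromal field with purple nucleus blobs at the given density."""
    hsv = _hsv_field(rng, shape, pink_hue, sat=0.32, val=0.90)
    nuclei = _scatter_nuclei(rng, shape, density, radius)
    if nuclei.any():
        nuc_hsv = _hsv_field(rng, shape, purple_hue, sat=0.55, val=0.55)
        hsv[nuclei] = nuc_hsv[nuclei]
    return _hsv_to_uint8(hsv)


def _blank_field(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Near-constant glass/background: per-channel std well under 3."""
    base = np.full((*shape, 3), 245.0)
    noise = rng.normal(0.0, 0.6, (*shape, 3))
    return np.clip(np.rint(base + noise), 0, 255).astype(np.uint8)


def _pen_strokes(
    rng: np.random.Generator,
    shape: tuple[int, int],
    target_fraction: float,
    thickness: float | None = None,
) -> np.ndarray:
    """Boolean mask of thick meandering polyline strokes covering roughly
    ``target_fraction`` of the raster."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    if target_fraction <= 0:
        return mask
    thick = thickness if thickness is not None else max(2.0, 0.03 * min(h, w))
    target = target_fraction * h * w
    count = 0
    for _ in range(400):
        if count >= target:
            break
        # one stroke: a random walk of disc stamps
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        ang = rng.uniform(0, 2 * np.pi)
        n_steps = rng.integers(10, 40)
        for _ in range(n_steps):
            sl, patch = _ellipse_patch(shape, cy, cx, thick, thick, 0.0)
            count += int((patch & ~mask[sl]).sum())
            mask[sl] |= patch
            ang += rng.normal(0.0, 0.35)
            cy = float(np.clip(cy + 1.5 * thick * np.sin(ang), 0, h - 1))
            cx = float(np.clip(cx + 1.5 * thick * np.cos(ang), 0, w - 1))
            if count >= target:
                break
    return mask


def _pen_color_field(rng: np.random.Generator, shape: tuple[int, int], kind: str) -> np.ndarray:
    hue, sat, val = _PEN_HSV[kind]
    hsv = _hsv_field(rng, shape, hue, sat, val, hue_jitter=3.0, sv_jitter=0.02)
    return _hsv_to_uint8(hsv)


def generate_tile(label: int, artifact: str, size_px: int, seed: int) -> np.ndarray:
    """Render one ``size_px`` x ``size_px`` RGB tile.

    Parameters
    ----------
    label : int
        1 for the positive (high nuclear density) class, 0 for negative.
    artifact : str
        One of :data:`ARTIFACT_CATEGORIES`.  "clean" is pure tissue; the
        others embed the named contamination (>= 60% coverage for blank/pen,
        <= 10% tissue for low_tissue).
    size_px : int
        Tile edge length, at least 32.
    seed : int
        Determines the raster completely together with the other arguments.
    """
    if artifact not in ARTIFACT_CATEGORIES:
        raise ValueError(
            f"unknown artifact category {artifact!r}; expected one of {ARTIFACT_CATEGORIES}"
        )
    if size_px < 32:
        raise ValueError(f"size_px must be >= 32, got {size_px}")
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label!r}")
    shape = (size_px, size_px)
    density = POSITIVE_NUCLEAR_DENSITY if label else NEGATIVE_NUCLEAR_DENSITY
    radius = max(3.0, size_px / 16.0)
    rng = _rng_for(seed, label, ARTIFACT_CATEGORIES.index(artifact), size_px)

    if artifact == "clean":
        return _tissue_field(rng, shape, density, radius)
    if artifact == "blank":
        return _blank_field(rng, shape)
    if artifact in _PEN_HSV:
        tile = _tissue_field(rng, shape, density, radius)
        strokes = _pen_strokes(rng, shape, target_fraction=0.70)
        pen = _pen_color_field(rng, shape, artifact)
        tile[strokes] = pen[strokes]
        return tile
    # low_tissue: a small tissue island (<= 10% of pixels) on glass
    tile = _blank_field(rng, shape)
    island_frac = rng.uniform(0.04, 0.08)
    r_eff = np.sqrt(island_frac * size_px * size_px / np.pi)
    cy = rng.uniform(0.3 * size_px, 0.7 * size_px)
    cx = rng.uniform(0.3 * size_px, 0.7 * size_px)
    island = _ellipse_mask(shape, cy, cx, r_eff, r_eff * rng.uniform(0.7, 1.0), rng.uniform(0, np.pi))
    tissue = _tissue_field(rng, shape, 0.5, radius * 0.6)
    tile[island] = tissue[island]
    return tile


def generate_slide(spec: SyntheticSlideSpec) -> SyntheticSlide:
    """Render a full pseudo-WSI: tissue field + blank regions + pen strokes.

    The truth mask labels every pixel tissue / pen / blank (background is
    reserved for empty margins, which the default layout does not produce).
    Realized category fractions track the spec fractions closely because
    regions are grown until the measured coverage reaches the target.
    """
    if spec.width_px < 32 or spec.height_px < 32:
        raise ValueError(
            f"slide dimensions {spec.width_px}x{spec.height_px} are smaller than one tile"
        )
    shape = (spec.height_px, spec.width_px)
    rng = _rng_for(spec.seed, spec.label)
    raster = _tissue_field(
        rng,
        shape,
        spec.effective_density,
        spec.nucleus_radius_px,
        purple_hue=spec.purple_hue_deg,
        pink_hue=spec.pink_hue_deg,
    )
    mask = np.full(shape, MASK_TISSUE, dtype=np.uint8)

    # blank (glass) rectangles
    if spec.blank_fraction > 0:
        blank = np.zeros(shape, dtype=bool)
        target = spec.blank_fraction * shape[0] * shape[1]
        for _ in range(200):
            if blank.sum() >= target:
                break
            bh = int(rng.uniform(0.1, 0.35) * shape[0])
            bw = int(rng.uniform(0.1, 0.35) * shape[1])
            y = rng.integers(0, shape[0] - bh + 1)
            x = rng.integers(0, shape[1] - bw + 1)
            blank[y : y + bh, x : x + bw] = True
        glass = _blank_field(rng, shape)
        raster[blank] = glass[blank]
        mask[blank] = MASK_BLANK

    # pen strokes over everything, in a random pen color per slide
    if spec.pen_mark_fraction > 0:
        strokes = _pen_strokes(rng, shape, spec.pen_mark_fraction)
        kind = ("pen_green", "pen_blue", "pen_gray")[rng.integers(0, 3)]
        pen = _pen_color_field(rng, shape, kind)
        raster[strokes] = pen[strokes]
        mask[strokes] = MASK_PEN

    return SyntheticSlide(spec=spec, raster=raster, truth_mask=mask)


def generate_cohort(
    n_positive: int,
    n_negative: int,
    base_seed: int,
    **overrides,
) -> list[SyntheticSlide]:
    """Generate a labeled cohort of pseudo-WSIs.

    Per-slide seeds are derived deterministically from ``base_seed``;
    keyword overrides are forwarded to every :class:`SyntheticSlideSpec`.
    """
    if n_positive < 0 or n_negative < 0:
        raise ValueError("cohort counts must be non-negative")
    n = n_positive + n_negative
    if n == 0:
        return []
    seeds = np.random.SeedSequence(int(base_seed)).generate_state(n) % (2**31)
    slides = []
    for i in range(n):
        label = 1 if i < n_positive else 0
        prefix = "bl" if label else "ctrl"
        idx = i if label else i - n_positive
        spec = SyntheticSlideSpec(
            slide_id=f"{prefix}_{idx:03d}",
            label=label,
            seed=int(seeds[i]),
            **overrides,
        )
        slides.append(generate_slide(spec))
    return slides


def save_slide(slide: SyntheticSlide, out_dir: str | Path) -> dict:
    """Write raster PNG + palette-coded truth-mask PNG + JSON spec sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = slide.spec.slide_id
    raster_path = out / f"{sid}.png"
    mask_path = out / f"{sid}.mask.png"
    spec_path = out / f"{sid}.json"
    Image.fromarray(slide.raster).save(raster_path)
    pal = Image.fromarray(slide.truth_mask, mode="P")
    pal.putpalette([0, 0, 0, 255, 105, 180, 0, 200, 0, 255, 255, 255] + [0] * (256 * 3 - 12))
    pal.save(mask_path)
    spec_path.write_text(json.dumps(dataclasses.asdict(slide.spec), indent=2))
    return {"slide_id": sid, "label": slide.spec.label, "path": str(raster_path), "seed": slide.spec.seed}


def save_cohort(slides: list[SyntheticSlide], out_dir: str | Path) -> Path:
    """Write every slide plus a cohort manifest CSV; returns the manifest path."""
    import pandas as pd

    out = Path(out_dir)
    rows = [save_slide(s, out) for s in slides]
    manifest = out / "cohort.csv"
    pd.DataFrame(rows, columns=["slide_id", "label", "path", "seed"]).to_csv(manifest, index=False)
    return manifest
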