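"""Four-stage tile quality control.

Stages run in a fixed order and short-circuit at the first failure:

1. background — pooled RGB standard deviation; blank/near-blank tiles have
   almost no variance.
2. pen — fraction of pixels inside any of three HSV pen-mark masks
   (green, gray, blue annotation ink).
3. purple_pink — hematoxylin(purple)-to-eosin(pink) pixel-count ratio; a
   low ratio signals scant cellularity, fibrosis, or fold/tear artifacts.
4. otsu — grayscale complement thresholded by Otsu; the fraction of pixels
   above threshold estimates tissue coverage.

All thresholds are configurable; the defaults below are the package's
calibration for H&E-like imagery.  Hue is always expressed in degrees
[0, 360), saturation and value in [0, 1].
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from skimage.color import rgb2hsv

STAGES = ("background", "pen", "purple_pink", "otsu")

#: (hue interval degrees, saturation interval, value interval) per pen color
DEFAULT_PEN_HSV_RANGES = {
    "green": ((80.0, 160.0), (0.25, 1.0), (0.2, 1.0)),
    "blue": ((200.0, 260.0), (0.25, 1.0), (0.2, 1.0)),
    # gray ink is desaturated mid-tone of any hue
    "gray": ((0.0, 360.0), (0.0, 0.12), (0.2, 0.8)),
}
DEFAULT_PURPLE_BAND = (250.0, 310.0)
DEFAULT_PINK_BAND = (310.0, 360.0)


@dataclasses.dataclass(frozen=True)
class QCThresholds:
    bg_std_min: float = 8.0
    pen_fraction_max: float = 0.05
    pen_hsv_ranges: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PEN_HSV_RANGES)
    )
    purple_band: tuple[float, float] = DEFAULT_PURPLE_BAND
    pink_band: tuple[float, float] = DEFAULT_PINK_BAND
    saturation_floor: float = 0.15
    pp_ratio_min: float = 0.3
    tissue_fraction_min: float = 0.10

    def __post_init__(self) -> None:
        for name in ("pen_fraction_max", "tissue_fraction_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pp_ratio_min <= 0:
            raise ValueError("pp_ratio_min must be positive")
        for band in (self.purple_band, self.pink_band):
            if not (0.0 <= band[0] < band[1] <= 360.0):
                raise ValueError(f"hue band {band} must lie within [0, 360)")
        lo1, hi1 = self.purple_band
        lo2, hi2 = self.pink_band
        if max(lo1, lo2) < min(hi1, hi2):
            raise ValueError("purple and pink hue bands must be disjoint")


@dataclasses.dataclass
class QCResult:
    """Outcome of run_qc: overall verdict, per-stage flags and scores.

    ``stage_flags`` maps each stage to True/False, or None when an earlier
    failure short-circuited it; ``scores`` only holds entries for stages
    that executed.
    """

    passed: bool
    stage_flags: dict[str, bool | None]
    scores: dict[str, float]

    @property
    def fail_stage(self) -> str | None:
        for stage in STAGES:
            if self.stage_flags.get(stage) is False:
                return stage
        return None


def _check_rgb(raster: np.ndarray) -> None:
    if raster.ndim != 3 or raster.shape[2] != 3 or raster.dtype != np.uint8:
        raise ValueError(
            f"expected 8-bit HxWx3 RGB raster, got shape {getattr(raster, 'shape', None)} "
            f"dtype {getattr(raster, 'dtype', None)}"
        )


def _hsv_deg(raster: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    hsv = rgb2hsv(raster)
    return hsv[..., 0] * 360.0, hsv[..., 1], hsv[..., 2]


def background_filter(raster: np.ndarray, bg_std_min: float = 8.0) -> tuple[bool, float]:
    """Pooled standard deviation over all pixels and channels (8-bit units)."""
    _check_rgb(raster)
    bg_std = float(raster.astype(np.float64).std())
    return bg_std >= bg_std_min, bg_std


def pen_mark_filter(
    raster: np.ndarray,
    pen_hsv_ranges: dict | None = None,
    pen_fraction_max: float = 0.05,
) -> tuple[bool, float]:
    """Fraction of pixels inside the union of the HSV pen-color masks."""
    _check_rgb(raster)
    ranges = pen_hsv_ranges if pen_hsv_ranges is not None else DEFAULT_PEN_HSV_RANGES
    hue, sat, val = _hsv_deg(raster)
    union = np.zeros(hue.shape, dtype=bool)
    masks = []
    for name, ((h0, h1), (s0, s1), (v0, v1)) in ranges.items():
        if h0 > h1 or s0 > s1 or v0 > v1:
            warnings.warn(f"degenerate HSV range for pen color {name!r}; skipping")
            continue
        m = (hue >= h0) & (hue <= h1) & (sat >= s0) & (sat <= s1) & (val >= v0) & (val <= v1)
        masks.append(m)
        union |= m
    if len(masks) > 1:
        overlap = np.zeros(hue.shape, dtype=int)
        for m in masks:
            overlap += m
        if (overlap > 1).any():
            warnings.warn("pen HSV ranges overlap; union of masks taken")
    pen_fraction = float(union.mean())
    return pen_fraction <= pen_fraction_max, pen_fraction


def purple_pink_filter(
    raster: np.ndarray,
    purple_band: tuple[float, float] = DEFAULT_PURPLE_BAND,
    pink_band: tuple[float, float] = DEFAULT_PINK_BAND,
    pp_ratio_min: float = 0.3,
    saturation_floor: float = 0.15,
) -> tuple[bool, float]:
    """Ratio of hematoxylin-hued to eosin-hued pixels.

    Only pixels with saturation above the floor qualify (near-neutral glass
    contributes to neither band).  An all-purple tile (zero pink count)
    passes with an infinite ratio; a tile with no qualifying pixels in
    either band carries no stain evidence and fails.
    """
    _check_rgb(raster)
    hue, sat, _ = _hsv_deg(raster)
    qualifying = sat >= saturation_floor
    purple = int(((hue >= purple_band[0]) & (hue < purple_band[1]) & qualifying).sum())
    pink = int(((hue >= pink_band[0]) & (hue < pink_band[1]) & qualifying).sum())
    if pink == 0:
        if purple > 0:
            return True, float("inf")
        return False, 0.0
    ratio = purple / pink
    return ratio >= pp_ratio_min, ratio


def otsu_threshold(values: np.ndarray) -> int:
    """Otsu's threshold on 8-bit values: maximize between-class variance
    over all 256 candidate thresholds; ties resolve to the lowest.

    A value v is assigned to the low class when v <= t.
    """
    hist = np.bincount(values.ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    p = hist / total
    omega0 = np.cumsum(p)  # weight of class {<= t}
    mu_cum = np.cumsum(p * np.arange(256))
    mu_total = mu_cum[-1]
    omega1 = 1.0 - omega0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(omega0 > 0, mu_cum / omega0, 0.0)
        mu1 = np.where(omega1 > 0, (mu_total - mu_cum) / omega1, 0.0)
    sigma_b = omega0 * omega1 * (mu0 - mu1) ** 2
    return int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximizer


def otsu_tissue_filter(
    raster: np.ndarray, tissue_fraction_min: float = 0.10
) -> tuple[bool, float, int]:
    """Tissue coverage via Otsu on the complemented grayscale.

    Grayscale is ITU-R BT.601 luma; complementing makes tissue (dark on a
    light background) the high class, so the tissue fraction is the share
    of complemented pixels strictly above the Otsu threshold.  A constant
    tile has a degenerate one-bin histogram and fails with fraction 0.
    """
    _check_rgb(raster)
    r = raster.astype(np.float64)
    luma = 0.299 * r[..., 0] + 0.587 * r[..., 1] + 0.114 * r[..., 2]
    gray = np.clip(np.rint(luma), 0, 255).astype(np.uint8)
    comp = (255 - gray).astype(np.uint8)
    if comp.min() == comp.max():
        return False, 0.0, int(comp.min())
    t = otsu_threshold(comp)
    tissue_fraction = float((comp > t).mean())
    return tissue_fraction >= tissue_fraction_min, tissue_fraction, t


def run_qc(raster: np.ndarray, thresholds: QCThresholds | None = None) -> QCResult:
    """Run the four stages in order, short-circuiting at the first failure."""
    th = thresholds if thresholds is not None else QCThresholds()
    flags: dict[str, bool | None] = {s: None for s in STAGES}
    scores: dict[str, float] = {}

    ok, bg_std = background_filter(raster, th.bg_std_min)
    flags["background"] = ok
    scores["bg_std"] = bg_std
    if not ok:
        return QCResult(False, flags, scores)

    ok, pen_fraction = pen_mark_filter(raster, th.pen_hsv_ranges, th.pen_fraction_max)
    flags["pen"] = ok
    scores["pen_fraction"] = pen_fraction
    if not ok:
        return QCResult(False, flags, scores)

    ok, pp_ratio = purple_pink_filter(
        raster, th.purple_band, th.pink_band, th.pp_ratio_min, th.saturation_floor
    )
    flags["purple_pink"] = ok
    scores["pp_ratio"] = pp_ratio
    if not ok:
        return QCResult(False, flags, scores)

    ok, tissue_fraction, t = otsu_tissue_filter(raster, th.tissue_fraction_min)
    flags["otsu"] = ok
    scores["tissue_fraction"] = tissue_fraction
    scores["otsu_threshold"] = float(t)
    return QCResult(ok, flags, scores)
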