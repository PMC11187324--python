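"""Slide tiling: fixed-size overlapping tile grids and magnification pyramids.

Coordinates are 0-based with half-open extents: a tile at origin (x, y)
covers columns [x, x+size) and rows [y, y+size).  ``x`` indexes columns,
``y`` rows.  Partial tiles at the right/bottom edge are dropped so every
tile is exactly ``tile_size_px`` square.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

#: nominal magnification -> resolution in micrometers per pixel
MAGNIFICATIONS = {"40x": 0.25, "20x": 0.5, "10x": 1.0, "5x": 2.0}
#: magnifications ordered from finest to coarsest
MAG_ORDER = ("40x", "20x", "10x", "5x")

DEFAULT_TILE_SIZE = 450
DEFAULT_OVERLAP = 20


@dataclasses.dataclass(frozen=True)
class TilePlan:
    """Grid of tile origins for one slide at one magnification."""

    slide_id: str
    magnification: str
    tile_size_px: int
    overlap_px: int
    origins: tuple[tuple[int, int], ...]  # (x, y), row-major

    @property
    def stride(self) -> int:
        return self.tile_size_px - self.overlap_px


@dataclasses.dataclass
class TileRecord:
    """One extracted tile: provenance coordinates plus the pixel data."""

    slide_id: str
    x: int
    y: int
    magnification: str
    tile_size_px: int
    raster: np.ndarray  # size x size x 3 uint8
    qc: object | None = None  # QCResult once tile_qc has run
    path: str | None = None


def _axis_origins(extent: int, tile: int, stride: int) -> list[int]:
    return list(range(0, extent - tile + 1, stride))


def plan_tiles(
    width_px: int,
    height_px: int,
    tile_size_px: int = DEFAULT_TILE_SIZE,
    overlap_px: int = DEFAULT_OVERLAP,
    slide_id: str = "",
    magnification: str = "40x",
) -> TilePlan:
    """Plan a row-major grid of overlapping tile origins.

    Origins step by ``stride = tile_size_px - overlap_px`` from 0, keeping
    only fully in-bounds positions, so the count is
    ``floor((W - tile)/stride + 1) * floor((H - tile)/stride + 1)``.
    """
    if overlap_px < 0 or tile_size_px <= overlap_px:
        raise ValueError(
            f"need tile_size_px > overlap_px >= 0, got {tile_size_px}, {overlap_px}"
        )
    if width_px < tile_size_px:
        raise ValueError(f"slide width {width_px} is smaller than tile size {tile_size_px}")
    if height_px < tile_size_px:
        raise ValueError(f"slide height {height_px} is smaller than tile size {tile_size_px}")
    stride = tile_size_px - overlap_px
    xs = _axis_origins(width_px, tile_size_px, stride)
    ys = _axis_origins(height_px, tile_size_px, stride)
    origins = tuple((x, y) for y in ys for x in xs)
    return TilePlan(
        slide_id=slide_id,
        magnification=magnification,
        tile_size_px=tile_size_px,
        overlap_px=overlap_px,
        origins=origins,
    )


def extract_tiles(raster: np.ndarray, plan: TilePlan) -> list[TileRecord]:
    """Cut the planned tiles out of a slide raster."""
    if raster.ndim != 3 or raster.shape[2] != 3:
        raise ValueError(f"expected HxWx3 raster, got shape {raster.shape}")
    h, w = raster.shape[:2]
    size = plan.tile_size_px
    records = []
    for x, y in plan.origins:
        if x < 0 or y < 0 or x + size > w or y + size > h:
            raise ValueError(
                f"tile origin ({x}, {y}) out of bounds for {w}x{h} slide at size {size}"
            )
        records.append(
            TileRecord(
                slide_id=plan.slide_id,
                x=x,
                y=y,
                magnification=plan.magnification,
                tile_size_px=size,
                raster=raster[y : y + size, x : x + size].copy(),
            )
        )
    return records


def downsample2(raster: np.ndarray) -> np.ndarray:
    """2x area-average downsample; odd trailing rows/columns are dropped."""
    h, w = raster.shape[:2]
    r = raster[: h - h % 2, : w - w % 2].astype(np.float64)
    blocks = r.reshape(h // 2, 2, w // 2, 2, -1).mean(axis=(1, 3))
    out = np.clip(np.rint(blocks), 0, 255).astype(np.uint8)
    return out if raster.ndim == 3 else out[..., 0]


def build_pyramid(raster: np.ndarray, levels: list[str] | tuple[str, ...]) -> dict[str, np.ndarray]:
    """Derive a magnification pyramid from the finest requested level.

    The input raster is taken to be at the finest (highest) magnification in
    ``levels``; each coarser level is produced by repeated 2x area-average
    downsampling (one octave per pyramid step).
    """
    if not levels:
        raise ValueError("levels must not be empty")
    unknown = set(levels) - set(MAGNIFICATIONS)
    if unknown:
        raise ValueError(f"unknown magnification levels: {sorted(unknown)}")
    ordered = [m for m in MAG_ORDER if m in set(levels)]
    pyramid = {}
    current = raster
    current_idx = MAG_ORDER.index(ordered[0])
    pyramid[ordered[0]] = current
    for mag in ordered[1:]:
        idx = MAG_ORDER.index(mag)
        for _ in range(idx - current_idx):
            current = downsample2(current)
        current_idx = idx
        pyramid[mag] = current
    return pyramid


def tile_slide(
    raster: np.ndarray,
    slide_id: str,
    levels: tuple[str, ...] = ("40x", "20x", "10x", "5x"),
    tile_size_px: int = DEFAULT_TILE_SIZE,
    overlap_px: int = DEFAULT_OVERLAP,
) -> list[TileRecord]:
    """Pyramid + plan + extract across magnification levels.

    Levels whose downsampled raster is smaller than one tile are skipped
    (coarse levels of a small slide simply contribute no tiles).
    """
    pyramid = build_pyramid(raster, levels)
    records = []
    for mag, level_raster in pyramid.items():
        h, w = level_raster.shape[:2]
        if h < tile_size_px or w < tile_size_px:
            continue
        plan = plan_tiles(
            w, h, tile_size_px, overlap_px, slide_id=slide_id, magnification=mag
        )
        records.extend(extract_tiles(level_raster, plan))
    return records


def write_tile_manifest(records: list[TileRecord], out_dir: str | Path) -> Path:
    """Store tiles as PNG plus a manifest CSV (slide_id,x,y,magnification,tile_size,path)."""
    import pandas as pd
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        name = f"{rec.slide_id}_{rec.magnification}_x{rec.x}_y{rec.y}.png"
        path = out / name
        Image.fromarray(rec.raster).save(path)
        rec.path = str(path)
        rows.append(
            {
                "slide_id": rec.slide_id,
                "x": rec.x,
                "y": rec.y,
                "magnification": rec.magnification,
                "tile_size": rec.tile_size_px,
                "path": str(path),
            }
        )
    manifest = out / "tiles.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
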