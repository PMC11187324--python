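"""Stain/color normalization by per-channel moment matching.

Tiles from different labs and scanners vary in stain intensity and white
balance.  Each tile is mapped into a luma + two-chroma opponent space
(YCbCr), its per-channel mean and standard deviation are matched to a
reference, and the result is converted back to 8-bit RGB with clipping.

Moment matching in a channel-wise *linear* opponent space makes the
transform exactly invariant to global brightness offsets and per-channel
affine shifts of the input — two tiles differing only by such a shift
normalize to bit-identical outputs.  Stain-vector deconvolution (Macenko
style) could be slotted in behind the same signatures.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
from skimage.color import rgb2ycbcr, ycbcr2rgb

logger = logging.getLogger(__name__)

FORMAT_VERSION = "1"


@dataclasses.dataclass(frozen=True)
class ReferenceStats:
    """Pooled per-channel moments of a reference tile set (YCbCr space)."""

    means: tuple[float, float, float]
    stds: tuple[float, float, float]
    provenance: str = "unspecified"
    version: str = FORMAT_VERSION

    def __post_init__(self) -> None:
        if len(self.means) != 3 or len(self.stds) != 3:
            raise ValueError("ReferenceStats requires exactly 3 channels")
        if any(s <= 0 for s in self.stds):
            raise ValueError(f"reference stds must be positive, got {self.stds}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceStats":
        d = json.loads(Path(path).read_text())
        return cls(
            means=tuple(d["means"]), stds=tuple(d["stds"]),
            provenance=d.get("provenance", "unspecified"),
            version=d.get("version", FORMAT_VERSION),
        )


def _to_opponent(raster: np.ndarray) -> np.ndarray:
    return rgb2ycbcr(raster.astype(np.float64) / 255.0)


def _from_opponent(ycc: np.ndarray) -> np.ndarray:
    rgb = ycbcr2rgb(ycc)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def fit_reference(tiles, provenance: str = "unspecified") -> ReferenceStats:
    """Pooled per-channel mean/std over all pixels of all tiles."""
    tiles = list(tiles)
    if not tiles:
        raise ValueError("need at least one tile to fit a reference")
    pixels = np.concatenate([_to_opponent(t).reshape(-1, 3) for t in tiles], axis=0)
    means = pixels.mean(axis=0)
    stds = pixels.std(axis=0)
    if np.any(stds <= 0):
        raise ValueError("reference tile set has a constant channel (zero variance)")
    return ReferenceStats(means=tuple(means.tolist()), stds=tuple(stds.tolist()),
                          provenance=provenance)


def _match_moments(ycc: np.ndarray, ref: ReferenceStats) -> np.ndarray:
    out = np.empty_like(ycc)
    mu_t = ycc.reshape(-1, 3).mean(axis=0)
    sd_t = ycc.reshape(-1, 3).std(axis=0)
    for c in range(3):
        if sd_t[c] < 1e-12:
            logger.warning("constant channel %d: shifted to reference mean", c)
            out[..., c] = ref.means[c]
        else:
            out[..., c] = (ycc[..., c] - mu_t[c]) / sd_t[c] * ref.stds[c] + ref.means[c]
    return out


def normalize_tile(raster: np.ndarray, ref: ReferenceStats, max_iter: int = 8) -> np.ndarray:
    """Match the tile's per-channel opponent-space moments to the reference.

    out = (in - mu_tile) / sigma_tile * sigma_ref + mu_ref, per channel,
    then back to 8-bit RGB with clipping.  A constant channel (sigma
    undefined) is shifted to the reference mean and logged.

    Gamut clipping is re-entrant: pixels pushed outside the RGB gamut are
    clipped and the moments re-matched until the clip/match cycle reaches a
    fixed point (in float), so applying the transform twice changes nothing
    beyond 8-bit quantization.  Every affine pass has the exact reference
    moments before clipping.
    """
    if raster.ndim != 3 or raster.shape[2] != 3:
        raise ValueError(f"expected HxWx3 raster, got shape {raster.shape}")
    rgb = raster.astype(np.float64) / 255.0
    for _ in range(max_iter):
        matched = _match_moments(rgb2ycbcr(rgb), ref)
        new_rgb = np.clip(ycbcr2rgb(matched), 0.0, 1.0)
        if np.abs(new_rgb - rgb).max() < 0.25 / 255.0:
            rgb = new_rgb
            break
        rgb = new_rgb
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def default_reference() -> ReferenceStats:
    """Reference moments of the package's canonical synthetic clean-tile set
    (10 tiles, seeds 0-4 per class, 64 px), computed on demand and cached."""
    global _DEFAULT_REF
    if _DEFAULT_REF is None:
        from .synthetic import generate_tile

        tiles = [generate_tile(label, "clean", 64, seed) for label in (1, 0) for seed in range(5)]
        _DEFAULT_REF = fit_reference(tiles, provenance="synthetic-clean-seed0..4-v1")
    return _DEFAULT_REF


_DEFAULT_REF: ReferenceStats | None = None
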