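"""Local Edge Intensity Analysis (LEIA).

Maps of chromatic and achromatic edge contrast (ΔS) measured between
neighbouring locations along horizontal, vertical and diagonal axes, and
the abundance-weighted coefficient of variation summarising such maps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vision import ConeCatchImage, ObserverModel, _chromatic_map

__all__ = ["EdgeContrastMap", "local_edge_map", "weighted_cov", "UndefinedCoVWarning"]

log = logging.getLogger(__name__)

# forward block-grid offsets: horizontal, vertical, both diagonals
_AXES = ((0, 1), (1, 0), (1, 1), (1, -1))


class UndefinedCoVWarning(UserWarning):
    """Raised as a warning when a CoV is undefined (flat region)."""


@dataclass
class EdgeContrastMap:
    """Per-location chromatic/achromatic edge contrast on a block grid.

    ``chromatic`` and ``achromatic`` are 2-D arrays over the block grid
    (NaN where a location had no valid axis comparison); ``weight`` counts
    the axis comparisons that contributed at each location and is 0 exactly
    where no valid comparison fell inside the region mask.
    """

    chromatic: np.ndarray
    achromatic: np.ndarray
    weight: np.ndarray
    region_label: str
    block_px: int

    @property
    def valid(self) -> np.ndarray:
        return self.weight > 0

    @property
    def chromatic_values(self) -> np.ndarray:
        return self.chromatic[self.valid]

    @property
    def achromatic_values(self) -> np.ndarray:
        return self.achromatic[self.valid]

    @property
    def weights(self) -> np.ndarray:
        return self.weight[self.valid].astype(float)

    def to_tiff(self, path) -> None:
        """Write chromatic / achromatic / weight rasters as a float TIFF
        stack for visual inspection (NaN marks excluded locations)."""
        import tifffile

        pages = np.stack(
            [self.chromatic, self.achromatic, self.weight.astype(float)]
        ).astype(np.float32)
        tifffile.imwrite(str(path), pages, photometric="minisblack")

    def to_dataframe(self) -> pd.DataFrame:
        rows, cols = np.nonzero(self.valid)
        return pd.DataFrame(
            {
                "row": rows,
                "col": cols,
                "chromatic_ds": self.chromatic[rows, cols],
                "achromatic_ds": self.achromatic[rows, cols],
                "weight": self.weight[rows, cols],
                "region": self.region_label,
            }
        )


def local_edge_map(
    img: ConeCatchImage,
    obs: ObserverModel,
    mask: np.ndarray,
    block_px: int = 2,
    region_label: str = "animal",
) -> EdgeContrastMap:
    """Tile the image into blocks and measure ΔS between neighbouring blocks.

    The image is tiled into non-overlapping ``block_px × block_px`` blocks
    (channelwise block means).  For every block whose centre pixel lies in
    ``mask``, chromatic and achromatic ΔS are computed against the forward
    neighbour along each of four axes (horizontal, vertical, two diagonals)
    whose centre also lies in the mask; the per-location value is the mean
    over available axes and the weight is the number of available axes.
    Blocks with no available axis are excluded.
    """
    img.validate_against(obs)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {img.shape}")
    if not mask.any():
        raise ValueError("region mask is empty")
    if block_px < 1:
        raise ValueError("block_px must be ≥ 1")
    h, w = img.shape
    nby, nbx = h // block_px, w // block_px
    if nby < 1 or nbx < 1:
        raise ValueError(f"block size {block_px} exceeds image {h}×{w}")

    ch = img.stack[: nby * block_px, : nbx * block_px, :]
    blocks = ch.reshape(nby, block_px, nbx, block_px, -1).mean(axis=(1, 3))
    centre = block_px // 2
    bmask = mask[centre : nby * block_px : block_px, centre : nbx * block_px : block_px]
    if not bmask.any():
        raise ValueError("no block centre falls inside the region mask")

    # perceptual log coordinates per block: chromatic map + scaled log-luminance
    m = _chromatic_map(obs.weber_fractions)
    chrom_coords = np.log(blocks[..., :-1]) @ m.T
    log_lum = np.log(blocks[..., -1])

    chrom_sum = np.zeros((nby, nbx))
    achro_sum = np.zeros((nby, nbx))
    count = np.zeros((nby, nbx), dtype=int)
    for dy, dx in _AXES:
        ys = slice(max(0, -dy), nby - max(0, dy))
        xs = slice(max(0, -dx), nbx - max(0, dx))
        yn = slice(max(0, dy), nby - max(0, -dy))
        xn = slice(max(0, dx), nbx - max(0, -dx))
        pair_ok = bmask[ys, xs] & bmask[yn, xn]
        dchrom = np.sqrt(
            ((chrom_coords[ys, xs] - chrom_coords[yn, xn]) ** 2).sum(axis=-1)
        )
        dachro = np.abs(log_lum[ys, xs] - log_lum[yn, xn]) / obs.luminance_weber
        chrom_sum[ys, xs] += np.where(pair_ok, dchrom, 0.0)
        achro_sum[ys, xs] += np.where(pair_ok, dachro, 0.0)
        count[ys, xs] += pair_ok

    valid = bmask & (count > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        chrom_mean = np.where(valid, chrom_sum / np.maximum(count, 1), np.nan)
        achro_mean = np.where(valid, achro_sum / np.maximum(count, 1), np.nan)
    return EdgeContrastMap(
        chromatic=chrom_mean,
        achromatic=achro_mean,
        weight=np.where(valid, count, 0),
        region_label=region_label,
        block_px=block_px,
    )


def weighted_cov(values, weights) -> float:
    """Abundance-weighted coefficient of variation (sd / mean).

    Frequency-style weights and the population (biased) variance
    convention: ``mean = Σwx/Σw``, ``var = Σw(x−mean)²/Σw``.  Scaling all
    weights by a common factor leaves the result unchanged.  A zero
    weighted mean (flat region) yields NaN with a warning; callers must
    drop such records.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape:
        raise ValueError("values and weights differ in length")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    pos = w > 0
    if pos.sum() < 2:
        raise ValueError("need at least two locations with positive weight")
    x, w = x[pos], w[pos]
    wsum = w.sum()
    mean = float((w * x).sum() / wsum)
    if mean <= 0:
        warnings.warn(
            "weighted mean is zero: coefficient of variation undefined",
            UndefinedCoVWarning,
            stacklevel=2,
        )
        log.warning("weighted_cov undefined (flat region); returning NaN")
        return float("nan")
    var = float((w * (x - mean) ** 2).sum() / wsum)
    return float(np.sqrt(var) / mean)
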