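"""Scene and table I/O.

Stacks travel as multi-page floating-point TIFFs (one page per channel,
chromatic channels first, luminance last); masks as PNG or TIFF with
nonzero meaning membership; records and species metadata as tidy CSV.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .vision import ConeCatchImage, ObserverModel, RegionMasks, ShapeMismatchError

__all__ = [
    "SceneIOError",
    "read_scene",
    "write_scene",
    "read_mask",
    "write_mask",
    "write_records",
    "read_records",
]

log = logging.getLogger(__name__)


class SceneIOError(IOError):
    """A scene file is missing, unreadable or inconsistent."""


def write_scene(path: str | Path, img: ConeCatchImage) -> None:
    """Write a stack as a planar float64 multi-page TIFF (lossless)."""
    planar = np.ascontiguousarray(np.moveaxis(img.stack, -1, 0))
    tifffile.imwrite(
        str(path),
        planar,
        photometric="minisblack",
        metadata={"pixels_per_cm": img.pixels_per_cm},
    )


def read_scene(
    stack_path: str | Path,
    mask_paths: dict[str, str | Path] | None = None,
    pixels_per_cm: float | None = None,
    obs: ObserverModel | None = None,
    floor_rel: float = 1e-6,
) -> tuple[ConeCatchImage, RegionMasks | None]:
    """Load a cone-catch stack (and optional animal/background masks).

    Integer-typed stacks are rescaled to [0, 1] floats with a logged note.
    The channel count is validated against the observer when one is given.
    ``mask_paths`` maps region names (``animal``, ``background``) to files.
    """
    try:
        raw = tifffile.imread(str(stack_path))
    except (FileNotFoundError, ValueError, tifffile.TiffFileError) as exc:
        raise SceneIOError(f"cannot read stack {stack_path}: {exc}") from exc
    if raw.ndim != 3:
        raise SceneIOError(f"stack {stack_path} is not 3-dimensional: {raw.shape}")
    # planar (C, H, W) pages -> (H, W, C); tolerate channel-last files
    if raw.shape[0] <= min(raw.shape[1:]):
        stack = np.moveaxis(raw, 0, -1)
    else:
        stack = raw
    if np.issubdtype(stack.dtype, np.integer):
        scale = float(np.iinfo(stack.dtype).max)
        log.info("integer stack %s rescaled to [0, 1] by 1/%g", stack_path, scale)
        stack = stack.astype(np.float64) / scale

    if pixels_per_cm is None:
        pixels_per_cm = _pixels_per_cm_from_tiff(stack_path)
    img = ConeCatchImage(stack, pixels_per_cm, floor_rel=floor_rel)
    if obs is not None:
        try:
            img.validate_against(obs)
        except ShapeMismatchError as exc:
            raise SceneIOError(str(exc)) from exc

    masks = None
    if mask_paths is not None:
        loaded = {name: read_mask(p, img.shape) for name, p in mask_paths.items()}
        for name, m in loaded.items():
            if not m.any():
                raise SceneIOError(f"mask {mask_paths[name]} ({name}) has no pixels set")
        masks = RegionMasks(animal=loaded["animal"], background=loaded["background"])
    return img, masks


def _pixels_per_cm_from_tiff(path) -> float:
    with tifffile.TiffFile(str(path)) as tf:
        meta = tf.shaped_metadata or ({},)
        ppcm = meta[0].get("pixels_per_cm")
    if ppcm is None:
        raise SceneIOError(
            f"{path} carries no pixels_per_cm metadata; pass it explicitly"
        )
    return float(ppcm)


def read_mask(path: str | Path, expected_shape: tuple[int, int]) -> np.ndarray:
    try:
        arr = iio.imread(str(path))
    except (FileNotFoundError, OSError) as exc:
        raise SceneIOError(f"cannot read mask {path}: {exc}") from exc
    if arr.ndim == 3:  # collapse RGB(A)
        arr = arr[..., 0]
    if arr.shape != expected_shape:
        raise SceneIOError(
            f"mask {path} shape {arr.shape} != stack shape {expected_shape}"
        )
    return arr != 0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(str(path), (np.asarray(mask, bool) * np.uint8(255)))


def write_records(path: str | Path, records: pd.DataFrame, run_id: str) -> None:
    """Write a tidy CSV with a run-id column tying it to the config hash."""
    out = records.copy()
    out.insert(0, "run_id", run_id)
    out.to_csv(path, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"species", "defence_class", "unpalatability", "distance_cm"}
    missing = required - set(df.columns)
    if missing:
        raise SceneIOError(f"records file {path} lacks columns {sorted(missing)}")
    return df
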