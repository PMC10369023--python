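"""Boldness and detectability of an animal's colour pattern.

Boldness is the internal contrastiness of the animal's own pattern
(abundance-weighted CoV of within-animal local edge contrast, ignoring the
background).  Detectability quantifies background matching as the absolute
difference between the animal's and its background's edge-contrast CoV;
low values mean a well-matched animal.  Both are computed per channel type
(achromatic "lum", chromatic "col") and per viewing distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation

from .leia import EdgeContrastMap, local_edge_map, weighted_cov
from .spatial import acuity_blur, rnl_ranked_filter
from .vision import ConeCatchImage, ObserverModel, RegionMasks

__all__ = [
    "DEFENCE_CLASSES",
    "PatternRecord",
    "boldness",
    "detectability",
    "background_annulus",
    "distance_profile",
    "records_to_frame",
    "DEFAULT_DISTANCES_CM",
]

log = logging.getLogger(__name__)

DEFENCE_CLASSES = ("NR", "II", "I_II")
DEFAULT_DISTANCES_CM = (2.0, 5.0, 10.0, 30.0)


@dataclass
class PatternRecord:
    """One individual × viewing distance × both channel types."""

    individual_id: str
    species: str
    defence_class: str
    unpalatability: float
    distance_cm: float
    lum_boldness: float
    col_boldness: float
    lum_detectability: float
    col_detectability: float

    def __post_init__(self) -> None:
        if self.defence_class not in DEFENCE_CLASSES:
            raise ValueError(
                f"defence_class must be one of {DEFENCE_CLASSES}, "
                f"got {self.defence_class!r}"
            )
        if not (0.0 <= self.unpalatability <= 1.0):
            raise ValueError("unpalatability must be in [0, 1]")

    @property
    def is_defined(self) -> bool:
        return all(
            math.isfinite(v)
            for v in (
                self.lum_boldness,
                self.col_boldness,
                self.lum_detectability,
                self.col_detectability,
            )
        )


def boldness(animal_map: EdgeContrastMap) -> tuple[float, float]:
    """(lum_boldness, col_boldness): CoV of the animal's own edge contrasts."""
    lum = weighted_cov(animal_map.achromatic_values, animal_map.weights)
    col = weighted_cov(animal_map.chromatic_values, animal_map.weights)
    return lum, col


def detectability(
    animal_map: EdgeContrastMap, background_map: EdgeContrastMap
) -> tuple[float, float]:
    """(lum, col) detectability: |CoV_animal − CoV_background| per channel."""
    lum_a, col_a = boldness(animal_map)
    lum_b = weighted_cov(background_map.achromatic_values, background_map.weights)
    col_b = weighted_cov(background_map.chromatic_values, background_map.weights)
    return abs(lum_a - lum_b), abs(col_a - col_b)


def background_annulus(animal_mask: np.ndarray, scale: float = 2.0) -> np.ndarray:
    """Default background ROI: a dilated annulus around the animal.

    The animal mask is dilated until its equivalent diameter reaches
    ``scale`` times the animal's, then the animal itself is removed.
    Stands in for the photographed natural background surrounding each
    individual.
    """
    animal_mask = np.asarray(animal_mask, dtype=bool)
    if not animal_mask.any():
        raise ValueError("animal mask is empty")
    eq_diam = 2.0 * math.sqrt(animal_mask.sum() / math.pi)
    grow = max(1, int(round(eq_diam * (scale - 1.0) / 2.0)))
    dilated = binary_dilation(animal_mask, iterations=grow)
    return dilated & ~animal_mask


def distance_profile(
    img: ConeCatchImage,
    masks: RegionMasks,
    obs: ObserverModel,
    distances_cm=DEFAULT_DISTANCES_CM,
    *,
    individual_id: str = "ind",
    species: str = "sp",
    defence_class: str = "NR",
    unpalatability: float = 0.0,
    k_cycle_to_sigma: float = 2.0,
    filter_radius_px: int = 2,
    filter_n_iter: int = 5,
    filter_keep_fraction: float = 0.5,
    block_px: int = 2,
    drop_undefined: bool = True,
) -> list[PatternRecord]:
    """Run the full perceptual chain at every viewing distance.

    Per distance: acuity blur → RNL ranked filter → local edge maps for the
    animal and background regions → boldness and detectability.  Records
    whose CoV is undefined (flat region) are dropped with a logged warning
    when ``drop_undefined`` is set.
    """
    distances = [float(d) for d in distances_cm]
    if any(d <= 0 for d in distances):
        raise ValueError("viewing distances must be positive")
    if distances != sorted(distances):
        raise ValueError("viewing distances must be sorted ascending")
    img.validate_against(obs)

    records: list[PatternRecord] = []
    for d in distances:
        try:
            blurred = acuity_blur(img, obs, d, k_cycle_to_sigma=k_cycle_to_sigma)
            filtered = rnl_ranked_filter(
                blurred,
                obs,
                radius_px=filter_radius_px,
                n_iter=filter_n_iter,
                keep_fraction=filter_keep_fraction,
            )
            amap = local_edge_map(filtered, obs, masks.animal, block_px, "animal")
            bmap = local_edge_map(filtered, obs, masks.background, block_px, "background")
            lum_b, col_b = boldness(amap)
            lum_d, col_d = detectability(amap, bmap)
        except Exception as exc:  # re-raise with distance context
            raise RuntimeError(
                f"{individual_id}: processing failed at distance {d} cm"
            ) from exc
        rec = PatternRecord(
            individual_id=individual_id,
            species=species,
            defence_class=defence_class,
            unpalatability=unpalatability,
            distance_cm=d,
            lum_boldness=lum_b,
            col_boldness=col_b,
            lum_detectability=lum_d,
            col_detectability=col_d,
        )
        if drop_undefined and not rec.is_defined:
            log.warning(
                "dropping undefined record: %s at %s cm", individual_id, d
            )
            continue
        records.append(rec)
    return records


def records_to_frame(records: list[PatternRecord]) -> pd.DataFrame:
    """Tidy table: one row per individual × distance."""
    return pd.DataFrame([asdict(r) for r in records])
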