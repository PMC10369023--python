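"""Synthetic cone-catch scenes and species cohorts.

Generates two-phase blob textures whose phase pair hits exact target
chromatic/achromatic ΔS contrasts (the targets are analytically inverted
through the RNL formulas), an elliptical animal with its own internal
pattern, and whole multi-species cohorts in which unpalatability is
statistically coupled — through a monotone effect map — to internal
pattern contrast and to animal/background similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, gaussian_filter

from .metrics import DEFENCE_CLASSES
from .vision import ConeCatchImage, ObserverModel, RegionMasks

__all__ = [
    "TextureSpec",
    "AnimalSpec",
    "SceneSpec",
    "EffectMap",
    "CohortSpec",
    "SceneSpecError",
    "generate_scene",
    "generate_cohort",
    "PAPER_STYLE_SPECIES_COUNTS",
]

# per-species individual counts of the 13-species default cohort (sums to 226)
PAPER_STYLE_SPECIES_COUNTS = (24, 21, 17, 15, 27, 15, 15, 25, 10, 8, 23, 8, 18)


class SceneSpecError(ValueError):
    """A scene or cohort specification is invalid or unattainable."""


@dataclass(frozen=True)
class TextureSpec:
    """Two-phase blob texture with exact target phase-pair contrasts."""

    base: tuple[float, ...] = (0.30, 0.35, 0.40, 0.35)
    element_size_px: float = 7.0
    chromatic_contrast: float = 1.0
    achromatic_contrast: float = 1.5

    def validate(self, n_channels: int) -> None:
        if len(self.base) != n_channels:
            raise SceneSpecError(
                f"texture base has {len(self.base)} channels, expected {n_channels}"
            )
        if any(b <= 0 for b in self.base):
            raise SceneSpecError("texture base catches must be positive")
        if self.element_size_px < 1:
            raise SceneSpecError("element_size_px must be ≥ 1")
        if self.chromatic_contrast < 0 or self.achromatic_contrast < 0:
            raise SceneSpecError("contrasts must be non-negative")


@dataclass(frozen=True)
class AnimalSpec(TextureSpec):
    """Elliptical animal: internal texture, boundary contrast vs background,
    and an optional focal marking (a central patch whose catches are offset
    from the body by target ΔS values — a large-scale pattern feature that
    partially survives acuity blur, unlike the fine internal texture)."""

    size_px: tuple[float, float] = (16.0, 11.0)  # semi-axes (y, x)
    boundary_chromatic_contrast: float = 0.0
    boundary_achromatic_contrast: float = 0.0
    marking_fraction: float = 0.42  # marking semi-axes relative to body
    marking_chromatic_contrast: float = 0.0
    marking_achromatic_contrast: float = 0.0

    def validate(self, n_channels: int) -> None:
        super().validate(n_channels)
        if min(self.size_px) < 2:
            raise SceneSpecError("animal semi-axes must be ≥ 2 px")
        if self.boundary_chromatic_contrast < 0 or self.boundary_achromatic_contrast < 0:
            raise SceneSpecError("boundary contrasts must be non-negative")
        if not (0.0 < self.marking_fraction < 1.0):
            raise SceneSpecError("marking_fraction must be in (0, 1)")
        if self.marking_chromatic_contrast < 0 or self.marking_achromatic_contrast < 0:
            raise SceneSpecError("marking contrasts must be non-negative")


@dataclass(frozen=True)
class SceneSpec:
    image_size_px: tuple[int, int] = (64, 64)
    pixels_per_cm: float = 40.0
    background: TextureSpec = field(default_factory=TextureSpec)
    animal: AnimalSpec = field(default_factory=AnimalSpec)
    pixel_noise_sd: float = 0.10
    mask_guard_px: int = 8
    seed: int = 0

    def validate(self, obs: ObserverModel) -> None:
        h, w = self.image_size_px
        if self.pixels_per_cm <= 0:
            raise SceneSpecError("pixels_per_cm must be positive")
        if self.pixel_noise_sd < 0:
            raise SceneSpecError("pixel_noise_sd must be non-negative")
        self.background.validate(obs.n_channels)
        self.animal.validate(obs.n_channels)
        ay, ax = self.animal.size_px
        if 2 * ay >= h or 2 * ax >= w:
            raise SceneSpecError("animal does not fit in the image")


def _opponent_direction(n_receptors: int) -> np.ndarray:
    """Fixed log-contrast direction used to realise chromatic targets."""
    v = np.zeros(n_receptors)
    v[0], v[-1] = 1.0, -1.0
    return v


def _delta_s_of_logs(df: np.ndarray, obs: ObserverModel) -> float:
    w = 1.0 / np.asarray(obs.weber_fractions) ** 2
    s2 = np.dot(w, df**2) - np.dot(w, df) ** 2 / w.sum()
    return float(np.sqrt(max(s2, 0.0)))


def _phase_log_offsets(
    chromatic_contrast: float, achromatic_contrast: float, obs: ObserverModel
) -> np.ndarray:
    """Log-space channel offsets between the two phases of a texture.

    Returns ``Δf`` of length ``n_channels`` (chromatic channels then
    luminance) such that phases ``base·exp(±Δf/2)`` are exactly the target
    chromatic and achromatic ΔS apart; both targets are linear in ``Δf``,
    making the inversion exact.
    """
    v = _opponent_direction(obs.n_receptors)
    unit = _delta_s_of_logs(v, obs)
    df = np.zeros(obs.n_channels)
    if chromatic_contrast > 0:
        df[: obs.n_receptors] = (chromatic_contrast / unit) * v
    df[-1] = achromatic_contrast * obs.luminance_weber
    return df


def _phase_field(
    shape: tuple[int, int], element_size_px: float, rng, region: np.ndarray | None = None
) -> np.ndarray:
    """Random two-phase blob field in {-0.5, +0.5} with ~50/50 coverage.

    Built from band-passed white noise (difference of Gaussians at the
    element scale) so the blob size spectrum is concentrated around
    ``element_size_px``: blur beyond that scale erases the texture rather
    than leaving low-frequency residue.  When ``region`` is given the
    phase threshold is the median over that region, balancing the two
    phases exactly where the texture will actually be sampled (a small
    region would otherwise carry a net phase imbalance that survives
    blurring as a spurious large-scale signal).
    """
    noise = rng.standard_normal(shape)
    s = max(element_size_px / 2.0, 0.5)
    smooth = gaussian_filter(noise, sigma=s, mode="wrap") - gaussian_filter(
        noise, sigma=2.0 * s, mode="wrap"
    )
    thr = np.median(smooth if region is None else smooth[region])
    return np.where(smooth >= thr, 0.5, -0.5)


def _texture_stack(
    shape: tuple[int, int], tex: TextureSpec, obs: ObserverModel, rng, region=None
) -> np.ndarray:
    df = _phase_log_offsets(tex.chromatic_contrast, tex.achromatic_contrast, obs)
    phase = _phase_field(shape, tex.element_size_px, rng, region)
    base = np.asarray(tex.base)
    return base[None, None, :] * np.exp(phase[:, :, None] * df[None, None, :])


def phase_pair(tex: TextureSpec, obs: ObserverModel) -> tuple[np.ndarray, np.ndarray]:
    """The two exact phase catch vectors of a texture (pre-noise)."""
    df = _phase_log_offsets(tex.chromatic_contrast, tex.achromatic_contrast, obs)
    base = np.asarray(tex.base)
    return base * np.exp(-df / 2), base * np.exp(df / 2)


def generate_scene(
    spec: SceneSpec, obs: ObserverModel | None = None
) -> tuple[ConeCatchImage, RegionMasks]:
    """Render one scene: blob background, elliptical patterned animal, masks.

    Deterministic given ``spec.seed``.  Multiplicative lognormal pixel
    noise is applied after construction (camera/scene noise is
    multiplicative in linear catch space).  The background mask is the
    image minus the animal dilated by a small guard ring.
    """
    obs = obs or ObserverModel.default()
    spec.validate(obs)
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size_px

    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ay, ax = spec.animal.size_px
    ellipse = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    guard = binary_dilation(ellipse, iterations=spec.mask_guard_px)

    stack = _texture_stack((h, w), spec.background, obs, rng, region=~guard)

    # animal base = background base shifted by the boundary target contrasts
    bdf = _phase_log_offsets(
        spec.animal.boundary_chromatic_contrast,
        spec.animal.boundary_achromatic_contrast,
        obs,
    )
    animal_base = tuple(np.asarray(spec.background.base) * np.exp(bdf))
    animal_tex = replace(spec.animal, base=animal_base)
    animal_stack = _texture_stack((h, w), animal_tex, obs, rng, region=ellipse)

    # focal marking: offset the central patch by its target contrasts
    if spec.animal.marking_achromatic_contrast > 0 or spec.animal.marking_chromatic_contrast > 0:
        mdf = _phase_log_offsets(
            spec.animal.marking_chromatic_contrast,
            spec.animal.marking_achromatic_contrast,
            obs,
        )
        mf = spec.animal.marking_fraction
        marking = ((yy - cy) / (ay * mf)) ** 2 + ((xx - cx) / (ax * mf)) ** 2 <= 1.0
        animal_stack = animal_stack * np.where(
            marking[:, :, None], np.exp(mdf)[None, None, :], 1.0
        )
    stack = np.where(ellipse[:, :, None], animal_stack, stack)

    if spec.pixel_noise_sd > 0:
        stack = stack * rng.lognormal(
            mean=-0.5 * spec.pixel_noise_sd**2, sigma=spec.pixel_noise_sd, size=stack.shape
        )

    masks = RegionMasks(animal=ellipse, background=~guard)
    return ConeCatchImage(stack, spec.pixels_per_cm), masks


@dataclass(frozen=True)
class EffectMap:
    """Monotone coupling from unpalatability ``u`` to pattern properties.

    ``u`` raises the animal's internal chromatic/achromatic contrast above
    the background baseline (``*_contrast_gain``, ΔS added at u = 1) and —
    when fine patterning is enabled for defended species — shrinks its
    internal element size from the background's toward ``fine_element_px``
    (fraction ``element_shrink`` at u = 1), which together control
    animal/background dissimilarity at close range.  All gains must be
    ≥ 0 so each mapping is monotone in ``u``; zero gains give a null map.
    """

    achromatic_contrast_gain: float = 3.5
    chromatic_contrast_gain: float = 7.0
    element_shrink: float = 0.5
    fine_element_px: float = 5.0
    marking_achromatic_gain: float = 10.0
    marking_chromatic_gain: float = 4.0
    undefended_offset_achromatic: float = 1.5
    undefended_offset_chromatic: float = 1.0

    def validate(self) -> None:
        gains = (
            self.achromatic_contrast_gain,
            self.chromatic_contrast_gain,
            self.marking_achromatic_gain,
            self.marking_chromatic_gain,
        )
        if min(gains) < 0:
            raise SceneSpecError("effect_map contrast gains must be ≥ 0 (monotone)")
        if min(self.undefended_offset_achromatic, self.undefended_offset_chromatic) < 0:
            raise SceneSpecError("undefended offsets must be ≥ 0 (monotone)")
        if not (0.0 <= self.element_shrink <= 1.0):
            raise SceneSpecError("element_shrink must be in [0, 1]")
        if self.fine_element_px < 1:
            raise SceneSpecError("fine_element_px must be ≥ 1")

    def animal_texture(
        self, u: float, background: TextureSpec, fine_pattern: bool
    ) -> dict:
        self.validate()
        el = background.element_size_px
        if fine_pattern:
            el = el + self.element_shrink * u * (self.fine_element_px - el)
        return {
            "element_size_px": el,
            "chromatic_contrast": background.chromatic_contrast
            + self.chromatic_contrast_gain * u,
            "achromatic_contrast": background.achromatic_contrast
            + self.achromatic_contrast_gain * u,
            "marking_chromatic_contrast": self.marking_chromatic_gain * u,
            "marking_achromatic_contrast": self.marking_achromatic_gain * u,
            "boundary_chromatic_contrast": self.undefended_offset_chromatic * (1.0 - u) ** 2,
            "boundary_achromatic_contrast": self.undefended_offset_achromatic * (1.0 - u) ** 2,
        }


# class-conditional unpalatability ranges (before range normalisation)
_U_RANGES = {"NR": (0.0, 0.15), "II": (0.40, 0.62), "I_II": (0.70, 1.0)}


@dataclass(frozen=True)
class CohortSpec:
    """A multi-species cohort with defence classes and coupled patterns."""

    n_species: int = 13
    class_counts: tuple[int, int, int] = (3, 4, 6)  # NR, II, I_II
    individuals_per_species: tuple[int, ...] | int | None = None
    effect_map: EffectMap = field(default_factory=EffectMap)
    fine_pattern_for_defended: bool = True
    scene: SceneSpec = field(default_factory=SceneSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 3:
            raise SceneSpecError("need at least 3 species")
        if sum(self.class_counts) != self.n_species:
            raise SceneSpecError("class_counts must sum to n_species")
        if min(self.class_counts) < 1:
            raise SceneSpecError("need at least one species per defence class")
        self.effect_map.validate()

    def species_counts(self, rng) -> tuple[int, ...]:
        if self.individuals_per_species is None:
            if self.n_species == len(PAPER_STYLE_SPECIES_COUNTS):
                return PAPER_STYLE_SPECIES_COUNTS
            return tuple(int(n) for n in rng.integers(8, 28, size=self.n_species))
        if isinstance(self.individuals_per_species, int):
            return (self.individuals_per_species,) * self.n_species
        if len(self.individuals_per_species) != self.n_species:
            raise SceneSpecError("individuals_per_species length != n_species")
        return tuple(self.individuals_per_species)


def generate_cohort(
    cspec: CohortSpec, obs: ObserverModel | None = None
) -> tuple[list[tuple[ConeCatchImage, RegionMasks, dict]], pd.DataFrame]:
    """Generate scenes for a whole cohort plus its species metadata table.

    Species are assigned to defence classes in class-severity order; each
    species draws an unpalatability ``u`` from its class-conditional range
    and the cohort's ``u`` values are then range-normalised to [0, 1].
    Every individual's animal texture is derived from ``u`` through the
    effect map; defended species (classes II and I_II) receive fine-scale
    internal elements when ``fine_pattern_for_defended`` is set.
    Deterministic given ``cspec.seed``.
    """
    obs = obs or ObserverModel.default()
    cspec.validate()
    rng = np.random.default_rng(cspec.seed)
    counts = cspec.species_counts(rng)

    classes: list[str] = []
    for cls, k in zip(DEFENCE_CLASSES, cspec.class_counts):
        classes.extend([cls] * k)
    u_raw = np.array([rng.uniform(*_U_RANGES[c]) for c in classes])
    span = u_raw.max() - u_raw.min()
    u_norm = (u_raw - u_raw.min()) / span if span > 0 else np.zeros_like(u_raw)

    scenes: list[tuple[ConeCatchImage, RegionMasks, dict]] = []
    meta_rows = []
    for s_idx, (cls, n_ind, u) in enumerate(zip(classes, counts, u_norm)):
        species = f"sp{s_idx:02d}"
        fine = cspec.fine_pattern_for_defended and cls != "NR"
        tex_kwargs = cspec.effect_map.animal_texture(float(u), cspec.scene.background, fine)
        meta_rows.append(
            {
                "species": species,
                "defence_class": cls,
                "unpalatability": float(u),
                "n_individuals": n_ind,
                **{f"animal_{k}": v for k, v in tex_kwargs.items()},
            }
        )
        for i in range(n_ind):
            seed = int(rng.integers(0, 2**31 - 1))
            spec = replace(
                cspec.scene,
                animal=replace(cspec.scene.animal, **tex_kwargs),
                seed=seed,
            )
            img, masks = generate_scene(spec, obs)
            meta = {
                "individual_id": f"{species}_i{i:03d}",
                "species": species,
                "defence_class": cls,
                "unpalatability": float(u),
            }
            scenes.append((img, masks, meta))
    return scenes, pd.DataFrame(meta_rows)
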