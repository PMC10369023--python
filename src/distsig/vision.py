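"""Receptor-noise-limited (RNL) colour and luminance contrast.

Implements the log-linear RNL model for an arbitrary number of receptor
channels: pairwise chromatic contrast ``ΔS`` (in just-noticeable-difference
units), achromatic (luminance) contrast, and an isometric embedding of
stimuli into an ``(n-1)``-dimensional chromaticity space in which Euclidean
distance equals chromatic ``ΔS``.

Conventions
-----------
* Catch vectors are strictly positive linear receptor stimulations.
* Per-channel noise is expressed as Weber fractions ``e_i``; smaller values
  mean finer discrimination.
* Image stacks are ``(H, W, n_receptors + 1)`` with the chromatic channels
  first and the luminance channel last.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import yaml
from scipy.linalg import null_space

__all__ = [
    "ObserverModel",
    "ConeCatchImage",
    "RegionMasks",
    "ChannelDomainError",
    "ShapeMismatchError",
    "chromatic_delta_s",
    "achromatic_delta_s",
    "to_rnl_coordinates",
    "perceptual_coordinates",
    "weber_fractions_from_abundance",
]


class ChannelDomainError(ValueError):
    """A receptor catch or luminance value is outside its valid domain."""


class ShapeMismatchError(ValueError):
    """Input dimensions do not match the observer definition."""


def weber_fractions_from_abundance(unit_noise: float, abundances) -> tuple[float, ...]:
    """Convert relative receptor abundances to per-channel Weber fractions.

    Uses ``e_i = unit_noise / sqrt(eta_i)`` where ``eta_i`` is the relative
    abundance of channel ``i``.  Provided as a convenience; observers store
    ``e_i`` directly.
    """
    eta = np.asarray(abundances, dtype=float)
    if unit_noise <= 0:
        raise ValueError("unit_noise must be positive")
    if np.any(eta <= 0):
        raise ValueError("abundances must be positive")
    return tuple(unit_noise / np.sqrt(eta))


@dataclass(frozen=True)
class ObserverModel:
    """Receptor-noise and spatial-acuity parameters of a visual system.

    Parameters
    ----------
    weber_fractions
        Per-chromatic-channel Weber fractions ``e_i`` (dimensionless, > 0).
    luminance_weber
        Weber fraction of the achromatic (luminance) channel.
    acuity_cpd
        Spatial acuity in cycles per degree.

    The default observer (:meth:`default`) is a trichromat with Weber
    fractions ``(0.05, 0.05, 0.05)``, luminance Weber ``0.05`` and an acuity
    of 3 cpd.  These are literature-derived placeholders for a
    triggerfish-like reef predator and are fully overridable.
    """

    weber_fractions: tuple[float, ...] = (0.05, 0.05, 0.05)
    luminance_weber: float = 0.05
    acuity_cpd: float = 3.0

    def __post_init__(self) -> None:
        wf = tuple(float(w) for w in self.weber_fractions)
        object.__setattr__(self, "weber_fractions", wf)
        if len(wf) < 2:
            raise ValueError("an observer needs at least two chromatic channels")
        if any(w <= 0 for w in wf):
            raise ValueError("all Weber fractions must be positive")
        if self.luminance_weber <= 0:
            raise ValueError("luminance Weber fraction must be positive")
        if self.acuity_cpd <= 0:
            raise ValueError("acuity_cpd must be positive")

    @property
    def n_receptors(self) -> int:
        return len(self.weber_fractions)

    @property
    def n_channels(self) -> int:
        """Total stack channels: chromatic receptors plus luminance."""
        return self.n_receptors + 1

    @classmethod
    def default(cls) -> "ObserverModel":
        return cls()

    @classmethod
    def from_config(cls, source) -> "ObserverModel":
        """Build an observer from a dict or a YAML/JSON file path.

        Recognised keys (optionally nested under ``observer``):
        ``weber_fractions``, ``luminance_weber``, ``acuity_cpd``.
        """
        if isinstance(source, (str, Path)):
            text = Path(source).read_text()
            if str(source).endswith(".json"):
                data = json.loads(text)
            else:
                data = yaml.safe_load(text)
        else:
            data = dict(source)
        if "observer" in data:
            data = data["observer"]
        return cls(
            weber_fractions=tuple(data["weber_fractions"]),
            luminance_weber=float(data["luminance_weber"]),
            acuity_cpd=float(data.get("acuity_cpd", 3.0)),
        )


@lru_cache(maxsize=32)
def _chromatic_map(weber_fractions: tuple[float, ...]) -> np.ndarray:
    """Linear map M with ``coords = M @ ln(q)`` isometric for chromatic ΔS.

    With weights ``w_i = 1 / e_i**2`` the squared chromatic contrast equals
    the squared norm of ``sqrt(w) * Δf`` projected onto the hyperplane
    orthogonal to ``sqrt(w)``; M composes that projection with the scaling.
    """
    w = 1.0 / np.asarray(weber_fractions, dtype=float) ** 2
    sw = np.sqrt(w)
    u = (sw / np.linalg.norm(sw))[None, :]
    basis = null_space(u)  # (n, n-1), orthonormal columns
    return basis.T * sw[None, :]


def _validate_catch(q, n_receptors: int, name: str) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape != (n_receptors,):
        raise ShapeMismatchError(
            f"{name} has shape {q.shape}, expected ({n_receptors},)"
        )
    bad = np.flatnonzero(~(q > 0))
    if bad.size:
        raise ChannelDomainError(
            f"{name} has non-positive catch in channel {bad[0]} ({q[bad[0]]!r})"
        )
    return q


def chromatic_delta_s(q_a, q_b, obs: ObserverModel) -> float:
    """Chromatic contrast ΔS between two catch vectors, in JND units.

    Uses log receptor contrasts ``Δf_i = ln(q_a_i / q_b_i)`` and the
    noise-weighted quadratic form of the n-receptor RNL model, written in
    its weighted-variance formulation::

        ΔS² = Σ w_i Δf_i² − (Σ w_i Δf_i)² / Σ w_i,   w_i = 1 / e_i²

    which is algebraically identical to the pairwise opponent form
    ``Σ_{i<j} w_i w_j (Δf_i − Δf_j)² / Σ w_i``.
    """
    q_a = _validate_catch(q_a, obs.n_receptors, "q_a")
    q_b = _validate_catch(q_b, obs.n_receptors, "q_b")
    df = np.log(q_a) - np.log(q_b)
    w = 1.0 / np.asarray(obs.weber_fractions) ** 2
    s2 = float(np.dot(w, df**2) - np.dot(w, df) ** 2 / w.sum())
    return float(np.sqrt(max(s2, 0.0)))


def achromatic_delta_s(l_a: float, l_b: float, obs: ObserverModel) -> float:
    """Achromatic contrast ``|ln(l_a / l_b)| / ω_lum`` in JND units."""
    if not (l_a > 0 and l_b > 0):
        raise ChannelDomainError(
            f"luminance values must be positive (got {l_a!r}, {l_b!r})"
        )
    return abs(float(np.log(l_a / l_b))) / obs.luminance_weber


def to_rnl_coordinates(q, obs: ObserverModel) -> np.ndarray:
    """Embed a catch vector into (n-1)-dimensional RNL chromaticity space.

    Euclidean distance between the coordinates of two stimuli equals their
    :func:`chromatic_delta_s`.  The basis is an arbitrary (but fixed and
    deterministic) orthonormal choice; only distances are meaningful.
    """
    q = _validate_catch(q, obs.n_receptors, "q")
    return _chromatic_map(obs.weber_fractions) @ np.log(q)


def perceptual_coordinates(stack: np.ndarray, obs: ObserverModel) -> np.ndarray:
    """Per-pixel perceptual coordinates for an ``(H, W, n+1)`` stack.

    Returns an ``(H, W, n)`` array: the first ``n-1`` axes are RNL
    chromaticity coordinates, the last is luminance ``ln(l)/ω``; Euclidean
    distance in the full space is the combined contrast
    ``sqrt(chromaticΔS² + achromaticΔS²)``.
    """
    if stack.shape[-1] != obs.n_channels:
        raise ShapeMismatchError(
            f"stack has {stack.shape[-1]} channels, observer expects {obs.n_channels}"
        )
    logq = np.log(stack[..., : obs.n_receptors])
    chrom = logq @ _chromatic_map(obs.weber_fractions).T
    achro = np.log(stack[..., -1:]) / obs.luminance_weber
    return np.concatenate([chrom, achro], axis=-1)


@dataclass
class ConeCatchImage:
    """A linear cone-catch stack with spatial calibration.

    ``stack`` is ``(H, W, n_receptors + 1)``: chromatic channels first,
    luminance last.  On construction every channel is floored at
    ``floor_rel`` times its maximum so that downstream log transforms are
    defined even for dark pixels.
    """

    stack: np.ndarray
    pixels_per_cm: float
    floor_rel: float = 1e-6

    def __post_init__(self) -> None:
        stack = np.asarray(self.stack, dtype=float)
        if stack.ndim != 3 or stack.shape[-1] < 3:
            raise ShapeMismatchError(
                f"stack must be (H, W, n_receptors+1) with ≥3 channels, got {stack.shape}"
            )
        if self.pixels_per_cm <= 0:
            raise ValueError("pixels_per_cm must be positive")
        if np.any(~np.isfinite(stack)) or np.any(stack < 0):
            raise ChannelDomainError("stack contains negative or non-finite values")
        if self.floor_rel > 0:
            floor = self.floor_rel * np.maximum(
                stack.reshape(-1, stack.shape[-1]).max(axis=0), 1.0e-30
            )
            stack = np.maximum(stack, floor[None, None, :])
        elif np.any(stack <= 0):
            raise ChannelDomainError(
                "stack has non-positive values and flooring is disabled"
            )
        self.stack = stack

    @property
    def shape(self) -> tuple[int, int]:
        return self.stack.shape[:2]

    @property
    def n_channels(self) -> int:
        return self.stack.shape[-1]

    @property
    def chromatic(self) -> np.ndarray:
        return self.stack[..., :-1]

    @property
    def luminance(self) -> np.ndarray:
        return self.stack[..., -1]

    def validate_against(self, obs: ObserverModel) -> None:
        if self.n_channels != obs.n_channels:
            raise ShapeMismatchError(
                f"image has {self.n_channels} channels but observer expects "
                f"{obs.n_channels} ({obs.n_receptors} chromatic + luminance)"
            )


@dataclass
class RegionMasks:
    """Boolean animal / background masks tied to one scene."""

    animal: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        self.animal = np.asarray(self.animal, dtype=bool)
        self.background = np.asarray(self.background, dtype=bool)
        if self.animal.shape != self.background.shape:
            raise ShapeMismatchError("animal and background masks differ in shape")
        if not self.animal.any():
            raise ValueError("animal mask is empty")
        if not self.background.any():
            raise ValueError("background mask is empty")
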