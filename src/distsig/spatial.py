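"""Distance-dependent image transformations.

The preprocessing chain applied before edge statistics are measured:
Gaussian acuity modelling (viewing-distance-dependent blur) followed by
RNL ranked filtering (edge-preserving perceptual smoothing).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.ndimage import gaussian_filter

from .vision import ConeCatchImage, ObserverModel, perceptual_coordinates

__all__ = ["acuity_sigma_px", "acuity_blur", "rnl_ranked_filter"]


def acuity_sigma_px(
    viewing_distance_cm: float,
    acuity_cpd: float,
    pixels_per_cm: float,
    k_cycle_to_sigma: float = 2.0,
) -> float:
    """Blur standard deviation, in pixels, at a given viewing distance.

    One resolvable cycle at the acuity limit subtends
    ``θ = (1/acuity_cpd) · π/180`` radians (small-angle approximation);
    its size on the scene at distance ``d`` is ``d·θ`` cm.  The Gaussian
    sigma is that cycle divided by ``k_cycle_to_sigma`` (default 2, i.e.
    one cycle ≈ 2σ).
    """
    if viewing_distance_cm <= 0:
        raise ValueError("viewing distance must be positive")
    if k_cycle_to_sigma <= 0:
        raise ValueError("k_cycle_to_sigma must be positive")
    theta = (1.0 / acuity_cpd) * math.pi / 180.0
    return viewing_distance_cm * theta * pixels_per_cm / k_cycle_to_sigma


def acuity_blur(
    img: ConeCatchImage,
    obs: ObserverModel,
    viewing_distance_cm: float,
    k_cycle_to_sigma: float = 2.0,
) -> ConeCatchImage:
    """Blur every channel with the distance-appropriate isotropic Gaussian.

    Uses reflective boundary handling so channel totals are conserved and
    edge statistics are not biased by frame darkening.  Dimensions (and
    hence mask alignment) are unchanged.
    """
    img.validate_against(obs)
    sigma = acuity_sigma_px(
        viewing_distance_cm, obs.acuity_cpd, img.pixels_per_cm, k_cycle_to_sigma
    )
    if sigma == 0.0:
        out = img.stack.copy()
    else:
        out = gaussian_filter(img.stack, sigma=(sigma, sigma, 0.0), mode="reflect")
    return ConeCatchImage(out, img.pixels_per_cm, floor_rel=0.0)


def rnl_ranked_filter(
    img: ConeCatchImage,
    obs: ObserverModel,
    radius_px: int = 2,
    n_iter: int = 5,
    keep_fraction: float = 0.5,
) -> ConeCatchImage:
    """Iterative edge-preserving smoothing driven by perceptual similarity.

    Per iteration each pixel is replaced by the channelwise mean of the
    subset of its ``(2r+1)²`` kernel neighbours (centre included, reflective
    padding) that rank nearest to the centre pixel by combined contrast
    ``sqrt(chromaticΔS² + achromaticΔS²)``; ``ceil(keep_fraction · kernel)``
    neighbours are kept.  ``keep_fraction = 1`` reduces one iteration to an
    unweighted box mean; a channelwise-constant image is a fixed point, and
    outputs never leave the convex hull of the input channel values.
    """
    img.validate_against(obs)
    if radius_px < 1:
        raise ValueError("radius_px must be ≥ 1")
    if n_iter < 1:
        raise ValueError("n_iter must be ≥ 1")
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError("keep_fraction must be in (0, 1]")
    h, w, c = img.stack.shape
    k = 2 * radius_px + 1
    if k > h or k > w:
        raise ValueError(f"kernel {k}×{k} exceeds image {h}×{w}")
    n_keep = math.ceil(keep_fraction * k * k)

    stack = img.stack
    swv = np.lib.stride_tricks.sliding_window_view
    for _ in range(n_iter):
        pad = np.pad(stack, ((radius_px,) * 2, (radius_px,) * 2, (0, 0)), mode="reflect")
        coords = perceptual_coordinates(pad, obs)
        centre = coords[radius_px : radius_px + h, radius_px : radius_px + w]
        # (h, w, n, k, k) perceptual windows; ranking uses squared distance
        cwin = swv(coords, (k, k), axis=(0, 1))
        d2 = ((cwin - centre[..., None, None]) ** 2).sum(axis=2).reshape(h, w, k * k)
        vwin = swv(pad, (k, k), axis=(0, 1)).reshape(h, w, c, k * k)
        if n_keep < k * k:
            sel = np.argpartition(d2, n_keep - 1, axis=-1)[..., :n_keep]
            kept = np.take_along_axis(vwin, sel[:, :, None, :], axis=-1)
        else:
            kept = vwin
        stack = np.ascontiguousarray(kept.mean(axis=-1))
    return ConeCatchImage(stack, img.pixels_per_cm, floor_rel=0.0)
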