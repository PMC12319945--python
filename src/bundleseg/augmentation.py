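"""Anatomy-constrained positive-pair construction and geometric augmentation.

Positive pairs for the contrastive loss are built by cropping a second patch
whose center lies within a small physical distance of the anchor (< 20 um by
default), constrained to white matter either by an explicit mask or by
iteratively resampling until the candidate's mean intensity falls in a
configured band typical of white-matter background.  The partner patch is
then perturbed by additive Gaussian noise followed by Gaussian blur with a
randomly chosen sigma.

Geometric augmentation for segmentation training applies one spatial
transform (translation, rotation, flips, scaling) to the image (bilinear) and
its label map (nearest neighbour).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .io import Section, extract_patch

__all__ = ["PairPolicy", "GeomPolicy", "make_positive_pair", "geometric_augment"]

logger = logging.getLogger(__name__)


@dataclass
class PairPolicy:
    max_crop_offset_um: float = 20.0
    wm_mean_intensity_range: tuple[float, float] = (0.04, 0.35)
    max_resample_attempts: int = 50
    noise_std: float = 0.02
    blur_sigma_range: tuple[float, float] = (0.05, 0.3)
    wm_min_coverage: float = 0.8
    augment_both: bool = False  # noise+blur on both patches instead of only the second

    def __post_init__(self) -> None:
        if self.max_crop_offset_um < 0:
            raise ValueError("offset must be >= 0")
        if self.blur_sigma_range[0] > self.blur_sigma_range[1]:
            raise ValueError("blur_sigma_range low must be <= high")


@dataclass
class GeomPolicy:
    translation_px: tuple[float, float] = (-50.0, 50.0)
    rotation_deg: tuple[float, float] = (-20.0, 20.0)
    hflip: bool = True
    vflip: bool = True
    scale: tuple[float, float] = (0.9, 1.2)


def _noise_and_blur(patch: np.ndarray, policy: PairPolicy, rng) -> np.ndarray:
    out = patch + rng.normal(0.0, policy.noise_std, size=patch.shape).astype(np.float32)
    sigma = rng.uniform(*policy.blur_sigma_range)
    out = ndi.gaussian_filter(out, sigma=(sigma, sigma, 0.0))
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def make_positive_pair(
    section: Section,
    anchor_xy: tuple[int, int],
    policy: PairPolicy,
    wm_mask: np.ndarray | None = None,
    seed: int = 0,
    patch_size: int = 256,
    return_info: bool = False,
):
    """Build (anchor patch, augmented nearby patch) centered at ``anchor_xy`` = (row, col).

    With ``return_info`` a third element reports the partner's center, the
    number of sampling attempts, and whether the anchor fallback was used.
    """
    rng = np.random.default_rng(seed)
    img = section.image
    max_off_px = policy.max_crop_offset_um / section.um_per_px
    patch_a = extract_patch(img, anchor_xy, patch_size).astype(np.float32)

    chosen = None
    attempts = 0
    center = tuple(anchor_xy)
    for attempts in range(1, max(1, policy.max_resample_attempts) + 1):
        theta = rng.uniform(0, 2 * np.pi)
        radius = rng.uniform(0, max_off_px)
        dr = int(round(radius * np.sin(theta)))
        dc = int(round(radius * np.cos(theta)))
        center = (anchor_xy[0] + dr, anchor_xy[1] + dc)
        cand = extract_patch(img, center, patch_size).astype(np.float32)
        if wm_mask is not None:
            cover = extract_patch(wm_mask.astype(np.float32), center, patch_size).mean()
            ok = cover >= policy.wm_min_coverage
        else:
            lo, hi = policy.wm_mean_intensity_range
            ok = lo <= float(cand.mean()) <= hi
        if ok:
            chosen = cand
            break
    fallback = chosen is None
    if fallback:
        logger.warning(
            "no valid positive-pair sample after %d attempts; falling back to anchor",
            policy.max_resample_attempts,
        )
        chosen = patch_a.copy()
        center = tuple(anchor_xy)

    patch_b = _noise_and_blur(chosen, policy, rng)
    if policy.augment_both:
        patch_a = _noise_and_blur(patch_a, policy, rng)
    if return_info:
        return patch_a, patch_b, dict(center=center, attempts=attempts, fallback=fallback)
    return patch_a, patch_b


def geometric_augment(
    patch: np.ndarray,
    pixel_labels: np.ndarray | None,
    policy: GeomPolicy,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Apply one random spatial transform to a patch and its label map.

    The image is interpolated bilinearly and the labels with nearest neighbour,
    so label values remain a subset of the input's values.
    """
    if pixel_labels is not None and pixel_labels.shape != patch.shape[:2]:
        raise ValueError("labels must match patch spatial size")
    rng = np.random.default_rng(seed)
    ty = rng.uniform(*policy.translation_px)
    tx = rng.uniform(*policy.translation_px)
    theta = np.deg2rad(rng.uniform(*policy.rotation_deg))
    s = rng.uniform(*policy.scale)
    fh = bool(policy.hflip and rng.random() < 0.5)
    fv = bool(policy.vflip and rng.random() < 0.5)

    h, w = patch.shape[:2]
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    ca, sa = np.cos(theta), np.sin(theta)
    rot = np.array([[ca, -sa], [sa, ca]]) * s
    if fv:
        rot = rot @ np.diag([-1.0, 1.0])
    if fh:
        rot = rot @ np.diag([1.0, -1.0])
    # output coordinate y maps to input coordinate: inv(rot) @ (y - center - t) + center
    inv = np.linalg.inv(rot)
    offset = center - inv @ (center + np.array([ty, tx]))

    def _warp(arr: np.ndarray, order: int) -> np.ndarray:
        if arr.ndim == 3:
            out = np.stack(
                [
                    ndi.affine_transform(
                        arr[..., c], inv, offset=offset, order=order, mode="reflect"
                    )
                    for c in range(arr.shape[2])
                ],
                axis=-1,
            )
        else:
            out = ndi.affine_transform(arr, inv, offset=offset, order=order, mode="reflect")
        return out

    patch_out = _warp(np.asarray(patch, dtype=np.float32), order=1).astype(np.float32)
    labels_out = None
    if pixel_labels is not None:
        labels_out = _warp(np.asarray(pixel_labels, dtype=np.float32), order=0)
        labels_out = labels_out.astype(pixel_labels.dtype)
    return patch_out, labels_out
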