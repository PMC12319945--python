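"""False-positive removal with continuity priors and morphological filters.

True fiber bundles persist across consecutive sections (1.2 mm apart), while
most false positives (terminal fields, glare, noise) do not.  The sections
are downsampled by a factor of 10, roughly aligned by translation (on the
centroid of the largest interior cavity — a ventricle proxy — or, failing
that, the tissue bounding box) into an approximate 3D volume.  A pluggable
consensus stage produces a low-resolution 3D segmentation of the main dense
bundles (the default z-averages neighbouring probability maps with a small
3D smoothing kernel and thresholds).  Each detected region in a section is
then removed if it lies more than 0.5 mm (in plane) from the averaged
consensus bundles of its up to two nearest neighbouring sections.

A second, morphological pass rejects regions smaller than 2 mm^2 and regions
closer than 0.5 mm to the tissue outline.

Filters only ever delete regions; survivor masks are returned unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.transform import downscale_local_mean

from .io import Section, px_to_mm2
from .inference import ProbabilityMap

__all__ = [
    "Region",
    "RegionSet",
    "StackVolume",
    "regions_from_mask",
    "estimate_tissue_mask",
    "build_stack",
    "stack_consensus",
    "neighbor_reference_masks",
    "continuity_filter",
    "morphology_filter",
    "postprocess_stack",
]


@dataclass
class Region:
    mask: np.ndarray  # full-resolution boolean mask
    area_mm2: float
    centroid_xy_px: tuple[float, float]  # (x, y) = (col, row)
    min_border_dist_mm: float | None = None
    matched_bundle_id: int | None = None


@dataclass
class RegionSet:
    section_index: int
    um_per_px: float
    shape: tuple[int, int]
    regions: list[Region] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.regions)

    def union_mask(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        for r in self.regions:
            out |= r.mask
        return out


def regions_from_mask(
    binary_mask: np.ndarray, um_per_px: float, section_index: int = 0
) -> RegionSet:
    """Connected components of a binary mask with physical areas."""
    lab = measure.label(np.asarray(binary_mask, dtype=bool), connectivity=2)
    regions = []
    for prop in measure.regionprops(lab):
        mask = lab == prop.label
        regions.append(
            Region(
                mask=mask,
                area_mm2=px_to_mm2(prop.area, um_per_px),
                centroid_xy_px=(prop.centroid[1], prop.centroid[0]),
            )
        )
    return RegionSet(
        section_index=section_index,
        um_per_px=um_per_px,
        shape=binary_mask.shape,
        regions=regions,
    )


def estimate_tissue_mask(section: Section, threshold: float = 0.04) -> np.ndarray:
    """Largest bright connected component with holes filled."""
    gray = section.image.mean(axis=2)
    fg = gray > threshold
    lab, n = ndi.label(fg)
    if n == 0:
        return fg
    sizes = ndi.sum_labels(fg, lab, index=np.arange(1, n + 1))
    main = lab == (1 + int(np.argmax(sizes)))
    return ndi.binary_fill_holes(main)


# ---------------------------------------------------------------------------
# stack building and consensus
# ---------------------------------------------------------------------------

@dataclass
class StackVolume:
    volume: np.ndarray  # n_sections x H' x W' aligned low-res probability maps
    offsets: list[tuple[int, int]]  # per-section (row, col) shift applied (low-res px)
    pad: list[tuple[int, int]]  # per-section (pad_h, pad_w) applied before shifting
    downsample: int
    um_per_px: float  # at full resolution
    section_indices: list[int] = field(default_factory=list)


def _landmark(section: Section, tissue_threshold: float = 0.04) -> tuple[float, float]:
    """Ventricle-proxy centroid, else the tissue bounding-box center."""
    tissue = estimate_tissue_mask(section, tissue_threshold)
    filled = ndi.binary_fill_holes(tissue)
    gray = section.image.mean(axis=2)
    cavities = filled & (gray <= tissue_threshold)
    lab, n = ndi.label(cavities)
    if n:
        sizes = ndi.sum_labels(cavities, lab, index=np.arange(1, n + 1))
        best = int(np.argmax(sizes))
        if sizes[best] >= 50:  # px; ignore speckle-scale cavities
            com = ndi.center_of_mass(lab == best + 1)
            return float(com[0]), float(com[1])
    rows, cols = np.nonzero(filled)
    if len(rows) == 0:
        return section.shape[0] / 2.0, section.shape[1] / 2.0
    return (
        (rows.min() + rows.max()) / 2.0,
        (cols.min() + cols.max()) / 2.0,
    )


def _shift_zero(arr: np.ndarray, dr: int, dc: int) -> np.ndarray:
    out = np.zeros_like(arr)
    h, w = arr.shape
    r0s, r0d = (dr, 0) if dr < 0 else (0, dr)
    c0s, c0d = (dc, 0) if dc < 0 else (0, dc)
    hh = h - abs(dr)
    ww = w - abs(dc)
    if hh > 0 and ww > 0:
        out[r0d : r0d + hh, c0d : c0d + ww] = arr[abs(r0s) : abs(r0s) + hh,
                                                  abs(c0s) : abs(c0s) + ww]
    return out


def build_stack(
    sections: list[Section],
    probability_maps: list[ProbabilityMap],
    downsample: int = 10,
) -> StackVolume:
    """Downsample, landmark-align (translation only), and stack probability maps."""
    if len(sections) < 2:
        raise ValueError("continuity requires at least 2 sections")
    if len(sections) != len(probability_maps):
        raise ValueError("sections and probability maps must correspond 1:1")

    lows, landmarks, pads = [], [], []
    hmax = max(int(np.ceil(s.shape[0] / downsample)) for s in sections)
    wmax = max(int(np.ceil(s.shape[1] / downsample)) for s in sections)
    for sec, pmap in zip(sections, probability_maps):
        p = pmap.probs
        h, w = p.shape
        ph = int(np.ceil(h / downsample)) * downsample - h
        pw = int(np.ceil(w / downsample)) * downsample - w
        low = downscale_local_mean(np.pad(p, ((0, ph), (0, pw))), (downsample, downsample))
        pad_h, pad_w = hmax - low.shape[0], wmax - low.shape[1]
        low = np.pad(low, ((0, pad_h), (0, pad_w)))
        lows.append(low.astype(np.float32))
        pads.append((pad_h, pad_w))
        lm = _landmark(sec)
        landmarks.append((lm[0] / downsample, lm[1] / downsample))

    ref = landmarks[0]
    offsets = []
    vol = np.zeros((len(sections), hmax, wmax), dtype=np.float32)
    for i, (low, lm) in enumerate(zip(lows, landmarks)):
        dr = int(round(ref[0] - lm[0]))
        dc = int(round(ref[1] - lm[1]))
        offsets.append((dr, dc))
        vol[i] = _shift_zero(low, dr, dc)
    return StackVolume(
        volume=vol,
        offsets=offsets,
        pad=pads,
        downsample=downsample,
        um_per_px=sections[0].um_per_px,
        section_indices=[s.section_index for s in sections],
    )


def stack_consensus(
    stack: StackVolume,
    threshold: float = 0.4,
    segmenter: Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Low-res 3D mask of the main dense bundles.

    The default stage averages z-adjacent probability maps with a small 3D
    mean kernel and thresholds at the inference threshold; any user-supplied
    3D segmenter with signature ``volume -> bool volume`` may replace it.
    """
    if segmenter is not None:
        return np.asarray(segmenter(stack.volume), dtype=bool)
    if stack.volume.size == 0:
        return np.zeros_like(stack.volume, dtype=bool)
    smoothed = ndi.uniform_filter(stack.volume, size=(3, 3, 3), mode="nearest")
    return smoothed >= threshold


def neighbor_reference_masks(
    stack: StackVolume,
    consensus: np.ndarray,
    position: int,
    full_shape: tuple[int, int],
) -> list[np.ndarray]:
    """Full-resolution consensus masks of the up to two nearest neighbours.

    ``position`` indexes into the stack (not the section_index).  Each
    neighbour's low-res consensus slice is shifted back into that section's
    own frame, upsampled by the stack's downsampling factor, and cropped to
    the full-resolution shape.
    """
    masks = []
    d = stack.downsample
    for j in (position - 1, position + 1):
        if not 0 <= j < stack.volume.shape[0]:
            continue
        low = consensus[j].astype(np.float32)
        dr, dc = stack.offsets[j]
        low = _shift_zero(low, -dr, -dc)
        full = np.repeat(np.repeat(low, d, axis=0), d, axis=1)
        full = full[: full_shape[0], : full_shape[1]]
        if full.shape != tuple(full_shape):
            full = np.pad(
                full,
                ((0, full_shape[0] - full.shape[0]), (0, full_shape[1] - full.shape[1])),
            )
        masks.append(full >= 0.5)
    return masks


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def continuity_filter(
    regions: RegionSet,
    neighbor_masks: list[np.ndarray],
    max_dist_mm: float = 0.5,
) -> RegionSet:
    """Remove regions farther than ``max_dist_mm`` from the averaged neighbour bundles.

    The reference mask is the mean of the available neighbour masks thresholded
    at 0.5 (>= convention).  Distance is the minimum in-plane Euclidean
    distance from any region pixel to the reference foreground; an empty
    reference removes every region.
    """
    if not neighbor_masks:
        raise ValueError("at least one neighbour mask is required")
    for m in neighbor_masks:
        if m.shape != regions.shape:
            raise ValueError("neighbour mask resolution does not match the section")
    ref = np.mean([m.astype(np.float32) for m in neighbor_masks], axis=0) >= 0.5
    if not ref.any():
        return RegionSet(regions.section_index, regions.um_per_px, regions.shape, [])
    dist_mm = ndi.distance_transform_edt(~ref) * regions.um_per_px / 1000.0
    survivors = [r for r in regions.regions if dist_mm[r.mask].min() <= max_dist_mm]
    return RegionSet(regions.section_index, regions.um_per_px, regions.shape, survivors)


def morphology_filter(
    regions: RegionSet,
    tissue_mask: np.ndarray,
    min_area_mm2: float = 2.0,
    min_border_dist_mm: float = 0.5,
) -> RegionSet:
    """Keep regions with area >= ``min_area_mm2`` and >= ``min_border_dist_mm`` from the outline."""
    if tissue_mask.shape != regions.shape:
        raise ValueError("tissue mask must match the section shape")
    border_dist_mm = (
        ndi.distance_transform_edt(tissue_mask) * regions.um_per_px / 1000.0
    )
    survivors = []
    for r in regions.regions:
        d = float(border_dist_mm[r.mask].min()) if r.mask.any() else 0.0
        r.min_border_dist_mm = d
        if r.area_mm2 >= min_area_mm2 and d >= min_border_dist_mm:
            survivors.append(r)
    return RegionSet(regions.section_index, regions.um_per_px, regions.shape, survivors)


def postprocess_stack(
    sections: list[Section],
    probability_maps: list[ProbabilityMap],
    threshold: float = 0.4,
    tissue_masks: list[np.ndarray] | None = None,
    min_area_mm2: float = 2.0,
    min_border_dist_mm: float = 0.5,
    max_dist_mm: float = 0.5,
    downsample: int = 10,
    use_continuity: bool = True,
    use_morphology: bool = True,
    segmenter: Callable[[np.ndarray], np.ndarray] | None = None,
) -> list[RegionSet]:
    """Binarize, then apply continuity and morphological filters to every section."""
    from .inference import binarize

    region_sets = [
        regions_from_mask(binarize(p, threshold), s.um_per_px, s.section_index)
        for s, p in zip(sections, probability_maps)
    ]
    if use_continuity and len(sections) >= 2:
        stack = build_stack(sections, probability_maps, downsample=downsample)
        consensus = stack_consensus(stack, threshold=threshold, segmenter=segmenter)
        filtered = []
        for pos, rs in enumerate(region_sets):
            masks = neighbor_reference_masks(stack, consensus, pos, rs.shape)
            filtered.append(continuity_filter(rs, masks, max_dist_mm=max_dist_mm))
        region_sets = filtered
    if use_morphology:
        if tissue_masks is None:
            tissue_masks = [estimate_tissue_mask(s) for s in sections]
        region_sets = [
            morphology_filter(rs, tm, min_area_mm2, min_border_dist_mm)
            for rs, tm in zip(region_sets, tissue_masks)
        ]
    return region_sets
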