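"""Continuity and morphology false-positive filters."""

import numpy as np
import pytest

from bundleseg.inference import ProbabilityMap
from bundleseg.io import Section
from bundleseg.postprocess import (
    RegionSet,
    StackVolume,
    build_stack,
    continuity_filter,
    estimate_tissue_mask,
    morphology_filter,
    neighbor_reference_masks,
    regions_from_mask,
    stack_consensus,
)

UM = 100.0  # 100 um/px -> 1 px = 0.1 mm; 2 mm^2 = 200 px


def _disk(shape, center, radius):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _regions(masks, shape=(128, 128)):
    lab = np.zeros(shape, dtype=bool)
    for m in masks:
        lab |= m
    return regions_from_mask(lab, um_per_px=UM)


class TestRegionsFromMask:
    def test_areas_and_centroids(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[10:20, 10:30] = True  # 200 px = 2.0 mm^2 at 100 um/px
        rs = regions_from_mask(mask, um_per_px=UM)
        assert len(rs) == 1
        assert rs.regions[0].area_mm2 == pytest.approx(2.0)
        assert rs.regions[0].centroid_xy_px == pytest.approx((19.5, 14.5))


class TestMorphologyFilter:
    def test_area_rule(self):
        shape = (128, 128)
        tissue = np.ones(shape, dtype=bool)
        small = np.zeros(shape, dtype=bool)
        small[60:70, 60:75] = True  # 150 px = 1.5 mm^2
        big = np.zeros(shape, dtype=bool)
        big[20:30, 20:45] = True  # 250 px = 2.5 mm^2
        rs = _regions([small, big], shape)
        out = morphology_filter(rs, tissue, min_area_mm2=2.0, min_border_dist_mm=0.5)
        assert len(out) == 1
        assert out.regions[0].area_mm2 == pytest.approx(2.5)

    def test_border_touching_removed(self):
        shape = (64, 64)
        tissue = np.ones(shape, dtype=bool)
        touching = np.zeros(shape, dtype=bool)
        touching[0:30, 0:30] = True
        rs = _regions([touching], shape)
        out = morphology_filter(rs, tissue, min_area_mm2=2.0, min_border_dist_mm=0.5)
        assert len(out) == 0

    def test_empty_input(self):
        rs = RegionSet(0, UM, (32, 32), [])
        out = morphology_filter(rs, np.ones((32, 32), dtype=bool))
        assert len(out) == 0

    def test_survivor_masks_unchanged(self):
        shape = (128, 128)
        tissue = np.ones(shape, dtype=bool)
        big = np.zeros(shape, dtype=bool)
        big[30:50, 30:50] = True
        rs = _regions([big], shape)
        out = morphology_filter(rs, tissue)
        np.testing.assert_array_equal(out.regions[0].mask, rs.regions[0].mask)


class TestContinuityFilter:
    def test_overlapping_region_kept(self):
        shape = (64, 64)
        reg = np.zeros(shape, dtype=bool)
        reg[20:30, 20:30] = True
        rs = _regions([reg], shape)
        out = continuity_filter(rs, [reg.copy()], max_dist_mm=0.5)
        assert len(out) == 1

    def test_distant_region_removed(self):
        shape = (64, 64)
        reg = np.zeros(shape, dtype=bool)
        reg[5:10, 5:10] = True
        ref = np.zeros(shape, dtype=bool)
        ref[40:45, 40:45] = True  # ~ 4-5 mm away at 100 um/px
        rs = _regions([reg], shape)
        out = continuity_filter(rs, [ref], max_dist_mm=0.5)
        assert len(out) == 0

    def test_empty_reference_removes_all(self):
        shape = (64, 64)
        reg = np.zeros(shape, dtype=bool)
        reg[20:30, 20:30] = True
        rs = _regions([reg], shape)
        out = continuity_filter(rs, [np.zeros(shape, dtype=bool)], max_dist_mm=0.5)
        assert len(out) == 0

    def test_two_neighbor_mean_threshold(self):
        """mean of two binary masks >= 0.5 behaves as their union."""
        shape = (64, 64)
        reg = np.zeros(shape, dtype=bool)
        reg[10:14, 10:14] = True
        n1 = np.zeros(shape, dtype=bool)
        n1[11:13, 11:13] = True
        n2 = np.zeros(shape, dtype=bool)
        rs = _regions([reg], shape)
        assert len(continuity_filter(rs, [n1, n2], max_dist_mm=0.5)) == 1

    def test_requires_neighbors(self):
        rs = RegionSet(0, UM, (8, 8), [])
        with pytest.raises(ValueError):
            continuity_filter(rs, [], max_dist_mm=0.5)


class TestBuildStack:
    def _section(self, img):
        return Section(image=img, um_per_px=UM)

    def _synthetic_pair(self, shift=(0, 0)):
        rngl = np.random.default_rng(0)
        base = np.full((200, 200), 0.01, dtype=np.float32)
        tissue = _disk((200, 200), (100, 100), 80)
        base[tissue] = 0.15
        cavity = _disk((200, 200), (100, 100), 10)
        base[cavity] = 0.01
        img0 = np.stack([base] * 3, axis=-1)
        img1 = np.roll(img0, shift, axis=(0, 1))
        p0 = np.zeros((200, 200), dtype=np.float32)
        p0[50:70, 50:70] = 1.0
        p1 = np.roll(p0, shift, axis=(0, 1))
        return (
            [self._section(img0), self._section(img1)],
            [ProbabilityMap(probs=p0, section_index=0),
             ProbabilityMap(probs=p1, section_index=1)],
        )

    def test_identical_sections_zero_offset(self):
        sections, pmaps = self._synthetic_pair()
        stack = build_stack(sections, pmaps, downsample=10)
        assert stack.offsets == [(0, 0), (0, 0)]

    def test_translation_recovered(self):
        sections, pmaps = self._synthetic_pair(shift=(30, 0))
        stack = build_stack(sections, pmaps, downsample=10)
        assert stack.offsets[0] == (0, 0)
        assert abs(stack.offsets[1][0] + 3) <= 1  # -3 +- 1 low-res px undoes +30 px
        # after alignment the bundle sits at the same low-res location
        pos0 = np.array(np.nonzero(stack.volume[0] > 0.5)).mean(axis=1)
        pos1 = np.array(np.nonzero(stack.volume[1] > 0.5)).mean(axis=1)
        assert np.abs(pos0 - pos1).max() <= 1.5

    def test_mixed_sizes_padded(self):
        sections, pmaps = self._synthetic_pair()
        small = Section(image=sections[0].image[:150, :150], um_per_px=UM)
        pm_small = ProbabilityMap(probs=pmaps[0].probs[:150, :150])
        stack = build_stack([sections[0], small], [pmaps[0], pm_small], downsample=10)
        assert stack.volume.shape == (2, 20, 20)

    def test_requires_two_sections(self):
        sections, pmaps = self._synthetic_pair()
        with pytest.raises(ValueError):
            build_stack(sections[:1], pmaps[:1])


class TestStackConsensus:
    def _vol(self, maps):
        arr = np.stack(maps).astype(np.float32)
        return StackVolume(volume=arr, offsets=[(0, 0)] * len(maps),
                           pad=[(0, 0)] * len(maps), downsample=10, um_per_px=UM)

    def test_persistent_bundle_kept(self):
        m = np.zeros((16, 16), dtype=np.float32)
        m[5:10, 5:10] = 1.0
        cons = stack_consensus(self._vol([m, m, m]), threshold=0.4)
        assert cons[1, 7, 7]

    def test_single_section_blip_suppressed(self):
        z = np.zeros((16, 16), dtype=np.float32)
        m = np.zeros((16, 16), dtype=np.float32)
        m[5:10, 5:10] = 1.0
        # blip present in one of three sections: z-mean 1/3 < 0.4
        cons = stack_consensus(self._vol([z, m, z]), threshold=0.4)
        assert not cons[1, 7, 7]

    def test_empty_maps_empty_consensus(self):
        z = np.zeros((8, 8), dtype=np.float32)
        cons = stack_consensus(self._vol([z, z]))
        assert not cons.any()

    def test_pluggable_segmenter(self):
        m = np.zeros((8, 8), dtype=np.float32)
        vol = self._vol([m, m])
        cons = stack_consensus(vol, segmenter=lambda v: np.ones_like(v, dtype=bool))
        assert cons.all()


def test_neighbor_reference_masks_roundtrip():
    vol = np.zeros((3, 10, 10), dtype=np.float32)
    vol[0, 2:4, 2:4] = 1.0
    stack = StackVolume(volume=vol, offsets=[(0, 0), (1, 0), (0, 0)],
                        pad=[(0, 0)] * 3, downsample=10, um_per_px=UM)
    cons = vol > 0.5
    masks = neighbor_reference_masks(stack, cons, 1, (100, 100))
    assert len(masks) == 2
    assert masks[0][25, 25]  # upsampled 10x from low-res (2,2)
    assert not masks[1].any()


def test_filter_order_stability(rng):
    """Continuity->morphology equals morphology->continuity: each filter is a
    per-region predicate that does not depend on which other regions survive."""
    shape = (96, 96)
    for _ in range(10):
        tissue = np.zeros(shape, dtype=bool)
        tissue[4:92, 4:92] = True
        masks = []
        occupied = np.zeros(shape, dtype=bool)
        for _k in range(4):
            h, w = rng.integers(4, 24, 2)
            r0, c0 = rng.integers(0, 70, 2)
            cand = np.zeros(shape, dtype=bool)
            cand[r0 : r0 + h, c0 : c0 + w] = True
            if not (cand & occupied).any():
                occupied |= cand
                masks.append(cand)
        nb = np.zeros(shape, dtype=bool)
        r0, c0 = rng.integers(0, 60, 2)
        nb[r0 : r0 + 20, c0 : c0 + 20] = True
        rs = regions_from_mask(occupied, um_per_px=UM)
        a = morphology_filter(continuity_filter(rs, [nb]), tissue)
        b = continuity_filter(morphology_filter(rs, tissue), [nb])
        assert sorted(r.mask.tobytes() for r in a.regions) == sorted(
            r.mask.tobytes() for r in b.regions
        )


def test_estimate_tissue_mask(tiny_section):
    est = estimate_tissue_mask(tiny_section.section)
    truth = tiny_section.tissue_mask
    inter = (est & truth).sum()
    union = (est | truth).sum()
    assert inter / union > 0.9
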