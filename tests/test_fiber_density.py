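"""Fiber density, pathway assignment, and the pathway ANOVA."""

import numpy as np
import pytest

from bundleseg.fiber_density import (
    CLAHEParams,
    assign_pathway,
    fiber_binary_map,
    fiber_density,
    pathway_anova,
)
from bundleseg.io import Section

NO_CLAHE = CLAHEParams(enabled=False)


def _section_from_gray(gray):
    img = np.stack([gray] * 3, axis=-1).astype(np.float32)
    return Section(image=img, um_per_px=40.0)


class TestFiberBinaryMap:
    def test_constant_region_has_no_fibers(self):
        sec = _section_from_gray(np.full((32, 32), 0.5))
        region = np.ones((32, 32), dtype=bool)
        fmap = fiber_binary_map(sec, region, NO_CLAHE)
        assert not fmap.any()  # nothing strictly above its own value

    def test_top_five_percent_rank_count(self, rng):
        vals = rng.permutation(1000) / 1000.0
        sec = _section_from_gray(vals.reshape(25, 40))
        region = np.ones((25, 40), dtype=bool)
        fmap = fiber_binary_map(sec, region, NO_CLAHE)
        assert abs(int(fmap.sum()) - 50) <= 1

    def test_percentile_is_within_region_only(self, rng):
        gray = np.zeros((40, 40))
        region = np.zeros((40, 40), dtype=bool)
        region[:20] = True
        gray[:20] = rng.permutation(800).reshape(20, 40) / 800.0
        gray[20:] = 5e5  # bright outside-region pixels must not shift the threshold
        sec = _section_from_gray(np.clip(gray, 0, 1))
        fmap = fiber_binary_map(sec, region, NO_CLAHE)
        assert not fmap[20:].any()
        assert abs(int(fmap.sum()) - 40) <= 1

    def test_monotone_transform_invariance(self, rng):
        vals = rng.random((30, 30))
        region = np.zeros((30, 30), dtype=bool)
        region[5:25, 5:25] = True
        base = fiber_binary_map(_section_from_gray(vals), region, NO_CLAHE)
        warped = fiber_binary_map(_section_from_gray(vals**3), region, NO_CLAHE)
        np.testing.assert_array_equal(base, warped)

    def test_small_region_warns(self):
        sec = _section_from_gray(np.random.default_rng(0).random((16, 16)))
        region = np.zeros((16, 16), dtype=bool)
        region[0, :10] = True
        with pytest.warns(UserWarning, match="px"):
            fiber_binary_map(sec, region, NO_CLAHE)

    def test_empty_region_rejected(self):
        sec = _section_from_gray(np.zeros((8, 8)))
        with pytest.raises(ValueError):
            fiber_binary_map(sec, np.zeros((8, 8), dtype=bool), NO_CLAHE)

    def test_fiber_map_recovers_rendered_strokes(self, tiny_section):
        """Pixels above the 95th percentile must land on the generator's strokes.

        The percentile rule marks ~5% of region pixels by construction, so when
        a bundle's stroke fraction exceeds 5% the map cannot recover every
        stroke pixel; precision and the rank-bounded recall are the meaningful
        checks.
        """
        s = tiny_section
        for reg in s.annotations.regions:
            fmap = fiber_binary_map(s.section, reg.mask, CLAHEParams())
            strokes = s.fiber_mask & reg.mask
            precision = (fmap & strokes).sum() / fmap.sum()
            assert precision >= 0.8
            stroke_frac = strokes.sum() / reg.mask.sum()
            max_recall = min(1.0, 0.05 / stroke_frac)
            recall = (fmap & strokes).sum() / strokes.sum()
            assert recall >= 0.8 * max_recall


class TestFiberDensity:
    def test_full_region_is_one(self):
        region = np.zeros((10, 10), dtype=bool)
        region[2:8, 2:8] = True
        assert fiber_density(region.copy(), region) == 1.0

    def test_empty_map_is_zero(self):
        region = np.ones((5, 5), dtype=bool)
        assert fiber_density(np.zeros((5, 5), dtype=bool), region) == 0.0

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            fiber_density(np.zeros((5, 5), dtype=bool), np.zeros((5, 5), dtype=bool))

    def test_synthetic_bundles_within_configured_band(self, tiny_stack, tiny_synth_cfg):
        lo, hi = tiny_synth_cfg.fiber_area_fraction_range
        for s in tiny_stack:
            for reg in s.annotations.regions:
                fd = fiber_density(s.fiber_mask, reg.mask)
                assert lo <= fd <= hi

    def test_tighter_boundary_never_decreases_fd(self, tiny_section):
        """Shrinking a region around fixed fibers concentrates them."""
        from scipy import ndimage as ndi

        s = tiny_section
        reg = s.annotations.regions[0].mask
        tighter = ndi.binary_erosion(reg, iterations=2)
        tighter |= s.fiber_mask & reg  # keep every fiber pixel
        fd_loose = fiber_density(s.fiber_mask, reg)
        fd_tight = fiber_density(s.fiber_mask, tighter)
        assert fd_tight >= fd_loose


class TestAssignPathway:
    def _rois(self):
        rois = np.zeros((40, 40), dtype=np.uint8)
        rois[:, :10] = 1  # IC
        rois[:, 15:25] = 2  # CC
        rois[:, 30:] = 3  # UF
        return rois

    def test_clear_majority(self):
        region = np.zeros((40, 40), dtype=bool)
        region[:, :9] = True
        assert assign_pathway(region, self._rois()) == "IC"

    def test_split_below_threshold_is_none(self):
        region = np.zeros((40, 40), dtype=bool)
        region[0:10, 15:18] = True  # 30% CC
        region[0:10, 30:33] = True  # 30% UF
        region[0:10, 10:14] = True  # 40% nowhere
        assert assign_pathway(region, self._rois(), min_overlap=0.4) == "none"

    def test_no_overlap_is_none(self):
        region = np.zeros((40, 40), dtype=bool)
        region[:, 11:14] = True
        assert assign_pathway(region, self._rois()) == "none"

    def test_generator_bundles_assigned_to_their_pathway(self, tiny_stack):
        hits = 0
        total = 0
        for s in tiny_stack:
            for reg in s.annotations.regions:
                name = assign_pathway(reg.mask, s.pathway_rois)
                total += 1
                hits += name != "none"
        assert hits / total >= 0.8


class TestAnova:
    def test_identical_groups_f_zero(self):
        vals = [0.08, 0.12, 0.10, 0.11]
        table = [("IC", v) for v in vals] + [("CC", v) for v in vals]
        f, p, _ = pathway_anova(table)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_matches_sums_of_squares_oracle(self, rng):
        groups = {
            "IC": rng.normal(0.13, 0.02, 12),
            "CC": rng.normal(0.11, 0.02, 9),
            "UF": rng.normal(0.11, 0.03, 7),
        }
        table = [(k, v) for k, vals in groups.items() for v in vals]
        f, p, summary = pathway_anova(table)
        # independent oracle: explicit between/within sums of squares
        all_vals = np.concatenate(list(groups.values()))
        grand = all_vals.mean()
        ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
        ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        dfb = len(groups) - 1
        dfw = len(all_vals) - len(groups)
        f_oracle = (ssb / dfb) / (ssw / dfw)
        assert f == pytest.approx(f_oracle, abs=1e-8)
        assert set(summary["pathway"]) == {"IC", "CC", "UF"}

    def test_type_i_error_calibration(self, rng):
        """Groups from one distribution must reject at ~ the nominal 5% rate."""
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            table = [("A", x) for x in rng.normal(size=8)] + [
                ("B", x) for x in rng.normal(size=8)
            ] + [("C", x) for x in rng.normal(size=8)]
            _, p, _ = pathway_anova(table)
            hits += p < 0.05
        assert 0.03 <= hits / n_sim <= 0.07

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            pathway_anova([("IC", 0.1), ("CC", 0.2)])
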