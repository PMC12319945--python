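"""Detection metrics: bundle matching, FPavg, ΔFD, FROC."""

import numpy as np
import pytest

from bundleseg.evaluation import delta_fd, fp_avg, froc, match_bundles
from bundleseg.inference import ProbabilityMap
from bundleseg.io import AnnotationSet, BundleRegion
from bundleseg.postprocess import RegionSet, regions_from_mask

SHAPE = (64, 64)


def _ann(masks):
    return AnnotationSet(0, [BundleRegion(mask=m) for m in masks])


def _pred(masks):
    rs = RegionSet(0, 100.0, SHAPE, [])
    from bundleseg.postprocess import Region

    for m in masks:
        rs.regions.append(Region(mask=m, area_mm2=float(m.sum()) / 100,
                                 centroid_xy_px=(0.0, 0.0)))
    return rs


def _box(r0, c0, r1, c1):
    m = np.zeros(SHAPE, dtype=bool)
    m[r0:r1, c0:c1] = True
    return m


class TestMatchBundles:
    def test_perfect_predictions(self):
        masks = [_box(5, 5, 15, 15), _box(30, 30, 45, 45)]
        res = match_bundles(_ann(masks), _pred([m.copy() for m in masks]))
        assert res.tpr == 1.0 and res.fp_count == 0

    def test_no_predictions(self):
        res = match_bundles(_ann([_box(5, 5, 15, 15)]), _pred([]))
        assert res.tpr == 0.0 and res.fp_count == 0

    def test_partial_detection_with_one_fp(self):
        manual = [_box(0, 0, 10, 10), _box(20, 20, 30, 30), _box(40, 40, 50, 50)]
        preds = [_box(0, 0, 10, 10), _box(20, 20, 30, 30), _box(55, 55, 63, 63)]
        res = match_bundles(_ann(manual), _pred(preds), min_frac=0.2)
        assert res.tpr == pytest.approx(2 / 3)
        assert res.fp_count == 1

    def test_min_frac_rule(self):
        manual = [_box(0, 0, 10, 10)]  # 100 px
        pred = [_box(0, 0, 10, 1)]  # overlaps 10 px = 10% of manual
        res = match_bundles(_ann(manual), _pred(pred), min_frac=0.2)
        assert res.tpr == 0.0
        # the thin prediction overlaps the manual bundle by 100% of ITS OWN area
        assert res.fp_count == 0

    def test_one_prediction_covers_two_manual(self):
        manual = [_box(0, 0, 10, 10), _box(12, 0, 22, 10)]
        pred = [_box(0, 0, 22, 10)]
        res = match_bundles(_ann(manual), _pred(pred), min_frac=0.2)
        assert res.tpr == 1.0 and res.fp_count == 0


class TestAggregates:
    def test_fp_avg_examples(self):
        r2 = match_bundles(_ann([]), _pred([_box(0, 0, 5, 5), _box(10, 10, 15, 15)]))
        r4 = match_bundles(_ann([]), _pred([_box(0, 0, 5, 5)] ))
        assert r2.fp_count == 2
        two = match_bundles(_ann([]), _pred([_box(0, 0, 5, 5), _box(10, 10, 15, 15),
                                             _box(20, 20, 25, 25), _box(30, 30, 35, 35)]))
        assert fp_avg([r2, two]) == pytest.approx(3.0)
        assert fp_avg([r2]) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            fp_avg([])

    def test_no_fps_anywhere(self):
        res = match_bundles(_ann([_box(0, 0, 8, 8)]), _pred([_box(0, 0, 8, 8)]))
        assert fp_avg([res, res]) == 0.0


class TestDeltaFD:
    def _match(self):
        m = [_box(0, 0, 10, 10)]
        return match_bundles(_ann(m), _pred([m[0].copy()]))

    def test_identical_fds_zero(self):
        assert delta_fd([0.1], [0.1], self._match()) == pytest.approx(0.0)

    def test_printed_arithmetic(self):
        # manual FD 10%, predicted 12% -> ΔFD = -2.0 percentage points
        assert delta_fd([0.10], [0.12], self._match()) == pytest.approx(-2.0)

    def test_tighter_prediction_negative(self):
        assert delta_fd([0.08], [0.11], self._match()) < 0

    def test_requires_matches(self):
        res = match_bundles(_ann([_box(0, 0, 5, 5)]), _pred([]))
        with pytest.raises(ValueError):
            delta_fd([0.1], [], res)


class TestFROC:
    def _maps_and_anns(self, rng):
        manual = [_box(10, 10, 30, 30)]
        probs = np.zeros(SHAPE, dtype=np.float32)
        probs[10:30, 10:30] = 0.85
        probs[45:55, 45:55] = 0.55  # false positive appears at lower thresholds
        pm = ProbabilityMap(probs=probs, section_index=0)
        return [pm], [_ann(manual)]

    def test_extreme_threshold_gives_origin(self, rng):
        pmaps, anns = self._maps_and_anns(rng)
        curve = froc(pmaps, anns, thresholds=[1.0, 0.9])
        fp, tpr, thr = curve.as_arrays()
        at_one = np.where(thr == 1.0)[0][0]
        assert tpr[at_one] == 0.0 and fp[at_one] == 0.0

    def test_tpr_monotone_in_threshold(self, rng):
        pmaps, anns = self._maps_and_anns(rng)
        thresholds = [0.9, 0.7, 0.5, 0.3, 0.1]
        curve = froc(pmaps, anns, thresholds=thresholds)
        by_thr = dict(zip(curve.thresholds, curve.tpr_at))
        tprs = [by_thr[t] for t in thresholds]
        assert all(a <= b for a, b in zip(tprs, tprs[1:]))

    def test_fp_appears_at_lower_threshold(self, rng):
        pmaps, anns = self._maps_and_anns(rng)
        curve = froc(pmaps, anns, thresholds=[0.7, 0.4])
        by_thr = dict(zip(curve.thresholds, curve.fpavg_at))
        assert by_thr[0.7] == 0.0 and by_thr[0.4] == 1.0

    def test_needs_two_thresholds(self, rng):
        pmaps, anns = self._maps_and_anns(rng)
        with pytest.raises(ValueError):
            froc(pmaps, anns, thresholds=[0.5])

    def test_invariant_to_region_order(self, rng):
        manual = [_box(0, 0, 10, 10), _box(20, 20, 30, 30)]
        preds = [_box(20, 20, 30, 30), _box(0, 0, 10, 10)]
        a = match_bundles(_ann(manual), _pred(preds))
        b = match_bundles(_ann(manual[::-1]), _pred(preds[::-1]))
        assert a.tpr == b.tpr and a.fp_count == b.fp_count
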