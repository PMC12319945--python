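"""Region-level detection metrics: bundle matching, TPR, FPavg, ΔFD, FROC.

A manually charted bundle counts as detected (true positive) when some
predicted region overlaps it by at least ``min_frac`` of the manual bundle's
area; a predicted region counts as a false positive when its overlap with
every manual bundle is below ``min_frac`` of its own area.  Counting is
non-exclusive: one prediction may validate several manual bundles and vice
versa.  The matching fraction (0.2 by default) is the single most
consequential free choice of the evaluation — it is deliberately low because
automated boundaries fit the fibers more tightly than manual outlines.

FROC curves sweep the binarization threshold, recording sensitivity (TPR)
versus average false positives per section (FPavg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AnnotationSet
from .postprocess import RegionSet

__all__ = ["MatchResult", "FROCCurve", "match_bundles", "fp_avg", "delta_fd", "froc"]


@dataclass
class MatchResult:
    detected: list[bool]  # per manual bundle
    matched_prediction: list[int | None]  # first matching prediction per manual bundle
    prediction_is_tp: list[bool]  # per predicted region
    tpr: float
    fp_count: int
    n_manual: int

    @property
    def tp_pairs(self) -> list[tuple[int, int]]:
        return [
            (m, p)
            for m, p in enumerate(self.matched_prediction)
            if p is not None
        ]


def match_bundles(
    manual: AnnotationSet,
    predicted: RegionSet,
    min_frac: float = 0.2,
) -> MatchResult:
    """Match predicted regions against manual bundles on one section."""
    if manual.regions and predicted.regions:
        if manual.regions[0].mask.shape != predicted.shape:
            raise ValueError("manual and predicted masks are in different frames")
    n_m = len(manual.regions)
    n_p = len(predicted.regions)
    inter = np.zeros((n_m, n_p), dtype=np.int64)
    for i, mreg in enumerate(manual.regions):
        for j, preg in enumerate(predicted.regions):
            inter[i, j] = int(np.logical_and(mreg.mask, preg.mask).sum())
    m_areas = np.array([int(r.mask.sum()) for r in manual.regions], dtype=np.int64)
    p_areas = np.array([int(r.mask.sum()) for r in predicted.regions], dtype=np.int64)

    detected, matched = [], []
    for i in range(n_m):
        hits = np.nonzero(inter[i] >= min_frac * m_areas[i])[0] if n_p else []
        got = len(hits) > 0
        detected.append(got)
        matched.append(int(hits[0]) if got else None)
    pred_tp = [
        bool(n_m and (inter[:, j] >= min_frac * p_areas[j]).any()) for j in range(n_p)
    ]
    tpr = float(sum(detected) / n_m) if n_m else 0.0
    return MatchResult(
        detected=detected,
        matched_prediction=matched,
        prediction_is_tp=pred_tp,
        tpr=tpr,
        fp_count=int(sum(not t for t in pred_tp)),
        n_manual=n_m,
    )


def fp_avg(match_results: list[MatchResult]) -> float:
    """Total false positives divided by the number of sections."""
    if not match_results:
        raise ValueError("need at least one section")
    return sum(m.fp_count for m in match_results) / len(match_results)


def aggregate_tpr(match_results: list[MatchResult]) -> float:
    """Detected manual bundles over all manual bundles, pooled across sections."""
    total = sum(m.n_manual for m in match_results)
    if total == 0:
        return 0.0
    return sum(sum(m.detected) for m in match_results) / total


def delta_fd(
    manual_fds: list[float],
    predicted_fds: list[float],
    matches: MatchResult,
) -> float:
    """Mean (manual FD − predicted FD) over matched pairs, as a percentage.

    Negative values indicate denser automatic regions, the signature of
    automatically segmented boundaries hugging the fibers more tightly.
    """
    pairs = matches.tp_pairs
    if not pairs:
        raise ValueError("no matched pairs")
    diffs = [manual_fds[m] - predicted_fds[p] for m, p in pairs]
    return float(np.mean(diffs) * 100.0)


@dataclass
class FROCCurve:
    thresholds: list[float]
    tpr_at: list[float]
    fpavg_at: list[float]

    def as_arrays(self):
        order = np.argsort(self.fpavg_at)
        return (
            np.asarray(self.fpavg_at)[order],
            np.asarray(self.tpr_at)[order],
            np.asarray(self.thresholds)[order],
        )


def froc(
    probability_maps,
    manual_annotations: list[AnnotationSet],
    thresholds,
    sections=None,
    postprocess_config: dict | None = None,
    min_frac: float = 0.2,
) -> FROCCurve:
    """FROC curve: (FPavg, TPR) per binarization threshold.

    When ``sections`` and ``postprocess_config`` are given, each threshold's
    binary maps run through the post-processing pipeline before matching;
    otherwise raw connected components are evaluated.
    """
    thresholds = list(thresholds)
    if len(thresholds) < 2:
        raise ValueError("need at least 2 thresholds")
    from .inference import binarize
    from .postprocess import postprocess_stack, regions_from_mask

    tprs, fpavgs = [], []
    for thr in thresholds:
        if sections is not None and postprocess_config is not None:
            region_sets = postprocess_stack(
                sections, probability_maps, threshold=thr, **postprocess_config
            )
        else:
            region_sets = [
                regions_from_mask(binarize(p, thr), um_per_px=1.0, section_index=i)
                for i, p in enumerate(probability_maps)
            ]
        results = [
            match_bundles(ann, rs, min_frac=min_frac)
            for ann, rs in zip(manual_annotations, region_sets)
        ]
        tprs.append(aggregate_tpr(results))
        fpavgs.append(fp_avg(results))
    order = np.argsort(fpavgs)
    return FROCCurve(
        thresholds=[thresholds[i] for i in order],
        tpr_at=[tprs[i] for i in order],
        fpavg_at=[fpavgs[i] for i in order],
    )
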