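"""Whole-section inference: tiled forward passes and thresholding.

Sections no larger than the tile size are processed in a single forward pass;
larger sections are covered by a tile grid (1024 px tiles by default, the
working size for full coronal sections), with optional overlap whose
predictions are averaged.  Edge tiles are padded by reflection and the
reassembled map is cropped back to the section size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

from .io import Section
from .network import DualHeadUNet

__all__ = ["ProbabilityMap", "predict_section", "binarize", "seg_probability"]


@dataclass
class ProbabilityMap:
    probs: np.ndarray  # H x W in [0, 1]
    section_index: int = 0
    tile_layout: list = field(default_factory=list)  # (row0, col0, h, w) per tile
    model_tag: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=np.float32)
        if p.min() < -1e-6 or p.max() > 1 + 1e-6:
            raise ValueError("probabilities must lie in [0, 1]")
        self.probs = np.clip(p, 0.0, 1.0)

    def save(self, path) -> None:
        tifffile.imwrite(path, self.probs.astype(np.float32))


def seg_probability(model: DualHeadUNet, tile_hw3: np.ndarray) -> np.ndarray:
    """Fiber-class probability for one H x W x 3 tile (inference mode)."""
    x = tile_hw3.transpose(2, 0, 1)[None].astype(np.float32)
    logits = model.forward(x, train=False).seg_logits[0]
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return (e[1] / e.sum(axis=0)).astype(np.float32)


def _model_divisor(model: DualHeadUNet) -> int:
    # U-Net needs 2^(depth-1); the classification arm two further poolings
    return 2 ** (model.cfg.depth - 1) * 4


def predict_section(
    model: DualHeadUNet,
    section: Section,
    tile_size: int = 1024,
    overlap_px: int = 0,
) -> ProbabilityMap:
    """Fiber-bundle probability map for a whole section."""
    div = _model_divisor(model)
    if tile_size % div:
        raise ValueError(
            f"tile_size {tile_size} not divisible by the model's required factor {div}"
        )
    if not 0 <= overlap_px < tile_size:
        raise ValueError("overlap_px must be in [0, tile_size)")
    h, w = section.shape
    img = section.image

    if h <= tile_size and w <= tile_size:
        ph = int(np.ceil(h / div) * div)
        pw = int(np.ceil(w / div) * div)
        padded = np.pad(img, ((0, ph - h), (0, pw - w), (0, 0)), mode="reflect")
        probs = seg_probability(model, padded)[:h, :w]
        return ProbabilityMap(
            probs=probs, section_index=section.section_index,
            tile_layout=[(0, 0, h, w)], model_tag="",
        )

    stride = tile_size - overlap_px
    acc = np.zeros((h, w), dtype=np.float64)
    cnt = np.zeros((h, w), dtype=np.float64)
    layout = []
    r_starts = list(range(0, max(h - overlap_px, 1), stride))
    c_starts = list(range(0, max(w - overlap_px, 1), stride))
    for r0 in r_starts:
        for c0 in c_starts:
            r1 = min(r0 + tile_size, h)
            c1 = min(c0 + tile_size, w)
            tile = img[r0:r1, c0:c1]
            th, tw = tile.shape[:2]
            if th < tile_size or tw < tile_size:
                tile = np.pad(
                    tile, ((0, tile_size - th), (0, tile_size - tw), (0, 0)), mode="reflect"
                )
            p = seg_probability(model, tile)[:th, :tw]
            acc[r0:r1, c0:c1] += p
            cnt[r0:r1, c0:c1] += 1.0
            layout.append((r0, c0, th, tw))
    probs = (acc / np.maximum(cnt, 1.0)).astype(np.float32)
    return ProbabilityMap(
        probs=probs, section_index=section.section_index, tile_layout=layout, model_tag=""
    )


def binarize(pmap: ProbabilityMap | np.ndarray, threshold: float = 0.4) -> np.ndarray:
    """Binary mask = probabilities >= threshold (ties included)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    probs = pmap.probs if isinstance(pmap, ProbabilityMap) else np.asarray(pmap)
    return probs >= threshold
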