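"""Seeded generator of synthetic dark-field-like tracer sections.

The generator emulates the statistical structure the segmentation method
assumes, so the whole pipeline is testable without real histology:

* a dark tissue background with a smooth intensity gradient and an even
  darker extra-tissue margin, plus a ventricle-like interior cavity that the
  stack-alignment step can use as a landmark;
* fiber bundles: elongated regions containing bright, roughly parallel,
  anti-aliased curvilinear strokes.  The ground-truth bundle region is the
  morphological closing of the stroke union followed by a fixed dilation
  (manual outlines are looser than the fibers themselves); the bright-pixel
  fraction inside each region is controlled to lie in a configured band
  (2-20% by default, the fiber-density range reported for real bundles);
* confounders placed outside bundle regions: terminal-field-like isotropic
  speckle patches at bundle-like brightness (the main false-positive source),
  smooth glare blobs, and a bright rim along the tissue border;
* smooth bundle drift across a stack of consecutive sections, so that
  cross-section continuity holds (and one bundle terminates partway through
  the stack, so termination is also represented).

Fixing the seed fixes every output byte.  All per-section randomness is
derived from ``(seed, section_index)`` so ``generate_section`` is consistent
with ``generate_stack``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line_aa

from .io import AnnotationSet, BundleRegion, Section, write_image, write_label_mask, write_manifest

__all__ = [
    "SynthConfig",
    "SyntheticSection",
    "PATHWAY_NAMES",
    "bundle_schedule",
    "generate_section",
    "generate_stack",
    "select_labeled",
    "save_stack",
]

PATHWAY_NAMES = {1: "IC", 2: "CC", 3: "UF"}

STROKE_THRESHOLD = 0.5  # rendered stroke intensity >= this counts as a bright pixel


@dataclass
class SynthConfig:
    image_height_px: int = 512
    image_width_px: int = 512
    um_per_px: float = 40.0  # one 512 px section spans ~20 mm, a coarse working scale
    n_sections: int = 20
    section_spacing_mm: float = 1.2
    n_bundles: int = 3
    fiber_area_fraction_range: tuple[float, float] = (0.02, 0.20)
    bundle_axis_ratio_range: tuple[float, float] = (2.0, 3.2)
    background_mean: float = 0.08
    background_gradient_amp: float = 0.04
    confounder_counts: dict = field(
        default_factory=lambda: {"terminal_fields": 2, "glare": 1}
    )
    drift_mm_per_section: float = 0.3
    seed: int = 0
    # rendering knobs (part of the stated world; rarely changed)
    stroke_brightness: float = 0.75
    terminal_field_brightness: float = 0.70  # unquantified in the field; exposed
    glare_brightness: float = 0.85
    closing_radius_px: int = 10
    dilation_px: int = 3
    min_region_area_mm2: float = 5.5  # true bundles sit well above the 2 mm^2 FP filter

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be > 0")
        if self.n_sections < 1:
            raise ValueError("n_sections must be >= 1")
        if self.n_bundles < 0:
            raise ValueError("n_bundles must be >= 0")
        lo, hi = self.fiber_area_fraction_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("fiber_area_fraction_range must satisfy 0 <= low < high <= 1")
        if self.drift_mm_per_section < 0:
            raise ValueError("drift must be >= 0")


@dataclass
class SyntheticSection:
    """Everything the generator knows about one synthetic section."""

    section: Section
    annotations: AnnotationSet | None
    wm_mask: np.ndarray
    pathway_rois: np.ndarray  # label image: 0 bg, 1 IC, 2 CC, 3 UF
    tissue_mask: np.ndarray
    fiber_mask: np.ndarray  # rendered bright strokes (ground-truth fibers)
    confounder_mask: np.ndarray

    def __iter__(self):
        # unpack like (section, annotations, wm_mask, pathway_rois)
        return iter((self.section, self.annotations, self.wm_mask, self.pathway_rois))


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _tissue_geometry(cfg: SynthConfig):
    h, w = cfg.image_height_px, cfg.image_width_px
    center = np.array([h / 2, w / 2])
    axes = np.array([0.45 * h, 0.44 * w])
    return center, axes


def _ventricle_geometry(cfg: SynthConfig):
    """Interior dark cavity used as the stack-alignment landmark."""
    h, w = cfg.image_height_px, cfg.image_width_px
    center = np.array([0.48 * h, 0.53 * w])  # off the pathway-ROI axes
    axes = np.array([0.045 * h, 0.022 * w])
    return center, axes


def _pathway_geometry(cfg: SynthConfig):
    """Three elongated white-matter ROIs (IC, CC, UF), fixed in the image frame."""
    h, w = cfg.image_height_px, cfg.image_width_px
    s = min(h, w)
    return {
        1: dict(center=(0.38 * h, 0.32 * w), angle=np.deg2rad(65), ax=(0.085 * s, 0.26 * s)),
        2: dict(center=(0.24 * h, 0.58 * w), angle=np.deg2rad(5), ax=(0.08 * s, 0.27 * s)),
        3: dict(center=(0.66 * h, 0.42 * w), angle=np.deg2rad(125), ax=(0.075 * s, 0.23 * s)),
    }


def _ellipse_mask(shape, center, r_radius, c_radius, rotation=0.0) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_ellipse(
        center[0], center[1], r_radius, c_radius, shape=shape, rotation=rotation
    )
    mask[rr, cc] = True
    return mask


def _pathway_label_image(cfg: SynthConfig) -> np.ndarray:
    shape = (cfg.image_height_px, cfg.image_width_px)
    out = np.zeros(shape, dtype=np.uint8)
    for k, g in _pathway_geometry(cfg).items():
        # skimage rotation convention: counter-clockwise about the row axis
        m = _ellipse_mask(shape, g["center"], g["ax"][0], g["ax"][1], rotation=g["angle"])
        out[m & (out == 0)] = k
    return out


# ---------------------------------------------------------------------------
# bundle schedule (stack-level script)
# ---------------------------------------------------------------------------

@dataclass
class BundleScript:
    bundle_id: int
    pathway: int  # ROI label the bundle travels in
    start_section: int
    end_section: int  # inclusive
    centroids: np.ndarray  # n_sections x 2 (row, col), valid on active sections
    angles: np.ndarray  # per-section stroke orientation (radians)
    half_axes: tuple[float, float]  # (long, short) support half-axes in px

    def active(self, section_index: int) -> bool:
        return self.start_section <= section_index <= self.end_section


def bundle_schedule(cfg: SynthConfig) -> list[BundleScript]:
    """Deterministic per-bundle trajectories for the whole stack.

    Each bundle is assigned to one pathway ROI and its centroid performs a
    bounded 1D walk along the ROI's major axis, guaranteeing a per-section
    displacement of at most ``drift_mm_per_section``.  If the stack is long
    enough, the last bundle terminates at 3/4 of the stack so that bundle
    birth/death is represented.
    """
    geo = _pathway_geometry(cfg)
    drift_px = cfg.drift_mm_per_section * 1000.0 / cfg.um_per_px
    s = min(cfg.image_height_px, cfg.image_width_px)
    t_center, t_axes = _tissue_geometry(cfg)
    v_center, v_axes = _ventricle_geometry(cfg)
    v_radius = float(v_axes.max())
    border_margin_px = 0.7 * 1000.0 / cfg.um_per_px  # clear of the 0.5 mm filter zone
    scripts: list[BundleScript] = []
    for b in range(cfg.n_bundles):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11, b]))
        pathway = 1 + b % 3
        g = geo[pathway]
        ratio = rng.uniform(*cfg.bundle_axis_ratio_range)
        a_long = rng.uniform(0.10, 0.14) * s
        half_axes = (a_long, a_long / ratio)
        angle = g["angle"] + rng.normal(0.0, np.deg2rad(6))

        # true bundles must stay comfortably inside the outer tissue border
        # (or the border-distance filter would delete them) and off the
        # ventricle cavity (which is interior tissue, so only a cosmetic bound)
        reach = a_long + cfg.dilation_px + border_margin_px
        reach_v = a_long + cfg.dilation_px + 2.0
        er_axes = np.maximum(t_axes - reach, 1.0)

        def _ok(pos):
            in_tissue = (
                ((pos[0] - t_center[0]) / er_axes[0]) ** 2
                + ((pos[1] - t_center[1]) / er_axes[1]) ** 2
            ) <= 1.0
            clear_of_ventricle = np.hypot(*(pos - v_center)) >= v_radius + reach_v
            return in_tissue and clear_of_ventricle

        # 1D walk along the ROI major axis, bouncing at +-limit
        limit = max(g["ax"][1] - a_long - cfg.dilation_px - 2, 1.0)
        u = rng.uniform(-0.5, 0.5) * limit
        direction = rng.choice([-1.0, 1.0])
        axis_vec = np.array([np.sin(g["angle"]), np.cos(g["angle"])])
        while abs(u) > 1e-9 and not _ok(np.asarray(g["center"]) + u * axis_vec):
            u *= 0.8  # pull the start toward the ROI center until valid
        centroids = np.zeros((cfg.n_sections, 2))
        angles = np.zeros(cfg.n_sections)
        for i in range(cfg.n_sections):
            centroids[i] = np.asarray(g["center"]) + u * axis_vec
            angles[i] = angle + rng.normal(0.0, np.deg2rad(3))
            step = direction * rng.uniform(0.6, 1.0) * drift_px
            cand = np.asarray(g["center"]) + (u + step) * axis_vec
            if abs(u + step) > limit or not _ok(cand):
                direction = -direction
                step = direction * abs(step)
                cand = np.asarray(g["center"]) + (u + step) * axis_vec
                if not _ok(cand):
                    step = 0.0  # boxed in: stay put this section
            u = float(np.clip(u + step, -limit, limit))

        end = cfg.n_sections - 1
        if b == cfg.n_bundles - 1 and cfg.n_sections >= 4 and cfg.n_bundles >= 2:
            end = (3 * (cfg.n_sections - 1)) // 4
        scripts.append(
            BundleScript(
                bundle_id=b,
                pathway=pathway,
                start_section=0,
                end_section=end,
                centroids=centroids,
                angles=angles,
                half_axes=half_axes,
            )
        )
    return scripts


# ---------------------------------------------------------------------------
# stroke rendering
# ---------------------------------------------------------------------------

def _sample_in_ellipse(rng, center, a, b, angle):
    r = np.sqrt(rng.uniform())
    t = rng.uniform(0, 2 * np.pi)
    u, v = a * r * np.cos(t), b * r * np.sin(t)
    ca, sa = np.cos(angle), np.sin(angle)
    return center[0] + u * sa + v * ca, center[1] + u * ca - v * sa


def _clip_to_ellipse(pts: np.ndarray, center, a, b, angle) -> np.ndarray:
    """Radially pull curve points that left the support ellipse back inside."""
    d = pts - np.asarray(center)
    ca, sa = np.cos(angle), np.sin(angle)
    u = d[:, 0] * sa + d[:, 1] * ca
    v = d[:, 0] * ca - d[:, 1] * sa
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    scale = np.where(rho > 1.0, 0.98 / np.maximum(rho, 1e-9), 1.0)
    return np.asarray(center) + d * scale[:, None]


def _stroke_segments(canvas, pts):
    h, w = canvas.shape
    pts = np.clip(np.round(pts).astype(int), [0, 0], [h - 1, w - 1])
    segs = []
    for q0, q1 in zip(pts[:-1], pts[1:]):
        if np.all(q0 == q1):
            continue
        rr, cc, val = line_aa(q0[0], q0[1], q1[0], q1[1])
        segs.append((rr, cc, val))
    return segs


def _draw_stroke(canvas: np.ndarray, rng, center, a, b, angle, length: float):
    """One anti-aliased quadratic-Bezier stroke; returns (rr, cc, val) triples."""
    p0 = np.array(_sample_in_ellipse(rng, center, a * 0.9, b * 0.9, angle))
    theta = angle + rng.normal(0.0, np.deg2rad(8))
    d = np.array([np.sin(theta), np.cos(theta)])
    p2 = p0 + d * length
    perp = np.array([-d[1], d[0]])
    p1 = (p0 + p2) / 2 + perp * rng.normal(0.0, 0.15 * length)
    ts = np.linspace(0.0, 1.0, max(4, int(length / 3)))
    pts = (
        np.outer((1 - ts) ** 2, p0) + np.outer(2 * (1 - ts) * ts, p1) + np.outer(ts**2, p2)
    )
    return _stroke_segments(canvas, _clip_to_ellipse(pts, center, a, b, angle))


def _paint(canvas: np.ndarray, strokes) -> None:
    canvas.fill(0.0)
    for segs in strokes:
        for rr, cc, val in segs:
            np.maximum.at(canvas, (rr, cc), val)


def _close_and_dilate(mask: np.ndarray, r_close: int, r_dilate: int) -> np.ndarray:
    """Morphological closing with a disk of radius r_close, then dilation by r_dilate.

    Computed with Euclidean distance transforms (closing = erosion of the
    dilation), which is fast for large radii.
    """
    if not mask.any():
        return mask.copy()
    dilated = ndi.distance_transform_edt(~mask) <= r_close
    closed = ndi.distance_transform_edt(dilated) > r_close
    closed |= mask  # EDT rounding must never lose actual fiber pixels
    return ndi.distance_transform_edt(~closed) <= r_dilate


def _placed_stroke(cfg, rng, canvas, bright, center, a, b, angle, length, mode):
    """Draw a stroke whose start point is chosen to 'cover' sparse ellipse area
    (extends the region and dilutes the fiber fraction) or to 'densify' the
    already-covered area (raises the fraction with little region growth)."""
    if not bright.any():
        return _draw_stroke(canvas, rng, center, a, b, angle, length)
    cand = np.array(
        [_sample_in_ellipse(rng, center, a * 0.9, b * 0.9, angle) for _ in range(10)]
    )
    rows, cols = np.nonzero(bright)
    pts = np.stack([rows, cols], axis=1).astype(float)
    # distance of each candidate start to the nearest bright pixel; 'cover'
    # aims just inside bridging range of the closing so the filled gap grows
    # the region faster than the numerator, 'densify' draws on top of cover
    d = np.sqrt(((cand[:, None, :] - pts[None, :, :]) ** 2).sum(-1)).min(axis=1)
    ideal = float(cfg.closing_radius_px) if mode == "cover" else 1.0
    pick = int(np.argmin(np.abs(d - ideal)))
    p0 = cand[pick]
    theta = angle + rng.normal(0.0, np.deg2rad(8))
    dvec = np.array([np.sin(theta), np.cos(theta)])
    p2 = p0 + dvec * length
    perp = np.array([-dvec[1], dvec[0]])
    p1 = (p0 + p2) / 2 + perp * rng.normal(0.0, 0.15 * length)
    ts = np.linspace(0.0, 1.0, max(4, int(length / 3)))
    pts_b = (
        np.outer((1 - ts) ** 2, p0) + np.outer(2 * (1 - ts) * ts, p1) + np.outer(ts**2, p2)
    )
    return _stroke_segments(canvas, _clip_to_ellipse(pts_b, center, a, b, angle))


def _render_bundle(cfg: SynthConfig, rng, script: BundleScript, section_index: int):
    """Render strokes for one bundle; returns (stroke canvas, region mask, target_fd)."""
    shape = (cfg.image_height_px, cfg.image_width_px)
    a, b = script.half_axes
    center = script.centroids[section_index]
    angle = script.angles[section_index]
    lo, hi = cfg.fiber_area_fraction_range
    span = hi - lo
    target = rng.uniform(lo + 0.15 * span, hi - 0.15 * span)

    ell_area = np.pi * a * b
    floor_px = min(
        cfg.min_region_area_mm2 * 1e6 / cfg.um_per_px**2, 0.9 * ell_area
    )
    length = float(np.clip(0.7 * a, 6.0, 1.1 * a))
    px_per_stroke = length * 1.8
    n0 = max(2, int(round(target * 0.8 * ell_area / px_per_stroke)))

    canvas = np.zeros(shape, dtype=np.float32)
    strokes = [_draw_stroke(canvas, rng, center, a, b, angle, length) for _ in range(n0)]
    osc = 0
    last = None
    for _ in range(120):
        _paint(canvas, strokes)
        bright = canvas >= STROKE_THRESHOLD
        region = _close_and_dilate(bright, cfg.closing_radius_px, cfg.dilation_px)
        n_region = int(region.sum())
        if n_region == 0:
            strokes.append(_draw_stroke(canvas, rng, center, a, b, angle, length))
            continue
        frac = bright.sum() / n_region
        if frac > hi - 0.1 * span:
            # too dense: drop a stroke (or shorten when only one remains)
            if len(strokes) > 1:
                strokes.pop()
            else:
                length = max(5.0, 0.7 * length)
                strokes = [_draw_stroke(canvas, rng, center, a, b, angle, length)]
            action = "remove"
        elif frac < lo + 0.1 * span:
            # short stroke on top of existing cover: raises the numerator
            strokes.append(
                _placed_stroke(cfg, rng, canvas, bright, center, a, b, angle,
                               max(5.0, 0.5 * length), "densify")
            )
            action = "densify"
        elif n_region < floor_px:
            # stroke into sparse territory: grows (and dilutes) the region
            strokes.append(
                _placed_stroke(cfg, rng, canvas, bright, center, a, b, angle,
                               max(5.0, 0.5 * length), "cover")
            )
            action = "cover"
        else:
            break
        if last is not None and {last, action} == {"remove", "cover"}:
            osc += 1
            if osc >= 3:  # finer-grained strokes break add/remove cycles
                length = max(5.0, 0.7 * length)
                osc = 0
        last = action
    _paint(canvas, strokes)
    bright = canvas >= STROKE_THRESHOLD
    region = _close_and_dilate(bright, cfg.closing_radius_px, cfg.dilation_px)
    frac = bright.sum() / max(int(region.sum()), 1)
    if not (lo <= frac <= hi):
        raise RuntimeError(
            f"bundle {script.bundle_id} section {section_index}: fiber fraction "
            f"{frac:.3f} escaped configured range [{lo}, {hi}]"
        )
    return canvas, region, target


# ---------------------------------------------------------------------------
# section assembly
# ---------------------------------------------------------------------------

def _background(
    cfg: SynthConfig, rng, tissue: np.ndarray, wm: np.ndarray, cavity: np.ndarray
) -> np.ndarray:
    h, w = tissue.shape
    yy, xx = np.mgrid[0:h, 0:w]
    theta = rng.uniform(0, 2 * np.pi)
    ramp = (yy * np.sin(theta) + xx * np.cos(theta)) / max(h, w)
    ramp = (ramp - ramp.min()) / max(float(np.ptp(ramp)), 1e-9) - 0.5
    bg = cfg.background_mean + cfg.background_gradient_amp * ramp
    bg = bg + rng.normal(0.0, 0.008, size=(h, w))
    bg = np.where(wm, bg + 0.02, bg)  # white matter is slightly brighter
    dark = tissue & ~cavity
    bg = np.where(dark, bg, 0.01 + rng.normal(0.0, 0.003, size=(h, w)))
    return np.clip(bg, 0.0, 1.0).astype(np.float32)


def _place_confounders(cfg: SynthConfig, rng, tissue, forbidden):
    """Speckle patches and glare blobs outside bundle regions; returns (field, mask)."""
    h, w = tissue.shape
    shape = (h, w)
    add = np.zeros(shape, dtype=np.float32)
    mask = np.zeros(shape, dtype=bool)
    interior = tissue & ~ndi.binary_dilation(forbidden, iterations=3)

    def _try_place(radius):
        for _ in range(60):
            r = rng.integers(radius, h - radius)
            c = rng.integers(radius, w - radius)
            blob = _ellipse_mask(shape, (r, c), radius, radius * rng.uniform(0.7, 1.0))
            if (blob & ~interior).sum() == 0:
                return blob
        return None

    for _ in range(int(cfg.confounder_counts.get("terminal_fields", 0))):
        radius = int(rng.uniform(0.03, 0.055) * min(h, w))
        blob = _try_place(radius)
        if blob is None:
            continue
        # isotropic speckle: scattered bright dots with no dominant orientation
        dots = (rng.random(shape) < 0.10) & blob
        dots = ndi.binary_dilation(dots, iterations=1) & blob
        add[dots] = np.maximum(add[dots], cfg.terminal_field_brightness)
        mask |= blob

    for _ in range(int(cfg.confounder_counts.get("glare", 0))):
        radius = int(rng.uniform(0.02, 0.04) * min(h, w))
        blob = _try_place(radius)
        if blob is None:
            continue
        dist = ndi.distance_transform_edt(blob)
        prof = (dist / max(dist.max(), 1e-9)) ** 0.7 * cfg.glare_brightness
        add = np.maximum(add, prof.astype(np.float32))
        mask |= blob

    return add, mask


def generate_section(cfg: SynthConfig, section_index: int) -> SyntheticSection:
    """Generate one synthetic section with its ground truth."""
    if not 0 <= section_index < cfg.n_sections:
        raise ValueError(f"section_index {section_index} outside [0, {cfg.n_sections})")
    shape = (cfg.image_height_px, cfg.image_width_px)
    t_center, t_axes = _tissue_geometry(cfg)
    # the ventricle is an interior cavity: rendered dark (it is the alignment
    # landmark) but still part of the tissue mask, so the border-distance
    # filter measures distance to the brain outline only
    tissue = _ellipse_mask(shape, t_center, t_axes[0], t_axes[1])
    v_center, v_axes = _ventricle_geometry(cfg)
    ventricle = _ellipse_mask(shape, v_center, v_axes[0], v_axes[1])
    pathways = _pathway_label_image(cfg)
    pathways[~tissue | ventricle] = 0

    scripts = bundle_schedule(cfg)
    rng_b = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3, section_index]))
    stroke_canvas = np.zeros(shape, dtype=np.float32)
    regions: list[BundleRegion] = []
    lo, hi = cfg.fiber_area_fraction_range
    for script in scripts:
        if not script.active(section_index):
            continue
        canvas, region, target = _render_bundle(cfg, rng_b, script, section_index)
        stroke_canvas = np.maximum(stroke_canvas, canvas)
        regions.append(
            BundleRegion(
                mask=region,
                density_category="dense" if target >= (lo + hi) / 2 else "moderate",
                bundle_id=script.bundle_id,
            )
        )

    bundle_union = np.zeros(shape, dtype=bool)
    for reg in regions:
        bundle_union |= reg.mask

    wm = pathways > 0
    wm |= ndi.binary_dilation(bundle_union, iterations=2)
    wm &= tissue & ~ventricle

    rng_s = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2, section_index]))
    gray = _background(cfg, rng_s, tissue, wm, ventricle)
    conf_add, conf_mask = _place_confounders(
        cfg, rng_s, tissue & ~ventricle, bundle_union
    )

    # bright rim along the tissue border (section-edge glare)
    rim = tissue & (ndi.distance_transform_edt(tissue) <= 2.5)
    gray = np.maximum(gray, np.where(rim, 0.45, 0.0).astype(np.float32))
    gray = np.maximum(gray, conf_add)
    fiber_mask = stroke_canvas >= STROKE_THRESHOLD
    gray = np.maximum(gray, (stroke_canvas * cfg.stroke_brightness).astype(np.float32))

    # slight channel correlation around the shared luminance
    img = np.stack([gray, gray * 0.95, gray * 0.88], axis=-1)
    img += rng_s.normal(0.0, 0.004, size=img.shape).astype(np.float32)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    section = Section(
        image=img,
        um_per_px=cfg.um_per_px,
        case_id="synthetic",
        section_index=section_index,
        spacing_mm=cfg.section_spacing_mm,
    )
    annotations = AnnotationSet(section_index=section_index, regions=regions)
    return SyntheticSection(
        section=section,
        annotations=annotations,
        wm_mask=wm,
        pathway_rois=pathways,
        tissue_mask=tissue,
        fiber_mask=fiber_mask,
        confounder_mask=conf_mask,
    )


def generate_stack(cfg: SynthConfig) -> list[SyntheticSection]:
    """Generate the full rostro-caudal stack."""
    return [generate_section(cfg, i) for i in range(cfg.n_sections)]


def select_labeled(n_sections: int, n_labeled: int, seed: int = 0) -> list[int]:
    """Evenly spaced labeled-section indices (deterministic)."""
    if n_labeled >= n_sections:
        return list(range(n_sections))
    idx = np.linspace(0, n_sections - 1, n_labeled)
    return sorted(set(int(round(i)) for i in idx))


def save_stack(stack: list[SyntheticSection], out_dir, bitdepth: int = 8) -> Path:
    """Write images/masks/ROIs and a stack manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in stack:
        i = s.section.section_index
        img_path = out_dir / f"section_{i:03d}.png"
        write_image(img_path, s.section.image, bitdepth=bitdepth)
        mask_path = out_dir / f"bundles_{i:03d}.png"
        write_label_mask(mask_path, s.annotations.label_mask(s.section.shape)
                         if s.annotations else np.zeros(s.section.shape, dtype=np.uint8))
        wm_path = out_dir / f"wm_{i:03d}.png"
        write_label_mask(wm_path, s.wm_mask.astype(np.uint8))
        pw_path = out_dir / f"pathways_{i:03d}.png"
        write_label_mask(pw_path, s.pathway_rois)
        rows.append(
            dict(
                section_index=i,
                image_path=img_path.name,
                bundle_mask_path=mask_path.name,
                wm_mask_path=wm_path.name,
                pathway_mask_path=pw_path.name,
                um_per_px=s.section.um_per_px,
                spacing_mm=s.section.spacing_mm,
                labeled=s.annotations is not None,
            )
        )
    manifest = out_dir / "manifest.csv"
    write_manifest(manifest, rows)
    return manifest
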