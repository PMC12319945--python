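"""Section/annotation I/O, physical-unit conversions, and patch sampling.

Conventions (fixed so that overlap and area computations are well defined):
row-major images, 0-based indices, pixel centers; polygons are given in
(x, y) = (column, row) pixel coordinates over the half-open image domain.

Supported raster formats are PNG and TIFF (JPEG2000 works only when Pillow
was built with an openjpeg codec, which is not guaranteed in this
environment).  Manual contours are accepted as label-mask PNGs or CSV polygon
tables; proprietary Neurolucida/IMOD files must be pre-exported by the user.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image
from skimage.draw import polygon as draw_polygon
from skimage import measure

__all__ = [
    "Section",
    "AnnotationSet",
    "PatchBatch",
    "read_section",
    "write_image",
    "read_label_mask",
    "write_label_mask",
    "mm2_to_px",
    "px_to_mm2",
    "um_to_px",
    "rasterize_polygon",
    "mask_to_polygons",
    "sample_patches",
    "read_manifest",
    "write_manifest",
]

DENSITY_CATEGORIES = ("dense", "moderate", "unknown")


@dataclass
class Section:
    """One digitized coronal section with physical calibration."""

    image: np.ndarray  # H x W x 3 float in [0, 1]
    um_per_px: float
    case_id: str = ""
    section_index: int = 0
    spacing_mm: float = 1.2

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be > 0")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be > 0")
        img = np.asarray(self.image, dtype=np.float32)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError("image must be H x W x 3")
        if img.min() < -1e-6 or img.max() > 1 + 1e-6:
            raise ValueError("image values must lie in [0, 1]")
        self.image = np.clip(img, 0.0, 1.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


@dataclass
class BundleRegion:
    mask: np.ndarray  # H x W bool
    density_category: str = "unknown"
    bundle_id: int | None = None

    def __post_init__(self) -> None:
        if self.density_category not in DENSITY_CATEGORIES:
            raise ValueError(f"density_category must be one of {DENSITY_CATEGORIES}")
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class AnnotationSet:
    """Per-section bundle regions; also used as a prediction container."""

    section_index: int
    regions: list[BundleRegion] = field(default_factory=list)

    def label_mask(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        """0 = background, k = k-th bundle (1-based)."""
        if shape is None:
            if not self.regions:
                raise ValueError("cannot infer shape of an empty AnnotationSet")
            shape = self.regions[0].mask.shape
        out = np.zeros(shape, dtype=np.uint16)
        for k, reg in enumerate(self.regions, start=1):
            out[reg.mask] = k
        return out

    def union_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        for reg in self.regions:
            out |= reg.mask
        return out

    @classmethod
    def from_label_mask(
        cls, label_mask: np.ndarray, section_index: int = 0,
        categories: dict[int, str] | None = None,
    ) -> "AnnotationSet":
        labels = np.unique(label_mask)
        regions = [
            BundleRegion(
                mask=label_mask == k,
                density_category=(categories or {}).get(int(k), "unknown"),
                bundle_id=int(k),
            )
            for k in labels
            if k != 0
        ]
        return cls(section_index=section_index, regions=regions)


@dataclass
class PatchBatch:
    """Training patches with optional pixel labels and positive-pair links."""

    patches: np.ndarray  # N x S x S x 3
    pixel_labels: np.ndarray | None = None  # N x S x S in {0,1}
    class_labels: np.ndarray | None = None  # N in {0 (background), 1 (fiber)}
    pair_index: np.ndarray | None = None  # patch -> positive-pair partner
    coords: np.ndarray | None = None  # N x 2 patch-center (row, col)

    def __post_init__(self) -> None:
        p = np.asarray(self.patches, dtype=np.float32)
        if p.ndim != 4 or p.shape[3] != 3 or p.shape[1] != p.shape[2]:
            raise ValueError("patches must be N x S x S x 3")
        self.patches = p
        if self.pixel_labels is not None:
            lab = np.asarray(self.pixel_labels)
            if lab.shape != p.shape[:3]:
                raise ValueError("pixel_labels must be N x S x S")
            if not np.isin(lab, (0, 1)).all():
                raise ValueError("pixel_labels must be binary")
            self.pixel_labels = lab.astype(np.uint8)
        if self.pair_index is not None:
            idx = np.asarray(self.pair_index)
            if not np.array_equal(idx[idx], np.arange(len(idx))):
                raise ValueError("pair_index must be a symmetric involution")
            self.pair_index = idx

    def __len__(self) -> int:
        return self.patches.shape[0]


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------

def _decode(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return tifffile.imread(path)
    with Image.open(path) as im:
        return np.asarray(im)


def _to_unit_float(img: np.ndarray) -> np.ndarray:
    if img.dtype == np.uint8:
        return img.astype(np.float32) / 255.0
    if img.dtype == np.uint16:
        return img.astype(np.float32) / 65535.0
    img = img.astype(np.float32)
    if img.size and img.max() > 1.0:
        img = img / img.max()
    return img


def read_section(
    path,
    um_per_px: float,
    section_index: int = 0,
    spacing_mm: float = 1.2,
    case_id: str = "",
    downsample: int = 1,
) -> Section:
    """Read a section image, rescale to [0, 1], and attach physical metadata.

    ``downsample`` block-averages the image in-plane by an integer factor and
    scales ``um_per_px`` up multiplicatively (e.g. 0.44 um/px images scanned at
    full resolution are analyzed at factor 4 = 1.76 um/px).
    """
    path = Path(path)
    try:
        img = _decode(path)
    except Exception as exc:  # noqa: BLE001 - normalize decoder errors
        raise IOError(f"cannot read section image {path}: {exc}") from exc
    img = _to_unit_float(np.asarray(img))
    if img.ndim == 2:
        warnings.warn(f"{path.name}: grayscale input promoted to 3 channels")
        img = np.stack([img] * 3, axis=-1)
    if img.shape[2] > 3:
        img = img[:, :, :3]  # drop alpha
    if downsample > 1:
        from skimage.transform import downscale_local_mean

        h, w = img.shape[:2]
        img = img[: h - h % downsample, : w - w % downsample]
        img = downscale_local_mean(img, (downsample, downsample, 1)).astype(np.float32)
        um_per_px = um_per_px * downsample
    return Section(
        image=np.clip(img, 0.0, 1.0),
        um_per_px=um_per_px,
        case_id=case_id,
        section_index=section_index,
        spacing_mm=spacing_mm,
    )


def write_image(path, image: np.ndarray, bitdepth: int = 8) -> None:
    """Write a [0,1] float image as 8-bit PNG or 8/16-bit TIFF."""
    path = Path(path)
    image = np.clip(np.asarray(image, dtype=np.float32), 0.0, 1.0)
    if bitdepth == 8:
        arr = np.round(image * 255).astype(np.uint8)
    elif bitdepth == 16:
        arr = np.round(image * 65535).astype(np.uint16)
    else:
        raise ValueError("bitdepth must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        if bitdepth == 16 and arr.ndim == 3:
            raise ValueError("16-bit RGB PNG not supported; use TIFF")
        Image.fromarray(arr).save(path)


def read_label_mask(path) -> np.ndarray:
    arr = _decode(Path(path))
    if arr.ndim != 2:
        raise IOError(f"label mask {path} must be single-channel")
    return arr.astype(np.uint16)


def write_label_mask(path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.max() > 65535:
        raise ValueError("too many labels for a 16-bit mask")
    Image.fromarray(labels.astype(np.uint16 if labels.max() > 255 else np.uint8)).save(
        Path(path)
    )


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

def mm2_to_px(area_mm2: float, um_per_px: float) -> float:
    """Convert an area in mm^2 to pixels at the given calibration."""
    if um_per_px <= 0:
        raise ValueError("um_per_px must be > 0")
    if area_mm2 < 0:
        raise ValueError("area must be >= 0")
    return area_mm2 * 1e6 / um_per_px**2


def px_to_mm2(area_px: float, um_per_px: float) -> float:
    if um_per_px <= 0:
        raise ValueError("um_per_px must be > 0")
    return area_px * um_per_px**2 / 1e6


def um_to_px(length_um: float, um_per_px: float) -> float:
    if um_per_px <= 0:
        raise ValueError("um_per_px must be > 0")
    return length_um / um_per_px


# ---------------------------------------------------------------------------
# polygons
# ---------------------------------------------------------------------------

def rasterize_polygon(poly_xy: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Fill a closed (x, y) polygon into a boolean mask of the given shape."""
    poly = np.asarray(poly_xy, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
        raise ValueError("polygon must be an M x 2 array with M >= 3")
    rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def mask_to_polygons(mask: np.ndarray) -> list[np.ndarray]:
    """Trace closed (x, y) contours around the foreground of a boolean mask."""
    contours = measure.find_contours(np.asarray(mask, dtype=float), 0.5)
    return [np.stack([c[:, 1], c[:, 0]], axis=1) for c in contours]


# ---------------------------------------------------------------------------
# patch sampling
# ---------------------------------------------------------------------------

def _reflect_pad_to(img: np.ndarray, size: int) -> np.ndarray:
    h, w = img.shape[:2]
    ph, pw = max(0, size - h), max(0, size - w)
    if ph == 0 and pw == 0:
        return img
    pad = [(0, ph), (0, pw)] + [(0, 0)] * (img.ndim - 2)
    return np.pad(img, pad, mode="reflect")


def extract_patch(image: np.ndarray, center_rc: tuple[int, int], size: int) -> np.ndarray:
    """Extract a size x size patch centered at (row, col); reflect at borders."""
    h, w = image.shape[:2]
    r0 = int(center_rc[0]) - size // 2
    c0 = int(center_rc[1]) - size // 2
    pad_top = max(0, -r0)
    pad_left = max(0, -c0)
    pad_bot = max(0, r0 + size - h)
    pad_right = max(0, c0 + size - w)
    if pad_top or pad_left or pad_bot or pad_right:
        pad = [(pad_top, pad_bot), (pad_left, pad_right)] + [(0, 0)] * (image.ndim - 2)
        image = np.pad(image, pad, mode="reflect")
        r0 += pad_top
        c0 += pad_left
    return image[r0 : r0 + size, c0 : c0 + size]


def sample_patches(
    section: Section,
    annotations: AnnotationSet | None,
    n: int,
    seed: int,
    patch_size: int = 256,
    fiber_overlap_frac: float = 0.05,
    tissue_mask: np.ndarray | None = None,
) -> PatchBatch:
    """Sample ``n`` random patches uniformly over the (non-border) tissue area.

    Pixel labels are rasterized from ``annotations`` when given; a patch is
    class-labeled fiber iff it overlaps any bundle region by at least
    ``fiber_overlap_frac`` of the patch area.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = np.random.default_rng(seed)
    img = _reflect_pad_to(section.image, patch_size)
    h, w = img.shape[:2]
    union = None
    if annotations is not None:
        union = _reflect_pad_to(
            annotations.union_mask(section.shape).astype(np.uint8), patch_size
        )

    half = patch_size // 2
    if tissue_mask is not None:
        tm = _reflect_pad_to(tissue_mask.astype(bool), patch_size)
        rows, cols = np.nonzero(tm)
        ok = (
            (rows >= half) & (rows <= h - patch_size + half)
            & (cols >= half) & (cols <= w - patch_size + half)
        )
        candidates = np.stack([rows[ok], cols[ok]], axis=1)
    else:
        candidates = None

    patches = np.empty((n, patch_size, patch_size, 3), dtype=np.float32)
    labels = (
        np.empty((n, patch_size, patch_size), dtype=np.uint8) if union is not None else None
    )
    class_labels = np.zeros(n, dtype=np.uint8)
    coords = np.empty((n, 2), dtype=np.int64)
    for i in range(n):
        if candidates is not None and len(candidates):
            r, c = candidates[rng.integers(len(candidates))]
        else:
            r = int(rng.integers(half, h - patch_size + half + 1))
            c = int(rng.integers(half, w - patch_size + half + 1))
        coords[i] = (r, c)
        patches[i] = extract_patch(img, (r, c), patch_size)
        if union is not None:
            lab = extract_patch(union, (r, c), patch_size)
            labels[i] = lab
            class_labels[i] = int(lab.mean() >= fiber_overlap_frac)
    return PatchBatch(
        patches=patches, pixel_labels=labels, class_labels=class_labels, coords=coords
    )


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

MANIFEST_FIELDS = (
    "section_index",
    "image_path",
    "bundle_mask_path",
    "wm_mask_path",
    "pathway_mask_path",
    "um_per_px",
    "spacing_mm",
    "labeled",
)


def write_manifest(path, rows: list[dict]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=MANIFEST_FIELDS)
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row.get(k, "") for k in MANIFEST_FIELDS})


def read_manifest(path) -> list[dict]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            row["section_index"] = int(row["section_index"])
            row["um_per_px"] = float(row["um_per_px"])
            row["spacing_mm"] = float(row["spacing_mm"])
            row["labeled"] = row.get("labeled", "true").lower() in ("1", "true", "yes")
            out.append(row)
    return sorted(out, key=lambda r: r["section_index"])
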