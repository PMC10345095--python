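"""WSI preprocessing: grid tiling of an annotated ROI, augmentation, color
normalization, pluggable patch-feature extraction, and bag assembly.

The slide itself is abstracted as a plain raster (tifffile handles pyramidal
TIFFs); magnification scales are treated as relative downsample factors from
the base level.  Feature extraction is an injected callable so synthetic
feature bags and toy backbones share one code path with a real CNN backbone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "TileGrid", "MultiScaleBag", "tile_roi", "augment", "normalize_color",
    "extract_patch_features", "assemble_bag", "rasterize_polygon",
    "identity_backbone", "mean_pixel_backbone", "tiny_conv_backbone",
    "read_slide_level",
]

SCALES = (5, 10, 20)


@dataclass
class TileGrid:
    """Stride-aligned patch grid over one scale of a slide.

    ``origins`` are 0-based top-left pixel coordinates at that scale; patches
    are half-open windows [x, x+patch)x[y, y+patch).
    """

    scale: int
    patch_size: int
    origins: np.ndarray                 # (n, 2) int (x, y)
    tissue_fraction: np.ndarray         # (n,) in [0, 1]

    def __len__(self):
        return len(self.origins)


@dataclass
class MultiScaleBag:
    """Per-scale instance matrices (patch features) + grid origins for one WSI."""

    patient_id: str
    features: dict = field(default_factory=dict)   # scale -> (n_s, d)
    coords: dict = field(default_factory=dict)     # scale -> (n_s, 2)

    def __post_init__(self):
        if not self.features:
            raise ValueError("a bag needs at least one scale")
        dims = set()
        for sc, mat in self.features.items():
            mat = np.asarray(mat)
            if mat.ndim != 2 or mat.shape[0] < 1:
                raise ValueError(f"scale {sc}: need a nonempty n x d matrix")
            dims.add(mat.shape[1])
            self.features[sc] = mat
            if sc in self.coords:
                self.coords[sc] = np.asarray(self.coords[sc])
                if len(self.coords[sc]) != len(mat):
                    raise ValueError(f"scale {sc}: coords/features length mismatch")
        if len(dims) != 1:
            raise ValueError("feature dimension differs across scales")

    @property
    def feature_dim(self) -> int:
        return next(iter(self.features.values())).shape[1]

    def sizes(self) -> dict:
        return {sc: m.shape[0] for sc, m in self.features.items()}


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

def tile_roi(roi_mask: np.ndarray, scale: int, patch_size: int = 512,
             stride: int | None = None, min_tissue: float = 0.5) -> TileGrid:
    """Exhaustive stride-aligned grid over the mask, filtered by tissue fraction.

    Every stride-aligned window intersecting the mask's bounding box is
    scored by the fraction of ROI pixels it covers (out-of-raster area counts
    as background); windows with ``tissue_fraction >= min_tissue`` are kept.
    """
    mask = np.asarray(roi_mask).astype(bool)
    stride = stride or patch_size
    if not mask.any():
        warnings.warn("empty ROI mask: returning empty grid")
        return TileGrid(scale, patch_size, np.empty((0, 2), int), np.empty(0))
    ys, xs = np.where(mask)
    y0 = (ys.min() // stride) * stride
    x0 = (xs.min() // stride) * stride
    origins, fracs = [], []
    area = float(patch_size * patch_size)
    for y in range(y0, ys.max() + 1, stride):
        for x in range(x0, xs.max() + 1, stride):
            window = mask[y:y + patch_size, x:x + patch_size]
            frac = window.sum() / area
            if frac >= min_tissue:
                origins.append((x, y))
                fracs.append(frac)
    return TileGrid(scale, patch_size, np.asarray(origins, int).reshape(-1, 2),
                    np.asarray(fracs))


def map_coords(coords, from_scale: int, to_scale: int) -> np.ndarray:
    """Map pixel coordinates between magnification scales (x scale ratio).

    Coordinates are stored at their own scale; a point at 10x maps to 20x by
    doubling and back by halving.
    """
    if from_scale <= 0 or to_scale <= 0:
        raise ValueError("scales must be positive")
    return np.asarray(coords, float) * (to_scale / from_scale)


def rasterize_polygon(vertices, shape) -> np.ndarray:
    """Rasterize a polygon annotation ((x, y) vertex list) into a binary mask."""
    from skimage.draw import polygon

    verts = np.asarray(vertices, float)
    rr, cc = polygon(verts[:, 1], verts[:, 0], shape=shape)
    mask = np.zeros(shape, bool)
    mask[rr, cc] = True
    return mask


def read_slide_level(path, downsample: int = 1) -> np.ndarray:
    """Read a (pyramidal) TIFF and return the raster downsampled by ``downsample``.

    A minimal slide-reader stand-in: picks the stored pyramid level whose
    downsample matches if present, otherwise strided subsampling of level 0.
    """
    import tifffile

    with tifffile.TiffFile(path) as tf:
        base = tf.series[0].levels[0].shape
        for level in tf.series[0].levels:
            if round(base[0] / level.shape[0]) == downsample:
                return level.asarray()
        arr = tf.series[0].levels[0].asarray()
    return arr[::downsample, ::downsample]


# ---------------------------------------------------------------------------
# augmentation and color normalization
# ---------------------------------------------------------------------------

_DETERMINISTIC_OPS = {
    "hflip": lambda img, rng: img[:, ::-1],
    "vflip": lambda img, rng: img[::-1, :],
    "rotate90": lambda img, rng: np.rot90(img, 1),
}
_RANDOM_OPS = {
    "rotate90s": lambda img, rng: np.rot90(img, int(rng.integers(0, 4))),
    "brightness": lambda img, rng: img * rng.uniform(0.8, 1.2),
    "contrast": lambda img, rng: (img - img.mean()) * rng.uniform(0.8, 1.2)
    + img.mean(),
}


def augment(patch_image: np.ndarray, ops, seed: int = 0) -> np.ndarray:
    """Apply training-time augmentations in order; shape is preserved.

    ``hflip``/``vflip``/``rotate90`` are deterministic; ``rotate90s`` (random
    multiple of 90 degrees), ``brightness`` and ``contrast`` draw from the
    seeded generator.
    """
    rng = np.random.default_rng(seed)
    out = np.asarray(patch_image, float)
    for op in ops:
        if op in _DETERMINISTIC_OPS:
            out = _DETERMINISTIC_OPS[op](out, rng)
        elif op in _RANDOM_OPS:
            out = _RANDOM_OPS[op](out, rng)
        else:
            raise ValueError(f"unknown augmentation op {op!r}")
    return np.ascontiguousarray(out)


# Reference channel statistics for the stain-statistics normalizer (H&E-like
# pinks; arbitrary fixed target so the map is a deterministic fixed point).
_REF_MEAN = np.array([200.0, 160.0, 190.0])
_REF_STD = np.array([35.0, 45.0, 30.0])


def normalize_color(patch_image: np.ndarray, method: str = "identity") -> np.ndarray:
    """Color normalization; ``identity`` is an exact no-op, ``stain_stats``
    matches per-channel mean/std to fixed reference statistics (idempotent)."""
    img = np.asarray(patch_image, float)
    if method == "identity":
        return patch_image
    if method != "stain_stats":
        raise ValueError(f"unknown normalization method {method!r}")
    flat = img.reshape(-1, img.shape[-1]) if img.ndim == 3 else img.reshape(-1, 1)
    mean, std = flat.mean(axis=0), flat.std(axis=0)
    std[std == 0] = 1.0
    k = min(len(mean), 3)
    out = (img - mean) / std * _REF_STD[:k] + _REF_MEAN[:k]
    return out


# ---------------------------------------------------------------------------
# feature extraction backbones (pluggable)
# ---------------------------------------------------------------------------

def identity_backbone(patch: np.ndarray) -> np.ndarray:
    """Pass-through for inputs that already are feature vectors."""
    return np.asarray(patch, float).ravel()


def mean_pixel_backbone(patch: np.ndarray) -> np.ndarray:
    """Per-channel mean intensity; a 3-d toy feature."""
    img = np.asarray(patch, float)
    return img.reshape(-1, img.shape[-1]).mean(axis=0) if img.ndim == 3 \
        else np.array([img.mean()])


class tiny_conv_backbone:
    """A small untrained convolutional summarizer (seeded random filters,
    ReLU, global average pooling).  Deterministic given the seed; used for
    smoke tests of the raw-image path without pretrained weights."""

    def __init__(self, out_dim: int = 16, seed: int = 0, kernel: int = 7):
        rng = np.random.default_rng(seed)
        self.filters = rng.normal(0, 0.2, size=(out_dim, kernel, kernel))
        self.kernel = kernel

    def __call__(self, patch: np.ndarray) -> np.ndarray:
        img = np.asarray(patch, float)
        if img.ndim == 3:
            img = img.mean(axis=-1)
        k, s = self.kernel, self.kernel  # stride = kernel: cheap downsample
        h = (img.shape[0] // s) * s
        w = (img.shape[1] // s) * s
        blocks = img[:h, :w].reshape(h // s, s, w // s, s).transpose(0, 2, 1, 3)
        resp = np.einsum("ijkl,fkl->fij", blocks, self.filters)
        return np.maximum(resp, 0).mean(axis=(1, 2))


def extract_patch_features(patches, backbone) -> np.ndarray:
    """Row i of the result is ``backbone(patches[i])``; order preserved."""
    rows = [np.asarray(backbone(p), float).ravel() for p in patches]
    if not rows:
        return np.empty((0, 0))
    d = rows[0].size
    if any(r.size != d for r in rows):
        raise ValueError("backbone output dimension is inconsistent")
    return np.vstack(rows)


def assemble_bag(patient_id: str, features: dict, coords: dict | None = None
                 ) -> MultiScaleBag:
    """Validate per-scale instance matrices into a :class:`MultiScaleBag`."""
    return MultiScaleBag(str(patient_id), dict(features), dict(coords or {}))
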