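"""Segmentation and per-cell feature extraction.

The quantification contract mirrors a high-content screening pipeline:
maximum-project the z-stack, segment nuclei on the DNA channel, grow cell
bodies from nucleus seeds on the cytoplasm channel, drop cells touching the
field border, and extract a fixed 28-element morphology + texture feature
vector per cell.

Texture features follow an open spot/edge/ridge (SER) formulation built from
Gaussian-derivative responses of the cytoplasm channel, normalised by mean
local intensity so that every texture score is invariant to multiplying the
image by a positive constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk, skeletonize
from skimage.segmentation import watershed


class SegmentationError(ValueError):
    """Raised when an image cannot be segmented (e.g. constant input)."""


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

CHANNEL_ROLES = ("nucleus", "cytoplasm", "paxillin", "actin", "donor", "acceptor")


@dataclass
class ImageField:
    """Pixel data indexed ``(channel, z, t, y, x)`` with channel roles.

    Singleton axes are allowed; 2D/3D/4D arrays are promoted on input by
    :meth:`from_array`.  ``pixel_size_um`` applies to y and x.
    """

    pixels: np.ndarray
    channel_roles: Dict[int, str] = field(default_factory=dict)
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 5:
            raise ValueError(
                f"pixels must be 5D (channel, z, t, y, x), got {self.pixels.ndim}D"
            )
        if self.pixels.size and self.pixels.min() < 0:
            raise ValueError("pixel values must be non-negative")
        n_channels = self.pixels.shape[0]
        for idx, role in self.channel_roles.items():
            if not (0 <= idx < n_channels):
                raise ValueError(f"channel role index {idx} out of range")
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {role!r}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @classmethod
    def from_array(
        cls,
        arr: np.ndarray,
        channel_roles: Optional[Dict[int, str]] = None,
        pixel_size_um: float = 1.0,
        axes: str = "cztyx",
    ) -> "ImageField":
        """Promote a lower-dimensional array, adding singleton axes.

        ``axes`` names the axes present in ``arr`` (subset of ``cztyx`` in
        that order, always ending with ``yx``).
        """
        arr = np.asarray(arr)
        if len(axes) != arr.ndim:
            raise ValueError("axes string must match array dimensionality")
        full = "cztyx"
        if any(a not in full for a in axes) or list(axes) != [
            a for a in full if a in axes
        ]:
            raise ValueError(f"axes must be an ordered subset of {full!r}")
        expand = tuple(i for i, a in enumerate(full) if a not in axes)
        arr5 = np.expand_dims(arr, expand)
        return cls(arr5, channel_roles or {}, pixel_size_um)

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape_yx(self) -> Tuple[int, int]:
        return self.pixels.shape[-2:]

    def channel_index(self, role: str) -> int:
        for idx, r in self.channel_roles.items():
            if r == role:
                return idx
        raise KeyError(f"no channel with role {role!r}")

    def plane(self, channel: int = 0, z: int = 0, t: int = 0) -> np.ndarray:
        """A single (y, x) plane."""
        return self.pixels[channel, z, t]

    def role_plane(self, role: str, z: int = 0, t: int = 0) -> np.ndarray:
        return self.plane(self.channel_index(role), z, t)


@dataclass
class LabelMask:
    """Integer label image; 0 is background, labels are consecutive."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2D")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def mask_of(self, lbl: int) -> np.ndarray:
        return self.labels == lbl


@dataclass
class CellRecord:
    """One segmented cell with its 28-element feature vector."""

    plate: str
    well: str
    field: int
    cell_id: int
    edge: bool
    features: Dict[str, float]

    def vector(self) -> np.ndarray:
        return np.array([self.features[n] for n in FEATURE_NAMES], dtype=float)


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    out = np.zeros_like(labels)
    for new, old in enumerate(ids, start=1):
        out[labels == old] = new
    return out


# --------------------------------------------------------------------------
# projection and segmentation
# --------------------------------------------------------------------------


def max_project(fld: ImageField) -> ImageField:
    """Maximum-intensity projection over z (idempotent)."""
    if fld.pixels.shape[1] < 1:
        raise ValueError("z axis must have length >= 1")
    proj = fld.pixels.max(axis=1, keepdims=True)
    return ImageField(proj, dict(fld.channel_roles), fld.pixel_size_um)


def segment_nuclei(
    nucleus_channel: np.ndarray,
    min_area_px: int = 60,
    smooth_sigma: float = 2.0,
) -> LabelMask:
    """Otsu-threshold the smoothed DNA channel and label nuclei.

    Objects smaller than ``min_area_px`` are removed and the remaining
    labels renumbered consecutively.  The threshold is the larger of Otsu on
    the smoothed image and a robust noise floor (median + 5 MAD-sigma), so a
    signal-free noise image yields no objects.  A constant image has no
    threshold and raises :class:`SegmentationError`.
    """
    img = np.asarray(nucleus_channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("nucleus channel must be 2D")
    if np.ptp(img) == 0:
        raise SegmentationError("cannot segment a constant image")
    smoothed = ndi.gaussian_filter(img, smooth_sigma)
    med = np.median(smoothed)
    floor = med + 5.0 * 1.4826 * np.median(np.abs(smoothed - med))
    thr = max(threshold_otsu(smoothed), floor)
    fg = smoothed > thr
    labels = cc_label(fg, connectivity=2)
    if min_area_px > 0 and labels.max():
        areas = np.bincount(labels.ravel())
        drop = np.flatnonzero(areas < min_area_px)
        labels[np.isin(labels, drop)] = 0
    return LabelMask(_relabel_consecutive(labels))


def segment_cells(
    cyto_channel: np.ndarray,
    nuclei: LabelMask,
    smooth_sigma: float = 2.0,
) -> LabelMask:
    """Grow one cell body per nucleus on the cytoplasm channel.

    Foreground is Otsu-thresholded (union of the nuclei, so a nucleus with
    no cytoplasm signal still yields a cell equal to its nucleus); cells are
    the watershed basins of the inverted smoothed intensity seeded by the
    nucleus labels.  Foreground blobs not reachable from any seed stay
    background, so cell count equals nucleus count.
    """
    img = np.asarray(cyto_channel, dtype=float)
    if img.shape != nuclei.labels.shape:
        raise ValueError("cytoplasm channel and nuclei mask shapes differ")
    if nuclei.n_labels == 0:
        warnings.warn("empty nuclei mask: returning empty cell mask")
        return LabelMask(np.zeros_like(nuclei.labels))
    smoothed = ndi.gaussian_filter(img, smooth_sigma)
    if np.ptp(smoothed) == 0:
        fg = nuclei.labels > 0
    else:
        fg = (smoothed > threshold_otsu(smoothed)) | (nuclei.labels > 0)
    labels = watershed(-smoothed, markers=nuclei.labels, mask=fg)
    # keep, per cell, only the connected component containing its nucleus
    out = np.zeros_like(labels)
    slices = ndi.find_objects(labels)
    for lbl in nuclei.label_ids:
        sl = slices[lbl - 1]
        if sl is None:  # pragma: no cover - seeds always lie in their basin
            out[nuclei.labels == lbl] = lbl
            continue
        sub = labels[sl] == lbl
        comp = cc_label(sub, connectivity=2)
        seed_comps = np.unique(comp[nuclei.labels[sl] == lbl])
        seed_comps = seed_comps[seed_comps > 0]
        if seed_comps.size:
            out[sl][comp == seed_comps[0]] = lbl
        else:  # pragma: no cover
            out[nuclei.labels == lbl] = lbl
    return LabelMask(out)


def remove_edge_objects(mask: LabelMask) -> Tuple[LabelMask, List[int]]:
    """Drop labels touching the field border; labels are renumbered.

    Returns the cleaned mask and the list of removed (original) labels.
    """
    labels = mask.labels
    border = np.concatenate(
        [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
    )
    removed = sorted(int(v) for v in np.unique(border) if v > 0)
    cleaned = labels.copy()
    if removed:
        cleaned[np.isin(cleaned, removed)] = 0
    return LabelMask(_relabel_consecutive(cleaned)), removed


# --------------------------------------------------------------------------
# SER texture responses
# --------------------------------------------------------------------------

SER_KINDS = ("spot", "hole", "edge", "ridge", "valley", "saddle", "bright", "dark")

_EPS = 1e-6


def ser_responses(
    image: np.ndarray,
    scale_px: float,
    kinds: Optional[Sequence[str]] = None,
) -> Dict[str, np.ndarray]:
    """Pixelwise SER responses at Gaussian scale ``scale_px``.

    All responses are non-negative and linear in the image:

    * ridge  = max(0, -lambda_min of the Hessian)  (bright lines)
    * valley = max(0, +lambda_max)                 (dark lines)
    * edge   = gradient magnitude
    * spot   = max(0, -Laplacian), hole = max(0, +Laplacian)
    * saddle = sqrt(-lambda_min * lambda_max) where the eigenvalues differ
      in sign, else 0
    * bright/dark = positive/negative deviation of the smoothed image from
      a 4x-coarser local mean

    Restricting ``kinds`` skips the derivative filters the requested
    responses do not need.
    """
    img = np.ascontiguousarray(image, dtype=np.float32)
    if scale_px <= 0:
        raise ValueError("scale_px must be positive")
    if kinds is None:
        kinds = SER_KINDS
    unknown = set(kinds) - set(SER_KINDS)
    if unknown:
        raise ValueError(f"unknown SER kinds {sorted(unknown)}")
    s = scale_px
    out: Dict[str, np.ndarray] = {}
    if np.ptp(img) == 0:  # constant image: all derivative responses vanish
        return {k: np.zeros_like(img) for k in kinds}

    need_hessian = {"spot", "hole", "ridge", "valley", "saddle"} & set(kinds)
    if need_hessian:
        hyy = ndi.gaussian_filter(img, s, order=(2, 0))
        hxx = ndi.gaussian_filter(img, s, order=(0, 2))
        hxy = ndi.gaussian_filter(img, s, order=(1, 1))
        trace = hxx + hyy
        root = np.sqrt(np.maximum((hxx - hyy) ** 2 + 4 * hxy**2, 0.0))
        lam_max = 0.5 * (trace + root)
        lam_min = 0.5 * (trace - root)
        if "spot" in kinds:
            out["spot"] = np.maximum(-trace, 0.0)
        if "hole" in kinds:
            out["hole"] = np.maximum(trace, 0.0)
        if "ridge" in kinds:
            out["ridge"] = np.maximum(-lam_min, 0.0)
        if "valley" in kinds:
            out["valley"] = np.maximum(lam_max, 0.0)
        if "saddle" in kinds:
            opposite = (lam_min < 0) & (lam_max > 0)
            out["saddle"] = np.where(
                opposite, np.sqrt(np.maximum(-lam_min * lam_max, 0.0)), 0.0
            )
    if "edge" in kinds:
        gy = ndi.gaussian_filter(img, s, order=(1, 0))
        gx = ndi.gaussian_filter(img, s, order=(0, 1))
        out["edge"] = np.hypot(gx, gy)
    if {"bright", "dark"} & set(kinds):
        smoothed = ndi.gaussian_filter(img, s)
        local = ndi.gaussian_filter(img, 4 * s, truncate=2.5)
        dev = smoothed - local
        if "bright" in kinds:
            out["bright"] = np.maximum(dev, 0.0)
        if "dark" in kinds:
            out["dark"] = np.maximum(-dev, 0.0)
    return out


def ser_score(
    response: np.ndarray, smoothed: np.ndarray, region: np.ndarray
) -> float:
    """Mean in-region response normalised by mean in-region intensity."""
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("region is empty")
    return float(response[region].mean() / (smoothed[region].mean() + _EPS))


def ser_ridge_score(
    image: np.ndarray, region: np.ndarray, scale_px: float
) -> float:
    """SER-Ridge score: line-like bright structure per unit intensity.

    Zero on constant images; invariant to multiplying the image by any
    positive constant.
    """
    img = np.asarray(image, dtype=float)
    resp = ser_responses(img, scale_px)["ridge"]
    smoothed = ndi.gaussian_filter(img, scale_px)
    return ser_score(resp, smoothed, region)


# --------------------------------------------------------------------------
# morphology
# --------------------------------------------------------------------------


def count_protrusions(
    mask: np.ndarray,
    min_length_px: float = 12.0,
    opening_radius: int = 2,
) -> int:
    """Count protrusions as pruned endpoints of the skeletonised mask.

    The mask is lightly opened to suppress boundary roughness, skeletonised,
    and each skeleton endpoint is traced towards the nearest junction; only
    endpoints whose branch is at least ``min_length_px`` long count.  A pure
    line (no junction) contributes both of its endpoints, so a spindle
    scores 2 and a disc 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if opening_radius > 0:
        mask = ndi.binary_opening(mask, structure=disk(opening_radius))
    if mask.sum() < 4:
        return 0
    skel = skeletonize(mask)
    coords = {tuple(p) for p in np.argwhere(skel)}
    if len(coords) < 2:
        return 0

    def neighbors(p):
        y, x = p
        out = []
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == dx == 0:
                    continue
                q = (y + dy, x + dx)
                if q in coords:
                    out.append(q)
        return out

    degree = {p: len(neighbors(p)) for p in coords}
    endpoints = [p for p, d in degree.items() if d == 1]
    count = 0
    for ep in endpoints:
        length = 0.0
        prev, cur = None, ep
        while True:
            if degree[cur] >= 3 and cur != ep:
                break  # reached a junction
            nxt = [q for q in neighbors(cur) if q != prev]
            if not nxt:
                break  # other end of an unbranched line
            step = nxt[0]
            length += np.hypot(step[0] - cur[0], step[1] - cur[1])
            prev, cur = cur, step
            if length > min_length_px:
                break
        if length >= min_length_px:
            count += 1
    return count


def _crop(mask: np.ndarray, pad: int = 2) -> np.ndarray:
    """Tight bounding-box crop of a boolean mask (with padding)."""
    ys, xs = np.nonzero(mask)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    h, w = mask.shape
    return mask[
        max(y0 - pad, 0) : min(y1 + pad, h), max(x0 - pad, 0) : min(x1 + pad, w)
    ]


def cell_roundness(mask: np.ndarray) -> float:
    """Roundness 4*pi*A/P^2 with a Crofton perimeter; 1 for a disc."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    mask = _crop(mask)
    props = regionprops(mask.astype(np.uint8))[0]
    perim = props.perimeter_crofton
    if perim == 0:
        return 1.0
    return float(min(4.0 * np.pi * props.area / perim**2, 1.0))


# --------------------------------------------------------------------------
# the 28-feature vector
# --------------------------------------------------------------------------

#: Gaussian scales (px) for the fine and coarse texture features.
SER_SCALES = (1.0, 2.0)

MORPHOLOGY_FEATURES = (
    "area_um2",
    "perimeter_um",
    "roundness",
    "length_um",
    "width_um",
    "axial_ratio",
    "eccentricity",
    "solidity",
    "extent",
    "convex_area_um2",
    "protrusion_count",
    "nucleus_area_um2",
    "nucleus_cell_area_ratio",
    "centroid_displacement_um",
)

TEXTURE_FEATURES = (
    "int_mean",
    "int_sd",
    "int_mad",
    "ser_spot_s1",
    "ser_hole_s1",
    "ser_edge_s1",
    "ser_ridge_s1",
    "ser_valley_s1",
    "ser_saddle_s1",
    "ser_bright_s1",
    "ser_dark_s1",
    "ser_ridge_s2",
    "ser_edge_s2",
    "ser_valley_s2",
)

#: The fixed, ordered feature contract: 14 morphology + 14 texture = 28.
FEATURE_NAMES: Tuple[str, ...] = MORPHOLOGY_FEATURES + TEXTURE_FEATURES
assert len(FEATURE_NAMES) == 28


#: SER kinds used at each scale in the 28-feature vector
_SER_KINDS_BY_SCALE = {
    SER_SCALES[0]: SER_KINDS,
    SER_SCALES[1]: ("ridge", "edge", "valley"),
}


class _TextureMaps:
    """Per-field cache of smoothed images and SER responses."""

    def __init__(self, image: np.ndarray):
        self.image = np.ascontiguousarray(image, dtype=np.float32)
        self.smoothed = {
            s: ndi.gaussian_filter(self.image, s) for s in SER_SCALES
        }
        self.responses = {
            s: ser_responses(self.image, s, _SER_KINDS_BY_SCALE[s])
            for s in SER_SCALES
        }


def extract_all_features(
    cells: LabelMask,
    nuclei: LabelMask,
    fld: ImageField,
    only: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Feature table for every label in ``cells`` (index = label id).

    Morphology is computed per label on its bounding-box crop; texture
    scores use labelled reductions over per-field response maps, so the
    cost per extra cell is small.
    """
    px = fld.pixel_size_um
    cyto = np.asarray(fld.role_plane("cytoplasm"), dtype=float)
    ids = [int(l) for l in (only if only is not None else cells.label_ids)]
    if not ids:
        return pd.DataFrame(columns=list(FEATURE_NAMES)).rename_axis("cell_id")

    cell_props = {p.label: p for p in regionprops(cells.labels)}
    nuc_props = {p.label: p for p in regionprops(nuclei.labels)}
    missing = [l for l in ids if l not in cell_props]
    if missing:
        raise KeyError(f"labels {missing} not present in cell mask")

    rows: Dict[int, Dict[str, float]] = {}
    for lbl in ids:
        p = cell_props[lbl]
        minor = max(p.axis_minor_length, 1.0)
        npx = nuc_props.get(lbl)
        nuc_area = float(npx.area) if npx is not None else 0.0
        disp = (
            float(np.hypot(*(np.subtract(p.centroid, npx.centroid))))
            if npx is not None
            else 0.0
        )
        rows[lbl] = {
            "area_um2": float(p.area) * px**2,
            "perimeter_um": float(p.perimeter_crofton) * px,
            "roundness": cell_roundness(p.image),
            "length_um": float(p.axis_major_length) * px,
            "width_um": float(p.axis_minor_length) * px,
            "axial_ratio": float(p.axis_major_length / minor),
            "eccentricity": float(p.eccentricity),
            "solidity": float(p.solidity),
            "extent": float(p.extent),
            "convex_area_um2": float(p.area_convex) * px**2,
            "protrusion_count": float(count_protrusions(p.image)),
            "nucleus_area_um2": nuc_area * px**2,
            "nucleus_cell_area_ratio": nuc_area / float(p.area),
            "centroid_displacement_um": disp * px,
        }

    # intensity + texture via labelled reductions
    labels = cells.labels
    means = ndi.mean(cyto, labels, ids)
    sds = ndi.standard_deviation(cyto, labels, ids)
    for lbl, m, s in zip(ids, means, sds):
        rows[lbl]["int_mean"] = float(m)
        rows[lbl]["int_sd"] = float(s)
        sl = cell_props[lbl].slice
        vals = cyto[sl][labels[sl] == lbl]
        rows[lbl]["int_mad"] = float(np.median(np.abs(vals - np.median(vals))))

    tex = _TextureMaps(cyto)
    s1, s2 = SER_SCALES
    for scale, kinds, tag in ((s1, SER_KINDS, "s1"), (s2, ("ridge", "edge", "valley"), "s2")):
        denom = np.asarray(ndi.mean(tex.smoothed[scale], labels, ids)) + _EPS
        for kind in kinds:
            numer = np.asarray(ndi.mean(tex.responses[scale][kind], labels, ids))
            for lbl, v in zip(ids, numer / denom):
                rows[lbl][f"ser_{kind}_{tag}"] = float(v)

    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))
    df.index.name = "cell_id"
    return df


def extract_features(
    lbl: int,
    cells: LabelMask,
    nuclei: LabelMask,
    fld: ImageField,
) -> Dict[str, float]:
    """The 28-element feature vector of one cell (see
    :func:`extract_all_features`)."""
    df = extract_all_features(cells, nuclei, fld, only=[int(lbl)])
    return df.loc[int(lbl)].to_dict()


def segment_field(
    fld: ImageField,
    min_nucleus_area_px: int = 60,
) -> Tuple[LabelMask, LabelMask, List[int]]:
    """Project, segment nuclei and cells, and drop border-touching cells.

    Returns (cells, nuclei, removed_edge_labels); the two masks share label
    ids after edge removal.
    """
    proj = max_project(fld)
    nuc_img = proj.role_plane("nucleus")
    cyto_img = proj.role_plane("cytoplasm")
    nuclei = segment_nuclei(nuc_img, min_area_px=min_nucleus_area_px)
    cells = segment_cells(cyto_img, nuclei)
    cleaned, removed = remove_edge_objects(cells)
    # renumber nuclei consistently with the surviving cells
    new_nuc = np.zeros_like(nuclei.labels)
    keep = [l for l in cells.label_ids if l not in removed]
    for new, old in enumerate(sorted(keep), start=1):
        new_nuc[nuclei.labels == old] = new
    return cleaned, LabelMask(new_nuc), removed
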