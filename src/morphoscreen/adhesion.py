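"""Focal-adhesion detection, tracking and quantification.

Adhesions are detected per frame on a background-corrected Paxillin channel,
linked frame-to-frame by maximal pixel overlap, filtered to tracks of at
least five frames, and summarised both statically (area, intensity, axial
ratio, longevity, spatial dispersion) and kinetically: the slope of
ln(intensity) versus time before (assembly) and after (disassembly) the
intensity peak, each fit gated at R^2 > 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from scipy.spatial import ConvexHull, QhullError
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .imaging import ImageField, LabelMask, ser_ridge_score


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class TrackFrame:
    t_index: int
    area_px: float
    mean_intensity: float
    centroid_xy: Tuple[float, float]  # (x, y)
    axial_ratio: float
    orientation_deg: float


@dataclass
class AdhesionTrack:
    track_id: int
    frames: List[TrackFrame]
    frame_interval_s: float = 60.0

    def __post_init__(self) -> None:
        ts = [f.t_index for f in self.frames]
        if any(b - a != 1 for a, b in zip(ts, ts[1:])):
            raise ValueError("track frames must be consecutive")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([f.mean_intensity for f in self.frames])

    @property
    def times_min(self) -> np.ndarray:
        return np.array([f.t_index for f in self.frames]) * self.frame_interval_s / 60.0

    @property
    def mean_centroid(self) -> Tuple[float, float]:
        xs = np.array([f.centroid_xy[0] for f in self.frames])
        ys = np.array([f.centroid_xy[1] for f in self.frames])
        return float(xs.mean()), float(ys.mean())


@dataclass
class KineticsFit:
    phase: str  # assembly / disassembly
    rate_per_min: float
    phase_length_min: float
    r_squared: float
    n_points: int


@dataclass
class StaticSummary:
    track_id: int
    mean_area: float
    mean_axial_ratio: float
    mean_intensity: float
    longevity_min: float
    mean_dist_centroid: float
    mean_dist_hull: float


# --------------------------------------------------------------------------
# detection
# --------------------------------------------------------------------------


def detect_adhesions(
    frame: np.ndarray,
    min_size_px: int = 10,
    highpass_sigma: float = 20.0,
) -> LabelMask:
    """Threshold a background-corrected frame and drop small components.

    Background is estimated by a wide Gaussian and subtracted; the
    threshold is the larger of Otsu on the high-pass image and a robust
    noise floor (median + 5 MAD-sigma), which keeps Otsu honest when
    adhesions cover a small fraction of the frame.
    """
    img = np.asarray(frame, dtype=float)
    hp = img - ndi.gaussian_filter(img, highpass_sigma)
    med = np.median(hp)
    mad_sigma = 1.4826 * np.median(np.abs(hp - med))
    floor = med + 5.0 * mad_sigma
    if np.ptp(hp) == 0:
        return LabelMask(np.zeros(img.shape, dtype=int))
    thr = max(threshold_otsu(hp), floor)
    labels = cc_label(hp > thr, connectivity=2)
    if labels.max():
        areas = np.bincount(labels.ravel())
        drop = np.flatnonzero(areas < min_size_px)
        labels[np.isin(labels, drop)] = 0
        # relabel consecutively
        ids = np.unique(labels)
        ids = ids[ids > 0]
        out = np.zeros_like(labels)
        for new, old in enumerate(ids, start=1):
            out[labels == old] = new
        labels = out
    return LabelMask(labels)


def _measure(labels: LabelMask, intensity: np.ndarray) -> Dict[int, TrackFrame]:
    out = {}
    for p in regionprops(labels.labels, intensity_image=intensity):
        minor = max(p.axis_minor_length, 1.0)
        out[p.label] = dict(
            area_px=float(p.area),
            mean_intensity=float(p.intensity_mean),
            centroid_xy=(float(p.centroid[1]), float(p.centroid[0])),
            axial_ratio=float(p.axis_major_length / minor),
            orientation_deg=float(np.degrees(p.orientation)) % 180.0,
        )
    return out


# --------------------------------------------------------------------------
# linking
# --------------------------------------------------------------------------


def link_tracks(
    masks: Sequence[LabelMask],
    intensity_frames: Sequence[np.ndarray],
    min_track_frames: int = 5,
    frame_interval_s: float = 60.0,
) -> List[AdhesionTrack]:
    """Link per-frame detections into tracks by maximal pixel overlap.

    Each object inherits the track of the previous-frame object it overlaps
    most (ties: larger overlap, then lower label).  When two tracks merge,
    the larger parent keeps the identity; when a track splits, the child
    with larger overlap keeps it and the other child starts a new track.
    Tracks shorter than ``min_track_frames`` are discarded.
    """
    if len(masks) != len(intensity_frames):
        raise ValueError("masks and intensity frames must align")
    if not masks:
        return []
    next_track = 1
    # per frame: {label -> track_id}
    assignments: List[Dict[int, int]] = []
    measures: List[Dict[int, dict]] = []
    for t, (mask, img) in enumerate(zip(masks, intensity_frames)):
        measures.append(_measure(mask, np.asarray(img, dtype=float)))
        cur: Dict[int, int] = {}
        if t == 0:
            for lbl in mask.label_ids:
                cur[int(lbl)] = next_track
                next_track += 1
        else:
            prev_mask = masks[t - 1]
            prev_assign = assignments[t - 1]
            # overlap counts between previous and current labels
            both = (prev_mask.labels > 0) & (mask.labels > 0)
            pairs: Dict[Tuple[int, int], int] = {}
            if both.any():
                pl = prev_mask.labels[both].astype(np.int64)
                cl = mask.labels[both].astype(np.int64)
                keys = pl * (mask.labels.max() + 1) + cl
                uniq, counts = np.unique(keys, return_counts=True)
                for k, n in zip(uniq, counts):
                    a = int(k // (mask.labels.max() + 1))
                    b2 = int(k % (mask.labels.max() + 1))
                    pairs[(a, b2)] = int(n)
            # choose best predecessor per current label
            best_prev: Dict[int, Tuple[int, int]] = {}  # cur -> (overlap, prev)
            for (a, b2), n in pairs.items():
                cand = best_prev.get(b2)
                if cand is None or n > cand[0] or (n == cand[0] and a < cand[1]):
                    best_prev[b2] = (n, a)
            # resolve competition for the same track (splits): larger overlap
            claimed: Dict[int, Tuple[int, int]] = {}  # track -> (overlap, cur label)
            for b2, (n, a) in sorted(best_prev.items()):
                tid = prev_assign.get(a)
                if tid is None:
                    continue
                cand = claimed.get(tid)
                if cand is None or n > cand[0] or (n == cand[0] and b2 < cand[1]):
                    claimed[tid] = (n, b2)
            winners = {b2: tid for tid, (n, b2) in claimed.items()}
            for lbl in mask.label_ids:
                lbl = int(lbl)
                if lbl in winners:
                    cur[lbl] = winners[lbl]
                else:
                    cur[lbl] = next_track
                    next_track += 1
        assignments.append(cur)

    # assemble tracks; a track interrupted by a gap keeps only its first run
    frames_by_track: Dict[int, List[TrackFrame]] = {}
    for t, (assign, meas) in enumerate(zip(assignments, measures)):
        for lbl, tid in assign.items():
            frames_by_track.setdefault(tid, []).append(
                TrackFrame(t_index=t, **meas[lbl])
            )
    tracks = []
    for tid, frames in sorted(frames_by_track.items()):
        frames.sort(key=lambda f: f.t_index)
        run = [frames[0]]
        for f in frames[1:]:
            if f.t_index == run[-1].t_index + 1:
                run.append(f)
            else:
                break
        if len(run) >= min_track_frames:
            tracks.append(AdhesionTrack(tid, run, frame_interval_s))
    return tracks


def track_movie(
    movie: ImageField,
    channel_role: str = "paxillin",
    min_size_px: int = 10,
    min_track_frames: int = 5,
) -> List[AdhesionTrack]:
    """Detect and link adhesions across all frames of a movie."""
    ch = movie.channel_index(channel_role)
    n_frames = movie.pixels.shape[2]
    frames = [movie.pixels[ch, 0, t] for t in range(n_frames)]
    masks = [detect_adhesions(f, min_size_px=min_size_px) for f in frames]
    interval = 60.0
    return link_tracks(masks, frames, min_track_frames, interval)


# --------------------------------------------------------------------------
# static and kinetic summaries
# --------------------------------------------------------------------------


def _dist_to_hull_boundary(point: np.ndarray, points: np.ndarray) -> float:
    """Distance from a point to the boundary of the 2D convex hull of
    ``points`` (0 when on the hull or the hull is degenerate)."""
    pts = np.unique(points, axis=0)
    if len(pts) < 3:
        # degenerate hull: boundary is the point/segment itself
        if len(pts) == 1:
            return float(np.hypot(*(point - pts[0])))
        return _point_segment_distance(point, pts[0], pts[1])
    try:
        hull = ConvexHull(pts)
    except QhullError:
        d = [
            _point_segment_distance(point, pts[i], pts[j])
            for i in range(len(pts))
            for j in range(i + 1, len(pts))
        ]
        return float(min(d))
    verts = pts[hull.vertices]
    d = [
        _point_segment_distance(point, verts[i], verts[(i + 1) % len(verts)])
        for i in range(len(verts))
    ]
    return float(min(d))


def _point_segment_distance(p, a, b) -> float:
    p, a, b = (np.asarray(v, dtype=float) for v in (p, a, b))
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return float(np.hypot(*(p - a)))
    t = float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.hypot(*(p - (a + t * ab))))


def static_summary(
    track: AdhesionTrack, all_tracks: Sequence[AdhesionTrack]
) -> StaticSummary:
    """Per-track static properties.

    Spatial dispersion is measured against the cloud of all track mean
    centroids in the movie: distance to the cloud centroid and to the
    boundary of its convex hull (0 for a track on the hull).
    """
    centroids = np.array([t.mean_centroid for t in all_tracks])
    own = np.array(track.mean_centroid)
    cloud_centroid = centroids.mean(axis=0)
    dist_centroid = float(np.hypot(*(own - cloud_centroid)))
    dist_hull = _dist_to_hull_boundary(own, centroids) if len(centroids) > 1 else 0.0
    return StaticSummary(
        track_id=track.track_id,
        mean_area=float(np.mean([f.area_px for f in track.frames])),
        mean_axial_ratio=float(np.mean([f.axial_ratio for f in track.frames])),
        mean_intensity=float(track.intensities.mean()),
        longevity_min=track.n_frames * track.frame_interval_s / 60.0,
        mean_dist_centroid=dist_centroid,
        mean_dist_hull=dist_hull,
    )


def summarize_tracks(tracks: Sequence[AdhesionTrack]) -> pd.DataFrame:
    rows = [static_summary(t, tracks).__dict__ for t in tracks]
    return pd.DataFrame(rows)


def fit_kinetics(
    track: AdhesionTrack,
    r2_gate: float = 0.9,
    background: float = 0.0,
    min_phase_points: int = 3,
) -> Tuple[List[KineticsFit], List[KineticsFit]]:
    """Log-linear assembly/disassembly fits around the intensity peak.

    Intensity is background-subtracted and floored at 1 count before the
    natural log.  Assembly is fit on [birth, peak], disassembly on
    [peak, death]; disassembly rates are reported positive.  Returns
    ``(retained, rejected)`` where rejected fits failed the R^2 gate.
    """
    inten = np.maximum(track.intensities - background, 1.0)
    times = track.times_min
    peak = int(np.argmax(inten))
    retained: List[KineticsFit] = []
    rejected: List[KineticsFit] = []

    def _fit(idx: np.ndarray, phase: str, sign: float):
        if idx.size < min_phase_points:
            return
        res = stats.linregress(times[idx], np.log(inten[idx]))
        r2 = float(res.rvalue**2) if not np.isnan(res.rvalue) else 0.0
        fit = KineticsFit(
            phase=phase,
            rate_per_min=float(sign * res.slope),
            phase_length_min=float(times[idx][-1] - times[idx][0]),
            r_squared=r2,
            n_points=int(idx.size),
        )
        (retained if r2 > r2_gate else rejected).append(fit)

    _fit(np.arange(0, peak + 1), "assembly", +1.0)
    _fit(np.arange(peak, len(inten)), "disassembly", -1.0)
    return retained, rejected


def quick_assembly_threshold(rates: Sequence[float]) -> float:
    """Upper-tercile cutoff used to label quick-assembling adhesions."""
    return float(np.quantile(np.asarray(rates, dtype=float), 2.0 / 3.0))


# --------------------------------------------------------------------------
# orientation
# --------------------------------------------------------------------------


def fa_orientation(
    adhesion_mask: np.ndarray,
    cell_mask: np.ndarray,
    min_axial_ratio: float = 1.05,
) -> Optional[float]:
    """Angle between adhesion and cell long axes, folded into [0, 90] deg.

    Returns None (orientation undefined) for near-circular adhesions with
    axial ratio below ``min_axial_ratio``.
    """
    angles = []
    for m in (adhesion_mask, cell_mask):
        p = regionprops(np.asarray(m, dtype=bool).astype(np.uint8))
        if not p:
            raise ValueError("empty mask")
        angles.append(p[0])
    ad, cell = angles
    minor = max(ad.axis_minor_length, 1e-9)
    if ad.axis_major_length / minor < min_axial_ratio:
        return None
    diff = np.degrees(ad.orientation - cell.orientation)
    diff = abs(diff) % 180.0
    return float(min(diff, 180.0 - diff))


# --------------------------------------------------------------------------
# kymographs and peak alignment
# --------------------------------------------------------------------------


def extract_kymograph(
    movie: ImageField,
    p0: Tuple[float, float],
    p1: Tuple[float, float],
    width_px: int = 3,
    channels: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Intensity along a line over time: array (channel, position, time).

    Samples by bilinear interpolation at unit spacing along the segment
    from ``p0`` to ``p1`` (x, y coordinates), averaging ``width_px``
    parallel lines across the segment normal.
    """
    if channels is None:
        channels = list(range(movie.n_channels))
    x0, y0 = p0
    x1, y1 = p1
    length = max(int(round(np.hypot(x1 - x0, y1 - y0))) + 1, 2)
    s = np.linspace(0.0, 1.0, length)
    xs = x0 + s * (x1 - x0)
    ys = y0 + s * (y1 - y0)
    norm = np.array([-(y1 - y0), x1 - x0], dtype=float)
    n = np.hypot(*norm)
    norm = norm / n if n > 0 else np.array([0.0, 1.0])
    offsets = np.arange(width_px) - (width_px - 1) / 2.0
    n_frames = movie.pixels.shape[2]
    out = np.zeros((len(channels), length, n_frames))
    for ci, ch in enumerate(channels):
        for t in range(n_frames):
            img = movie.pixels[ch, 0, t]
            acc = np.zeros(length)
            for off in offsets:
                coords = np.stack([ys + off * norm[1], xs + off * norm[0]])
                acc += ndi.map_coordinates(img, coords, order=1, mode="nearest")
            out[ci, :, t] = acc / len(offsets)
    return out


def align_to_peak(
    traces: Sequence[Tuple[np.ndarray, np.ndarray]],
) -> Dict[str, np.ndarray]:
    """Align (paxillin, actin) trace pairs to each pair's Paxillin peak.

    Each pair is shifted so its Paxillin maximum sits at offset 0; means and
    standard deviations are computed per offset over the traces that cover
    it.  Returns offsets plus mean/sd arrays per channel and coverage n.
    """
    if not traces:
        raise ValueError("no traces")
    peaks = [int(np.argmax(np.asarray(p))) for p, _ in traces]
    lo = min(-pk for pk in peaks)
    hi = max(len(p) - pk for (p, _), pk in zip(traces, peaks))
    offsets = np.arange(lo, hi)
    sums = {k: np.zeros(len(offsets)) for k in ("pax", "act")}
    sq = {k: np.zeros(len(offsets)) for k in ("pax", "act")}
    cover = np.zeros(len(offsets), dtype=int)
    for (pax, act), pk in zip(traces, peaks):
        pax = np.asarray(pax, dtype=float)
        act = np.asarray(act, dtype=float)
        idx = np.arange(len(pax)) - pk - lo
        cover[idx] += 1
        sums["pax"][idx] += pax
        sums["act"][idx] += act
        sq["pax"][idx] += pax**2
        sq["act"][idx] += act**2
    valid = cover > 0
    out = {"offsets": offsets[valid], "n": cover[valid]}
    for k in ("pax", "act"):
        mean = sums[k][valid] / cover[valid]
        var = np.maximum(sq[k][valid] / cover[valid] - mean**2, 0.0)
        out[f"{k}_mean"] = mean
        out[f"{k}_sd"] = np.sqrt(var)
    return out


# --------------------------------------------------------------------------
# ring texture
# --------------------------------------------------------------------------


def fa_ring_texture(
    actin_image: np.ndarray,
    adhesion_mask: np.ndarray,
    ring_inner_um: float = 0.0,
    ring_outer_um: float = 2.0,
    pixel_size_um: float = 1.0,
    scale_px: float = 1.0,
) -> float:
    """SER-Ridge score of the actin channel in a ring around an adhesion.

    The ring is ``dilate(mask, outer) \\ dilate(mask, inner)`` (the mask
    itself is always excluded), with radii converted from um to px.
    """
    mask = np.asarray(adhesion_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty adhesion mask")
    inner_px = max(int(round(ring_inner_um / pixel_size_um)), 0)
    outer_px = int(round(ring_outer_um / pixel_size_um))
    if outer_px <= inner_px:
        raise ValueError("ring_outer_um must exceed ring_inner_um")
    outer = ndi.binary_dilation(mask, iterations=outer_px)
    inner = ndi.binary_dilation(mask, iterations=inner_px) if inner_px else mask
    ring = outer & ~inner
    return ser_ridge_score(actin_image, ring, scale_px)
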