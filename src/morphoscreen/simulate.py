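"""Synthetic imagery and series with known ground truth.

Everything the analysis pipeline consumes can be generated here: shape
populations rendered into two-channel fields, whole plates, focal-adhesion
time-lapse movies, per-adhesion FRET donor/acceptor series, actin ring
texture fixtures, and z-resolved invasion stacks.  All generators are
deterministic given their preset and seed; child streams are derived with
:func:`morphoscreen._rng.derive_seed`.

Rendering is deliberately parametric and noise-simple (hard silhouettes on a
flat background plus additive Gaussian noise) so that every planted
parameter is analytically known and recoverable.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._rng import derive_seed, rng_from
from .imaging import ImageField
from .invasion import InvasionStack
from .presets import (
    SHAPE_PRESETS,
    AdhesionMoviePreset,
    InvasionPreset,
    PopulationPreset,
    RingTexturePreset,
    ShapePreset,
)


class CanvasTooSmallError(ValueError):
    """Requested canvas cannot hold the cell geometry."""


class DensityError(RuntimeError):
    """Cells could not be placed without overlap."""


# --------------------------------------------------------------------------
# single-cell rendering
# --------------------------------------------------------------------------

NUCLEUS_BODY_FRACTION = 0.45  # nucleus semi-axes relative to the body's
#: rendered foreground levels (a.u.); noise is additive on top of these
NUCLEUS_LEVEL = 800.0
CYTO_LEVEL = 500.0


def _cell_extent(shape: ShapePreset) -> float:
    a = shape.body_radius_px
    reach = a + shape.protrusion_length_px if shape.n_protrusions else a
    return reach + shape.protrusion_width_px / 2.0 + 3.0


def render_cell(
    shape: ShapePreset,
    rng_seed: int,
    canvas_px: Optional[int] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Render one cell and nucleus mask on a square canvas.

    The body is an ellipse (eccentricity per the preset, random
    orientation); protrusions are capsules anchored inside the body.
    Spindle protrusions are antipodal along the major axis; star
    protrusions are evenly spaced with angular jitter.  The nucleus is a
    concentric ellipse strictly inside the body.
    """
    rng = np.random.default_rng(rng_seed)
    need = int(np.ceil(2 * _cell_extent(shape))) + 2
    if canvas_px is None:
        canvas_px = need
    elif canvas_px < need:
        raise CanvasTooSmallError(
            f"canvas {canvas_px} px cannot hold geometry needing {need} px"
        )
    n = canvas_px
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    y = yy - c
    x = xx - c

    a = shape.body_radius_px
    b = a * np.sqrt(1.0 - shape.eccentricity**2)
    theta = rng.uniform(0, np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    u = x * ct + y * st  # along major axis
    v = -x * st + y * ct
    body = (u / a) ** 2 + (v / b) ** 2 <= 1.0

    mask = body.copy()
    if shape.n_protrusions:
        if shape.class_name == "spindle":
            phis = np.array([theta, theta + np.pi])
        else:
            k = shape.n_protrusions
            base = rng.uniform(0, 2 * np.pi)
            phis = base + 2 * np.pi * np.arange(k) / k
            phis = phis + rng.uniform(-0.15, 0.15, size=k) * (2 * np.pi / k)
        half_w = shape.protrusion_width_px / 2.0
        for phi in phis:
            d = np.array([np.cos(phi), np.sin(phi)])  # (dx, dy)
            # body radius along phi (ellipse polar form about the centre)
            cu = np.cos(phi - theta)
            su = np.sin(phi - theta)
            r_edge = 1.0 / np.sqrt((cu / a) ** 2 + (su / b) ** 2)
            p0 = 0.5 * r_edge * d
            p1 = (r_edge + shape.protrusion_length_px) * d
            seg = p1 - p0
            seg_len2 = float(seg @ seg)
            tproj = ((x - p0[0]) * seg[0] + (y - p0[1]) * seg[1]) / seg_len2
            tproj = np.clip(tproj, 0.0, 1.0)
            px_ = p0[0] + tproj * seg[0]
            py_ = p0[1] + tproj * seg[1]
            mask |= np.hypot(x - px_, y - py_) <= half_w

    na, nb = NUCLEUS_BODY_FRACTION * a, NUCLEUS_BODY_FRACTION * b
    nucleus = (u / na) ** 2 + (v / nb) ** 2 <= 1.0
    return mask, nucleus


# --------------------------------------------------------------------------
# fields of view
# --------------------------------------------------------------------------


def _jittered_shape(base: ShapePreset, rng: np.random.Generator) -> ShapePreset:
    """Per-cell size jitter; star protrusion count varies in 4..6."""
    kw = dict(
        class_name=base.class_name,
        body_radius_px=float(
            base.body_radius_px * np.clip(1 + 0.07 * rng.standard_normal(), 0.8, 1.2)
        ),
        n_protrusions=base.n_protrusions,
        protrusion_length_px=float(
            base.protrusion_length_px
            * np.clip(1 + 0.10 * rng.standard_normal(), 0.7, 1.3)
        ),
        protrusion_width_px=base.protrusion_width_px,
        eccentricity=base.eccentricity,
    )
    if base.class_name == "star":
        kw["n_protrusions"] = int(rng.integers(4, 7))
    return ShapePreset(**kw)


def render_field(
    pop: PopulationPreset,
    field_size_px: Tuple[int, int] = (1024, 1024),
    max_attempts: int = 1000,
) -> Tuple[ImageField, pd.DataFrame]:
    """Render a population into one two-channel field.

    Cells are placed by rejection sampling with a 3-px clearance, wholly
    inside the field so the planted mixture is exactly the composition of
    the analyzable (non-border) population; any cell that does intersect
    the border is flagged ``edge``.  Returns the field (channels: nucleus,
    cytoplasm) and the ground-truth table with columns
    ``cell_id, class, x, y, edge`` (x = column, y = row, 0-based
    pixel-centred centroids).
    """
    rng = np.random.default_rng(pop.seed)
    h, w = field_size_px
    classes = sorted(pop.mixture_weights)
    probs = [pop.mixture_weights[c] for c in classes] + [pop.unclassified_weight]
    names = classes + ["unclassified"]
    drawn = rng.choice(len(names), size=pop.n_cells, p=probs)

    nuc_img = np.zeros((h, w), dtype=float)
    cyto_img = np.zeros((h, w), dtype=float)
    occupied = np.zeros((h, w), dtype=bool)
    rows = []
    from scipy import ndimage as ndi

    for i, ci in enumerate(drawn):
        cls = names[ci]
        base = SHAPE_PRESETS[pop.ambiguous_shape if cls == "unclassified" else cls]
        shape = _jittered_shape(base, rng)
        cell_seed = int(rng.integers(0, 2**31))
        cmask, nmask = render_cell(shape, cell_seed)
        n = cmask.shape[0]
        if n >= h or n >= w:
            raise CanvasTooSmallError(
                f"cell canvas {n} px does not fit field {field_size_px}"
            )
        placed = False
        for _ in range(max_attempts):
            top = int(rng.integers(0, h - n))
            left = int(rng.integers(0, w - n))
            cy, cx = top + n // 2, left + n // 2
            y0, y1 = max(top, 0), min(top + n, h)
            x0, x1 = max(left, 0), min(left + n, w)
            if y1 <= y0 or x1 <= x0:
                continue
            sub_c = cmask[y0 - top : y1 - top, x0 - left : x1 - left]
            sub_n = nmask[y0 - top : y1 - top, x0 - left : x1 - left]
            if not sub_c.any() or not sub_n.any():
                continue
            # 3-px clearance between cells
            grown = ndi.binary_dilation(sub_c, iterations=3)
            if (occupied[y0:y1, x0:x1] & grown).any():
                continue
            occupied[y0:y1, x0:x1] |= grown
            cyto_img[y0:y1, x0:x1][sub_c] = CYTO_LEVEL
            nuc_img[y0:y1, x0:x1][sub_n] = NUCLEUS_LEVEL
            ys, xs = np.nonzero(sub_c)
            edge = bool(
                sub_c.sum() < cmask.sum()
                or y0 == 0 and (ys == 0).any()
                or x0 == 0 and (xs == 0).any()
                or y1 == h and (ys == y1 - y0 - 1).any()
                or x1 == w and (xs == x1 - x0 - 1).any()
            )
            rows.append(
                {
                    "cell_id": i + 1,
                    "class": cls,
                    "x": float(xs.mean() + x0),
                    "y": float(ys.mean() + y0),
                    "edge": edge,
                }
            )
            placed = True
            break
        if not placed:
            raise DensityError(
                f"could not place cell {i + 1}/{pop.n_cells} after "
                f"{max_attempts} attempts; reduce density"
            )

    if pop.noise_sd > 0:
        nuc_img = nuc_img + rng.normal(0, pop.noise_sd, size=(h, w))
        cyto_img = cyto_img + rng.normal(0, pop.noise_sd, size=(h, w))
    pixels = np.clip(np.stack([nuc_img, cyto_img]), 0, None)
    fld = ImageField.from_array(
        pixels, channel_roles={0: "nucleus", 1: "cytoplasm"}, axes="cyx"
    )
    gt = pd.DataFrame(rows, columns=["cell_id", "class", "x", "y", "edge"])
    return fld, gt


def simulate_population(
    pop: PopulationPreset,
    field_size_px: Tuple[int, int] = (1024, 1024),
    cells_per_field: int = 40,
) -> List[Tuple[ImageField, pd.DataFrame]]:
    """Split a population over several fields (derived per-field seeds)."""
    out = []
    remaining = pop.n_cells
    i = 0
    while remaining > 0:
        k = min(cells_per_field, remaining)
        sub = pop.with_(n_cells=k, seed=derive_seed(pop.seed, "field", i))
        out.append(render_field(sub, field_size_px))
        remaining -= k
        i += 1
    return out


# --------------------------------------------------------------------------
# plates and screens
# --------------------------------------------------------------------------

_ROWS96 = "ABCDEFGH"


def make_plate_layout(
    reagents: Sequence[str],
    library: str = "siGenome",
    n_replicate_wells: int = 2,
    n_plates: int = 2,
    n_control_wells: int = 6,
    control_reagent: str = "non_targeting",
    plate_prefix: str = "P",
    seed: int = 0,
) -> pd.DataFrame:
    """A 96-well plate map: two technical replicates per reagent per plate,
    duplicate plates as biological replicates, randomised control wells."""
    wells = [f"{r}{c:02d}" for r in _ROWS96 for c in range(1, 13)]
    needed = len(reagents) * n_replicate_wells + n_control_wells
    if needed > len(wells):
        raise ValueError(f"layout needs {needed} wells, a plate has {len(wells)}")
    rows = []
    for p in range(1, n_plates + 1):
        rng = rng_from(seed, "layout", p)
        order = list(rng.permutation(len(wells)))
        slots = iter(order)
        for rep in range(1, n_replicate_wells + 1):
            for reagent in reagents:
                rows.append(
                    {
                        "plate": f"{plate_prefix}{p}",
                        "well": wells[next(slots)],
                        "reagent": reagent,
                        "library": library,
                        "replicate": rep,
                        "is_control": False,
                    }
                )
        for k in range(n_control_wells):
            rows.append(
                {
                    "plate": f"{plate_prefix}{p}",
                    "well": wells[next(slots)],
                    "reagent": control_reagent,
                    "library": library,
                    "replicate": k + 1,
                    "is_control": True,
                }
            )
    return pd.DataFrame(rows)


def generate_screen(
    layout: pd.DataFrame,
    effects: Dict[str, PopulationPreset],
    rng_seed: int,
    control_preset: PopulationPreset,
    cells_per_well: int = 40,
    fields_per_well: int = 1,
    field_size_px: Tuple[int, int] = (1024, 1024),
    inherit_control: bool = True,
) -> Dict[Tuple[str, str, int], Tuple[ImageField, pd.DataFrame]]:
    """Render every well of a plate layout.

    Control wells use ``control_preset``; other reagents look up their
    effect preset, inheriting the control preset when absent (unless
    ``inherit_control`` is off, which raises a configuration error).
    Replicate wells and plates use distinct derived seeds.
    """
    out = {}
    for _, row in layout.iterrows():
        if row["is_control"]:
            preset = control_preset
        elif row["reagent"] in effects:
            preset = effects[row["reagent"]]
        elif inherit_control:
            preset = control_preset
        else:
            raise KeyError(f"no effect preset for reagent {row['reagent']!r}")
        per_field = max(1, cells_per_well // fields_per_well)
        for f in range(fields_per_well):
            seed = derive_seed(rng_seed, row["plate"], row["well"], f)
            sub = preset.with_(n_cells=per_field, seed=seed)
            out[(row["plate"], row["well"], f)] = render_field(sub, field_size_px)
    return out


def simulate_screen_counts(
    layout: pd.DataFrame,
    effects: Dict[str, PopulationPreset],
    rng_seed: int,
    control_preset: PopulationPreset,
    n_cells_per_well: int = 300,
) -> pd.DataFrame:
    """Per-well shape-class counts drawn from the planted mixtures.

    The count-level twin of :func:`generate_screen` for screen-scale
    simulations: each well's class composition is a multinomial draw from
    its reagent's planted mixture (cell count Poisson around
    ``n_cells_per_well``), skipping rendering and segmentation.
    """
    classes = sorted(
        set(control_preset.mixture_weights)
        | {c for p in effects.values() for c in p.mixture_weights}
    )
    rows = []
    for _, row in layout.iterrows():
        preset = (
            control_preset
            if row["is_control"] or row["reagent"] not in effects
            else effects[row["reagent"]]
        )
        rng = rng_from(rng_seed, "counts", row["plate"], row["well"])
        n = max(1, int(rng.poisson(n_cells_per_well)))
        probs = [preset.mixture_weights.get(c, 0.0) for c in classes]
        probs.append(preset.unclassified_weight)
        counts = rng.multinomial(n, np.asarray(probs) / np.sum(probs))
        rec = dict(row)
        rec["n_cells"] = n
        for c, k in zip(classes + ["unclassified"], counts):
            rec[f"count_{c}"] = int(k)
        rows.append(rec)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# focal-adhesion movies
# --------------------------------------------------------------------------


def generate_fa_movie(
    preset: AdhesionMoviePreset,
    n_frames: int = 40,
    frame_size_px: Tuple[int, int] = (960, 960),
    include_actin: bool = False,
    actin_lead_frames: int = 0,
) -> Tuple[ImageField, pd.DataFrame]:
    """Time-lapse of stationary elliptical adhesions.

    Each adhesion's intensity rises as ``I_peak * exp(k_a * dt)`` to its
    peak frame and decays as ``I_peak * exp(-k_d * dt)`` after it (dt in
    minutes); shape and position are constant over its life.  Ground truth
    records per-frame area, intensity, centroid, orientation and axial
    ratio.  With ``include_actin`` a second channel carries the same
    profiles advanced by ``actin_lead_frames``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if preset.longevity_min_frames < 2:
        raise ValueError("adhesion longevity below 2 frames is undefined")
    rng = np.random.default_rng(preset.seed)
    h, w = frame_size_px
    dt_min = preset.frame_interval_s / 60.0

    yy, xx = np.mgrid[0:h, 0:w]
    occupied = np.zeros((h, w), dtype=bool)
    adhesions = []
    from scipy import ndimage as ndi

    for i in range(preset.n_adhesions):
        area = max(float(rng.normal(preset.area_mean_px, preset.area_sd_px)), 20.0)
        q = max(float(rng.normal(preset.axial_ratio_mean, preset.axial_ratio_sd)), 1.05)
        a = np.sqrt(area * q / np.pi)
        b = np.sqrt(area / (np.pi * q))
        theta = float(rng.uniform(0, np.pi))
        peak = max(
            float(rng.normal(preset.intensity_mean, preset.intensity_sd)),
            preset.background + 8 * preset.noise_sd + 50.0,
        )
        lon = int(
            np.clip(
                round(rng.normal(preset.longevity_mean_frames, preset.longevity_sd_frames)),
                preset.longevity_min_frames,
                max(preset.longevity_min_frames, n_frames - 1),
            )
        )
        birth = int(rng.integers(0, max(1, n_frames - lon + 1)))
        placed = False
        for _ in range(2000):
            cy = float(rng.uniform(a + 4, h - a - 4))
            cx = float(rng.uniform(a + 4, w - a - 4))
            u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
            v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
            mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            grown = ndi.binary_dilation(mask, iterations=6)
            if not (occupied & grown).any():
                occupied |= grown
                placed = True
                break
        if not placed:
            raise DensityError(f"could not place adhesion {i + 1}")
        adhesions.append(
            dict(
                track_id=i + 1,
                mask=mask,
                area=float(mask.sum()),
                cy=cy,
                cx=cx,
                theta=theta,
                axial_ratio=q,
                peak=peak,
                birth=birth,
                longevity=lon,
                peak_frame=birth + int(round(0.45 * (lon - 1))),
            )
        )

    def profile(ad, f):
        if not (ad["birth"] <= f < ad["birth"] + ad["longevity"]):
            return 0.0
        d = (f - ad["peak_frame"]) * dt_min
        k = preset.assembly_rate_per_min if d <= 0 else -preset.disassembly_rate_per_min
        return ad["peak"] * float(np.exp(k * d)) if d <= 0 else ad["peak"] * float(
            np.exp(-preset.disassembly_rate_per_min * d)
        )

    n_ch = 2 if include_actin else 1
    movie = np.zeros((n_ch, 1, n_frames, h, w), dtype=float)
    gt_rows = []
    for f in range(n_frames):
        frame = np.full((h, w), preset.background, dtype=float)
        actin = np.full((h, w), preset.background, dtype=float)
        for ad in adhesions:
            inten = profile(ad, f)
            if inten > 0:
                frame[ad["mask"]] += inten
                gt_rows.append(
                    {
                        "track_id": ad["track_id"],
                        "t": f,
                        "area_px": ad["area"],
                        "intensity": inten,
                        "x": ad["cx"],
                        "y": ad["cy"],
                        "orientation_deg": np.degrees(ad["theta"]) % 180.0,
                        "axial_ratio": ad["axial_ratio"],
                    }
                )
            if include_actin:
                ai = profile(ad, f + actin_lead_frames)
                if ai > 0:
                    actin[ad["mask"]] += ai
        if preset.noise_sd > 0:
            frame = frame + rng.normal(0, preset.noise_sd, size=(h, w))
            if include_actin:
                actin = actin + rng.normal(0, preset.noise_sd, size=(h, w))
        movie[0, 0, f] = np.clip(frame, 0, None)
        if include_actin:
            movie[1, 0, f] = np.clip(actin, 0, None)

    roles = {0: "paxillin"}
    if include_actin:
        roles[1] = "actin"
    fld = ImageField(movie, roles)
    gt = pd.DataFrame(
        gt_rows,
        columns=[
            "track_id",
            "t",
            "area_px",
            "intensity",
            "x",
            "y",
            "orientation_deg",
            "axial_ratio",
        ],
    )
    return fld, gt


# --------------------------------------------------------------------------
# FRET tension series
# --------------------------------------------------------------------------


def generate_fret_series(preset) -> pd.DataFrame:
    """Per-adhesion, per-frame donor/acceptor intensities with ground truth.

    The sensor's closed fraction follows a raised-bump profile from a
    per-track baseline to ``closed_fraction_peak`` mid-life, with
    track-average closure equal to ``closed_fraction_mean``; the
    acceptor/donor ratio scales as 1/(1 - closed fraction) so the tension
    index (donor/acceptor) is proportional to ground-truth tension
    ``tension_scale * (1 - closed_fraction)``.
    """
    rng = np.random.default_rng(preset.seed)
    rows = []
    r_base = preset.acceptor_base / preset.donor_base
    for i in range(preset.n_adhesions):
        L = int(
            np.clip(
                round(rng.normal(preset.track_length_mean, preset.track_length_sd)),
                preset.track_length_min,
                None,
            )
        )
        t = np.arange(L)
        g = np.sin(np.pi * t / max(L - 1, 1)) ** 2
        g_bar = float(g.mean())
        c_mean = float(
            np.clip(preset.closed_fraction_mean + rng.normal(0, 0.01), 0.0, 0.98)
        )
        c_peak = float(
            np.clip(preset.closed_fraction_peak + rng.normal(0, 0.01), c_mean, 0.99)
        )
        denom = max(1.0 - g_bar, 1e-9)
        c_base = (c_mean - c_peak * g_bar) / denom
        c = np.clip(c_base + (c_peak - c_base) * g, 0.0, 0.995)
        donor = preset.donor_base * (1.0 + preset.noise_cv * rng.standard_normal(L))
        ratio = r_base / np.maximum(1.0 - c, 1e-3)
        acceptor = donor * ratio * (1.0 + preset.noise_cv * rng.standard_normal(L))
        tension = preset.tension_scale * (1.0 - c)
        for k in range(L):
            rows.append(
                {
                    "track_id": i + 1,
                    "t": k,
                    "donor": max(float(donor[k]), 1e-6),
                    "acceptor": max(float(acceptor[k]), 1e-6),
                    "closed_fraction": float(c[k]),
                    "true_tension": float(tension[k]),
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# actin ring texture fixtures
# --------------------------------------------------------------------------


def generate_ring_texture(
    preset: RingTexturePreset, index: int = 0
) -> Tuple[np.ndarray, np.ndarray]:
    """One actin image + central adhesion mask for ring-texture scoring.

    Filament geometry is drawn from a stream keyed by ``(seed, index)``
    only — not by the preset name — so paired presets differing only in
    contrast render identical geometry and the score fold isolates the
    planted contrast ratio.
    """
    rng = rng_from(preset.seed, "ring", index)
    n = preset.canvas_px
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    img = np.full((n, n), preset.background, dtype=float)
    amp = preset.contrast * preset.background
    for _ in range(preset.n_filaments):
        phi = rng.uniform(0, np.pi)
        offset = rng.uniform(-n / 4.0, n / 4.0)
        # signed distance to the line through (centre + offset * normal)
        d = (
            (xx - c) * np.sin(phi)
            - (yy - c) * np.cos(phi)
            - offset
        )
        img += amp * np.exp(-(d**2) / (2 * preset.filament_sigma_px**2))
    if preset.noise_sd > 0:
        img = img + rng.normal(0, preset.noise_sd, size=(n, n))
    mask = (xx - c) ** 2 + (yy - c) ** 2 <= preset.adhesion_radius_px**2
    return np.clip(img, 0, None), mask


# --------------------------------------------------------------------------
# invasion stacks
# --------------------------------------------------------------------------


def generate_invasion_stack(
    preset: InvasionPreset,
    render_images: bool = False,
    field_size_px: Tuple[int, int] = (512, 512),
    nucleus_radius_px: float = 5.0,
    noise_sd: float = 8.0,
) -> InvasionStack:
    """Allocate nuclei over z-planes multinomially from the preset.

    With ``render_images`` each plane also gets a rendered nucleus image
    (discs at random non-overlapping positions plus noise) for exercising
    the counting pipeline.
    """
    if preset.n_cells == 0:
        raise ValueError("n_cells must be >= 1: invasion index undefined")
    rng = np.random.default_rng(preset.seed)
    depths = sorted(preset.depth_distribution)
    probs = np.array([preset.depth_distribution[d] for d in depths])
    counts = rng.multinomial(preset.n_cells, probs / probs.sum())
    images = None
    if render_images:
        images = []
        h, w = field_size_px
        r = nucleus_radius_px
        yy, xx = np.mgrid[0:h, 0:w]
        for k in counts:
            img = np.zeros((h, w), dtype=float)
            centres = []
            for _ in range(int(k)):
                for _attempt in range(2000):
                    cy = rng.uniform(r + 2, h - r - 2)
                    cx = rng.uniform(r + 2, w - r - 2)
                    if all(np.hypot(cy - py, cx - px) > 2 * r + 3 for py, px in centres):
                        centres.append((cy, cx))
                        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = NUCLEUS_LEVEL
                        break
                else:
                    raise DensityError("could not place nucleus without overlap")
            if noise_sd > 0:
                img = np.clip(img + rng.normal(0, noise_sd, size=(h, w)), 0, None)
            images.append(img)
    return InvasionStack(
        plane_depths_um=[float(d) for d in depths],
        counts=[int(k) for k in counts],
        plane_images=images,
    )
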