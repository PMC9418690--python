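"""End-to-end workflows tying the stages together.

These are the entry points the analysis drivers, the CLI and the acceptance
checks use: train exemplar classifiers from rendered single cells, classify
whole synthetic populations from pixels, recover focal-adhesion fold
changes from paired movies, summarise FRET tension folds, score ring
textures and compute invasion indices.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import adhesion, fret, invasion, screen
from ._rng import derive_seed
from .imaging import ImageField, extract_all_features, segment_field
from .presets import (
    FA_MOVIE_PRESETS,
    INVASION_PRESETS,
    POPULATION_PRESETS,
    RING_TEXTURE_PRESETS,
    SHAPE_PRESETS,
    TENSION_PRESETS,
    AdhesionMoviePreset,
    PopulationPreset,
)
from .simulate import (
    _jittered_shape,
    generate_fa_movie,
    generate_fret_series,
    generate_invasion_stack,
    generate_ring_texture,
    render_cell,
    simulate_population,
)


# --------------------------------------------------------------------------
# exemplar training
# --------------------------------------------------------------------------


def render_exemplar_field(
    shape_name: str, seed: int, noise_sd: float = 30.0
) -> ImageField:
    """One jittered cell of the named shape, centred in its own field."""
    rng = np.random.default_rng(seed)
    shape = _jittered_shape(SHAPE_PRESETS[shape_name], rng)
    cmask, nmask = render_cell(shape, int(rng.integers(0, 2**31)))
    n = cmask.shape[0] + 12
    cyto = np.zeros((n, n))
    nuc = np.zeros((n, n))
    off = 6
    cyto[off : off + cmask.shape[0], off : off + cmask.shape[1]][cmask] = 500.0
    nuc[off : off + nmask.shape[0], off : off + nmask.shape[1]][nmask] = 800.0
    if noise_sd > 0:
        cyto = cyto + rng.normal(0, noise_sd, (n, n))
        nuc = nuc + rng.normal(0, noise_sd, (n, n))
    return ImageField.from_array(
        np.clip(np.stack([nuc, cyto]), 0, None),
        channel_roles={0: "nucleus", 1: "cytoplasm"},
        axes="cyx",
    )


def exemplar_features(
    shape_names: Sequence[str],
    n_per_class: int = 50,
    seed: int = 0,
    noise_sd: float = 30.0,
) -> Tuple[pd.DataFrame, List[str]]:
    """Feature table and labels for rendered exemplar cells.

    Each exemplar is rendered alone, run through the same segmentation and
    feature extraction as screen images, and labelled with its true class.
    """
    feats = []
    labels = []
    for cls in shape_names:
        got = 0
        attempt = 0
        while got < n_per_class:
            fld = render_exemplar_field(
                cls, derive_seed(seed, "exemplar", cls, attempt), noise_sd
            )
            attempt += 1
            cells, nuclei, _ = segment_field(fld)
            if cells.n_labels != 1:
                continue  # segmentation failure on this draw; try the next
            feats.append(extract_all_features(cells, nuclei, fld))
            labels.append(cls)
            got += 1
    return pd.concat(feats, ignore_index=True), labels


#: Default decision margin for exemplar classifiers: the winning one-vs-rest
#: discriminant must beat the runner-up by the full unit target separation
#: (+1 vs -1 training targets).  Exemplar-like cells score gaps near 2,
#: genuinely intermediate morphologies near 0, so the unit gap is a natural
#: scale, not a fitted constant.
DEFAULT_DECISION_MARGIN = 1.0


def train_exemplar_classifier(
    shape_names: Sequence[str],
    n_per_class: int = 50,
    seed: int = 0,
    decision_margin: float = DEFAULT_DECISION_MARGIN,
) -> screen.ShapeClassifier:
    X, y = exemplar_features(shape_names, n_per_class, seed)
    return screen.train_classifiers(X, y, decision_margin=decision_margin)


# --------------------------------------------------------------------------
# population classification from pixels
# --------------------------------------------------------------------------


def classify_population(
    pop: PopulationPreset,
    clf: screen.ShapeClassifier,
    field_size_px: Tuple[int, int] = (1024, 1024),
    cells_per_field: int = 40,
) -> Tuple[screen.PQMS, pd.DataFrame]:
    """Segment, featurise and classify a rendered population.

    Returns the pQMS over all segmented non-edge cells and a per-cell table
    with assignments and matched ground truth (nearest planted centroid
    within 5 px, where available).
    """
    fields = simulate_population(pop, field_size_px, cells_per_field)
    assignments: List[str] = []
    rows = []
    for fi, (fld, gt) in enumerate(fields):
        cells, nuclei, _ = segment_field(fld)
        if cells.n_labels == 0:
            continue
        feats = extract_all_features(cells, nuclei, fld)
        assigned = screen.classify(feats, clf)
        assignments.extend(assigned)
        # match segmented cells to planted ground truth by centroid
        from scipy import ndimage as ndi

        coms = ndi.center_of_mass(
            cells.labels > 0, cells.labels, list(cells.label_ids)
        )
        for lbl, (cy, cx), cls in zip(cells.label_ids, coms, assigned):
            true_class = None
            if len(gt):
                d = np.hypot(gt["y"] - cy, gt["x"] - cx)
                j = int(d.idxmin())
                if d.loc[j] <= 5.0:
                    true_class = gt.loc[j, "class"]
            rows.append(
                {
                    "field": fi,
                    "cell_id": int(lbl),
                    "assigned": cls,
                    "true_class": true_class,
                    "x": float(cx),
                    "y": float(cy),
                }
            )
    pqms = screen.compute_pqms(assignments, pop.name, clf.class_names)
    return pqms, pd.DataFrame(rows)


SOFT_CLASSES = ("round", "spindle", "star")
STIFF_CLASSES = ("spindle", "small_flat", "big_flat")


def run_shape_pipeline(
    preset_name: str,
    seed: int,
    n_cells: Optional[int] = None,
    n_exemplars: int = 50,
) -> screen.PQMS:
    """Train classifiers and classify one shipped population preset."""
    pop = POPULATION_PRESETS[preset_name]
    classes = STIFF_CLASSES if "stiff" in preset_name else SOFT_CLASSES
    if n_cells is not None:
        pop = pop.with_(n_cells=n_cells)
    pop = pop.with_(seed=derive_seed(seed, "population", preset_name))
    clf = train_exemplar_classifier(
        classes, n_per_class=n_exemplars, seed=derive_seed(seed, "exemplars")
    )
    pqms, _ = classify_population(pop, clf)
    return pqms


# --------------------------------------------------------------------------
# focal-adhesion fold changes
# --------------------------------------------------------------------------


def fa_statics(
    preset: AdhesionMoviePreset,
    n_frames: int = 40,
    min_size_px: int = 10,
    min_track_frames: int = 5,
) -> pd.DataFrame:
    """Detect, track and summarise one movie preset."""
    movie, _ = generate_fa_movie(preset, n_frames)
    tracks = adhesion.track_movie(
        movie, min_size_px=min_size_px, min_track_frames=min_track_frames
    )
    return adhesion.summarize_tracks(tracks)


def fa_fold_changes(
    preset_num: str,
    preset_den: str = "fa_wt",
    seed: int = 1,
    n_frames: int = 40,
) -> Dict[str, float]:
    """Fold changes (numerator over denominator preset) of mean statics."""
    out = {}
    summaries = {}
    for name in (preset_num, preset_den):
        p = FA_MOVIE_PRESETS[name].with_(seed=derive_seed(seed, "fa", name))
        summaries[name] = fa_statics(p, n_frames=n_frames)
    for col, key in [
        ("mean_area", "area"),
        ("mean_intensity", "intensity"),
        ("mean_axial_ratio", "axial_ratio"),
        ("longevity_min", "longevity"),
    ]:
        out[key] = float(
            summaries[preset_num][col].mean() / summaries[preset_den][col].mean()
        )
    return out


# --------------------------------------------------------------------------
# FRET tension folds
# --------------------------------------------------------------------------


def tension_fold_changes(
    preset_num: str = "tension_kd",
    preset_den: str = "tension_wt",
    seed: int = 1,
) -> Dict[str, float]:
    """Fold change of mean per-track mean and minimum tension index."""
    summaries = {}
    for name in (preset_num, preset_den):
        p = TENSION_PRESETS[name].with_(seed=derive_seed(seed, "fret", name))
        series = generate_fret_series(p)
        summaries[name] = fret.summarize_tension(series)
    return {
        "mean_tension": float(
            summaries[preset_num]["mean_tension"].mean()
            / summaries[preset_den]["mean_tension"].mean()
        ),
        "min_tension": float(
            summaries[preset_num]["min_tension"].mean()
            / summaries[preset_den]["min_tension"].mean()
        ),
    }


# --------------------------------------------------------------------------
# ring texture
# --------------------------------------------------------------------------


def ring_texture_scores(
    preset_name: str, n_fixtures: int = 100, seed: int = 1, scale_px: float = 1.0
) -> np.ndarray:
    preset = RING_TEXTURE_PRESETS[preset_name].with_(seed=derive_seed(seed, "ring"))
    scores = []
    for i in range(n_fixtures):
        img, mask = generate_ring_texture(preset, index=i)
        scores.append(
            adhesion.fa_ring_texture(img, mask, ring_outer_um=2.0, scale_px=scale_px)
        )
    return np.asarray(scores)


def ring_texture_median_fold(
    n_fixtures: int = 100, seed: int = 1
) -> float:
    kd = ring_texture_scores("ring_kd", n_fixtures, seed)
    wt = ring_texture_scores("ring_wt", n_fixtures, seed)
    return float(np.median(kd) / np.median(wt))


# --------------------------------------------------------------------------
# invasion
# --------------------------------------------------------------------------


def invasion_summary(preset_name: str, seed: int = 1) -> Dict[str, float]:
    preset = INVASION_PRESETS[preset_name].with_(
        seed=derive_seed(seed, "invasion", preset_name)
    )
    stack = generate_invasion_stack(preset)
    index, per_depth = invasion.invasion_index(stack)
    return {
        "index_pct": index,
        "at_or_beyond_40um_pct": invasion.fraction_at_or_beyond(stack, 40.0),
        **{f"pct_at_{int(d)}um": v for d, v in per_depth.items()},
    }


# --------------------------------------------------------------------------
# hit-calling simulation
# --------------------------------------------------------------------------


def simulate_hit_screen(
    n_null_reagents: int = 95,
    n_hit_reagents: int = 5,
    seed: int = 1,
    n_cells_per_well: int = 300,
    z_threshold: float = 1.5,
    min_replicates: int = 2,
    library: str = "siGenome",
) -> Tuple[set, set, List[screen.ScreenResult]]:
    """One simulated screen: planted shape-shifting reagents among nulls.

    Null reagents share the control mixture; planted hits use the
    ECT2-like star-enriched mixture.  Wells are simulated at the count
    level, shape percentages normalised per plate, and hits called with
    the replicate rule.  Returns (planted, called, results).
    """
    from .simulate import make_plate_layout, simulate_screen_counts

    control = POPULATION_PRESETS["control_soft"]
    effect = POPULATION_PRESETS["ect2_soft"]
    nulls = [f"null_{i:03d}" for i in range(n_null_reagents)]
    hits = [f"hit_{i:02d}" for i in range(n_hit_reagents)]
    rng = np.random.default_rng(derive_seed(seed, "reagent_order"))
    reagents = [str(r) for r in rng.permutation(nulls + hits)]
    # two technical replicate wells per reagent on one plate; balanced
    # plate chunks of at most 45 reagents fit a 96-well plate with controls
    n_chunks = int(np.ceil(len(reagents) / 45))
    layouts = []
    for p, chunk in enumerate(np.array_split(reagents, n_chunks)):
        layouts.append(
            make_plate_layout(
                list(chunk),
                library=library,
                n_replicate_wells=2,
                n_plates=1,
                plate_prefix=f"P{p}_",
                seed=derive_seed(seed, "layout", p),
            )
        )
    layout = pd.concat(layouts, ignore_index=True)
    counts = simulate_screen_counts(
        layout,
        {h: effect for h in hits},
        rng_seed=derive_seed(seed, "screen"),
        control_preset=control,
        n_cells_per_well=n_cells_per_well,
    )
    classes = sorted(control.mixture_weights)
    for c in classes:
        counts[f"pct_{c}"] = 100.0 * counts[f"count_{c}"] / counts["n_cells"]
    ztable = screen.normalize_screen(counts, [f"pct_{c}" for c in classes])
    results = screen.call_hits(
        ztable,
        [f"pct_{c}" for c in classes],
        threshold=z_threshold,
        min_replicates=min_replicates,
    )
    called = screen.hit_reagents(results)
    return set(hits), called, results
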