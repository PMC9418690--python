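"""Shipped simulation presets.

Every input the analysis pipeline consumes can be simulated from a named
preset with known ground truth.  The shipped presets encode the effect sizes
reported for the WM266-4 melanoma RhoGEF/RhoGAP morphology screen:

* soft-substrate control populations are 45% round / 26% spindle / 23% star
  (6% ambiguous), the ECT2-depleted population is enriched to 51% star, and
  the stiff-substrate control is 32% spindle / 49% small-flat / 16% big-flat;
* ARHGEF9 knockdown shifts focal-adhesion morphology by 1.62x (mean area),
  1.35x (mean Paxillin intensity) and 1.04x (axial ratio) relative to
  wild-type, while FAK inhibition (PF-573228) extends mean adhesion
  longevity 1.25x;
* knockdown reduces mean adhesion tension 0.92x and minimum tension 0.65x
  (vinculin FRET sensor, tension index = donor/acceptor ratio);
* knockdown raises the SER-Ridge actin texture score around adhesions by a
  median 1.6x (diffuse, high-contrast sparse filaments vs the dense
  low-contrast control meshwork);
* 33% of control cells vs 27% of knockdown cells invade a soft collagen gel
  (10% vs 8% reach >= 40 um; 2% vs <1% reach the deepest imaged plane).

Preset parameter *ratios* are the planted truths that the acceptance tests
recover; absolute values (radii, intensities, densities) are round numbers
chosen to be realistic for 20x / 63x imaging at ~1 um/px and are documented
in ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict

__all__ = [
    "ShapePreset",
    "PopulationPreset",
    "AdhesionMoviePreset",
    "TensionPreset",
    "RingTexturePreset",
    "InvasionPreset",
    "SHAPE_PRESETS",
    "POPULATION_PRESETS",
    "FA_MOVIE_PRESETS",
    "TENSION_PRESETS",
    "RING_TEXTURE_PRESETS",
    "INVASION_PRESETS",
]


# --------------------------------------------------------------------------
# cell silhouettes
# --------------------------------------------------------------------------

VALID_SHAPE_CLASSES = (
    "round",
    "spindle",
    "star",
    "small_flat",
    "big_flat",
    "ambiguous",
)


@dataclass(frozen=True)
class ShapePreset:
    """Parametric cell silhouette: elliptical body + capsule protrusions."""

    class_name: str
    body_radius_px: float
    n_protrusions: int = 0
    protrusion_length_px: float = 0.0
    protrusion_width_px: float = 6.0
    eccentricity: float = 0.0

    def __post_init__(self) -> None:
        if self.class_name not in VALID_SHAPE_CLASSES:
            raise ValueError(f"unknown shape class {self.class_name!r}")
        if self.body_radius_px <= 0:
            raise ValueError("body_radius_px must be positive")
        if self.n_protrusions < 0:
            raise ValueError("n_protrusions must be non-negative")
        if self.protrusion_width_px <= 0:
            raise ValueError("protrusion_width_px must be positive")
        if not (0.0 <= self.eccentricity < 1.0):
            raise ValueError("eccentricity must be in [0, 1)")
        if self.class_name == "round" and self.n_protrusions != 0:
            raise ValueError("round cells have no protrusions")
        if self.class_name == "spindle" and self.n_protrusions != 2:
            raise ValueError("spindle cells have exactly 2 protrusions")
        if self.class_name == "star" and self.n_protrusions < 3:
            raise ValueError("star cells have >= 3 protrusions")


#: Soft-substrate exemplar silhouettes (round / spindle / star) plus the
#: deliberately intermediate "ambiguous" silhouette (one protrusion) used
#: for the unclassified mass.  Stiff-substrate exemplars (spindle /
#: small_flat / big_flat) differ in spread area; big_flat >= 1.5x small_flat.
SHAPE_PRESETS: Dict[str, ShapePreset] = {
    "round": ShapePreset("round", body_radius_px=18.0),
    "spindle": ShapePreset(
        "spindle",
        body_radius_px=13.0,
        n_protrusions=2,
        protrusion_length_px=38.0,
        protrusion_width_px=7.0,
        eccentricity=0.55,
    ),
    "star": ShapePreset(
        "star",
        body_radius_px=14.0,
        n_protrusions=5,
        protrusion_length_px=30.0,
        protrusion_width_px=7.0,
    ),
    "small_flat": ShapePreset("small_flat", body_radius_px=16.0),
    "big_flat": ShapePreset("big_flat", body_radius_px=30.0),
    "ambiguous": ShapePreset(
        "ambiguous",
        body_radius_px=15.0,
        n_protrusions=1,
        protrusion_length_px=18.0,
        protrusion_width_px=9.0,
        eccentricity=0.15,
    ),
    # intermediate flat disc for the stiff-substrate unclassified mass
    "ambiguous_flat": ShapePreset("ambiguous", body_radius_px=23.0),
}

assert (
    SHAPE_PRESETS["big_flat"].body_radius_px
    >= 1.5 * SHAPE_PRESETS["small_flat"].body_radius_px
)


# --------------------------------------------------------------------------
# populations
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationPreset:
    """A mixture of exemplar shapes rendered into fields of view."""

    name: str
    mixture_weights: Dict[str, float]
    unclassified_weight: float
    n_cells: int
    noise_sd: float = 30.0
    seed: int = 0
    #: which ambiguous silhouette carries the unclassified mass
    ambiguous_shape: str = "ambiguous"

    def __post_init__(self) -> None:
        total = sum(self.mixture_weights.values()) + self.unclassified_weight
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {total}")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def with_(self, **kw) -> "PopulationPreset":
        return replace(self, **kw)


POPULATION_PRESETS: Dict[str, PopulationPreset] = {
    # soft substrate, non-targeting control: 45/26/23 (+6 unclassified)
    "control_soft": PopulationPreset(
        name="control_soft",
        mixture_weights={"round": 0.45, "spindle": 0.26, "star": 0.23},
        unclassified_weight=0.06,
        n_cells=2000,
    ),
    # ECT2 depletion enriches the star shape to 51%; the remaining mass is
    # split round/spindle with the control's unclassified fraction.
    "ect2_soft": PopulationPreset(
        name="ect2_soft",
        mixture_weights={"round": 0.20, "spindle": 0.23, "star": 0.51},
        unclassified_weight=0.06,
        n_cells=2000,
    ),
    # ARHGEF9 depletion on soft gel enriches star and spindle forms
    "arhgef9_soft": PopulationPreset(
        name="arhgef9_soft",
        mixture_weights={"round": 0.20, "spindle": 0.37, "star": 0.37},
        unclassified_weight=0.06,
        n_cells=2000,
    ),
    # stiff substrate control: 32% spindle / 49% small flat / 16% big flat
    "control_stiff": PopulationPreset(
        name="control_stiff",
        mixture_weights={
            "spindle": 0.32,
            "small_flat": 0.49,
            "big_flat": 0.16,
        },
        unclassified_weight=0.03,
        n_cells=2000,
        ambiguous_shape="ambiguous_flat",
    ),
    # ARHGEF9 depletion on stiff substrate enriches the big-flat form
    "arhgef9_stiff": PopulationPreset(
        name="arhgef9_stiff",
        mixture_weights={
            "spindle": 0.20,
            "small_flat": 0.37,
            "big_flat": 0.40,
        },
        unclassified_weight=0.03,
        n_cells=2000,
        ambiguous_shape="ambiguous_flat",
    ),
}


# --------------------------------------------------------------------------
# focal-adhesion movies
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AdhesionMoviePreset:
    """Time-lapse of exponentially assembling/disassembling adhesions.

    ``area_mean_px``, ``intensity_mean`` and ``axial_ratio_mean`` are the
    planted per-adhesion morphology means; kinetic rates are per minute on
    natural-log intensity.  ``fa_arhgef9`` / ``fa_wt`` parameter ratios are
    1.62 (area), 1.35 (intensity) and 1.04 (axial ratio);
    ``fa_pf573288`` / ``fa_wt`` longevity ratio is 1.25.
    """

    name: str
    n_adhesions: int
    area_mean_px: float = 150.0
    area_sd_px: float = 30.0
    intensity_mean: float = 600.0
    intensity_sd: float = 90.0
    axial_ratio_mean: float = 2.2
    axial_ratio_sd: float = 0.4
    assembly_rate_per_min: float = 0.05
    disassembly_rate_per_min: float = 0.04
    longevity_mean_frames: float = 16.0
    longevity_sd_frames: float = 4.0
    longevity_min_frames: int = 7
    frame_interval_s: float = 60.0
    noise_sd: float = 15.0
    background: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_adhesions <= 0:
            raise ValueError("n_adhesions must be positive")
        for name in (
            "area_mean_px",
            "area_sd_px",
            "intensity_mean",
            "intensity_sd",
            "assembly_rate_per_min",
            "disassembly_rate_per_min",
            "frame_interval_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.axial_ratio_mean < 1:
            raise ValueError("axial_ratio_mean must be >= 1")
        if self.longevity_mean_frames < 5:
            raise ValueError("longevity_mean_frames must be >= 5")

    def with_(self, **kw) -> "AdhesionMoviePreset":
        return replace(self, **kw)


_FA_WT = AdhesionMoviePreset(name="fa_wt", n_adhesions=100, seed=0)

FA_MOVIE_PRESETS: Dict[str, AdhesionMoviePreset] = {
    "fa_wt": _FA_WT,
    "fa_arhgef9": _FA_WT.with_(
        name="fa_arhgef9",
        area_mean_px=_FA_WT.area_mean_px * 1.62,
        area_sd_px=_FA_WT.area_sd_px * 1.62,
        intensity_mean=_FA_WT.intensity_mean * 1.35,
        intensity_sd=_FA_WT.intensity_sd * 1.35,
        axial_ratio_mean=_FA_WT.axial_ratio_mean * 1.04,
    ),
    "fa_pf573288": _FA_WT.with_(
        name="fa_pf573288",
        longevity_mean_frames=_FA_WT.longevity_mean_frames * 1.25,
        longevity_sd_frames=_FA_WT.longevity_sd_frames * 1.25,
    ),
}

#: planted fold changes, asserted in tests against the preset fields
FA_PRESET_FOLDS = {
    ("fa_arhgef9", "fa_wt"): {"area": 1.62, "intensity": 1.35, "axial_ratio": 1.04},
    ("fa_pf573288", "fa_wt"): {"longevity": 1.25},
}


# --------------------------------------------------------------------------
# FRET tension series
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TensionPreset:
    """Per-adhesion donor/acceptor series from a vinculin tension sensor.

    The sensor's closed fraction sets the acceptor/donor ratio; ground-truth
    tension is ``tension_scale * (1 - closed_fraction)``.  Closure follows a
    unimodal within-track profile from a baseline up to
    ``closed_fraction_peak`` (the tension minimum), with track-average
    closure ``closed_fraction_mean``.  Planted tension_kd / tension_wt folds:
    mean tension (1-0.54)/(1-0.50) = 0.92, minimum tension
    (1-0.805)/(1-0.70) = 0.65.
    """

    name: str
    n_adhesions: int
    closed_fraction_mean: float
    closed_fraction_peak: float
    donor_base: float = 500.0
    acceptor_base: float = 500.0
    tension_scale: float = 2.0
    track_length_mean: float = 30.0
    track_length_sd: float = 5.0
    track_length_min: int = 10
    noise_cv: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_adhesions <= 0:
            raise ValueError("n_adhesions must be positive")
        for name in ("closed_fraction_mean", "closed_fraction_peak"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.donor_base <= 0 or self.acceptor_base <= 0:
            raise ValueError("channel baselines must be positive")
        if self.tension_scale <= 0:
            raise ValueError("tension_scale must be positive")

    @property
    def planted_mean_tension(self) -> float:
        return self.tension_scale * (1.0 - self.closed_fraction_mean)

    @property
    def planted_min_tension(self) -> float:
        return self.tension_scale * (1.0 - self.closed_fraction_peak)

    def with_(self, **kw) -> "TensionPreset":
        return replace(self, **kw)


TENSION_PRESETS: Dict[str, TensionPreset] = {
    "tension_wt": TensionPreset(
        name="tension_wt",
        n_adhesions=200,
        closed_fraction_mean=0.50,
        closed_fraction_peak=0.70,
    ),
    "tension_kd": TensionPreset(
        name="tension_kd",
        n_adhesions=200,
        closed_fraction_mean=0.54,
        closed_fraction_peak=0.805,
    ),
}


# --------------------------------------------------------------------------
# actin ring texture fixtures
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RingTexturePreset:
    """Actin texture fixture around a single adhesion.

    Filaments are rendered as thin lines of amplitude
    ``contrast * background`` on a flat background; since the SER-Ridge
    score is linear in filament amplitude and normalised by mean ring
    intensity, the planted score fold between two presets is their contrast
    ratio.  ``ring_kd`` / ``ring_wt`` contrast ratio is 1.6 (sparse
    high-contrast filaments in knockdown vs a dense low-contrast control
    meshwork).
    """

    name: str
    contrast: float
    n_filaments: int = 4
    background: float = 200.0
    adhesion_radius_px: float = 4.0
    filament_sigma_px: float = 1.0
    canvas_px: int = 48
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contrast <= 0:
            raise ValueError("contrast must be positive")

    def with_(self, **kw) -> "RingTexturePreset":
        return replace(self, **kw)


RING_TEXTURE_PRESETS: Dict[str, RingTexturePreset] = {
    "ring_wt": RingTexturePreset(name="ring_wt", contrast=0.25),
    "ring_kd": RingTexturePreset(name="ring_kd", contrast=0.40),
}


# --------------------------------------------------------------------------
# 3D invasion stacks
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class InvasionPreset:
    """Multinomial allocation of nuclei over imaged z-planes.

    Depths label plane centres (um above the well bottom).  The planted
    per-depth fractions give invasion indices (mass at 30/60/90 um) of 33%
    for ``invasion_wt`` and 27% for ``invasion_kd``, with 10% vs 8% of cells
    at or beyond 40 um and 2% vs 1% at the deepest plane.
    """

    name: str
    n_cells: int
    depth_distribution: Dict[float, float] = field(
        default_factory=lambda: {0.0: 1.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.depth_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"depth probabilities must sum to 1, got {total}")
        if any(p < 0 for p in self.depth_distribution.values()):
            raise ValueError("depth probabilities must be non-negative")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")

    def with_(self, **kw) -> "InvasionPreset":
        return replace(self, **kw)


INVASION_PRESETS: Dict[str, InvasionPreset] = {
    "invasion_wt": InvasionPreset(
        name="invasion_wt",
        n_cells=10000,
        depth_distribution={0.0: 0.67, 30.0: 0.23, 60.0: 0.08, 90.0: 0.02},
    ),
    "invasion_kd": InvasionPreset(
        name="invasion_kd",
        n_cells=10000,
        depth_distribution={0.0: 0.73, 30.0: 0.19, 60.0: 0.07, 90.0: 0.01},
    ),
}
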