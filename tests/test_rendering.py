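"""Synthetic generators: cell rendering, fields, movies, series, stacks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import skeletonize

from morphoscreen._rng import derive_seed
from morphoscreen.presets import (
    FA_MOVIE_PRESETS,
    FA_PRESET_FOLDS,
    INVASION_PRESETS,
    POPULATION_PRESETS,
    SHAPE_PRESETS,
    TENSION_PRESETS,
    InvasionPreset,
    PopulationPreset,
    ShapePreset,
)
from morphoscreen.simulate import (
    CanvasTooSmallError,
    generate_fa_movie,
    generate_fret_series,
    generate_invasion_stack,
    generate_screen,
    make_plate_layout,
    render_cell,
    render_field,
)


class TestRenderCell:
    def test_round_disc_is_circular(self):
        mask, nucleus = render_cell(SHAPE_PRESETS["round"], 1)
        props = regionprops(mask.astype(np.uint8))[0]
        circ = 4 * np.pi * props.area / props.perimeter_crofton**2
        assert circ >= 0.9
        assert nucleus.sum() > 0 and not (nucleus & ~mask).any()

    def test_spindle_elongation_from_moments(self):
        # oracle: second moments of the rendered mask itself
        shape = ShapePreset(
            "spindle", 13, 2, protrusion_length_px=40, protrusion_width_px=7
        )
        mask, _ = render_cell(shape, 2)
        props = regionprops(mask.astype(np.uint8))[0]
        assert props.axis_major_length / props.axis_minor_length >= 2.0

    @pytest.mark.parametrize("n_protrusions", [3, 4, 5])
    def test_star_skeleton_endpoints_match(self, n_protrusions):
        # oracle: skeletonise and count degree-1 pixels directly
        shape = ShapePreset(
            "star", 14, n_protrusions, protrusion_length_px=30, protrusion_width_px=7
        )
        mask, _ = render_cell(shape, 3)
        skel = skeletonize(mask)
        coords = {tuple(p) for p in np.argwhere(skel)}
        endpoints = sum(
            1
            for (y, x) in coords
            if sum(
                (y + dy, x + dx) in coords
                for dy in (-1, 0, 1)
                for dx in (-1, 0, 1)
                if (dy, dx) != (0, 0)
            )
            == 1
        )
        assert endpoints == n_protrusions

    def test_mask_single_connected_component(self):
        for name, preset in SHAPE_PRESETS.items():
            mask, _ = render_cell(preset, 11)
            assert cc_label(mask).max() == 1, name

    def test_canvas_too_small_raises(self):
        with pytest.raises(CanvasTooSmallError):
            render_cell(SHAPE_PRESETS["spindle"], 1, canvas_px=40)


class TestRenderField:
    def test_ground_truth_frequencies_multinomial(self):
        # oracle: exact 3-sd binomial bounds on planted class counts
        pop = POPULATION_PRESETS["control_soft"].with_(n_cells=200, seed=1)
        _, gt = render_field(pop, (2048, 2048))
        assert len(gt) == 200
        probs = dict(pop.mixture_weights, unclassified=pop.unclassified_weight)
        for cls, p in probs.items():
            k = (gt["class"] == cls).sum()
            sd = np.sqrt(200 * p * (1 - p))
            assert abs(k - 200 * p) <= 3 * sd, cls

    def test_zero_cells_pure_noise(self):
        pop = PopulationPreset("empty", {"round": 1.0}, 0.0, 0, seed=2)
        fld, gt = render_field(pop, (128, 128))
        assert gt.empty
        assert fld.pixels.shape == (2, 1, 1, 128, 128)

    def test_determinism_bit_identical(self):
        pop = POPULATION_PRESETS["control_soft"].with_(n_cells=15, seed=9)
        f1, g1 = render_field(pop, (512, 512))
        f2, g2 = render_field(pop, (512, 512))
        assert np.array_equal(f1.pixels, f2.pixels)
        pd.testing.assert_frame_equal(g1, g2)

    def test_every_cell_in_ground_truth_once(self, small_soft_field):
        _, gt = small_soft_field
        assert gt["cell_id"].is_unique and len(gt) == 25


class TestGenerateScreen:
    def test_planted_hit_enriches_star(self):
        layout = make_plate_layout(["null", "hit"], n_plates=1, n_control_wells=2)
        control = POPULATION_PRESETS["control_soft"].with_(n_cells=12)
        effect = POPULATION_PRESETS["ect2_soft"].with_(n_cells=12)
        out = generate_screen(layout, {"hit": effect}, 3, control, cells_per_well=12)
        star = {"hit": [], "null": []}
        for (_, well, _), (fld, gt) in out.items():
            reagent = layout.set_index("well").loc[well, "reagent"]
            if reagent in star:
                star[reagent].append((gt["class"] == "star").mean())
        assert np.mean(star["hit"]) > np.mean(star["null"])

    def test_empty_layout_empty_output(self):
        layout = make_plate_layout([], n_control_wells=0, n_plates=1)
        out = generate_screen(
            layout, {}, 1, POPULATION_PRESETS["control_soft"].with_(n_cells=5)
        )
        assert out == {}

    def test_duplicate_plates_use_distinct_seeds(self):
        layout = make_plate_layout(["a"], n_plates=2, n_control_wells=0)
        control = POPULATION_PRESETS["control_soft"].with_(n_cells=5)
        out = generate_screen(
            layout, {}, 1, control, cells_per_well=5, field_size_px=(512, 512)
        )
        by_plate = {}
        for (plate, _, _), (fld, _) in out.items():
            by_plate.setdefault(plate, []).append(fld.pixels)
        plates = sorted(by_plate)
        assert len(plates) == 2
        assert not np.array_equal(by_plate[plates[0]][0], by_plate[plates[1]][0])

    def test_missing_effect_without_inheritance_raises(self):
        layout = make_plate_layout(["orphan"], n_plates=1, n_control_wells=0)
        with pytest.raises(KeyError):
            generate_screen(
                layout,
                {},
                1,
                POPULATION_PRESETS["control_soft"].with_(n_cells=5),
                inherit_control=False,
            )


class TestFaMovie:
    def test_noiseless_log_slope_exact(self):
        preset = FA_MOVIE_PRESETS["fa_wt"].with_(
            n_adhesions=3, noise_sd=0.0, background=0.0, seed=4
        )
        _, gt = generate_fa_movie(preset, n_frames=30)
        for _, track in gt.groupby("track_id"):
            track = track.sort_values("t")
            logi = np.log(track["intensity"].to_numpy())
            peak = int(np.argmax(logi))
            if peak >= 2:
                slopes = np.diff(logi[: peak + 1])
                assert np.allclose(slopes, preset.assembly_rate_per_min, atol=1e-9)
            if len(logi) - peak >= 3:
                slopes = np.diff(logi[peak:])
                assert np.allclose(slopes, -preset.disassembly_rate_per_min, atol=1e-9)

    def test_preset_fold_parameters_match_documented(self):
        # preset fidelity: the shipped ratios are the documented fold changes
        wt = FA_MOVIE_PRESETS["fa_wt"]
        kd = FA_MOVIE_PRESETS["fa_arhgef9"]
        pf = FA_MOVIE_PRESETS["fa_pf573288"]
        folds = FA_PRESET_FOLDS[("fa_arhgef9", "fa_wt")]
        assert kd.area_mean_px / wt.area_mean_px == pytest.approx(folds["area"])
        assert kd.intensity_mean / wt.intensity_mean == pytest.approx(
            folds["intensity"]
        )
        assert kd.axial_ratio_mean / wt.axial_ratio_mean == pytest.approx(
            folds["axial_ratio"]
        )
        assert pf.longevity_mean_frames / wt.longevity_mean_frames == pytest.approx(
            FA_PRESET_FOLDS[("fa_pf573288", "fa_wt")]["longevity"]
        )

    def test_single_frame_movie_tracks_length_one(self):
        preset = FA_MOVIE_PRESETS["fa_wt"].with_(n_adhesions=4, seed=6)
        _, gt = generate_fa_movie(preset, n_frames=1)
        assert (gt.groupby("track_id").size() == 1).all()

    def test_too_short_longevity_rejected(self):
        with pytest.raises(ValueError):
            FA_MOVIE_PRESETS["fa_wt"].with_(longevity_mean_frames=3)


class TestFretSeries:
    def test_closed_fraction_limits(self):
        lo = TENSION_PRESETS["tension_wt"].with_(
            n_adhesions=20,
            closed_fraction_mean=0.0,
            closed_fraction_peak=0.0,
            noise_cv=0.0,
            seed=1,
        )
        hi = lo.with_(closed_fraction_mean=1.0, closed_fraction_peak=1.0)
        s_lo, s_hi = generate_fret_series(lo), generate_fret_series(hi)
        r_lo = (s_lo["acceptor"] / s_lo["donor"]).mean()
        r_hi = (s_hi["acceptor"] / s_hi["donor"]).mean()
        assert r_hi > r_lo
        assert s_hi["true_tension"].max() < s_lo["true_tension"].min()

    def test_ratio_monotone_in_closure(self):
        base = TENSION_PRESETS["tension_wt"].with_(n_adhesions=50, seed=2)
        ratios = []
        for cm, cp in [(0.3, 0.5), (0.6, 0.8)]:
            s = generate_fret_series(
                base.with_(closed_fraction_mean=cm, closed_fraction_peak=cp)
            )
            ratios.append((s["acceptor"] / s["donor"]).mean())
        assert ratios[0] < ratios[1]

    def test_ground_truth_tension_identity(self):
        p = TENSION_PRESETS["tension_wt"].with_(n_adhesions=10, seed=3)
        s = generate_fret_series(p)
        expect = p.tension_scale * (1 - s["closed_fraction"])
        assert np.allclose(s["true_tension"], expect)


class TestInvasionStack:
    def test_all_mass_at_surface_zero_index(self):
        from morphoscreen.invasion import invasion_index

        p = InvasionPreset(
            "surface", 500, {0.0: 1.0, 30.0: 0.0, 60.0: 0.0, 90.0: 0.0}, seed=1
        )
        idx, _ = invasion_index(generate_invasion_stack(p))
        assert idx == 0.0

    def test_fractions_within_binomial_bound(self):
        p = INVASION_PRESETS["invasion_wt"].with_(n_cells=10000, seed=5)
        stack = generate_invasion_stack(p)
        assert stack.total == 10000
        for d, k in zip(stack.plane_depths_um, stack.counts):
            prob = p.depth_distribution[d]
            sd = np.sqrt(10000 * prob * (1 - prob))
            assert abs(k - 10000 * prob) <= 3 * sd

    def test_zero_cells_is_error(self):
        with pytest.raises(ValueError):
            generate_invasion_stack(INVASION_PRESETS["invasion_wt"].with_(n_cells=0))


class TestPresetFidelity:
    def test_population_presets_encode_reported_proportions(self):
        soft = POPULATION_PRESETS["control_soft"]
        assert soft.mixture_weights == {"round": 0.45, "spindle": 0.26, "star": 0.23}
        assert POPULATION_PRESETS["ect2_soft"].mixture_weights["star"] == 0.51
        stiff = POPULATION_PRESETS["control_stiff"]
        assert stiff.mixture_weights == {
            "spindle": 0.32,
            "small_flat": 0.49,
            "big_flat": 0.16,
        }

    def test_tension_presets_encode_planted_folds(self):
        wt, kd = TENSION_PRESETS["tension_wt"], TENSION_PRESETS["tension_kd"]
        assert kd.planted_mean_tension / wt.planted_mean_tension == pytest.approx(0.92)
        assert kd.planted_min_tension / wt.planted_min_tension == pytest.approx(0.65)

    def test_invasion_presets_encode_planted_fractions(self):
        wt = INVASION_PRESETS["invasion_wt"].depth_distribution
        kd = INVASION_PRESETS["invasion_kd"].depth_distribution
        assert sum(wt[d] for d in (30.0, 60.0, 90.0)) == pytest.approx(0.33)
        assert sum(kd[d] for d in (30.0, 60.0, 90.0)) == pytest.approx(0.27)
        assert wt[60.0] + wt[90.0] == pytest.approx(0.10)  # at/beyond 40 um
        assert kd[60.0] + kd[90.0] == pytest.approx(0.08)

    def test_ring_presets_encode_planted_contrast(self):
        from morphoscreen.presets import RING_TEXTURE_PRESETS

        wt, kd = RING_TEXTURE_PRESETS["ring_wt"], RING_TEXTURE_PRESETS["ring_kd"]
        assert kd.contrast / wt.contrast == pytest.approx(1.6)

    def test_flat_size_invariant(self):
        assert (
            SHAPE_PRESETS["big_flat"].body_radius_px
            >= 1.5 * SHAPE_PRESETS["small_flat"].body_radius_px
        )


class TestSeedDerivation:
    def test_stable_and_distinct(self):
        a = derive_seed(1, "P1", "A01", 0)
        assert a == derive_seed(1, "P1", "A01", 0)
        assert a != derive_seed(1, "P1", "A02", 0)
        assert a != derive_seed(2, "P1", "A01", 0)
        assert 0 <= a < 2**31
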