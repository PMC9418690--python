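"""Adhesion detection, tracking, kinetics, orientation, kymographs, rings."""

import numpy as np
import pytest

from morphoscreen.adhesion import (
    AdhesionTrack,
    TrackFrame,
    align_to_peak,
    detect_adhesions,
    extract_kymograph,
    fa_orientation,
    fa_ring_texture,
    fit_kinetics,
    link_tracks,
    static_summary,
    track_movie,
)
from morphoscreen.imaging import ImageField
from morphoscreen.presets import FA_MOVIE_PRESETS, RING_TEXTURE_PRESETS
from morphoscreen.simulate import generate_fa_movie, generate_ring_texture


def _frame_with_blobs(blobs, shape=(240, 240), background=40.0, noise_sd=5.0, seed=0):
    rng = np.random.default_rng(seed)
    img = np.full(shape, background)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cy, cx, r, amp in blobs:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] += amp
    return np.clip(img + rng.normal(0, noise_sd, shape), 0, None)


def _track(intensities, interval_s=60.0, area=80.0):
    frames = [
        TrackFrame(t, area, float(i), (5.0, 5.0), 2.0, 30.0)
        for t, i in enumerate(intensities)
    ]
    return AdhesionTrack(1, frames, interval_s)


class TestDetect:
    def test_counts_planted_adhesions(self):
        rng = np.random.default_rng(1)
        blobs = []
        taken = []
        while len(blobs) < 12:
            cy, cx = rng.uniform(20, 220, 2)
            if all(np.hypot(cy - y, cx - x) > 25 for y, x in taken):
                taken.append((cy, cx))
                blobs.append((cy, cx, 4, 500.0))
        mask = detect_adhesions(_frame_with_blobs(blobs), min_size_px=10)
        assert mask.n_labels == 12

    def test_small_object_dropped(self):
        img = _frame_with_blobs([(100, 100, 1.5, 500.0)], noise_sd=0.0)  # 8 px area
        assert detect_adhesions(img, min_size_px=10).n_labels == 0

    def test_blank_frame_zero(self):
        img = np.full((100, 100), 40.0) + np.random.default_rng(2).normal(
            0, 5, (100, 100)
        )
        assert detect_adhesions(np.clip(img, 0, None)).n_labels == 0


class TestLinking:
    def test_stationary_adhesion_single_track(self):
        frames = [
            _frame_with_blobs([(60, 60, 5, 500.0)], shape=(120, 120), seed=t)
            for t in range(10)
        ]
        masks = [detect_adhesions(f) for f in frames]
        tracks = link_tracks(masks, frames)
        assert len(tracks) == 1 and tracks[0].n_frames == 10

    def test_short_track_excluded(self):
        frames = [
            _frame_with_blobs(
                [(60, 60, 5, 500.0)] if t < 4 else [], shape=(120, 120), seed=t
            )
            for t in range(8)
        ]
        masks = [detect_adhesions(f) for f in frames]
        assert link_tracks(masks, frames, min_track_frames=5) == []

    def test_two_adhesions_no_identity_swap(self):
        frames = [
            _frame_with_blobs(
                [(40, 40, 5, 500.0), (90, 90, 5, 500.0)], shape=(130, 130), seed=t
            )
            for t in range(8)
        ]
        masks = [detect_adhesions(f) for f in frames]
        tracks = link_tracks(masks, frames)
        assert len(tracks) == 2
        for tr in tracks:
            xs = [f.centroid_xy[0] for f in tr.frames]
            assert np.ptp(xs) < 3.0  # each track stays on one adhesion

    def test_empty_movie(self):
        assert link_tracks([], []) == []

    def test_tracking_recovers_planted_tracks(self):
        preset = FA_MOVIE_PRESETS["fa_wt"].with_(n_adhesions=30, seed=12)
        movie, gt = generate_fa_movie(preset, n_frames=25, frame_size_px=(512, 512))
        tracks = track_movie(movie)
        planted = gt.groupby("track_id").agg(
            n=("t", "size"), x=("x", "first"), y=("y", "first")
        )
        assert len(tracks) >= 0.95 * len(planted)
        # identity preservation: every measured track sits on one planted
        # adhesion for its whole life
        for tr in tracks:
            xs = np.array([f.centroid_xy[0] for f in tr.frames])
            ys = np.array([f.centroid_xy[1] for f in tr.frames])
            d = np.hypot(planted["x"].to_numpy() - xs.mean(), planted["y"].to_numpy() - ys.mean())
            j = int(np.argmin(d))
            assert d[j] <= 3.0
            assert np.hypot(xs - xs.mean(), ys - ys.mean()).max() <= 3.0
            assert tr.n_frames == planted.iloc[j]["n"]


class TestStatics:
    def test_single_track_zero_distances(self):
        tr = _track([100, 120, 140, 120, 100])
        s = static_summary(tr, [tr])
        assert s.mean_dist_centroid == 0.0 and s.mean_dist_hull == 0.0
        assert s.longevity_min == 5.0

    def test_unit_square_geometry(self):
        tracks = []
        for i, (x, y) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
            frames = [TrackFrame(t, 50, 100, (float(x), float(y)), 1.5, 0.0) for t in range(5)]
            tracks.append(AdhesionTrack(i + 1, frames, 60.0))
        for tr in tracks:
            s = static_summary(tr, tracks)
            assert s.mean_dist_centroid == pytest.approx(np.sqrt(2) / 2)
            assert s.mean_dist_hull == pytest.approx(0.0, abs=1e-12)


class TestKinetics:
    def test_noiseless_exponential_exact(self):
        k = 0.05
        inten = [500 * np.exp(k * (t - 9)) for t in range(10)]
        retained, rejected = fit_kinetics(_track(inten))
        assert rejected == []
        fit = retained[0]
        assert fit.phase == "assembly"
        assert fit.rate_per_min == pytest.approx(k, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_disassembly_rate_reported_positive(self):
        inten = [500 * np.exp(-0.04 * t) for t in range(8)]
        retained, _ = fit_kinetics(_track(inten))
        assert retained[0].phase == "disassembly"
        assert retained[0].rate_per_min == pytest.approx(0.04, abs=1e-6)

    def test_noise_tracks_rejected_by_r2_gate(self):
        rng = np.random.default_rng(3)
        n_rej = n_tot = 0
        for i in range(100):
            inten = rng.uniform(100, 500, 12)
            retained, rejected = fit_kinetics(_track(inten))
            n_tot += len(retained) + len(rejected)
            n_rej += len(rejected)
        assert n_rej >= 0.95 * n_tot

    def test_planted_rate_distribution_recovered(self):
        rng = np.random.default_rng(4)
        rates = []
        for i in range(100):
            fr = [
                max(600 * np.exp(0.04 * (t - 11)) + rng.normal(0, 8), 1.0)
                for t in range(12)
            ]
            retained, _ = fit_kinetics(_track(fr))
            rates += [f.rate_per_min for f in retained if f.phase == "assembly"]
        assert np.mean(rates) == pytest.approx(0.04, rel=0.10)

    def test_monotone_track_single_phase(self):
        inten = [100 * np.exp(0.05 * t) for t in range(10)]
        retained, rejected = fit_kinetics(_track(inten))
        assert len(retained) + len(rejected) == 1


class TestOrientation:
    def _cell(self):
        yy, xx = np.mgrid[0:140, 0:140]
        return ((xx - 70) / 55.0) ** 2 + ((yy - 70) / 18.0) ** 2 <= 1

    def test_parallel_perpendicular_circular(self):
        yy, xx = np.mgrid[0:140, 0:140]
        cell = self._cell()
        par = (np.abs(yy - 70) <= 2) & (np.abs(xx - 40) <= 9)
        perp = (np.abs(xx - 100) <= 2) & (np.abs(yy - 70) <= 9)
        circ = (xx - 70) ** 2 + (yy - 80) ** 2 <= 9
        assert fa_orientation(par, cell) == pytest.approx(0.0, abs=2.0)
        assert fa_orientation(perp, cell) == pytest.approx(90.0, abs=2.0)
        assert fa_orientation(circ, cell) is None

    def test_rotation_invariance(self):
        cell = self._cell()
        yy, xx = np.mgrid[0:140, 0:140]
        ad = (np.abs(yy - xx) <= 3) & (np.abs(xx - 70) <= 10)  # 45 degrees
        a0 = fa_orientation(ad, cell)
        a90 = fa_orientation(np.rot90(ad), np.rot90(cell))
        assert a0 == pytest.approx(a90, abs=2.0)


class TestKymograph:
    def _bar_movie(self, move=0):
        mov = np.zeros((1, 1, 6, 50, 50))
        for t in range(6):
            x0 = 10 + move * t
            mov[0, 0, t, 23:27, x0 : x0 + 20] = 100.0
        return ImageField(mov, {0: "paxillin"})

    def test_static_bar_time_constant(self):
        kg = extract_kymograph(self._bar_movie(0), (5, 25), (44, 25))
        assert np.allclose(kg[0, :, 0], kg[0, :, -1])

    def test_translating_bar_unit_slope(self):
        kg = extract_kymograph(self._bar_movie(1), (5, 25), (44, 25))
        # leading edge of the bar advances 1 px per frame
        edges = [int(np.flatnonzero(kg[0, :, t] > 50)[-1]) for t in range(6)]
        slopes = np.diff(edges)
        assert np.allclose(slopes, 1)

    def test_empty_channel_zero_trace(self):
        mov = np.zeros((1, 1, 4, 30, 30))
        kg = extract_kymograph(ImageField(mov, {0: "paxillin"}), (2, 15), (27, 15))
        assert np.all(kg == 0)


class TestAlignToPeak:
    def test_shifted_identical_tracks_recover_profile(self):
        t = np.arange(40)
        prof = np.exp(-0.5 * ((t - 20) / 4.0) ** 2)
        traces = [(np.roll(prof, s), np.roll(prof, s)) for s in (-3, 0, 4)]
        out = align_to_peak(traces)
        i0 = np.flatnonzero(out["offsets"] == 0)[0]
        assert out["pax_mean"][i0] == pytest.approx(prof.max())
        common = out["n"] == 3
        assert np.allclose(out["pax_sd"][common], 0.0, atol=1e-6)

    def test_planted_actin_lead_recovered(self):
        t = np.arange(40)
        traces = []
        for s in (0, 2, 5):
            pax = np.exp(-0.5 * ((t - 15 - s) / 3.0) ** 2)
            act = np.exp(-0.5 * ((t - 12 - s) / 3.0) ** 2)
            traces.append((pax, act))
        out = align_to_peak(traces)
        act_peak = out["offsets"][np.argmax(out["act_mean"])]
        assert act_peak == -3

    def test_single_track_sd_zero(self):
        t = np.arange(20)
        prof = np.exp(-0.5 * ((t - 8) / 2.0) ** 2)
        out = align_to_peak([(prof, prof)])
        assert np.allclose(out["pax_mean"], prof)
        assert np.allclose(out["pax_sd"], 0.0)


class TestRingTexture:
    def test_constant_ring_zero(self):
        yy, xx = np.mgrid[0:40, 0:40]
        mask = (yy - 20) ** 2 + (xx - 20) ** 2 <= 16
        assert fa_ring_texture(np.full((40, 40), 9.0), mask) == 0.0

    def test_sparse_filaments_score_higher_than_dense_meshwork(self):
        # dense low-contrast meshwork (control-like) vs sparse high-contrast
        # filaments (knockdown-like): the planted generator orders kd > wt
        wt = generate_ring_texture(RING_TEXTURE_PRESETS["ring_wt"], 0)
        kd = generate_ring_texture(RING_TEXTURE_PRESETS["ring_kd"], 0)
        assert fa_ring_texture(*kd) > fa_ring_texture(*wt)

    def test_planted_contrast_fold_recovered(self):
        from morphoscreen.pipeline import ring_texture_median_fold

        fold = ring_texture_median_fold(n_fixtures=60, seed=2)
        assert fold == pytest.approx(1.6, rel=0.15)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            fa_ring_texture(np.ones((20, 20)), np.zeros((20, 20), dtype=bool))


class TestFoldRecovery:
    def test_mean_area_fold_recovers_preset_ratio(self):
        # scaled-down version of the paired-movie comparison
        from morphoscreen._rng import derive_seed

        summaries = {}
        for name in ("fa_wt", "fa_arhgef9"):
            p = FA_MOVIE_PRESETS[name].with_(
                n_adhesions=40, seed=derive_seed(3, name)
            )
            movie, _ = generate_fa_movie(p, n_frames=30, frame_size_px=(640, 640))
            tracks = track_movie(movie)
            summaries[name] = np.mean(
                [np.mean([f.area_px for f in t.frames]) for t in tracks]
            )
        fold = summaries["fa_arhgef9"] / summaries["fa_wt"]
        assert fold == pytest.approx(1.62, rel=0.10)
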