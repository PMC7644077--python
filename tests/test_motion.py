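import numpy as np
import pytest

from cellmag.motion import (DIRECTIONS_DEG, assign_direction, build_grid,
                            center_of_mass_track, detect_moving_segments,
                            phase_annotate, probe_line_pixels,
                            render_directors, segment_motion_sum)
from cellmag.synthio import FixtureSpec, make_ring
from cellmag.videoio import VideoSequence


def _video(frames, fps=10.0):
    return VideoSequence(np.asarray(frames), fps)


class TestBuildGrid:
    def test_lattice_matches_brute_force_enumeration(self):
        h = w = 32
        l = 7
        grid = build_grid((h, w), l)
        expected = set()
        for n in range(0, h // l + 1):
            for m in range(0, w // l + 1):
                horiz = {(l * n, x) for x in range(l * m + 1, l * (m + 1))}
                vert = {(y, l * m) for y in range(l * n + 1, l * (n + 1))}
                if all(y < h and x < w for y, x in horiz) and l * n < h:
                    expected.add(frozenset(horiz))
                if all(y < h and x < w for y, x in vert) and l * m < w:
                    expected.add(frozenset(vert))
        got = {frozenset(s.pixels) for s in grid.segments}
        assert got == expected
        for seg in grid.segments:
            assert len(seg.pixels) == l - 1  # strict inequalities of the lattice
            assert all(0 <= y < h and 0 <= x < w for y, x in seg.pixels)

    def test_even_or_oversized_length_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            build_grid((32, 32), 8)
        with pytest.raises(ValueError):
            build_grid((32, 32), 35)


class TestDetectMovingSegments:
    def test_static_video_triggers_nothing(self):
        grid = build_grid((16, 16), 5)
        v = _video(np.full((8, 16, 16, 1), 0.4))
        assert detect_moving_segments(v, grid, mth=1e-9) == []

    def test_blinking_pixel_matches_hand_computed_sum(self):
        grid = build_grid((16, 16), 5)
        frames = np.full((16, 16, 16, 1), 0.2)
        # blink pixel (y=0, x=2) — on the first horizontal segment
        frames[1::2, 0, 2, 0] += 0.5
        v = _video(frames)
        hits = detect_moving_segments(v, grid, mth=0.0)
        # hand computation: 15 frame pairs, each |Δ| = 0.5
        expected = 15 * 0.5
        assert len(hits) == 1
        seg, s = hits[0]
        assert (0, 2) in seg.pixels
        assert s == pytest.approx(expected)
        assert segment_motion_sum(v, seg) == pytest.approx(expected)

    def test_statistic_invariant_under_time_reversal(self):
        rng = np.random.default_rng(0)
        frames = rng.random((10, 16, 16, 1))
        grid = build_grid((16, 16), 5)
        fwd = detect_moving_segments(_video(frames), grid, 0.0)
        rev = detect_moving_segments(_video(frames[::-1]), grid, 0.0)
        np.testing.assert_allclose([s for _, s in fwd], [s for _, s in rev])


class TestCenterOfMass:
    def test_symmetric_profile_centers_at_zero(self):
        frames = np.zeros((2, 16, 16, 1))
        l, c = 7, (8, 8)
        pix = probe_line_pixels(c, l, 90.0)
        weights = [1, 2, 3, 9, 3, 2, 1]
        for (y, x), wgt in zip(pix, weights):
            frames[:, y, x, 0] = wgt / 10
        cm = center_of_mass_track(_video(frames), c, l, 90.0)
        np.testing.assert_allclose(cm, 0.0, atol=1e-12)

    def test_dark_line_defaults_to_center(self):
        frames = np.zeros((2, 16, 16, 1))
        cm = center_of_mass_track(_video(frames), (8, 8), 7, 0.0)
        np.testing.assert_array_equal(cm, 0.0)

    def test_rms_matches_two_pass_oracle(self):
        rng = np.random.default_rng(1)
        frames = rng.random((12, 16, 16, 1))
        v = _video(frames)
        cm = center_of_mass_track(v, (8, 8), 7, 45.0)
        # brute-force oracle for the rms about the temporal mean
        mean = sum(cm) / len(cm)
        oracle = (sum((c - mean) ** 2 for c in cm) / len(cm)) ** 0.5
        grid = build_grid((16, 16), 7)
        seg = next(s for s in grid.segments if s.center == (10, 7))
        d = assign_direction(v, seg, 7)
        # recompute the 45° score the slow way for the same probe center
        cm2 = center_of_mass_track(v, seg.center, 7, 45.0)
        mean2 = sum(cm2) / len(cm2)
        oracle2 = (sum((c - mean2) ** 2 for c in cm2) / len(cm2)) ** 0.5
        assert d.scores[45.0] == pytest.approx(oracle2, abs=1e-12)
        assert oracle == pytest.approx(np.sqrt(np.mean((cm - cm.mean()) ** 2)))


def _lattice_blob_video(direction_deg, grid, amplitude_px=1.5, size=96,
                        n_frames=48):
    """Sparse bright blobs sitting on grid-segment centers (the probe lines
    are centered on the moving feature, as they are on a cell edge),
    translating sinusoidally along ``direction_deg``."""
    from cellmag.synthio import fourier_shift_image
    sites = []
    for seg in grid.segments:
        y, x = seg.center
        if 12 <= y <= size - 12 and 12 <= x <= size - 12 and \
                all((y - a) ** 2 + (x - b) ** 2 >= 18 ** 2 for a, b in sites):
            sites.append((y, x))
    yy, xx = np.mgrid[0:size, 0:size]
    img = np.zeros((size, size))
    for cy, cx in sites:
        img += 0.8 * np.exp(-0.5 * ((yy - cy) ** 2 + (xx - cx) ** 2) / 1.5 ** 2)
    img = np.clip(img, 0, 1)
    t = np.arange(n_frames) / 24.0
    disp = amplitude_px * np.sin(2 * np.pi * 1.0 * t)
    theta = np.deg2rad(direction_deg)
    uy, ux = np.cos(theta), np.sin(theta)
    frames = np.stack([fourier_shift_image(img, d * uy, d * ux)
                       for d in disp])
    return VideoSequence(np.clip(frames, 0, 1)[..., None], 24.0), len(sites)


class TestAssignDirection:
    @pytest.mark.parametrize("direction", DIRECTIONS_DEG)
    def test_recovers_injected_translation_direction(self, direction):
        grid = build_grid((96, 96), 9)
        video, n_sites = _lattice_blob_video(direction, grid)
        hits = detect_moving_segments(video, grid, mth=0.0)
        # empirical MTH, as the method prescribes: keep the feature-bearing
        # segments (their motion statistic dwarfs their neighbours')
        top = max(s for _, s in hits)
        hits = [(seg, s) for seg, s in hits if s > 0.5 * top]
        n_checked = n_correct = 0
        for seg, s in hits:
            d = assign_direction(video, seg, 9, s)
            if d is None:
                continue
            n_checked += 1
            if d.theta_d == direction:
                n_correct += 1
        assert n_checked >= n_sites
        assert n_correct / n_checked >= 0.95

    def test_static_segment_suppressed(self):
        grid = build_grid((16, 16), 5)
        v = _video(np.full((6, 16, 16, 1), 0.3))
        assert assign_direction(v, grid.segments[5], 5) is None

    def test_border_probe_skipped_with_warning(self):
        grid = build_grid((16, 16), 5)
        rng = np.random.default_rng(0)
        v = _video(rng.random((6, 16, 16, 1)))
        border_seg = next(s for s in grid.segments if s.center[0] == 0)
        with pytest.warns(UserWarning, match="skipped"):
            assert assign_direction(v, border_seg, 5) is None

    def test_ring_rightmost_edge_moves_radially(self):
        spec = FixtureSpec(kind="ring", size=(64, 64), n_frames=48,
                           frame_rate_hz=24.0, motion_freq_hz=1.0,
                           amplitude_px=2.0, noise_sigma=0.0, seed=0)
        video, radii = make_ring(spec)
        # probe centered on the rightmost edge of the ring
        center = (32, int(round(31.5 + radii.mean())))
        grid_l = 9
        scores = {}
        for theta in DIRECTIONS_DEG:
            cm = center_of_mass_track(video, center, grid_l, theta)
            scores[theta] = np.sqrt(np.mean((cm - cm.mean()) ** 2))
        # radial direction at the rightmost point is horizontal (90°)
        assert max(scores, key=scores.get) == 90.0


class TestPhaseAnnotate:
    def _cm_video(self, cm_series, l=7):
        """Video whose probe-line center of mass follows ``cm_series``:
        a narrow bright spot moving along a vertical line."""
        t = len(cm_series)
        frames = np.zeros((t, 32, 32, 1))
        half = (l - 1) // 2
        hs = np.arange(-half, half + 1)
        for ti, c in enumerate(cm_series):
            frames[ti, 16 + hs, 16, 0] = np.exp(-0.5 * (hs - c) ** 2)
        return _video(frames)

    def test_sine_track_flips_phase_at_the_extrema(self):
        t = np.arange(40)
        cm = np.sin(2 * np.pi * t / 20)
        v = self._cm_video(cm)
        kymo = phase_annotate(v, (16, 16), 7, 0.0, n_fit=4)
        flips = np.nonzero(np.diff(np.sign(kymo.phase_sign)))[0]
        # sine extrema at t = 5, 15, 25, 35: derivative changes sign there
        for expected in (5, 15, 25, 35):
            assert np.any(np.abs(flips - expected) <= 1)

    def test_monotonic_drift_keeps_a_single_phase(self):
        cm = np.linspace(-2, 2, 30)
        v = self._cm_video(cm)
        kymo = phase_annotate(v, (16, 16), 7, 0.0, n_fit=4)
        assert np.all(kymo.phase_sign == 1)

    def test_ring_expansion_and_contraction_halves(self):
        spec = FixtureSpec(kind="ring", size=(64, 64), n_frames=96,
                           frame_rate_hz=24.0, motion_freq_hz=0.5,
                           amplitude_px=2.0, noise_sigma=0.0, seed=0)
        video, radii = make_ring(spec)
        center = (32, int(round(31.5 + radii.mean())))
        kymo = phase_annotate(video, center, 9, 90.0, n_fit=5)
        truth = np.sign(np.gradient(radii))
        # sign-flip timing: agreement away from the extrema themselves
        interior = np.abs(np.gradient(radii)) > 0.3 * np.abs(np.gradient(radii)).max()
        agree = np.mean(kymo.phase_sign[interior] == truth[interior])
        assert agree > 0.9

    def test_short_video_rejected(self):
        v = self._cm_video(np.zeros(8))
        with pytest.raises(ValueError):
            phase_annotate(v, (16, 16), 7, 0.0, n_fit=5)
        with pytest.raises(ValueError, match="n_fit"):
            phase_annotate(v, (16, 16), 7, 0.0, n_fit=2)


class TestRenderDirectors:
    def test_empty_list_is_identity(self, rgb_video):
        out = render_directors(rgb_video, [])
        np.testing.assert_array_equal(out.frames, rgb_video.frames)

    def test_one_director_draws_one_arrow(self):
        frames = np.zeros((4, 32, 32, 1))
        v = _video(frames)
        grid = build_grid((32, 32), 7)
        moving = np.zeros((6, 32, 32, 1))
        moving[1::2, 16 + np.arange(-3, 4), 16, 0] = 0.8  # vertical flicker
        mv = _video(moving)
        seg = min(grid.segments, key=lambda s: abs(s.center[0] - 16)
                  + abs(s.center[1] - 16))
        d = assign_direction(mv, seg, 7)
        out = render_directors(v, [d])
        changed = np.nonzero((out.frames[0, :, :, 0] != 0))
        assert len(changed[0]) > 0
        # single line segment through the director center
        assert len(changed[0]) <= 2 * max(out.shape[1:3])

    def test_ring_directors_draw_radial_arrows(self):
        from cellmag.motion import MotionDirector
        spec = FixtureSpec(kind="ring", size=(64, 64), n_frames=48,
                           frame_rate_hz=24.0, motion_freq_hz=1.0,
                           amplitude_px=2.0, noise_sigma=0.0, seed=0)
        video, radii = make_ring(spec)
        r = radii.mean()
        # radial direction is 90° (horizontal) at the left/right edge
        # points and 0° (vertical) at the top/bottom ones
        directors = [
            MotionDirector((32, int(31.5 + r)), 90.0,
                           {0.0: 0.1, 45.0: 0.2, 90.0: 1.0, 135.0: 0.2}, 1.0),
            MotionDirector((int(31.5 + r), 32), 0.0,
                           {0.0: 1.0, 45.0: 0.2, 90.0: 0.1, 135.0: 0.2}, 1.0),
        ]
        out = render_directors(video, directors, scale=1.0)
        burned = np.nonzero(out.frames[0, :, :, 0] != video.frames[0, :, :, 0])
        assert len(burned[0]) > 0
        for y, x in zip(*burned):
            # every burned pixel lies on one of the two radial probe axes
            assert (y == 32 and abs(x - int(31.5 + r)) <= 12) or \
                   (x == 32 and abs(y - int(31.5 + r)) <= 12)
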