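"""Stimulus synthesis: contrast arithmetic, textures, movies, ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emdlobula import (
    StimulusSpec,
    make_dot_texture,
    make_movie,
    make_panorama,
    michelson_contrast,
    naka_rushton,
    rms_contrast,
)
from emdlobula.stimulus import load_movie, save_movie


class TestMichelsonContrast:
    @pytest.mark.parametrize(
        "imax, imin, expected",
        [
            (0.75, 0.25, 0.5),
            (0.5, 0.25, 1 / 3),
            (0.9, 0.1, 0.8),
            (0.3, 0.3, 0.0),
            (0.0, 0.0, 0.0),
        ],
    )
    def test_values(self, imax, imin, expected):
        assert michelson_contrast(imax, imin) == pytest.approx(expected, abs=1e-12)

    def test_rejects_negative_and_inverted(self):
        with pytest.raises(ValueError):
            michelson_contrast(0.5, -0.1)
        with pytest.raises(ValueError):
            michelson_contrast(0.2, 0.5)


class TestRmsContrast:
    def test_constant_image_is_zero(self):
        assert rms_contrast(np.full((8, 8), 0.4)) == pytest.approx(0.0, abs=1e-12)

    def test_two_value_image(self):
        # half pixels a, half pixels b: population SD/mean = |b-a|/(a+b)
        a, b = 0.2, 0.6
        img = np.array([[a, b], [b, a]])
        assert rms_contrast(img) == pytest.approx(abs(b - a) / (a + b), rel=1e-12)

    @given(st.floats(min_value=0.1, max_value=50.0))
    @settings(deadline=None, max_examples=20)
    def test_scale_invariance(self, k):
        img = np.linspace(0.1, 0.9, 25).reshape(5, 5)
        assert rms_contrast(k * img) == pytest.approx(rms_contrast(img), rel=1e-9)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            rms_contrast(np.zeros((4, 4)))


class TestNakaRushton:
    def test_half_saturation_at_mean(self):
        out = naka_rushton(np.array([0.3]), i_mean=0.3, mu=0.7)
        assert out[0] == pytest.approx(0.5)

    def test_zero_maps_to_zero(self):
        assert naka_rushton(np.array([0.0]), 1.0)[0] == 0.0

    def test_bright_scalar(self):
        expected = 100**0.7 / (100**0.7 + 1)
        assert naka_rushton(np.array([100.0]), 1.0, mu=0.7)[0] == pytest.approx(expected)

    def test_output_stays_below_one(self):
        out = naka_rushton(np.geomspace(1e-3, 1e6, 50), i_mean=1.0)
        assert np.all((out >= 0) & (out < 1))


class TestDotTexture:
    def test_block_values_at_80_percent(self):
        tex = make_dot_texture((16, 16), 8, 0.8, 0.5, seed=0)
        assert set(np.round(np.unique(tex), 12)) <= {0.1, 0.9}

    def test_zero_contrast_constant(self):
        tex = make_dot_texture((12, 12), 4, 0.0, 0.5, seed=0)
        assert np.all(tex == 0.5)

    def test_same_seed_reproducible(self):
        a = make_dot_texture((40, 40), 8, 0.8, 0.5, seed=5)
        b = make_dot_texture((40, 40), 8, 0.8, 0.5, seed=5)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("contrast", [0.1, 0.3, 0.5, 0.8, 1.0])
    def test_measured_contrast_matches_request(self, contrast):
        tex = make_dot_texture((64, 64), 8, contrast, 0.5, seed=2)
        measured = michelson_contrast(tex.max(), tex.min())
        assert measured == pytest.approx(contrast, abs=1e-12)

    def test_out_of_range_contrast_rejected(self):
        with pytest.raises(ValueError):
            make_dot_texture((8, 8), 4, 0.8, i0=0.7)


class TestPanorama:
    def test_contrast_tracks_request_and_positive(self):
        scene = make_panorama((120, 400), c_rms=2.0, seed=3)
        assert scene.min() > 0
        assert rms_contrast(scene) == pytest.approx(2.0, rel=0.5)


class TestMakeMovie:
    def test_square_mask_geometry_and_translation(self):
        spec = StimulusSpec(
            kind="square", figure_width=34.0, figure_height=34.0,
            figure_speed=66.0, duration_frames=10, rng_seed=0,
        )
        movie = make_movie(spec)
        mask0 = movie.gt_masks[0]
        rows = np.flatnonzero(mask0.any(axis=1))
        cols = np.flatnonzero(mask0.any(axis=0))
        assert len(rows) == 103 and len(cols) == 103  # round(34/0.33)
        # 66 deg/s at 100 Hz and 0.33 deg/px -> 2 px per frame
        for t in range(9):
            assert np.array_equal(
                movie.gt_masks[t + 1], np.roll(movie.gt_masks[t], 2, axis=1)
            )

    def test_frame_shape_follows_spec(self):
        spec = StimulusSpec(duration_frames=1)
        assert spec.frame_shape == (273, 545)

    def test_theta_envelope_and_texture_move_oppositely(self):
        spec = StimulusSpec(
            kind="theta", figure_width=25.0, figure_height=90.0,
            figure_speed=66.0, internal_texture_speed=-66.0,
            duration_frames=6, figure_start_deg=20.0, rng_seed=3,
        )
        movie = make_movie(spec)
        # envelope: +2 px/frame
        assert np.array_equal(
            movie.gt_masks[1], np.roll(movie.gt_masks[0], 2, axis=1)
        )
        # interior texture slips -4 px/frame relative to the envelope
        # (envelope +2, texture -2 on screen)
        for t in range(5):
            c0 = np.flatnonzero(movie.gt_masks[t][0])
            c1 = np.flatnonzero(movie.gt_masks[t + 1][0])
            reg_t = movie.frames[t][:, c0]
            reg_t1 = movie.frames[t + 1][:, c1]
            assert np.array_equal(reg_t1[:, :-4], reg_t[:, 4:])

    def test_wide_field_grating_contrast_and_empty_mask(self):
        spec = StimulusSpec(
            kind="wide_field_grating", elevation_extent=70.0,
            grating_wavelength=17.8, background_luminances=(0.25, 0.75),
            figure_speed=0.0, background_speed=33.0, duration_frames=3,
        )
        movie = make_movie(spec)
        frame = movie.frames[0]
        assert michelson_contrast(frame.max(), frame.min()) == pytest.approx(0.5)
        assert not movie.gt_masks.any()

    def test_bar_on_ground_mask_translation_with_wraparound(self):
        spec = StimulusSpec(
            kind="bar_on_ground", figure_width=25.0, figure_speed=66.0,
            background_speed=-66.0, duration_frames=300, rng_seed=1,
        )
        movie = make_movie(spec)
        for t in (0, 150, 298):  # includes frames after azimuthal wrap
            assert np.array_equal(
                movie.gt_masks[t + 1], np.roll(movie.gt_masks[t], 2, axis=1)
            )
            assert movie.gt_masks[t].any()

    def test_mirrored_spec_gives_exactly_mirrored_movie(self):
        spec = StimulusSpec(
            kind="bar_on_ground", duration_frames=8, figure_speed=66.0,
            background_speed=-33.0, rng_seed=11,
        )
        fwd = make_movie(spec)
        rev = make_movie(spec.mirrored())
        assert np.array_equal(rev.frames, fwd.frames[:, :, ::-1])
        assert np.array_equal(rev.gt_masks, fwd.gt_masks[:, :, ::-1])

    def test_subpixel_speed_warns(self):
        spec = StimulusSpec(duration_frames=2, figure_speed=20.0)
        with pytest.warns(UserWarning, match="whole number of pixels"):
            make_movie(spec)

    def test_luminance_bounds_all_kinds(self):
        for kind, extra in [
            ("edge", {}),
            ("small_obj", dict(figure_width=8.9, figure_height=8.9, elevation_extent=70.0)),
            ("bar_plus_grating", dict(figure_width=8.9, elevation_extent=70.0,
                                      background_luminances=(0.25, 0.5), figure_luminance=0.0)),
            ("synthetic_scene_bar", dict(azimuth_extent=360.0, elevation_extent=97.0,
                                         deg_per_pixel=0.39, figure_width=15.0,
                                         figure_speed=-33.0, background_speed=33.0)),
        ]:
            spec = StimulusSpec(kind=kind, duration_frames=3, **extra)
            movie = make_movie(spec)
            assert movie.frames.min() >= 0.0 and movie.frames.max() <= 1.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            StimulusSpec(kind="nonsense")


def test_movie_roundtrip(tmp_path):
    spec = StimulusSpec(
        kind="bar_on_ground", azimuth_extent=30.0, elevation_extent=15.0,
        figure_width=10.0, duration_frames=3, rng_seed=4,
    )
    movie = make_movie(spec)
    save_movie(movie, tmp_path / "mov")
    loaded = load_movie(tmp_path / "mov")
    assert np.array_equal(loaded.gt_masks, movie.gt_masks)
    assert np.abs(loaded.frames - movie.frames).max() <= 1.0 / 65535
    assert loaded.spec == movie.spec
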