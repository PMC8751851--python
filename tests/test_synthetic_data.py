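import numpy as np
import pytest
from scipy import stats

from mreyetrack.ngm import MotionState
from mreyetrack.synthetic_data import (
    AXIAL,
    SAGITTAL,
    IntensityModel,
    PopulationConfig,
    make_kinematic_fixture,
    render_slice,
    render_volume,
    sample_motion,
    sample_population,
    slice_geometry,
)
from mreyetrack.validation import voxelize_outer_border


class TestSamplePopulation:
    def test_seeded_reproducibility(self):
        a = sample_population(10, rng=123)
        b = sample_population(10, rng=123)
        for ea, eb in zip(a, b):
            assert np.allclose(ea.model.sclera.semi_axes, eb.model.sclera.semi_axes)
            assert np.allclose(ea.model.center, eb.model.center)

    def test_law_of_large_numbers_diameter(self):
        eyes = sample_population(1000, rng=7)
        mean_d = np.mean([e.model.diameter for e in eyes])
        assert abs(mean_d - 24.0) < 0.2

    def test_zero_variance_identical(self):
        cfg = PopulationConfig(
            center_sd_mm=0.0, diameter_sd=0.0, axis_ratio_sd=0.0,
            angle_sd_deg=0.0, structure_angle_jitter_deg=0.0,
            structure_semi_rel_sd=0.0,
        )
        eyes = sample_population(5, cfg, rng=1)
        ref = eyes[0].model
        for e in eyes[1:]:
            assert np.allclose(e.model.sclera.semi_axes, ref.sclera.semi_axes)
            assert np.allclose(e.model.lens.center, ref.lens.center)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            sample_population(2, PopulationConfig(diameter_sd=-1.0), rng=0)
        with pytest.raises(ValueError):
            sample_population(0, rng=0)

    def test_physiologic_bounds(self):
        eyes = sample_population(50, rng=5)
        for e in eyes:
            assert 20.0 <= e.model.diameter <= 28.0
            assert np.abs(e.model.cornea_rotation).max() <= 20.0
            assert np.abs(e.model.lens_rotation).max() <= 20.0


class TestRenderVolume:
    def test_noise_free_no_blur_two_levels(self, eye_model):
        inten = IntensityModel(inside_sd=0, outside_sd=0, lens_sd=0, blur_px=0)
        vol = render_volume(eye_model, rng=0, intensity=inten)
        d = vol.data
        pure = (np.isclose(d, 0.7) | np.isclose(d, 0.2)).mean()
        assert pure > 0.9  # the rest are partial-volume boundary voxels
        assert ((d >= 0.2 - 1e-9) & (d <= 0.7 + 1e-9)).all()

    def test_interior_exterior_means(self, eye_model, noisy_volume):
        mask = voxelize_outer_border(
            eye_model, noisy_volume.affine, noisy_volume.data.shape
        )
        lens = eye_model.lens
        # erode to avoid boundary / lens voxels
        interior = mask & ~lens.contains(_grid_points(noisy_volume)).reshape(
            mask.shape
        )
        assert abs(noisy_volume.data[interior].mean() - 0.7) < 0.05
        assert abs(noisy_volume.data[~mask].mean() - 0.2) < 0.05

    def test_seed_determinism(self, eye_model):
        a = render_volume(eye_model, rng=42)
        b = render_volume(eye_model, rng=42)
        assert np.array_equal(a.data, b.data)

    def test_noise_variances_close_to_recipe(self, eye_model):
        inten = IntensityModel(blur_px=0.0)
        vol = render_volume(eye_model, rng=3, intensity=inten)
        mask = voxelize_outer_border(eye_model, vol.affine, vol.data.shape)
        core = eye_model.sclera.implicit_norm(_grid_points(vol)).reshape(
            mask.shape
        ) < 0.8
        out = eye_model.sclera.implicit_norm(_grid_points(vol)).reshape(
            mask.shape
        ) > 1.2
        v_in = vol.data[core].var()
        v_out = vol.data[out].var()
        assert abs(v_in - 0.01) < 0.002
        assert abs(v_out - 0.04) < 0.008

    def test_eye_outside_fov_rejected(self, eye_model):
        from mreyetrack.synthetic_data import VolumeProtocol

        with pytest.raises(ValueError):
            render_volume(
                eye_model, VolumeProtocol(margin_mm=-2.0), rng=0
            )


def _grid_points(vol):
    idx = np.indices(vol.data.shape).reshape(3, -1).T.astype(float)
    return idx @ vol.affine[:3, :3].T + vol.affine[:3, 3]


class TestRenderSlice:
    def test_zero_pose_shows_all_structures(self, eye_model):
        sl = render_slice(eye_model, MotionState(), AXIAL, rng=0)
        d = sl.data
        # bright vitreous, dark surround and a dark lens patch well inside
        assert d.max() > 0.55
        # locate the lens center in pixel coordinates and check the patch
        p2 = sl.frame.to_2d(eye_model.lens.center)
        inv = np.linalg.inv(sl.affine2d)
        ij = (inv @ np.array([p2[0], p2[1], 1.0]))[:2].round().astype(int)
        patch = d[ij[0] - 2 : ij[0] + 3, ij[1] - 2 : ij[1] + 3]
        assert patch.min() < 0.45  # lens visible
        # and the vitreous around it is bright
        ring = d[ij[0] - 8 : ij[0] - 5, ij[1] - 1 : ij[1] + 2]
        assert ring.mean() > 0.5

    def test_inplane_shift_moves_image(self, eye_model, noisefree_intensity):
        geom = slice_geometry(eye_model, AXIAL)
        a = render_slice(eye_model, MotionState(), AXIAL, rng=0,
                         intensity=noisefree_intensity, geometry=geom).data
        t = np.array([2.0, 0.0, 0.0])
        b = render_slice(eye_model, MotionState(t), AXIAL, rng=0,
                         intensity=noisefree_intensity, geometry=geom).data
        from skimage.registration import phase_cross_correlation

        shift, _, _ = phase_cross_correlation(b, a, upsample_factor=20)
        moved_mm = shift * AXIAL.pixel_spacing
        assert abs(np.linalg.norm(moved_mm) - 2.0) < 0.3

    def test_seed_determinism(self, eye_model):
        a = render_slice(eye_model, MotionState(), SAGITTAL, rng=9)
        b = render_slice(eye_model, MotionState(), SAGITTAL, rng=9)
        assert np.array_equal(a.data, b.data)

    def test_plane_missing_eye_rejected(self, eye_model):
        with pytest.raises(ValueError):
            render_slice(eye_model, MotionState((0, 0, 30.0)), AXIAL, rng=0)


class TestSampleMotion:
    def test_bounds(self):
        motions = sample_motion(200, rng=0)
        t = np.array([m.translation for m in motions])
        r = np.array([[m.rot_x, m.rot_z, m.torsion] for m in motions])
        assert np.abs(t).max() <= 2.0
        assert np.abs(r).max() <= 20.0

    def test_seed_reproducibility(self):
        a = sample_motion(5, rng=3)
        b = sample_motion(5, rng=3)
        assert all(
            np.allclose(x.translation, y.translation) for x, y in zip(a, b)
        )

    def test_marginals_uniform(self):
        motions = sample_motion(10_000, rng=1)
        tx = np.array([m.translation[0] for m in motions])
        rz = np.array([m.rot_z for m in motions])
        ks_t = stats.kstest(tx, stats.uniform(loc=-2, scale=4).cdf).statistic
        ks_r = stats.kstest(rz, stats.uniform(loc=-20, scale=40).cdf).statistic
        assert ks_t < 0.02 and ks_r < 0.02


class TestKinematicFixture:
    def test_blink_truth_by_construction(self):
        _, truth, _, _ = make_kinematic_fixture(
            "blink", {"retraction_amp_mm": 1.5}, rng=0, render=False
        )
        assert truth.retraction.max() == pytest.approx(1.5, abs=0.02)

    def test_saccade_spans_twelve_degrees(self):
        _, truth, _, _ = make_kinematic_fixture("saccade", rng=0, render=False)
        rot = truth.horizontal_rotation
        assert rot[-1] - rot[0] == pytest.approx(12.0, abs=0.3)

    def test_seeded_frames_reproducible(self):
        f1, _, _, _ = make_kinematic_fixture(
            "blink", {"duration_ms": 200.0}, rng=5
        )
        f2, _, _, _ = make_kinematic_fixture(
            "blink", {"duration_ms": 200.0}, rng=5
        )
        assert np.array_equal(f1, f2)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_kinematic_fixture("wink", rng=0, render=False)


class TestPoseEquivariance:
    def test_translated_render_matches_shifted_render(self, eye_model,
                                                      noisefree_intensity):
        """Rendering a translated eyeball equals translating the render, to
        partial-volume tolerance."""
        geom = slice_geometry(eye_model, AXIAL)
        a = render_slice(eye_model, MotionState(), AXIAL, rng=0,
                         intensity=noisefree_intensity, geometry=geom).data
        s = AXIAL.pixel_spacing
        b = render_slice(eye_model, MotionState((2 * s, 0, 0)), AXIAL, rng=0,
                         intensity=noisefree_intensity, geometry=geom).data
        # world +x is the axial frame's second in-plane axis
        shifted = np.roll(a, 2, axis=1)
        diff = np.abs(b[4:-4, 4:-4] - shifted[4:-4, 4:-4])
        assert diff.mean() < 0.01
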