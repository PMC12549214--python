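"""Synthetic speckle, MESI sequences, bundle rendering, and flow phantoms."""
import numpy as np
import pytest

from fibermesi import (
    BundleGeometry,
    ChannelGeometry,
    ContrastCurve,
    ExposureLadder,
    SyntheticScene,
    fit_mesi,
    flow_to_mean_speed,
    mesi_variance,
    nearest_fiber_contrast,
    per_fiber_intensity,
    render_through_bundle,
    segment_fibers,
    synth_flow_phantom,
    synth_mesi_sequence,
    synth_speckle_frame,
)
from fibermesi.errors import InputError, ParameterError


# ----------------------------------------------------------------------
# synth_speckle_frame
# ----------------------------------------------------------------------

def test_zero_contrast_gives_constant_frame():
    frame = synth_speckle_frame((8, 8), 500.0, 0.0, seed=0)
    assert np.all(frame == 500.0)


def test_unit_contrast_is_exponential_limit():
    frame = synth_speckle_frame((512, 512), 1000.0, 1.0, seed=3)
    k = frame.std(ddof=1) / frame.mean()
    assert 0.99 <= k <= 1.01


def test_partial_contrast_statistics():
    frame = synth_speckle_frame((512, 512), 1000.0, 0.3, seed=5)
    assert frame.std(ddof=1) / frame.mean() == pytest.approx(0.3, rel=0.01)
    assert frame.mean() == pytest.approx(1000.0, rel=0.01)


def test_super_rayleigh_contrast_rejected():
    with pytest.raises(ParameterError):
        synth_speckle_frame((8, 8), 1000.0, 1.2, seed=0)
    with pytest.raises(ParameterError):
        synth_speckle_frame((8, 8), 0.0, 0.3, seed=0)


def test_frame_generation_is_deterministic():
    a = synth_speckle_frame((64, 64), 1000.0, 0.4, seed=11)
    b = synth_speckle_frame((64, 64), 1000.0, 0.4, seed=11)
    assert np.array_equal(a, b)


# ----------------------------------------------------------------------
# synth_mesi_sequence
# ----------------------------------------------------------------------

def _uniform_scene(tau_c, rho=0.95, beta=0.5, nu=0.01, shape=(128, 128)):
    return SyntheticScene(
        region_labels=np.zeros(shape, dtype=int),
        tau_c_by_region=[tau_c],
        rho_by_region=[rho],
        beta=beta,
        nu=nu,
    )


def test_mean_intensity_conserved_across_exposures():
    # 256x256 frames: at the largest per-pixel contrast (~0.7) the standard
    # error of the frame mean is ~0.3%, well inside the 1% conservation bound
    frames = synth_mesi_sequence(
        _uniform_scene(1e-3, shape=(256, 256)), ExposureLadder.default(), seed=2
    )
    assert len(frames) == 15
    for f in frames:
        assert f.mean() == pytest.approx(1000.0, rel=0.01)


def test_static_limit_contrast_squared_approaches_beta():
    # tau_c far above the longest exposure, fully dynamic light, no noise floor
    scene = _uniform_scene(1e4, rho=1.0, nu=0.0, shape=(192, 192))
    frames = synth_mesi_sequence(scene, ExposureLadder.default(), seed=4)
    for f in frames:
        k2 = (f.std(ddof=1) / f.mean()) ** 2
        assert k2 == pytest.approx(scene.beta, rel=0.05)


def test_noise_floor_limit():
    scene = _uniform_scene(1e-9, nu=0.01, shape=(192, 192))
    frames = synth_mesi_sequence(scene, ExposureLadder.default(), seed=6)
    for f in frames:
        k2 = (f.std(ddof=1) / f.mean()) ** 2
        assert k2 == pytest.approx(0.01, rel=0.1)


def test_regional_contrast_tracks_the_forward_model():
    labels = np.zeros((128, 128), dtype=int)
    labels[:, 64:] = 1
    scene = SyntheticScene(
        region_labels=labels,
        tau_c_by_region=[5e-2, 5e-4],
        rho_by_region=[0.95, 0.95],
    )
    ladder = ExposureLadder.default()
    frames = synth_mesi_sequence(scene, ladder, seed=8)
    for T, f in zip(ladder.times, frames):
        for region, tau in [(0, 5e-2), (1, 5e-4)]:
            vals = f[labels == region]
            k2 = (vals.std(ddof=1) / vals.mean()) ** 2
            want = mesi_variance(T, tau, scene.beta, 0.95, scene.nu)
            assert k2 == pytest.approx(want, rel=0.08, abs=2e-3)


def test_sequence_is_bit_deterministic():
    scene = _uniform_scene(1e-3)
    a = synth_mesi_sequence(scene, ExposureLadder.default(), seed=9)
    b = synth_mesi_sequence(scene, ExposureLadder.default(), seed=9)
    assert all(np.array_equal(x, y) for x, y in zip(a, b))


# ----------------------------------------------------------------------
# render_through_bundle
# ----------------------------------------------------------------------

def test_constant_scene_renders_constant_cores_and_dark_dead_space():
    geom = BundleGeometry(n_rings=3, pitch=12.0, core_radius=4.0, origin=(60.0, 60.0))
    rendered, fmap = render_through_bundle(np.full((30, 30), 7.0), geom, magnification=4.0)
    assert fmap.n_fibers == 37  # 1 + 3*3*4
    assert np.allclose(rendered[fmap.labels > 0], 7.0)
    assert np.all(rendered[fmap.labels == 0] == 0.0)


def test_footprint_mean_matches_local_scene_value():
    # a smooth linear ramp: the aperture-averaged value must equal the ramp
    # at the footprint center to within the half-pixel discretization
    geom = BundleGeometry(
        n_rings=3, pitch=12.0, core_radius=4.0, origin=(60.0, 60.0), rotation_deg=5.0
    )
    ramp = np.fromfunction(lambda r, c: 2.0 * r + 0.5 * c + 10.0, (30, 30))
    rendered, fmap = render_through_bundle(ramp, geom, magnification=4.0)
    vals = per_fiber_intensity(rendered, fmap)
    sample_centers = fmap.centers / 4.0  # back to the sample plane
    expected = 2.0 * sample_centers[:, 0] + 0.5 * sample_centers[:, 1] + 10.0
    np.testing.assert_allclose(vals, expected, rtol=0.02)


def test_bundle_exceeding_frame_raises():
    geom = BundleGeometry(n_rings=5, pitch=12.0, core_radius=4.0, origin=(60.0, 60.0))
    with pytest.raises(InputError):
        render_through_bundle(np.ones((30, 30)), geom, magnification=4.0)


def test_core_overlap_rejected_by_geometry():
    with pytest.raises(ParameterError):
        BundleGeometry(n_rings=2, pitch=8.0, core_radius=4.5, origin=(40.0, 40.0))


def test_geometry_yaml_round_trip(tmp_path):
    geom = BundleGeometry(
        n_rings=4, pitch=9.0, core_radius=3.5, origin=(50.0, 52.0), rotation_deg=7.0
    )
    geom.to_yaml(tmp_path / "g.yaml")
    assert BundleGeometry.from_yaml(tmp_path / "g.yaml") == geom


def test_scene_yaml_round_trip(tmp_path):
    scene = _uniform_scene(2e-3, shape=(16, 16))
    scene.to_yaml(tmp_path / "s.yaml")
    back = SyntheticScene.from_yaml(tmp_path / "s.yaml")
    np.testing.assert_allclose(back.tau_c_by_region, scene.tau_c_by_region)
    assert np.array_equal(back.region_labels, scene.region_labels)


# ----------------------------------------------------------------------
# end-to-end closure: render -> segment -> nearest-fiber contrast -> fit
# ----------------------------------------------------------------------

def test_bundle_pipeline_recovers_channel_ict_within_five_percent():
    tau_true = 5e-4  # ICT 2000 1/s
    scene = _uniform_scene(tau_true, shape=(94, 94))
    geom = BundleGeometry(
        n_rings=15, pitch=12.0, core_radius=4.0, origin=(188.0, 188.0),
        rotation_deg=10.0,
    )
    ladder = ExposureLadder.default()
    rng = np.random.default_rng(20240616)

    flat, _ = render_through_bundle(
        np.full(scene.shape, float(scene.mean_intensity)), geom, magnification=4.0
    )
    fmap = segment_fibers(flat, radius_range=(3.0, 5.0))
    assert fmap.n_fibers == geom.fiber_count

    # flat-field correction: segmented discs inevitably include a few dark
    # dead-space pixels, a fixed per-fiber intensity pattern that would
    # otherwise add an exposure-independent floor to the contrast
    flat_vals = per_fiber_intensity(flat, fmap)

    def frame_contrast(frame):
        rendered, _ = render_through_bundle(frame, geom, magnification=4.0)
        vals = per_fiber_intensity(rendered, fmap) / flat_vals
        return np.nanmean(nearest_fiber_contrast(vals, fmap, k=36).values())

    # instrumentation-factor calibration on a static reference through the
    # same optics: in the static, fully dynamic-free limit K^2 -> beta, so
    # the measured contrast gives the effective beta of the bundle path
    static_k = [
        frame_contrast(
            synth_speckle_frame(scene.shape, 1000.0, np.sqrt(scene.beta), rng)
        )
        for _ in range(30)
    ]
    beta_eff = np.mean(static_k) ** 2

    n_sequences = 50
    per_seq_k = [
        [frame_contrast(f) for f in synth_mesi_sequence(scene, ladder, rng)]
        for _ in range(n_sequences)
    ]
    k2 = np.mean(per_seq_k, axis=0) ** 2
    fit = fit_mesi(
        ContrastCurve(ladder, k2, n_sequences_averaged=n_sequences),
        fixed_beta=beta_eff,
    )
    assert fit.converged
    assert fit.ict == pytest.approx(1.0 / tau_true, rel=0.05)


# ----------------------------------------------------------------------
# flow phantom
# ----------------------------------------------------------------------

def test_channel_tau_is_inverse_linear_in_flow():
    geom = ChannelGeometry(shape=(32, 32), width_px=16)
    scenes = synth_flow_phantom([1.0, 2.0, 4.0], geom, calibration=200.0)
    taus = [s.tau_c_by_region[1] for s in scenes]
    assert taus[0] == pytest.approx(1.0 / 200.0)
    assert taus[1] == pytest.approx(taus[0] / 2)
    assert taus[2] == pytest.approx(taus[0] / 4)
    # background untouched
    assert all(s.tau_c_by_region[0] == scenes[0].tau_c_by_region[0] for s in scenes)


def test_nonpositive_flow_rates_rejected():
    geom = ChannelGeometry(shape=(16, 16), width_px=8)
    with pytest.raises(ParameterError):
        synth_flow_phantom([1.0, 0.0], geom)
    with pytest.raises(ParameterError):
        synth_flow_phantom([1.0], geom, calibration=-5.0)


def test_channel_labels_are_a_centered_band():
    lab = ChannelGeometry(shape=(16, 16), width_px=8, axis=1).labels()
    assert np.all(lab[4:12, :] == 1)
    assert np.all(lab[:4, :] == 0) and np.all(lab[12:, :] == 0)


def test_flow_speed_conversion():
    assert flow_to_mean_speed(0.0, 300.0) == 0.0
    assert flow_to_mean_speed(10.0, 300.0) == pytest.approx(1.852, abs=1e-3)
    assert flow_to_mean_speed(100.0, 300.0) == pytest.approx(18.52, abs=1e-2)
    with pytest.raises(ParameterError):
        flow_to_mean_speed(1.0, 0.0)
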