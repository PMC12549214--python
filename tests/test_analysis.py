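"""ROI curves, ICT time courses, occlusion rules, and comparison metrics."""
import numpy as np
import pytest

from fibermesi import (
    ContrastCurve,
    ExposureLadder,
    FiberContrastMap,
    OcclusionEvents,
    TimeCourse,
    cnr,
    detect_occlusion,
    ict_timecourse,
    mesi_variance,
    pearson_r2,
    roi_average_curve,
)
from fibermesi.errors import InputError


def _ladder(n=6):
    return ExposureLadder(np.geomspace(1e-4, 1e-2, n))


def _pixel_sequences(rng, n_seq=3, n_exp=6, shape=(8, 8)):
    """Random per-exposure pixel contrast maps with a NaN border."""
    seqs = []
    for _ in range(n_seq):
        maps = []
        for _ in range(n_exp):
            m = rng.uniform(0.1, 0.9, shape)
            m[0, :] = np.nan
            maps.append(m)
        seqs.append(maps)
    return seqs


# ----------------------------------------------------------------------
# roi_average_curve
# ----------------------------------------------------------------------

def test_identical_sequences_average_to_the_single_sequence(rng):
    one = _pixel_sequences(rng, n_seq=1)[0]
    roi = np.zeros((8, 8), dtype=bool)
    roi[2:5, 2:5] = True
    a = roi_average_curve([one], roi, _ladder())
    b = roi_average_curve([one] * 100, roi, _ladder())
    np.testing.assert_allclose(a.k2, b.k2)
    assert b.n_sequences_averaged == 100


def test_two_sequences_average_their_roi_means():
    lad = ExposureLadder([1e-3, 2e-3])
    roi = np.ones((4, 4), dtype=bool)
    seq_a = [np.full((4, 4), 0.2), np.full((4, 4), 0.1)]
    seq_b = [np.full((4, 4), 0.4), np.full((4, 4), 0.3)]
    curve = roi_average_curve([seq_a, seq_b], roi, lad)
    np.testing.assert_allclose(curve.k2, [0.3**2, 0.2**2])


def test_matches_brute_force_double_loop(rng):
    seqs = _pixel_sequences(rng)
    roi = np.zeros((8, 8), dtype=bool)
    roi[1:6, 3:7] = True
    curve = roi_average_curve(seqs, roi, _ladder())
    members = np.argwhere(roi)
    for e in range(6):
        frame_means = []
        for s in seqs:
            vals = [s[e][r, c] for r, c in members if np.isfinite(s[e][r, c])]
            frame_means.append(np.mean(vals))
        assert curve.k2[e] == pytest.approx(np.mean(frame_means) ** 2, rel=1e-12)


def test_permutation_invariant_over_sequences(rng):
    seqs = _pixel_sequences(rng, n_seq=4)
    roi = np.ones((8, 8), dtype=bool)
    a = roi_average_curve(seqs, roi, _ladder())
    b = roi_average_curve(seqs[::-1], roi, _ladder())
    np.testing.assert_allclose(a.k2, b.k2)


def test_fiber_map_sequences_exclude_invalid_fibers():
    lad = ExposureLadder([1e-3, 2e-3])
    valid = np.array([True, True, False])
    maps = [
        FiberContrastMap(np.array([0.2, 0.4, 9.0]), valid, 4),
        FiberContrastMap(np.array([0.1, 0.3, 9.0]), valid, 4),
    ]
    curve = roi_average_curve([maps], np.array([0, 1, 2]), lad)
    np.testing.assert_allclose(curve.k2, [0.3**2, 0.2**2])


def test_entirely_invalid_roi_is_an_error():
    lad = ExposureLadder([1e-3, 2e-3])
    m = np.full((4, 4), np.nan)
    with pytest.raises(InputError):
        roi_average_curve([[m, m]], np.ones((4, 4), dtype=bool), lad)


# ----------------------------------------------------------------------
# ict_timecourse
# ----------------------------------------------------------------------

def _constant_contrast_sequences(tau_c, n_seq, ladder, beta=0.5, rho=0.95, nu=0.01):
    """Noise-free uniform contrast maps following the forward model."""
    k = np.sqrt(mesi_variance(ladder.as_array(), tau_c, beta, rho, nu))
    seq = [np.full((4, 4), ki) for ki in k]
    return [seq] * n_seq


def test_stationary_scene_gives_flat_time_course():
    lad = ExposureLadder.default()
    seqs = _constant_contrast_sequences(1e-3, 5, lad)
    tc = ict_timecourse(seqs, np.ones((4, 4), dtype=bool), lad, beta_bar=0.5)
    np.testing.assert_allclose(tc.ict_values, 1000.0, rtol=1e-4)
    np.testing.assert_allclose(tc.timestamps, 0.3 * np.arange(5))


def test_step_change_in_tau_halves_the_ict():
    lad = ExposureLadder.default()
    seqs = (
        _constant_contrast_sequences(1e-3, 3, lad)
        + _constant_contrast_sequences(2e-3, 3, lad)
    )
    tc = ict_timecourse(seqs, np.ones((4, 4), dtype=bool), lad, beta_bar=0.5)
    np.testing.assert_allclose(tc.ict_values[:3], 1000.0, rtol=1e-4)
    np.testing.assert_allclose(tc.ict_values[3:], 500.0, rtol=1e-4)


def test_empty_sequence_list_is_an_error():
    with pytest.raises(InputError):
        ict_timecourse([], np.ones((4, 4), dtype=bool), _ladder(), beta_bar=0.5)


def test_failed_per_sequence_fit_yields_nan_not_zero():
    lad = ExposureLadder.default()
    flat_seq = [np.full((4, 4), 0.1)] * 15  # flat curve: non-identifiable
    good = _constant_contrast_sequences(1e-3, 1, lad)
    tc = ict_timecourse(good + [flat_seq], np.ones((4, 4), dtype=bool), lad, 0.5)
    assert np.isfinite(tc.ict_values[0])
    assert np.isnan(tc.ict_values[1])


# ----------------------------------------------------------------------
# detect_occlusion
# ----------------------------------------------------------------------

def _tc(values, dt=1.0):
    return TimeCourse(np.arange(len(values)) * dt, np.asarray(values, dtype=float))


def test_constant_high_flow_has_no_occlusion():
    ev = detect_occlusion(_tc([2000.0] * 100))
    assert ev.occlusion_start is None and ev.clearance_time is None


def test_step_drop_sets_occlusion_start():
    vals = [3000.0] * 30 + [800.0] * 30
    ev = detect_occlusion(_tc(vals))
    assert ev.occlusion_start == 30.0


def test_short_excursion_does_not_clear_but_sustained_one_does():
    # drop at t=10; 30 s above threshold (insufficient), dip, then a >= 60 s
    # recovery starting at t=100
    vals = (
        [2000.0] * 10 + [700.0] * 20 + [1800.0] * 30 + [900.0] * 40
        + [2500.0] * 80
    )
    ev = detect_occlusion(_tc(vals), threshold=1500.0, persistence=60.0)
    assert ev.occlusion_start == 10.0
    assert ev.clearance_time == 100.0


def test_recovery_without_enough_trailing_record_is_not_clearance():
    vals = [2000.0] * 5 + [700.0] * 5 + [2500.0] * 30  # only 30 s of recovery
    ev = detect_occlusion(_tc(vals), threshold=1500.0, persistence=60.0)
    assert ev.occlusion_start == 5.0
    assert ev.clearance_time is None


def test_uniform_time_shift_shifts_events():
    vals = [3000.0] * 20 + [800.0] * 20 + [2500.0] * 100
    a = detect_occlusion(_tc(vals))
    shifted = TimeCourse(np.arange(len(vals)) + 500.0, np.asarray(vals))
    b = detect_occlusion(shifted)
    assert b.occlusion_start == a.occlusion_start + 500.0
    assert b.clearance_time == a.clearance_time + 500.0


def test_clearance_must_follow_onset():
    with pytest.raises(InputError):
        OcclusionEvents(occlusion_start=50.0, clearance_time=40.0)


def test_timecourse_csv_round_trip(tmp_path):
    tc = _tc([2000.0, 1800.0, np.nan, 900.0], dt=0.3)
    p = tmp_path / "tc.csv"
    tc.to_csv(p)
    back = TimeCourse.from_csv(p)
    np.testing.assert_allclose(back.timestamps, tc.timestamps)
    np.testing.assert_allclose(back.ict_values, tc.ict_values)


# ----------------------------------------------------------------------
# pearson_r2
# ----------------------------------------------------------------------

def test_identity_and_affine_relations_give_unit_r2():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert pearson_r2(x, x) == pytest.approx(1.0)
    assert pearson_r2(x, -2 * x + 7) == pytest.approx(1.0)


def test_hand_computed_value():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([1.0, 2.0, 2.0, 4.0])
    # closed-form Pearson: cov / (sx * sy), squared
    r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
    )
    assert pearson_r2(x, y) == pytest.approx(r**2, rel=1e-12)


def test_affine_transform_invariance(rng):
    x = rng.normal(size=20)
    y = rng.normal(size=20)
    base = pearson_r2(x, y)
    assert pearson_r2(3 * x - 1, y) == pytest.approx(base, rel=1e-10)
    assert pearson_r2(x, -0.5 * y + 4) == pytest.approx(base, rel=1e-10)


def test_degenerate_inputs_are_errors():
    with pytest.raises(InputError):
        pearson_r2([1.0, 2.0], [1.0, 2.0])  # too short
    with pytest.raises(InputError):
        pearson_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])  # zero variance


# ----------------------------------------------------------------------
# cnr
# ----------------------------------------------------------------------

def test_cnr_arithmetic():
    # signal mean 0.2, background mean 0.5, background std 0.1 -> 3.0
    profile = np.array([0.2, 0.2, 0.2, 0.4, 0.5, 0.6])
    sig = [0, 1, 2]
    bg = [3, 4, 5]
    assert cnr(profile, sig, bg) == pytest.approx(3.0)


def test_identical_distributions_give_near_zero_cnr(rng):
    profile = rng.normal(0.5, 0.1, 2000)
    sig = np.arange(0, 1000)
    bg = np.arange(1000, 2000)
    assert cnr(profile, sig, bg) < 0.1


def test_overlapping_or_empty_index_sets_rejected():
    profile = np.arange(10, dtype=float)
    with pytest.raises(InputError):
        cnr(profile, [0, 1], [1, 2])
    with pytest.raises(InputError):
        cnr(profile, [], [1, 2])
    with pytest.raises(InputError):
        cnr(profile, [0, 1], [2, 2])  # zero background std (one unique value)
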