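"""Reproducible in-silico validation studies.

Each study generates synthetic data with the simulator, runs the full
analysis pipeline on it, and reports the recovered quantities against the
known ground truth.  They are the package's own closure experiments:

* parameter recovery of the MESI fit (noiseless sweep and noisy Monte Carlo),
* flow-phantom linearity of recovered ICT vs. flow rate,
* concordance between the free-space sliding-window path and the
  bundle-render + nearest-fiber path on a common scene,
* contrast-to-noise comparison of the two contrast operators across a
  simulated flow channel.

All randomness is funneled through one seed per study.  Problem sizes are
the package's defaults for a desk-scale run; see ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .analysis import cnr, pearson_r2, roi_average_curve
from .bundle import nearest_fiber_contrast, per_fiber_intensity
from .errors import InputError
from .simulate import (
    BundleGeometry,
    ChannelGeometry,
    SyntheticScene,
    render_through_bundle,
    synth_flow_phantom,
    synth_mesi_sequence,
)
from .speckle import (
    ContrastCurve,
    ExposureLadder,
    fit_mesi,
    mesi_variance,
    sliding_window_contrast,
    two_stage_beta_fit,
)

__all__ = [
    "noiseless_recovery_sweep",
    "noisy_ict_recovery",
    "phantom_linearity_study",
    "dual_path_concordance_study",
    "cnr_comparison_study",
]

# shared scene-wide ground truth for the studies
_BETA = 0.5
_RHO = 0.95
_NU = 0.01
_MEAN = 1000.0


def noiseless_recovery_sweep(
    tau_c_values=None,
    beta: float = _BETA,
    rho: float = _RHO,
    nu: float = _NU,
) -> dict:
    """Fit noiseless forward-model curves; report worst relative errors.

    With no noise the fit is an exact inversion, so recovered (beta, rho,
    tau_c, nu) should match the generating values to near machine precision
    across correlation times spanning 1e-5 to 1e-1 s.
    """
    if tau_c_values is None:
        tau_c_values = np.geomspace(1e-5, 1e-1, 9)
    ladder = ExposureLadder.default()
    T = ladder.as_array()
    worst = {"beta": 0.0, "rho": 0.0, "tau_c": 0.0, "nu": 0.0}
    for tc in tau_c_values:
        curve = ContrastCurve(ladder, mesi_variance(T, tc, beta, rho, nu))
        fit = fit_mesi(curve)
        worst["beta"] = max(worst["beta"], abs(fit.beta - beta) / beta)
        worst["rho"] = max(worst["rho"], abs(fit.rho - rho) / rho)
        worst["tau_c"] = max(worst["tau_c"], abs(fit.tau_c - tc) / tc)
        worst["nu"] = max(worst["nu"], abs(fit.nu - nu) / nu)
    worst["max"] = max(worst.values())
    return worst


def noisy_ict_recovery(
    seed: int,
    n_curves: int = 100,
    noise_sigma: float = 0.02,
    tau_c: float = 1e-3,
    beta: float = _BETA,
    rho: float = _RHO,
    nu: float = _NU,
) -> dict:
    """Monte-Carlo ICT recovery under multiplicative curve noise.

    Each synthetic curve is the forward model times (1 + N(0, sigma)) per
    exposure (sigma = 2% by default, the residual scatter left after
    100-sequence averaging); beta is fixed at truth, mirroring the second
    stage of the two-stage protocol.  Reports the median relative ICT error.
    """
    rng = np.random.default_rng(seed)
    ladder = ExposureLadder.default()
    T = ladder.as_array()
    k2_true = mesi_variance(T, tau_c, beta, rho, nu)
    errs = []
    for _ in range(n_curves):
        k2 = k2_true * (1.0 + rng.normal(0.0, noise_sigma, size=T.size))
        curve = ContrastCurve(ladder, np.clip(k2, 1e-12, None))
        fit = fit_mesi(curve, fixed_beta=beta)
        errs.append(abs(fit.ict - 1.0 / tau_c) * tau_c)
    errs = np.asarray(errs)
    return {
        "median_rel_err": float(np.median(errs)),
        "p90_rel_err": float(np.percentile(errs, 90)),
        "n_curves": n_curves,
    }


# ----------------------------------------------------------------------
# flow phantom
# ----------------------------------------------------------------------

def phantom_linearity_study(
    seed: int,
    flow_rates=None,
    shape: tuple[int, int] = (96, 96),
    channel_width: int = 48,
    n_sequences: int = 100,
    window: int = 7,
) -> dict:
    """Recover ICT vs flow rate through the free-space pipeline.

    Ten flow rates (1-10 uL/min by default), 100 MESI sequences per rate,
    7x7 sliding-window contrast, full-channel-width ROI, two-stage beta fit
    across the rates.  Reports the linear-regression R^2 of recovered ICT on
    flow rate and the fitted slope (ground-truth calibration: 200 s^-1 per
    uL/min).
    """
    if flow_rates is None:
        flow_rates = np.arange(1.0, 11.0)
    geom = ChannelGeometry(shape=shape, width_px=channel_width, axis=1)
    scenes = synth_flow_phantom(flow_rates, geom)
    ladder = ExposureLadder.default()
    rng = np.random.default_rng(seed)

    rows, cols = shape
    lo = (rows - channel_width) // 2
    half = (window - 1) // 2
    roi = np.zeros(shape, dtype=bool)
    # interior of the channel band, clear of the invalid contrast border
    roi[lo + half + 1 : lo + channel_width - half - 1, half + 1 : cols - half - 1] = True

    curves = []
    for scene in scenes:
        mean_k = np.zeros(ladder.count)
        seqs = []
        for _ in range(n_sequences):
            frames = synth_mesi_sequence(scene, ladder, rng)
            seqs.append([sliding_window_contrast(f, window) for f in frames])
        curves.append(roi_average_curve(seqs, roi, ladder))

    beta_bar, fits = two_stage_beta_fit(curves)
    icts = np.array([f.ict for f in fits])
    reg = stats.linregress(flow_rates, icts)
    return {
        "flow_rates": np.asarray(flow_rates, dtype=float),
        "icts": icts,
        "beta_bar": beta_bar,
        "r2": float(reg.rvalue**2),
        "slope": float(reg.slope),
    }


# ----------------------------------------------------------------------
# dual-path concordance
# ----------------------------------------------------------------------

def _stripe_scene(
    n_stripes: int = 10,
    stripe_px: int = 14,
    shape: tuple[int, int] = (176, 176),
    ict_range: tuple[float, float] = (500.0, 5000.0),
) -> tuple[SyntheticScene, np.ndarray, int]:
    """Scene of horizontal stripes whose ICT spans a 10x range."""
    rows, cols = shape
    start = (rows - n_stripes * stripe_px) // 2
    rr = np.arange(rows)
    labels = np.clip((rr - start) // stripe_px, 0, n_stripes - 1)
    labels = np.broadcast_to(labels[:, None], shape).copy()
    icts = np.geomspace(ict_range[0], ict_range[1], n_stripes)
    scene = SyntheticScene(
        region_labels=labels,
        tau_c_by_region=1.0 / icts,
        rho_by_region=np.full(n_stripes, _RHO),
        mean_intensity=_MEAN,
        beta=_BETA,
        nu=_NU,
    )
    return scene, icts, start


def dual_path_concordance_study(
    seed: int,
    n_sequences: int = 20,
    magnification: float = 4.0,
) -> dict:
    """ICT concordance between the sliding-window and nearest-fiber paths.

    A common 10-stripe scene (ICT 500-5000 1/s) is processed two ways:
    (a) full-resolution frames + 7x7 sliding-window contrast, and (b) the
    same scene imaged through a simulated fiber bundle at 4x magnification
    with per-fiber segmentation ground truth + nearest-36-fiber contrast.
    Each path gets its own two-stage beta fit: fiber-aperture averaging
    rescales the bundle path's speckle variance uniformly (a lower
    effective beta), which the free first-stage beta absorbs.  Reports
    the Pearson R^2 between the two ICT sets and each path's ICT vector.
    """
    scene, icts_true, start = _stripe_scene()
    n_stripes = icts_true.size
    stripe_px = 14
    shape = scene.shape
    ladder = ExposureLadder.default()
    rng = np.random.default_rng(seed)
    window = 7
    k_neighbors = 36

    geometry = BundleGeometry(
        n_rings=43,
        pitch=8.0,
        core_radius=3.5,
        origin=(shape[0] * magnification / 2, shape[1] * magnification / 2),
        rotation_deg=10.0,
    )

    # ROIs: pixel bands (free-space) and fiber bands (bundle), kept clear of
    # stripe boundaries so no window / fiber neighborhood mixes stripes
    half = (window - 1) // 2
    pixel_rois = []
    for i in range(n_stripes):
        mask = np.zeros(shape, dtype=bool)
        r0 = start + i * stripe_px
        mask[r0 + 5 : r0 + 9, half : shape[1] - half] = True
        pixel_rois.append(mask)

    fs_seqs: list[list[np.ndarray]] = []
    fb_seqs: list[list] = []
    fmap = None
    for _ in range(n_sequences):
        frames_fs = synth_mesi_sequence(scene, ladder, rng)
        frames_fb = synth_mesi_sequence(scene, ladder, rng)  # second camera
        fs_seqs.append([sliding_window_contrast(f, window) for f in frames_fs])
        maps = []
        for f in frames_fb:
            rendered, fmap = render_through_bundle(
                f, geometry, dead_space_level=0.0, magnification=magnification
            )
            intens = per_fiber_intensity(rendered, fmap)
            maps.append(nearest_fiber_contrast(intens, fmap, k=k_neighbors))
        fb_seqs.append(maps)

    # fiber ROIs from the ground-truth map: valid fibers whose sample-plane
    # center lies in the stripe interior (clear of ring-3 neighborhoods)
    sample_rows = fmap.centers[:, 0] / magnification
    last_valid = fb_seqs[0][0].valid
    fiber_rois = []
    for i in range(n_stripes):
        r0 = start + i * stripe_px
        ids = np.flatnonzero(
            last_valid & (sample_rows >= r0 + 6) & (sample_rows < r0 + 8)
        )
        if ids.size < 10:
            raise InputError(f"stripe {i} has too few interior fibers ({ids.size})")
        fiber_rois.append(ids)

    fs_curves = [
        roi_average_curve(fs_seqs, m, ladder, roi_id=f"stripe{i}")
        for i, m in enumerate(pixel_rois)
    ]
    fb_curves = [
        roi_average_curve(fb_seqs, ids, ladder, roi_id=f"stripe{i}")
        for i, ids in enumerate(fiber_rois)
    ]
    _, fs_fits = two_stage_beta_fit(fs_curves)
    _, fb_fits = two_stage_beta_fit(fb_curves)
    ict_fs = np.array([f.ict for f in fs_fits])
    ict_fb = np.array([f.ict for f in fb_fits])
    return {
        "ict_true": icts_true,
        "ict_free_space": ict_fs,
        "ict_fiber_bundle": ict_fb,
        "r2": pearson_r2(ict_fs, ict_fb),
    }


# ----------------------------------------------------------------------
# CNR comparison of the two contrast operators
# ----------------------------------------------------------------------

def cnr_comparison_study(
    seed: int,
    exposure_s: float = 7.5e-3,
    n_frames: int = 5,
) -> dict:
    """Cross-channel contrast profiles: sliding window vs nearest fiber.

    A flow channel (ICT 2000 1/s) in a static background is imaged through
    a simulated bundle two ways: at 1x magnification with 7x7 sliding-window
    contrast (individual cores unresolved, windows mix cores and dead
    space), and at 4x with per-fiber nearest-36 contrast.  The
    contrast-to-noise ratio of the channel against the background is
    computed on each cross-channel profile.
    """
    shape = (128, 128)
    geom = ChannelGeometry(shape=shape, width_px=40, axis=0)
    labels = geom.labels()
    scene = SyntheticScene(
        region_labels=labels,
        tau_c_by_region=[0.05, 5e-4],
        rho_by_region=[_RHO, _RHO],
        mean_intensity=_MEAN,
        beta=_BETA,
        nu=_NU,
    )
    rng = np.random.default_rng(seed)
    ladder1 = ExposureLadder([exposure_s])

    bundle_1x = BundleGeometry(
        n_rings=15, pitch=4.0, core_radius=1.5, origin=(64.0, 64.0)
    )
    bundle_4x = BundleGeometry(
        n_rings=15, pitch=16.0, core_radius=6.0, origin=(256.0, 256.0)
    )

    # path A: sliding window on the 1x bundle face
    cmaps = []
    # path B: nearest-fiber on the 4x bundle face
    fiber_k = []
    fmap4 = None
    for _ in range(n_frames):
        frame = synth_mesi_sequence(scene, ladder1, rng)[0]
        rendered1, _ = render_through_bundle(frame, bundle_1x, magnification=1.0)
        cmaps.append(sliding_window_contrast(rendered1, 7))

        frame4 = synth_mesi_sequence(scene, ladder1, rng)[0]
        rendered4, fmap4 = render_through_bundle(frame4, bundle_4x, magnification=4.0)
        intens = per_fiber_intensity(rendered4, fmap4)
        fiber_k.append(nearest_fiber_contrast(intens, fmap4, k=36))

    # cross-channel profile A: column profile averaged over central rows,
    # restricted to columns the bundle face actually covers
    c0, c1 = 8, 120
    band = np.stack(cmaps)[:, 54:75, c0:c1]
    profile_a = np.nanmean(band.reshape(-1, band.shape[-1]), axis=0)
    channel = (44, 84)  # column extent of the channel
    sig_a = np.arange(channel[0] + 6, channel[1] - 6) - c0
    bg_a = np.concatenate([np.arange(16, 40), np.arange(88, 112)]) - c0
    cnr_window = cnr(profile_a, sig_a, bg_a)

    # cross-channel profile B: fibers in a central horizontal band, by column
    valid = np.all([fk.valid for fk in fiber_k], axis=0)
    mean_fiber_contrast = np.mean([fk.contrast for fk in fiber_k], axis=0)
    sample_rows = fmap4.centers[:, 0] / 4.0
    sample_cols = fmap4.centers[:, 1] / 4.0
    band = valid & (np.abs(sample_rows - 64.0) <= 4.0)
    ids = np.flatnonzero(band)
    order = np.argsort(sample_cols[ids])
    ids = ids[order]
    profile_b = mean_fiber_contrast[ids]
    cols_b = sample_cols[ids]
    sig_b = np.flatnonzero((cols_b > channel[0] + 6) & (cols_b < channel[1] - 6))
    bg_b = np.flatnonzero(
        ((cols_b > 16) & (cols_b < 40)) | ((cols_b > 88) & (cols_b < 112))
    )
    cnr_fiber = cnr(profile_b, sig_b, bg_b)

    return {"cnr_sliding_window": cnr_window, "cnr_nearest_fiber": cnr_fiber}
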