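"""Synthetic dynamic-speckle and fiber-bundle data generation.

The generator produces the data the analysis pipeline consumes, with known
ground truth: speckle frames whose spatial contrast follows the MESI model
at each exposure, hexagonally packed bundle renders with inter-core dead
space, and microfluidic flow-phantom scenes whose channel inverse
correlation time is proportional to flow rate.

Speckle statistics model: pixel intensities are drawn i.i.d. from a Gamma
distribution whose first two moments match the prescribed mean and contrast
(shape 1/K^2, scale mean*K^2).  Fully developed speckle (K = 1) is the
exponential-intensity special case.  Spatial correlation of real speckle
grains (1-2 pixels) is not modeled; contrast and the MESI fit depend only
on the first two moments at ROI scale.  Frame mean intensity is held
constant across exposures, emulating source-power modulation that equalizes
pixel intensities across the exposure ladder.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .bundle import FiberMap, hex_lattice_centers
from .errors import InputError, ParameterError
from .speckle import ExposureLadder, mesi_variance

__all__ = [
    "SyntheticScene",
    "BundleGeometry",
    "ChannelGeometry",
    "synth_speckle_frame",
    "synth_mesi_sequence",
    "render_through_bundle",
    "synth_flow_phantom",
    "flow_to_mean_speed",
]

RngLike = Union[int, np.random.Generator, None]


def _as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SyntheticScene:
    """Ground-truth field for simulation and recovery tests.

    ``region_labels`` is a 2D integer map; ``tau_c_by_region`` and
    ``rho_by_region`` give the correlation time (s) and dynamic-scattering
    fraction per region label.  ``beta`` (instrumentation factor) and ``nu``
    (K^2 noise floor) are scene-wide, as they are instrument properties.
    """

    region_labels: np.ndarray
    tau_c_by_region: np.ndarray
    rho_by_region: np.ndarray
    mean_intensity: float = 1000.0
    beta: float = 0.5
    nu: float = 0.01
    read_noise_std: float = 0.0  # optional additive Gaussian read noise (DN)

    def __post_init__(self) -> None:
        self.region_labels = np.asarray(self.region_labels, dtype=int)
        self.tau_c_by_region = np.atleast_1d(np.asarray(self.tau_c_by_region, dtype=float))
        self.rho_by_region = np.atleast_1d(np.asarray(self.rho_by_region, dtype=float))
        n_regions = int(self.region_labels.max()) + 1
        if self.tau_c_by_region.size < n_regions or self.rho_by_region.size < n_regions:
            raise InputError("tau_c/rho must be defined for every region label")
        if np.any(self.tau_c_by_region <= 0):
            raise ParameterError("tau_c must be > 0 in every region")
        if np.any((self.rho_by_region <= 0) | (self.rho_by_region > 1)):
            raise ParameterError("rho must be in (0, 1] in every region")
        if self.mean_intensity <= 0:
            raise ParameterError("mean_intensity must be > 0")
        if self.beta <= 0:
            raise ParameterError("beta must be > 0")
        if self.nu < 0:
            raise ParameterError("nu must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.region_labels.shape

    @property
    def tau_c_field(self) -> np.ndarray:
        """Per-pixel correlation-time map."""
        return self.tau_c_by_region[self.region_labels]

    @property
    def rho_field(self) -> np.ndarray:
        return self.rho_by_region[self.region_labels]

    # -- serialization -------------------------------------------------
    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "region_labels": self.region_labels.tolist(),
                    "tau_c_by_region": self.tau_c_by_region.tolist(),
                    "rho_by_region": self.rho_by_region.tolist(),
                    "mean_intensity": float(self.mean_intensity),
                    "beta": float(self.beta),
                    "nu": float(self.nu),
                    "read_noise_std": float(self.read_noise_std),
                }
            )
        )

    @classmethod
    def from_yaml(cls, path) -> "SyntheticScene":
        d = yaml.safe_load(Path(path).read_text())
        return cls(
            region_labels=np.asarray(d["region_labels"]),
            tau_c_by_region=np.asarray(d["tau_c_by_region"]),
            rho_by_region=np.asarray(d["rho_by_region"]),
            mean_intensity=d["mean_intensity"],
            beta=d["beta"],
            nu=d["nu"],
            read_noise_std=d.get("read_noise_std", 0.0),
        )


@dataclass(frozen=True)
class BundleGeometry:
    """Idealized hexagonally packed fiber bundle in camera pixels."""

    n_rings: int
    pitch: float
    core_radius: float
    origin: tuple[float, float]
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rings < 0:
            raise ParameterError("n_rings must be >= 0")
        if self.pitch <= 0 or self.core_radius <= 0:
            raise ParameterError("pitch and core_radius must be > 0")
        if self.core_radius >= self.pitch / 2:
            raise ParameterError("cores must not overlap (core_radius < pitch/2)")

    @property
    def fiber_count(self) -> int:
        return 1 + 3 * self.n_rings * (self.n_rings + 1)

    def centers(self) -> np.ndarray:
        return hex_lattice_centers(
            self.n_rings, self.pitch, self.origin, self.rotation_deg
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "n_rings": self.n_rings,
                    "pitch": self.pitch,
                    "core_radius": self.core_radius,
                    "origin": list(self.origin),
                    "rotation_deg": self.rotation_deg,
                }
            )
        )

    @classmethod
    def from_yaml(cls, path) -> "BundleGeometry":
        d = yaml.safe_load(Path(path).read_text())
        return cls(
            n_rings=int(d["n_rings"]),
            pitch=float(d["pitch"]),
            core_radius=float(d["core_radius"]),
            origin=tuple(d["origin"]),
            rotation_deg=float(d.get("rotation_deg", 0.0)),
        )


# ----------------------------------------------------------------------
# speckle frame synthesis
# ----------------------------------------------------------------------

def synth_speckle_frame(
    shape: tuple[int, int],
    mean_intensity: float,
    target_contrast: float,
    seed: RngLike = None,
) -> np.ndarray:
    """Single frame of i.i.d. Gamma-distributed speckle intensities.

    Gamma(shape = 1/K^2, scale = mean * K^2) matches the requested mean and
    contrast K.  K = 0 returns a constant frame.  K > 1 (super-Rayleigh
    statistics) is outside this generator's model and raises.
    """
    if mean_intensity <= 0:
        raise ParameterError("mean_intensity must be > 0")
    if not (0 <= target_contrast <= 1):
        raise ParameterError("target_contrast must be in [0, 1]")
    if target_contrast == 0:
        return np.full(shape, float(mean_intensity))
    rng = _as_rng(seed)
    k2 = target_contrast**2
    return rng.gamma(shape=1.0 / k2, scale=mean_intensity * k2, size=shape)


def synth_mesi_sequence(
    scene: SyntheticScene,
    ladder: ExposureLadder,
    seed: RngLike = None,
) -> list[np.ndarray]:
    """One MESI sequence: one frame per exposure, shortest first.

    Per region the target K^2 at exposure T comes from the MESI forward
    model with the region's (tau_c, rho) and the scene-wide (beta, nu);
    frame pixels are Gamma draws at that contrast and the scene mean
    intensity (constant across exposures).  Optional additive Gaussian read
    noise is applied last, clipped at zero.
    """
    rng = _as_rng(seed)
    labels = scene.region_labels
    frames = []
    for T in ladder.times:
        k2_regions = np.array(
            [
                mesi_variance(T, tc, scene.beta, r, scene.nu)
                for tc, r in zip(scene.tau_c_by_region, scene.rho_by_region)
            ]
        )
        if np.any(k2_regions > 1.0):
            raise ParameterError(
                "scene parameters imply contrast > 1, outside the Gamma model"
            )
        k2_field = k2_regions[labels]
        frame = np.empty(labels.shape, dtype=float)
        pos = k2_field > 0
        # one vectorized draw with per-pixel shape/scale
        frame[pos] = rng.gamma(
            shape=1.0 / k2_field[pos],
            scale=scene.mean_intensity * k2_field[pos],
        )
        frame[~pos] = scene.mean_intensity
        if scene.read_noise_std > 0:
            frame = np.clip(
                frame + rng.normal(0.0, scene.read_noise_std, size=frame.shape),
                0.0,
                None,
            )
        frames.append(frame)
    return frames


# ----------------------------------------------------------------------
# bundle rendering
# ----------------------------------------------------------------------

def _footprint_weight_matrix(
    centers: np.ndarray,
    radius: float,
    shape: tuple[int, int],
    supersample: int = 4,
):
    """Sparse (n_fibers x n_pixels) row-normalized aperture weight matrix.

    Weight of pixel p for fiber f is the fraction of p's area covered by
    f's circular footprint, estimated on a supersampled subgrid.  Each row
    sums to 1, so a fiber's transmitted value is the area-weighted mean of
    the underlying image over its aperture.
    """
    from scipy import sparse

    rows, cols = shape
    half = int(np.ceil(radius)) + 1
    sub = (np.arange(supersample) + 0.5) / supersample - 0.5
    data, col_idx, row_ptr = [], [], [0]
    for cy, cx in centers:
        y0 = max(int(np.floor(cy)) - half, 0)
        y1 = min(int(np.ceil(cy)) + half, rows - 1)
        x0 = max(int(np.floor(cx)) - half, 0)
        x1 = min(int(np.ceil(cx)) + half, cols - 1)
        yy = np.arange(y0, y1 + 1)
        xx = np.arange(x0, x1 + 1)
        # coverage per pixel in the bounding box
        sy = yy[:, None, None, None] + sub[None, None, :, None] - cy
        sx = xx[None, :, None, None] + sub[None, None, None, :] - cx
        cov = np.mean(sy**2 + sx**2 <= radius * radius, axis=(2, 3))
        nz = np.nonzero(cov)
        if nz[0].size == 0:
            raise InputError("a fiber footprint covers no underlying pixels")
        w = cov[nz]
        data.append(w / w.sum())
        col_idx.append((yy[nz[0]] * cols + xx[nz[1]]))
        row_ptr.append(row_ptr[-1] + w.size)
    return sparse.csr_matrix(
        (np.concatenate(data), np.concatenate(col_idx), np.asarray(row_ptr)),
        shape=(len(centers), rows * cols),
    )


@functools.lru_cache(maxsize=8)
def _bundle_model(
    geometry: BundleGeometry,
    out_shape: tuple[int, int],
    in_shape: tuple[int, int],
    magnification: float,
):
    """Cached (output label image, sample-plane aperture weights, centers)."""
    centers = geometry.centers()
    r = geometry.core_radius
    rows, cols = out_shape
    if np.any(centers[:, 0] - r < -0.5) or np.any(centers[:, 0] + r > rows - 0.5) \
       or np.any(centers[:, 1] - r < -0.5) or np.any(centers[:, 1] + r > cols - 0.5):
        raise InputError("bundle cores exceed the output frame")

    from .bundle import _assign_pixels

    out_labels = _assign_pixels(out_shape, centers, np.full(len(centers), r))

    sample_centers = centers / magnification
    sample_r = r / magnification
    in_rows, in_cols = in_shape
    if np.any(sample_centers[:, 0] > in_rows - 0.5) or np.any(sample_centers[:, 1] > in_cols - 0.5):
        raise InputError("bundle footprint exceeds the underlying image")
    weights = _footprint_weight_matrix(sample_centers, sample_r, in_shape)
    return out_labels, weights, centers


def bundle_footprint_means(
    underlying: np.ndarray,
    geometry: BundleGeometry,
    magnification: float = 4.0,
) -> np.ndarray:
    """Per-fiber area-weighted mean of the underlying image over each core's
    footprint at the sample plane (what each fiber physically transmits)."""
    img = np.asarray(underlying, dtype=float)
    out_shape = (
        int(round(img.shape[0] * magnification)),
        int(round(img.shape[1] * magnification)),
    )
    _, weights, _ = _bundle_model(geometry, out_shape, img.shape, magnification)
    return weights @ img.ravel()


def render_through_bundle(
    underlying: np.ndarray,
    geometry: BundleGeometry,
    dead_space_level: float = 0.0,
    magnification: float = 4.0,
) -> tuple[np.ndarray, FiberMap]:
    """Image the sample plane through a fiber bundle onto the camera.

    Each core's output pixels carry the mean of the underlying image over
    the core's footprint at the sample plane (fibers scramble spatial
    structure but conserve collected intensity); inter-core dead space is
    set to ``dead_space_level``.  Returns the rendered image and the exact
    ground-truth :class:`FiberMap`, for segmentation validation.
    """
    img = np.asarray(underlying, dtype=float)
    if img.ndim != 2:
        raise InputError("underlying image must be 2D")
    out_shape = (
        int(round(img.shape[0] * magnification)),
        int(round(img.shape[1] * magnification)),
    )
    out_labels, weights, centers = _bundle_model(
        geometry, out_shape, img.shape, magnification
    )
    means = weights @ img.ravel()
    lut = np.concatenate([[dead_space_level], means])
    rendered = lut[out_labels]
    fmap = FiberMap(
        centers=centers,
        radii=np.full(len(centers), geometry.core_radius),
        labels=out_labels,
        image_shape=out_shape,
    )
    return rendered, fmap


# ----------------------------------------------------------------------
# flow phantom
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelGeometry:
    """A straight microfluidic channel band through a 2D scene.

    The channel runs along ``axis`` (0 = along rows/vertical, 1 = along
    columns/horizontal) with the given width in pixels, centered.
    """

    shape: tuple[int, int]
    width_px: int
    axis: int = 1

    def labels(self) -> np.ndarray:
        if self.axis not in (0, 1):
            raise ParameterError("axis must be 0 or 1")
        rows, cols = self.shape
        lab = np.zeros(self.shape, dtype=int)
        extent = rows if self.axis == 1 else cols
        lo = (extent - self.width_px) // 2
        hi = lo + self.width_px
        if self.axis == 1:
            lab[lo:hi, :] = 1
        else:
            lab[:, lo:hi] = 1
        return lab


# Default link between flow rate and channel ICT: Q = 10 uL/min -> 2000 1/s.
DEFAULT_ICT_PER_FLOW = 200.0  # s^-1 per (uL/min)


def synth_flow_phantom(
    flow_rates: Sequence[float],
    channel_geometry: ChannelGeometry,
    calibration: float = DEFAULT_ICT_PER_FLOW,
    base_scene: Optional[SyntheticScene] = None,
) -> list[SyntheticScene]:
    """Scenes of a microfluidic phantom at a list of flow rates (uL/min).

    The channel region's ICT is linear in flow rate: tau_c = 1/(calibration
    * Q).  Background (label 0) keeps the base scene's slow/static
    parameters.  ``base_scene`` defaults to a tissue-like background with
    tau_c = 0.05 s and rho = 0.95.
    """
    rates = np.asarray(flow_rates, dtype=float)
    if rates.size == 0 or np.any(rates <= 0):
        raise ParameterError("flow rates must be positive")
    if calibration <= 0:
        raise ParameterError("calibration must be > 0")
    labels = channel_geometry.labels()
    if base_scene is None:
        base_scene = SyntheticScene(
            region_labels=labels,
            tau_c_by_region=[0.05, 1.0],
            rho_by_region=[0.95, 0.95],
        )
    scenes = []
    for q in rates:
        tau = base_scene.tau_c_by_region.copy()
        tau[1] = 1.0 / (calibration * q)
        scenes.append(
            replace(
                base_scene,
                region_labels=labels,
                tau_c_by_region=tau,
                rho_by_region=base_scene.rho_by_region.copy(),
            )
        )
    return scenes


def flow_to_mean_speed(q_ul_per_min: float, channel_side_um: float) -> float:
    """Mean flow speed (mm/s) in a square channel from volumetric rate.

    speed = Q / area: Q in uL/min is mm^3/min; a side of ``channel_side_um``
    gives an area of (side/1000)^2 mm^2; dividing by 60 converts to mm/s.
    """
    if channel_side_um <= 0:
        raise ParameterError("channel side must be > 0")
    if q_ul_per_min < 0:
        raise ParameterError("flow rate must be >= 0")
    area_mm2 = (channel_side_um / 1000.0) ** 2
    return q_ul_per_min / area_mm2 / 60.0
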