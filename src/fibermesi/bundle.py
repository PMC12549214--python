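"""Fiber-bundle segmentation, geometry, and the nearest-fiber contrast operator.

An imaging fiber bundle transmits an image through thousands of individual
cores separated by non-transmitting cladding ("dead space").  Sliding-window
speckle contrast computed on the proximal bundle face mixes core and dead
space pixels and skews contrast values.  Instead, each fiber core is
segmented from a flat-field image, its mean intensity per frame is treated
as a single speckle sample, and contrast is computed as std/mean over a
fiber and its nearest neighbors (36 by default -- the three hexagonal rings
around a core, which keeps the sample size between a 5x5 and a 7x7 window).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import tifffile
from scipy.spatial import cKDTree
from skimage.feature import canny
from skimage.filters import threshold_otsu
from skimage.transform import hough_circle, hough_circle_peaks

from .errors import InputError, ParameterError, SegmentationError

__all__ = [
    "FiberMap",
    "FiberContrastMap",
    "segment_fibers",
    "per_fiber_intensity",
    "hex_ring_count",
    "hex_lattice_centers",
    "nearest_fibers",
    "nearest_fiber_contrast",
]


def hex_ring_count(n_rings: int) -> int:
    """Cumulative number of fibers in the first ``n_rings`` hexagonal rings
    around a central fiber (the center itself excluded).

    Ring r contributes 6r fibers, so the total is 3 * n * (n + 1):
    6, 18, 36, 60 for 1-4 rings.
    """
    if not isinstance(n_rings, (int, np.integer)):
        raise ParameterError("n_rings must be an integer")
    if n_rings < 0:
        raise ParameterError("n_rings must be >= 0")
    return 3 * int(n_rings) * (int(n_rings) + 1)


def hex_lattice_centers(
    n_rings: int,
    pitch: float = 1.0,
    origin: tuple[float, float] = (0.0, 0.0),
    rotation_deg: float = 0.0,
) -> np.ndarray:
    """(row, col) centers of a hexagonally packed lattice out to ``n_rings``.

    Axial coordinates (q, r) with hex distance max(|q|, |r|, |q+r|) <= n_rings
    are mapped to Cartesian positions with center spacing ``pitch``, rotated
    by ``rotation_deg`` about the origin (bundles are generally not aligned
    with the camera's pixel grid).  The center fiber comes first; remaining
    fibers are sorted by (ring, row, col) for determinism.
    """
    if n_rings < 0:
        raise ParameterError("n_rings must be >= 0")
    pts = []
    for q in range(-n_rings, n_rings + 1):
        for r in range(-n_rings, n_rings + 1):
            ring = max(abs(q), abs(r), abs(q + r))
            if ring > n_rings:
                continue
            row = pitch * (np.sqrt(3.0) / 2.0) * r
            col = pitch * (q + r / 2.0)
            pts.append((ring, row, col))
    pts.sort()
    rel = np.array([(row, col) for _, row, col in pts], dtype=float)
    if rotation_deg:
        th = np.deg2rad(rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rel = rel @ rot.T
    return rel + np.asarray(origin, dtype=float)


@dataclass
class FiberMap:
    """Segmented fiber geometry: centers, radii, and pixel memberships.

    ``labels`` is an integer image the same shape as the source: 0 marks
    dead space, value i+1 marks pixels belonging to fiber i.  A KD-tree over
    the centers answers nearest-fiber queries.
    """

    centers: np.ndarray  # (n, 2) subpixel (row, col)
    radii: np.ndarray  # (n,)
    labels: np.ndarray  # 2D int, 0 = dead space
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        self.labels = np.asarray(self.labels)
        self.image_shape = tuple(self.image_shape)
        n = len(self.centers)
        if self.radii.size == 1 and n > 1:
            self.radii = np.full(n, float(self.radii[0]))
        if self.radii.size != n:
            raise InputError("radii length does not match number of centers")
        if self.labels.shape != self.image_shape:
            raise InputError("label image shape does not match image_shape")
        rows, cols = self.image_shape
        if np.any(self.centers[:, 0] < 0) or np.any(self.centers[:, 0] > rows - 1) or \
           np.any(self.centers[:, 1] < 0) or np.any(self.centers[:, 1] > cols - 1):
            raise InputError("fiber centers must lie inside the image bounds")
        if n > 1:
            tree = cKDTree(self.centers)
            d, _ = tree.query(self.centers, k=2)
            if np.any(d[:, 1] < 1.0):
                raise InputError("two fiber centers are closer than 1 pixel")
        counts = np.bincount(self.labels.ravel(), minlength=n + 1)
        if np.any(counts[1 : n + 1] == 0):
            raise InputError("every fiber must own at least one pixel")
        self._tree = cKDTree(self.centers)
        self._pixel_counts = counts[1 : n + 1]
        self._neighbor_cache: dict[int, np.ndarray] = {}

    @property
    def n_fibers(self) -> int:
        return len(self.centers)

    def pixel_membership(self, fiber_id: int) -> np.ndarray:
        """(m, 2) integer pixel coordinates belonging to one fiber."""
        return np.argwhere(self.labels == fiber_id + 1)

    def nearest(self, fiber_id: int, k: int) -> np.ndarray:
        return nearest_fibers(self, fiber_id, k)

    # -- serialization -------------------------------------------------
    def to_files(self, json_path, labels_tiff_path) -> None:
        """JSON (centers, radii, shape) + 16-bit label TIFF (0 = dead space)."""
        Path(json_path).write_text(
            json.dumps(
                {
                    "centers": self.centers.tolist(),
                    "radii": self.radii.tolist(),
                    "image_shape": list(self.image_shape),
                },
                indent=2,
            )
        )
        if self.n_fibers > np.iinfo(np.uint16).max - 1:
            raise InputError("too many fibers for a 16-bit label image")
        tifffile.imwrite(labels_tiff_path, self.labels.astype(np.uint16))

    @classmethod
    def from_files(cls, json_path, labels_tiff_path) -> "FiberMap":
        d = json.loads(Path(json_path).read_text())
        labels = tifffile.imread(labels_tiff_path)
        return cls(
            centers=np.asarray(d["centers"]),
            radii=np.asarray(d["radii"]),
            labels=labels,
            image_shape=tuple(d["image_shape"]),
        )


@dataclass
class FiberContrastMap:
    """Per-fiber speckle contrast with validity flags."""

    contrast: np.ndarray
    valid: np.ndarray
    k_neighbors: int

    def __post_init__(self) -> None:
        self.contrast = np.asarray(self.contrast, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.contrast.shape != self.valid.shape:
            raise InputError("contrast and valid must have the same length")
        if np.any(self.contrast[self.valid] < 0):
            raise InputError("valid contrast values must be >= 0")

    def values(self) -> np.ndarray:
        """Contrast with NaN at invalid fibers."""
        out = np.where(self.valid, self.contrast, np.nan)
        return out


def _assign_pixels(
    shape: tuple[int, int], centers: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    """Label image: each pixel within a fiber's radius goes to the nearest center."""
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    coords = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    tree = cKDTree(centers)
    dist, idx = tree.query(coords, k=1)
    labels = np.where(dist <= radii[idx], idx + 1, 0)
    return labels.reshape(shape).astype(np.int32)


def segment_fibers(
    flatfield: np.ndarray,
    radius_range: tuple[float, float],
    sensitivity: float = 0.5,
    canny_sigma: float = 1.0,
) -> FiberMap:
    """Segment fiber cores from an evenly illuminated flat-field image.

    Circular cores are detected with a Hough circular-feature accumulator on
    a Canny edge map.  ``radius_range`` is the (min, max) core radius in
    pixels; ``sensitivity`` in (0, 1] scales the accumulator acceptance
    threshold (lower values detect fainter circles).  Every pixel within a
    detected radius of a center is assigned to that fiber; conflicting
    claims go to the nearest center.
    """
    img = np.asarray(flatfield, dtype=float)
    if img.ndim != 2:
        raise InputError("flat-field image must be 2D")
    rmin, rmax = radius_range
    if rmin <= 0 or rmax <= rmin:
        raise ParameterError("radius_range must satisfy 0 < min < max")
    if not (0 < sensitivity <= 1):
        raise ParameterError("sensitivity must be in (0, 1]")

    raw = np.asarray(flatfield)
    if np.issubdtype(raw.dtype, np.integer):
        sat = np.mean(raw == np.iinfo(raw.dtype).max)
        if sat >= 0.01:
            warnings.warn(
                f"flat-field appears saturated ({sat:.1%} of pixels at max DN)",
                RuntimeWarning,
                stacklevel=2,
            )

    peak = img.max()
    if peak <= 0:
        raise SegmentationError("flat-field is blank; zero fibers detected")
    edges = canny(img / peak, sigma=canny_sigma)

    radii = np.arange(int(np.floor(rmin)), int(np.ceil(rmax)) + 1)
    accum = hough_circle(edges, radii)
    # cores are bright in a flat-field: zero the accumulator over dark
    # (dead-space) pixels so interstitial ghost peaks can neither be
    # detected nor suppress a true core peak during non-max suppression
    if np.ptp(img) > 0:
        accum = accum * (img >= threshold_otsu(img))[None, :, :]
    min_d = max(int(np.floor(2 * rmin)) - 1, 1)
    vals, ccol, crow, crad = hough_circle_peaks(
        accum,
        radii,
        min_xdistance=min_d,
        min_ydistance=min_d,
        threshold=sensitivity * accum.max(),
        total_num_peaks=np.inf,
    )
    if len(crow) == 0:
        raise SegmentationError("zero fibers detected in flat-field image")

    centers = np.column_stack([crow, ccol]).astype(float)
    # keep the strongest detection per core across radii: two true cores
    # can never be closer than 2 * rmin, so that spacing bounds the dedup
    order = np.argsort(np.asarray(vals))[::-1]
    keep: list[int] = []
    tree = cKDTree(centers)
    taken = np.zeros(len(centers), dtype=bool)
    dedup_r = max(float(rmin), 2.0 * float(rmin) - 0.5)
    for i in order:
        if taken[i]:
            continue
        keep.append(i)
        for j in tree.query_ball_point(centers[i], r=dedup_r):
            taken[j] = True
    keep.sort()
    centers = centers[keep]
    rads = np.asarray(crad, dtype=float)[keep]

    rows, cols = img.shape
    inside = (
        (centers[:, 0] >= 0) & (centers[:, 0] <= rows - 1)
        & (centers[:, 1] >= 0) & (centers[:, 1] <= cols - 1)
    )
    centers, rads = centers[inside], rads[inside]
    if len(centers) == 0:
        raise SegmentationError("zero fibers detected in flat-field image")

    labels = _assign_pixels(img.shape, centers, rads)
    return FiberMap(centers=centers, radii=rads, labels=labels, image_shape=img.shape)


def per_fiber_intensity(raw: np.ndarray, fmap: FiberMap) -> np.ndarray:
    """Mean raw intensity over each fiber's pixel membership."""
    img = np.asarray(raw, dtype=float)
    if img.shape != fmap.image_shape:
        raise InputError(
            f"image shape {img.shape} does not match fiber map {fmap.image_shape}"
        )
    n = fmap.n_fibers
    sums = np.bincount(fmap.labels.ravel(), weights=img.ravel(), minlength=n + 1)
    return sums[1 : n + 1] / fmap._pixel_counts


def _neighbor_table(fmap: FiberMap, k: int) -> np.ndarray:
    """(n, k) nearest-neighbor fiber ids, distance-sorted, ties by ascending id.

    Cached on the map, since per-frame contrast reuses the same geometry.
    """
    if k in fmap._neighbor_cache:
        return fmap._neighbor_cache[k]
    n = fmap.n_fibers
    if k > n - 1:
        raise InputError(f"k={k} exceeds available neighbors ({n - 1})")
    kq = min(n, k + 16)  # slack so boundary ties can be re-sorted deterministically
    dist, idx = fmap._tree.query(fmap.centers, k=kq)
    table = np.empty((n, k), dtype=int)
    for f in range(n):
        d, ids = dist[f], idx[f]
        mask = ids != f
        d, ids = d[mask], ids[mask]
        order = np.lexsort((ids, d))
        table[f] = ids[order][:k]
    fmap._neighbor_cache[k] = table
    return table


def nearest_fibers(fmap: FiberMap, fiber_id: int, k: int = 36) -> np.ndarray:
    """Ids of the ``k`` fibers nearest to ``fiber_id`` by center distance.

    The fiber itself is excluded; ties at equal distance break by ascending
    fiber id.  On an ideal hexagonal lattice, k = 6/18/36/60 returns exactly
    hexagonal rings 1/2/3/4.
    """
    if not (0 <= fiber_id < fmap.n_fibers):
        raise InputError(f"fiber_id {fiber_id} out of range")
    if k < 1:
        raise ParameterError("k must be >= 1")
    if k > fmap.n_fibers - 1:
        raise InputError(
            f"k={k} exceeds available neighbors ({fmap.n_fibers - 1})"
        )
    d = np.linalg.norm(fmap.centers - fmap.centers[fiber_id], axis=1)
    ids = np.arange(fmap.n_fibers)
    mask = ids != fiber_id
    d, ids = d[mask], ids[mask]
    order = np.lexsort((ids, d))
    return ids[order][:k]


def nearest_fiber_contrast(
    intensities: np.ndarray,
    fmap: FiberMap,
    k: int = 36,
    include_self: bool = True,
    max_neighbor_distance: Optional[float] = None,
) -> FiberContrastMap:
    """Speckle contrast per fiber from its k nearest fibers' mean intensities.

    For each fiber the sample is the fiber itself (when ``include_self``)
    plus its ``k`` nearest fibers; contrast is the sample standard deviation
    over the sample mean of the per-fiber intensities.  Fibers near the
    bundle edge, whose k-th neighbor is farther than ``max_neighbor_distance``,
    are flagged invalid rather than computed from a stretched neighborhood.
    The default cutoff is (m + 0.5) * pitch, with m the smallest ring count
    whose hexagonal neighborhood holds k fibers and pitch the median
    nearest-neighbor spacing; pass ``np.inf`` to disable the cutoff.
    Fibers whose sample mean is zero are flagged invalid, not raised.
    """
    vals = np.asarray(intensities, dtype=float)
    n = fmap.n_fibers
    if vals.shape != (n,):
        raise InputError(
            f"intensities length {vals.shape} does not match fiber count {n}"
        )
    if k > n - 1:
        return FiberContrastMap(
            contrast=np.zeros(n), valid=np.zeros(n, dtype=bool), k_neighbors=k
        )

    table = _neighbor_table(fmap, k)
    if include_self:
        sample_ids = np.column_stack([np.arange(n), table])
    else:
        sample_ids = table

    if max_neighbor_distance is None:
        d1, _ = fmap._tree.query(fmap.centers, k=2)
        pitch = float(np.median(d1[:, 1]))
        m = 1
        while hex_ring_count(m) < k:
            m += 1
        max_neighbor_distance = (m + 0.5) * pitch

    kth = np.linalg.norm(
        fmap.centers[table[:, -1]] - fmap.centers, axis=1
    )
    valid = kth <= max_neighbor_distance

    sample = vals[sample_ids]
    mean = sample.mean(axis=1)
    std = sample.std(axis=1, ddof=1)
    contrast = np.zeros(n)
    ok = mean > 0
    contrast[ok] = std[ok] / mean[ok]
    valid = valid & ok
    return FiberContrastMap(contrast=contrast, valid=valid, k_neighbors=k)
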