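"""Sequence-level analysis: ROI curves, ICT time courses, occlusion events,
and comparison metrics (Pearson R^2, contrast-to-noise ratio).

Averaging order follows the acquisition protocol: the mean contrast within
the ROI is computed for each frame first, then averaged across sequences
per exposure; the averaged contrast is squared to form the speckle-variance
curve that the MESI model is fit to.  For time courses, contrast is *not*
averaged across sequences: each sequence yields its own curve and fit, so
dynamic flow changes (e.g. a vessel occlusion) are resolved at the sequence
period (~0.3 s).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .bundle import FiberContrastMap
from .errors import InputError, ParameterError
from .speckle import ContrastCurve, ExposureLadder, fit_mesi

__all__ = [
    "TimeCourse",
    "OcclusionEvents",
    "roi_average_curve",
    "ict_timecourse",
    "detect_occlusion",
    "pearson_r2",
    "cnr",
    "DEFAULT_SEQUENCE_PERIOD",
    "OCCLUSION_THRESHOLD",
    "CLEARANCE_PERSISTENCE",
]

DEFAULT_SEQUENCE_PERIOD = 0.3  # s per MESI sequence (15 exposures + readout)
OCCLUSION_THRESHOLD = 1500.0  # 1/s: vessel counts as occluded below this ICT
CLEARANCE_PERSISTENCE = 60.0  # s: ICT must stay above threshold this long


@dataclass
class TimeCourse:
    """Per-sequence ICT values for one ROI."""

    timestamps: np.ndarray  # s from start
    ict_values: np.ndarray  # 1/s, NaN where the per-sequence fit failed
    roi_id: str = ""

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.ict_values = np.asarray(self.ict_values, dtype=float)
        if self.timestamps.shape != self.ict_values.shape:
            raise InputError("timestamps and ict_values must have equal length")
        if np.any(np.diff(self.timestamps) <= 0):
            raise InputError("timestamps must be strictly increasing")
        finite = self.ict_values[np.isfinite(self.ict_values)]
        if np.any(finite < 0):
            raise InputError("ICT values must be >= 0")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"time_s": self.timestamps, "ict_per_s": self.ict_values}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, roi_id: str = "") -> "TimeCourse":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(df["time_s"].to_numpy(), df["ict_per_s"].to_numpy(), roi_id=roi_id)


@dataclass
class OcclusionEvents:
    """Occlusion onset / clearance times detected from an ICT time course."""

    occlusion_start: Optional[float]
    clearance_time: Optional[float]
    threshold: float = OCCLUSION_THRESHOLD
    persistence: float = CLEARANCE_PERSISTENCE

    def __post_init__(self) -> None:
        if (
            self.occlusion_start is not None
            and self.clearance_time is not None
            and self.clearance_time <= self.occlusion_start
        ):
            raise InputError("clearance must come after occlusion onset")


SequenceContrast = Sequence[Union[np.ndarray, FiberContrastMap]]


def _frame_values(frame: Union[np.ndarray, FiberContrastMap]) -> np.ndarray:
    """Flatten one frame's contrast data with NaN marking invalid entries."""
    if isinstance(frame, FiberContrastMap):
        return frame.values()
    return np.asarray(frame, dtype=float).ravel()


def roi_average_curve(
    sequences: Sequence[SequenceContrast],
    roi: np.ndarray,
    ladder: ExposureLadder,
    roi_id: str = "",
) -> ContrastCurve:
    """ROI-and-sequence-averaged speckle-variance curve.

    ``sequences`` is a list of MESI sequences; each sequence is a list of
    per-exposure contrast data, either 2D pixel contrast maps (free-space /
    sliding-window path) or :class:`FiberContrastMap` objects (bundle path).
    ``roi`` selects pixels (boolean mask or flat indices) or fiber ids.
    Invalid entries (NaN pixels, invalid fibers) are excluded from the ROI
    mean.  Per exposure: mean over sequences of the per-frame ROI mean
    contrast; the result is squared into K^2.
    """
    if len(sequences) == 0:
        raise InputError("need at least one sequence")
    n_exp = ladder.count
    roi = np.asarray(roi)
    if roi.dtype == bool:
        roi = np.flatnonzero(roi.ravel())
    if roi.size == 0:
        raise InputError("ROI is empty")

    mean_k = np.zeros(n_exp)
    for seq in sequences:
        if len(seq) != n_exp:
            raise InputError(
                f"sequence has {len(seq)} frames, ladder expects {n_exp}"
            )
        for j, frame in enumerate(seq):
            vals = _frame_values(frame)[roi]
            if np.all(~np.isfinite(vals)):
                raise InputError("ROI is entirely invalid in at least one frame")
            mean_k[j] += np.nanmean(vals)
    mean_k /= len(sequences)
    return ContrastCurve(
        ladder=ladder,
        k2=mean_k**2,
        n_sequences_averaged=len(sequences),
        roi_id=roi_id,
    )


def ict_timecourse(
    sequences: Sequence[SequenceContrast],
    roi: np.ndarray,
    ladder: ExposureLadder,
    beta_bar: float,
    period: float = DEFAULT_SEQUENCE_PERIOD,
    roi_id: str = "",
) -> TimeCourse:
    """Un-averaged ICT time course: one fixed-beta MESI fit per sequence.

    ``beta_bar`` should come from a two-stage fit on baseline data.  A
    sequence whose fit does not converge contributes NaN, not zero.
    """
    if len(sequences) == 0:
        raise InputError("empty sequence list")
    if period <= 0:
        raise ParameterError("sequence period must be > 0")
    ict = np.full(len(sequences), np.nan)
    for i, seq in enumerate(sequences):
        curve = roi_average_curve([seq], roi, ladder, roi_id=roi_id)
        try:
            fit = fit_mesi(curve, fixed_beta=beta_bar)
        except (InputError, ParameterError):
            continue
        if fit.converged:
            ict[i] = fit.ict
    timestamps = np.arange(len(sequences)) * period
    return TimeCourse(timestamps=timestamps, ict_values=ict, roi_id=roi_id)


def detect_occlusion(
    tc: TimeCourse,
    threshold: float = OCCLUSION_THRESHOLD,
    persistence: float = CLEARANCE_PERSISTENCE,
) -> OcclusionEvents:
    """Apply the occlusion / clearance rules to an ICT time course.

    Occlusion starts at the first sample with ICT below ``threshold``.
    Clearance is the first timestamp t after onset such that every sample in
    [t, t + persistence] is at or above the threshold, with the record
    extending through t + persistence; a shorter excursion above threshold
    does not count.  NaN samples never satisfy either rule.
    """
    if tc.timestamps.size == 0:
        raise InputError("time course is empty")
    t = tc.timestamps
    v = tc.ict_values
    below = np.isfinite(v) & (v < threshold)
    if not np.any(below):
        return OcclusionEvents(None, None, threshold, persistence)
    i0 = int(np.argmax(below))
    start = float(t[i0])

    clearance = None
    for i in range(i0 + 1, t.size):
        if not (np.isfinite(v[i]) and v[i] >= threshold):
            continue
        end = t[i] + persistence
        if t[-1] < end:
            break  # record too short to certify persistence
        window = (t >= t[i]) & (t <= end)
        w = v[window]
        if np.all(np.isfinite(w) & (w >= threshold)):
            clearance = float(t[i])
            break
    return OcclusionEvents(start, clearance, threshold, persistence)


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Square of the Pearson correlation coefficient between two series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("series must be 1D and of equal length")
    if x.size < 3:
        raise InputError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("series with zero variance have undefined correlation")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def cnr(
    profile: Sequence[float],
    signal_index_set: Sequence[int],
    background_index_set: Sequence[int],
) -> float:
    """Contrast-to-noise ratio along a 1D profile.

    CNR = |mean(signal) - mean(background)| / std(background), with the
    sample standard deviation.  The index sets must be disjoint and
    nonempty.
    """
    p = np.asarray(profile, dtype=float)
    sig = np.asarray(signal_index_set, dtype=int)
    bg = np.asarray(background_index_set, dtype=int)
    if sig.size == 0 or bg.size == 0:
        raise InputError("signal and background index sets must be nonempty")
    if np.intersect1d(sig, bg).size:
        raise InputError("signal and background index sets must be disjoint")
    s = p[sig]
    b = p[bg]
    bstd = np.std(b, ddof=1) if b.size > 1 else 0.0
    if bstd == 0:
        raise InputError("background has zero standard deviation; CNR undefined")
    return float(abs(np.mean(s) - np.mean(b)) / bstd)
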