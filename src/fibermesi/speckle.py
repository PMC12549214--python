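"""Speckle contrast and the multi-exposure speckle imaging (MESI) model.

Speckle contrast is K = sigma / <I> computed over a spatial sample of
intensities.  The MESI model predicts the speckle variance K^2 as a function
of camera exposure time T for a field with correlation time ``tau_c``::

    K^2(T) = beta * rho^2 * (exp(-2x) - 1 + 2x) / (2 x^2)
           + 4 * beta * rho * (1 - rho) * (exp(-x) - 1 + x) / x^2
           + nu,            x = T / tau_c

where ``beta`` is the instrumentation factor, ``rho`` the fraction of
dynamically scattered light, and ``nu`` an exposure-independent noise floor.
The flow index reported per region is the inverse correlation time
ICT = 1 / tau_c (units 1/s): faster flow decorrelates the speckle field
sooner, shortening tau_c.

Fitting follows the two-stage protocol used for multi-ROI experiments:
``beta`` is first fitted freely per curve, the fitted values are averaged,
and every curve is refit with ``beta`` held at that average.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import least_squares

from .errors import InputError, ParameterError

__all__ = [
    "ExposureLadder",
    "ContrastCurve",
    "MESIFit",
    "sliding_window_contrast",
    "mesi_variance",
    "fit_mesi",
    "two_stage_beta_fit",
]

logger = logging.getLogger(__name__)

# Default MESI exposure ladder: 15 log-spaced exposures, 50 us to 80 ms.
DEFAULT_T_MIN = 50e-6
DEFAULT_T_MAX = 80e-3
DEFAULT_N_EXPOSURES = 15

# Below this x = T/tau_c the closed-form visibility terms lose precision to
# cancellation and a Taylor series is used instead.
_SERIES_X = 1e-4


def _read_json_text(source) -> str:
    """Accept a JSON string or a path to a JSON file."""
    if isinstance(source, Path):
        return source.read_text()
    s = str(source)
    if s.lstrip().startswith("{"):
        return s
    return Path(s).read_text()


@dataclass(frozen=True)
class ExposureLadder:
    """Ordered exposure times (seconds) of one MESI sequence."""

    times: tuple[float, ...]

    def __init__(self, times: Sequence[float]):
        arr = np.asarray(times, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ParameterError("exposure ladder must be a non-empty 1D sequence")
        if np.any(arr <= 0):
            raise ParameterError("all exposure times must be > 0")
        if np.any(np.diff(arr) <= 0):
            raise ParameterError("exposure times must be strictly increasing")
        object.__setattr__(self, "times", tuple(arr.tolist()))

    @classmethod
    def default(
        cls,
        count: int = DEFAULT_N_EXPOSURES,
        t_min: float = DEFAULT_T_MIN,
        t_max: float = DEFAULT_T_MAX,
    ) -> "ExposureLadder":
        """Log-spaced ladder from ``t_min`` to ``t_max`` inclusive."""
        return cls(np.geomspace(t_min, t_max, count))

    @property
    def count(self) -> int:
        return len(self.times)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)


@dataclass
class ContrastCurve:
    """Speckle variance K^2 per exposure for one ROI or fiber."""

    ladder: ExposureLadder
    k2: np.ndarray
    n_sequences_averaged: int = 1
    roi_id: str = ""

    def __post_init__(self) -> None:
        self.k2 = np.asarray(self.k2, dtype=float)
        if self.k2.ndim != 1 or self.k2.size != self.ladder.count:
            raise InputError(
                f"k2 length {self.k2.size} does not match ladder length "
                f"{self.ladder.count}"
            )
        finite = self.k2[np.isfinite(self.k2)]
        if np.any(finite < 0):
            raise InputError("speckle variance values must be >= 0")

    # -- serialization -------------------------------------------------
    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"exposure_s": self.ladder.as_array(), "k2": self.k2}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_sequences_averaged: int = 1, roi_id: str = "") -> "ContrastCurve":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(
            ExposureLadder(df["exposure_s"].to_numpy()),
            df["k2"].to_numpy(),
            n_sequences_averaged=n_sequences_averaged,
            roi_id=roi_id,
        )

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "exposure_s": list(self.ladder.times),
                "k2": self.k2.tolist(),
                "n_sequences_averaged": self.n_sequences_averaged,
                "roi_id": self.roi_id,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "ContrastCurve":
        d = json.loads(_read_json_text(source))
        return cls(
            ExposureLadder(d["exposure_s"]),
            np.asarray(d["k2"]),
            n_sequences_averaged=d.get("n_sequences_averaged", 1),
            roi_id=d.get("roi_id", ""),
        )


@dataclass
class MESIFit:
    """Result of fitting the MESI model to one contrast curve."""

    beta: float
    rho: float
    tau_c: float
    nu: float
    ict: float = field(default=np.nan)
    residual_norm: float = np.nan
    converged: bool = False
    message: str = ""

    def __post_init__(self) -> None:
        # ict is always derived, never supplied independently
        self.ict = 1.0 / self.tau_c

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "beta": self.beta,
                "rho": self.rho,
                "tau_c": self.tau_c,
                "nu": self.nu,
                "ict": self.ict,
                "residual_norm": self.residual_norm,
                "converged": self.converged,
                "message": self.message,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "MESIFit":
        d = json.loads(_read_json_text(source))
        fit = cls(
            beta=d["beta"], rho=d["rho"], tau_c=d["tau_c"], nu=d["nu"],
            residual_norm=d.get("residual_norm", np.nan),
            converged=d.get("converged", False),
            message=d.get("message", ""),
        )
        return fit

    def to_csv(self, path) -> None:
        rows = [
            ("beta", self.beta),
            ("rho", self.rho),
            ("tau_c", self.tau_c),
            ("nu", self.nu),
            ("ict", self.ict),
            ("residual_norm", self.residual_norm),
            ("converged", float(self.converged)),
        ]
        pd.DataFrame(rows, columns=["parameter", "value"]).to_csv(path, index=False)


# ----------------------------------------------------------------------
# contrast operator
# ----------------------------------------------------------------------

def sliding_window_contrast(image: np.ndarray, window: int = 7) -> np.ndarray:
    """Spatial speckle contrast map K = sigma / <I> over a sliding window.

    The standard deviation is the sample standard deviation (divisor N-1,
    N = window^2).  Border pixels whose window does not fit entirely inside
    the image, and pixels whose window mean is zero, are returned as NaN.

    Parameters
    ----------
    image : 2D array of nonnegative intensities.
    window : odd integer >= 3, no larger than either image dimension.
    """
    if not isinstance(window, (int, np.integer)):
        raise ParameterError("window must be an integer")
    if window % 2 == 0 or window < 3:
        raise ParameterError(f"window must be odd and >= 3, got {window}")
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise InputError(f"image must be 2D, got ndim={img.ndim}")
    if window > img.shape[0] or window > img.shape[1]:
        raise InputError(
            f"image {img.shape} is smaller than the {window}x{window} window"
        )
    if np.any(img < 0):
        raise InputError("image intensities must be nonnegative")

    n = window * window
    mean = ndimage.uniform_filter(img, size=window, mode="constant")
    meansq = ndimage.uniform_filter(img * img, size=window, mode="constant")
    # sample (N-1) variance; clip tiny negative round-off
    var = np.clip(meansq - mean * mean, 0.0, None) * (n / (n - 1))

    out = np.full_like(img, np.nan)
    half = (window - 1) // 2
    interior = np.zeros(img.shape, dtype=bool)
    interior[half : img.shape[0] - half, half : img.shape[1] - half] = True
    valid = interior & (mean > 0)
    out[valid] = np.sqrt(var[valid]) / mean[valid]
    # interior pixels with zero mean: all-zero window, contrast undefined
    return out


# ----------------------------------------------------------------------
# MESI forward model
# ----------------------------------------------------------------------

def _decay_term(y: np.ndarray) -> np.ndarray:
    """(exp(-y) - 1 + y) / y^2, series-protected for small y.

    Tends to 1/2 as y -> 0 and to 1/y as y -> inf.
    """
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)
    small = y < 2 * _SERIES_X  # both model terms switch at x = _SERIES_X
    ys = y[small]
    # Taylor: 1/2 - y/6 + y^2/24 - y^3/120 + y^4/720
    out[small] = (
        0.5 - ys / 6.0 + ys**2 / 24.0 - ys**3 / 120.0 + ys**4 / 720.0
    )
    yl = y[~small]
    out[~small] = (np.expm1(-yl) + yl) / (yl * yl)
    return out


def mesi_variance(T, tau_c, beta, rho, nu):
    """Speckle variance K^2 predicted by the MESI model.

    Vectorized over ``T``.  Scalar input returns a scalar.
    """
    T_arr = np.asarray(T, dtype=float)
    if np.any(T_arr <= 0):
        raise ParameterError("exposure time T must be > 0")
    if tau_c <= 0:
        raise ParameterError("tau_c must be > 0")
    if beta <= 0:
        raise ParameterError("beta must be > 0")
    if not (0 < rho <= 1):
        raise ParameterError("rho must be in (0, 1]")
    if nu < 0:
        raise ParameterError("nu must be >= 0")
    x = T_arr / tau_c
    # first term: beta rho^2 (e^{-2x} - 1 + 2x) / (2 x^2) = 2 beta rho^2 d(2x)
    k2 = (
        2.0 * beta * rho * rho * _decay_term(2.0 * x)
        + 4.0 * beta * rho * (1.0 - rho) * _decay_term(x)
        + nu
    )
    if np.isscalar(T) or np.ndim(T) == 0:
        return float(k2)
    return k2


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------

def _initial_guess(T: np.ndarray, k2: np.ndarray) -> tuple[float, float, float, float]:
    """Deterministic, data-driven start: (tau_c0, beta0, rho0, nu0)."""
    nu0 = float(np.min(k2))
    beta0 = max(float(np.max(k2)) - nu0, 1e-6)
    rho0 = 0.9
    mid = 0.5 * (float(np.max(k2)) + float(np.min(k2)))
    tau_c0 = float(T[int(np.argmin(np.abs(k2 - mid)))])
    return tau_c0, beta0, rho0, nu0


def _solve(T, k2, tau_c0, beta0, rho0, nu0, fixed_beta, beta_hi, nu_hi, log_tau_bounds):
    """One bounded least-squares solve in (log tau_c, [beta], rho, nu)."""
    lo_t, hi_t = log_tau_bounds
    if fixed_beta is None:
        x0 = [np.log(tau_c0), beta0, rho0, nu0]
        lb = [lo_t, 1e-8, 1e-3, 0.0]
        ub = [hi_t, beta_hi, 1.0, nu_hi]

        def resid(theta):
            return mesi_variance(T, np.exp(theta[0]), theta[1], theta[2], theta[3]) - k2
    else:
        x0 = [np.log(tau_c0), rho0, nu0]
        lb = [lo_t, 1e-3, 0.0]
        ub = [hi_t, 1.0, nu_hi]

        def resid(theta):
            return mesi_variance(T, np.exp(theta[0]), fixed_beta, theta[1], theta[2]) - k2

    x0 = np.clip(x0, lb, ub)
    return least_squares(
        resid, x0, bounds=(lb, ub), method="trf",
        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000,
    )


def fit_mesi(
    curve: ContrastCurve,
    fixed_beta: Optional[float] = None,
    bounds: Optional[dict] = None,
) -> MESIFit:
    """Fit the MESI model to a contrast curve by nonlinear least squares.

    tau_c is optimized on a log scale (positivity, conditioning); beta, rho
    and nu are box-bounded.  When ``fixed_beta`` is given, beta is held
    constant and only (rho, tau_c, nu) are free.  A deterministic multi-start
    over the ladder's exposure times as tau_c seeds is used if the first
    solve does not reduce the residual essentially to the data scale.

    ``bounds`` may override the default parameter box with keys
    ``beta_max``, ``nu_max``, ``tau_c_min``, ``tau_c_max``.
    """
    T = curve.ladder.as_array()
    k2 = np.asarray(curve.k2, dtype=float)
    finite = np.isfinite(k2)
    T, k2 = T[finite], k2[finite]

    n_free = 3 if fixed_beta is not None else 4
    if T.size < max(5, n_free):
        raise InputError(
            f"need at least {max(5, n_free)} finite exposures to fit, got {T.size}"
        )
    if fixed_beta is not None and fixed_beta <= 0:
        raise ParameterError("fixed_beta must be > 0")

    bounds = bounds or {}
    beta_hi = bounds.get("beta_max", 2.0)
    nu_hi = bounds.get("nu_max", max(float(np.max(k2)), 1e-12))
    lo_t = np.log(bounds.get("tau_c_min", T.min() / 1e4))
    hi_t = np.log(bounds.get("tau_c_max", T.max() * 1e4))

    tau_c0, beta0, rho0, nu0 = _initial_guess(T, k2)

    span = float(np.max(k2) - np.min(k2))
    if span <= 1e-12 * max(float(np.max(np.abs(k2))), 1.0):
        # flat curve: no exposure dependence, tau_c carries no signal
        return MESIFit(
            beta=fixed_beta if fixed_beta is not None else beta0,
            rho=rho0, tau_c=tau_c0, nu=nu0,
            residual_norm=float(np.sum((k2 - np.mean(k2)) ** 2)),
            converged=False,
            message="non-identifiable: flat contrast curve (no variance across exposures)",
        )

    beta0 = min(beta0, beta_hi)
    nu0 = min(nu0, nu_hi)
    args = (fixed_beta, beta_hi, nu_hi, (lo_t, hi_t))

    best = _solve(T, k2, tau_c0, beta0, rho0, nu0, *args)
    # fall back to a deterministic multi-start over the ladder when the first
    # solve leaves >1% of the curve's variance unexplained or pins tau_c at a
    # bound -- symptoms of a bad starting basin
    variance = np.sum((k2 - np.mean(k2)) ** 2)
    suspicious = (
        best.cost > 0.01 * variance
        or best.x[0] <= lo_t + 1e-9
        or best.x[0] >= hi_t - 1e-9
    )
    if suspicious:
        target = max(1e-16 * np.sum(k2**2), 1e-30)
        for tau_seed in T:
            if np.isclose(tau_seed, tau_c0):
                continue
            trial = _solve(T, k2, tau_seed, beta0, rho0, nu0, *args)
            if trial.cost < best.cost:
                best = trial
            if best.cost <= target:
                break

    theta = best.x
    if fixed_beta is None:
        tau_c, beta, rho, nu = np.exp(theta[0]), theta[1], theta[2], theta[3]
    else:
        tau_c, rho, nu = np.exp(theta[0]), theta[1], theta[2]
        beta = fixed_beta
    return MESIFit(
        beta=float(beta), rho=float(rho), tau_c=float(tau_c), nu=float(nu),
        residual_norm=float(2.0 * best.cost),
        converged=bool(best.success),
        message=best.message,
    )


def two_stage_beta_fit(
    curves: Sequence[ContrastCurve],
    bounds: Optional[dict] = None,
) -> tuple[float, list[MESIFit]]:
    """Two-stage protocol: fit beta freely per curve, average, refit fixed.

    Stage 1 fits every curve with beta free.  ``beta_bar`` is the unweighted
    arithmetic mean of the converged stage-1 betas (non-converged curves are
    excluded with a warning).  Stage 2 refits every curve with
    ``fixed_beta = beta_bar``.  Returns ``(beta_bar, stage2_fits)``.
    """
    if len(curves) == 0:
        raise InputError("need at least one curve")
    stage1 = [fit_mesi(c, bounds=bounds) for c in curves]
    betas = [f.beta for f in stage1 if f.converged]
    n_bad = len(stage1) - len(betas)
    if n_bad:
        warnings.warn(
            f"{n_bad} of {len(stage1)} stage-1 fits did not converge; "
            "excluded from the beta average",
            RuntimeWarning,
            stacklevel=2,
        )
    if not betas:
        raise InputError("no stage-1 fit converged; cannot average beta")
    beta_bar = float(np.mean(betas))
    stage2 = [fit_mesi(c, fixed_beta=beta_bar, bounds=bounds) for c in curves]
    return beta_bar, stage2
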