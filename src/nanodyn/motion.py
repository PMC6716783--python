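"""Single-molecule motion analysis from 2D trajectories.

The workflow mirrors single-particle-tracking practice for membrane
receptors imaged by TIRF microscopy: compute the time-averaged mean
squared displacement (TA-MSD) of each trajectory, fit the anomalous
diffusion law

    TA-MSD(t) = 4 * D * t**alpha + 4 * sigma_err**2

where ``D`` is the generalized diffusion coefficient (um^2 s^-alpha),
``alpha`` the anomalous diffusion exponent and ``sigma_err`` a constant
per-coordinate localization-error SD (um), then sort each molecule into
one of four motion classes (immobile, subdiffusion, normal diffusion,
superdiffusion) from the fitted (D, alpha).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "MSDCurve",
    "MotionFit",
    "ClassifierThresholds",
    "MotionClass",
    "FitConfig",
    "time_averaged_msd",
    "fit_msd",
    "classify_motion",
    "summarize_cohort",
    "EmptyCohortError",
]


class EmptyCohortError(ValueError):
    """Raised when every trajectory in a cohort is excluded by filters."""


@dataclass
class Trajectory:
    """Time-ordered 2D positions of one tracked molecule.

    Parameters
    ----------
    frames : array of int
        Observed frame indices, strictly increasing, 0-based. Gaps
        (missing frames from tracker gap-closing) are allowed and are
        simply absent from this array.
    xy : array, shape (n, 2)
        Positions in micrometres.
    dt : float
        Frame interval in seconds; the time of frame ``i`` is ``i * dt``.
    label : str
        Optional condition / ground-truth tag.
    """

    frames: np.ndarray
    xy: np.ndarray
    dt: float
    label: str = ""
    track_id: str | int = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.frames.ndim != 1 or self.xy.shape != (self.frames.size, 2):
            raise ValueError("frames must be 1D and xy must be (n_frames, 2)")
        if self.frames.size < 2:
            raise ValueError("a trajectory needs at least 2 observed frames")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("coordinates must be finite")
        if not (math.isfinite(self.dt) and self.dt > 0):
            raise ValueError("dt must be a positive finite number")

    @property
    def n_observed(self) -> int:
        return int(self.frames.size)

    @property
    def span(self) -> int:
        """Number of frames from first to last observation, inclusive."""
        return int(self.frames[-1] - self.frames[0] + 1)

    @property
    def is_gapped(self) -> bool:
        return self.n_observed < self.span

    @property
    def missing_fraction(self) -> float:
        return 1.0 - self.n_observed / self.span


@dataclass
class MSDCurve:
    """TA-MSD of one trajectory: ``msd[i]`` is the mean over all observed
    frame pairs separated by ``lags[i]`` of the squared displacement."""

    lags: np.ndarray
    times: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray


@dataclass
class MotionFit:
    """Fitted anomalous-diffusion parameters for one trajectory."""

    D: float
    alpha: float
    sigma_err: float
    residual_norm: float
    converged: bool
    n_frames_used: int


class MotionClass(str, Enum):
    IMMOBILE = "immobile"
    SUBDIFFUSION = "subdiffusion"
    NORMAL = "normal"
    SUPERDIFFUSION = "superdiffusion"


@dataclass
class ClassifierThresholds:
    """Decision boundaries of the four-class motion classifier.

    Molecules with D below ``d_immobile`` are immobile; mobile molecules
    are split by alpha: ``< alpha_low`` subdiffusive, ``> alpha_high``
    superdiffusive, otherwise normal (both boundaries inclusive for
    normal). ``min_frames`` is the shortest trajectory analyzed.
    """

    d_immobile: float = 0.01
    alpha_low: float = 0.75
    alpha_high: float = 1.25
    min_frames: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.alpha_low < self.alpha_high):
            raise ValueError("need 0 < alpha_low < alpha_high")
        if self.d_immobile <= 0:
            raise ValueError("d_immobile must be positive")


@dataclass
class FitConfig:
    """Controls for the TA-MSD fit.

    max_lag_fraction bounds the computed lag range at a fraction of the
    track length; lag_cap bounds the *fitted* range absolutely — TA-MSD
    estimates at long lags average few, strongly correlated pairs and
    carry most of the variance, so the fit uses short lags only.

    weighting: "inverse_msd" (default) weights each lag by
    sqrt(n_pairs)/msd, the reciprocal of the approximate SD of a TA-MSD
    point (whose noise scales with its own magnitude); "pairs" weights
    by sqrt(n_pairs); "none" is ordinary least squares.

    sigma_fixed pins the localization-error SD (um) instead of fitting
    it per trajectory; cohort summaries use this in a second pass with
    the pooled estimate, since localization error is a property of the
    instrument, not the molecule, and a free per-trajectory offset
    inflates the variance of the alpha estimate.
    """

    max_lag_fraction: float = 0.25
    lag_cap: int = 12
    weighting: str = "inverse_msd"
    sigma_fixed: float | None = None
    max_missing_fraction: float = 0.20
    pool_sigma_err: bool = True

    def __post_init__(self) -> None:
        if self.weighting not in ("inverse_msd", "pairs", "none"):
            raise ValueError("weighting must be inverse_msd, pairs or none")
        if self.sigma_fixed is not None and self.sigma_fixed < 0:
            raise ValueError("sigma_fixed must be non-negative")


def time_averaged_msd(traj: Trajectory, max_lag_fraction: float = 0.25) -> MSDCurve:
    """Compute the TA-MSD of a single trajectory.

    For each integer lag ``n`` up to ``floor(max_lag_fraction * (N - 1))``
    (``N`` = span in frames) the MSD is the mean of
    ``|r(i + n) - r(i)|**2`` over every pair of *observed* frames
    separated by exactly ``n`` frames; gapped frames simply contribute no
    pairs. Lags with no observed pair are omitted from the curve.
    """
    if not (0 < max_lag_fraction <= 1):
        raise ValueError("max_lag_fraction must be in (0, 1]")
    span = traj.span
    max_lag = int(math.floor(max_lag_fraction * (span - 1)))
    max_lag = max(max_lag, 1)

    frames = traj.frames
    xy = traj.xy
    lags, msds, counts = [], [], []
    if not traj.is_gapped:
        # contiguous track: every lag-n pair is rows (i, i+n)
        for lag in range(1, max_lag + 1):
            d = xy[lag:] - xy[:-lag]
            sq = np.einsum("ij,ij->i", d, d)
            lags.append(lag)
            msds.append(float(sq.mean()))
            counts.append(sq.size)
    else:
        # gap-aware pairing over observed frames only
        frame_to_idx = {int(f): i for i, f in enumerate(frames)}
        for lag in range(1, max_lag + 1):
            sq = []
            for i, f in enumerate(frames):
                j = frame_to_idx.get(int(f) + lag)
                if j is not None:
                    d = xy[j] - xy[i]
                    sq.append(d[0] * d[0] + d[1] * d[1])
            if sq:
                lags.append(lag)
                msds.append(float(np.mean(sq)))
                counts.append(len(sq))
    if not lags:
        raise ValueError("no valid frame pair at any lag")
    lags_arr = np.asarray(lags, dtype=np.int64)
    return MSDCurve(
        lags=lags_arr,
        times=lags_arr * traj.dt,
        msd=np.asarray(msds),
        n_pairs=np.asarray(counts, dtype=np.int64),
    )


def _msd_model(t: np.ndarray, D: float, alpha: float, sigma: float) -> np.ndarray:
    return 4.0 * D * np.power(t, alpha) + 4.0 * sigma * sigma


def _initial_guess(times: np.ndarray, msd: np.ndarray) -> tuple[float, float, float]:
    # log-log regression of the offset-corrected curve
    eps = np.finfo(float).eps
    y = np.clip(msd - msd.min(), eps, None)
    # guard against all-equal curves
    if np.allclose(msd, msd[0]):
        sigma0 = math.sqrt(max(msd[0], 0.0)) / 2.0
        return 1e-12, 1.0, sigma0
    slope, intercept = np.polyfit(np.log(times), np.log(y), 1)
    alpha0 = float(np.clip(slope, 0.05, 2.0))
    d0 = float(np.exp(intercept) / 4.0)
    d0 = max(d0, 1e-12)
    sigma0 = math.sqrt(max(msd.min(), 0.0)) / 2.0
    return d0, alpha0, sigma0


def fit_msd(curve: MSDCurve, config: FitConfig | None = None) -> MotionFit:
    """Bounded least-squares fit of ``4*D*t**alpha + 4*sigma**2``.

    D in [0, inf), alpha in [0, 2], sigma in [0, inf). Initialization
    from a log-log linear regression of the offset-corrected curve. The
    ``converged`` flag reports the optimizer's own success status;
    non-converged fits should be excluded by callers, never coerced.
    """
    config = config or FitConfig()
    # lag-range selection happens when the curve is computed; here only cap
    keep = curve.lags <= config.lag_cap
    times = curve.times[keep]
    msd = curve.msd[keep]
    n_pairs = curve.n_pairs[keep]
    if times.size < 5:
        raise ValueError("need at least 5 lags to fit the TA-MSD model")

    if config.weighting == "inverse_msd":
        weights = np.sqrt(n_pairs) / np.clip(np.abs(msd), 1e-12, None)
        weights /= weights.max()
    elif config.weighting == "pairs":
        weights = np.sqrt(n_pairs / n_pairs.max())
    else:
        weights = None

    d0, alpha0, sigma0 = _initial_guess(times, msd)
    fixed = config.sigma_fixed

    def residuals(p: np.ndarray) -> np.ndarray:
        if fixed is None:
            model = _msd_model(times, p[0], p[1], p[2])
        else:
            model = _msd_model(times, p[0], p[1], fixed)
        r = model - msd
        return r * weights if weights is not None else r

    if fixed is None:
        x0 = [d0, alpha0, sigma0]
        bounds = ([0.0, 0.0, 0.0], [np.inf, 2.0, np.inf])
    else:
        x0 = [d0, alpha0]
        bounds = ([0.0, 0.0], [np.inf, 2.0])
    try:
        res = optimize.least_squares(
            residuals,
            x0=x0,
            bounds=bounds,
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        ok = bool(res.success and np.all(np.isfinite(res.x)))
        if ok:
            D, alpha = res.x[0], res.x[1]
            sigma = res.x[2] if fixed is None else fixed
            cost = float(np.linalg.norm(res.fun))
        else:
            D = alpha = sigma = cost = np.nan
    except Exception:  # optimizer blow-up -> honest failure flag
        ok, D, alpha, sigma, cost = False, np.nan, np.nan, np.nan, np.nan
    return MotionFit(
        D=float(D),
        alpha=float(alpha),
        sigma_err=float(sigma),
        residual_norm=cost,
        converged=ok,
        n_frames_used=int(times.size),
    )


def classify_motion(
    fit: MotionFit, thresholds: ClassifierThresholds | None = None
) -> MotionClass:
    """Assign exactly one motion class from a converged fit.

    Boundary semantics: D equal to the immobile threshold counts as
    mobile (the immobile rule is a strict ``<``); alpha exactly at
    either boundary counts as normal diffusion.
    """
    thresholds = thresholds or ClassifierThresholds()
    if not fit.converged:
        raise ValueError("cannot classify a non-converged fit; filter first")
    if fit.D < thresholds.d_immobile:
        return MotionClass.IMMOBILE
    if fit.alpha < thresholds.alpha_low:
        return MotionClass.SUBDIFFUSION
    if fit.alpha > thresholds.alpha_high:
        return MotionClass.SUPERDIFFUSION
    return MotionClass.NORMAL


@dataclass
class CohortSummary:
    """Pooled per-class counts and fractions for one set of trajectories."""

    n_analyzed: int
    n_excluded_short: int
    n_excluded_gapped: int
    n_excluded_nonconverged: int
    fractions: dict[str, float]
    fits: list[MotionFit] = field(default_factory=list, repr=False)
    classes: list[MotionClass] = field(default_factory=list, repr=False)

    def to_frame(self, condition: str = "") -> pd.DataFrame:
        rows = [
            {
                "condition": condition,
                "class": cls.value,
                "n": sum(1 for c in self.classes if c is cls),
                "fraction": self.fractions[cls.value],
            }
            for cls in MotionClass
        ]
        return pd.DataFrame(rows)


def summarize_cohort(
    trajectories: list[Trajectory],
    thresholds: ClassifierThresholds | None = None,
    fit_config: FitConfig | None = None,
) -> CohortSummary:
    """Fit and classify every eligible trajectory; pool class fractions.

    Trajectories observed for fewer than ``thresholds.min_frames`` frames
    are excluded, as are tracks missing more than
    ``fit_config.max_missing_fraction`` of their frames and fits that do
    not converge. Fractions are pooled over trajectories and sum to 1
    over the analyzed set.

    With ``fit_config.pool_sigma_err`` (default), fitting is two-pass:
    per-trajectory free-offset fits give a pooled (median)
    localization-error SD, and every trajectory is refitted with the
    offset fixed at that value. Localization error is set by the
    instrument and labeling, so one value per imaging condition is the
    right model; freeing it per trajectory roughly doubles the spread of
    the alpha estimates.
    """
    thresholds = thresholds or ClassifierThresholds()
    fit_config = fit_config or FitConfig()

    n_short = n_gapped = n_nonconv = 0
    curves: list[MSDCurve] = []
    for traj in trajectories:
        if traj.n_observed < thresholds.min_frames:
            n_short += 1
            continue
        if traj.missing_fraction > fit_config.max_missing_fraction:
            n_gapped += 1
            continue
        curves.append(time_averaged_msd(traj, fit_config.max_lag_fraction))

    first_pass = [fit_msd(c, fit_config) for c in curves]
    if fit_config.pool_sigma_err and fit_config.sigma_fixed is None:
        sigmas = [f.sigma_err for f in first_pass if f.converged]
        if sigmas:
            pooled = float(np.median(sigmas))
            refit_config = FitConfig(
                max_lag_fraction=fit_config.max_lag_fraction,
                lag_cap=fit_config.lag_cap,
                weighting=fit_config.weighting,
                sigma_fixed=pooled,
                max_missing_fraction=fit_config.max_missing_fraction,
                pool_sigma_err=False,
            )
            first_pass = [fit_msd(c, refit_config) for c in curves]

    fits: list[MotionFit] = []
    classes: list[MotionClass] = []
    for fit in first_pass:
        if not fit.converged:
            n_nonconv += 1
            continue
        fits.append(fit)
        classes.append(classify_motion(fit, thresholds))

    if not fits:
        raise EmptyCohortError(
            f"all {len(trajectories)} trajectories excluded "
            f"(short={n_short}, gapped={n_gapped}, non-converged={n_nonconv})"
        )
    if n_short or n_gapped or n_nonconv:
        logger.info(
            "cohort exclusions: short=%d gapped=%d non-converged=%d",
            n_short,
            n_gapped,
            n_nonconv,
        )
    n = len(fits)
    fractions = {
        cls.value: sum(1 for c in classes if c is cls) / n for cls in MotionClass
    }
    return CohortSummary(
        n_analyzed=n,
        n_excluded_short=n_short,
        n_excluded_gapped=n_gapped,
        n_excluded_nonconverged=n_nonconv,
        fractions=fractions,
        fits=fits,
        classes=classes,
    )
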