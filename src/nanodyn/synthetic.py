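"""Synthetic inputs with known ground truth for every pipeline stage.

Trajectories are realized as fractional Brownian motion (fBm), the
minimal Gaussian process whose MSD follows the anomalous-diffusion law
``4*D*t**alpha`` fitted downstream: each coordinate is fBm with Hurst
exponent H = alpha/2 scaled so that Var[x(t) - x(0)] = 2*D*t**alpha,
plus iid Gaussian localization noise of SD ``sigma_err`` per coordinate
per frame (which contributes the constant ``4*sigma_err**2`` TA-MSD
offset). Increments are exact fractional Gaussian noise: sampled from
the true fGn covariance via Cholesky factorization for short tracks and
Davies-Harte circulant embedding for long ones — no Euler-type
approximation, so the generator doubles as an oracle for the fit.

Point patterns emulate gold-particle maps and PALM localization fields:
homogeneous Poisson (CSR) or Thomas cluster processes in a rectangular
window. Spectra, kinetic traces, dose-response tables and binding
traces realize, noise-free, the exact models the analysis modules fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fret_spectra import EMISSION_GRID_NM, EmissionSpectrum
from .motion import Trajectory
from .point_pattern import PointPattern

__all__ = [
    "TrajectorySpec",
    "CohortSpec",
    "PatternSpec",
    "simulate_fbm_trajectory",
    "simulate_cohort",
    "simulate_point_pattern",
    "simulate_spectrum",
    "simulate_kinetic_trace",
    "simulate_dose_response",
    "simulate_binding_traces",
    "fgn_covariance",
    "CHOLESKY_MAX_N",
]

CHOLESKY_MAX_N = 2048

# sensitized-emission component centers/widths used by simulate_spectrum:
# one Gaussian inside the liquid-ordered band (530-590 nm) and one inside
# the liquid-disordered band (590-650 nm)
LO_PEAK_NM = 570.0
LD_PEAK_NM = 610.0
FRET_PEAK_SD_NM = 12.0
DONOR_PEAK_NM = 490.0
DONOR_PEAK_SD_NM = 14.0


@dataclass(frozen=True)
class TrajectorySpec:
    """Ground-truth parameters of one simulated trajectory.

    D is the generalized diffusion coefficient (um^2 s^-alpha), alpha
    the anomalous diffusion exponent in (0, 2], sigma_err the
    per-coordinate localization-error SD (um), dt the frame interval
    (s; 30 ms by default, the acquisition interval the trajectory data
    emulate).
    """

    n_frames: int
    D: float
    alpha: float
    sigma_err: float = 0.0
    dt: float = 0.03
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not (0 < self.alpha <= 2):
            raise ValueError("alpha must be in (0, 2]")
        for name in ("D", "sigma_err", "dt"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """A labeled mixture of trajectory populations."""

    components: tuple[tuple[str, TrajectorySpec, int], ...]
    seed: int

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("cohort needs at least one component")
        labels = [label for label, _, _ in self.components]
        if len(set(labels)) != len(labels):
            raise ValueError("component labels must be unique")
        if any(count < 1 for _, _, count in self.components):
            raise ValueError("component counts must be >= 1")


@dataclass(frozen=True)
class PatternSpec:
    """Point-process parameters in a rectangular window (nm).

    ``intensity`` is points/nm^2 for CSR and parents/nm^2 for the Thomas
    process; Thomas offspring counts are Poisson(mean_offspring) and
    offspring are displaced isotropically with SD ``cluster_sd`` nm.
    """

    window: tuple[float, float, float, float]
    process: str
    intensity: float
    mean_offspring: float = 0.0
    cluster_sd: float = 0.0
    seed: int | None = None
    toroidal: bool = False

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.window
        if not (x1 > x0 and y1 > y0):
            raise ValueError("window must have positive area")
        if self.process not in ("csr", "thomas"):
            raise ValueError("process must be 'csr' or 'thomas'")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")
        if self.process == "thomas":
            if self.mean_offspring <= 0:
                raise ValueError("thomas process needs mean_offspring > 0")
            if self.cluster_sd < 0:
                raise ValueError("cluster_sd must be non-negative")

    @property
    def area(self) -> float:
        x0, y0, x1, y1 = self.window
        return (x1 - x0) * (y1 - y0)


def fgn_covariance(n: int, hurst: float, scale2: float) -> np.ndarray:
    """Autocovariance gamma(0..n-1) of fractional Gaussian noise.

    gamma(k) = scale2/2 * (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H}), where
    scale2 is the variance of one increment.
    """
    k = np.arange(n, dtype=float)
    two_h = 2.0 * hurst
    return 0.5 * scale2 * (
        np.abs(k + 1) ** two_h - 2.0 * np.abs(k) ** two_h + np.abs(k - 1) ** two_h
    )


def _fgn_cholesky(n: int, hurst: float, scale2: float, rng: np.random.Generator,
                  n_series: int) -> np.ndarray:
    from scipy.linalg import cholesky, toeplitz

    gamma = fgn_covariance(n, hurst, scale2)
    cov = toeplitz(gamma)
    # tiny jitter guards against round-off loss of positive definiteness
    try:
        chol = cholesky(cov, lower=True)
    except np.linalg.LinAlgError:
        chol = cholesky(cov + 1e-12 * scale2 * np.eye(n), lower=True)
    z = rng.standard_normal((n, n_series))
    return chol @ z


def _fgn_circulant(n: int, hurst: float, scale2: float, rng: np.random.Generator,
                   n_series: int) -> np.ndarray:
    """Davies-Harte sampling: embed the fGn covariance in a circulant
    matrix of size 2n whose eigenvalues (FFT of the first row) are
    non-negative for fGn, then color complex Gaussian noise."""
    gamma = fgn_covariance(n + 1, hurst, scale2)
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # length 2n
    eig = np.fft.fft(row).real
    eig = np.clip(eig, 0.0, None)  # clip tiny negative round-off
    m = row.size
    out = np.empty((n, n_series))
    for j in range(n_series):
        z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
        w = np.fft.fft(np.sqrt(eig / (2.0 * m)) * z)
        out[:, j] = w[:n].real * math.sqrt(2.0)
    return out


def _sample_fgn(n: int, hurst: float, scale2: float, rng: np.random.Generator,
                n_series: int = 1) -> np.ndarray:
    """Exact fGn sample paths, shape (n, n_series)."""
    if scale2 == 0.0:
        return np.zeros((n, n_series))
    if n <= CHOLESKY_MAX_N:
        return _fgn_cholesky(n, hurst, scale2, rng, n_series)
    return _fgn_circulant(n, hurst, scale2, rng, n_series)


def simulate_fbm_trajectory(
    spec: TrajectorySpec, rng: np.random.Generator | None = None
) -> Trajectory:
    """One fBm trajectory with localization noise, per ``spec``.

    The increment variance is ``2*D*dt**alpha`` per coordinate so that
    Var[x(t) - x(0)] = 2*D*t**alpha and the 2D ensemble MSD equals
    4*D*t**alpha + 4*sigma_err**2 at observed positions.
    """
    if rng is None:
        if spec.seed is None:
            raise ValueError("provide spec.seed or an explicit rng")
        rng = np.random.default_rng(spec.seed)
    n_inc = spec.n_frames - 1
    hurst = spec.alpha / 2.0
    scale2 = 2.0 * spec.D * spec.dt**spec.alpha
    increments = _sample_fgn(n_inc, hurst, scale2, rng, n_series=2)
    path = np.vstack([np.zeros((1, 2)), np.cumsum(increments, axis=0)])
    if spec.sigma_err > 0:
        path = path + rng.normal(0.0, spec.sigma_err, size=path.shape)
    return Trajectory(
        frames=np.arange(spec.n_frames), xy=path, dt=spec.dt
    )


def simulate_cohort(spec: CohortSpec) -> tuple[list[Trajectory], list[str]]:
    """Simulate a labeled mixture of trajectory populations.

    Output order is deterministic (components in declared order, tracks
    in index order) and the whole cohort is reproducible from
    ``spec.seed`` alone.
    """
    seeds = np.random.SeedSequence(spec.seed).spawn(len(spec.components))
    trajectories: list[Trajectory] = []
    labels: list[str] = []
    for (label, traj_spec, count), ss in zip(spec.components, seeds):
        rng = np.random.default_rng(ss)
        for i in range(count):
            traj = simulate_fbm_trajectory(traj_spec, rng=rng)
            traj.label = label
            traj.track_id = f"{label}_{i}"
            trajectories.append(traj)
            labels.append(label)
    return trajectories, labels


def simulate_point_pattern(spec: PatternSpec) -> PointPattern:
    """CSR or Thomas-process realization inside ``spec.window``.

    Thomas offspring falling outside the window are discarded (mimicking
    an imaged membrane sheet) unless ``spec.toroidal`` wraps them back —
    the wrap exists for closed-form checks only.
    """
    if spec.seed is None:
        raise ValueError("PatternSpec.seed is required for simulation")
    rng = np.random.default_rng(spec.seed)
    x0, y0, x1, y1 = spec.window
    w, h = x1 - x0, y1 - y0

    if spec.process == "csr":
        n = rng.poisson(spec.intensity * spec.area)
        pts = np.column_stack(
            [rng.uniform(x0, x1, size=n), rng.uniform(y0, y1, size=n)]
        )
        return PointPattern(points=pts, window=spec.window)

    n_parents = rng.poisson(spec.intensity * spec.area)
    parents = np.column_stack(
        [rng.uniform(x0, x1, size=n_parents), rng.uniform(y0, y1, size=n_parents)]
    )
    offspring = []
    for p in parents:
        k = rng.poisson(spec.mean_offspring)
        if k == 0:
            continue
        pts = p + rng.normal(0.0, spec.cluster_sd, size=(k, 2))
        offspring.append(pts)
    if offspring:
        pts = np.vstack(offspring)
        if spec.toroidal:
            pts[:, 0] = x0 + np.mod(pts[:, 0] - x0, w)
            pts[:, 1] = y0 + np.mod(pts[:, 1] - y0, h)
        else:
            inside = (
                (pts[:, 0] >= x0)
                & (pts[:, 0] <= x1)
                & (pts[:, 1] >= y0)
                & (pts[:, 1] <= y1)
            )
            pts = pts[inside]
    else:
        pts = np.empty((0, 2))
    return PointPattern(points=pts, window=spec.window)


def _gaussian(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sd) ** 2)


def simulate_spectrum(
    lo_weight: float,
    amplitude: float = 50.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    donor_amplitude: float = 1000.0,
) -> tuple[EmissionSpectrum, EmissionSpectrum]:
    """Donor-only and donor+sensitized-emission spectra on the native
    460-650 nm / 5-nm grid.

    The sample spectrum is the donor emission plus two sensitized
    Gaussian components centered inside the liquid-ordered (530-590 nm)
    and liquid-disordered (590-650 nm) bands with weights ``lo_weight``
    and ``1 - lo_weight``, plus iid Gaussian noise. ``amplitude`` scales
    the total sensitized emission; with ``noise_sd == 0`` the sample
    equals the generating model exactly.
    """
    if not (0.0 <= lo_weight <= 1.0):
        raise ValueError("lo_weight must be in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    wl = EMISSION_GRID_NM.copy()
    donor = donor_amplitude * _gaussian(wl, DONOR_PEAK_NM, DONOR_PEAK_SD_NM)
    fret = amplitude * (
        lo_weight * _gaussian(wl, LO_PEAK_NM, FRET_PEAK_SD_NM)
        + (1.0 - lo_weight) * _gaussian(wl, LD_PEAK_NM, FRET_PEAK_SD_NM)
    )
    sample = donor + fret
    if noise_sd > 0:
        sample = sample + rng.normal(0.0, noise_sd, size=wl.size)
    return (
        EmissionSpectrum(wavelengths=wl, intensity=donor),
        EmissionSpectrum(wavelengths=wl.copy(), intensity=sample),
    )


def logistic_response(
    dose: np.ndarray | float,
    bottom: float,
    top: float,
    log_ec50: float,
    hill: float = 1.0,
) -> np.ndarray:
    """Four-parameter logistic response; dose 0 maps to ``bottom``."""
    dose = np.asarray(dose, dtype=float)
    out = np.full(dose.shape, float(bottom))
    pos = dose > 0
    out[pos] = bottom + (top - bottom) / (
        1.0 + 10.0 ** ((log_ec50 - np.log10(dose[pos])) * hill)
    )
    return out


def simulate_dose_response(
    doses_m: np.ndarray,
    bottom: float = 0.0,
    top: float = 100.0,
    log_ec50: float = -9.0,
    hill: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Dose-response table on the 4PL model with additive Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    doses_m = np.asarray(doses_m, dtype=float)
    if np.any(doses_m < 0):
        raise ValueError("doses must be non-negative (0 = vehicle)")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        y = logistic_response(doses_m, bottom, top, log_ec50, hill)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=y.shape)
        rows.append(
            pd.DataFrame(
                {"dose_M": doses_m, "replicate": rep, "response": y}
            )
        )
    return pd.concat(rows, ignore_index=True)


def association_response(
    times_s: np.ndarray,
    conc_m: float,
    kon: float,
    koff: float,
    bmax: float,
) -> np.ndarray:
    """Mono-exponential association: Bmax*L/(L + koff/kon) *
    (1 - exp(-(kon*L + koff)*t)); observed rate k_obs = kon*L + koff."""
    times_s = np.asarray(times_s, dtype=float)
    kd = koff / kon
    k_obs = kon * conc_m + koff
    return bmax * conc_m / (conc_m + kd) * (1.0 - np.exp(-k_obs * times_s))


def simulate_binding_traces(
    times_s: np.ndarray,
    concs_m: np.ndarray,
    kon: float = 1e6,
    koff: float = 1e-3,
    bmax: float = 100.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Association traces at several ligand concentrations (tidy table)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    concs_m = np.asarray(concs_m, dtype=float)
    if np.any(concs_m <= 0):
        raise ValueError("ligand concentrations must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for conc in concs_m:
        y = association_response(times_s, conc, kon, koff, bmax)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=y.shape)
        rows.append(pd.DataFrame({"conc_M": conc, "time_s": times_s, "signal": y}))
    return pd.concat(rows, ignore_index=True)


def simulate_kinetic_trace(
    times_s: np.ndarray,
    t_stim_s: float,
    plateau_fold: float = 2.0,
    rate_per_s: float = 0.01,
    baseline_num: float = 100.0,
    baseline_den: float = 100.0,
    num_nm: float = 665.0,
    den_nm: float = 616.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    well: str = "A1",
    condition: str = "",
):
    """Two-channel kinetic trace whose blank-free ratio rises
    mono-exponentially from 1 to ``plateau_fold`` after ``t_stim_s``.

    The numerator channel carries the response; the denominator is
    constant. Noise-free output lies exactly on the generating model.
    """
    from .pharmacology import KineticTrace

    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    times_s = np.asarray(times_s, dtype=float)
    rng = np.random.default_rng(seed)
    fold = np.ones_like(times_s)
    post = times_s >= t_stim_s
    fold[post] = 1.0 + (plateau_fold - 1.0) * (
        1.0 - np.exp(-rate_per_s * (times_s[post] - t_stim_s))
    )
    num = baseline_num * fold
    den = np.full_like(times_s, baseline_den)
    if noise_sd > 0:
        num = num + rng.normal(0.0, noise_sd, size=num.shape)
        den = den + rng.normal(0.0, noise_sd, size=den.shape)
    return KineticTrace(
        times=times_s,
        channels={num_nm: num, den_nm: den},
        blanks={num_nm: 0.0, den_nm: 0.0},
        baseline_window=(times_s[0], t_stim_s),
        well=well,
        condition=condition,
    )
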