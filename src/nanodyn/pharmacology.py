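"""Plate-reader pharmacology: ratiometric kinetics, logistic
dose-response, binding kinetics and pathway-bias estimation.

These operations are shared by receptor-clustering (TR-FRET 665/616),
internalization (DERET 620/520), ligand-uptake (520/620) and biosensor
(535/485) assays. Kinetic responses are blank-subtracted channel ratios
normalized to each well's own pre-stimulation baseline and summarized
as trapezoidal AUC; concentration series are fitted with 3- or
4-parameter logistic curves; binding is quantified either by saturation
(one-site specific binding, B = Bmax*L/(Kd+L)) or by a global fit of
mono-exponential association traces at two or more ligand
concentrations sharing (kon, koff, Bmax), with Kd = koff/kon. Pathway
bias is the reference-agonist-normalized potency difference between two
readouts (delta-delta log EC50), computed within experiment so no error
propagation is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "KineticTrace",
    "DoseResponseFit",
    "BindingFit",
    "BiasEstimate",
    "ratiometric_trace",
    "normalize_to_baseline",
    "auc_response",
    "fit_logistic",
    "bias_estimate",
    "fit_saturation_binding",
    "fit_association_kinetics",
    "membrane_profile_series",
]


@dataclass
class KineticTrace:
    """Multi-channel kinetic plate-reader read for one well."""

    times: np.ndarray
    channels: dict[float, np.ndarray]
    blanks: dict[float, float] = field(default_factory=dict)
    baseline_window: tuple[float, float] | None = None
    well: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")
        self.channels = {
            float(k): np.asarray(v, dtype=float) for k, v in self.channels.items()
        }
        for nm, y in self.channels.items():
            if y.shape != self.times.shape:
                raise ValueError(f"channel {nm:g} nm does not align with times")


@dataclass
class DoseResponseFit:
    """Logistic dose-response parameters. ``hill`` is fixed at 1 in the
    3-parameter mode. ``top >= bottom`` is enforced by fitting the span
    ``top - bottom`` on [0, inf)."""

    log_ec50: float
    top: float
    bottom: float
    hill: float
    n_params: int
    se: dict[str, float]
    converged: bool
    residual_norm: float = float("nan")

    @property
    def emax(self) -> float:
        return self.top

    @property
    def ec50_m(self) -> float:
        return 10.0**self.log_ec50


@dataclass
class BindingFit:
    """Binding parameters; in kinetic mode kd == koff/kon by identity."""

    kd: float
    bmax: float
    mode: str
    kon: float = float("nan")
    koff: float = float("nan")
    converged: bool = True
    se: dict[str, float] = field(default_factory=dict)


@dataclass
class BiasEstimate:
    """Pathway-bias ledger.

    ``per_experiment`` holds experiment-specific delta log EC50 values
    (reference agonist minus test agonist, per pathway) and delta-delta
    log EC50 (reference pathway minus test pathway); ``summary`` is the
    mean +/- SEM over experiments per agonist. The sign convention is
    recorded in ``convention``.
    """

    per_experiment: pd.DataFrame
    summary: pd.DataFrame
    reference_agonist: str
    reference_pathway: str
    test_pathway: str
    convention: str = (
        "delta = logEC50(reference agonist) - logEC50(agonist); "
        "delta_delta = delta(reference pathway) - delta(test pathway)"
    )


def ratiometric_trace(
    trace: KineticTrace, numerator_nm: float, denominator_nm: float
) -> np.ndarray:
    """Blank-subtracted channel ratio r(t) = (num - blank)/(den - blank)."""
    for nm in (numerator_nm, denominator_nm):
        if float(nm) not in trace.channels:
            raise KeyError(f"channel {nm:g} nm not present in trace")
    num = trace.channels[float(numerator_nm)] - trace.blanks.get(float(numerator_nm), 0.0)
    den = trace.channels[float(denominator_nm)] - trace.blanks.get(
        float(denominator_nm), 0.0
    )
    zero = den == 0
    if np.any(zero):
        bad = trace.times[zero]
        raise ZeroDivisionError(
            f"denominator channel {denominator_nm:g} nm is zero after blank "
            f"subtraction at t = {bad.tolist()}"
        )
    return num / den


def normalize_to_baseline(
    series: np.ndarray,
    times: np.ndarray,
    baseline_window: tuple[float, float],
) -> tuple[np.ndarray, float]:
    """Divide a series by its mean over the baseline window.

    Returns the fold-from-baseline series and the baseline mean.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if baseline_window is None:
        raise ValueError("a baseline window is required")
    t0, t1 = baseline_window
    mask = (times >= t0) & (times <= t1)
    if mask.sum() < 2:
        raise ValueError("baseline window must contain at least 2 points")
    base = float(series[mask].mean())
    if base <= 0:
        raise ValueError(f"baseline mean is {base:g}; normalization undefined")
    return series / base, base


def auc_response(
    series: np.ndarray, times: np.ndarray, mode: str = "above_baseline"
) -> float:
    """Trapezoidal AUC of a kinetic response.

    ``above_baseline`` integrates (series - 1), appropriate for
    baseline-normalized fold-change traces where 1.0 means no response;
    ``raw`` integrates the series itself.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if series.size < 2:
        raise ValueError("need at least 2 time points")
    if mode == "above_baseline":
        return float(np.trapezoid(series - 1.0, times))
    if mode == "raw":
        return float(np.trapezoid(series, times))
    raise ValueError("mode must be 'above_baseline' or 'raw'")


def _logistic(dose: np.ndarray, bottom: float, span: float, log_ec50: float,
              hill: float) -> np.ndarray:
    out = np.full(dose.shape, bottom, dtype=float)
    pos = dose > 0
    out[pos] = bottom + span / (
        1.0 + 10.0 ** ((log_ec50 - np.log10(dose[pos])) * hill)
    )
    return out


def fit_logistic(
    dose_m: np.ndarray,
    response: np.ndarray,
    n_params: int = 4,
    bottom_fixed: float | None = None,
) -> DoseResponseFit:
    """Least-squares 3- or 4-parameter logistic fit on the log-dose axis.

    Model: y = bottom + (top - bottom) / (1 + 10**((logEC50 - log10 d) * hill)).
    The 3-parameter mode fixes hill = 1; ``bottom_fixed`` optionally pins
    the bottom asymptote. Vehicle observations (dose 0) anchor the
    bottom rather than being placed on the log axis. Standard errors come
    from the Jacobian at the optimum.
    """
    dose_m = np.asarray(dose_m, dtype=float)
    response = np.asarray(response, dtype=float)
    if dose_m.shape != response.shape:
        raise ValueError("dose and response must align")
    if n_params not in (3, 4):
        raise ValueError("n_params must be 3 or 4")
    n_free = n_params - (0 if bottom_fixed is None else 1)
    if np.unique(dose_m).size < n_free + 1:
        raise ValueError(f"need at least {n_free + 1} distinct doses")

    fit_hill = n_params == 4
    fit_bottom = bottom_fixed is None

    y_lo, y_hi = float(response.min()), float(response.max())
    span0 = max(y_hi - y_lo, 1e-9)
    pos_doses = dose_m[dose_m > 0]
    lec0 = float(np.median(np.log10(pos_doses)))

    names: list[str] = []
    x0: list[float] = []
    lo: list[float] = []
    hi: list[float] = []
    if fit_bottom:
        names.append("bottom"); x0.append(y_lo); lo.append(-np.inf); hi.append(np.inf)
    names.append("span"); x0.append(span0); lo.append(0.0); hi.append(np.inf)
    names.append("log_ec50"); x0.append(lec0); lo.append(-np.inf); hi.append(np.inf)
    if fit_hill:
        names.append("hill"); x0.append(1.0); lo.append(1e-3); hi.append(10.0)

    def unpack(p: np.ndarray) -> tuple[float, float, float, float]:
        vals = dict(zip(names, p))
        bottom = vals.get("bottom", bottom_fixed if bottom_fixed is not None else 0.0)
        return bottom, vals["span"], vals["log_ec50"], vals.get("hill", 1.0)

    def residuals(p: np.ndarray) -> np.ndarray:
        return _logistic(dose_m, *unpack(p)) - response

    res = optimize.least_squares(
        residuals, x0=x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    ok = bool(res.success and np.all(np.isfinite(res.x)))
    bottom, span, log_ec50, hill = unpack(res.x)

    se: dict[str, float] = {}
    dof = response.size - len(names)
    if ok and dof > 0:
        s2 = 2.0 * res.cost / dof
        try:
            cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
            se = {n: float(math.sqrt(max(cov[i, i], 0.0)))
                  for i, n in enumerate(names)}
        except np.linalg.LinAlgError:
            se = {}
    return DoseResponseFit(
        log_ec50=float(log_ec50),
        top=float(bottom + span),
        bottom=float(bottom),
        hill=float(hill),
        n_params=n_params,
        se=se,
        converged=ok,
        residual_norm=float(np.linalg.norm(res.fun)),
    )


def bias_estimate(
    log_ec50_table: pd.DataFrame,
    reference_agonist: str,
    reference_pathway: str,
    test_pathway: str,
) -> BiasEstimate:
    """Experiment-wise potency-bias ledger from a logEC50 table.

    ``log_ec50_table`` needs columns ``agonist``, ``pathway``,
    ``experiment``, ``log_ec50``; every (agonist, pathway) cell must be
    present within each experiment (agonists are run in parallel on the
    same ligand dilutions, which is what licenses the propagation-free
    within-experiment subtraction). For each experiment and pathway:
    delta = logEC50(reference agonist) - logEC50(agonist); then
    delta_delta = delta(reference pathway) - delta(test pathway). The
    reference agonist has delta == 0 in every pathway and delta_delta == 0
    identically.
    """
    required = {"agonist", "pathway", "experiment", "log_ec50"}
    missing_cols = required - set(log_ec50_table.columns)
    if missing_cols:
        raise ValueError(f"table is missing columns: {sorted(missing_cols)}")
    pathways = {reference_pathway, test_pathway}
    df = log_ec50_table[log_ec50_table["pathway"].isin(pathways)].copy()
    agonists = sorted(df["agonist"].unique())
    if reference_agonist not in agonists:
        raise ValueError(f"reference agonist {reference_agonist!r} absent from table")

    rows = []
    for exp, g in df.groupby("experiment"):
        cell = g.set_index(["agonist", "pathway"])["log_ec50"]
        if cell.index.duplicated().any():
            dup = cell.index[cell.index.duplicated()][0]
            raise ValueError(f"duplicate cell {dup} in experiment {exp!r}")
        for agonist in agonists:
            deltas = {}
            for pathway in (reference_pathway, test_pathway):
                for who in (reference_agonist, agonist):
                    if (who, pathway) not in cell.index:
                        raise ValueError(
                            f"missing cell (agonist={who!r}, pathway={pathway!r}) "
                            f"in experiment {exp!r}"
                        )
                deltas[pathway] = float(
                    cell[(reference_agonist, pathway)] - cell[(agonist, pathway)]
                )
            rows.append(
                {
                    "experiment": exp,
                    "agonist": agonist,
                    f"delta_log_ec50_{reference_pathway}": deltas[reference_pathway],
                    f"delta_log_ec50_{test_pathway}": deltas[test_pathway],
                    "delta_delta_log_ec50": deltas[reference_pathway]
                    - deltas[test_pathway],
                }
            )
    per_exp = pd.DataFrame(rows)
    summary = (
        per_exp.groupby("agonist")["delta_delta_log_ec50"]
        .agg(["mean", "sem", "count"])
        .rename(columns={"mean": "delta_delta_log_ec50", "count": "n_experiments"})
        .reset_index()
    )
    return BiasEstimate(
        per_experiment=per_exp,
        summary=summary,
        reference_agonist=reference_agonist,
        reference_pathway=reference_pathway,
        test_pathway=test_pathway,
    )


def fit_saturation_binding(conc_m: np.ndarray, signal: np.ndarray) -> BindingFit:
    """One-site specific binding: B = Bmax * L / (Kd + L), Kd, Bmax >= 0."""
    conc_m = np.asarray(conc_m, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if np.unique(conc_m).size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if np.allclose(signal, signal[0]):
        return BindingFit(kd=float("nan"), bmax=float("nan"),
                          mode="saturation", converged=False)
    bmax0 = float(signal.max())
    kd0 = float(np.median(conc_m))

    def residuals(p: np.ndarray) -> np.ndarray:
        bmax, kd = p
        return bmax * conc_m / (kd + conc_m) - signal

    res = optimize.least_squares(
        residuals, x0=[bmax0, kd0], bounds=([0, 0], [np.inf, np.inf]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    ok = bool(res.success and np.all(np.isfinite(res.x)))
    se: dict[str, float] = {}
    dof = signal.size - 2
    if ok and dof > 0:
        s2 = 2.0 * res.cost / dof
        try:
            cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
            se = {"bmax": float(math.sqrt(max(cov[0, 0], 0.0))),
                  "kd": float(math.sqrt(max(cov[1, 1], 0.0)))}
        except np.linalg.LinAlgError:
            se = {}
    return BindingFit(
        kd=float(res.x[1]), bmax=float(res.x[0]), mode="saturation",
        converged=ok, se=se,
    )


def _association_model(times: np.ndarray, conc: float, kon: float, koff: float,
                       bmax: float) -> np.ndarray:
    kd = koff / kon
    return bmax * conc / (conc + kd) * (1.0 - np.exp(-(kon * conc + koff) * times))


def fit_association_kinetics(traces: pd.DataFrame) -> BindingFit:
    """Global fit of association traces at >= 2 ligand concentrations.

    ``traces`` is tidy with columns ``conc_M``, ``time_s``, ``signal``
    (baseline-subtracted). The model
    Y_L(t) = Bmax * L / (L + koff/kon) * (1 - exp(-(kon*L + koff)*t))
    shares (kon, koff, Bmax) across concentrations; a single
    concentration cannot separate kon from koff and is rejected.
    Kd = koff/kon.
    """
    required = {"conc_M", "time_s", "signal"}
    if not required.issubset(traces.columns):
        raise ValueError(f"traces table needs columns {sorted(required)}")
    concs = np.sort(traces["conc_M"].unique())
    if concs.size < 2:
        raise ValueError("need traces at two or more ligand concentrations")
    groups = [
        (float(c), g["time_s"].to_numpy(float), g["signal"].to_numpy(float))
        for c, g in traces.groupby("conc_M")
    ]
    y_scale = max(float(traces["signal"].abs().max()), 1e-12)
    t_scale = float(traces["time_s"].max())
    # crude initialization: plateau ~ Bmax at the top concentration,
    # k_obs ~ 1/t_scale split between kon*L and koff
    bmax0 = y_scale
    koff0 = 0.5 / t_scale
    kon0 = 0.5 / (t_scale * float(concs[-1]))

    def residuals(logp: np.ndarray) -> np.ndarray:
        kon, koff, bmax = np.exp(logp)
        return np.concatenate(
            [_association_model(t, c, kon, koff, bmax) - y for c, t, y in groups]
        )

    res = optimize.least_squares(
        residuals,
        x0=np.log([kon0, koff0, bmax0]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
        max_nfev=20000,
    )
    ok = bool(res.success and np.all(np.isfinite(res.x)))
    kon, koff, bmax = np.exp(res.x)
    return BindingFit(
        kd=float(koff / kon), bmax=float(bmax), mode="kinetic",
        kon=float(kon), koff=float(koff), converged=ok,
    )


def membrane_profile_series(
    profiles: list[list[np.ndarray]],
    times: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Surface-signal kinetics from membrane intensity profiles.

    ``profiles[i]`` holds the 1D intensity segments drawn across the
    plasma membrane at frame i. Per frame the segment maxima are
    averaged; the series is normalized to its time-0 value and
    summarized by the above-baseline AUC. Returns (normalized series,
    AUC).
    """
    times = np.asarray(times, dtype=float)
    if len(profiles) != times.size:
        raise ValueError("one profile set per time point is required")
    if any(len(segs) < 1 for segs in profiles):
        raise ValueError("every frame needs at least one segment")
    series = np.asarray(
        [np.mean([np.max(np.asarray(s, dtype=float)) for s in segs])
         for segs in profiles]
    )
    if series[0] <= 0:
        raise ValueError("time-0 surface signal must be positive")
    normalized = series / series[0]
    return normalized, auc_response(normalized, times, mode="above_baseline")
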