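# Methods

`nanodyn` quantifies how a cell-surface receptor reorganizes in plasma
membrane nanodomains after agonist stimulation, from four kinds of raw
measurement: single-molecule trajectories, 2D localization maps,
emission spectral scans of a solvatochromic membrane probe, and
two-channel kinetic plate-reader traces. This note describes the models
behind each stage, the parameters that matter, the numerical choices,
and what the synthetic-data generators do and do not emulate.

## Single-molecule motion analysis (`nanodyn.motion`)

**Model.** The time-averaged mean squared displacement of one 2D
trajectory sampled at frame interval `dt` is fitted with the
anomalous-diffusion law

    TA-MSD(t) = 4 D t^alpha + 4 sigma_err^2

where `D` (um^2 s^-alpha) is the generalized diffusion coefficient,
`alpha` the anomalous diffusion exponent (alpha < 1 subdiffusion,
alpha ~ 1 Brownian motion, alpha > 1 directed/superdiffusion) and
`sigma_err` (um) the per-coordinate localization-error SD, which adds a
constant offset to every lag. TA-MSD at lag n averages
`|r(i+n) - r(i)|^2` over all observed frame pairs; tracks with gaps
(tracker gap-closing) contribute only their observed pairs, and tracks
missing more than 20% of their frames are excluded.

**Classification.** Each converged fit is assigned exactly one of four
classes: immobile if `D < 0.01` um^2 s^-alpha; otherwise normal
diffusion if `0.75 <= alpha <= 1.25`, subdiffusion if `alpha < 0.75`,
superdiffusion if `alpha > 1.25`. Both alpha boundaries count as
normal, and `D` exactly at 0.01 counts as mobile. Only trajectories
observed for at least 100 frames are analyzed. Class fractions are
pooled over trajectories, not averaged per cell.

**Fitting choices.** The TA-MSD is computed out to a quarter of the
track length but fitted only over lags 1–12 by default: long-lag TA-MSD
points average few, strongly correlated pairs and carry most of the
variance. The fit is bounded nonlinear least squares (`D >= 0`,
`0 <= alpha <= 2`, `sigma_err >= 0`), initialized from a log–log linear
regression of the offset-corrected curve, with each lag weighted by
`sqrt(n_pairs)/msd` — the reciprocal of the approximate SD of a TA-MSD
point, whose sampling noise scales with its own magnitude. Ordinary and
pair-count weighting are available as options.

Cohort summaries fit in two passes. Free per-trajectory offsets make
`sigma_err` and `alpha` partially degenerate over a short lag window and
roughly double the spread of the alpha estimates; but localization
error is a property of the instrument, labeling and exposure, not of
the individual molecule. The first pass fits every trajectory with a
free offset; the median `sigma_err` over converged fits is then fixed
and everything refitted. On simulated mixtures of the four regimes at
150 frames this raises per-class recovery from roughly 55–85% to
97–100%. Single-pass free-offset fitting remains available
(`FitConfig(pool_sigma_err=False)`), as does pinning the offset to a
known value (`sigma_fixed`).

Non-converged fits are excluded and counted, never coerced. A cohort in
which every trajectory is filtered out raises an explicit error.

## Trajectory simulation (`nanodyn.synthetic`)

Each coordinate of a simulated trajectory is fractional Brownian motion
with Hurst exponent `H = alpha/2`, scaled so that
`Var[x(t) - x(0)] = 2 D t^alpha`, plus iid Gaussian localization noise
of SD `sigma_err` per coordinate per frame — the exact stochastic
realization of the fitted law, including its `4 sigma_err^2` offset.
Increments are exact fractional Gaussian noise drawn from the true
covariance

    C(k) = (s^2/2) (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H}),
    s^2 = 2 D dt^alpha,

via Cholesky factorization of the Toeplitz covariance for tracks of up
to 2,048 steps and Davies–Harte circulant embedding above that. No
Euler-type approximation is involved, so the generator doubles as an
oracle: the ensemble MSD matches the closed form to Monte-Carlo error,
which the tests check at the 3-SE level over 2,000 trajectories.

fBm is a modeling choice: it is the minimal stationary-increment
Gaussian process consistent with a power-law MSD. Real membrane
trajectories may instead reflect confinement, hop diffusion or
transient binding; the generators make no claim about mechanism, only
about the statistical structure the downstream fit assumes. Defaults
(30-ms frame interval, 20-nm localization error, 150-frame tracks,
regimes immobile D = 0.001/alpha = 1, subdiffusive D = 0.05/alpha = 0.4,
normal D = 0.05/alpha = 1, superdiffusive D = 0.05/alpha = 1.6) match
typical TIRF single-particle-tracking acquisitions of membrane GPCRs.

## Spatial point patterns (`nanodyn.point_pattern`)

**Nearest-neighbor distances.** `NND_i = min_{j != i} |p_i - p_j|`,
reported per point with the mean, computed on raw image coordinates
with **no edge correction** — matching direct measurement on electron
micrographs of membrane sheets. A toroidal (minimum-image) metric
exists solely so tests can use the closed form: under complete spatial
randomness with intensity lambda the mean NND is `1/(2 sqrt(lambda))`.
A Monte-Carlo CSR null (`csr_null`) simulates fixed-n uniform patterns
in the same window and reports
`p = (1 + #{null mean <= observed}) / (n_sims + 1)` for the clustering
direction; calibration tests confirm the p-value is uniform under CSR.

**Oligomer counting.** PALM localization tables are first deduplicated:
points are sorted by (x, y) for determinism and greedily scanned, and
any point within the 10-nm deduplication radius of an already-retained
point is discarded as a re-activation of the same fluorophore. For each
retained molecule the cluster size is the number of retained molecules
within the 50-nm association radius, inclusive of itself; the mean of
these per-molecule neighborhood counts is the reported average cluster
size. The per-molecule neighborhood reading (rather than connected
components) is deliberate; the production path uses a k-d tree but is
tested to be identical to a brute-force O(n^2) oracle up to n = 2,000.
The source protocol does not specify the order of the discount rule;
greedy in-sorted-order is a deterministic choice.

**Generators.** CSR patterns are homogeneous Poisson in the window;
clustered patterns are a Thomas process (Poisson parents,
Poisson-distributed offspring displaced isotropically with SD
`cluster_sd`). Offspring falling outside the window are discarded, like
molecules outside an imaged membrane sheet; a toroidal wrap exists for
closed-form checks.

## Lo/Ld spectral decomposition (`nanodyn.fret_spectra`)

Emission scans (460–650 nm, 5-nm steps) from a lanthanide donor on the
receptor plus a solvatochromic membrane probe are processed as: blank
subtraction; ratiometric normalization of each scan to its own 490-nm
donor signal; subtraction of the normalized donor-only scan, leaving
the probe-specific sensitized emission (zero at 490 nm by construction
and invariant to gain on either input). The liquid-ordered fraction is
the trapezoidal area over 530–590 nm divided by the 530–650 nm total;
the liquid-disordered fraction is the 590–650 nm complement. The two
bands share the 590-nm trapezoid endpoint, so lo + ld = 1 exactly —
integration is on the native 5-nm grid with no interpolation.
Negative post-subtraction intensities are retained, not clipped;
fractions can therefore leave [0, 1] on pathological inputs, and a
non-positive total band area raises rather than silently truncating.
Two faster readouts are provided: the ratio of stimulus-induced
increases at 570 nm vs 610 nm, and baseline-normalized 570/490 and
610/490 kinetic ratio traces. Blank subtraction accepts a full blank
spectrum or a scalar (per-wavelength is the default).

The spectrum generator superimposes a donor Gaussian at 490 nm and two
sensitized-emission Gaussians centered at 570 and 610 nm (SD 12 nm)
with weights `lo_weight` and `1 - lo_weight`; band fractions of
noise-free spectra are checked against the analytic Gaussian band
integrals. Real probe spectra are asymmetric and solvent-broadened;
the generator reproduces band geometry, not photophysics.

## Plate-reader pharmacology (`nanodyn.pharmacology`)

**Kinetic ratios and AUC.** Responses are blank-subtracted channel
ratios (clustering 665/616, internalization 620/520, binding 520/620,
biosensors 535/485), normalized to each well's own pre-stimulation
baseline mean, and summarized as the trapezoidal integral of
(fold-change - 1). Both raw and baseline-normalized AUC are available
because assay variants differ in whether per-well normalization
precedes integration.

**Dose-response.** `y = bottom + (top - bottom)/(1 + 10^{(logEC50 -
log10 d) hill})`, fitted by bounded least squares with the span
(top - bottom) constrained non-negative and hill > 0; the 3-parameter
mode fixes hill = 1. Vehicle (dose 0) observations anchor the bottom
asymptote instead of being placed on the log axis. Standard errors come
from the Jacobian at the optimum; simulation tests check both bias
(< 0.05 log units) and Wald-interval coverage.

**Binding.** Saturation mode fits one-site specific binding
`B = Bmax L/(Kd + L)`. Kinetic mode fits
`Y_L(t) = Bmax L/(L + koff/kon) (1 - e^{-(kon L + koff) t})` globally
across two or more ligand concentrations with shared (kon, koff, Bmax)
— a single concentration cannot separate kon from koff and is rejected
— parameterized in logs to keep rates positive; `Kd = koff/kon` by
identity and the observed rate is affine in L (`k_obs = kon L + koff`),
which the tests verify on noise-free fits.

**Pathway bias.** From a table of per-experiment logEC50 values
(agonist x pathway), within each experiment:
`delta = logEC50(reference agonist) - logEC50(agonist)` per pathway,
then `delta_delta = delta(reference pathway) - delta(test pathway)`.
The reference agonist is identically zero; swapping the pathways flips
the sign. Because agonists are run in parallel in the same experiment
on the same dilutions, the subtraction is done within experiment and
summarized as mean ± SEM over experiments with no error propagation.
The sign convention is recorded in the result object's `convention`
field rather than assumed.

**Membrane profiles.** Time-lapse surface-signal kinetics reduce each
frame's membrane line profiles to the mean of per-segment peak
intensities, normalized to time 0, with the above-baseline AUC as the
summary.

## Reproducibility and problem sizes

Every stochastic routine takes an explicit seed (or NumPy Generator);
identical seed means bitwise-identical output, which the tests assert
for every generator and for the Monte-Carlo null. The test suite and
`scripts/acceptance.py` use cohorts of 300–800 trajectories of 150
frames, ensembles of 2,000 trajectories for the fBm MSD consistency
check, point patterns up to n = 2,000 for oracle equivalence, and
150–200 replicates for Monte-Carlo calibration and fit-bias studies —
sizes chosen so each recovery estimate has a sampling error comfortably
below the tolerance being asserted while the whole suite runs in about
a minute.

## Known limitations

- The motion stage consumes trajectories; detection and linking from
  raw movies are out of scope, as are hidden-Markov or Bayesian
  per-step classifiers and 3D diffusion.
- fBm is an adequacy assumption, not a mechanistic claim; confinement
  radius, hop length and binding kinetics are not identifiable from the
  TA-MSD power law alone.
- NND is reported without edge correction; for small windows at low
  density the raw mean NND is biased upward relative to the infinite-
  plane closed form (the toroidal option exists for calibration, not
  analysis).
- Oligomer counting does not model fluorophore blinking kinetics beyond
  the fixed deduplication radius; counts are association-radius
  neighborhoods, not photophysically corrected stoichiometries.
- Bias estimates are relative-potency (delta-delta logEC50) only;
  operational-model transduction coefficients are out of scope.
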