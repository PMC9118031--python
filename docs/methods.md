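# Methods

This note documents the models and procedures implemented in
`bearrhythms`, the assumptions behind them, the defaults that matter, and
what the synthetic test bed does and does not establish about real data.

## Seasonal segmentation

Den phenology is operationalised through sustained daily-mean body
temperature (Tb) thresholds: den entry is the first day of a run of seven
observed daily means ≤ 36.4 °C, den exit the first day of a run of seven
observed daily means ≥ 36.7 °C.  Two choices deserve note:

* **Search windows.** "Autumn" and "spring" are bounded as Aug 1 – Jan 31
  and Feb 1 – Jul 31 (configurable).  When segmentation runs through
  `build_state_map`, the exit search additionally starts after the
  detected entry, so a warm spell in the spring a record begins in cannot
  masquerade as den exit.
* **Missing days break runs.** A day with no samples cannot satisfy the
  threshold condition; runs are never bridged by imputation, because the
  definition requires seven *observed* daily means.

Transition states get per-variable extents because the seasonal drift
starts at different leads: defaults are (pre-entry, post-entry, pre-exit,
post-exit) = (13, 30, 33, 0) days for Tb, (24, 30, 63, 0) for HR and
(25, 9, 10, 0) for activity.  The pre-entry and pre-exit leads are
field-established values; the post-entry extent for HR and all post-exit
extents are package defaults and are exposed in configuration.  State
intervals are half-open day ranges; overlapping transitions (a short
hibernation) are truncated at their midpoint with a logged warning, after
which the entry transition always ends no later than the exit transition
begins.

## Windowing

Rhythm detection needs roughly ten cycles of the longest diel period, so
each state is tiled into consecutive 25-day windows from the state start;
a terminal remainder is kept iff it spans ≥ 15 days (merging it backward
would exceed the 25-day maximum, so remainders are dropped instead).  A
window is discarded when the time between consecutive retained samples —
or between a window boundary and the nearest sample — exceeds 48 h, or
when fewer than 8 samples remain.  The "season" grouping factor is the
calendar year of the window start for active windows and the den-entry
year for hibernation and transition windows, so one winter forms one
season despite spanning the year boundary.

## Lomb-Scargle rhythm detection

The classical normalized periodogram is computed on mean-centered values
with the phase origin τ chosen per frequency so the sine and cosine terms
decouple; the power at each frequency equals the least-squares reduction
from fitting a sinusoid there, scaled by twice the sample variance.  Two
independent routes verify the implementation: a brute-force least-squares
fit (relative agreement 1e-8 on random uneven designs) and
`scipy.signal.lombscargle` (1e-6).

* **Grid.** Frequencies are evenly spaced with step 1/(oversampling ×
  window length) and truncated to the 2–168 h band, endpoints bracketing
  it.  Oversampling defaults to 4, which resolves peak locations to a
  fraction of the natural Fourier spacing without excessive cost; tests
  and guarantees are stated at grid-step resolution.
* **Significance.** The classification default is Baluev's aliasing-free
  false-alarm bound p = 1 − (1 − e^(−z)) exp(−τ(z)) with
  τ(z) = W√z·e^(−z) and W = (f_hi − f_lo)·√(4π·var(t)).  The plain
  independent-frequency formula p = 1 − (1 − e^(−z))^M with M the
  un-oversampled band count is also provided, but simulation shows it
  understates the false-alarm rate of an oversampled band maximum
  (≈ 2.6% rejections at nominal α = 0.01 versus 0.5–1% for Baluev): the
  continuous maximum has a larger effective multiplicity than the Fourier
  count.  α defaults to 0.01, matching the convention of the periodogram
  software this analysis style is usually run with; both α and the method
  are configurable.
* **Bands.** Ultradian [2, 18) h, diel [18, 36) h, infradian [36, 168] h,
  half-open at the boundaries (a peak at exactly 18 h is diel).  Only the
  highest peak is classified; a non-significant peak yields "arrhythmic"
  with the peak period still reported.  Periods below 2 h are not
  searched even at 2-min HR cadence.

## Covariates

Day length uses the Forsythe solar-declination model with the 0.8333°
sun-elevation offset (atmospheric refraction plus solar half-diameter),
verified against an independent reference implementation to 1e-6 hours.
Sunrise/sunset for plot overlays derive from the same declination plus
Spencer's equation of time, so (sunset − sunrise) matches the day-length
covariate by construction.  Day-length direction is the endpoint-to-
endpoint sign over the window, ties called "increasing".

Weather is interpolated to the bear's location (den coordinates during
hibernation and transitions, home-range coordinates otherwise; den
relocations switch coordinates from their recorded date) by
inverse-distance weighting over the k = 3 nearest stations with power 2
and great-circle distances — conventional defaults, as the method itself
does not fix them.  A target within 1 m of a station receives that
station's values exactly.  Environmental covariates are arithmetic means
over the window's days; windows with missing covariates are dropped by
the model stage.

## Multinomial rhythm-probability models

The per-window rhythm class is modelled with multinomial logistic
regression fitted by penalized maximum likelihood, a deterministic
analogue of the Bayesian mixed-model formulation this analysis is usually
run with: ridge-penalized group indicators (bear, season) play the role
of flat-prior random intercepts at their posterior mode, and grouped
K-fold cross-validated elpd replaces PSIS-LOO.  Smooth terms use
Eilers–Marx P-splines — a uniform (unclamped) cubic B-spline basis with a
second-order difference penalty — rather than literal thin-plate
splines: the penalty null space is exactly the straight line, so heavy
smoothing shrinks a smooth term to a linear effect, which is the
behaviour that matters for model comparison.  A sum-to-zero constraint is
absorbed into each basis for identifiability.

* The objective is the mean negative log-likelihood plus ½λβᵀSβ per
  smooth and ½ρ‖β‖² for group blocks (ρ = 1 by default); penalties are
  not rescaled with n, so duplicating every row leaves estimates
  unchanged.  Full Newton iterations with backtracking converge to
  gradient norms far below the documented 1e-6 criterion; a coefficient
  norm exceeding 50 flags (quasi-)separation or an empty class, with a
  warning.
* λ is selected on the grid {0.01, 0.1, 1, 10, 100} by internal
  cross-validated predictive density when a spec contains smooths.
* The reference class is "diel" when present (the most frequent class in
  this setting); standard errors come from the observed information.
* Cross-validation folds keep all windows of one bear together
  (approximating the leave-one-group-out structure implied by group
  effects), default 10 folds; the elpd standard error is √(n·var) of the
  pointwise values.  Folds whose training part lacks a class are fitted
  anyway and pay for it on the held-out side.
* Stacking maximizes Σᵢ log Σₘ wₘ pₘᵢ over the simplex (concave; solved
  deterministically from the uniform start); models with identical
  held-out predictions share their weight equally.  `compare_models`
  stacks the models within 4 elpd of the best, mirroring the usual
  near-tie convention.
* The a-priori candidate sets (15 hibernation models over snow depth, day
  length, ambient temperature, den attributes and intrinsic predictors;
  13 active-state models including the day-length × direction
  interaction) are constructible by name via `candidate_models`.

## Synthetic test bed

The generator emulates the structure of bear biologging records: Tb every
5–30 min (default 20), HR 2-min means, activity 5-min bi-axial sums in
[0, 510]; diel (24 h) + ultradian (12 h) oscillation during the active
season, a multiday component (default 120 h) at a depressed mean during
hibernation, linear daily-mean drifts through the transitions anchored so
the Tb thresholds are crossed exactly on the configured den dates, AR(1)
measurement noise (default coefficient 0.8), and gaps of 14/3 days after
captures/disturbances.  Activity keeps a small 24 h component (5 counts)
in the den, so the empirically observed persistence of diel activity
during hibernation is reproducible as a scenario rather than an artefact.
Default state means (Tb 37.3/34.5 °C, HR 70/15 bpm) and amplitudes are
plausible round numbers for this species, not measured values — no public
dataset pins them.  Weather tables place mean ambient temperature within
−15.4–19.1 °C and snow depth within 0–0.63 m (zero June–September),
matching the study area's reported ranges.

Because the active-season oscillations average to zero over a full day at
cadences dividing 24 h, daily means follow the planted trajectory
exactly: with zero noise every detector recovers ground truth exactly,
and at 0.2 °C white noise den dates are recovered within ±1 day (the
threshold day itself sits exactly on the threshold, so a one-day slip is
the expected boundary behaviour).

What passing these tests does **not** show: real Tb traces are not
piecewise-linear-plus-sinusoid, transitions are not linear, rhythm
periods drift within windows, and real noise is neither stationary nor
Gaussian.  The synthetic cohort validates the *machinery* — detection
thresholds, tiling arithmetic, periodogram correctness, calibration,
model recovery — not the biological conclusions drawn from any particular
field dataset.

## Problem sizes and numerical choices

Simulation-based checks run at desk scale by design: 20 random designs
for oracle equivalence, 200 windows per rhythm class for recovery, 2000
noise windows for calibration, 50 bear-years for phenology, and 10–20
cohorts of n = 2000 for model recovery.  Timestamps are stored in a fixed
UTC+1 civil time zone (the study region, no DST).  All tabular I/O is
plain CSV; every pipeline output records the configuration hash and seed,
and identical configuration plus seed reproduces outputs byte for byte.

## Known limitations

* No MCMC and hence no posterior credible intervals; uncertainty comes
  from observed-information standard errors and cross-validation.
* Only the highest periodogram peak is classified; simultaneous rhythms
  (a true 24 h + 12 h mixture) are reported by their stronger component.
* No kriging, variogram fitting or elevation correction for weather; no
  GPS movement analysis or den-microclimate modelling.
* The day-length model saturates at |latitude| ≳ 66°; polar records would
  need a different formulation.
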