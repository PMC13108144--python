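# Methods

This note documents the models, the synthetic world the package is
tested against, the numerical choices, and the limitations a user
should know before trusting a green test suite.

## Uptake models

Intracellular drug accumulation is described empirically, not
mechanistically. The normalized fluorescence f(t) follows either

* one saturating exponential, f = P(1 − e^(−Qt)), plateau P
  (dimensionless normalized fluorescence), rate Q (s⁻¹); or
* the sum of two, f = A(1 − e^(−Bt)) + C(1 − e^(−Dt)), plateau A + C,
  stored fast-rate-first (B ≥ D).

Both force f(0) = 0: time zero is drug introduction (re-zeroed per
phase in two-phase experiments). Non-negative amplitudes and positive
rates make every model curve monotone non-decreasing. No efflux
(washout) phase is modelled, and no transport mechanism is assigned to
either component; the second component is simply what resistant cells
empirically require.

Derived quantities: plateau (P or A + C), half-time to plateau
(ln 2 / Q in closed form; root-bracketing on the monotone curve for two
components), and the per-component plateau shares A/(A+C), C/(A+C).

## Fitting

Bounded trust-region least squares (`scipy.optimize.least_squares`,
TRF, analytic Jacobian), amplitudes ≥ 0 and rates > 0, tolerances 1e-10,
with multi-start initialization by variable projection: rates are
surveyed on a log-spaced grid spanning sub-resolvable (0.1/span) to
super-Nyquist (2/Δt) scales, amplitudes are solved by non-negative
linear least squares at each fixed rate (pair), and the best starts are
refined. One two-exponential start is always seeded from the
one-exponential solution, which guarantees the nested model never ends
with a larger residual sum of squares. If TRF exhausts its iteration
budget (a flat valley when the second component is vestigial, or an
ill-conditioned crawl when the two rates nearly coincide), it is
restarted from the stall point up to six times — restarting resets the
trust region and reliably finishes the descent; this is what makes
near-degenerate published rows (rates 2e-4 vs 3e-4 over a 3000 s
window) recoverable to machine precision from noiseless data.

A fitted rate pair agreeing within 5% is reported as the
one-exponential reduction with a `rate-collapse` flag, since the
two-component model is unidentifiable there. Goodness of fit R is the
Pearson correlation between observed and fitted values; R² variants
are deliberately out of scope.

## Model selection

The extra-sum-of-squares F-test compares the nested pair:
F = ((RSS₁ − RSS₂)/2)/(RSS₂/(n − 4)), upper tail of F(2, n − 4),
default α = 0.05. Two numerical points matter:

* RSS₂ for the test comes from an *unconstrained-amplitude* refit
  (rates stay positive). The F reference distribution assumes
  unconstrained nested least squares; with the physical C ≥ 0 bound
  the statistic is clamped at zero in roughly half the null replicates
  and the measured type-I error fell to ~0.01. With the unconstrained
  RSS₂ it measures ~0.03 at α = 0.05 — still slightly conservative,
  because the slow rate D is unidentified under the null (the classic
  unidentified-nuisance-parameter situation), which no choice of RSS
  can fully repair. Reported parameters always come from the bounded
  fit.
* A perfect two-exponential fit (noiseless synthetic input) makes F
  undefined; the richer model is then selected with p = 0 and a
  `degenerate-perfect-fit` flag — unless the simple model is *also*
  numerically perfect, in which case parsimony keeps it
  (`degenerate-both-perfect`).

The test assumes independent homoscedastic residuals. Duty-cycle
sampling induces autocorrelation in real traces; this is ignored, and
on fully processed (rather than directly simulated) noisy traces the
test can be anti-conservative. Known limitation.

## Trace processing

Peak/valley segmentation labels a sample peak when it exceeds the
midpoint of the rolling 10th/90th percentiles (window: five
peak/valley periods). Two refinements proved necessary to make the
noiseless generator→processing round trip exact (< 1e-9):

* Baseline knots (per-valley-run medians) are screened by a local
  Theil–Sen consistency check: a knot sitting above the robust line
  through its neighbours is contaminated by uptake signal (at very
  early exposure f(t) ≈ 0, so the first peak half-period is
  mislabelled valley) and is dropped. Contamination is always upward,
  so the rejection is one-sided and survives background drift.
* After a first baseline pass, samples are reclassified against the
  baseline itself (peak iff the excess exceeds max(5σ̂, 10⁻⁶·scale)),
  and the baseline is re-estimated from the refined labels.

The baseline interpolates linearly between surviving knots and
extrapolates *linearly* (outermost knot slope) beyond them — flat end
extrapolation cannot reproduce a drifting background at the trace ends.
Exactness holds for backgrounds linear between valley segments; a
background with a sharp apex between two valleys would be rounded off.

Spikes are removed with a Hampel filter: a sample deviating from its
centered 7-sample window median by more than 6 × 1.4826 × MAD (MAD of
the same window) is replaced by that median. Locally monotone noiseless
series are exact fixed points, and the filter is idempotent. The
half-window at each trace end is left untested. With Gaussian noise and
no true spikes, the 7-sample MAD occasionally underestimates spread,
so ~1% of samples may be falsely replaced by their local median; the
induced bias is far below the noise level.

Normalization divides by the extracellular DNR fluorescence step
(known for synthetic traces, user-supplied otherwise). When absent, a
logged fallback scales by the mean early-exposure signal — documented
as approximate, never silent.

## Synthetic world

The generator emulates the stated experimental conditions: 1 s sampling
over 3000 s (plateaus of the published rate constants are reached
within ~2000–3000 s), a 60 s window-crossing period with 50% duty
(the alternation mechanism was not quantified; a fixed square duty
cycle is a convention), background 100 a.u. with optional linear
drift, additive Gaussian noise, Poisson-timed single-sample positive
spikes, and a normalization step of 100 a.u. Cohort heterogeneity is
lognormal per parameter — (median, geometric CV), σ = ln(1 + gcv) —
matching the positivity and right skew of the published single-cell
spreads; cohort draws use per-cell spawned seeds, so the drawn
parameter multiset depends only on the cohort seed.

What the generator does *not* emulate: photobleaching, focus drift,
cell movement other than the fixed duty cycle, detector nonlinearity,
multiplicative noise, and any efflux phase. A green round-trip test
therefore establishes correctness of the pipeline's arithmetic and
statistics under the stated noise model, not robustness to every
artifact of real recordings.

## SASCA / DISCA

Two-phase traces are split at the metadata-supplied switch time
(changepoint detection is out of scope). Phase 2 is re-zeroed in time
and offset-subtracted by the phase-1 fitted *level at the switch* —
identical to the phase-1 plateau when the switch happens at steady
state, as the protocol intends, but unbiased when phase 1 has not
quite saturated (plateau subtraction leaves a ~0.7% offset for
cell-58-like kinetics switched at ~1000 s and biases the rate fold by
~2%). Phase-2 parameters are therefore *incremental*. Because the
published same-cell table does not state which convention its
inhibitor-phase plateau uses, both plateau folds are reported:
incremental (A+C)₂/(A+C)₁ and cumulative ((A+C)₁+(A+C)₂)/(A+C)₁. For
cell 58 these give 0.60 and 1.60 — neither equals the originally
reported ~1.4-fold plateau increase, a discrepancy we record rather
than resolve. The fast-rate fold 0.0973/0.0556 = 1.750 is unambiguous.

Cross-cell (DISCA) summaries report per-group parameter ranges, range
overlap, and a two-sided Mann–Whitney rank test as a descriptive
statistic (the group sizes involved, 20 vs 4, do not support more).

## Tunable parameters (defaults)

| parameter | default | why |
|---|---|---|
| sample interval | 1 s | convention; acquisition rate not reported |
| duration | 3000 s | plateau reached for published rates |
| window period / duty | 60 s / 0.5 | convention; mechanism not quantified |
| segmentation window | 5 periods | local enough to track the uptake rise |
| spike window / k | 7 / 6 | Hampel defaults; no rule was stated |
| baseline knot rejection | 6 × 1.4826 × MAD, one-sided | contamination is upward |
| selection α | 0.05 | conventional; threshold not stated |
| rate-collapse guard | 5% | below it Eq-level identifiability is gone |
| fit tolerances | 1e-10, ≤ 800 evals/start, ≤ 6 restarts | machine-precision noiseless recovery at acceptable cost |

## Limitations

* The F-test calibration is approximate (see above); selection
  frequencies, not exact p-values, are the tested contract.
* Baseline exactness assumes the background is piecewise linear
  between valley segments.
* The normalization fallback makes f comparable only up to a scale
  factor; fitted rates are unaffected (the model is scale-equivariant).
* Parameters of near-coincident rate pairs are reported only through
  the collapse guard; no confidence intervals are computed anywhere.
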