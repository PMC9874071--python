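# Methods

This note documents the models, numerical choices and limitations of
the package; it is the place where open design questions are settled
and justified.

## Response measures

Spikes are counted in a half-open response window, by default
[70, 270) ms after tone onset — 200 ms starting after the 50 ms
stimulus on-ramp plus response latency.  Half-open windows guarantee a
spike is never double-counted by adjacent windows.

The spontaneous baseline is the 200 ms immediately preceding each tone
onset, pooled over all trials of a phase.  Protocols that describe the
baseline only as "inter-stimulus activity" leave the exact window open;
an equal-length pre-stimulus window is the least biased choice because
it matches the response window's count statistics, and the window
bounds are configurable where a different convention is needed.
Z-scores are computed per phase with that phase's own baseline: pairing
can change spontaneous firing, and the z-score is defined against the
same condition's baseline.

Normalization divides a unit's mean counts by the unit's single largest
mean count taken *jointly* over the pre- and post-pairing maps.  A
per-phase maximum would force both phases to peak at 1 and erase any
post-pairing amplitude change; the joint convention keeps amplitude
changes expressible while bounding values in [0, 1].

## Tuning model

The tuning curve is a four-parameter Gaussian on the octave axis
x = log2(f/1 kHz):

    r(x) = offset + gain · exp(−½((x − μ)/σ)²)

The octave axis is the only self-consistent choice when widths and BF
shifts are reported in octaves: a Gaussian symmetric in octaves has a
well-defined FWHM in octaves (2√(2 ln 2)·σ) at every BF.  The
normalized-density form 1/(σ√2π)·exp(·) cannot represent an independent
offset and peak height, so the prefactor is absorbed into `gain`; the
four reported quantities are offset, gain (Rmax), BF and FWHM.

Constraints:

* **A** — BF within the tested frequency range.
* **B** — tuning width above a floor of 0.0235 octaves.  The floor is
  applied to the FWHM because "tuning width" is reported as FWHM
  throughout; applying it to σ instead (a ~2.35× stricter floor) is
  available via `floor_on="sigma"`.
* **C** — peak (offset + gain) at most 1.5× the measured profile
  maximum.  The cap presumes a positive maximum; on an (unrealistic)
  all-negative z-score profile it is vacuous.  The maximum is the
  per-phase profile maximum; a per-session variant would couple the two
  phases' fits and is intentionally not the default.
* **D** — offset ≥ 0 for non-negative scales (spike counts cannot be
  negative); for z-scored profiles, offset within 50% of the profile
  minimum.

### Optimization

The fit minimizes squared error with Nelder–Mead in a smoothly
reparameterized space: μ and offset are logistic-squashed into their
bounds, σ is an exponential above its floor, and gain is a logistic
share of the remaining peak headroom (cap − offset).  Every iterate is
therefore feasible and the returned parameters satisfy A–D by
construction — no penalty terms, clamping or post-hoc projection are
needed, which keeps the objective smooth and the constraint logic
auditable in one place.

Seven restarts are seeded from the empirical profile peak and at
±0.25, ±0.5 and ±0.75 octaves around it (starting width 0.5 octaves,
starting offset/gain from the profile minimum and range).  The restart
with the best VAF wins; near-exact ties go to the narrower width, which
makes degenerate single-point profiles deterministic.  Stopping
tolerances are xatol 3·10⁻⁴ (transformed scale), fatol 10⁻⁶, 300
iterations per restart — on noiseless profiles this recovers parameters
to ~10⁻⁵, far inside the 10⁻³ documented guarantee, and on Poisson data
the residual optimizer error is negligible against sampling noise.

Degenerate inputs are rejected rather than guessed at: profiles with
fewer than 5 points, non-finite values, or zero variance (VAF is
undefined there).  VAF is 1 − SS_res/SS_tot, clipped below at zero for
reporting; the formula is the standard one, adopted because published
analyses cite it without restating it.

## Group inference

The design is phase (pre/post, within-unit) × drug × pairing side
(between-unit).  With exactly two within levels the classical mixed
(split-plot) ANOVA decomposes exactly into two effect-coded OLS
problems: per-unit phase means carry the between effects, per-unit
pre−post differences carry the within effects (the difference-model
intercept is the phase main effect).  Type-III single-df F statistics
are the squared coefficient t's; partial η² uses each stratum's own
error SS.  The test suite verifies this equals the textbook
sums-of-squares decomposition on balanced tables and statsmodels'
Type-III OLS ANOVA on unbalanced ones.  A generalized linear mixed
model with a single per-unit random intercept followed by an ANOVA
agrees with this decomposition on this design; the classical route is
used because it is exact, dependency-light and fast enough for
Monte-Carlo calibration.

Pairing side is classified from the *fitted pre-pairing BF*: "above"
iff the conditioning tone is above it.  A tone exactly at the BF has no
side; such units are excluded and logged, never silently assigned.

Post-hocs per parameter form a fixed 16-comparison family: paired
pre/post tests pooled by drug (2) and by side (2), their between-group
difference-of-differences companions (2), the four per-cell paired
tests, and the six cell-pair difference comparisons.  The difference
convention is diff = mean(pre) − mean(post), so a post-pairing increase
prints negative.  Cohen's Dz (= t/√n) is used for paired tests, Cohen's
D with pooled SD for independent ones; 95% CIs use the t distribution
at the test's df.  BH-FDR is applied within each parameter's family —
the natural unit of simultaneous inference here, since parameters are
reported separately.  Printed df in the source literature for this
design are occasionally inconsistent with the stated cell sizes;
standard df (n−1 paired; n_a+n_b−2 independent) are used throughout.

## Population curves

Fitted curves: each included unit's Gaussian is evaluated on a common
−2…+2 octave grid (0.05 steps, spanning the plotted range at smooth
resolution) centred on that unit's pre-pairing BF, then averaged with
SEM = SD/√n.  The pre-phase curve peaks at 0 by construction.

Unfitted curves bypass the model: the intensity-averaged normalized
profile is shifted so its pre-pairing argmax (ties broken toward the
lower frequency, for determinism) sits at step 0 on the quarter-octave
axis.  Averaging truncates to steps where at least half the units
contribute — shifting necessarily misaligns profile edges, and
truncation avoids edge artifacts without inventing data by
interpolation; per-step contribution counts are emitted.  Paired
t-tests on the unfitted BF (in grid steps) and on the normalized peak
amplitude test for post-pairing changes without the fit in the loop.
When every unit's pre and post profiles are exactly identical the
difference scores have zero variance and the paired t is undefined
(0/0); the tests reject this degenerate input rather than reporting
t = 0.  A no-VAF-filter variant of the unfitted analysis is available
by marking all units included.

## Synthetic experiments

Each simulated unit fires as an inhomogeneous Poisson process with

    rate(f, I) = spont + s_I · (offset_rate + gain_rate · exp(−½((x − bf)/σ)²))

counted over 200 ms windows; spontaneous counts are Poisson at the
baseline rate.  Poisson spiking is the minimal noise model consistent
with spike counts, and the z-score stage is insensitive to its exact
form.  Intensity enters as a non-decreasing multiplicative scale
(0.55/0.70/0.85/1.00 for 50–80 dB SPL) — a monotone level dependence
without modelling rate-level functions, which the analysis collapses
anyway.

Default cohort geometry is the study design: 21 quarter-octave
frequencies × 4 intensities × 10 blocks, cells of 20/17/15/14 units
(echoing 37 drug + 29 vehicle included units without claiming the exact
cell split), conditioning tone snapped to the grid frequency nearest
0.5 octaves from the true BF on the assigned side.  Per-unit truths:
BF uniform on the interior grid (1 octave margin), σ lognormal (median
0.35 oct ⇒ median FWHM ≈ 0.8 oct), peak gain ~Gamma(10, 5) spikes/s,
tuning floor ~Gamma(2, 1.5), spontaneous rate ~Gamma(5, 1) — typical
awake-cortex orders of magnitude giving peak z-scores around 5–10 and
VAFs mostly above 0.9.  The default pairing effect is −0.4 octaves BF
and +0.12 octaves FWHM in the tPA/above cell only, the
repulsion-plus-widening pattern the pipeline exists to detect; all
other cells are null.

Randomness uses a master seed with per-unit derived substreams
(`default_rng([seed, unit_index, phase])`), so changing one unit never
perturbs another and appending blocks never reshuffles earlier ones.

What the generator does *not* emulate: rate-level non-monotonicity,
inhibitory sidebands and asymmetric tuning skirts, non-Poisson count
dispersion, slow drift or adaptation across blocks, and correlated
noise between units.  Passing recovery tests therefore demonstrate
correctness of the estimation machinery under the stated generative
assumptions, not robustness to every pathology of real recordings.

## Problem sizes used in the checks

The heavy verification jobs run at deliberately chosen scales: ANOVA
type-I calibration uses 2,000 parameter-level null cohorts at the
default cell sizes (no spike simulation — the ANOVA consumes fitted
parameters, so calibrating at the parameter level is exact and cheap);
end-to-end effect recovery uses 100 replicates with 8 units in the
effect cell and 3 elsewhere at the full 10-block trial count, a design
chosen so the binding power constraint (the FWHM paired test,
Dz ≈ 1.6 per unit at this trial count) retains >95% power while the
whole check stays desk-scale.

## Known limitations

* The Gaussian is symmetric in octaves; strongly skewed tuning curves
  are summarized by their best symmetric approximation and may fail the
  VAF criterion.
* Constraint C couples offset and gain through the shared peak cap, so
  on profiles whose maximum is barely positive the feasible gain range
  is small and fits will look flat.
* The mixed ANOVA assumes one observation per unit × phase (the fitted
  parameter); trial-level variance is not propagated into the
  group-level inference, matching the two-stage summary-statistics
  approach it implements.
* The CLI `stats` subcommand classifies side from the fits table alone;
  pairing-tie exclusions there are silent in the output tables (they
  are logged in the all-in-one `run` manifest).
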