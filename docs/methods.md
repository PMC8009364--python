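# Methods

This note records the modelling choices behind `chronocollide`, the
reasoning for its defaults, and what its tests do and do not establish.

## Reference frame and ephemeris

All computations use a single reference point (default 47.85° N, 16.52° E,
zone Europe/Vienna — Eisenstadt, the capital of the Burgenland study
region) and police-reported **local civil time** including DST. Accident
registers record wall-clock times, so sunrise/sunset are converted into
the same scale rather than the reverse; across a region of ~0°5′
east–west extent the event-time lag is well under a minute and a single
reference point suffices.

**Solar events.** Sunrise/sunset come from the standard solar-position
formulation: fractional year → equation of time and solar declination →
hour angle at zenith 90.833° (34′ refraction + 16′ semidiameter), iterated
twice for the event hour. This is the accuracy class (≈1 min) of the
almanac calculators practitioners use; the test suite bounds the error
against an independent ecliptic-longitude/sidereal-time implementation at
≤ 3 minutes over all 1,826 study days. Latitudes beyond ±66° are rejected:
the analysis presumes every date has a sunrise and sunset.

**Lunar age.** A mean-synodic model: age = (UTC − anchor new moon
2000-01-06 18:14 UTC) mod 29.53 d, and moon day = ⌊age⌋ + 1, so the
full-moon center (age 14.765 d) always falls inside day 15. True phases
drift up to ±0.6 d around the mean cycle; at the day resolution of the
moon-day classification this is immaterial (catalogued full-moon instants
land on days 14–16), and it is the same construction the original
annotation tools used. No topocentric correction or illuminated fraction
is computed.

**Seasons.** Astronomical season boundaries are the actual equinox and
solstice instants per year, from the classical mean-phenomena polynomials
with the 24-term periodic correction (minute-level accuracy; TT−UT is
ignored as negligible at day resolution). Intervals are half-open at day
resolution in local time: the boundary date belongs to the season that
begins on it. The alternative (boundary day closes the old season) moves
at most a handful of records per year between adjacent seasons.

## Classification

Illumination windows per date, all half-open and left-closed:
NbD = [00:00, sunrise−40′), DA = [sunrise−40′, sunrise), DL = [sunrise,
sunset), DU = [sunset, sunset+40′), NaD = [sunset+40′, 24:00). The
40-minute operational twilight is a configuration parameter
(`twilight_minutes`). A record at exactly sunrise is daylight and at
exactly sunset is dusk; the convention matters only for minute-exact
boundary records. LR3 is the deterministic collapse NI = {NbD, NaD},
TW = {DA, DU}.

Records with a date but no clock time are kept for date-level analyses
(season, month, weekday, day of year, moon day — the moon day is taken at
local noon, where the age error across a day is < 0.04 d) but excluded,
and counted, in illumination tables.

Day of year is put on a fixed 1..365 axis by merging Feb 29 into day 59;
this avoids a cyclic-design column supported by a single observation in
one year out of five.

Moon day 30 is a partial cell: the synodic month is 29.53 d, so day 30
exists for only 0.53 d per cycle and collects systematically few events.
It is removed (default `drop_moon_day_30`) before smoothing; leaving it in
would manufacture a sharp artificial dip at the cycle seam.

## Linear models on yearly proportions

The unit of replication is the **year**: each category's within-year
proportion is one observation, giving k × 5 responses in a balanced
one-way layout. OLS with successive-difference coding estimates adjacent
category differences directly (and forces the intercept to the grand mean
of category means — exactly 1/k for proportions, which the tests exploit
as an arithmetic identity); treatment coding re-expresses the same fit
against a reference category. The codings span the same column space, so
fitted values, residuals and R² are identical — an invariance the suite
checks. Proportions within a year are weakly negatively correlated by
construction (they sum to 1); the models treat them as independent, as is
conventional for this descriptive use.

Tukey HSD uses the one-way residual mean square with k groups and k(r−1)
degrees of freedom and the studentized-range distribution; letters come
from the insert-and-absorb algorithm (groups sharing a letter are not
significantly different at α = 0.05, an equivalence the suite verifies
pair by pair). With zero residual variance the adjusted p is reported as
0 for unequal pairs. Residual normality is checked by Shapiro–Wilk
(3 ≤ n ≤ 5000).

## Cyclic spline smoothers

Responses are **counts per (year × cell)** — day-of-year cells 1..365
(1,825 observations over five years) and moon-day cells 1..29 (145
observations) — fitted with a Gaussian likelihood. At these cell counts
(means of roughly 6–80 events) the normal approximation to the count
distribution is adequate, and a Gaussian fit keeps GCV, edf and the
deviance decomposition elementary.

The basis is a cyclic cubic regression spline in the value/second-
derivative parameterization: k nominal basis functions = k−1 distinct
evenly spaced knots whose wrap-around continuity (value, first, second
derivative) yields a cyclic tridiagonal system; the penalty is the exact
integrated squared second derivative, with constants in its null space.
A sum-to-zero constraint over the observed covariate values identifies
the smooth against the intercept, leaving k−2 free coefficients — with
the default k = 10, a reference df of 8. Smoothness λ is selected by GCV,
n·RSS/(n − tr A)², minimized on a 121-point log grid spanning 24 decades
around the design's largest singular value, then refined by golden
section. The fit is computed through an SVD reparameterization that makes
the penalty the identity, so each λ costs O(p) once the decomposition is
done.

Numerical edge cases: λ = 0 with as many knot-located observations as
free parameters reproduces the interpolating periodic spline (RSS = 0 to
machine precision); λ → ∞ collapses to the intercept-only fit (edf 0,
deviance explained 0); a constant response is fitted exactly without
failure. On shared data with shared knots the whole stack — edf, deviance
explained, fitted curve — agrees with R `mgcv`'s `gam(y ~ s(x, bs="cc"))`
to about 10⁻⁶, which the suite asserts via `Rscript`.

Uncertainty bands are pointwise ±1.96 SE from the Bayesian posterior
covariance (B′B + λS)⁻¹σ̂² of the penalized coefficients. The
**horizontal-line test** declares the cycle non-flat when no constant
fits inside the bands on a 200-point grid (max lower > min upper); it is
the graphical test used in applied GAM work. The smooth term's
significance is additionally summarized by an F-type statistic
((TSS−RSS)/edf)/(RSS/(n−1−edf)); this is an approximation — no attempt is
made to reproduce any particular package's hybrid reference-df test, and
the statistic is labelled as what it is.

## Synthetic generator

The generator draws an inhomogeneous Poisson process over the study years
with intensity `base · month(t) · weekday(t) · diel(t) · lunar(t)`,
sampled by thinning against the constant envelope (inversion has no
closed form because the diel factor follows each date's actual
sunrise/sunset — the generator and the classifier deliberately share one
solar geometry, which lets the tests compare classified shares against
numerically integrated intensity shares).

Default conditions emulate the study region's published record: ~6.45
events/day (≈11,770 over five years, 2,000–2,600 per year), monthly
multipliers proportional to the published monthly shares (November/May/
October peaks), weekday multipliers with the Friday peak, illumination
multipliers that put roughly half of events at night with dusk denser
than dawn (NbD 1.4, DA 6.6, DL 1.0, DU 9.4, NaD 3.7 before
time-weighted normalization), and a lunar modulation
1 + a·cos(2π(age − 14.765)/29.53) with a = 0.2 by default (a moderate
full-moon excess; recovery experiments use a = 0.5). Each multiplier set
is normalized to a time-weighted mean of one, so `base_daily_rate` is the
expected daily count. Resemblance to the published marginals, not
equality, is the goal; realized proportions are emergent.

What the generator does **not** emulate: spatial structure, traffic
volume, weather, reporting-rate drift across years, within-window diel
gradients (the diel factor is piecewise constant per illumination
window), and any interaction between factors (the intensity is a pure
product). Passing recovery tests therefore demonstrate that the pipeline
detects multiplicative temporal structure of realistic magnitude in
realistic volumes — not that real accident data meet these assumptions.

## Problem sizes in the tests

The suite runs the full five-year default volume (~11,700 records)
through annotation, tables, models and smoothers; the parameter-recovery
battery uses 20 replicates at that volume; pipeline-level tests use a
two-year, 4 events/day configuration to keep file-system round-trips
quick. The ephemeris cross-check covers every study day (1,826 dates).

## Known limitations

* The mean-synodic moon model is a phase clock, not an ephemeris; studies
  needing true full-moon instants (±7 h) should substitute one.
* The report-rate comparison treats hunting-bag losses as a complete
  reference (the convention of the underlying registers), which is itself
  an approximation.
* Proportion-scale OLS ignores the sum-to-one constraint's covariance and
  any year-level autocorrelation.
* GCV can undersmooth short, noisy cycles; λ can be fixed manually where
  that matters.
* The deposited five-year study dataset cannot ship with the package, so
  the two tests that reproduce its printed statistics require the user to
  supply `data/s1_records.csv`; all other tests are self-contained.
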