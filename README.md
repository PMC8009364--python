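# chronocollide

Temporal analysis of deer–vehicle accidents (DVAs) from timestamped
police-report records.

Wildlife–vehicle collisions, and roe deer (*Capreolus capreolus*)
collisions in particular, cluster in time: around dusk and dawn, on
particular weekdays, in the rutting and hunting seasons, and — more
controversially — around full moon. Quantifying those patterns from
accident registers requires annotating each record with the solar and
lunar state at the accident instant, and then fitting models that respect
the circular nature of the time axes. `chronocollide` packages that whole
workflow for anyone working with dated, clocked roadkill records:
wildlife-management researchers, road-safety analysts and hunting
authorities.

## What it computes

Each accident record (calendar date, local clock time) is annotated at a
configurable reference point (default: Eisenstadt, Austria, 47.85° N
16.52° E, zone Europe/Vienna) with:

* **sunrise/sunset** (standard solar-position algorithm, ≈1-minute
  accuracy) and the derived **illumination category** — coarse
  LR3 (NI night / DL daylight / TW twilight) and fine LR5 (NbD night
  before dawn / DA dawn / DL daylight / DU dusk / NaD night after dusk),
  with dawn/dusk defined as fixed 40-minute windows before sunrise and
  after sunset;
* **moon day** 1–30 from the mean-synodic lunar age
  (age = time since a reference new moon mod 29.53 d; day 15 contains the
  full-moon center; the partial day 30 is dropped before smoothing);
* **astronomical season** (equinox/solstice boundaries computed per year),
  month, ISO weekday and day of year (Feb 29 merged into day 59).

On top of the annotation:

* **Frequency tables** — category × year counts, within-year proportions
  `p_ij = n_ij / n_.j`, and cross-year mean ± SD, the standard descriptive
  surface of roadkill studies.
* **Sequential-contrast linear models** — OLS of the yearly proportions on
  the category with successive-difference coding, where each coefficient
  estimates the difference of adjacent category means
  (`β_j = μ_{j+1} − μ_j`) and the intercept the grand mean of category
  means (exactly `1/k` for proportions); or treatment coding against a
  reference category. Tukey HSD post hoc with a compact letter display,
  R², and Shapiro–Wilk residual checks.
* **Cyclic cubic regression-spline smoothers** — Gaussian penalized
  regression of counts per (year × day-of-year) or (year × moon-day) cell,

      min ‖y − α − Bβ‖² + λ β′Sβ,

  with a periodic cubic basis B, second-derivative penalty S, λ chosen by
  GCV, effective degrees of freedom edf = tr of the smoother matrix,
  deviance explained 1 − RSS/TSS, pointwise 95% bands, and the
  horizontal-line test (no constant fits inside the bands ⇔ the cycle is
  real at the 5% level). The implementation agrees with R `mgcv`'s
  `s(x, bs="cc")` to ~10⁻⁶ on shared data.
* A **synthetic accident generator** — an inhomogeneous Poisson process
  whose intensity multiplies monthly, weekday, illumination-window and
  lunar factors (thinning against a constant envelope), sharing its solar
  geometry with the classifier, for testing and parameter-recovery
  studies.

## Worked example

```python
from chronocollide import (StudyConfig, SyntheticConfig, generate,
                           annotate_records, frequency_table,
                           CategoryContrastModel, CyclicSmoother)

config = StudyConfig()
records = generate(SyntheticConfig(seed=42), config)   # 11700 records
ann = annotate_records(records, config)

season = frequency_table(ann, "season")
print(season.summary())
#         mean_pct  sd_pct  total_count
# season
# spring      24.4     0.7         2859
# summer      21.2     0.7         2483
# autumn      32.2     0.9         3769
# winter      22.1     1.2         2589

fit = CategoryContrastModel(season).fit()
print(fit.summary().round(3))
#                Estimate     SE  t-value    p
# Intercept         0.250  0.002  128.749  0.0
# summer-spring    -0.032  0.005   -5.849  0.0
# autumn-summer     0.110  0.005   19.986  0.0
# winter-autumn    -0.101  0.005  -18.350  0.0

moon = CyclicSmoother.from_counts(ann, "moon_day").fit()
print(moon.summary())
# {'edf': 3.139, 'ref_df': 8, 'deviance_explained': 0.5365,
#  'horizontal_line_rejected': True, ...}   peak at moon day 15.6
```

Reading: autumn holds 32.2 ± 0.9 % of each year's accidents; the intercept
0.250 is the grand mean of the four seasonal shares (1/4 by construction);
`autumn-summer = 0.110` says autumn's share exceeds summer's by 11
percentage points (t = 20.0, p < 0.001). The moon-day smoother uses 3.1 of
its 8 available degrees of freedom, explains 54 % of the deviance of the
yearly moon-day counts, and peaks at day 15.6 — next to the full-moon
center the generator was told to favour.

The same pipeline runs from the shell:

```
chronocollide simulate --out records.csv --seed 42
chronocollide run records.csv --out results/ --hunting-csv hunting.csv
```

writing frequency tables, the five standard contrast models (seasons,
months, weekdays, LR3, LR5), Tukey letters, both smoother curves with
bands, report rates and a run manifest as plain CSV/JSON.

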