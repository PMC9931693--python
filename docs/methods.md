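# Methods

## Problem and scope

Microwave fat meters estimate tissue water content at the spot under the
sensor and report a lipid-like value. Because killer whales eat whole
fish, the instrument must be calibrated to *whole-body* lipid content
(% wet weight), including gonads and viscera, before its readings are
ecologically meaningful. This package implements that calibration, the
survey statistics that apply it to a river-entry test fishery organised
into five management units (MUs: Spring5_2, Spring4_2, Summer5_2,
Summer4_1, Fall4_1), the migration-difficulty correlation analysis, and
the prey-requirement bioenergetics. Genetic stock identification,
laboratory extraction chemistry, instrument hardware interfacing and the
internals of the killer-whale energetics model are out of scope; MU
labels, tissue lipid fractions and the predator population's annual
energy demand enter as data.

## Whole-body lipid from proximate analysis

A homogenized fish is modelled as two compartments, somatic (carcase
plus viscera) and gonad. Dried-subsample lipid fractions are converted
to wet-mass fractions by `f_wet = f_dry · (1 − water_frac)` and combined
by mass weighting. Replicates (somatic ×3, gonad ×2) are averaged
arithmetically before conversion; no outlier rejection. GSI is stored as
the ratio gonad/somatic mass; percent rendering is an I/O concern.

## Calibration regression

Three families are fitted to (reading, whole-body lipid) for each of the
seven position combinations (positions averaged arithmetically; listwise
deletion per combination):

- **Model II** — both variables carry error. Closed forms: SMA slope
  `sign(r)·sd(y)/sd(x)` (default, since the axes have different units);
  MA from the covariance eigen-problem. The coefficient of determination
  reported is the squared correlation, adjusted for two parameters.
- **Model II on ln x** — as used by earlier fat-meter calibrations.
- **Segmented** — continuous two-segment least squares in hinge form
  `y = b0 + b1·x + d·max(0, x − ψ)`. The breakpoint is profiled over
  every midpoint between adjacent sorted unique readings having at least
  3 points per segment, then refined by bounded scalar minimization
  between the best candidate's neighbours (xatol 1e-10). Residual
  degrees of freedom count 4 estimated quantities (intercept, two
  slopes, ψ). With no admissible candidate the fit degrades to a single
  line with a `degenerate` flag. This deterministic grid-plus-refinement
  scheme is exhaustively checkable against a brute-force grid oracle,
  which the tests do.

Ranking is by adjusted R², ties broken toward fewer positions then lower
position index (parsimony). Covariate checks are nested-F tests built
directly from least-squares residual sums of squares: an interaction
test for GSI/body-mass effect modification, and a two-stage ANCOVA
(slope homogeneity, then adjusted intercepts) for sex.

The published coefficients ship as `PiecewiseCalibration.published()`:
β₀ = −1.973, β₁ = 6.758, slope change δ = −6.202, ψ = 1.059, floor 0.6.
The second segment's printed "±6.202" is interpreted as a *slope change*
(slope above ψ = 0.556): the alternative readings (6.758 or 12.96 above
ψ) would map the maximum observed reading 16.8 to >100% lipid, which is
physically impossible, whereas 0.556 maps it to ≈ 13.9%, inside the
observed lipid range. This interpretation is configurable. Predictions
are clipped to [0, 100]%; readings below the instrument floor are
evaluated at the floor with a warning rather than rejected, since field
sheets contain them.

## Survey statistics

Records are pandas DataFrames (one row per fish). Energy density is
affine in lipid, `ED = a + b·L`; the default conversion is the ordinary
least-squares fit through the five packaged MU (mean lipid, mean ED)
pairs, a = 819.96 kcal/kg, b = 84.29 kcal/kg per percentage point; an
external coefficient pair can be supplied instead. The 50%-run date is
the first date at which cumulative catch reaches half the MU total.
ANOVA uses `scipy.stats.f_oneway`; Tukey HSD uses scipy's numerically
integrated studentized-range distribution, with compact letters assigned
by insert-and-absorb at α = 0.05. The Spring4_2 MU (n = 9) is excluded
from the ANOVA/Tukey and ANCOVA contrasts by default but kept in
summaries and the conversion fit. The hatchery/wild contrast is a Welch
t-test restricted to one stock so origin is the only grouping factor.
Weeks are ISO weeks of the capture date. Within-season declines are
reported two ways — regression slope × observed span, and last-week mean
minus first-week mean — because either reading of a "decline over the
run" is defensible.

## Migration difficulty

Work and slope are computed **per stock** and then averaged within MU;
averaging first and then combining would be inconsistent with the
packaged MU-level table, whose work/slope values differ from the
product/ratio of its mean elevation and distance. Because the per-stock
source lists are not published, the MU-level index table ships in
`reference.py` and the correlation analysis replays from it; a per-stock
CSV path is supported for users with their own data. Pearson p-values
use the t transform with n − 2 df; with only five MUs the analysis has
limited power, as in the original.

## Bioenergetics

Gonad energy uses a fixed gonad energy density of 7.79 kJ/g. The mass in
the worked example (8 kg) is treated as *total* body mass
(`m_gonad = m·GSI/(1+GSI)`): this is the only basis that reproduces the
~4720 kJ worked value; a somatic basis (`m·GSI`, giving 6232 kJ) is
retained as an option. kcal→kJ is fixed at 4.184. The predator model is
not re-implemented: the population's annual energy demand is
back-calculated from the reference scenario (245,000 fish/year × 8 kg ×
1900 kcal/kg = 3.724 × 10⁹ kcal/year) and alternative single-MU diets
are evaluated as `energy / (prey_mass × ED)`.

## Synthetic data generator

The generator emulates the study's sampling design, not its raw data.

**Calibration cohort** (63 fish; 21 "troll" 2019, 42 test-fishery 2020):
whole-body lipid uniform on (2.0, 13.9)% — the pre-image of the observed
reading span [0.6, 16.8] under the published curve, putting ≈ 27% of
readings below ψ (the immature marine fish); total mass uniform on
(0.25, 11.05) kg; GSI uniform (0.01, 0.17); gonad lipid normal by sex
(female 10.03 ± 1.89%, male 0.68 ± 0.36%). The somatic lipid fraction is
solved so the mass-weighted whole-body value equals the drawn lipid
exactly, and dried-replicate triplets are generated symmetric about
their mean so replicate averaging reproduces it to machine precision;
the position-1 reading is the exact inverse of the true calibration plus
meter noise (default sd 0.15 meter units), clamped at the floor.
Positions 2–3 add independent meter noise (default sd 0.8), which
reproduces the position-1-best ranking.

**Survey** (Table of packaged defaults): per-MU sample sizes
289/9/72/966/473, run windows from the printed first/last catch dates,
capture days uniform within the window, expected lipid declining
linearly from start to end of run (declines 5/4/5/6/4 pp; the Spring4_2
value is not printed and is set at the fall-like low end). The residual
lipid SD is deconvolved from the printed season-pooled SD —
`sd_resid² = sd² − decline²/12 − f(1−f)Δ²` (the last term only for the
hatchery-mixture MU) — so the generated marginal SD matches the printed
one. The fall MU has hatchery fraction 0.25 with a −0.82 pp lipid offset
applied symmetrically about the MU mean (wild +fΔ, hatchery −(1−f)Δ),
preserving the configured marginal mean. GSI rises within-run 0.1→0.2
(Fall4_1) and 0.08→0.15 (Summer4_1). Readings are the noiseless inverse
of the calibration at the simulated lipid, so measurement error is
folded into the configured lipid SD.

**What the generator does not emulate:** gill-net size selectivity and
the alternating two-net schedule, non-uniform within-run arrival
density (so the simulated 50%-run date sits near the window midpoint,
unlike the skewed observed dates), covariance between lipid and body
size, and year-to-year variation. Passing tests therefore demonstrate
that the estimators recover known structure under the study's sample
sizes and noise levels — not that the field data satisfy the generative
assumptions.

One bookkeeping note: the per-MU sample sizes sum to 1809 while the
study's text reports 1566 individuals; the generator follows the
detailed table and the discrepancy is documented here rather than
resolved.

## Numerical choices and degenerate inputs

- CSV floats are written with `%.17g` and parsed with pandas'
  `round_trip` precision so file round trips are bit-exact.
- Constant-response regressions return slope 0 with p = 1 (no spread, no
  evidence of trend) instead of propagating a 0/0 p-value.
- A Tukey group with n < 2 is excluded with a notice; an empty MU is
  omitted from summaries with a log message; CPUE rows with non-positive
  effort are dropped and counted.
- Dates are day-of-year integers in all statistics; ISO-8601 at I/O.

## Known limitations

- The lipid→energy-density conversion is fitted to five MU-level means,
  not fish-level pairs, so its coefficients carry the aggregation error
  of that table; downstream energy differences inherit a few percent of
  uncertainty.
- With five MUs the difficulty correlations are fragile to any single
  MU's value.
- Replicated simulation shows the Tukey letter grouping of the two
  highest-lipid MUs (true means 0.1 pp apart at n = 289/72) flips to
  "significantly different" in roughly 5–7% of seeded survey replicates;
  this is intrinsic sampling variability of the study design, not an
  estimator defect, and the corresponding stability check in the test
  suite documents it by failing its 95% bar at ≈ 93%.
- The 21-model ranking refits the segmented family per combination
  without propagating breakpoint uncertainty into the ranking.
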