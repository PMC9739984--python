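# Methods

## Estimation chain

The package estimates dietary environmental footprints by combining a
frequency instrument with a quantity instrument. The propensity
questionnaire (PQ) yields, per respondent and food group, a count 1–10 and
a period (day/week/month/year); counts are converted to occurrences/day by
the fixed divisors 1, 7, 30 and 365 (no calendar-aware variants). The 24-h
recall (24HR), pooled over the cohort, yields each group's per-capita
amount per occasion and the preparation mix. The chain is then

1. estimated food consumption `EFC = frequency × per-capita g / 1000`
   (kg/day per group);
2. daily footprint `F = Σ EFC_i × impact_i`, where `impact_i` is the
   group's weighted life-cycle coefficient, computed separately for carbon
   (g CO₂eq/kg), water (L/kg) and ecological (m²/kg) footprints;
3. estimated energy `Ekcal = Σ EFC_i × 10 × kcal100_i`, where `kcal100_i`
   is the group's unweighted mean energy density over the composition
   table's foods and the factor 10 converts kg to 100-g portions — the
   energy equation is otherwise dimensionally inconsistent, and only this
   reading produces plausible kcal/day magnitudes;
4. energy standardization `EEF = F × 1000 / Ekcal`, removing differences in
   overall diet size so that footprints per 1000 kcal compare dietary
   *composition*.

Respondents with zero estimated energy keep their raw totals but are
excluded from all adjusted analyses, with a logged count; they are never
silently imputed.

### Per-capita estimation

The per-occasion amount of a group is the mean of its 24HR mass amounts
weighted by the number of times each food was consumed; a median-based
variant is available (`estimator="median"`) because survey protocols are
often ambiguous between the two, but the weighted mean is the default and
the one all calibration results use. Volumes (mL) are converted to mass
through an explicit dilution table — food-level rules take precedence over
group-level rules, and a missing rule is an error, never a silent 1 g/mL
assumption. Foods observed in the recall must resolve to a coefficient row
directly or through a user-supplied alias map; unresolved foods abort with
the full list of misses, since silent dropping would bias group
coefficients toward whatever happened to match.

Per-capita amounts are pooled across the cohort by default: a single recall
day is too sparse to characterize an individual's 12-month portion
behaviour, and the group-level PQ frequency already carries the individual
signal. An `individual` mode substitutes each respondent's own recall
amounts where available (falling back to pooled values) for sensitivity
analysis.

## Stratification and decomposition

Tertiles of the adjusted (per-1000-kcal) footprint — the adjusted basis is
the default because stratum medians are conventionally reported on that
scale — are assigned by stable rank order: cut points are the empirical 1/3
and 2/3 quantiles (linear interpolation), but membership comes from a
stable sort so the three strata always differ in size by at most one even
under heavy ties; an all-tied input emits a warning. Contribution tables
divide the pooled per-group addends by the pooled total within each
stratum, so percentages sum to 100 exactly and are invariant to uniform
coefficient rescaling.

## Statistical tests

Footprint distributions in such cohorts are right-skewed, so comparisons
are rank-based and two-sided throughout. Mann–Whitney uses the exact
enumeration null for tie-free pooled samples up to n = 12 and otherwise the
normal approximation with tie correction and (by default) continuity
correction; the reported statistic is min(U_x, U_y). Kruskal–Wallis uses
the tie-corrected H with a chi-square reference on k − 1 df; on two groups
it coincides with the Mann–Whitney normal approximation without continuity
correction (H = z²), which the tests verify numerically. The normality
screen is a one-sample Kolmogorov–Smirnov test against a normal with
sample-estimated mean and SD; since estimating parameters makes the
asymptotic p anti-conservative (the Lilliefors situation), the result
carries an explicit caveat note. Compact letter displays assign one letter
per maximal clique of the "not significantly different" graph from pairwise
Mann–Whitney tests at α, unadjusted by default (a Bonferroni flag exists) —
so two categories share a letter exactly when their pairwise p ≥ α.

## Correspondence analysis

Tertile × category tables (missing "DA/DK" answers dropped with logged
counts, all-zero rows/columns removed with a warning) are decomposed from
first principles: with correspondence matrix `P = N/n` and masses `r`, `c`,
the standardized residuals `S = D_r^{-1/2}(P − r cᵀ)D_c^{-1/2}` are
factored by SVD. Squared singular values are the principal inertias and
satisfy `Σλ = χ²/n` to numerical precision; both row and column points are
reported in principal coordinates so the two clouds share one map, and each
category is additionally assigned its nearest tertile by chi-square
distance (Euclidean in full principal coordinates) — a numeric substitute
for the ellipse overlays such maps usually carry, whose construction is not
standardized. The association verdict is the standard rule, associated iff
p < α (strict inequality at the boundary); the alternative "observed χ²
below the critical value" condition is computed and surfaced in the
rationale but never enforced, because it inverts the usual rejection
region.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, not any real
population's diet. Food groups (default 41) are apportioned among six
classes — ruminant meat, other animal, processed, staple, plant, beverage —
by largest remainder; coefficient magnitudes are drawn uniformly from
class-specific ranges chosen so animal-source classes dominate (ruminant
CF 25–45 kg CO₂eq/kg vs plant 0.3–1.2 kg/kg; all values synthetic, none
taken from any published LCA database). Covariates are drawn independently
from configurable category marginals defaulting to a published survey
cohort's frequencies (e.g. 42.1% male, 53.5% adult, 35.3% white, income
quintiles ≈20% each; marginals renormalized to sum exactly to 1).
Consumption is modelled per respondent × group as a lognormally perturbed
class baseline rate (occasions/day) times a multiplicative covariate
effect: an entry `{"income": {"ruminant_meat": 1.5}}` scales the rate (and
recall amounts) geometrically from 1.0 in Q1 to 1.5 in Q5. Rates become PQ
(count, period) pairs by choosing the smallest period whose expected count
reaches 1 and clipping the rounded count to 1–10; groups appear in the
single-day recall with probability min(rate, 1). Class baselines (rates
0.1–0.6 occasions/day, portions 80–200 g) were set once so a default cohort
eats ~13 group-occasions and ~2300 estimated kcal per day. A fallback
mechanism guarantees every PQ-reported group at least one pooled recall
observation, preserving referential integrity. All draws flow from one
seed through four per-table child streams, so cohorts are byte-identical
across runs.

What the generator does **not** emulate: correlated covariates (income and
schooling are drawn independently), seasonal or day-of-week recall
structure, within-person day-to-day variance, portion-size reporting error,
and real Brazilian diet composition. Passing tests therefore demonstrate
the correctness and calibration of the estimation chain, not the
plausibility of any substantive footprint value.

## Numerical choices and problem sizes

Totals and their per-group addends use the same summation order, so
conservation holds exactly; identity checks assert 1e-9 relative (most hold
to machine epsilon). Replicated experiments run the dense-matrix evaluation
path, which the tests verify against the row-wise reference to 1e-9. The
calibration experiments use 1000 null replicates and 100 effect replicates
at the study size n = 411 (type-I error empirically ≈5%, power against the
1.5× income effect ≈100%); identity sweeps use 200 cohorts of 12
respondents × 8 groups, where the arithmetic is the same and generation is
cheap.

## Known limitations

- Group-level coefficients weight foods by recall `times` only, not by
  amount × times; with strongly heterogeneous within-group portions the two
  weightings diverge.
- The pooled per-capita default makes between-person variation come from
  frequency alone; the individual mode exists but single-day recalls make
  it noisy.
- The KS screen's p-value is anti-conservative by construction (flagged in
  the result rather than replaced by a Lilliefors table).
- Compact letter displays inherit the unadjusted pairwise error rate unless
  the Bonferroni flag is set.
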