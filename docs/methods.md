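# Methods

## The model

`mealopt` treats a meal as a nonnegative vector of grams over food categories
(the 31-category What We Eat in America scheme by default) and a
food-composition matrix as nutrient densities per 100 g per category, so the
nutrients of a meal are the linear map `density.T @ grams / 100`. Nutrient
guidelines — absolute amounts, or percent-of-energy bounds linearized with
Atwater factors (4 kcal/g for protein, carbohydrate and added sugar; 9 kcal/g
for fats) — compile to linear inequalities over the gram vector. The
optimization step finds the guideline-compliant meal minimizing deviation from
an observed one under either the absolute (Σ|Δgrams|) or the relative
(Σ|Δgrams|/observed) objective. Both become exact LPs with the standard split
of each deviation into nonnegative parts; HiGHS (`scipy.optimize.linprog`)
solves them, with feasibility/optimality tolerance 1e−8 and constraint rows
flagged binding at |slack| ≤ 1e−6.

Assumptions worth stating:

- **Closed bounds.** Guidelines printed as strict ("sodium < 460 mg") compile
  as non-strict inequalities; LP theory needs closed feasible sets, and a
  binding optimum then sits exactly on the printed bound.
- **Zero-observed foods under the relative objective** are held at zero: the
  relative deviation is undefined at obs = 0, and the intent of the objective
  is precisely not to introduce foods that are not eaten. The absolute
  objective leaves all categories free.
- **Mean-level optimization.** One LP per population is run on the group-mean
  pattern; per-individual optimization is a straightforward extension but is
  not implemented, so no statistical comparison of observed vs optimized
  patterns is offered.
- **Alternative optima** are possible in degenerate geometries; the solver's
  vertex is reported as-is. Tests assert objective values and constraint
  status, not uniqueness of quantities.

## Scoring and stratification

NRF9.3 = (NR − LIM) × 100 over whole-day intakes, energy-adjusted to
2000 kcal. Each qualifying ratio is capped at 1 (= 100 %DV) *before* summing,
so NR ∈ [0, 9] and one abundant nutrient cannot compensate for another's
inadequacy; each limiting term counts only the per-nutrient excess over its
MRV, floored at zero per nutrient. The defaults are the nine DVs
(protein 50 g, fiber 28 g, vitamin A 900 µg RAE, vitamin C 90 mg, vitamin D
20 µg, calcium 1300 mg, iron 18 mg, potassium 4700 mg, magnesium 420 mg) and
three MRVs (added sugar 50 g, saturated fat 20 g, sodium 2300 mg); vitamin D
deliberately takes the slot often given to vitamin E, reflecting its status as
a nutrient of public health concern. The score is scale-invariant: multiplying
all nutrients and energy by a common factor changes nothing.

Tertiles are assigned within each age group by ranking NRF9.3. When the group
size is not divisible by 3, the extra members go to the lower tertiles first
(sizes n = 10 → {4, 3, 3}); ties are broken by person id so runs are
reproducible. Stratification is unweighted.

Breakfast is self-reported: episodes labelled breakfast/desayuno/brunch
(case-insensitive, configurable) are pooled per day, and a pooled episode of
strictly less than 50 kcal — or no such episode — marks a skipper, excluded
from all downstream stages. Exactly 50 kcal counts as a consumer.

## Guideline parameters

The packaged breakfast guideline set (data/ibri_guidelines.yaml) covers energy
(300–500 kcal), macronutrient percent-energy bands (carbohydrate 55–75 %E,
total fat 20–30 %E, SFA < 10 %E, added sugar < 10 %E) and 17 nutrient
amounts. Paired values apply children-first (e.g. calcium ≥ 390 mg children /
≥ 325 mg adults; thiamin 0.3/0.2 mg; riboflavin 0.5/0.4 mg; B12
0.6/0.5 µg); single values apply to both populations. The vitamin A bound is
read as µg RAE. The separate 510 mg calcium target used by the two-food
worked example belongs to that example only and is not part of this set.

## Synthetic data

The generator exists so the whole pipeline is testable without survey
downloads; it emulates structure, not any particular population's intake
distribution.

- **Composition (`paper_like`).** Twelve breakfast-typical categories carry
  hand-set realistic per-100 g profiles — milk (48 kcal, 1 g SFA,
  120 mg calcium), cheese (290 kcal, 12 g SFA), processed meat (290 kcal,
  7 g SFA, 1000 mg sodium), sweet bakery (400 kcal, 7 g SFA), eggs (180 kcal,
  4.5 g SFA), mixed dishes (215 kcal, 3.7 g SFA), plus fruit, 100 % juice,
  both ready-to-eat cereal categories (fortified: the low-sugar cereal carries
  30 mg iron, 7 µg vitamin D and 600 µg folate per 100 g, as fortified US
  cereals do), nuts/beans/soy, coffee & tea and yogurt. The anchors make the
  packaged guideline LP feasible — a milk + fortified-cereal + fruit + nuts
  breakfast inside 300–500 kcal meets every bound — which is the property the
  real food supply has and a fully random matrix need not. The remaining 19
  categories draw macronutrients from log-uniform ranges bracketing the
  anchored profiles, derive energy from Atwater arithmetic (so percent-energy
  constraints stay meaningful), and draw micronutrients log-uniformly.
  Generation is bit-reproducible under a seed.
- **Population.** Each record gets an age (≈ 40 % children), a latent diet
  quality q ~ U(0, 1), a morning meal assembled from per-category habit
  probabilities and typical servings (milk most common; the fruit probability
  rises with q), occasionally split into breakfast + brunch or labelled
  desayuno, a small itemized lunch, and an aggregate non-breakfast remainder
  vector whose qualifying nutrients rise and limiting nutrients fall with q.
  Day totals are items × composition + remainder, so extraction closure holds
  exactly. A requested skipper fraction gets either no morning meal or one
  scaled below 50 kcal. Because q drives both the remainder and morning
  fruit, tertiles recover a T1 < T2 < T3 fruit gradient — a designed-in
  property, useful for verifying stratification, not an empirical finding.
- **What passing tests do not show.** Synthetic records have no survey
  weights, no day-to-day variance, no item-level food codes, and much simpler
  covariance between nutrients than real recalls; pipeline results on them
  validate the machinery, not any substantive claim about US breakfasts.
  Optimizing real NHANES breakfasts would require the FNDDS/FPED-derived
  composition matrix, which is out of scope.

## The brute-force oracle

Small LPs (≤ 3 free categories) are cross-checked against an exhaustive grid
search that is independent of the LP path. The search box is derived from the
constraints: upper-bounded coordinates take their cap from all-nonnegative
≤-rows; otherwise the bound is the observed value plus the single-coordinate
repair need Σⱼ deficitⱼ/aⱼᵢ, which provably contains the optimum for pure
minimum-constraint systems. The observed point and the box edges sit exactly
on the grid, feasibility is strict, and the step defaults to ~60 points per
axis with a ~3·10⁶-point cap. Whenever a feasible grid point lies within one
step per coordinate of the LP optimum, the oracle objective is within one
grid step per coordinate of the LP value; randomized comparison suites build
problems with fat feasibility margins so this holds.

## Numerical choices and degenerate inputs

- Infeasible systems never raise: the solution object carries status
  `infeasible` plus the guideline rows most violated at the observed point.
- An all-zero observed pattern under the relative objective with any binding
  minimum is reported infeasible (every food is pinned at zero).
- Reported distances are recomputed from the returned pattern rather than
  taken from the solver objective, so solution invariants hold exactly for
  the numbers users see.
- Optimized quantities below 1e−12 g are snapped to zero.
- Report tables round to one decimal for display only; CSV/JSON writers keep
  full precision and serialize deterministically (same inputs → same bytes).

## Known limitations

No survey-weighted statistics, no cost modelling, no portion-size or
integer constraints, no MyPlate cup/ounce-equivalent units (grams
throughout), no per-individual optimization, and no time-of-day meal
definition — breakfast is whatever the respondent called breakfast.
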