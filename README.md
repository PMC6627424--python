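# mealopt

Meal-level diet optimization for dietary-survey data.

Nutrition surveys such as 24-hour recalls describe what people actually eat at
individual meals. `mealopt` asks a practical question of those data: *how
little would a low-quality breakfast have to change to meet nutrient
recommendations?* It is aimed at nutrition epidemiologists and modellers who
work with food-composition tables and meal-coded intake records.

The pipeline:

1. **Score** whole-day diets with the Nutrient Rich Food index
   **NRF9.3** = (NR − LIM) × 100, where
   NR = Σ₉ min(intakeᵢ · 2000/energy / DVᵢ, 1) over nine qualifying nutrients
   (protein, fiber, vitamins A/C/D, calcium, iron, potassium, magnesium) and
   LIM = Σ₃ max(intakeᵢ · 2000/energy / MRVᵢ − 1, 0) over three limiting
   nutrients (added sugar, saturated fat, sodium).
2. **Stratify** each age group (children 6–17, adults 18+) into tertiles
   T1 < T2 < T3 of NRF9.3.
3. **Extract breakfasts** by self-report (labels breakfast/desayuno/brunch,
   pooled); anyone providing < 50 kcal in the morning is a skipper and is
   excluded.
4. **Optimize** the mean T1 breakfast with two linear programs that meet the
   IBRI breakfast nutrient guidelines while deviating minimally from the
   observed grams xᵢ per food category:
   - absolute: min D = Σᵢ |xᵢ − obsᵢ| (grams)
   - relative: min D = Σᵢ |xᵢ − obsᵢ| / obsᵢ (unitless; foods not eaten stay out)

   Both are exact LPs after the standard split xᵢ = obsᵢ + pᵢ − nᵢ, solved
   with HiGHS via `scipy.optimize.linprog`.

## Worked example

A breakfast of one serving of milk (250 g at 120 mg calcium/100 g) and one of
cheese (30 g at 600 mg/100 g) provides 480 mg of calcium; the breakfast target
is 510 mg. The two objectives close the 30 mg gap through different foods:

```python
import mealopt as mo

comp, observed, guidelines = mo.fixture_calcium_example()
model = mo.DeviationLP.from_guidelines(observed, comp, guidelines, "adults")
print(mo.solve_relative(model).summary())
print(mo.solve_absolute(model).summary())
```

```
Deviation LP (relative objective)
  status:   optimal
  distance: 0.1000
  binding:  calcium_mg:min
  categories changed: 1
    milk                        250.0 ->    275.0 g
Deviation LP (absolute objective)
  status:   optimal
  distance: 5.0000 g
  binding:  calcium_mg:min
  categories changed: 1
    cheese                       30.0 ->     35.0 g
```

The relative objective grows milk by 10 % (distance 0.1 beats the 17 % cheese
increase); the absolute objective adds 5 g of cheese (5 g beats 25 g of milk).
In both, the calcium constraint binds: the optimized meal sits exactly on
510 mg.

The full pipeline runs the same machinery over a population:

```python
comp = mo.generate_composition(1, 31, "paper_like")
records = mo.generate_population(7, 300, 0.25, comp)
result = mo.run_pipeline(records, comp, "children")
print(result.report.nutrient_table)   # observed vs optimized, pass/binding flags
```

A CLI mirrors this: `mealopt optimize --composition comp.csv --observed
pattern.csv --objective both --population children --out report` and
`mealopt simulate --seed 1 --n 300 --out sim`.

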