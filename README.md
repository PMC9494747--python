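# mcdm-survey

Multi-criteria decision analysis of modeler surveys in staged
model-intercomparison studies.

## The problem

Multi-model ensemble studies of agroecosystem biogeochemistry (crop yield,
N₂O emissions, grassland productivity) release their input data to the
participating modelers in successive calibration stages. How much importance
each modeler attributes to each input variable — and how much the modelers
agree with one another — is a real, measurable source of ensemble
uncertainty. This package implements the survey-analysis pipeline for that
question: it takes each modeler's pairwise comparison matrices (one per
variable category, plus one over the categories themselves) and their
category-level influence ratings, and produces consistency screening,
variable importances by protocol stage, agreement and group-difference
statistics, and the link between importance and ensemble prediction error.

It is written for analysts of model-intercomparison surveys, but every step
is generic: any staged protocol (categories → variables → stages) can be
supplied as a JSON config. The packaged default protocol has 7 categories,
55 variables and 5 stages, with 28 variables released at stage 1.

## The methods

- **Priorities and consistency.** A judge's reciprocal ratio matrix A
  (a\_ij = importance of i over j) is condensed into the normalized
  principal eigenvector w (power iteration). Internal contradiction is
  measured by CI = (λ\_max − n)/(n − 1) and CR = CI/RI(n) against Saaty's
  random index table; the screening rule flags CR > 10 % for review and
  excludes any modeler with CR > 30 %.
- **DEMATEL.** Each judge's category-level direct-influence matrix D is
  normalized to N = D/s, s = max(max row sum, max column sum), and the total
  relation matrix T = N(I − N)⁻¹ accumulates direct and indirect influence.
  Row sums G (influence given) and column sums R (received) classify
  categories as net influencers (G − R > 0) or receivers.
- **ANP integration.** The column-normalized T weights each source
  category's dependence on every target category; local variable priorities
  fill a column-stochastic supermatrix whose limit (repeated squaring, with
  a Cesàro average for periodic chains) gives global variable importances
  P\_i. Summed within stages these give cumulative stage importances ΣP\_s.
- **Agreement.** Kendall's coefficient of concordance with tie correction,
  W = 12·SS / (m²(n³ − n) − m·F), F = Σ\_judges Σ\_ties (t³ − t),
  with the χ² = m(n − 1)W significance approximation (df = n − 1) and an
  optional exact permutation test. Group differences in ratings use a
  one-way MANOVA: Wilks' Λ = det(W)/det(W + B) with Rao's F approximation,
  plus per-variable ANOVA follow-ups.
- **Error link.** The model error rate MER\_s = RRMSE\_s / ΣP\_s expresses
  ensemble prediction error per unit of modeling importance accessed up to
  stage s; stage-over-stage percent changes (vs stage 1) summarize what each
  data release bought.
- **Synthetic surveys.** Because the motivating survey's raw responses are
  not deposited, a generator produces bundles with known ground truth:
  Dirichlet latent weights, a shared/idiosyncratic mixture (drives W),
  multiplicative log-normal judgment noise (drives CR), group-level weight
  shifts (drives the MANOVA), and a ground-truth influence structure.

## Worked example

```python
import mcdm_survey as ms

spec = ms.GeneratorSpec(protocol=ms.default_protocol(), n_modelers=20, seed=42)
bundle, truth = ms.generate_survey(spec)

screening, retained = ms.screen_modelers(bundle)
table = ms.importance_table(bundle, retained=retained)
w = ms.concordance_by_category(bundle, retained=retained)
pooled = ms.pool_influence(bundle, retained)

sigma_p = ms.cumulative_importance(table.stage_totals)
series = ms.generate_rrmse(truth, [1.60, 1.20, 1.41, 0.80, 0.85], output_name="N2O")
mer_table = ms.mer(series, sigma_p)
```

prints (via the obvious `print` calls):

```
retained 20 of 20 modelers; mean CR = 0.071
stage importances: {1: 0.576, 2: 0.356, 3: 0.011, 4: 0.021, 5: 0.036}
Kendall W (SOI): 0.224 significant: True
CL: G-R = 1.098 (influencer), outgoing share = 0.77
MER: [1.615 1.218 1.426 0.805 0.85 ] pct vs stage 1: [  0.  -24.6 -11.7 -50.2 -47.4]
```

Reading: all 20 synthetic judges pass the 30 % consistency cut-off with a
mean CR of about 7 %; stage 1 carries most of the importance mass; judges
agree more than chance on soil-information priorities (W = 0.22 over 9
items, significant at p < 0.05); the experimental-climate category is a net
influencer sending 77 % of its total relation outward; and the model error
rate per unit of accessed importance drops by about 50 % once stage-4 data
arrive.

The same analyses are available from the shell:

```sh
mcdm-survey simulate --n-modelers 20 --seed 42 --out-dir survey/
mcdm-survey priorities --survey survey/          # consistency screening
mcdm-survey anp --survey survey/                 # stage-wise importances
mcdm-survey concordance --survey survey/         # Kendall's W per category
mcdm-survey dematel --survey survey/             # influence profiles
mcdm-survey mer --rrmse survey/rrmse.csv         # error per unit importance
```

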