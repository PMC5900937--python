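# screenmine

Association-rule mining and latent-structure analysis of chronic-disease
screening indicators in primary-care electronic medical records.

Guideline-recommended screens — blood pressure (BP), body mass index (BMI),
waist circumference (WC), LDL cholesterol, glycaemia (A1c/fasting glucose),
and the lifestyle items smoking, alcohol, diet and exercise — are recorded
inconsistently in primary care. Treating each patient's chart as a market
basket of *present* screens, `screenmine` discovers and ranks which screens
tend to be recorded together, information that can drive data-driven
prompting ("you just recorded a BP — would you also like to record a
weight?"). It is a library for epidemiologists and health-services
researchers working with binary presence/absence indicator matrices, with a
thin CLI for end-to-end runs.

## Methods

**Rule mining.** Apriori enumerates itemsets with support ≥ σ (default 2%),
and single-consequent rules A → B with confidence P(B|A) ≥ κ (default 80%)
are scored with lift L = P(A,B)/(P(A)P(B)) and with the **standardized
lift**

    L* = (L − λ) / (ν − λ),
    ν  = 1 / max{P(A), P(B)},
    λ  = max{ (P(A)+P(B)−1)/(P(A)P(B)),  4σ/(1+σ)²,  σ/(P(A)P(B)),  κ/P(B) },

which rescales L onto [0, 1] by the Fréchet- and threshold-implied bounds so
that rules with very different marginal prevalences become comparable.
Rules are clustered by consequent and *redundant* rules — those whose
antecedent is a proper subset of another same-consequent rule's antecedent —
are pruned, keeping the antecedent-maximal rules. Multilevel rules repeat
the analysis on three category indicators (any vitals / laboratory /
lifestyle item present).

**Latent structure.** Pairwise tetrachoric correlations (profile maximum
likelihood under a dichotomized bivariate normal, thresholds fixed at the
inverse-normal quantiles of the margins) feed an exploratory factor
analysis: iterated principal-axis extraction of 3 factors with oblique
oblimin (quartimin) rotation, item-to-factor assignment by dominant
loading, and Cronbach α = k/(k−1)·(1 − Σsᵢ²/s_T²) per item group.

**Synthetic cohorts.** Because the source EMR extract cannot be shared, a
latent-probit (Gaussian copula) generator draws cohorts with exactly
specified marginal prevalences and a known factor-structured latent
correlation matrix ΛΦΛᵀ + Ψ, giving every downstream stage a testable
ground truth. See `docs/methods.md` for details and assumptions.

## Worked example

```python
from screenmine import apriori, generate_rules, worked_fixture

T = worked_fixture()                 # 10 patients x items {a, b, c}
freq = apriori(T, min_support=0.05)  # 7 frequent itemsets
for rule, m in generate_rules(freq, min_confidence=0.80):
    print(rule, f"supp={m.support:.2f} conf={m.confidence:.3f} "
                f"lift={m.lift:.4f} L*={m.standardized_lift:.2f}")
```

prints

```
{b,c} -> {a} supp=0.10 conf=1.000 lift=1.2500 L*=1.00
{a,c} -> {b} supp=0.10 conf=1.000 lift=1.1111 L*=1.00
{a} -> {b} supp=0.80 conf=1.000 lift=1.1111 L*=1.00
{b} -> {a} supp=0.80 conf=0.889 lift=1.1111 L*=1.00
```

`{a} -> {b}` has lift 0.8/(0.8·0.9) = 1.1111: a and b co-occur about 11%
more often than independence would predict, and L* = 1 because that lift
sits exactly at the upper bound ν = 1/0.9 the marginals allow. The
`examples/` directory has one short script per capability (simulation,
mining and pruning, category rules, latent structure); an end-to-end run is

```sh
screenmine all --seed 7 --outdir results/
```

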