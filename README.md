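# pharmirt

Bayesian item-response-theory (IRT) indices of national pharmaceutical
regulation from binary WHO-style survey data.

National capacity to regulate medicines — does a country have a medicines
regulatory authority, published Good Manufacturing Practice requirements, a
pharmacovigilance system, supplier prequalification? — cannot be observed
directly. What can be observed are yes/no answers to survey questions about
the *de jure* presence of such institutions and policies. `pharmirt` treats
those answers as noisy indicators of three latent dimensions of regulatory
quality and estimates them jointly with the measurement properties of every
question:

- **State Regulatory Infrastructure** (14 items: medicines policy, MRA
  powers and funding, published good-practice guidelines, ...)
- **Monitoring the Private Market** (26 items across legal framework,
  supply-chain inspection — including a composite inspection-regularity
  item with *regular* and *annual* variants — and pharmacovigilance)
- **Public Quality Control** (18 items: public-sector inspection, testing,
  tender transparency, supplier prequalification)

The package is aimed at health-systems and comparative-politics researchers
who want latent-trait indices with honest uncertainty instead of ad-hoc
additive scores, and ships a synthetic-data generator so the entire
pipeline runs, and is tested, without access to restricted survey data.

## Model

For country *i* and item *j*, the observed binary response is the sign of a
latent continuous response under a one-factor probit model:

```
x*_ij = λ_j φ_i − α_j + e_ij,   e_ij ~ N(0, 1),   x_ij = 1{x*_ij > 0}
```

- `φ_i` — the country's latent regulatory quality (standard-normal prior,
  which fixes the scale of the factor),
- `λ_j` — item discrimination: how sharply the response probability rises
  with `φ` (the data-driven "weight" of the item),
- `α_j` — item difficulty: how much regulatory quality it takes before a
  positive answer becomes likely.

Item parameters carry independent N(0, 2²) priors. The model is fitted by
data-augmented Gibbs sampling (truncated-normal augmentation of `x*`,
conjugate normal updates for `φ` and for each `(λ_j, α_j)` pair); sign
(reflection) invariance is resolved by constraining one anchor item's
discrimination positive. Missing responses are excluded from the
likelihood. Posterior draws feed rank-probability analyses —
`P(φ_a > φ_b)`, `P(country in group has the highest/lowest score)` —
computed on joint draws so posterior correlation between countries is
honoured, and cross-index comparisons (R², corner occupancy as a
necessary-condition diagnostic).

## Worked example

```bash
pharmirt all --index infrastructure --seed 5 \
    --iterations 22000 --burnin 2000 --thin 10 --out-dir runs/infra
```

which logs the pipeline stages and writes `survey.csv` (synthetic 78×14
response matrix with ground-truth sidecars), `matrix.csv`, `draws/`,
`item_summary.csv`, `country_scores.csv`, `diagnostics.csv` and
`run_manifest.json`. The same in Python:

```python
import pharmirt as pi

matrix, truth = pi.paperlike_scenario("infrastructure", seed=5)
draws = pi.fit(matrix, pi.ModelConfig(anchor_item="5.05.03", n_burnin=2000,
                                      n_iterations=22000, thinning=10, seed=6))
items, countries = pi.summarize(draws)
print(items[["item_id", "discrimination_mean", "difficulty_mean", "flagged"]].head(3))
print(countries.head(2))
a, b = countries["country_id"].iloc[:2]
print(f"P(phi_{a} > phi_{b}) =", pi.rank_pair_probability(draws, a, b))
print("P(top country is truly highest) =",
      pi.extreme_probability(draws, [a], "highest"))
```

prints (seed 5):

```
   item_id  discrimination_mean  difficulty_mean  flagged
0  5.05.11             2.831103         2.290264    False
1  5.01.15             2.622033        -0.872814    False
2  3.01.04             2.104097         1.721354    False
  country_id  score_mean  score_sd  ci90_low  ci90_high
0        ACL    1.765183  0.501298  1.062329   2.657368
1        ACZ    1.720555  0.499075  0.979596   2.590320
P(phi_ACL > phi_ACZ) = 0.5235
P(top country is truly highest) = 0.1835
```

Items are ordered by posterior-mean discrimination (items with a
significant share of posterior mass below zero are flagged and sorted
last); country scores come with posterior SDs and 90% credible intervals.
The rank probabilities show why intervals alone mislead: the top two
countries are nearly exchangeable (0.52), and the apparent leader has only
an 18% posterior probability of truly ranking first.

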