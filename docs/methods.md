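# Methods

## Measurement model

Each index is a one-factor binary-item probit IRT (normal-ogive) model. For
country *i* = 1..N and item *j* = 1..J,

    x*_ij = λ_j φ_i − α_j + e_ij,   e_ij ~ N(0, 1),   x_ij = 1{x*_ij > 0},

so P(x_ij = 1 | φ_i) = Φ(λ_j φ_i − α_j). The single cut point is fixed at
zero because every modelled item is dichotomous; the difficulty α_j enters
as the intercept. The latent score φ_i has a standard-normal prior, which
fixes the location and scale of the factor; λ_j and α_j carry independent
N(0, 2²) priors — proper and weakly informative on the scale where
empirical discrimination and difficulty estimates for survey instruments of
this kind fall (roughly −1 to 4). Priors are configurable through
`ModelConfig`.

Two identification issues and their resolutions:

- **Reflection invariance.** The likelihood is unchanged under the joint
  sign flip (λ, φ) → (−λ, −φ). We constrain a single *anchor* item's
  discrimination positive (per-index defaults in the registry:
  `5.05.03`, `5.07.01`, `7.10.10.01S` — each a strongly discriminating
  item of its index). Constraining only one loading deliberately leaves
  other items free to take negative posterior mass: a near-zero or negative
  loading is a substantive finding about an item, not something to rule out
  a priori. `ModelConfig.anchor_sign` exposes the direction of the
  constraint so the reflection symmetry is testable; with a weakly loading
  anchor the constraint merely truncates within a mode instead of selecting
  one, which is why the defaults anchor on strong items.
- **Scale.** Fixed by the φ prior rather than by normalising loadings,
  matching the convention under which the synthetic generator draws truth.

Missing responses are excluded from every conditional sum (a
missing-at-random likelihood). For this conjugate model that is
mathematically equivalent to imputing missing cells inside the sampler and
discarding them, but has lower Monte-Carlo variance and keeps the
likelihood honest about what was observed.

## Gibbs sampler

All full conditionals are conjugate (data augmentation):

1. **Augmentation.** For each observed cell, x*_ij ~ N(λ_j φ_i − α_j, 1)
   truncated to (0, ∞) if x_ij = 1 and to (−∞, 0] if x_ij = 0. Draws use
   inverse-CDF sampling routed through the complementary normal CDF on the
   numerically small side (`scipy.special.ndtr`/`ndtri`), so they remain
   finite and correct for linear predictors far from the cut point.
2. **Scores.** φ_i | · ~ N(m_i, v_i) with v_i = 1/(1 + Σ_obs λ_j²),
   m_i = v_i Σ_obs λ_j (x*_ij + α_j).
3. **Item parameters.** (λ_j, α_j) | · is the bivariate-normal posterior of
   a linear regression of the item's x* column on the design (φ_i, −1)
   under the normal prior; the 2×2 updates are evaluated analytically and
   vectorised across items. The anchor item's λ is drawn from its
   sign-truncated marginal, then α from its exact conditional given λ —
   the marginal of a bivariate normal truncated only in λ is the truncated
   univariate marginal, so the pair is an exact draw from the constrained
   conditional.

Default chain settings are 20,000 burn-in, 120,000 iterations, thinning 10
(12,000 retained draws; ~10 s for a 78×14 matrix). Tests and the
acceptance script pass shorter explicit chains sized to what they measure.
A single `numpy` Generator seeded from `ModelConfig.seed` drives the whole
chain, so fits are bit-reproducible; the deterministic start is unit
loadings on the anchor's side of the reflection, zero difficulties and
scores. Non-finite state aborts with the iteration index (never observed in
testing; the truncated-normal inversion is the only step with tail risk).

### Independent scoring route

`phi_posterior_quadrature` computes posterior means of φ for fixed item
parameters by probabilists' Gauss–Hermite quadrature (151 nodes,
log-likelihoods accumulated before a single stabilised exponentiation).
It shares no code path with the Gibbs machinery beyond the probit
definition and serves as the deterministic cross-check: at 50,000 Gibbs
draws the two routes agree to well within 0.02 for arbitrary response
patterns.

## Synthetic data

The generator emulates the target survey wave: N = 78 countries; J = 14,
26, or 18 binary items (ids from the packaged registry); truth drawn as
λ_j ~ U[0.2, 2.2] and α_j ~ U[−1, 1.5] — ranges bracketing the
discrimination/difficulty regimes such instruments produce — with
φ_i ~ N(0, 1) matching the model's identification convention; responses
from the probit model above; 5% of cells masked missing completely at
random (the real survey's nonresponse mechanism is unknown, so recovery
results are conditional on the MCAR stand-in). Country codes are
deterministic ISO-alpha-3-shaped placeholders (AAA, AAB, ...).

What passing tests on these data do **not** show about real surveys:
robustness to informative missingness, to multidimensional or correlated
latent traits, to item responses shared across indices for the same
country, or to coding error in the source tables. They do show that the
sampler targets the correct posterior and that the reporting pipeline
preserves it.

## Item registry and composite coding

The packaged registry (YAML) defines the three item sets, labels,
private-market aspect tags (legal framework / supply chain /
pharmacovigilance) and per-index anchors. Exactly one private-market item
is derived rather than asked directly: the regularity-of-inspections
composite, coded from per-segment years-between-inspections
(manufacturers, retail distributors, dispensing points):

- **regular** variant: 1 if all three segments are inspected at least
  every three years, or any single segment at least every year;
- **annual** variant: 1 only if all three segments are inspected at least
  every year (strictly harder, giving the two private-market model
  variants their distinct composite columns).

If any source segment is missing the composite is missing — even when an
observed segment could already decide the regular rule — to avoid
fabricating inspection coverage from partial answers. Non-positive
frequencies are rejected as coding errors. Continuous survey variables are
otherwise excluded by design.

## Reporting conventions

- Posterior summaries use empirical moments of retained draws, population
  (ddof = 0) SDs, and equal-tailed 90% intervals (5th–95th percentile).
- Item tables are ordered by posterior-mean discrimination, descending;
  items whose discrimination carries at least a threshold fraction
  (default 0.10, configurable and recorded in output metadata) of posterior
  mass below zero are flagged as weakly identified and sorted last.
- Rank probabilities are computed on joint draws — P(φ_a > φ_b) is the
  fraction of draws with that ordering — because marginal credible
  intervals overstate overlap when scores are a posteriori correlated.
  Exact ties (possible only with degenerate draws) count as not-greater.
- Group extreme probabilities use the per-draw argmax/argmin over an
  optional sub-universe of countries.
- Cross-index association is the squared Pearson correlation of
  posterior-mean scores (the comparison concerns point scores; a
  draws-based R² posterior is out of scope). The "empty corner"
  necessary-condition diagnostic counts countries strictly below the
  x-quantile (default 0.25) on one index and strictly above the y-quantile
  (default 0.75) on the other; strict comparisons against interpolated
  sample quantiles make the count invariant under strictly monotone
  transforms of either axis. Any excluded countries are user-supplied and
  recorded in the report, never chosen automatically.

## Diagnostics

Every pipeline run computes per-parameter effective sample size
(`arviz.ess`) and a Geweke-style z-score comparing the means of the first
10% and last 50% of each chain, standardised by ESS-adjusted standard
errors of the segments. |z| > 3 or ESS < 100 are logged as warnings and
counted in the run manifest.

## Simulation sizes used in the test suite

Chosen as the smallest designs that measure each property with useful
precision: conditional-moment checks at 10⁵–2·10⁵ draws (3 Monte-Carlo-SE
tolerances); quadrature agreement at 50,000 draws / 10 patterns;
recovery at N = 1000, J = 14 pooled over 8 datasets (RMSE) and N = 78
pooled over 3 datasets (correlations) — pooling because a single truth
draw's error is dominated by whether it contains high-discrimination items,
whose posterior SD is ~0.2–0.3 at N = 1000 and ~0.4 at N = 78 regardless
of chain length; interval calibration over 200 datasets at 500 retained
draws each.

## Known limitations

- One factor per index, binary items only; no ordinal or mixed responses,
  no multi-factor structure, no cross-index joint model.
- Sequential single-chain sampler; convergence is monitored, not proven.
  Between-mode mixing relies on the anchor constraint.
- The corner diagnostic is a descriptive operationalisation of a visual
  pattern, not a formal necessary-condition test.
- Index values are *de jure* measures of rules on the books, not of
  enforcement quality.
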