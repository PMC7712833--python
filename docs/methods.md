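# Methods

## Model

Let `y_i` be the number stillborn and `t_i` the total number born in
farrowing `i` of sow `s(i)`. The observation model is a product of
multiplicative binomial (MBN) distributions,

```
f(y | t, φ, θ) = Π_i MBN(y_i | t_i, φ_i, θ),
MBN(x | nb, φ, θ) = C(nb,x) φ^x (1−φ)^{nb−x} θ^{x(nb−x)} / K_nb(φ, θ),
K_{nb−a}(φ, θ)   = Σ_{j=0}^{nb−a} C(nb−a, j) φ^j (1−φ)^{nb−a−j} θ^{(j+a)(nb−a−j)},
```

with a single dispersion parameter θ shared by all litters (θ = 1 recovers
the binomial; θ < 1 means positively dependent piglet fates and
overdispersion). The per-event death probability of a litter is
`p = φ K_{nb−1}/K_nb`, which equals `E[x]/nb`.

Litter size is Gaussian, `t = X b_t + Z u_t + Z p_t + e_t`,
`e_t ~ N(0, I σ²_et)`. The logit of φ takes one of five linear predictors
sharing `X b_l + Z u_l + Z p_l`: nothing extra (I), `λ1 d` (II),
`λ1 d + λ2 d²` (III), or the same with cross-specific coefficients
`λ1k`, `λ2k` (IV, V), with `d_i = t_i − t̄`. Two modelling commitments are
worth stating explicitly:

* the recursion is **phenotypic**: the observed integer `t_i` enters
  `d_i`, never its model prediction, because mortality at farrowing is
  conditioned on the litter that was actually carried;
* `t̄` is the unweighted mean of observed litter size over all records,
  frozen into the model specification so a fitted model is reusable on new
  data;
* `t_i` appears twice on different scales: as a real-valued Gaussian
  response, and as the integer event count `nb` of the MBN.

Priors: `(u_l, u_t) ~ N(0, A ⊗ G)` with A the numerator relationship
matrix; `(p_l, p_t) ~ N(0, I ⊗ P)`; flat priors on `b_t`, `b_l`, the λ's,
and (within bounds) on G, P diagonals, σ²_et and θ. Default bounds:
variances in (1e−6, 100), θ in (1e−3, 5]; G and P additionally constrained
positive definite. The bounds are vague relative to the magnitudes at
which the model operates (variances of order 0.05–4.5, θ near 0.8).

## Identifiability conventions

The predictors carry no intercept. All 9 cross levels are kept — cross
effects absorb the overall mean, making them directly comparable — while
the first parity and first year-season level are dropped (absorbed).
Summaries additionally report cross effects as deviations from their
9-level mean, which is the convention-free quantity.

The Dickerson system (direct `D_E, D_R, D_T`, maternal `M_E, M_R, M_T`,
heterosis `H_ER, H_ET, H_RT`; e.g. `b(ER) = ½D_E + ½D_R + M_R + H_ER` for
a sow with E sire and R dam) has rank 8: adding a constant to every D and
subtracting it from every M leaves all cross effects unchanged. The solver
returns the minimum-norm least-squares solution with rank and residual
metadata. Heterosis effects and within-block differences are estimable and
are verified against their closed forms, e.g.
`H_ER = (b_ER + b_RE − b_EE − b_RR)/2`.

## Sampler

One iteration cycles four blocks:

1. **Gaussian locations** (`b_t`, `u_t`, `p_t`): single-site Gibbs scans
   with exact conjugate normal full conditionals. For `u_t`, the
   conditional uses the sparse rows of A⁻¹ and the coupling to `u_l`
   through G⁻¹; assembling and factorizing the full mixed-model equations
   every iteration would cost far more at pedigree sizes in the thousands
   for no statistical gain.
2. **Logit locations** (`b_l`, `u_l`, `p_l`, λ's): single-site Gaussian
   random-walk Metropolis. Acceptance uses only the MBN terms of the
   affected records (each record's current log-likelihood is cached, so a
   proposal costs one pmf evaluation) plus the Gaussian prior terms
   coupling `u_l ↔ u_t` and `p_l ↔ p_t`. Pedigree individuals without
   records take prior-only moves.
3. **Variances**: with flat priors, `G | u ~ IW(U'A⁻¹U, q_u − 3)` and
   `P | p ~ IW(P'P, q_p − 3)` (density convention
   `|Σ|^{−(df+p+1)/2} exp(−½ tr(S Σ⁻¹))`, p = 2), and
   `σ²_et | e ~ SSR/χ²_{N−2}`. Draws outside the bounds or non-PD are
   rejected and redrawn (truncation); more than 10⁴ consecutive rejections
   raises an error advising wider bounds. If the sufficient statistic is
   degenerate (effects frozen at zero, or q < 5), the diagonal is drawn
   directly from the power-law density ∝ x^(−q/2) truncated to the bounds,
   which is the corresponding flat-prior conditional.
4. **θ**: random-walk Metropolis on log θ (flat prior on θ inside bounds,
   with the log-scale Jacobian), evaluating the full MBN likelihood since
   θ enters every litter's normalizer.

Proposal standard deviations — one per block — adapt every 25 iterations
during burn-in toward an acceptance rate of 0.44 (multiplicative updates,
floored at 1e−4) and are frozen afterwards, so post-burn-in draws come
from a fixed, valid MH kernel. All randomness flows from one numpy
Generator seeded by the configuration; chains are bitwise reproducible.

Correctness anchors: on a toy with a single free parameter the MCMC
marginal matches deterministic grid integration (Kolmogorov–Smirnov
distance < 0.05 at 50k draws); conjugate toys match hand-solved normal
posteriors; the MBN pmf itself is exact to 1e−12 against brute-force
enumeration for nb ≤ 30.

## Numerical choices

* All MBN arithmetic in log space with log-sum-exp; `θ^{x(nb−x)}` spans
  hundreds of orders of magnitude otherwise. Sampling inverts the exact
  CDF over the nb+1 support points (litter sizes are small).
* A is built by the tabular method with inbreeding; A⁻¹ directly by
  Henderson's rules with Mendelian-sampling variances
  `δ_i = ½ − ¼(F_s + F_d)` from memoised kinship recursions. Unknown
  parents are unrelated founders of their declared population; no genetic
  groups.
* CPO uses the harmonic-mean estimator via log-sum-exp of negated
  log-likelihoods; a zero-likelihood draw zeroes that record's CPO with a
  warning. By default the likelihood entering CPO is the MBN probability
  of `y_i` alone (conditional on the sampled effects): the five candidate
  models differ only on the logit side, so they are compared on the same
  response. The joint (stillbirth + litter size) variant is available as a
  switch.
* HPD intervals are shortest-interval (not equal-tailed), computed from
  sorted draws.

## Synthetic-data generator

The generator emulates the motivating study design: founders per variety
(E 13♂/34♀, R 18♂/62♀, T 38♂/69♀), an intermediate generation of purebred
matings sized so a boar sires ~8 and a dam produces ~3 of the next
generation, and a sow generation with the surveyed counts per cross
(EE 100, ER 527, ET 177, RE 196, RR 175, RT 488, TE 36, TR 343, TT 68 —
sire breed letter first), scalable by a single factor. Each sow
contributes 3–6 records (uniform), parity 1..n capped at 6, year-season
assigned uniformly over 30 levels.

True parameters default to the magnitudes at which the method operates:
mean litter size 8.46, per-event stillbirth rate 0.0296, λ1 = 0.257,
θ = 0.816, σ²_et = 4.497, G and P built from variances
(0.050, 0.397, r_a = 0.203) and (0.418, 0.368, r_p = 0.028), litter-size
cross means and logit-side cross deviations at reported values (unreported
logit deviations set to 0).

Generation draws `(u_l, u_t) ~ N(0, A ⊗ G)` exactly by gene-dropping
(Mendelian-sampling recursion, no dense A), `(p_l, p_t) ~ N(0, I ⊗ P)`,
rounds Gaussian litter size to an integer floored at 1, and draws
stillbirths from the MBN at
`logit φ = base + systematic + u_l + p_l + recursion`.

Two calibration choices matter. Year-season effects are drawn centred
(balanced deviations). And because the founder pools are small, the
realized mean breeding value of the sow generation drifts by ±0.1 piglets
between runs; the generator therefore solves for two global constants —
one shifting the litter-size predictor, one the logit baseline — so that
the realized record-weighted mean litter size equals `t̄` and the expected
litter-size-weighted stillbirth rate equals its target (the latter by root
finding on the exact MBN per-event probabilities). Only fixed constants
absorb the drift; the random effects keep their exact `N(0, A ⊗ G)` and
`N(0, I ⊗ P)` laws, just as the cross effects of a fitted model would
absorb the same drift in real data.

What the generator does **not** emulate: selection or non-random mating by
merit, litter-level covariates (piglet weights, farrowing duration),
missing records, and real year-season seasonality. Passing recovery tests
therefore show that the sampler inverts its own generative model at
realistic parameter values and design sizes — not that the model is
correct for any particular farm's data.

## Problem sizes and test design

Desk-scale settings used throughout the test-suite and the acceptance
script, chosen once:

* default chain 30,000 iterations, 5,000 burn-in, thin 10 (long chains are
  a configuration change);
* parameter recovery: quarter-scale design (~530 sows, ~2,400 records),
  model II truth; posterior means of λ1, θ, σ²_et land within 3 posterior
  sds of the generating values and the sign of λ1 is recovered;
* model comparison: ten replicates of a 12%-scale design (~1,100 records
  each, the smallest size at which λ1 is clearly identified — posterior sd
  ≈ 0.03–0.04 against a generating value of 0.257), models I and II fit
  with 5,000-iteration chains; LogCPO prefers the recursive truth in all
  ten.

## Known limitations

* Single-site MH on the logit side mixes slowly for strongly confounded
  blocks (θ versus the logit-scale variances on small datasets); short
  chains on a few hundred records leave θ near its starting value. The
  default chain length is sized for the quarter-scale design and above.
* Overdispersion with θ < 1 puts non-trivial mass on whole-litter loss;
  at a few hundred records this makes λ1 weakly identified, which is a
  property of the model, not of the sampler.
* The Gaussian litter-size model hands a rounded, floored integer to the
  MBN when simulating; litter sizes of 0 are not generated.
* Dickerson D and M are reported as minimum-norm values plus deviations;
  their absolute levels are conventions, only contrasts carry meaning.
* No multiple chains, tempering, or automatic convergence stopping;
  inspect acceptance rates and traces, or rerun with another seed.
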