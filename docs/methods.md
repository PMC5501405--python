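# Methods

## The model

Respondents choose among three inhalers per question: two fictitious
profiles (A, B) built from the attribute schema and the respondent's own
current inhaler. The random-utility model behind every stage of the package
is

    U_ij = x_ij' β + c_ij β_cost + 1[j = current] (δ + b_i) + ε_ij,

where `x_ij` is the dummy coding of the six device attributes against their
reference levels, `c_ij` the cost increment in €/month (linear in utility),
`δ` an alternative-specific constant for the current inhaler capturing
status-quo preference, `b_i ~ N(0, σ²)` a patient-level random effect on
that constant, and `ε_ij` independent standard Gumbel errors, one draw per
alternative per choice set.

Because a single utility draw underlies both steps of the stated two-step
protocol (A vs B, then winner vs current), the observed outcome is exactly
the descending sort of the three utilities — a complete ranking. The
likelihood is therefore the rank-ordered ("exploded") logit: the ranking
probability is a product of multinomial-logit choices over successively
smaller alternative sets,

    P(r₁ ≻ r₂ ≻ r₃ | b) = e^{V₁}/(e^{V₁}+e^{V₂}+e^{V₃}) · e^{V₂}/(e^{V₂}+e^{V₃}).

The patient effect is integrated out per respondent with Gauss–Hermite
quadrature (default 15 nodes; plain rather than adaptive — the integral is
one-dimensional and a node-count sweep in the tests shows the σ = 0 limit
and moderate-σ likelihoods agree with high-node references far below the
optimizer tolerance). With σ fixed at 0 the likelihood reduces exactly to
the plain exploded logit, which the tests verify at several node counts.

The random effect sits on the status-quo constant only. A patient intercept
common to all three alternatives would cancel from every logit contrast;
the only patient-constant term that survives is alternative-specific, and
correlating the repeated keep-my-inhaler choices is precisely what the
repeated-measures correction is for.

### Estimation

Maximum likelihood by BFGS with an analytic gradient (the stagewise score
`x_chosen − Σ p_j x_j`, averaged over quadrature nodes with the
per-respondent posterior node weights), followed by damped Newton polish
steps when the gradient has not reached the 1e-5 tolerance. σ is estimated
as log σ to keep it positive; starting values are 0 for utility terms,
−0.05 for cost, and σ = 0.1. Standard errors come from the inverse observed
information (central-difference Hessian of the analytic gradient), with σ
mapped back by the delta method. Odds ratios are `exp(estimate)`; p-values
are two-sided Wald tests. No multiple-testing correction is applied —
p-values are reported raw, matching how such tables are usually printed.

### Willingness to pay

WTP for an attribute move is `estimate(term) / (−estimate(cost))`, in
€/month. Credibility intervals come from random-walk Metropolis on the
exploded-logit log-likelihood with flat priors (flat on log σ), initialized
at the MLE with proposal covariance `(2.38/√d)² · vcov`. The WTP ratio is
computed per retained draw; the posterior mean and the central 95%
percentile interval are reported alongside the MLE point ratio (the
posterior mean of a ratio exceeds the ratio of means — Jensen — so the two
are intentionally kept distinct). Draws with a nonnegative cost coefficient,
where the ratio is undefined, are excluded and counted; at study scale they
essentially never occur. Defaults: 30 000 iterations, 5 000 burn-in,
thinning 5. An acceptance rate outside [0.1, 0.6] triggers a warning to
rescale the proposal.

## Design generation

Designs are scored by D-efficiency, `det(M(β))^{1/p} / n_sets`, where `M`
is the multinomial-logit Fisher information `Σ_s X_s'(P_s − p_s p_s')X_s`
over the design's two-alternative sets. The prior is β = 0
(utility-neutral): no pilot estimates are assumed, and main-effects dummy
coding honours the no-interaction assumption. The search is classical
coordinate exchange: from each of 20 seeded random starts, every (set,
alternative, attribute) coordinate is revisited and every alternative level
tried, keeping strict improvements only (the incumbent wins ties, for
stability), with incremental information updates. Two constraints hold
throughout: no set may pair two identical profiles, and no two sets may
show the same unordered profile pair — a questionnaire should not repeat a
question. Level overlap on individual attributes is allowed.

At β = 0 with cost entered linearly, the optimum allocates cost to its
extreme levels (€0 and €10) while all categorical attributes balance
perfectly — the expected behaviour of D-optimality for a linear term, worth
knowing when comparing against orthogonal-array instruments that balance
all four cost levels.

Blocking into three blocks of 12 minimizes the maximum per-block deviation
of level frequencies from perfect balance by greedy pairwise swaps from a
seeded random equal split. The status-quo alternative is not part of design
optimization: its profile differs per respondent and is unknown at design
time.

## The synthetic cohort

The generator emulates the study sample: 201 asthma and 93 COPD
respondents. Within disease group, covariates are drawn independently from
marginals matched to the published sample description:

| covariate | asthma | COPD | distribution |
|---|---|---|---|
| age (years) | mean 40.3, SD 13.4 | mean 48.5, SD 15.2 | normal, truncated at 18; location calibrated so the truncated mean hits the target |
| female | 68.7% | 54.8% | Bernoulli |
| device | 47% Turbuhaler / 53% Diskus | same | categorical |
| income band | published 6-band split | published split | categorical |
| monthly cost (€) | mean 11.9, SD 21.9 | mean 22.1, SD 37.4 | lognormal, moment-matched |
| HUI3 | mean 0.71, SD 0.25 | mean 0.54, SD 0.30 | beta, moment-matched |
| satisfied | 52% | 46% | remainder split 5:3 neutral:unsatisfied (not published; documented default) |

Blocks are assigned round-robin after a seeded shuffle. The two current
devices map to fixed attribute profiles (2–3 preparation steps, dry-cloth
mouthpiece care, fixed orientation, not usable when breathless; they differ
on the dose counter and lactose taste) with a €0 cost increment — the
published study never tabulates these profiles, so they are overridable
configuration, and results involving the status-quo contrast depend on
them. Choice simulation defaults to the published stratified coefficient
tables as true utilities, with σ = 0.5 for the status-quo random effect
(the study reports no σ; 0.5 gives repeated-choice correlation of a size
typical for stated-preference panels and is the package-wide simulation
default).

What the generator does **not** emulate: covariate dependence within group
(only marginals are published), item nonresponse and inattention, any
learning or fatigue over the 12 questions, and HUI3 dimension structure
(the score is carried as an opaque covariate). Passing recovery tests
therefore show that the estimator inverts its own data-generating process
at study scale — not that real respondents behave this way.

Seeding: one master seed expands via `numpy.random.SeedSequence` into
per-respondent and per-(respondent, set) substreams, so any record can be
regenerated independently of iteration order and exports are byte-stable.

## Interaction analyses

Disease × attribute: the pooled model is refit with products of every
coded attribute column (and cost) with the COPD indicator; each attribute's
interaction block gets a joint Wald chi-square p-value, plus a pooled
likelihood-ratio test, and stratified fits are recommended when any block
is significant at 0.05. Covariate × status-quo: one model per covariate
with the covariate × current-inhaler product (gender as a female indicator,
age centered, disease as COPD indicator, income as an ordinal 1–5 score
with non-answers dropped from that model only, satisfaction as two dummies
against "unsatisfied").

## Numerical choices and degenerate inputs

- Exploded probabilities use max-subtracted log-sum-exp throughout; the
  permutation oracle agreement is 1e-12.
- Singular information matrices score a D-efficiency of 0; designs with too
  few sets to identify all coded parameters fall back to the best start
  rather than failing.
- A constant coded column makes its correlations undefined: reported as
  missing with a warning, not as 0.
- Zero standard errors make Wald tests raise rather than return p = 0.
- Estimates above 15 in absolute value trigger a separation warning naming
  the column.
- Ties in coordinate exchange keep the incumbent, making the search
  deterministic given its seed.

## Validation experiment sizes

The canned experiments in `inhalerdce.validation` use: 50 replicates for
parameter recovery (201 × 12, σ = 0.5, 15 quadrature nodes), 100 replicates
for disease × cost interaction power (294 respondents, 7 nodes), and 100
replicate studies for WTP interval coverage with a shortened Metropolis
chain (2 000 iterations, 500 burn-in, thinning 2, 5 nodes) — chain length
and node counts chosen as the smallest giving stable 2.5/97.5 percentiles
in pilot runs, and stated here because interval endpoints at this chain
length still carry a few percent of Monte-Carlo noise.

## Known limitations

- The regenerated design follows the stated criteria (D-efficiency,
  main effects, 36 sets, 3 blocks) but is not the original instrument,
  which is unpublished; published-coefficient comparisons are recovery
  checks on synthetic data, not replications.
- The exploded-ranking reading of the two-step protocol is the standard
  interpretation of a rank-ordered logit on three alternatives; modeling
  the two binary stages separately would discard the transitivity
  information and is not implemented.
- The random effect is normal by assumption; its distributional form is
  not identified from the published tables.
- WTP ratios are reported in €/month at the attribute-level contrasts of
  the coding; no WTP-space estimation or Krinsky–Robb/delta intervals.
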