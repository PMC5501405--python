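# inhalerdce

A discrete choice experiment (DCE) toolkit for studying patient preferences
over dry-powder inhaler devices — for health economists and outcomes
researchers who need the full quantitative arc of a stated-preference study
in one reproducible pipeline:

1. **Design**: D-efficient fractional-factorial choice designs (36 paired
   choice sets in 3 blocks of 12 by default) by coordinate exchange, with
   balance/orthogonality diagnostics.
2. **Simulation**: a synthetic cohort emulating a 294-respondent study
   sample (201 asthma, 93 COPD) and two-step choices — fictitious inhaler A
   vs B, then the winner vs the respondent's current inhaler — generated
   from a rank-ordered logit.
3. **Estimation**: maximum likelihood for the rank-ordered (exploded) logit
   with a patient-level random effect on the status-quo constant, odds
   ratios, Wald tests, disease × attribute and covariate × status-quo
   interaction models.
4. **Willingness to pay**: WTP ratios with 95% credibility intervals from a
   random-walk Metropolis chain.

## The model

Each choice set offers three alternatives with utilities

    U_ij = x_ij' β + c_ij β_cost + 1[j = current] (δ + b_i) + ε_ij,

with dummy-coded device attributes `x` (ease of use, dose counter, dose
confirmation, mouthpiece hygiene, handling flexibility, usability when
breathless), a linear monthly cost increment `c` (€0/3/6/10), a status-quo
constant δ with patient effect `b_i ~ N(0, σ²)`, and Gumbel errors. The
observed two-step choice reveals the full utility ranking, whose
probability "explodes" into sequential logit stages:

    P(r₁ ≻ r₂ ≻ r₃) = E_b [ e^{V₁}/Σ₃ e^{V} · e^{V₂}/Σ₂ e^{V} ].

Willingness to pay for an attribute move is `β_term / (−β_cost)` in
€/month, with intervals from the per-draw ratio along an MCMC chain.

## Worked example

Run the full simulated study from the shell (a few minutes; all stages are
seeded and byte-reproducible):

```bash
inhalerdce run --seed 1 --out demo_output
```

or the equivalent in Python:

```python
from inhalerdce import RunConfig, run_pipeline
report = run_pipeline(RunConfig(master_seed=1, out_dir="demo_output"))
print(report.fit_tables["asthma"].head(3))
```

The run (about 5 minutes) writes every table as CSV plus a text report
under `demo_output/`. Excerpts from `report.txt` of the `--seed 1` run:

```
D-efficiency: 0.3248
duplicate sets: 0

Marginal utilities — asthma
                               term  estimate  std_error  p_value  odds_ratio
                ease_of_use[1 step]    0.5763     0.0603   0.0000      1.7795
          ease_of_use[2 to 3 steps]    0.2731     0.0584   0.0000      1.3140
                  dose_counter[yes]    0.4102     0.0417   0.0000      1.5072
                               cost   -0.1159     0.0046   0.0000      0.8906
                    current_inhaler    0.2632     0.0795   0.0009      1.3011
                           sigma_re    0.5511     0.0523      NaN         NaN

Willingness to pay (€/month) — asthma
                term                 point  posterior_mean  ci_low  ci_high
 ease_of_use[1 step]                 4.975           4.973   3.994    6.094
   dose_counter[yes]                 3.541           3.565   2.857    4.296
```

Reading this: the asthma cohort was simulated with a one-step ease-of-use
marginal utility of 0.55, a cost coefficient of −0.114 and a status-quo
random effect SD of 0.5 (the published estimates), and the fit recovers
0.576 (SE 0.060), −0.116 and 0.551 on this single draw. The WTP row says a
one-step preparation inhaler is worth about €5 per month of extra
out-of-pocket cost to these synthetic respondents (95% credibility interval
€4.0–€6.1), computed as 0.576 / 0.116 per MCMC draw. The estimate/OR pair
0.5763 → 1.7795 illustrates the odds-ratio transform exp(β).

Individual stages are also available as subcommands (`design`, `simulate`,
`fit`, `wtp`, `report`) and as library functions (`search_design`,
`generate_respondents`, `simulate_study`, `fit_mle`, `mcmc_sample`,
`wtp_table`, ...).

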