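"""Simulation studies validating the estimation pipeline at study scale.

Three canned experiments, all fully seeded: parameter recovery of the
published asthma utilities across replicate synthetic studies, power to
detect the asthma/COPD difference in cost sensitivity via the disease ×
cost interaction, and frequentist coverage of the MCMC credibility interval
for the one-step ease-of-use willingness to pay.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .cohort import (
    CohortConfig,
    cohort_to_frame,
    default_cohort_config,
    generate_respondents,
)
from .design import Design, search_design
from .model import ModelSpec, fit_mle, wald_block_test
from .params import ASTHMA_ESTIMATES, estimates_only
from .schema import inhaler_schema
from .simulate import TrueModel, simulate_study_frame
from .wtp import MCMCConfig, mcmc_sample, wtp_credible, wtp_point, wtp_ratio

ONE_STEP = "ease_of_use[1 step]"


def _sub_seed(seed: int, *key: int) -> int:
    return int(
        np.random.SeedSequence([seed, *key]).generate_state(1)[0] % (2**31 - 1)
    )


def study_design(seed: int, n_restarts: int = 10) -> Design:
    """The 36-set, 3-block design used by the simulation experiments."""
    return search_design(
        inhaler_schema(), 36, 3, seed=_sub_seed(seed, 0), n_restarts=n_restarts
    )


def asthma_only_config() -> CohortConfig:
    cfg = default_cohort_config()
    return CohortConfig(asthma=cfg.asthma, copd=replace(cfg.copd, n=0))


def replicate_recovery(
    n_replicates: int = 50,
    seed: int = 42,
    sigma_re: float = 0.5,
    quadrature_nodes: int = 15,
    design: Design | None = None,
) -> pd.DataFrame:
    """Fit replicate synthetic asthma studies at the published utilities.

    Each replicate draws a fresh 201-respondent asthma cohort, simulates its
    12 choice sets under the published asthma coefficients with a
    status-quo random effect of SD ``sigma_re``, and refits by maximum
    likelihood. Returns one row of estimates per replicate.
    """
    design = design or study_design(seed)
    truth = TrueModel.asthma_defaults(sigma_re=sigma_re)
    spec = ModelSpec(quadrature_nodes=quadrature_nodes)
    cfg = asthma_only_config()
    rows = []
    for rep in range(n_replicates):
        cohort = generate_respondents(cfg, seed=_sub_seed(seed, 1, rep))
        frame = simulate_study_frame(
            cohort, design, truth, seed=_sub_seed(seed, 2, rep)
        )
        fit = fit_mle(frame, cohort_to_frame(cohort), spec)
        row = fit.estimates.to_dict()
        row["converged"] = fit.converged
        row["replicate"] = rep
        rows.append(row)
    return pd.DataFrame(rows).set_index("replicate")


def recovery_truth(sigma_re: float = 0.5) -> dict[str, float]:
    truth = dict(estimates_only(ASTHMA_ESTIMATES))
    truth["sigma_re"] = sigma_re
    return truth


def interaction_power(
    n_replicates: int = 100,
    seed: int = 7,
    sigma_re: float = 0.5,
    quadrature_nodes: int = 7,
    alpha: float = 0.05,
    design: Design | None = None,
) -> pd.DataFrame:
    """Disease × cost interaction detection across replicate pooled studies.

    Each replicate simulates the full 294-respondent cohort, asthma
    respondents under the asthma utilities (cost −0.114) and COPD
    respondents under the COPD utilities (cost −0.067), then fits the pooled
    model with attribute × disease interactions and records the Wald
    p-value of the cost interaction block.
    """
    from .pipeline import simulate_mixed_cohort

    design = design or study_design(seed)
    spec = ModelSpec(
        quadrature_nodes=quadrature_nodes,
        interactions=[
            (a.name, "disease") for a in inhaler_schema()
        ],
    )
    rows = []
    for rep in range(n_replicates):
        cohort = generate_respondents(
            default_cohort_config(), seed=_sub_seed(seed, 3, rep)
        )
        frame = simulate_mixed_cohort(
            cohort, design, seed=_sub_seed(seed, 4, rep), sigma_re=sigma_re
        )
        fit = fit_mle(frame, cohort_to_frame(cohort), spec)
        p = wald_block_test(fit, ["cost:COPD"])
        rows.append({"replicate": rep, "p_cost_interaction": p,
                     "detected": p < alpha})
    return pd.DataFrame(rows).set_index("replicate")


def wtp_coverage(
    n_studies: int = 100,
    seed: int = 9,
    sigma_re: float = 0.5,
    quadrature_nodes: int = 5,
    mcmc: MCMCConfig | None = None,
    design: Design | None = None,
    term: str = ONE_STEP,
) -> pd.DataFrame:
    """Coverage of the 95% MCMC credibility interval for one-step WTP.

    Simulates replicate asthma studies at the published utilities, runs the
    Metropolis chain on each, and checks whether the central 95% interval of
    the per-draw WTP ratio covers the true ratio 0.55 / 0.114.
    """
    design = design or study_design(seed)
    truth_model = TrueModel.asthma_defaults(sigma_re=sigma_re)
    true_ratio = wtp_ratio(estimates_only(ASTHMA_ESTIMATES), term)
    spec = ModelSpec(quadrature_nodes=quadrature_nodes)
    cfg = asthma_only_config()
    rows = []
    for rep in range(n_studies):
        cohort = generate_respondents(cfg, seed=_sub_seed(seed, 5, rep))
        frame = simulate_study_frame(
            cohort, design, truth_model, seed=_sub_seed(seed, 6, rep)
        )
        fit = fit_mle(frame, cohort_to_frame(cohort), spec)
        chain_cfg = mcmc or MCMCConfig(
            n_iter=2000, burn_in=500, thin=2, seed=0
        )
        chain_cfg = replace(chain_cfg, seed=_sub_seed(seed, 7, rep))
        draws = mcmc_sample(fit, chain_cfg)
        res = wtp_credible(draws, term, point=wtp_point(fit, term))
        rows.append(
            {
                "replicate": rep,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "posterior_mean": res.posterior_mean,
                "point": res.point,
                "covers": res.ci_low <= true_ratio <= res.ci_high,
            }
        )
    return pd.DataFrame(rows).set_index("replicate")
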