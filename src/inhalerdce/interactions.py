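"""Interaction analyses: disease × attribute and covariate × status-quo.

Two questions from the study design: (1) do asthma and COPD patients value
attributes differently (if so, stratified models are warranted), and (2) do
respondent characteristics shift the propensity to keep the current inhaler?
Both are answered by refitting the rank-ordered logit with product terms and
reporting Wald (and, for the pooled comparison, likelihood-ratio) tests.
No multiple-testing correction is applied; p-values are reported raw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import pandas as pd
from scipy import stats

from .errors import DataError
from .model import (
    FitResult,
    ModelSpec,
    SQ_TERM,
    fit_mle,
    wald_block_test,
)

DEFAULT_INTERACTION_ATTRS = (
    "ease_of_use",
    "dose_counter",
    "dose_confirmation",
    "hygiene",
    "flexibility",
    "breathless_use",
    "cost",
)
TABLE5_COVARIATES = ("gender", "age", "disease", "income", "satisfaction")


@dataclass
class DiseaseInteractionResult:
    per_attribute_p: pd.Series  # block Wald p per attribute's interaction terms
    lrt_statistic: float
    lrt_df: int
    lrt_p: float
    recommend_stratified: bool
    pooled_fit: FitResult
    interacted_fit: FitResult


def test_disease_interactions(
    data: pd.DataFrame,
    cohort: pd.DataFrame,
    spec: ModelSpec | None = None,
    attributes: tuple[str, ...] = DEFAULT_INTERACTION_ATTRS,
    alpha: float = 0.05,
) -> DiseaseInteractionResult:
    """Test whether attribute valuations differ between asthma and COPD.

    Fits the pooled model and the model with attribute × disease product
    terms; reports a Wald chi-square p-value per attribute's interaction
    block, the pooled-vs-interacted likelihood-ratio test, and a
    recommendation to stratify when any block is significant at ``alpha``.
    """
    spec = spec or ModelSpec()
    if cohort["disease"].nunique() < 2:
        raise DataError("interaction inestimable: cohort has a single disease group")

    pooled = fit_mle(data, cohort, replace(spec, interactions=[]))
    int_spec = replace(
        spec, interactions=[(a, "disease") for a in attributes]
    )
    interacted = fit_mle(data, cohort, int_spec)

    per_attr = {}
    for a in attributes:
        terms = [n for n in interacted.names if n.endswith(":COPD")
                 and (n.startswith(f"{a}[") or n == f"{a}:COPD")]
        per_attr[a] = wald_block_test(interacted, terms)
    per_attr = pd.Series(per_attr)

    n_int = sum(n.endswith(":COPD") for n in interacted.names)
    lrt = 2.0 * (interacted.log_likelihood - pooled.log_likelihood)
    lrt_p = float(stats.chi2.sf(max(lrt, 0.0), df=n_int))
    return DiseaseInteractionResult(
        per_attribute_p=per_attr,
        lrt_statistic=float(lrt),
        lrt_df=n_int,
        lrt_p=lrt_p,
        recommend_stratified=bool((per_attr < alpha).any()),
        pooled_fit=pooled,
        interacted_fit=interacted,
    )


def _attribute_blocks(fit: FitResult, spec: ModelSpec) -> dict[str, list[str]]:
    blocks: dict[str, list[str]] = {}
    for a in spec.attributes:
        if a.kind == "continuous":
            blocks[a.name] = [a.name]
        else:
            blocks[a.name] = [f"{a.name}[{l}]" for l in a.coded_levels]
    blocks[SQ_TERM] = [SQ_TERM]
    return blocks


def covariate_interaction_table(
    data: pd.DataFrame,
    cohort: pd.DataFrame,
    spec: ModelSpec | None = None,
    covariates: tuple[str, ...] = TABLE5_COVARIATES,
) -> pd.DataFrame:
    """Per-covariate models with a covariate × current-inhaler product term.

    For each covariate the model is refit with the product of the covariate
    and the status-quo dummy; the returned table has one column per
    covariate and one row per attribute (joint Wald p over that attribute's
    coefficients), plus rows for the current-inhaler constant and for the
    interaction block itself. Respondents without an income answer are
    dropped from the income model only.
    """
    spec = spec or ModelSpec()
    table: dict[str, pd.Series] = {}
    for cov in covariates:
        cov_data, cov_cohort = data, cohort
        if cov == "income":
            answered = cohort.loc[
                cohort["income_band"] != "no answer", "respondent_id"
            ]
            if len(answered) < len(cohort):
                warnings.warn(
                    f"dropping {len(cohort) - len(answered)} respondents with no "
                    "income answer from the income interaction model",
                    stacklevel=2,
                )
            cov_cohort = cohort[cohort["respondent_id"].isin(answered)]
            cov_data = data[data["respondent_id"].isin(answered)]
        fit = fit_mle(
            cov_data, cov_cohort, replace(spec, interactions=[(cov, "status_quo")])
        )
        col = {}
        for attr, terms in _attribute_blocks(fit, spec).items():
            col[attr] = wald_block_test(fit, terms)
        int_terms = [n for n in fit.names if n.startswith(f"{SQ_TERM}:")]
        col[f"{SQ_TERM} × characteristic"] = wald_block_test(fit, int_terms)
        table[cov] = pd.Series(col)
    return pd.DataFrame(table)
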