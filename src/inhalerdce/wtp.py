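"""Willingness-to-pay inference with MCMC credibility intervals.

The WTP for moving an attribute to a given level is the marginal utility of
that move divided by the marginal utility of keeping €1/month — i.e.
estimate(term) / (−estimate(cost)). Interval estimates come from a
random-walk Metropolis chain on the exploded-logit log-likelihood with flat
priors (flat on log sigma), initialized at the MLE with the scaled MLE
covariance as proposal; the WTP ratio is computed per retained draw and
summarized by its posterior mean and central 95% interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, EstimationError
from .model import FitResult, SIGMA_TERM, ranking_loglik

logger = logging.getLogger(__name__)


@dataclass
class MCMCConfig:
    """Random-walk Metropolis settings."""

    n_iter: int = 30_000
    burn_in: int = 5_000
    thin: int = 5
    proposal_scale: float | None = None  # default 2.38 / sqrt(dim)
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ConfigError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ConfigError("thin must be >= 1")


@dataclass
class WTPResult:
    term: str
    point: float  # MLE ratio, €/month
    posterior_mean: float
    ci_low: float
    ci_high: float
    n_draws: int
    group: str | None = None


def wtp_ratio(estimates, term: str) -> float:
    """WTP ratio on a coefficient mapping: estimate(term) / (−estimate(cost)).

    Raises when the cost coefficient is nonnegative — the ratio is then
    undefined and is never silently sign-flipped.
    """
    cost = float(estimates["cost"])
    if cost >= 0:
        raise EstimationError(
            f"cost coefficient {cost:.4f} is nonnegative; WTP is undefined"
        )
    return float(estimates[term]) / (-cost)


def wtp_point(fit: FitResult, term: str) -> float:
    """Point WTP from a converged fit, in €/month."""
    return wtp_ratio(fit.estimates, term)


def mcmc_sample(fit: FitResult, config: MCMCConfig) -> pd.DataFrame:
    """Posterior draws by random-walk Metropolis, initialized at the MLE.

    Samples on the internal scale (coefficients, log sigma) with flat
    priors; the returned frame is on the reporting scale (sigma
    exponentiated). Deterministic given ``config.seed``; logs the acceptance
    rate and warns when it leaves [0.1, 0.6].
    """
    enc, spec = fit.encoded, fit.spec
    x = fit.params_internal.copy()
    d = x.size
    scale = config.proposal_scale or 2.38 / np.sqrt(d)
    cov = fit.vcov_internal
    # guard: proposal covariance must be positive definite
    evals = np.linalg.eigvalsh(0.5 * (cov + cov.T))
    jitter = max(0.0, 1e-10 - float(evals.min()))
    L = np.linalg.cholesky(0.5 * (cov + cov.T) + jitter * np.eye(d)) * scale

    rng = np.random.default_rng(config.seed)
    ll = ranking_loglik(x, enc, spec)
    kept = []
    n_accept = 0
    for it in range(config.n_iter):
        prop = x + L @ rng.standard_normal(d)
        try:
            ll_prop = ranking_loglik(prop, enc, spec)
        except FloatingPointError:
            ll_prop = -np.inf
        if np.log(rng.random()) < ll_prop - ll:
            x, ll = prop, ll_prop
            n_accept += 1
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            kept.append(x.copy())

    rate = n_accept / config.n_iter
    logger.info("Metropolis acceptance rate: %.3f", rate)
    if not 0.1 <= rate <= 0.6:
        import warnings

        warnings.warn(
            f"Metropolis acceptance rate {rate:.3f} outside [0.1, 0.6]; "
            "consider rescaling the proposal",
            stacklevel=2,
        )

    draws = np.asarray(kept)
    names = [n for n in fit.names if n != SIGMA_TERM]
    out = pd.DataFrame(draws[:, : len(names)], columns=names)
    if spec.has_random_effect:
        out[SIGMA_TERM] = np.exp(draws[:, -1])
    return out


def wtp_credible(
    draws: pd.DataFrame,
    term: str,
    point: float | None = None,
    group: str | None = None,
) -> WTPResult:
    """Posterior WTP summary for one term from MCMC draws.

    Draws with a nonnegative cost coefficient (where the ratio is undefined)
    are excluded and their fraction logged.
    """
    valid = draws["cost"] < 0
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning(
            "excluding %d/%d draws with nonnegative cost coefficient",
            n_bad,
            len(draws),
        )
    sub = draws.loc[valid]
    if not len(sub):
        raise EstimationError("no draws with negative cost coefficient")
    ratios = sub[term] / (-sub["cost"])
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return WTPResult(
        term=term,
        point=float("nan") if point is None else float(point),
        posterior_mean=float(ratios.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_draws=int(len(sub)),
        group=group,
    )


def wtp_table(
    fit: FitResult,
    draws: pd.DataFrame,
    terms: list[str] | None = None,
    group: str | None = None,
) -> pd.DataFrame:
    """WTP point estimates and 95% credibility intervals for many terms."""
    if terms is None:
        terms = [
            n
            for n in fit.names
            if n not in ("cost", SIGMA_TERM) and not n.startswith("cost")
        ]
    rows = []
    for t in terms:
        res = wtp_credible(draws, t, point=wtp_point(fit, t), group=group)
        rows.append(
            {
                "term": res.term,
                "group": group,
                "point": res.point,
                "posterior_mean": res.posterior_mean,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "n_draws": res.n_draws,
            }
        )
    return pd.DataFrame(rows)


def compare_groups(wtp_a: pd.DataFrame, wtp_b: pd.DataFrame) -> pd.DataFrame:
    """Side-by-side WTP for two groups with differences and interval overlap."""
    a = wtp_a.set_index("term")
    b = wtp_b.set_index("term")
    only_a = sorted(set(a.index) - set(b.index))
    only_b = sorted(set(b.index) - set(a.index))
    if only_a or only_b:
        raise ConfigError(
            f"term sets differ: only in first {only_a}, only in second {only_b}"
        )
    out = pd.DataFrame(
        {
            "point_a": a["point"],
            "point_b": b["point"],
            "difference": b["point"] - a["point"],
            "mean_a": a["posterior_mean"],
            "mean_b": b["posterior_mean"],
            "intervals_overlap": (a["ci_low"] <= b["ci_high"])
            & (b["ci_low"] <= a["ci_high"]),
        }
    )
    return out.reset_index()
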