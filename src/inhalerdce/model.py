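"""Rank-ordered (exploded) logit with a status-quo patient effect.

The ranking of the three alternatives in a choice set is modeled as a
sequence of multinomial-logit choices over the not-yet-ranked alternatives
("exploding" the ranking): with utilities V_1 >= ranking order,

    P(ranking) = prod_stages exp(V_chosen) / sum_{j in remaining} exp(V_j).

A patient-level normal random effect b_i ~ N(0, sigma^2) on the current-
inhaler constant correlates a respondent's repeated status-quo choices; the
marginal likelihood integrates it out with Gauss–Hermite quadrature. The
log-likelihood and its analytic gradient are fully vectorized; sigma is
estimated on the log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from .errors import ConfigError, DataError, EstimationError
from .schema import AttributeSpec, inhaler_schema

SQ_TERM = "current_inhaler"
SIGMA_TERM = "sigma_re"
_INCOME_ORDER = {
    "<€22,500": 1.0,
    "€25,000–€34,999": 2.0,
    "€35,000–€49,999": 3.0,
    "€50,000–€74,999": 4.0,
    "€75,000+": 5.0,
    "no answer": np.nan,
}


@dataclass
class ModelSpec:
    """What the rank-ordered logit includes and how it is integrated.

    interactions lists pairs ``(attribute_or_covariate, target)`` where the
    target is ``"disease"`` (attribute effects differ between asthma and
    COPD; reference asthma) or ``"status_quo"`` (a respondent covariate
    shifts the current-inhaler constant).
    """

    attributes: list[AttributeSpec] = field(default_factory=inhaler_schema)
    cost_as_continuous: bool = True
    include_status_quo_constant: bool = True
    random_effect: str = "status_quo"  # "none" | "status_quo"
    interactions: list[tuple[str, str]] = field(default_factory=list)
    quadrature_nodes: int = 15

    def __post_init__(self):
        if self.quadrature_nodes < 1:
            raise ConfigError("quadrature_nodes must be >= 1")
        if self.random_effect not in ("none", "status_quo"):
            raise ConfigError(f"unknown random_effect {self.random_effect!r}")
        if not self.cost_as_continuous:
            raise ConfigError("cost must be coded as a continuous variable")

    @property
    def has_random_effect(self) -> bool:
        return self.random_effect == "status_quo"


@dataclass
class EncodedData:
    """Design arrays for the likelihood, rows sorted by (respondent, set, rank)."""

    X: np.ndarray  # (n_rows, p) fixed-effect columns
    sq: np.ndarray  # (n_rows,) status-quo indicator (random-effect loading)
    names: list[str]
    resp_of_set: np.ndarray  # (n_sets,) respondent codes, nondecreasing
    resp_first_set: np.ndarray  # (n_resp,) index of each respondent's first set
    respondent_ids: np.ndarray
    n_sets: int
    n_resp: int

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


def _covariate_columns(
    cov: str, resp_df: pd.DataFrame
) -> tuple[list[str], np.ndarray]:
    """Per-respondent coding of an interaction covariate (columns, values)."""
    if cov == "gender":
        return ["female"], (resp_df["gender"] == "female").to_numpy(float)[:, None]
    if cov == "age":
        age = resp_df["age"].to_numpy(float)
        return ["age"], (age - age.mean())[:, None]
    if cov == "disease":
        return ["COPD"], (resp_df["disease"] == "COPD").to_numpy(float)[:, None]
    if cov == "income":
        vals = resp_df["income_band"].map(_INCOME_ORDER).to_numpy(float)
        return ["income"], vals[:, None]
    if cov == "satisfaction":
        out = np.column_stack(
            [
                (resp_df["satisfaction"] == "neutral").to_numpy(float),
                (resp_df["satisfaction"] == "satisfied").to_numpy(float),
            ]
        )
        return ["satisfaction[neutral]", "satisfaction[satisfied]"], out
    if cov in resp_df.columns:  # any numeric respondent covariate (e.g. hui3)
        vals = resp_df[cov].to_numpy(float)
        return [cov], (vals - np.nanmean(vals))[:, None]
    raise ConfigError(f"unknown interaction covariate {cov!r}")


def encode(
    data: pd.DataFrame,
    cohort: pd.DataFrame | None = None,
    spec: ModelSpec | None = None,
) -> EncodedData:
    """Code long-format ranking data into likelihood arrays.

    One dummy column per non-reference level, cost as its numeric € value,
    a status-quo indicator column, and interaction columns as products.
    Rows come out sorted by (respondent, set, rank) so each consecutive
    triple is one exploded choice set, best alternative first.
    """
    spec = spec or ModelSpec()
    df = data.sort_values(
        ["respondent_id", "set_id", "rank"], kind="mergesort"
    ).reset_index(drop=True)

    counts = df.groupby(["respondent_id", "set_id"], sort=False)["rank"].agg(
        ["size", "min", "max", "nunique"]
    )
    bad = counts[
        (counts["size"] != 3)
        | (counts["min"] != 1)
        | (counts["max"] != 3)
        | (counts["nunique"] != 3)
    ]
    if len(bad):
        rid, sid = bad.index[0]
        raise DataError(
            f"respondent {rid}, set {sid}: ranks are not a permutation of 1..3"
        )

    cols: list[np.ndarray] = []
    names: list[str] = []
    for a in spec.attributes:
        values = df[a.name]
        if a.kind == "continuous":
            cols.append(values.to_numpy(float))
            names.append(a.name)
        else:
            known = values.isin(a.levels)
            if not known.all():
                i = int(np.flatnonzero(~known.to_numpy())[0])
                raise DataError(
                    f"row {i}: unknown level {values.iloc[i]!r} for attribute "
                    f"{a.name!r}"
                )
            for lvl in a.coded_levels:
                cols.append((values == lvl).to_numpy(float))
                names.append(f"{a.name}[{lvl}]")

    sq = (df["alt_id"] == "current").to_numpy(float)
    if spec.include_status_quo_constant:
        cols.append(sq)
        names.append(SQ_TERM)

    resp_ids = df["respondent_id"].to_numpy()
    if spec.interactions:
        if cohort is None:
            raise ConfigError("interaction terms need a cohort table")
        resp_df = cohort.set_index("respondent_id")
        missing = set(resp_ids) - set(resp_df.index)
        if missing:
            raise DataError(f"respondents missing from cohort: {sorted(missing)[:5]}")
        row_resp = resp_df.loc[resp_ids]
        X_so_far = dict(zip(names, cols))
        for what, target in spec.interactions:
            if target == "disease":
                copd = (row_resp["disease"] == "COPD").to_numpy(float)
                if copd.std() == 0:
                    raise DataError(
                        "disease interactions inestimable: only one disease group"
                    )
                base_cols = [
                    n
                    for n in names
                    if n == what or n.startswith(f"{what}[")
                ]
                if not base_cols:
                    raise ConfigError(f"no coded column for attribute {what!r}")
                for n in base_cols:
                    cols.append(X_so_far[n] * copd)
                    names.append(f"{n}:COPD")
            elif target == "status_quo":
                sub_names, vals = _covariate_columns(what, row_resp)
                for j, sn in enumerate(sub_names):
                    v = vals[:, j]
                    keep = ~np.isnan(v)
                    if not keep.all():
                        raise DataError(
                            f"covariate {what!r} has missing values; drop those "
                            "respondents before fitting"
                        )
                    if v.std() == 0:
                        raise DataError(
                            f"covariate {what!r} is constant: collinear with the "
                            "status-quo constant"
                        )
                    cols.append(sq * v)
                    names.append(f"{SQ_TERM}:{sn}")
            else:
                raise ConfigError(f"unknown interaction target {target!r}")

    X = np.column_stack(cols)
    uniq, resp_codes = np.unique(resp_ids, return_inverse=True)
    resp_of_set = resp_codes[::3]
    if np.any(np.diff(resp_of_set) < 0):
        raise DataError("rows are not grouped by respondent after sorting")
    resp_first_set = np.concatenate(([0], np.flatnonzero(np.diff(resp_of_set)) + 1))
    return EncodedData(
        X=X,
        sq=sq,
        names=names,
        resp_of_set=resp_of_set,
        resp_first_set=resp_first_set,
        respondent_ids=uniq,
        n_sets=X.shape[0] // 3,
        n_resp=len(uniq),
    )


def exploded_ranking_logprob(utilities, ranking) -> float:
    """log P(ranking) for one choice set with arbitrarily many alternatives.

    ``ranking`` lists alternative indices best-first. Reference (scalar)
    implementation used as the oracle for the vectorized likelihood.
    """
    u = np.asarray(utilities, float)
    ranking = list(ranking)
    if sorted(ranking) != list(range(len(u))):
        raise DataError(f"ranking {ranking} is not a permutation")
    total = 0.0
    remaining = ranking[:]
    while len(remaining) > 1:
        chosen = remaining[0]
        total += u[chosen] - logsumexp(u[remaining])
        remaining = remaining[1:]
    return float(total)


@lru_cache(maxsize=32)
def _gh_nodes_cached(n: int) -> tuple[np.ndarray, np.ndarray]:
    t, w = np.polynomial.hermite.hermgauss(n)
    return t, np.log(w) - 0.5 * np.log(np.pi)


def _gh_nodes(spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    if not spec.has_random_effect:
        return np.zeros(1), np.zeros(1)
    return _gh_nodes_cached(spec.quadrature_nodes)


def ranking_loglik(
    params: np.ndarray,
    enc: EncodedData,
    spec: ModelSpec,
    with_grad: bool = False,
):
    """Marginal exploded-logit log-likelihood (and, optionally, its gradient).

    ``params`` stacks the fixed-effect coefficients in ``enc.names`` order,
    followed by log(sigma) when the spec has a random effect. With sigma
    fixed at 0 (``random_effect="none"``) this reduces exactly to the plain
    exploded logit.
    """
    params = np.asarray(params, float)
    p = len(enc.names)
    expected = p + (1 if spec.has_random_effect else 0)
    if params.shape != (expected,):
        raise ValueError(f"expected {expected} parameters, got {params.shape}")
    beta = params[:p]
    t, logw = _gh_nodes(spec)
    if spec.has_random_effect:
        with np.errstate(over="ignore"):
            sigma = np.exp(params[p])
        if not np.isfinite(sigma) or sigma > 1e6:
            raise FloatingPointError(f"random-effect SD overflow (log sigma = {params[p]:.3g})")
        b = np.sqrt(2.0) * sigma * t  # (K,)
    else:
        b = np.zeros(1)
    K = b.size

    V = enc.X @ beta  # (n_rows,)
    Vk = V[:, None] + enc.sq[:, None] * b[None, :]  # (n_rows, K)
    if not np.all(np.isfinite(Vk)):
        raise FloatingPointError("non-finite utilities; check parameter scale")
    V3 = Vk.reshape(enc.n_sets, 3, K)

    m3 = V3.max(axis=1, keepdims=True)
    e3 = np.exp(V3 - m3)
    s3 = e3.sum(axis=1)
    m2 = np.maximum(V3[:, 1, :], V3[:, 2, :])
    e2a = np.exp(V3[:, 1, :] - m2)
    e2b = np.exp(V3[:, 2, :] - m2)
    s2 = e2a + e2b
    # log P(set) = V(rank1) - lse(all three) + V(rank2) - lse(last two)
    logp_set = (
        V3[:, 0, :]
        - (m3[:, 0, :] + np.log(s3))
        + V3[:, 1, :]
        - (m2 + np.log(s2))
    )  # (n_sets, K)

    L_ik = np.add.reduceat(logp_set, enc.resp_first_set, axis=0)  # (n_resp, K)
    if spec.has_random_effect:
        ll_i = logsumexp(L_ik + logw[None, :], axis=1)
    else:
        ll_i = L_ik[:, 0]
    ll = float(ll_i.sum())
    if not with_grad:
        return ll

    # posterior node weights per respondent
    if spec.has_random_effect:
        omega = np.exp(L_ik + logw[None, :] - ll_i[:, None])  # (n_resp, K)
    else:
        omega = np.ones_like(L_ik)
    # stage-choice probabilities and per-row score wrt utilities
    p3 = e3 / s3[:, None, :]
    g = np.empty_like(V3)
    g[:, 0, :] = 1.0 - p3[:, 0, :]
    g[:, 1, :] = 1.0 - p3[:, 1, :] - e2a / s2
    g[:, 2, :] = -p3[:, 2, :] - e2b / s2
    g_rows = g.reshape(enc.n_rows, K)
    w_rows = omega[enc.resp_of_set].repeat(3, axis=0)  # (n_rows, K)
    c_rows = (w_rows * g_rows).sum(axis=1)
    grad_beta = enc.X.T @ c_rows
    if spec.has_random_effect:
        # dV/dlog(sigma) = b_k on status-quo rows
        grad_ls = float(enc.sq @ ((w_rows * g_rows) @ b))
        grad = np.concatenate([grad_beta, [grad_ls]])
    else:
        grad = grad_beta
    return ll, grad


@dataclass
class FitResult:
    """Maximum-likelihood fit of the rank-ordered logit."""

    names: list[str]
    estimates: pd.Series
    std_errors: pd.Series
    vcov: pd.DataFrame
    log_likelihood: float
    converged: bool
    n_respondents: int
    n_records: int
    spec: ModelSpec
    params_internal: np.ndarray  # sampling scale: (beta..., log sigma)
    vcov_internal: np.ndarray
    encoded: EncodedData

    @property
    def odds_ratios(self) -> pd.Series:
        return odds_ratios(self)

    @property
    def p_values(self) -> pd.Series:
        return wald_tests(self)

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "estimate": self.estimates,
                "std_error": self.std_errors,
            }
        )
        try:
            out["p_value"] = self.p_values
        except EstimationError:
            out["p_value"] = np.nan
        out["odds_ratio"] = self.odds_ratios
        return out


def _hessian_from_grad(fun_grad, x: np.ndarray) -> np.ndarray:
    """Central-difference Hessian from an analytic gradient."""
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        h = 1e-5 * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        gp = fun_grad(xp)
        gm = fun_grad(xm)
        H[i] = (gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


def fit_mle(
    data: pd.DataFrame,
    cohort: pd.DataFrame | None = None,
    spec: ModelSpec | None = None,
    start: np.ndarray | None = None,
    gtol: float = 1e-5,
) -> FitResult:
    """Fit the rank-ordered logit by quasi-Newton maximization.

    Starting values: 0 for utility terms, -0.05 for cost, log(0.1) for the
    random-effect SD. Standard errors come from the inverse observed
    information (central-difference Hessian of the analytic gradient); the
    SD is mapped back from the log scale by the delta method. Convergence is
    declared when the gradient's max norm falls below ``gtol``; on a
    non-converged fit the standard errors are withheld (NaN).
    """
    spec = spec or ModelSpec()
    enc = encode(data, cohort, spec)
    p = len(enc.names)

    if start is None:
        start = np.zeros(p + (1 if spec.has_random_effect else 0))
        for j, n in enumerate(enc.names):
            if n == "cost" or n.startswith("cost:"):
                start[j] = -0.05
        if spec.has_random_effect:
            start[p] = np.log(0.1)

    def negll(x):
        try:
            ll, g = ranking_loglik(x, enc, spec, with_grad=True)
        except FloatingPointError:
            return np.inf, np.zeros_like(x)
        return -ll, -g

    res = optimize.minimize(
        negll, start, jac=True, method="BFGS",
        options={"gtol": gtol, "maxiter": 500},
    )
    xhat = res.x
    ll, ghat = ranking_loglik(xhat, enc, spec, with_grad=True)
    # Newton polish: BFGS can stop on line-search precision loss before the
    # gradient tolerance; a few damped Newton steps with the observed
    # information finish the climb.
    for _ in range(5):
        if np.max(np.abs(ghat)) <= gtol:
            break
        H = _hessian_from_grad(
            lambda x: -ranking_loglik(x, enc, spec, True)[1], xhat
        )
        try:
            step = np.linalg.solve(H, ghat)
        except np.linalg.LinAlgError:
            break
        for damp in (1.0, 0.5, 0.25, 0.1):
            cand = xhat + damp * step
            try:
                ll_c, g_c = ranking_loglik(cand, enc, spec, with_grad=True)
            except FloatingPointError:
                continue
            if ll_c >= ll:
                xhat, ll, ghat = cand, ll_c, g_c
                break
        else:
            break
    converged = bool(np.max(np.abs(ghat)) <= gtol)

    names = list(enc.names)
    est_internal = xhat.copy()
    H = _hessian_from_grad(lambda x: -ranking_loglik(x, enc, spec, True)[1], xhat)
    try:
        vcov_internal = np.linalg.inv(H)
        if not np.all(np.isfinite(vcov_internal)) or np.any(
            np.diag(vcov_internal) < 0
        ):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        vcov_internal = np.linalg.pinv(H)
        converged = False

    if spec.has_random_effect:
        names_out = names + [SIGMA_TERM]
        sigma = float(np.exp(xhat[p]))
        # delta method: d sigma / d log sigma = sigma
        J = np.eye(p + 1)
        J[p, p] = sigma
        vcov_out = J @ vcov_internal @ J.T
        est_out = np.concatenate([xhat[:p], [sigma]])
    else:
        names_out = names
        vcov_out = vcov_internal
        est_out = xhat

    se = np.sqrt(np.clip(np.diag(vcov_out), 0, None))
    if not res.success and not converged:
        warnings.warn(
            "optimizer did not converge; standard errors withheld", stacklevel=2
        )
        se = np.full_like(se, np.nan)
    big = [n for n, e in zip(names, est_out) if abs(e) > 15]
    if big:
        warnings.warn(
            f"implausibly large estimate(s) for {big}; a column may perfectly "
            "predict the rankings (separation)",
            stacklevel=2,
        )

    return FitResult(
        names=names_out,
        estimates=pd.Series(est_out, index=names_out),
        std_errors=pd.Series(se, index=names_out),
        vcov=pd.DataFrame(vcov_out, index=names_out, columns=names_out),
        log_likelihood=float(ll),
        converged=converged,
        n_respondents=enc.n_resp,
        n_records=enc.n_sets,
        spec=spec,
        params_internal=est_internal,
        vcov_internal=vcov_internal,
        encoded=enc,
    )


def odds_ratios(fit: FitResult) -> pd.Series:
    """exp(estimate) for every utility-scale term (the SD is excluded)."""
    terms = [n for n in fit.names if n != SIGMA_TERM]
    return np.exp(fit.estimates[terms])


def wald_tests(fit: FitResult) -> pd.Series:
    """Two-sided normal p-values for estimate / SE, utility-scale terms."""
    terms = [n for n in fit.names if n != SIGMA_TERM]
    se = fit.std_errors[terms]
    if np.any(se == 0):
        zero = list(se.index[se == 0])
        raise EstimationError(f"degenerate fit: zero standard error for {zero}")
    z = fit.estimates[terms] / se
    return pd.Series(2 * stats.norm.sf(np.abs(z)), index=terms)


def wald_block_test(fit: FitResult, terms: list[str]) -> float:
    """Joint Wald chi-square p-value that a block of coefficients is zero."""
    missing = [t for t in terms if t not in fit.names]
    if missing:
        raise ConfigError(f"terms not in fit: {missing}")
    est = fit.estimates[terms].to_numpy()
    V = fit.vcov.loc[terms, terms].to_numpy()
    stat = float(est @ np.linalg.solve(V, est))
    return float(stats.chi2.sf(stat, df=len(terms)))
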