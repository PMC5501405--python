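"""End-to-end study pipeline: design → simulate → fit → interactions → WTP.

Chains the package stages on either simulated or user-supplied choice data
and writes every table as CSV plus a human-readable text report. One master
seed drives all stages through recorded per-stage substream seeds, so a
rerun with the same configuration reproduces every CSV byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    CohortConfig,
    cohort_to_frame,
    default_cohort_config,
    generate_respondents,
)
from .design import Design, design_diagnostics, search_design, write_design
from .errors import ConfigError, DataError
from .interactions import covariate_interaction_table, test_disease_interactions
from .model import ModelSpec, fit_mle
from .schema import AttributeSpec, inhaler_schema, load_schema
from .simulate import TrueModel, rankings_to_frame, simulate_study
from .wtp import MCMCConfig, compare_groups, mcmc_sample, wtp_table

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the master seed."""
    idx = {"design": 0, "cohort": 1, "simulate": 2, "fit": 3, "mcmc": 4}[stage]
    return int(
        np.random.SeedSequence([master_seed, 1000 + idx]).generate_state(1)[0]
        % (2**31 - 1)
    )


@dataclass
class RunConfig:
    """Configuration of a full simulated study run."""

    schema_path: str | None = None
    n_sets: int = 36
    n_blocks: int = 3
    design_restarts: int = 10
    cohort: CohortConfig | None = None
    sigma_re: float = 0.5
    quadrature_nodes: int = 15
    mcmc: MCMCConfig | None = None
    master_seed: int = 0
    out_dir: str = "study_output"

    def load_attributes(self) -> list[AttributeSpec]:
        if self.schema_path is None:
            return inhaler_schema()
        path = Path(self.schema_path)
        if not path.exists():
            raise ConfigError(f"schema file {path} does not exist")
        return load_schema(path)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        mcmc = raw.pop("mcmc", None)
        cfg = cls(**raw)
        if mcmc is not None:
            cfg.mcmc = MCMCConfig(**mcmc)
        return cfg


@dataclass
class StudyReport:
    design_diagnostics: dict
    cohort_summary: pd.DataFrame
    fit_tables: dict[str, pd.DataFrame]
    disease_interactions: pd.DataFrame
    covariate_interactions: pd.DataFrame
    wtp_tables: dict[str, pd.DataFrame]
    wtp_comparison: pd.DataFrame
    provenance: dict


def cohort_summary(cohort_df: pd.DataFrame) -> pd.DataFrame:
    """Demographic summary, one column per disease group plus the total."""
    groups = {d: g for d, g in cohort_df.groupby("disease")}
    groups["total"] = cohort_df
    rows = {}
    for name, g in groups.items():
        col = {
            "n": len(g),
            "age_mean": g["age"].mean(),
            "age_sd": g["age"].std(),
            "female_pct": 100 * (g["gender"] == "female").mean(),
            "cost_mean": g["current_cost"].mean(),
            "cost_sd": g["current_cost"].std(),
            "hui3_mean": g["hui3"].mean(),
            "hui3_sd": g["hui3"].std(),
        }
        for device, cnt in g["current_inhaler"].value_counts().items():
            col[f"device: {device}"] = cnt
        for band, cnt in g["income_band"].value_counts().items():
            col[f"income: {band}"] = cnt
        rows[name] = pd.Series(col)
    return pd.DataFrame(rows)


def simulate_mixed_cohort(
    cohort, design: Design, seed: int, sigma_re: float = 0.5
) -> pd.DataFrame:
    """Simulate each disease group under its own published utilities."""
    models = {
        "asthma": TrueModel.asthma_defaults(sigma_re),
        "COPD": TrueModel.copd_defaults(sigma_re),
    }
    frames = []
    for disease, model in models.items():
        sub = [r for r in cohort if r.disease == disease]
        if not sub:
            continue
        records = simulate_study(sub, design, model, seed=seed)
        frames.append(rankings_to_frame(records, sub, design))
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: RunConfig) -> StudyReport:
    """Run every stage and write all artifacts under ``config.out_dir``."""
    t0 = time.time()
    attrs = config.load_attributes()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {s: stage_seed(config.master_seed, s) for s in
             ("design", "cohort", "simulate", "mcmc")}

    logger.info("stage 1/5: design search (%d sets, %d blocks)",
                config.n_sets, config.n_blocks)
    design = search_design(
        attrs, config.n_sets, config.n_blocks,
        seed=seeds["design"], n_restarts=config.design_restarts,
    )
    diag = design.diagnostics or design_diagnostics(design)
    write_design(design, out / "design.csv", out / "design_diagnostics.json")

    logger.info("stage 2/5: cohort generation")
    cohort_cfg = config.cohort or default_cohort_config()
    if cohort_cfg.n_blocks != config.n_blocks:
        cohort_cfg = replace(cohort_cfg, n_blocks=config.n_blocks)
    cohort = generate_respondents(cohort_cfg, seed=seeds["cohort"])
    cohort_df = cohort_to_frame(cohort)
    cohort_df.to_csv(out / "cohort.csv", index=False)
    summary = cohort_summary(cohort_df)
    summary.to_csv(out / "cohort_summary.csv")

    logger.info("stage 3/5: choice simulation")
    rankings = simulate_mixed_cohort(
        cohort, design, seed=seeds["simulate"], sigma_re=config.sigma_re
    )
    rankings.to_csv(out / "rankings.csv", index=False)

    logger.info("stage 4/5: estimation and interaction tests")
    spec = ModelSpec(attributes=attrs, quadrature_nodes=config.quadrature_nodes)
    inter = test_disease_interactions(rankings, cohort_df, spec)
    disease_tbl = pd.DataFrame(
        {
            "wald_p": inter.per_attribute_p,
        }
    )
    disease_tbl.loc["(likelihood ratio, pooled vs interacted)", "wald_p"] = (
        inter.lrt_p
    )
    disease_tbl.to_csv(out / "disease_interactions.csv")
    cov_tbl = covariate_interaction_table(rankings, cohort_df, spec)
    cov_tbl.to_csv(out / "covariate_interactions.csv")

    fit_tables: dict[str, pd.DataFrame] = {}
    wtp_tables: dict[str, pd.DataFrame] = {}
    fits = {}
    mcmc_cfg = config.mcmc or MCMCConfig(seed=seeds["mcmc"])
    for disease in ("asthma", "COPD"):
        ids = cohort_df.loc[cohort_df["disease"] == disease, "respondent_id"]
        sub = rankings[rankings["respondent_id"].isin(ids)]
        if not len(sub):
            continue
        fit = fit_mle(sub, cohort_df, spec)
        fits[disease] = fit
        tbl = fit.summary().reset_index(names="term")
        tbl.to_csv(out / f"fit_{disease}.csv", index=False)
        with open(out / f"fit_{disease}.json", "w") as fh:
            json.dump(
                {
                    "log_likelihood": fit.log_likelihood,
                    "converged": fit.converged,
                    "n_respondents": fit.n_respondents,
                    "n_records": fit.n_records,
                    "terms": fit.names,
                    "vcov": fit.vcov.to_numpy().tolist(),
                },
                fh,
            )
        fit_tables[disease] = tbl
        logger.info("stage 5/5: MCMC willingness-to-pay (%s)", disease)
        draws = mcmc_sample(fit, replace(mcmc_cfg, seed=mcmc_cfg.seed))
        draws.to_csv(out / f"mcmc_draws_{disease}.csv", index=False)
        w = wtp_table(fit, draws, group=disease)
        w.to_csv(out / f"wtp_{disease}.csv", index=False)
        wtp_tables[disease] = w

    if len(wtp_tables) == 2:
        comparison = compare_groups(wtp_tables["asthma"], wtp_tables["COPD"])
    else:
        comparison = pd.DataFrame()
    if len(comparison):
        comparison.to_csv(out / "wtp_comparison.csv", index=False)

    provenance = {
        "package_version": __version__,
        "master_seed": config.master_seed,
        "stage_seeds": seeds,
        "n_sets": config.n_sets,
        "n_blocks": config.n_blocks,
        "sigma_re": config.sigma_re,
        "quadrature_nodes": config.quadrature_nodes,
        "mcmc": {
            "n_iter": mcmc_cfg.n_iter,
            "burn_in": mcmc_cfg.burn_in,
            "thin": mcmc_cfg.thin,
            "seed": mcmc_cfg.seed,
        },
        "elapsed_seconds": round(time.time() - t0, 2),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)

    report = StudyReport(
        design_diagnostics=diag.to_dict(),
        cohort_summary=summary,
        fit_tables=fit_tables,
        disease_interactions=disease_tbl,
        covariate_interactions=cov_tbl,
        wtp_tables=wtp_tables,
        wtp_comparison=comparison,
        provenance=provenance,
    )
    _write_text_report(report, out / "report.txt")
    return report


def _write_text_report(report: StudyReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("Inhaler discrete choice experiment — simulated study report\n")
        fh.write("=" * 64 + "\n\n")
        fh.write(f"D-efficiency: {report.design_diagnostics['d_efficiency']:.4f}\n")
        fh.write(
            "duplicate sets: "
            f"{report.design_diagnostics['duplicate_set_count']}\n\n"
        )
        fh.write("Cohort summary\n--------------\n")
        fh.write(report.cohort_summary.round(3).to_string() + "\n\n")
        for disease, tbl in report.fit_tables.items():
            fh.write(f"Marginal utilities — {disease}\n")
            fh.write("-" * 32 + "\n")
            fh.write(tbl.round(4).to_string(index=False) + "\n\n")
        fh.write("Disease × attribute interactions (p-values)\n")
        fh.write(report.disease_interactions.round(4).to_string() + "\n\n")
        fh.write("Current-inhaler × covariate interactions (p-values)\n")
        fh.write(report.covariate_interactions.round(4).to_string() + "\n\n")
        for disease, tbl in report.wtp_tables.items():
            fh.write(f"Willingness to pay (€/month) — {disease}\n")
            fh.write(tbl.round(3).to_string(index=False) + "\n\n")


REQUIRED_COLUMNS = ("respondent_id", "set_id", "alt_id", "rank")


def validate_choice_csv(
    data, attrs: list[AttributeSpec] | None = None
) -> pd.DataFrame:
    """Row-level diagnostics on the long-format choice contract.

    Checks: three alternatives (A, B, current, no duplicates) per
    (respondent, set); ranks a permutation of 1..3; attribute levels in the
    schema; step-2 winner is the rank-1 alternative and the A/B order
    matches the step-1 choice. Returns a dataframe of violations (empty when
    the file is valid).
    """
    df = pd.read_csv(data) if not isinstance(data, pd.DataFrame) else data
    attrs = attrs or inhaler_schema()
    problems = []

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"missing required columns: {missing}")

    for a in attrs:
        if a.name not in df.columns:
            problems.append(
                {"respondent_id": None, "set_id": None,
                 "issue": f"missing attribute column {a.name!r}"}
            )
            continue
        if a.kind == "categorical":
            bad = ~df[a.name].isin(a.levels)
            for i in np.flatnonzero(bad.to_numpy()):
                problems.append(
                    {
                        "respondent_id": df["respondent_id"].iloc[i],
                        "set_id": df["set_id"].iloc[i],
                        "issue": f"unknown level {df[a.name].iloc[i]!r} "
                        f"for {a.name!r}",
                    }
                )

    for (rid, sid), grp in df.groupby(["respondent_id", "set_id"]):
        alts = list(grp["alt_id"])
        if sorted(alts) != ["A", "B", "current"]:
            issue = (
                "duplicated alt_id"
                if len(set(alts)) < len(alts)
                else f"alternatives {sorted(alts)} != ['A', 'B', 'current']"
            )
            problems.append({"respondent_id": rid, "set_id": sid, "issue": issue})
            continue
        ranks = sorted(grp["rank"])
        if ranks != [1, 2, 3]:
            problems.append(
                {
                    "respondent_id": rid,
                    "set_id": sid,
                    "issue": f"ranks {ranks} are not a permutation of 1..3",
                }
            )
            continue
        if {"step1_choice", "step2_choice"} <= set(grp.columns):
            by_rank = grp.sort_values("rank")
            ranking = list(by_rank["alt_id"])
            step1 = by_rank["step1_choice"].iloc[0]
            step2 = by_rank["step2_choice"].iloc[0]
            if ranking[0] != step2:
                problems.append(
                    {
                        "respondent_id": rid,
                        "set_id": sid,
                        "issue": f"rank-1 alternative {ranking[0]!r} is not the "
                        f"step-2 winner {step2!r}",
                    }
                )
            loser = "B" if step1 == "A" else "A"
            if ranking.index(step1) > ranking.index(loser):
                problems.append(
                    {
                        "respondent_id": rid,
                        "set_id": sid,
                        "issue": "A/B order contradicts step1_choice",
                    }
                )
    return pd.DataFrame(problems, columns=["respondent_id", "set_id", "issue"])
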