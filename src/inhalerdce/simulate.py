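"""Two-step choice simulation under a rank-ordered logit process.

Each simulated question presents two fictitious inhalers (A, B) and the
respondent's current inhaler. Utilities are

    U_j = x_j' beta + cost_j * beta_cost + 1[j = current] (delta_sq + b_i) + eps_j

with independent standard Gumbel errors eps_j (one draw per alternative per
set) and a normal patient effect b_i ~ N(0, sigma_re^2) on the status-quo
constant, shared across a respondent's sets. The respondent first picks
between A and B, then between that winner and the current inhaler; because
one utility draw underlies both steps, the observed two-step outcome is
exactly the descending utility sort, i.e. a full ranking of the three
alternatives.

Seeding expands a single master seed into per-respondent and per-(respondent,
set) substreams, so any record can be regenerated independently of order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Respondent, current_profile
from .design import ChoiceSet, Design
from .errors import DataError
from .params import ASTHMA_ESTIMATES, COPD_ESTIMATES, estimates_only
from .schema import AttributeSpec, Profile, code_profile, coded_names, inhaler_schema

ALT_IDS = ("A", "B", "current")


@dataclass
class TrueModel:
    """Data-generating parameters of the simulator.

    beta maps coded device-attribute columns (e.g. ``"ease_of_use[1 step]"``)
    to marginal utilities; beta_cost is the utility per €/month of extra
    out-of-pocket cost; delta_sq the current-inhaler (status-quo) constant;
    sigma_re the SD of the patient effect on that constant.
    """

    beta: dict[str, float]
    beta_cost: float
    delta_sq: float
    sigma_re: float = 0.0

    def __post_init__(self):
        if self.sigma_re < 0:
            raise DataError("sigma_re must be nonnegative")

    @classmethod
    def from_estimates(
        cls, table: dict[str, tuple[float, float]], sigma_re: float = 0.5
    ) -> "TrueModel":
        est = estimates_only(table)
        beta = {
            k: v for k, v in est.items() if k not in ("cost", "current_inhaler")
        }
        return cls(
            beta=beta,
            beta_cost=est["cost"],
            delta_sq=est["current_inhaler"],
            sigma_re=sigma_re,
        )

    @classmethod
    def asthma_defaults(cls, sigma_re: float = 0.5) -> "TrueModel":
        return cls.from_estimates(ASTHMA_ESTIMATES, sigma_re)

    @classmethod
    def copd_defaults(cls, sigma_re: float = 0.5) -> "TrueModel":
        return cls.from_estimates(COPD_ESTIMATES, sigma_re)


@dataclass
class RankingRecord:
    """One respondent × choice set observation."""

    respondent_id: int
    set_id: int
    step1_choice: str  # "A" | "B"
    step2_choice: str  # ranking[0]: the step-1 winner or "current"
    ranking: tuple[str, str, str]

    def __post_init__(self):
        if sorted(self.ranking) != sorted(ALT_IDS):
            raise DataError(f"ranking {self.ranking} is not a permutation of {ALT_IDS}")
        if self.step1_choice not in ("A", "B"):
            raise DataError(f"step1_choice {self.step1_choice!r} must be A or B")
        if self.ranking[0] != self.step2_choice:
            raise DataError("ranking[0] must equal the step-2 winner")
        loser = "B" if self.step1_choice == "A" else "A"
        if self.ranking.index(self.step1_choice) > self.ranking.index(loser):
            raise DataError("relative order of A and B contradicts step1_choice")


def _coded_utility(
    profile: Profile, model: TrueModel, attrs: list[AttributeSpec]
) -> float:
    x = code_profile(profile, attrs)
    names = coded_names(attrs)
    beta = np.array(
        [model.beta.get(n, 0.0) if n != "cost" else model.beta_cost for n in names]
    )
    return float(x @ beta)


def deterministic_utilities(
    respondent: Respondent,
    choice_set: ChoiceSet,
    model: TrueModel,
    attrs: list[AttributeSpec] | None = None,
    profile_map=None,
) -> np.ndarray:
    """Systematic utilities (V_A, V_B, V_current), including the patient effect."""
    attrs = attrs if attrs is not None else inhaler_schema()
    v = [
        _coded_utility(p, model, attrs) for p in choice_set.alternatives
    ]
    cur = current_profile(respondent, profile_map)
    v.append(
        _coded_utility(cur, model, attrs) + model.delta_sq + respondent.random_effect
    )
    return np.asarray(v)


def sample_rankings(
    det_utils: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Descending-utility orderings for n independent Gumbel draws.

    Returns an (n, 3) array of alternative indices (0=A, 1=B, 2=current),
    best first. Vectorized; used by the record-level simulator with n=1 and
    by Monte-Carlo convergence checks with large n.
    """
    u = np.asarray(det_utils) + rng.gumbel(size=(n, len(det_utils)))
    return np.argsort(-u, axis=1, kind="stable")


def _record_from_order(respondent_id: int, set_id: int, order: np.ndarray) -> RankingRecord:
    ranking = tuple(ALT_IDS[i] for i in order)
    step1 = "A" if ranking.index("A") < ranking.index("B") else "B"
    return RankingRecord(
        respondent_id=respondent_id,
        set_id=set_id,
        step1_choice=step1,
        step2_choice=ranking[0],
        ranking=ranking,
    )


def simulate_choice_set(
    respondent: Respondent,
    choice_set: ChoiceSet,
    model: TrueModel,
    seed: int | np.random.Generator = 0,
    attrs: list[AttributeSpec] | None = None,
    profile_map=None,
) -> RankingRecord:
    """Simulate one two-step question; deterministic given seed."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    v = deterministic_utilities(respondent, choice_set, model, attrs, profile_map)
    order = sample_rankings(v, 1, rng)[0]
    return _record_from_order(respondent.respondent_id, choice_set.set_id, order)


def draw_random_effects(
    cohort: list[Respondent], model: TrueModel, seed: int
) -> None:
    """Assign each respondent a latent N(0, sigma_re^2) effect, in place."""
    for r in cohort:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1, r.respondent_id]))
        r.random_effect = float(model.sigma_re * rng.standard_normal())


def simulate_study(
    cohort: list[Respondent],
    design: Design,
    model: TrueModel,
    seed: int = 0,
    profile_map=None,
) -> list[RankingRecord]:
    """One RankingRecord per respondent × choice set of their assigned block."""
    attrs = design.attributes
    draw_random_effects(cohort, model, seed)
    block_sets = {b: design.sets_in_block(b) for b in design.block_sizes()}
    records = []
    for r in cohort:
        for cs in block_sets.get(r.block_id, []):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, 2, r.respondent_id, cs.set_id])
            )
            records.append(
                simulate_choice_set(r, cs, model, rng, attrs, profile_map)
            )
    return records


def rankings_to_frame(
    records: list[RankingRecord],
    cohort: list[Respondent],
    design: Design,
    profile_map=None,
) -> pd.DataFrame:
    """Long-format export: one row per alternative, latent effects stripped."""
    attrs = design.attributes
    by_resp = {r.respondent_id: r for r in cohort}
    by_set = {cs.set_id: cs for cs in design.choice_sets}
    rows = []
    for rec in records:
        resp = by_resp[rec.respondent_id]
        cs = by_set[rec.set_id]
        profiles = {
            "A": cs.alternatives[0],
            "B": cs.alternatives[1],
            "current": current_profile(resp, profile_map),
        }
        for alt_id in ALT_IDS:
            prof = profiles[alt_id]
            row = {
                "respondent_id": rec.respondent_id,
                "block_id": cs.block_id,
                "set_id": rec.set_id,
                "alt_id": alt_id,
            }
            row.update({a.name: prof[a.name] for a in attrs})
            row["rank"] = rec.ranking.index(alt_id) + 1
            row["step1_choice"] = rec.step1_choice
            row["step2_choice"] = rec.step2_choice
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_study_frame(
    cohort: list[Respondent],
    design: Design,
    model: TrueModel,
    seed: int = 0,
    profile_map=None,
) -> pd.DataFrame:
    records = simulate_study(cohort, design, model, seed, profile_map)
    return rankings_to_frame(records, cohort, design, profile_map)
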