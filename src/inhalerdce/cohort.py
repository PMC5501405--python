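"""Synthetic respondent cohorts emulating the study sample.

The study surveyed 294 dry-powder-inhaler users (201 asthma, 93 COPD), each
using one of two devices (Symbicort Turbuhaler or Seretide Diskus). The
generator draws covariates from configured marginal distributions — age
(normal, truncated at 18 with the location calibrated so the truncated mean
hits the configured mean), gender, device, income band, satisfaction,
monthly out-of-pocket cost (lognormal, moment-matched), and the HUI3 health
utility (beta, moment-matched) — independently within disease group, and
assigns respondents to design blocks round-robin after a seeded shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigError
from .schema import Profile

INCOME_BANDS = (
    "<€22,500",
    "€25,000–€34,999",
    "€35,000–€49,999",
    "€50,000–€74,999",
    "€75,000+",
    "no answer",
)
SATISFACTION_LEVELS = ("unsatisfied", "neutral", "satisfied")
DEVICES = ("Symbicort Turbuhaler", "Seretide Diskus")
MIN_AGE = 18.0


@dataclass
class Respondent:
    respondent_id: int
    disease: str  # "asthma" | "COPD"
    age: float
    gender: str  # "male" | "female"
    income_band: str
    satisfaction: str
    current_inhaler: str
    current_cost: float  # €/month out-of-pocket
    hui3: float
    block_id: int = 0
    random_effect: float = 0.0  # latent; never exported to analysis files

    def __post_init__(self):
        if not 0.0 <= self.hui3 <= 1.0:
            raise ConfigError(f"hui3 {self.hui3} outside [0, 1]")
        if self.current_cost < 0:
            raise ConfigError("current_cost must be nonnegative")
        if self.age < MIN_AGE:
            raise ConfigError(f"age {self.age} below {MIN_AGE}")


@dataclass
class GroupConfig:
    """Marginal covariate distributions for one disease group."""

    n: int
    age_mean: float
    age_sd: float
    female_frac: float
    device_probs: dict[str, float]
    income_probs: dict[str, float]
    satisfaction_probs: dict[str, float]
    cost_mean: float
    cost_sd: float
    hui3_mean: float
    hui3_sd: float

    def __post_init__(self):
        if self.n < 0:
            raise ConfigError("group size must be >= 0")
        for label, probs in (
            ("device_probs", self.device_probs),
            ("income_probs", self.income_probs),
            ("satisfaction_probs", self.satisfaction_probs),
        ):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-8:
                raise ConfigError(f"{label} sum to {total}, not 1")


@dataclass
class CohortConfig:
    asthma: GroupConfig
    copd: GroupConfig
    n_blocks: int = 3


def default_cohort_config() -> CohortConfig:
    """Study-sample defaults: 201 asthma + 93 COPD respondents.

    Group means/SDs and category proportions follow the published sample
    description. The satisfaction split beyond the reported satisfied
    fractions (52% asthma, 46% COPD) is not published; the remainder is
    split 5:3 between neutral and unsatisfied as a documented default.
    """
    asthma = GroupConfig(
        n=201,
        age_mean=40.30,
        age_sd=13.44,
        female_frac=0.6866,
        device_probs={DEVICES[0]: 95 / 201, DEVICES[1]: 106 / 201},
        income_probs=dict(
            zip(INCOME_BANDS, np.array([97, 39, 30, 15, 2, 18]) / 201)
        ),
        satisfaction_probs={"satisfied": 0.52, "neutral": 0.30, "unsatisfied": 0.18},
        cost_mean=11.89,
        cost_sd=21.93,
        hui3_mean=0.71,
        hui3_sd=0.25,
    )
    copd = GroupConfig(
        n=93,
        age_mean=48.48,
        age_sd=15.16,
        female_frac=0.5484,
        device_probs={DEVICES[0]: 44 / 93, DEVICES[1]: 49 / 93},
        income_probs=dict(
            zip(INCOME_BANDS, np.array([40, 14, 15, 7, 6, 11]) / 93)
        ),
        satisfaction_probs={"satisfied": 0.46, "neutral": 0.34, "unsatisfied": 0.20},
        cost_mean=22.11,
        cost_sd=37.37,
        hui3_mean=0.54,
        hui3_sd=0.30,
    )
    return CohortConfig(asthma=asthma, copd=copd, n_blocks=3)


def _truncnorm_loc(target_mean: float, sd: float, lower: float) -> float:
    """Location mu such that a normal(mu, sd) truncated at `lower` has the
    target mean (so configured means are hit exactly despite truncation)."""
    if target_mean <= lower:
        raise ConfigError(f"mean {target_mean} must exceed truncation {lower}")

    def gap(mu):
        a = (lower - mu) / sd
        return stats.truncnorm.mean(a, np.inf, loc=mu, scale=sd) - target_mean

    return optimize.brentq(gap, lower - 10 * sd, target_mean + sd)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2, np.sqrt(sigma2)


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    var = sd**2
    if var >= mean * (1 - mean):
        raise ConfigError("hui3 variance too large for a beta distribution")
    nu = mean * (1 - mean) / var - 1
    return mean * nu, (1 - mean) * nu


def _draw_group(
    cfg: GroupConfig, disease: str, start_id: int, rng: np.random.Generator
) -> list[Respondent]:
    n = cfg.n
    if n == 0:
        return []
    a = (MIN_AGE - _truncnorm_loc(cfg.age_mean, cfg.age_sd, MIN_AGE)) / cfg.age_sd
    loc = _truncnorm_loc(cfg.age_mean, cfg.age_sd, MIN_AGE)
    ages = stats.truncnorm.rvs(
        a, np.inf, loc=loc, scale=cfg.age_sd, size=n, random_state=rng
    )
    genders = np.where(rng.random(n) < cfg.female_frac, "female", "male")
    devices = rng.choice(
        list(cfg.device_probs), size=n, p=list(cfg.device_probs.values())
    )
    incomes = rng.choice(
        list(cfg.income_probs), size=n, p=list(cfg.income_probs.values())
    )
    satisfaction = rng.choice(
        list(cfg.satisfaction_probs),
        size=n,
        p=list(cfg.satisfaction_probs.values()),
    )
    mu, sigma = _lognormal_params(cfg.cost_mean, cfg.cost_sd)
    costs = rng.lognormal(mu, sigma, size=n)
    alpha, beta_p = _beta_params(cfg.hui3_mean, cfg.hui3_sd)
    hui3 = rng.beta(alpha, beta_p, size=n)
    return [
        Respondent(
            respondent_id=start_id + i,
            disease=disease,
            age=float(ages[i]),
            gender=str(genders[i]),
            income_band=str(incomes[i]),
            satisfaction=str(satisfaction[i]),
            current_inhaler=str(devices[i]),
            current_cost=float(costs[i]),
            hui3=float(hui3[i]),
        )
        for i in range(n)
    ]


def generate_respondents(
    config: CohortConfig | None = None, seed: int = 0
) -> list[Respondent]:
    """Draw a synthetic cohort; deterministic given seed.

    Blocks are assigned round-robin over a seeded shuffle of the whole
    cohort, so each block receives an (almost) equal share of each group.
    """
    config = config or default_cohort_config()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    cohort = _draw_group(config.asthma, "asthma", 0, rng)
    cohort += _draw_group(config.copd, "COPD", config.asthma.n, rng)
    order = rng.permutation(len(cohort))
    for rank, i in enumerate(order):
        cohort[i].block_id = rank % config.n_blocks
    return cohort


def cohort_to_frame(cohort: list[Respondent]) -> pd.DataFrame:
    """Respondent table as exported to analysis files (latent effect dropped)."""
    return pd.DataFrame(
        [
            {
                "respondent_id": r.respondent_id,
                "disease": r.disease,
                "age": r.age,
                "gender": r.gender,
                "income_band": r.income_band,
                "satisfaction": r.satisfaction,
                "current_inhaler": r.current_inhaler,
                "current_cost": r.current_cost,
                "hui3": r.hui3,
                "block_id": r.block_id,
            }
            for r in cohort
        ]
    )


# Default attribute profiles shown for the two current devices. The study
# never tabulates these, so they are overridable configuration; the defaults
# mirror the devices' familiar handling (2-3 preparation steps, dry-cloth
# mouthpiece care, fixed inhalation orientation, not usable when breathless)
# and differ on the dose counter and lactose taste. The cost increment of the
# current inhaler is €0: its cost level is the status-quo expenditure.
DEFAULT_DEVICE_PROFILES: dict[str, Profile] = {
    "Symbicort Turbuhaler": Profile(
        {
            "ease_of_use": "2 to 3 steps",
            "dose_counter": "no",
            "dose_confirmation": "no taste of lactose",
            "hygiene": "cleaned with a dry cloth",
            "flexibility": "certain position",
            "breathless_use": "no",
            "cost": 0.0,
        }
    ),
    "Seretide Diskus": Profile(
        {
            "ease_of_use": "2 to 3 steps",
            "dose_counter": "yes",
            "dose_confirmation": "taste of lactose",
            "hygiene": "cleaned with a dry cloth",
            "flexibility": "certain position",
            "breathless_use": "no",
            "cost": 0.0,
        }
    ),
}


def current_profile(
    respondent: Respondent, profile_map: dict[str, Profile] | None = None
) -> Profile:
    """The attribute profile describing a respondent's current inhaler."""
    profile_map = profile_map or DEFAULT_DEVICE_PROFILES
    try:
        return profile_map[respondent.current_inhaler]
    except KeyError:
        raise ConfigError(
            f"no profile configured for device {respondent.current_inhaler!r}"
        ) from None
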