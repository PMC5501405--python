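"""Published study estimates used as simulation defaults and worked examples.

The stratified rank-ordered logit estimates from the source study (marginal
utilities on the dummy coding of :func:`inhalerdce.schema.inhaler_schema`,
the linear cost coefficient per €/month, and the current-inhaler constant)
are recorded here. They serve two roles: defaults for the synthetic
data-generating process, and reference values for consistency checks
(odds-ratio and willingness-to-pay transforms of printed coefficients).
"""

from __future__ import annotations

# term -> (estimate, standard error)
ASTHMA_ESTIMATES: dict[str, tuple[float, float]] = {
    "ease_of_use[1 step]": (0.55, 0.081),
    "ease_of_use[2 to 3 steps]": (0.281, 0.069),
    "dose_counter[yes]": (0.377, 0.047),
    "dose_confirmation[taste of lactose]": (0.333, 0.045),
    "hygiene[can be replaced]": (-0.032, 0.063),
    "hygiene[can be washed]": (0.026, 0.063),
    "flexibility[any position]": (0.164, 0.045),
    "breathless_use[yes]": (0.5, 0.051),
    "cost": (-0.114, 0.012),
    "current_inhaler": (0.207, 0.086),
}

COPD_ESTIMATES: dict[str, tuple[float, float]] = {
    "ease_of_use[1 step]": (0.282, 0.118),
    "ease_of_use[2 to 3 steps]": (0.203, 0.1),
    "dose_counter[yes]": (0.419, 0.069),
    "dose_confirmation[taste of lactose]": (0.362, 0.066),
    "hygiene[can be replaced]": (-0.028, 0.091),
    "hygiene[can be washed]": (-0.073, 0.092),
    "flexibility[any position]": (-0.03, 0.065),
    "breathless_use[yes]": (0.549, 0.075),
    "cost": (-0.067, 0.017),
    "current_inhaler": (0.137, 0.126),
}

# published odds ratios, as printed
ASTHMA_ODDS_RATIOS: dict[str, float] = {
    "ease_of_use[1 step]": 1.733,
    "ease_of_use[2 to 3 steps]": 1.324,
    "dose_counter[yes]": 1.458,
    "dose_confirmation[taste of lactose]": 1.395,
    "hygiene[can be replaced]": 0.968,
    "hygiene[can be washed]": 1.027,
    "flexibility[any position]": 1.178,
    "breathless_use[yes]": 1.649,
    "cost": 0.893,
    "current_inhaler": 1.23,
}

COPD_ODDS_RATIOS: dict[str, float] = {
    "ease_of_use[1 step]": 1.326,
    "ease_of_use[2 to 3 steps]": 1.226,
    "dose_counter[yes]": 1.52,
    "dose_confirmation[taste of lactose]": 1.436,
    "hygiene[can be replaced]": 0.972,
    "hygiene[can be washed]": 0.929,
    "flexibility[any position]": 0.97,
    "breathless_use[yes]": 1.731,
    "cost": 0.936,
    "current_inhaler": 1.147,
}

# published WTP point estimates and 95% credibility intervals, €/month
ASTHMA_WTP: dict[str, tuple[float, float, float]] = {
    "ease_of_use[1 step]": (4.83, 3.77, 5.90),
    "breathless_use[yes]": (4.49, 2.95, 6.02),
    "dose_counter[yes]": (3.38, 2.11, 4.65),
    "dose_confirmation[taste of lactose]": (2.98, 1.98, 3.97),
    "flexibility[any position]": (1.45, 0.63, 2.28),
}

COPD_WTP: dict[str, tuple[float, float, float]] = {
    "breathless_use[yes]": (7.70, 5.65, 9.76),
    "dose_counter[yes]": (5.87, 3.98, 7.77),
    "dose_confirmation[taste of lactose]": (5.09, 3.29, 6.89),
    "ease_of_use[1 step]": (3.95, 0.70, 7.19),
}


def estimates_only(table: dict[str, tuple[float, float]]) -> dict[str, float]:
    return {k: v[0] for k, v in table.items()}
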