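"""Survival summaries -> daily transition probabilities (DEALE).

The declining exponential approximation of life expectancy (DEALE) treats a
population whose survival is S at time t as if it faced a constant hazard
lambda = -ln S / t.  With t expressed in months of 30.4375 days, the daily
transition probability is

    dp = 1 - exp(ln S / (t * 30.4375)),

so that (1 - dp)^(t * 30.4375) = S exactly.  Medians enter with S = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .profiles import DAYS_PER_MONTH, SUBGROUP_ORDER, SubgroupId, WaitlistProfile

__all__ = ["DailyRates", "deale_daily_prob", "build_daily_rates"]

#: Horizon over which post-transplant survival is summarized, in months.
POST_LT_SURVIVAL_HORIZON_MONTHS = 60.0


def deale_daily_prob(survival_fraction, t_months):
    """Daily event probability implied by survival ``S`` at ``t`` months.

    Accepts scalars or numpy arrays; S must lie in (0, 1] and t must be
    positive.  Returns exactly 0.0 when S == 1, and is strictly decreasing
    in both S and t otherwise.
    """
    S = np.asarray(survival_fraction, dtype=float)
    t = np.asarray(t_months, dtype=float)
    if np.any(~np.isfinite(S)) or np.any(S <= 0) or np.any(S > 1):
        raise ValueError(f"survival_fraction must lie in (0, 1], got {survival_fraction!r}")
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise ValueError(f"t_months must be positive, got {t_months!r}")
    dp = -np.expm1(np.log(S) / (t * DAYS_PER_MONTH))
    if dp.ndim == 0:
        return float(dp)
    return dp


@dataclass(frozen=True)
class DailyRates:
    """Per-stratum daily transition probabilities for the cohort model."""

    dp_death: Mapping[SubgroupId, float]
    dp_transplant: Mapping[SubgroupId, float]
    dp_post_lt_death: Mapping[SubgroupId, float]

    def __post_init__(self) -> None:
        for g in SUBGROUP_ORDER:
            d = self.dp_death[g]
            t = self.dp_transplant[g]
            p = self.dp_post_lt_death[g]
            for name, v in (("dp_death", d), ("dp_transplant", t), ("dp_post_lt_death", p)):
                if not (0 <= v < 1):
                    raise ValueError(f"{name}[{g.value}] out of [0, 1): {v}")
            if d + t >= 1:
                raise ValueError(
                    f"dp_death + dp_transplant must stay below 1 for a one-day "
                    f"cycle; stratum {g.value} has {d + t}"
                )

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(death, transplant, post-LT death) arrays in SUBGROUP_ORDER."""
        return (
            np.array([self.dp_death[g] for g in SUBGROUP_ORDER]),
            np.array([self.dp_transplant[g] for g in SUBGROUP_ORDER]),
            np.array([self.dp_post_lt_death[g] for g in SUBGROUP_ORDER]),
        )


def build_daily_rates(profile: WaitlistProfile) -> DailyRates:
    """Convert a waiting-list profile into per-stratum daily probabilities.

    Pre-transplant death/dropout and transplant probabilities come from the
    stratum medians (S = 0.5); post-transplant death from the 5-year
    post-transplant survival over a 60-month horizon.
    """
    death, tx, post = {}, {}, {}
    for g in SUBGROUP_ORDER:
        p = profile[g]
        death[g] = deale_daily_prob(0.5, p.median_wl_survival)
        tx[g] = deale_daily_prob(0.5, p.median_time_to_lt)
        post[g] = deale_daily_prob(
            p.post_lt_5yr_survival, POST_LT_SURVIVAL_HORIZON_MONTHS
        )
    return DailyRates(dp_death=death, dp_transplant=tx, dp_post_lt_death=post)
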