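"""Monte Carlo uncertainty analysis and log-linear harm metamodel.

Draws waiting-list parameters independently and uniformly from their tested
ranges, runs the Markov harm engine for every draw, and summarizes how each
covariate drives the harm with an ordinary-least-squares regression of
ln(harm) on the covariates.  A published four-covariate simplified equation
for the harm is also provided as a standalone evaluator.

Covariate units follow the published regression: the organ decrease enters
in percentage points (0-100), waiting-list shares as proportions (0-1),
the donors-to-list ratio dimensionless, and medians in months.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import markov
from .hazards import POST_LT_SURVIVAL_HORIZON_MONTHS, deale_daily_prob
from .profiles import (
    SUBGROUP_ORDER,
    ParameterRanges,
    SubgroupId,
    WaitlistProfile,
)

__all__ = [
    "MetamodelFit",
    "run_monte_carlo",
    "fit_harm_metamodel",
    "simplified_harm",
    "SIMPLIFIED_COEFFICIENTS",
    "DEFAULT_COVARIATES",
]

_SHORT = {
    SubgroupId.MELD_LE20: "meld_le20",
    SubgroupId.MELD_21_30: "meld_21_30",
    SubgroupId.MELD_GT30: "meld_gt30",
    SubgroupId.HCC: "hcc",
}

#: Regressor set of the published harm metamodel (response: ln harm).
DEFAULT_COVARIATES: tuple[str, ...] = (
    "organ_decrease_pct",
    "organs_over_wl",
    "wl_size",
    "frac_meld_gt20",
    "frac_meld_gt30",
    "frac_hcc",
    "median_surv_meld_le20",
    "median_surv_meld_21_30",
    "median_surv_meld_gt30",
    "median_surv_hcc",
    "time_to_lt_meld_le20",
    "time_to_lt_meld_21_30",
    "time_to_lt_meld_gt30",
    "time_to_lt_hcc",
)

#: Published simplified-equation coefficients:
#: ln harm = a + b * organ decrease (pp) + c * share MELD>20 + d * share HCC
#:           + e * donors/list ratio
SIMPLIFIED_COEFFICIENTS: tuple[float, float, float, float, float] = (
    3.07, 0.03, 1.18, -0.88, -1.03
)


def _sample_uniform(rng: np.ndarray, low: float, high: float, n: int) -> np.ndarray:
    if low == high:
        return np.full(n, low)
    return rng.uniform(low, high, size=n)


def run_monte_carlo(
    base: WaitlistProfile,
    ranges: ParameterRanges,
    n_draws: int,
    seed: int,
    horizon_days: int = markov.DEFAULT_HORIZON_DAYS,
    harmed_cohort: str = "non_hcc",
) -> pd.DataFrame:
    """Sample parameter draws and compute the harm of one allocation for each.

    Every profile parameter and the organ decrease are drawn independently
    and uniformly within ``ranges`` (stratum shares renormalized to sum to
    one after sampling); the harm engine runs vectorized over all draws.
    Returns one row per draw with the covariates, the sampled post-transplant
    survivals, and ``harm_life_months`` / ``extra_death_risk``.
    Deterministic given ``seed``.
    """
    if n_draws < 1:
        raise ValueError(f"n_draws must be >= 1, got {n_draws}")
    rng = np.random.default_rng(seed)
    n = n_draws

    wl_size = _sample_uniform(rng, *ranges.wl_size, n)
    organs = _sample_uniform(rng, *ranges.organs_per_year, n)
    dec = _sample_uniform(rng, *ranges.organ_decrease, n)

    surv = np.column_stack(
        [_sample_uniform(rng, *ranges.median_wl_survival[g], n) for g in SUBGROUP_ORDER]
    )
    ttlt = np.column_stack(
        [_sample_uniform(rng, *ranges.median_time_to_lt[g], n) for g in SUBGROUP_ORDER]
    )
    post5 = np.column_stack(
        [_sample_uniform(rng, *ranges.post_lt_5yr_survival[g], n) for g in SUBGROUP_ORDER]
    )
    fracs = np.column_stack(
        [_sample_uniform(rng, *ranges.wl_fraction[g], n) for g in SUBGROUP_ORDER]
    )
    fracs = fracs / fracs.sum(axis=1, keepdims=True)

    dp_death = deale_daily_prob(0.5, surv)
    dp_tx = deale_daily_prob(0.5, ttlt)
    dp_post = deale_daily_prob(post5, POST_LT_SURVIVAL_HORIZON_MONTHS)

    harm, risk, _, _ = markov.harm_batch(
        wl_size, organs, dec, dp_death, dp_tx, dp_post, fracs,
        horizon_days=horizon_days, harmed_cohort=harmed_cohort,
    )

    i21, i30, ihcc = (SUBGROUP_ORDER.index(g) for g in (
        SubgroupId.MELD_21_30, SubgroupId.MELD_GT30, SubgroupId.HCC))
    out = {
        "organ_decrease_pct": 100.0 * dec,
        "organs_over_wl": organs / wl_size,
        "wl_size": wl_size,
        "frac_meld_gt20": fracs[:, i21] + fracs[:, i30],
        "frac_meld_gt30": fracs[:, i30],
        "frac_hcc": fracs[:, ihcc],
    }
    for j, g in enumerate(SUBGROUP_ORDER):
        out[f"median_surv_{_SHORT[g]}"] = surv[:, j]
    for j, g in enumerate(SUBGROUP_ORDER):
        out[f"time_to_lt_{_SHORT[g]}"] = ttlt[:, j]
    for j, g in enumerate(SUBGROUP_ORDER):
        out[f"post_lt_5yr_survival_{_SHORT[g]}"] = post5[:, j]
    out["organs_per_year"] = organs
    out["harm_life_months"] = harm
    out["extra_death_risk"] = risk
    return pd.DataFrame(out)


@dataclass(frozen=True)
class MetamodelFit:
    """OLS fit of ln(harm) on the covariate set.

    ``table`` has one row per term (including the intercept) with columns
    ``estimate``, ``std_error``, ``t_ratio``, ``p_value``.
    """

    table: pd.DataFrame
    r_squared: float
    n_draws: int
    covariates: tuple[str, ...]

    def coefficient(self, name: str) -> float:
        return float(self.table.loc[name, "estimate"])

    def to_text(self) -> str:
        """Formatted coefficient table."""
        df = self.table.copy()
        lines = [f"ln(harm) metamodel, n = {self.n_draws}, R^2 = {self.r_squared:.4f}",
                 f"{'term':<26}{'Estimate':>12}{'Std Error':>12}{'T Ratio':>10}{'p-Value':>10}"]
        for name, row in df.iterrows():
            p = row["p_value"]
            p_str = "<0.0001" if p < 1e-4 else f"{p:.4f}"
            lines.append(
                f"{name:<26}{row['estimate']:>12.4f}{row['std_error']:>12.4f}"
                f"{row['t_ratio']:>10.2f}{p_str:>10}"
            )
        return "\n".join(lines)


def fit_harm_metamodel(
    draws: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    response: str = "harm_life_months",
) -> MetamodelFit:
    """Ordinary least squares of ln(harm) on the covariates.

    Requires at least 50 draws and a full-rank design; rank deficiency
    raises an error naming the offending covariates.
    """
    if len(draws) < 50:
        raise ValueError(f"need >= 50 draws to fit the metamodel, got {len(draws)}")
    missing = [c for c in covariates if c not in draws.columns]
    if missing:
        raise ValueError(f"draws table lacks covariates: {missing}")
    y_raw = draws[response].to_numpy(dtype=float)
    if np.any(y_raw <= 0):
        raise ValueError("response must be strictly positive to take ln(harm)")
    X = draws.loc[:, list(covariates)].to_numpy(dtype=float)

    degenerate = [c for c, s in zip(covariates, X.std(axis=0)) if s == 0]
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        if not degenerate:
            corr = np.corrcoef(X, rowvar=False)
            pairs = [
                (covariates[i], covariates[j])
                for i in range(len(covariates))
                for j in range(i + 1, len(covariates))
                if abs(corr[i, j]) > 1 - 1e-10
            ]
            degenerate = [f"{a}~{b}" for a, b in pairs] or list(covariates)
        raise ValueError(f"design matrix is rank deficient; check covariates: {degenerate}")

    model = sm.OLS(np.log(y_raw), design).fit()
    names = ["intercept", *covariates]
    table = pd.DataFrame(
        {
            "estimate": model.params,
            "std_error": model.bse,
            "t_ratio": model.tvalues,
            "p_value": model.pvalues,
        }
    )
    table.index = names
    return MetamodelFit(
        table=table,
        r_squared=float(model.rsquared),
        n_draws=len(draws),
        covariates=tuple(covariates),
    )


def simplified_harm(
    organ_decrease_pct,
    frac_meld_gt20,
    frac_hcc,
    donors_over_wl,
    coefficients: Optional[Sequence[float]] = None,
):
    """Published four-covariate simplified harm equation, in life-months.

    harm = exp(a + b * organ decrease (percentage points)
                 + c * share of the list with MELD > 20
                 + d * share of the list with HCC
                 + e * donors-to-list ratio)

    with published coefficients ``(a, b, c, d, e) = (3.07, 0.03, 1.18,
    -0.88, -1.03)`` by default; pass ``coefficients`` to use a refit.
    Accepts scalars or arrays.
    """
    a, b, c, d, e = coefficients if coefficients is not None else SIMPLIFIED_COEFFICIENTS
    dec = np.asarray(organ_decrease_pct, dtype=float)
    f20 = np.asarray(frac_meld_gt20, dtype=float)
    fh = np.asarray(frac_hcc, dtype=float)
    r = np.asarray(donors_over_wl, dtype=float)
    if np.any((dec < 0) | (dec >= 100)):
        raise ValueError("organ_decrease_pct must lie in [0, 100)")
    for name, v in (("frac_meld_gt20", f20), ("frac_hcc", fh)):
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"{name} must be a fraction in [0, 1]")
    if np.any(r <= 0):
        raise ValueError("donors_over_wl must be > 0")
    out = np.exp(a + b * dec + c * f20 + d * fh + e * r)
    if out.ndim == 0:
        return float(out)
    return out
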