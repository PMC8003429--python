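"""Synthetic patient-level waiting-list registry and profile re-estimation.

The national registry behind the packaged Italian profile is restricted, so
this module generates a patient-level stand-in with the statistical
structure the downstream model assumes: per-stratum exponential (constant
hazard) times to death/dropout and to transplant competing with each other,
staggered entry over an accrual window, administrative censoring, and
exponential post-transplant mortality calibrated to the 5-year survival.

Because transplant assignment within a stratum is independent of the death
process by construction, plain Kaplan-Meier estimates recover the
configured medians without the dependent-censoring corrections a real
registry would need; :func:`estimate_profile_from_registry` closes the loop
by re-estimating a :class:`~wlharm.profiles.WaitlistProfile` from the
generated records.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .profiles import (
    DAYS_PER_MONTH,
    SUBGROUP_ORDER,
    SubgroupId,
    SubgroupParams,
    WaitlistProfile,
)

__all__ = [
    "EVENT_TRANSPLANTED",
    "EVENT_DIED_OR_DROPPED",
    "EVENT_CENSORED",
    "Registry",
    "generate_registry",
    "estimate_profile_from_registry",
]

EVENT_TRANSPLANTED = "transplanted"
EVENT_DIED_OR_DROPPED = "died_or_dropped"
EVENT_CENSORED = "censored"

POST_LT_ALIVE = "alive"
POST_LT_DEAD = "dead"

#: 5 years in days, matching the 60-month post-transplant summary horizon.
_FIVE_YEARS_DAYS = 60 * DAYS_PER_MONTH

_COLUMNS = [
    "patient_id",
    "subgroup",
    "entry_day",
    "event",
    "event_day",
    "post_lt_status",
    "post_lt_followup_day",
]


@dataclass(frozen=True)
class Registry:
    """A collection of per-patient waiting-list records.

    ``records`` is a DataFrame with one row per patient and columns
    ``patient_id, subgroup, entry_day, event, event_day, post_lt_status,
    post_lt_followup_day`` (the last two populated only for transplanted
    patients).
    """

    records: pd.DataFrame
    accrual_window: int
    admin_censor_day: int

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"registry missing columns: {missing}")
        if (df["event_day"] < df["entry_day"]).any():
            raise ValueError("event_day must be >= entry_day for every record")
        if (df["event_day"] > self.admin_censor_day).any():
            raise ValueError("event_day must not exceed admin_censor_day")
        is_tx = df["event"] == EVENT_TRANSPLANTED
        if df.loc[is_tx, "post_lt_status"].isna().any():
            raise ValueError("transplanted records require post_lt_status")
        if df.loc[~is_tx, "post_lt_status"].notna().any():
            raise ValueError("post_lt_status is present only for transplanted records")

    def __len__(self) -> int:
        return len(self.records)

    def to_csv(self, path: str | os.PathLike) -> None:
        """Write one row per patient, design parameters in a comment header."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# accrual_window: {self.accrual_window}\n")
            fh.write(f"# admin_censor_day: {self.admin_censor_day}\n")
            self.records.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "Registry":
        meta = {}
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
        body_lines = []
        for line in text.splitlines():
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition(":")
                meta[key.strip()] = int(value)
            else:
                body_lines.append(line)
        df = pd.read_csv(io.StringIO("\n".join(body_lines)))
        return cls(
            records=df,
            accrual_window=meta["accrual_window"],
            admin_censor_day=meta["admin_censor_day"],
        )


def _median_to_daily_scale(median_months: float) -> float:
    """Exponential scale (mean, days) with the given median in months."""
    return median_months * DAYS_PER_MONTH / math.log(2)


def generate_registry(
    profile: WaitlistProfile,
    n_patients: int,
    accrual_window: int,
    admin_censor_day: int,
    seed: int,
) -> Registry:
    """Simulate a patient-level registry matching a waiting-list profile.

    Per patient: the stratum is drawn from the profile's fractions, entry is
    uniform on the accrual window, latent exponential times to death/dropout
    and to transplant compete, and the earlier one is observed unless the
    administrative censoring date comes first.  Transplanted patients get an
    exponential post-transplant death time whose 5-year survival matches the
    profile.  Deterministic given ``seed``.
    """
    if n_patients < 1:
        raise ValueError(f"n_patients must be >= 1, got {n_patients}")
    if not 0 <= accrual_window <= admin_censor_day:
        raise ValueError(
            "accrual_window must lie in [0, admin_censor_day], got "
            f"{accrual_window} vs {admin_censor_day}"
        )
    rng = np.random.default_rng(seed)
    fracs = np.array([profile[g].wl_fraction for g in SUBGROUP_ORDER])
    group_idx = rng.choice(len(SUBGROUP_ORDER), size=n_patients, p=fracs)
    entry = rng.integers(0, accrual_window + 1, size=n_patients)

    exit_scale = np.array(
        [_median_to_daily_scale(profile[g].median_wl_survival) for g in SUBGROUP_ORDER]
    )
    tx_scale = np.array(
        [_median_to_daily_scale(profile[g].median_time_to_lt) for g in SUBGROUP_ORDER]
    )
    post_hazard = np.array(
        [-math.log(profile[g].post_lt_5yr_survival) / _FIVE_YEARS_DAYS
         for g in SUBGROUP_ORDER]
    )

    t_exit = rng.exponential(exit_scale[group_idx])
    t_tx = rng.exponential(tx_scale[group_idx])
    first = np.minimum(t_exit, t_tx)
    event_day = entry + np.ceil(first).astype(np.int64)
    is_tx = t_tx < t_exit

    censored = event_day > admin_censor_day
    event = np.where(
        censored, EVENT_CENSORED, np.where(is_tx, EVENT_TRANSPLANTED, EVENT_DIED_OR_DROPPED)
    )
    event_day = np.minimum(event_day, admin_censor_day)

    post_status = np.full(n_patients, np.nan, dtype=object)
    post_follow = np.full(n_patients, np.nan)
    tx_mask = (~censored) & is_tx
    n_tx = int(tx_mask.sum())
    if n_tx:
        hz = post_hazard[group_idx[tx_mask]]
        with np.errstate(divide="ignore"):
            t_post = np.where(hz > 0, rng.exponential(1.0, size=n_tx) / np.where(hz > 0, hz, 1.0), np.inf)
        death_day = event_day[tx_mask] + np.ceil(t_post)
        alive = death_day > admin_censor_day
        post_status[tx_mask] = np.where(alive, POST_LT_ALIVE, POST_LT_DEAD)
        post_follow[tx_mask] = np.where(alive, admin_censor_day, death_day)

    df = pd.DataFrame(
        {
            "patient_id": np.arange(n_patients),
            "subgroup": [SUBGROUP_ORDER[i].value for i in group_idx],
            "entry_day": entry,
            "event": event,
            "event_day": event_day,
            "post_lt_status": post_status,
            "post_lt_followup_day": post_follow,
        }
    )
    return Registry(records=df, accrual_window=accrual_window,
                    admin_censor_day=admin_censor_day)


def _km_median_days(durations: np.ndarray, observed: np.ndarray, label: str) -> float:
    """Kaplan-Meier median with linear interpolation and a day-grid correction.

    Event days are recorded on an integer day grid (each duration is the
    ceiling of a continuous time), so the raw step-function median is biased
    upward by about half a day plus the step granularity.  Interpolating the
    survival curve linearly across the step that crosses 0.5 and shifting by
    half a day removes both grid effects.
    """
    km = KaplanMeierFitter()
    km.fit(durations, event_observed=observed)
    sf = km.survival_function_.iloc[:, 0]
    t = sf.index.to_numpy(dtype=float)
    s = sf.to_numpy(dtype=float)
    if s[-1] > 0.5:
        raise ValueError(
            f"Kaplan-Meier median not reached for {label}; "
            "longer follow-up or more events are needed"
        )
    idx = int(np.argmax(s <= 0.5))
    median = t[idx]
    if idx > 0 and s[idx - 1] < 1.0:
        # interpolate across the crossing step once the curve has begun to
        # fall; a first drop straight through 0.5 is a mass point and keeps
        # the step median
        t1, t2, s1, s2 = t[idx - 1], t[idx], s[idx - 1], s[idx]
        median = t1 + (s1 - 0.5) / (s1 - s2) * (t2 - t1)
    return max(median - 0.5, 0.5)  # continuity correction for ceil'd days


def estimate_profile_from_registry(registry: Registry) -> WaitlistProfile:
    """Re-estimate a waiting-list profile from patient-level records.

    Per stratum: Kaplan-Meier median time to death/dropout (transplant and
    administrative censoring treated as censoring), Kaplan-Meier median time
    to transplant (death/censoring as censoring), empirical 5-year
    post-transplant survival, and the empirical stratum share.  The list
    size is the mean daily census over the final year of follow-up, and the
    organ supply is the transplant count over that same year.
    """
    df = registry.records
    n_total = len(df)
    subgroups: dict[SubgroupId, SubgroupParams] = {}
    for g in SUBGROUP_ORDER:
        sub = df[df["subgroup"] == g.value]
        n_events = int((sub["event"] != EVENT_CENSORED).sum())
        if len(sub) < 10 or n_events < 1:
            raise ValueError(
                f"stratum {g.value} needs >= 10 records with >= 1 event "
                f"(has {len(sub)} records, {n_events} events)"
            )
        durations = (sub["event_day"] - sub["entry_day"]).to_numpy(dtype=float)
        durations = np.maximum(durations, 0.5)  # same-day exits still at risk
        died = (sub["event"] == EVENT_DIED_OR_DROPPED).to_numpy()
        txed = (sub["event"] == EVENT_TRANSPLANTED).to_numpy()
        median_exit = _km_median_days(durations, died, f"{g.value} death/dropout")
        median_tx = _km_median_days(durations, txed, f"{g.value} transplant")

        post = sub[txed]
        if len(post):
            post_dur = (post["post_lt_followup_day"] - post["event_day"]).to_numpy(dtype=float)
            post_dur = np.maximum(post_dur, 0.5)
            post_dead = (post["post_lt_status"] == POST_LT_DEAD).to_numpy()
            if post_dead.any():
                km = KaplanMeierFitter()
                km.fit(post_dur, event_observed=post_dead)
                surv5 = float(
                    km.survival_function_at_times(_FIVE_YEARS_DAYS).iloc[0]
                )
            else:
                surv5 = 1.0
        else:
            surv5 = 1.0
        surv5 = min(max(surv5, 1e-12), 1.0)

        subgroups[g] = SubgroupParams(
            median_wl_survival=median_exit / DAYS_PER_MONTH,
            median_time_to_lt=median_tx / DAYS_PER_MONTH,
            post_lt_5yr_survival=surv5,
            wl_fraction=len(sub) / n_total,
        )

    window_start = max(registry.admin_censor_day - 365, 0)
    window_days = registry.admin_censor_day - window_start
    entry = df["entry_day"].to_numpy()
    on_list_until = np.where(
        df["event"] == EVENT_CENSORED, registry.admin_censor_day, df["event_day"]
    )
    overlap = np.clip(
        np.minimum(on_list_until, registry.admin_censor_day) - np.maximum(entry, window_start),
        0,
        None,
    )
    wl_size = max(float(overlap.sum()) / window_days, 2.0)

    tx_days = df.loc[df["event"] == EVENT_TRANSPLANTED, "event_day"].to_numpy()
    organs = int(((tx_days > window_start) & (tx_days <= registry.admin_censor_day)).sum())
    organs_per_year = max(float(organs) * 365.0 / window_days, 1e-9)

    return WaitlistProfile(
        wl_size=wl_size, organs_per_year=organs_per_year, subgroups=subgroups
    )
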