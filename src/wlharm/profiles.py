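"""Population-level waiting-list profiles and shortage scenarios.

A :class:`WaitlistProfile` bundles everything the downstream Markov model
needs to know about a liver-transplant waiting list: its size, the yearly
organ supply, and per-stratum summaries (median pre-transplant survival,
median time to transplant, 5-year post-transplant survival, stratum share).
Patients are stratified into three cirrhotic severity bands by MELD score
(<=20, 21-30, >30) plus a separate HCC stratum independent of MELD.

The packaged default is the Italian national-average centre over the
2012-2018 listing period; :class:`ParameterRanges` carries the tested
uncertainty interval for each quantity.
"""

from __future__ import annotations

import enum
import json
import math
import os
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import yaml

__all__ = [
    "SubgroupId",
    "SUBGROUP_ORDER",
    "SubgroupParams",
    "WaitlistProfile",
    "ParameterRanges",
    "ShortageScenario",
    "ProfileValidationError",
    "load_profile",
    "save_profile",
    "default_italian_profile",
    "default_parameter_ranges",
]

#: Days per month used for every month<->day conversion in the package.
DAYS_PER_MONTH = 365.25 / 12  # = 30.4375

_FRACTION_SUM_TOL = 1e-9


class ProfileValidationError(ValueError):
    """Raised when a profile/config value violates its invariant.

    The message always names the offending field.
    """


class SubgroupId(str, enum.Enum):
    """Waiting-list stratum: three MELD severity bands plus HCC."""

    MELD_LE20 = "meld_le20"
    MELD_21_30 = "meld_21_30"
    MELD_GT30 = "meld_gt30"
    HCC = "hcc"


#: Canonical ordering used for array representations everywhere.
SUBGROUP_ORDER: tuple[SubgroupId, ...] = (
    SubgroupId.MELD_LE20,
    SubgroupId.MELD_21_30,
    SubgroupId.MELD_GT30,
    SubgroupId.HCC,
)


@dataclass(frozen=True)
class SubgroupParams:
    """Summary parameters of one waiting-list stratum.

    Parameters
    ----------
    median_wl_survival
        Median time to death/dropout on the list, in months (> 0).
    median_time_to_lt
        Median time to transplant, in months (> 0).
    post_lt_5yr_survival
        5-year post-transplant survival, as a fraction in (0, 1].
    wl_fraction
        Share of the waiting list in this stratum, fraction in [0, 1].
    """

    median_wl_survival: float
    median_time_to_lt: float
    post_lt_5yr_survival: float
    wl_fraction: float

    def __post_init__(self) -> None:
        for name in ("median_wl_survival", "median_time_to_lt"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ProfileValidationError(
                    f"{name} must be a finite positive number of months, got {v!r}"
                )
        v = self.post_lt_5yr_survival
        if not (isinstance(v, (int, float)) and 0 < v <= 1):
            raise ProfileValidationError(
                f"post_lt_5yr_survival must be a fraction in (0, 1], got {v!r}"
            )
        v = self.wl_fraction
        if not (isinstance(v, (int, float)) and 0 <= v <= 1):
            raise ProfileValidationError(
                f"wl_fraction must be a fraction in [0, 1], got {v!r}"
            )


@dataclass(frozen=True)
class WaitlistProfile:
    """A complete waiting-list description driving the harm model."""

    wl_size: float
    organs_per_year: float
    subgroups: Mapping[SubgroupId, SubgroupParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.wl_size) and self.wl_size >= 2):
            raise ProfileValidationError(
                f"wl_size must be >= 2 patients, got {self.wl_size!r}"
            )
        if not (math.isfinite(self.organs_per_year) and self.organs_per_year > 0):
            raise ProfileValidationError(
                f"organs_per_year must be > 0, got {self.organs_per_year!r}"
            )
        missing = [g.value for g in SUBGROUP_ORDER if g not in self.subgroups]
        if missing:
            raise ProfileValidationError(f"missing subgroups: {missing}")
        total = sum(self.subgroups[g].wl_fraction for g in SUBGROUP_ORDER)
        if abs(total - 1.0) > _FRACTION_SUM_TOL:
            raise ProfileValidationError(
                f"subgroup wl_fraction values must sum to 1, got {total!r}"
            )
        # freeze the mapping
        object.__setattr__(self, "subgroups", dict(self.subgroups))

    def __getitem__(self, group: SubgroupId) -> SubgroupParams:
        return self.subgroups[group]

    def with_updates(self, **kwargs) -> "WaitlistProfile":
        """Return a copy with top-level fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        """Plain-dict representation (fractions, months) for serialization."""
        return {
            "wl_size": self.wl_size,
            "organs_per_year": self.organs_per_year,
            "subgroups": {
                g.value: {
                    "median_wl_survival": self.subgroups[g].median_wl_survival,
                    "median_time_to_lt": self.subgroups[g].median_time_to_lt,
                    "post_lt_5yr_survival": self.subgroups[g].post_lt_5yr_survival,
                    "wl_fraction": self.subgroups[g].wl_fraction,
                }
                for g in SUBGROUP_ORDER
            },
        }


@dataclass(frozen=True)
class ShortageScenario:
    """Fractional decrease in organ supply; 0 means usual availability."""

    organ_decrease: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.organ_decrease < 1):
            raise ProfileValidationError(
                "organ_decrease must lie in [0, 1); with a decrease of 1 no "
                f"organ ever arrives (got {self.organ_decrease!r})"
            )


@dataclass(frozen=True)
class ParameterRanges:
    """Per-parameter uniform (low, high) bounds for sensitivity analysis.

    Keys of the per-subgroup mappings follow :data:`SUBGROUP_ORDER`; each
    value is a ``(low, high)`` tuple on the same scale as the corresponding
    :class:`WaitlistProfile` field (months, fractions).
    """

    wl_size: tuple[float, float]
    organs_per_year: tuple[float, float]
    median_wl_survival: Mapping[SubgroupId, tuple[float, float]]
    median_time_to_lt: Mapping[SubgroupId, tuple[float, float]]
    post_lt_5yr_survival: Mapping[SubgroupId, tuple[float, float]]
    wl_fraction: Mapping[SubgroupId, tuple[float, float]]
    organ_decrease: tuple[float, float] = (0.0, 0.8)

    def __post_init__(self) -> None:
        def check(name: str, lo: float, hi: float) -> None:
            if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi):
                raise ProfileValidationError(f"invalid range for {name}: ({lo}, {hi})")

        check("wl_size", *self.wl_size)
        check("organs_per_year", *self.organs_per_year)
        for fname in (
            "median_wl_survival",
            "median_time_to_lt",
            "post_lt_5yr_survival",
            "wl_fraction",
        ):
            mapping = getattr(self, fname)
            for g in SUBGROUP_ORDER:
                if g not in mapping:
                    raise ProfileValidationError(f"{fname} range missing for {g.value}")
                check(f"{fname}[{g.value}]", *mapping[g])
        lo, hi = self.organ_decrease
        if not (0 <= lo <= hi < 1):
            raise ProfileValidationError(
                f"organ_decrease range must lie within [0, 1), got ({lo}, {hi})"
            )

    def contains(self, profile: WaitlistProfile) -> bool:
        """True if every profile parameter lies inside its range."""

        def inside(v: float, rng: tuple[float, float]) -> bool:
            return rng[0] <= v <= rng[1]

        if not inside(profile.wl_size, self.wl_size):
            return False
        if not inside(profile.organs_per_year, self.organs_per_year):
            return False
        for g in SUBGROUP_ORDER:
            p = profile[g]
            if not inside(p.median_wl_survival, self.median_wl_survival[g]):
                return False
            if not inside(p.median_time_to_lt, self.median_time_to_lt[g]):
                return False
            if not inside(p.post_lt_5yr_survival, self.post_lt_5yr_survival[g]):
                return False
            if not inside(p.wl_fraction, self.wl_fraction[g]):
                return False
        return True


# ---------------------------------------------------------------------------
# Packaged defaults: Italian national average, 2012-2018 listing period.
# ---------------------------------------------------------------------------

_ITALY_DEFAULT = {
    "wl_size": 58.0,
    "organs_per_year": 49.0,
    "subgroups": {
        SubgroupId.MELD_LE20: SubgroupParams(29.5, 12.8, 0.83, 0.37),
        SubgroupId.MELD_21_30: SubgroupParams(6.7, 4.4, 0.81, 0.13),
        SubgroupId.MELD_GT30: SubgroupParams(0.9, 0.7, 0.76, 0.04),
        SubgroupId.HCC: SubgroupParams(20.7, 9.5, 0.81, 0.46),
    },
}

_ITALY_RANGES = ParameterRanges(
    wl_size=(46.0, 70.0),
    organs_per_year=(39.0, 59.0),
    median_wl_survival={
        SubgroupId.MELD_LE20: (27.9, 32.0),
        SubgroupId.MELD_21_30: (6.0, 8.1),
        SubgroupId.MELD_GT30: (0.8, 1.6),
        SubgroupId.HCC: (18.6, 21.7),
    },
    median_time_to_lt={
        SubgroupId.MELD_LE20: (12.1, 14.0),
        SubgroupId.MELD_21_30: (3.9, 5.1),
        SubgroupId.MELD_GT30: (0.5, 1.3),
        SubgroupId.HCC: (8.9, 10.2),
    },
    post_lt_5yr_survival={
        SubgroupId.MELD_LE20: (0.75, 0.90),
        SubgroupId.MELD_21_30: (0.73, 0.90),
        SubgroupId.MELD_GT30: (0.68, 0.84),
        SubgroupId.HCC: (0.72, 0.90),
    },
    wl_fraction={
        SubgroupId.MELD_LE20: (0.30, 0.45),
        SubgroupId.MELD_21_30: (0.10, 0.15),
        SubgroupId.MELD_GT30: (0.03, 0.05),
        SubgroupId.HCC: (0.37, 0.55),
    },
    organ_decrease=(0.0, 0.8),
)


def default_italian_profile() -> WaitlistProfile:
    """The Italian average-centre waiting-list profile (2012-2018).

    Idempotent; returns a value-equal profile on every call.
    """
    return WaitlistProfile(
        wl_size=_ITALY_DEFAULT["wl_size"],
        organs_per_year=_ITALY_DEFAULT["organs_per_year"],
        subgroups=dict(_ITALY_DEFAULT["subgroups"]),
    )


def default_parameter_ranges() -> ParameterRanges:
    """Tested uncertainty ranges around the Italian average profile."""
    return _ITALY_RANGES


# ---------------------------------------------------------------------------
# Config file I/O.  YAML mapping, JSON accepted as alternate dialect.
# Percent-valued keys carry an explicit `_pct` suffix.
# ---------------------------------------------------------------------------

_PCT_KEYS = {"post_lt_5yr_survival", "wl_fraction"}


def _read_fraction(block: Mapping, key: str, context: str) -> float | None:
    """Read ``key`` (fraction) or ``key_pct`` (percent) from a mapping."""
    has_frac = key in block
    has_pct = f"{key}_pct" in block
    if has_frac and has_pct:
        raise ProfileValidationError(
            f"{context}: specify either {key} or {key}_pct, not both"
        )
    if has_frac:
        return float(block[key])
    if has_pct:
        return float(block[f"{key}_pct"]) / 100.0
    return None


def _parse_subgroup(
    group: SubgroupId, block: Mapping, defaults: SubgroupParams
) -> SubgroupParams:
    ctx = f"subgroups.{group.value}"
    if not isinstance(block, Mapping):
        raise ProfileValidationError(f"{ctx} must be a mapping, got {type(block)}")
    known = {
        "median_wl_survival",
        "median_time_to_lt",
        "post_lt_5yr_survival",
        "post_lt_5yr_survival_pct",
        "wl_fraction",
        "wl_fraction_pct",
    }
    unknown = set(block) - known
    if unknown:
        raise ProfileValidationError(f"{ctx}: unknown keys {sorted(unknown)}")
    vals = {}
    for key in ("median_wl_survival", "median_time_to_lt"):
        vals[key] = float(block[key]) if key in block else getattr(defaults, key)
    for key in _PCT_KEYS:
        v = _read_fraction(block, key, ctx)
        vals[key] = getattr(defaults, key) if v is None else v
    try:
        return SubgroupParams(**vals)
    except ProfileValidationError as exc:
        raise ProfileValidationError(f"{ctx}: {exc}") from None


def profile_from_dict(data: Mapping) -> WaitlistProfile:
    """Build a validated profile from a plain mapping.

    Missing optional keys are filled from the packaged Italian defaults.
    """
    if not isinstance(data, Mapping):
        raise ProfileValidationError(f"profile must be a mapping, got {type(data)}")
    base = default_italian_profile()
    known = {"wl_size", "organs_per_year", "subgroups", "name"}
    unknown = set(data) - known
    if unknown:
        raise ProfileValidationError(f"unknown top-level keys {sorted(unknown)}")
    wl_size = float(data.get("wl_size", base.wl_size))
    organs = float(data.get("organs_per_year", base.organs_per_year))
    sub_blocks = data.get("subgroups", {})
    if not isinstance(sub_blocks, Mapping):
        raise ProfileValidationError("subgroups must be a mapping")
    by_value = {g.value: g for g in SUBGROUP_ORDER}
    unknown_groups = set(sub_blocks) - set(by_value)
    if unknown_groups:
        raise ProfileValidationError(
            f"unknown subgroups {sorted(unknown_groups)}; "
            f"expected {sorted(by_value)}"
        )
    subgroups = {
        g: _parse_subgroup(g, sub_blocks.get(g.value, {}), base[g])
        for g in SUBGROUP_ORDER
    }
    return WaitlistProfile(wl_size=wl_size, organs_per_year=organs, subgroups=subgroups)


def load_profile(path: str | os.PathLike) -> WaitlistProfile:
    """Load and validate a waiting-list profile from a YAML or JSON file."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    try:
        data = yaml.safe_load(text)  # YAML is a JSON superset
    except yaml.YAMLError as exc:
        raise ProfileValidationError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        raise ProfileValidationError(f"empty profile file: {path}")
    return profile_from_dict(data)


def save_profile(profile: WaitlistProfile, path: str | os.PathLike) -> None:
    """Write a profile to YAML (or JSON when the path ends in .json)."""
    data = profile.to_dict()
    with open(path, "w", encoding="utf-8") as fh:
        if str(path).endswith(".json"):
            json.dump(data, fh, indent=2)
        else:
            yaml.safe_dump(data, fh, sort_keys=False)


def packaged_profile_path() -> str:
    """Filesystem path of the packaged Italian default profile file."""
    return str(resources.files("wlharm").joinpath("data/italy_2012_2018.yaml"))
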