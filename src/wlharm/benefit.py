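"""Individual transplant benefit, net benefit and MELD eligibility thresholds.

Five-year transplant survival benefit (life expectancy with transplantation
minus without, in life-months) is given by published linear formulas:

    T2 HCC:   benefit = 1.14 * MELD - 0.46 * log10(AFP) + 0.52
    non-HCC:  benefit = 0.89 * MELD - 3.59

where AFP is serum alpha-fetoprotein in ng/mL.  An allocation is
appropriate when this individual benefit exceeds the harm that using the
organ imposes on the rest of the waiting list; the net benefit is their
difference.  The MELD threshold for a given harm is the largest integer
MELD whose benefit does *not* exceed the harm — candidates must exceed it
to qualify.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .markov import DEFAULT_HORIZON_DAYS, compute_harm
from .profiles import WaitlistProfile

__all__ = [
    "CandidateKind",
    "Candidate",
    "NetBenefitResult",
    "MELD_MIN",
    "MELD_MAX",
    "ALL_ELIGIBLE",
    "NONE_ELIGIBLE",
    "benefit_t2hcc",
    "benefit_nonhcc",
    "candidate_benefit",
    "net_benefit",
    "meld_threshold",
    "threshold_curve",
    "net_benefit_curve",
]

MELD_MIN = 6
MELD_MAX = 40

#: Sentinel threshold meaning every MELD in [6, 40] qualifies.
ALL_ELIGIBLE = 5
#: Sentinel meaning no MELD in [6, 40] qualifies (harm exceeds any benefit).
NONE_ELIGIBLE: Optional[int] = None


class CandidateKind(str, enum.Enum):
    T2_HCC = "t2_hcc"
    NON_HCC = "non_hcc"


@dataclass(frozen=True)
class Candidate:
    """A transplant candidate; AFP is required exactly for T2 HCC."""

    kind: CandidateKind
    meld: int
    afp: Optional[float] = None

    def __post_init__(self) -> None:
        if not (MELD_MIN <= self.meld <= MELD_MAX):
            raise ValueError(f"MELD must lie in [{MELD_MIN}, {MELD_MAX}], got {self.meld}")
        if self.kind is CandidateKind.T2_HCC:
            if self.afp is None or not (self.afp > 0):
                raise ValueError("T2 HCC candidates require alpha-fetoprotein > 0 ng/mL")
        elif self.afp is not None:
            raise ValueError("alpha-fetoprotein applies only to T2 HCC candidates")


@dataclass(frozen=True)
class NetBenefitResult:
    benefit_months: float
    harm_months: float
    net_months: float


def benefit_t2hcc(meld: float, afp: float) -> float:
    """Five-year transplant benefit of a T2 HCC candidate, in life-months.

    Strictly increasing in MELD, decreasing in AFP (base-10 logarithm).
    """
    if afp <= 0:
        raise ValueError(f"alpha-fetoprotein must be > 0 ng/mL, got {afp!r}")
    if not (MELD_MIN <= meld <= MELD_MAX):
        raise ValueError(f"MELD must lie in [{MELD_MIN}, {MELD_MAX}], got {meld!r}")
    return 1.14 * meld - 0.46 * math.log10(afp) + 0.52


def benefit_nonhcc(meld: float) -> float:
    """Five-year transplant benefit of a non-HCC cirrhotic candidate."""
    if not (MELD_MIN <= meld <= MELD_MAX):
        raise ValueError(f"MELD must lie in [{MELD_MIN}, {MELD_MAX}], got {meld!r}")
    return 0.89 * meld - 3.59


def candidate_benefit(kind: CandidateKind, meld: float, afp: Optional[float] = None) -> float:
    if kind is CandidateKind.T2_HCC:
        if afp is None:
            raise ValueError("T2 HCC benefit requires alpha-fetoprotein")
        return benefit_t2hcc(meld, afp)
    return benefit_nonhcc(meld)


def net_benefit(candidate: Candidate, harm_months: float) -> NetBenefitResult:
    """Individual benefit minus harm to others; sign decides appropriateness."""
    if harm_months < 0:
        raise ValueError(f"harm_months must be >= 0, got {harm_months!r}")
    b = candidate_benefit(candidate.kind, candidate.meld, candidate.afp)
    return NetBenefitResult(benefit_months=b, harm_months=harm_months,
                            net_months=b - harm_months)


def meld_threshold(
    harm_months: float,
    kind: CandidateKind,
    afp: Optional[float] = None,
) -> Optional[int]:
    """Largest integer MELD whose benefit does not outweigh the harm.

    A candidate qualifies only with a MELD strictly above the returned
    value.  Returns :data:`ALL_ELIGIBLE` (5) when even MELD 6 outweighs the
    harm, and :data:`NONE_ELIGIBLE` (None) when not even MELD 40 does.
    """
    if harm_months < 0:
        raise ValueError(f"harm_months must be >= 0, got {harm_months!r}")
    if candidate_benefit(kind, MELD_MAX, afp) <= harm_months:
        return NONE_ELIGIBLE
    if candidate_benefit(kind, MELD_MIN, afp) > harm_months:
        return ALL_ELIGIBLE
    threshold = MELD_MIN
    for meld in range(MELD_MIN, MELD_MAX + 1):
        if candidate_benefit(kind, meld, afp) <= harm_months:
            threshold = meld
    return threshold


def threshold_curve(
    profile: WaitlistProfile,
    kind: CandidateKind,
    afp: Optional[float] = None,
    decreases: Sequence[float] = (),
    horizon_days: int = DEFAULT_HORIZON_DAYS,
    harmed_cohort: str = "non_hcc",
) -> pd.DataFrame:
    """MELD eligibility thresholds across organ-shortage scenarios.

    Columns: ``organ_decrease``, ``harm_life_months``, ``meld_threshold``
    (NaN when no MELD qualifies).  Thresholds are non-decreasing in the
    organ decrease.
    """
    rows = []
    for dec in decreases:
        harm = compute_harm(profile, dec, horizon_days=horizon_days,
                            harmed_cohort=harmed_cohort).harm_life_months
        thr = meld_threshold(harm, kind, afp)
        rows.append(
            {
                "organ_decrease": dec,
                "harm_life_months": harm,
                "meld_threshold": np.nan if thr is NONE_ELIGIBLE else thr,
            }
        )
    return pd.DataFrame(rows)


def net_benefit_curve(
    profile: WaitlistProfile,
    kind: CandidateKind,
    afp: Optional[float] = None,
    meld_grid: Sequence[float] = tuple(range(MELD_MIN, MELD_MAX + 1)),
    decreases: Sequence[float] = (0.0,),
    horizon_days: int = DEFAULT_HORIZON_DAYS,
    harmed_cohort: str = "non_hcc",
) -> pd.DataFrame:
    """Net benefit over a MELD grid for each shortage scenario.

    Long-format DataFrame with columns ``organ_decrease``, ``meld``,
    ``benefit_months``, ``harm_life_months``, ``net_months``.
    """
    rows = []
    for dec in decreases:
        harm = compute_harm(profile, dec, horizon_days=horizon_days,
                            harmed_cohort=harmed_cohort).harm_life_months
        for meld in meld_grid:
            b = candidate_benefit(kind, meld, afp)
            rows.append(
                {
                    "organ_decrease": dec,
                    "meld": meld,
                    "benefit_months": b,
                    "harm_life_months": harm,
                    "net_months": b - harm,
                }
            )
    return pd.DataFrame(rows)
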