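"""Synthetic registry generation and profile re-estimation."""

import numpy as np
import pandas as pd
import pytest

from wlharm import (
    Registry,
    SubgroupId,
    SubgroupParams,
    estimate_profile_from_registry,
    generate_registry,
)
from wlharm.profiles import DAYS_PER_MONTH, SUBGROUP_ORDER
from wlharm.registry import (
    EVENT_CENSORED,
    EVENT_DIED_OR_DROPPED,
    EVENT_TRANSPLANTED,
)


def _all_die_registry(day: int) -> Registry:
    """Every patient in every stratum dies on the same follow-up day."""
    rows = []
    pid = 0
    for g in SUBGROUP_ORDER:
        for _ in range(12):
            rows.append(
                {
                    "patient_id": pid,
                    "subgroup": g.value,
                    "entry_day": 0,
                    "event": EVENT_DIED_OR_DROPPED,
                    "event_day": day,
                    "post_lt_status": None,
                    "post_lt_followup_day": np.nan,
                }
            )
            pid += 1
    # a matching transplant arm so time-to-transplant medians exist
    for g in SUBGROUP_ORDER:
        for _ in range(12):
            rows.append(
                {
                    "patient_id": pid,
                    "subgroup": g.value,
                    "entry_day": 0,
                    "event": EVENT_TRANSPLANTED,
                    "event_day": day,
                    "post_lt_status": "alive",
                    "post_lt_followup_day": float(day + 400),
                }
            )
            pid += 1
    return Registry(pd.DataFrame(rows), accrual_window=0, admin_censor_day=day + 400)


class TestGenerateRegistry:
    def test_deterministic_given_seed(self, italian_profile):
        a = generate_registry(italian_profile, 500, 365, 3000, seed=4)
        b = generate_registry(italian_profile, 500, 365, 3000, seed=4)
        pd.testing.assert_frame_equal(a.records, b.records)
        c = generate_registry(italian_profile, 500, 365, 3000, seed=5)
        assert not a.records.equals(c.records)

    def test_no_transplants_when_waiting_time_is_astronomical(self, italian_profile):
        subgroups = {
            g: SubgroupParams(
                italian_profile[g].median_wl_survival,
                1e12,  # effectively never transplanted
                italian_profile[g].post_lt_5yr_survival,
                italian_profile[g].wl_fraction,
            )
            for g in SUBGROUP_ORDER
        }
        profile = italian_profile.with_updates(subgroups=subgroups)
        reg = generate_registry(profile, 400, 365, 3000, seed=0)
        assert (reg.records["event"] != EVENT_TRANSPLANTED).all()

    def test_record_invariants(self, italian_profile):
        reg = generate_registry(italian_profile, 800, 730, 3000, seed=1)
        df = reg.records
        assert (df.event_day >= df.entry_day).all()
        assert (df.event_day <= reg.admin_censor_day).all()
        is_tx = df.event == EVENT_TRANSPLANTED
        assert df.loc[is_tx, "post_lt_status"].notna().all()
        assert df.loc[~is_tx, "post_lt_status"].isna().all()

    def test_invalid_arguments(self, italian_profile):
        with pytest.raises(ValueError):
            generate_registry(italian_profile, 0, 365, 3000, seed=0)
        with pytest.raises(ValueError):
            generate_registry(italian_profile, 10, 4000, 3000, seed=0)

    def test_outcome_mix_direction(self, italian_profile):
        """Seven-year accrual, eight-year censoring: transplantation is the
        dominant observed outcome, ahead of death/dropout."""
        reg = generate_registry(italian_profile, 4000, 7 * 365, 8 * 365, seed=2)
        shares = reg.records["event"].value_counts(normalize=True)
        assert shares[EVENT_CENSORED] < 1
        assert shares[EVENT_DIED_OR_DROPPED] < shares[EVENT_TRANSPLANTED] < 1


class TestCsvRoundTrip:
    def test_round_trip(self, italian_profile, tmp_path):
        reg = generate_registry(italian_profile, 300, 365, 3000, seed=7)
        path = tmp_path / "registry.csv"
        reg.to_csv(path)
        back = Registry.from_csv(path)
        assert back.accrual_window == reg.accrual_window
        assert back.admin_censor_day == reg.admin_censor_day
        pd.testing.assert_frame_equal(
            back.records, reg.records, check_dtype=False
        )


class TestEstimateProfile:
    def test_all_die_on_day_d(self):
        day = 200
        est = estimate_profile_from_registry(_all_die_registry(day))
        for g in SUBGROUP_ORDER:
            assert est[g].median_wl_survival == pytest.approx(
                day / DAYS_PER_MONTH, rel=0.01
            )

    def test_no_post_lt_deaths_gives_full_survival(self):
        est = estimate_profile_from_registry(_all_die_registry(200))
        for g in SUBGROUP_ORDER:
            assert est[g].post_lt_5yr_survival == 1.0

    def test_stratum_without_records_is_named(self, italian_profile):
        reg = generate_registry(italian_profile, 300, 365, 3000, seed=7)
        pruned = reg.records[reg.records.subgroup != SubgroupId.MELD_GT30.value]
        bad = Registry(pruned, reg.accrual_window, reg.admin_censor_day)
        with pytest.raises(ValueError, match="meld_gt30"):
            estimate_profile_from_registry(bad)

    def test_recovery_single_seed_is_loose(self, italian_profile):
        """One n=5000 draw recovers every configured parameter within 25%
        (the tight 10-seed-average check lives in the acceptance suite)."""
        reg = generate_registry(italian_profile, 5000, 365, 15 * 365, seed=0)
        est = estimate_profile_from_registry(reg)
        for g in SUBGROUP_ORDER:
            truth = italian_profile[g]
            assert est[g].median_wl_survival == pytest.approx(
                truth.median_wl_survival, rel=0.25
            )
            assert est[g].median_time_to_lt == pytest.approx(
                truth.median_time_to_lt, rel=0.25
            )
            assert est[g].wl_fraction == pytest.approx(truth.wl_fraction, rel=0.25)
            assert est[g].post_lt_5yr_survival == pytest.approx(
                truth.post_lt_5yr_survival, rel=0.1
            )

    def test_memoryless_exit_times_survive_left_truncation(self, italian_profile):
        """With exponential exits, dropping the first 90 days of each
        patient's waiting time leaves the estimated median unchanged."""
        reg = generate_registry(italian_profile, 20000, 0, 20 * 365, seed=3)
        df = reg.records
        hcc = df[df.subgroup == SubgroupId.HCC.value]
        dur = (hcc.event_day - hcc.entry_day).to_numpy(dtype=float)
        died = (hcc.event == EVENT_DIED_OR_DROPPED).to_numpy()
        from wlharm.registry import _km_median_days

        full = _km_median_days(np.maximum(dur, 0.5), died, "full")
        keep = dur > 90
        trunc = _km_median_days(dur[keep] - 90, died[keep], "truncated")
        assert trunc == pytest.approx(full, rel=0.1)
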