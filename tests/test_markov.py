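"""Markov cohort engine: arithmetic, closed-form oracles, harm behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wlharm import (
    CohortState,
    SubgroupId,
    build_daily_rates,
    compute_harm,
    harm_curve,
    microsim_cohort,
    organ_interarrival_days,
    simulate_cohort,
)
from wlharm.markov import DEFAULT_HORIZON_DAYS, _simulate_unit, harm_batch
from wlharm.profiles import DAYS_PER_MONTH, SUBGROUP_ORDER


class TestOrganInterarrival:
    @pytest.mark.parametrize(
        "organs, decrease, expected",
        [
            (36, 0.0, 10.14),   # ~10 days at usual supply
            (36, 0.5, 20.28),   # ~20 days when supply halves
            (49, 0.0, 365 / 49),
        ],
    )
    def test_worked_values(self, organs, decrease, expected):
        assert organ_interarrival_days(organs, decrease) == pytest.approx(expected, abs=5e-3)

    def test_errors(self):
        with pytest.raises(ValueError):
            organ_interarrival_days(0, 0.0)
        with pytest.raises(ValueError):
            organ_interarrival_days(36, 1.0)


class TestSimulateUnit:
    def test_no_transitions_gives_full_horizon(self):
        le, dead = _simulate_unit(0.0, 0.0, 0.0, 0.0, DEFAULT_HORIZON_DAYS)
        assert le == pytest.approx(60.0, abs=0.01)
        assert dead == 0.0

    def test_certain_death_first_cycle(self):
        le, dead = _simulate_unit(1.0, 0.0, 0.0, 0.0, DEFAULT_HORIZON_DAYS)
        assert le == pytest.approx(1.0 / DAYS_PER_MONTH, abs=1e-12)
        assert dead == pytest.approx(1.0, abs=1e-12)

    def test_geometric_series_closed_form(self):
        """Death-only cohort matches the geometric-series life expectancy."""
        dp = 0.01
        le, dead = _simulate_unit(dp, 0.0, 0.0, 0.0, DEFAULT_HORIZON_DAYS)
        expected = sum((1 - dp) ** k for k in range(DEFAULT_HORIZON_DAYS)) / DAYS_PER_MONTH
        assert le == pytest.approx(expected, rel=1e-3)
        assert dead == pytest.approx(1 - (1 - dp) ** DEFAULT_HORIZON_DAYS, rel=1e-9)

    def test_conservation_under_default_rates(self, italian_profile):
        d, t, mu = build_daily_rates(italian_profile).as_arrays()
        # raises internally if per-cycle mass drifts beyond 1e-9
        _simulate_unit(d, t, mu, 14.9, DEFAULT_HORIZON_DAYS, check_conservation=True)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        d=st.floats(min_value=0.0, max_value=0.4),
        t=st.floats(min_value=0.0, max_value=0.4),
        mu=st.floats(min_value=0.0, max_value=0.1),
        susp=st.floats(min_value=0.0, max_value=40.0),
    )
    def test_conservation_property(self, d, t, mu, susp):
        _simulate_unit(d, t, mu, susp, 400, check_conservation=True)

    def test_suspension_bounds(self):
        with pytest.raises(ValueError):
            _simulate_unit(0.1, 0.1, 0.0, -1.0, 100)
        with pytest.raises(ValueError):
            _simulate_unit(0.1, 0.1, 0.0, 100.0, 100)


class TestSimulateCohort:
    def test_per_stratum_outputs(self, italian_profile):
        rates = build_daily_rates(italian_profile)
        initial = CohortState.from_waiting_counts({g: 10.0 for g in SUBGROUP_ORDER})
        le, dead = simulate_cohort(rates, initial)
        assert set(le) == set(SUBGROUP_ORDER)
        # the sickest stratum has the shortest expected survival
        assert le[SubgroupId.MELD_GT30] == min(le.values())
        assert all(0 < v < 1 for v in dead.values())

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CohortState.from_waiting_counts({SubgroupId.HCC: -1.0})


class TestMicrosimOracle:
    def test_cohort_matches_microsimulation(self, italian_profile):
        """Expected-value recursion vs per-patient simulation, per stratum."""
        rates = build_daily_rates(italian_profile)
        initial = CohortState.from_waiting_counts({g: 1.0 for g in SUBGROUP_ORDER})
        le, dead = simulate_cohort(rates, initial)
        for i, g in enumerate(SUBGROUP_ORDER):
            m_le, m_dead = microsim_cohort(
                rates.dp_death[g],
                rates.dp_transplant[g],
                rates.dp_post_lt_death[g],
                n_patients=100_000,
                seed=10 + i,
            )
            assert m_le == pytest.approx(le[g], rel=5e-3)
            assert m_dead == pytest.approx(dead[g], abs=6e-3)


class TestComputeHarm:
    def test_harm_is_positive_and_consistent(self, italian_profile):
        res = compute_harm(italian_profile, 0.0)
        assert res.harm_life_months > 0
        assert res.extra_death_risk > 0
        assert res.delay_days == pytest.approx(365 / 49, rel=1e-12)
        assert res.harm_life_months == pytest.approx(
            res.le_no_allocation - res.le_with_allocation, rel=1e-9
        )

    def test_monotone_in_organ_decrease(self, italian_profile):
        harms = [compute_harm(italian_profile, d).harm_life_months for d in (0.0, 0.25, 0.5)]
        assert harms[0] < harms[1] < harms[2]

    def test_interarrival_scaling_at_quarter_decrease(self, italian_profile):
        """A 25% supply drop lengthens the delay 4/3-fold and the harm nearly so."""
        h0 = compute_harm(italian_profile, 0.0).harm_life_months
        h25 = compute_harm(italian_profile, 0.25).harm_life_months
        assert h25 / h0 == pytest.approx(4 / 3, rel=0.05)

    def test_no_death_channel_no_harm(self, italian_profile):
        subgroups = {
            g: italian_profile[g].__class__(
                median_wl_survival=1e9,
                median_time_to_lt=italian_profile[g].median_time_to_lt,
                post_lt_5yr_survival=italian_profile[g].post_lt_5yr_survival,
                wl_fraction=italian_profile[g].wl_fraction,
            )
            for g in SUBGROUP_ORDER
        }
        profile = italian_profile.with_updates(subgroups=subgroups)
        res = compute_harm(profile, 0.0)
        assert res.extra_death_risk == pytest.approx(0.0, abs=1e-6)

    def test_all_minus_candidate_cohort_is_larger(self, italian_profile):
        """Keeping the HCC stratum in the harmed cohort adds its losses."""
        non_hcc = compute_harm(italian_profile, 0.0)
        full = compute_harm(italian_profile, 0.0, harmed_cohort="all_minus_candidate")
        assert full.harm_life_months > non_hcc.harm_life_months
        assert full.extra_death_risk > non_hcc.extra_death_risk

    def test_unknown_cohort_mode(self, italian_profile):
        with pytest.raises(ValueError, match="harmed_cohort"):
            compute_harm(italian_profile, 0.0, harmed_cohort="everyone")


class TestHarmCurve:
    def test_single_point_matches_compute_harm(self, italian_profile):
        df = harm_curve(italian_profile, [0.0])
        res = compute_harm(italian_profile, 0.0)
        assert len(df) == 1
        assert df.harm_life_months.iloc[0] == res.harm_life_months
        assert df.extra_death_risk.iloc[0] == res.extra_death_risk

    def test_monotone_over_grid(self, italian_profile):
        df = harm_curve(italian_profile, np.linspace(0, 0.7, 8))
        assert (np.diff(df.harm_life_months) > 0).all()
        assert (np.diff(df.extra_death_risk) > 0).all()


class TestHarmBatch:
    def test_batch_matches_scalar_path(self, italian_profile):
        d, t, mu = build_daily_rates(italian_profile).as_arrays()
        fr = np.array([[italian_profile[g].wl_fraction for g in SUBGROUP_ORDER]] * 3)
        dec = np.array([0.0, 0.25, 0.5])
        harm, risk, _, _ = harm_batch(
            np.full(3, 58.0), np.full(3, 49.0), dec,
            np.tile(d, (3, 1)), np.tile(t, (3, 1)), np.tile(mu, (3, 1)), fr,
        )
        for i, dv in enumerate(dec):
            res = compute_harm(italian_profile, float(dv))
            assert harm[i] == pytest.approx(res.harm_life_months, rel=1e-12)
            assert risk[i] == pytest.approx(res.extra_death_risk, rel=1e-12)
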