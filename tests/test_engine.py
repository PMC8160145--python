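"""Unit and property tests for the stock-flow simulation engine."""

import numpy as np
import pytest

from mhsd import (
    CapacityModifiers,
    ConfigurationError,
    ModelParams,
    RegionConfig,
    ShockParams,
    aggregate_regions,
    capacity_at,
    cumulative_outcomes,
    init_state,
    shock_multiplier,
    simulate,
    step,
    wait_time,
)
from mhsd.engine import (
    DAYS_PER_YEAR,
    N_PERSON,
    STOCKS,
    ScenarioOutcome,
    date_to_t,
)

from conftest import FAST_DT


def make_config(pop=1_000_000.0, prevalence=0.135, **over) -> RegionConfig:
    kw = dict(
        region_id="test",
        initial_population=pop,
        births_rate=12_000.0,
        net_migration=1_500.0,
        background_mortality=0.0065,
        initial_distress_prevalence=prevalence,
        service_capacities={"gp": 3_300.0, "specialist": 1_700.0,
                            "inpatient": 50.0, "cmhc": 2_000.0},
        capacity_growth={"gp": 0.022, "specialist": 0.018,
                         "inpatient": 0.010, "cmhc": 0.0},
    )
    kw.update(over)
    return RegionConfig(**kw)


def inert_params() -> ModelParams:
    """All rates zero: a step must leave the state unchanged."""
    p = ModelParams()
    for name in (
        "distress_onset_rate", "recovery_untreated", "help_seeking_rate",
        "refer_specialist", "refer_cmhc", "refer_online", "refer_inpatient",
        "inpatient_discharge_rate", "base_disengagement_rate",
        "disengagement_wait_sensitivity", "re_engagement_rate",
        "post_attempt_engage_rate", "post_attempt_return_rate",
        "attempt_hazard_untreated", "attempt_hazard_in_care",
        "attempt_hazard_post_attempt", "ed_rate_untreated",
        "ed_rate_post_attempt", "intake_rate",
    ):
        setattr(p, name, 0.0)
    return p


# ---------------------------------------------------------------- init_state


class TestInitState:
    @pytest.mark.parametrize("prevalence,expected_distressed", [
        (0.135, 135_000.0),
        (0.0, 0.0),
        (1.0, 1_000_000.0),
    ])
    def test_population_split(self, prevalence, expected_distressed):
        state = init_state(make_config(prevalence=prevalence), ModelParams())
        distressed = sum(
            v for k, v in state.stocks.items() if k != "well"
        )
        assert distressed == pytest.approx(expected_distressed, rel=1e-12)
        assert state.population == pytest.approx(1_000_000.0, rel=1e-12)

    def test_prevalence_one_empties_well(self):
        state = init_state(make_config(prevalence=1.0), ModelParams())
        assert state.stocks["well"] == 0.0

    def test_cumulatives_start_at_zero(self):
        state = init_state(make_config(), ModelParams())
        assert all(v == 0.0 for v in state.cumulatives.values())

    def test_zero_population_rejected(self):
        with pytest.raises(ConfigurationError):
            make_config(pop=0.0)


# ------------------------------------------------------- elementary operators


class TestCapacityAt:
    def test_compound_growth_one_year(self):
        cfg = make_config(service_capacities={"gp": 100.0, "specialist": 1.0,
                                              "inpatient": 1.0, "cmhc": 1.0},
                          capacity_growth={"gp": 0.05})
        assert capacity_at("gp", 1.0, cfg) == pytest.approx(105.0)

    def test_lever_doubles_growth_rate(self):
        cfg = make_config(service_capacities={"gp": 100.0, "specialist": 1.0,
                                              "inpatient": 1.0, "cmhc": 1.0},
                          capacity_growth={"gp": 0.05})
        mods = CapacityModifiers(growth_multiplier={"gp": 2.0}, start_t=0.0)
        assert capacity_at("gp", 1.0, cfg, mods) == pytest.approx(110.0)

    def test_cmhc_default_increment_keeps_capacity_constant(self):
        cfg = make_config(capacity_growth={"cmhc": 0.0})
        for t in (0.0, 5.0, 20.0):
            assert capacity_at("cmhc", t, cfg) == pytest.approx(2_000.0)

    def test_cmhc_additive_increment(self):
        cfg = make_config(capacity_growth={"cmhc": 0.0})
        mods = CapacityModifiers(cmhc_increment_per_10k=0.5, start_t=0.0)
        # pop 1e6 -> 100 ten-thousands -> +50 contacts/week per year
        assert capacity_at("cmhc", 2.0, cfg, mods) == pytest.approx(2_100.0)

    def test_unknown_service_raises(self):
        with pytest.raises(KeyError):
            capacity_at("dentist", 0.0, make_config())


class TestWaitTime:
    @pytest.mark.parametrize("queue,throughput,expected", [
        (30.0, 10.0, 3.0),
        (0.0, 10.0, 0.0),
        (0.0, 0.0, 0.0),
        (1000.0, 10.0, 52.0),  # capped
    ])
    def test_littles_law_with_cap(self, queue, throughput, expected):
        assert wait_time(queue, throughput) == pytest.approx(expected)

    def test_saturated_service_returns_cap(self):
        assert wait_time(5.0, 0.0, cap=26.0) == 26.0


class TestShockMultiplier:
    def test_pulse_off_before_start(self):
        assert shock_multiplier(date_to_t("2020-02-01"), ShockParams()) == 1.0

    def test_pulse_on_inside(self):
        sh = ShockParams(onset_multiplier=1.2)
        assert shock_multiplier(date_to_t("2020-06-01"), sh) == 1.2

    def test_duration_moves_only_end_date(self):
        short = ShockParams(duration=1.0, onset_multiplier=1.2)
        long = ShockParams(duration=3.0, onset_multiplier=1.2)
        t_mid = short.start + 2.0
        assert shock_multiplier(t_mid, short) == 1.0
        assert shock_multiplier(t_mid, long) == 1.2
        # height unchanged
        assert shock_multiplier(short.start, short) == 1.2
        assert shock_multiplier(long.start, long) == 1.2


# ------------------------------------------------------------------- stepping


class TestStep:
    def test_zero_dynamics_is_identity(self):
        cfg = make_config(births_rate=0.0, net_migration=0.0,
                          background_mortality=0.0)
        p = inert_params()
        s0 = init_state(cfg, p)
        s1 = step(s0, p, cfg)
        for name in STOCKS:
            assert s1.stocks[name] == pytest.approx(s0.stocks[name], abs=1e-9)

    def test_single_onset_flow_first_order(self):
        cfg = make_config(births_rate=0.0, net_migration=0.0,
                          background_mortality=0.0, prevalence=0.0)
        p = inert_params()
        p.distress_onset_rate = 0.2
        p.shock = ShockParams(start=100.0)  # pulse far outside the step
        s0 = init_state(cfg, p)
        dt = 0.4375 / DAYS_PER_YEAR
        s1 = step(s0, p, cfg, dt=dt)
        expected = s0.stocks["well"] * 0.2 * dt
        assert s0.stocks["well"] - s1.stocks["well"] == pytest.approx(expected)
        assert s1.stocks["distressed_not_in_care"] == pytest.approx(expected)

    def test_person_conservation_over_run(self, baseline_traj_28y, configs):
        """Population change equals (births + migration - deaths - suicides)
        accumulated, to floating-point precision, at every grid point."""
        traj = baseline_traj_28y
        cfg = configs[0]
        s = traj.states
        pop = s[:, :N_PERSON].sum(axis=1)
        inflow = cfg.births_rate + cfg.net_migration
        bgd = s[:, traj.states.shape[1] - 1]  # background_deaths counter
        sui = s[:, N_PERSON]  # suicide_deaths counter
        expected = pop[0] + inflow * traj.times - (bgd - bgd[0]) - (sui - sui[0])
        assert np.allclose(pop, expected, rtol=1e-10)

    def test_non_negativity_every_step(self, baseline_traj_28y):
        assert baseline_traj_28y.states[:, :N_PERSON].min() >= 0.0

    def test_cumulatives_non_decreasing(self, baseline_traj_28y):
        cums = baseline_traj_28y.states[:, N_PERSON:]
        assert (np.diff(cums, axis=0) >= -1e-9).all()

    def test_determinism_bit_identical(self, hne_config):
        p = ModelParams()
        a = simulate(hne_config, p, t_end=3.0, dt_days=FAST_DT)
        b = simulate(hne_config, ModelParams(), t_end=3.0, dt_days=FAST_DT)
        assert np.array_equal(a.states, b.states)

    def test_monotone_shock_response(self, hne_config):
        """A stronger distress-onset pulse cannot reduce cumulative
        suicides over the pandemic decade."""
        window = (date_to_t("2020-03-01"), 20.0)
        suicides = []
        for mult in (1.0, 1.1, 1.3):
            p = ModelParams()
            p.shock = ShockParams(onset_multiplier=mult)
            traj = simulate(hne_config, p, t_end=20.5, dt_days=FAST_DT)
            suicides.append(cumulative_outcomes(traj, window).suicides)
        assert suicides[0] <= suicides[1] <= suicides[2]

    def test_capacity_binding(self, baseline_traj_28y, configs):
        """Completed GP consultations per week never exceed capacity."""
        traj = baseline_traj_28y
        cfg = configs[0]
        consults_per_week = traj.derived["gp_consultations_per_yr"] / (
            DAYS_PER_YEAR / 7.0
        )
        cap = np.array(
            [capacity_at("gp", t, cfg) for t in traj.times]
        )
        assert (consults_per_week <= cap * (1 + 1e-9)).all()

    def test_step_size_convergence(
        self, baseline_traj_28y, baseline_traj_28y_half_dt
    ):
        o1 = cumulative_outcomes(baseline_traj_28y, (0.0, 28.0))
        o2 = cumulative_outcomes(baseline_traj_28y_half_dt, (0.0, 28.0))
        for name in ("suicides", "ed_presentations", "disengagements"):
            a, b = getattr(o1, name), getattr(o2, name)
            assert abs(a - b) / b < 0.01


# ----------------------------------------------------------------- outcomes


def make_outcome(sid="s", region="R", window=(10.0, 20.0), tri=(1, 2, 3)):
    return ScenarioOutcome(sid, region, window, *tri)


class TestOutcomes:
    def test_zero_length_window(self, baseline_traj_28y):
        o = cumulative_outcomes(baseline_traj_28y, (5.0, 5.0))
        assert o.suicides == 0.0
        assert o.ed_presentations == 0.0
        assert o.disengagements == 0.0

    def test_full_span_equals_final_counters(self, baseline_traj_28y):
        o = cumulative_outcomes(baseline_traj_28y, (0.0, 28.0))
        final = baseline_traj_28y.state_at(28.0).cumulatives
        assert o.suicides == pytest.approx(final["suicide_deaths"])
        assert o.ed_presentations == pytest.approx(final["ed_presentations"])

    def test_abutting_windows_add(self, baseline_traj_28y):
        a = cumulative_outcomes(baseline_traj_28y, (2.0, 9.0))
        b = cumulative_outcomes(baseline_traj_28y, (9.0, 16.0))
        u = cumulative_outcomes(baseline_traj_28y, (2.0, 16.0))
        assert a.suicides + b.suicides == pytest.approx(u.suicides)
        assert a.disengagements + b.disengagements == pytest.approx(
            u.disengagements
        )

    def test_window_outside_span_rejected(self, baseline_traj_28y):
        with pytest.raises(ValueError):
            cumulative_outcomes(baseline_traj_28y, (0.0, 99.0))

    def test_aggregate_sums_componentwise(self):
        a = make_outcome(tri=(471.0, 42_423.0, 164_293.0))
        b = make_outcome(tri=(1307.0, 113_478.0, 380_678.0))
        phn = aggregate_regions([a, b])
        assert phn.region_id == "PHN"
        assert phn.suicides == 1778.0
        assert phn.ed_presentations == 155_901.0
        assert phn.disengagements == 544_971.0

    def test_aggregate_single_region_is_identity(self):
        a = make_outcome(tri=(5.0, 6.0, 7.0))
        phn = aggregate_regions([a])
        assert phn.as_tuple() == a.as_tuple()

    def test_aggregate_rejects_mismatched_windows(self):
        a = make_outcome(window=(0.0, 1.0))
        b = make_outcome(window=(0.0, 2.0))
        with pytest.raises(ValueError):
            aggregate_regions([a, b])
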