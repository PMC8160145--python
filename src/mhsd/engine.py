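"""Stock-flow simulator of a regional mental-health system.

The model tracks a regional population moving between psychological-distress
and service states: people are either well (low or no psychological distress,
K10 <= 15) or distressed (K10 >= 16), and distressed people may travel one of
several service pathways spanning the primary-to-tertiary continuum — general
practice, psychiatrist/allied specialist care, community mental healthcare
(CMHC), psychiatric inpatient care and online services — or disengage from
care before recovery.  A suicidal-behaviour component generates suicide
attempts at state-specific hazards; a fixed fraction of attempts is
hospitalised (the self-harm hospitalisation proxy) and a fixed case-fatality
fraction dies.  Emergency-department (ED) presentations are generated as
events from crisis states and from attempts.

Eleven person stocks are integrated with an explicit Euler scheme on a fixed
sub-weekly grid (default one sixteenth of a week = 0.4375 days), with all
outflows from a stock jointly rationed so no stock can go negative.  Four
event counters (suicide deaths, self-harm hospitalisations, ED presentations,
disengagement events) and a background-mortality counter accumulate alongside
the stocks.

Time is measured in fractional years since 1 January 2011 on a 365-day
calendar, so the 28-year horizon at the default step is exactly 23,360 steps.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = [
    "DAYS_PER_YEAR",
    "WEEKS_PER_YEAR",
    "DEFAULT_DT_DAYS",
    "EPOCH",
    "STOCKS",
    "RegionConfig",
    "ShockParams",
    "ModelParams",
    "CapacityModifiers",
    "RegionState",
    "Trajectory",
    "ScenarioOutcome",
    "ConfigurationError",
    "IntegrationError",
    "date_to_t",
    "t_to_date",
    "wait_time",
    "shock_multiplier",
    "capacity_at",
    "init_state",
    "step",
    "simulate",
    "cumulative_outcomes",
    "aggregate_regions",
]

# --------------------------------------------------------------------------
# Time conventions
# --------------------------------------------------------------------------

DAYS_PER_YEAR = 365.0
WEEKS_PER_YEAR = DAYS_PER_YEAR / 7.0
#: Output/integration step: one sixteenth of a week.
DEFAULT_DT_DAYS = 0.4375
#: Model time zero.
EPOCH = _dt.date(2011, 1, 1)


def date_to_t(d: _dt.date | str) -> float:
    """Convert a calendar date to fractional years since 1 Jan 2011."""
    if isinstance(d, str):
        d = _dt.date.fromisoformat(d)
    return (d - EPOCH).days / DAYS_PER_YEAR


def t_to_date(t: float) -> _dt.date:
    """Inverse of :func:`date_to_t` (rounded to the nearest day)."""
    return EPOCH + _dt.timedelta(days=round(t * DAYS_PER_YEAR))


# --------------------------------------------------------------------------
# Stock layout
# --------------------------------------------------------------------------

#: Person stocks, in state-vector order.
STOCKS = (
    "well",
    "distressed_not_in_care",
    "awaiting_gp",
    "in_gp_care",
    "awaiting_specialist",
    "in_specialist_care",
    "in_cmhc_care",
    "inpatient",
    "online_services",
    "disengaged",
    "post_attempt",
)
N_PERSON = len(STOCKS)

# cumulative counters appended to the state vector
CUMULATIVES = (
    "suicide_deaths",
    "self_harm_hospitalisations",
    "ed_presentations",
    "disengagement_events",
    "background_deaths",
)
N_STATE = N_PERSON + len(CUMULATIVES)

_IDX = {name: i for i, name in enumerate(STOCKS + CUMULATIVES)}

SERVICES = ("gp", "specialist", "inpatient", "cmhc")


class ConfigurationError(ValueError):
    """Invalid region configuration or parameters."""


class IntegrationError(RuntimeError):
    """The Euler update produced a non-finite or negative stock."""


# --------------------------------------------------------------------------
# Configuration & parameters
# --------------------------------------------------------------------------


@dataclass
class RegionConfig:
    """Static description of one region (an LHD-like sub-catchment).

    Capacities are service events per week (consultations, sessions,
    contacts, admissions); per-person service intensities in
    :class:`ModelParams` convert them into maximum caseloads.
    """

    region_id: str
    initial_population: float
    births_rate: float  # persons/yr
    net_migration: float  # persons/yr
    background_mortality: float  # fraction/yr
    initial_distress_prevalence: float
    service_capacities: dict[str, float]  # service_id -> events/week
    capacity_growth: dict[str, float]  # service_id -> fraction/yr
    burden_share: float = 1.0

    def __post_init__(self) -> None:
        if self.initial_population <= 0:
            raise ConfigurationError(
                f"initial_population must be > 0, got {self.initial_population}"
            )
        if not 0.0 <= self.initial_distress_prevalence <= 1.0:
            raise ConfigurationError(
                "initial_distress_prevalence must be in [0, 1], got "
                f"{self.initial_distress_prevalence}"
            )
        for sid in SERVICES:
            if sid not in self.service_capacities:
                raise ConfigurationError(f"missing capacity for service {sid!r}")
            if self.service_capacities[sid] < 0:
                raise ConfigurationError(f"capacity for {sid!r} must be >= 0")


@dataclass
class ShockParams:
    """Rectangular multiplicative pulse on distress-onset incidence.

    Represents the surge in psychological-distress incidence from
    pandemic-related unemployment and social dislocation beginning
    March 2020.
    """

    start: float = field(default_factory=lambda: date_to_t("2020-03-01"))
    duration: float = 2.0  # years
    onset_multiplier: float = 1.075

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigurationError("shock duration must be > 0")
        if self.onset_multiplier < 1:
            raise ConfigurationError("shock onset_multiplier must be >= 1")


@dataclass
class ModelParams:
    """All free rates, fractions and hazards of the model.

    Rates are per person-year unless noted.  Defaults are the package's
    documented baseline parameterisation, tuned so the default synthetic
    region reproduces the observed regional scale of distress prevalence
    (~13.5 per 100 adults), suicide mortality (~13.7 per 100,000/yr) and
    service activity; they stand in for a region-specific calibrated set.
    """

    # distress dynamics
    distress_onset_rate: float = 0.075
    recovery_untreated: float = 0.50
    help_seeking_rate: float = 0.75
    intake_rate: float = 26.0  # queue-processing propensity, /yr

    # referral rates out of GP care, /yr
    refer_specialist: float = 0.35
    refer_cmhc: float = 0.18
    refer_online: float = 0.25
    refer_inpatient: float = 0.08

    # treatment success (recovery to well), /yr, per service
    treatment_success: dict[str, float] = field(
        default_factory=lambda: {
            "gp": 0.60,
            "specialist": 0.90,
            "cmhc": 0.80,
            "online": 0.70,
        }
    )
    inpatient_discharge_rate: float = 12.0  # /yr (mean stay ~1 month), to CMHC

    # disengagement & re-engagement
    base_disengagement_rate: float = 0.47  # /yr from care states and queues
    disengagement_wait_sensitivity: float = 0.040  # /yr per week of wait
    re_engagement_rate: float = 0.70  # disengaged -> GP queue, /yr
    post_attempt_engage_rate: float = 4.0  # post-attempt -> CMHC care, /yr
    post_attempt_return_rate: float = 2.0  # post-attempt -> distressed, /yr

    # suicidal behaviour
    attempt_hazard_untreated: float = 0.0315  # events/person/yr
    attempt_hazard_in_care: float = 0.021
    attempt_hazard_post_attempt: float = 0.30
    attempt_case_fatality: float = 0.030
    hospitalised_fraction: float = 0.33

    # ED presentations, events/person/yr
    ed_rate_untreated: float = 0.068
    ed_rate_post_attempt: float = 0.60

    # service intensities: events consumed per person in care per year
    contacts_per_year: dict[str, float] = field(
        default_factory=lambda: {
            "gp": 10.0,
            "specialist": 20.0,
            "cmhc": 26.0,
        }
    )

    # intervention-controlled dials (baseline: inert)
    help_seeking_multiplier: float = 1.0
    safe_space_diversion: float = 0.0  # fraction of ED flow diverted, [0,1)
    acute_care_diversion: float = 0.0  # fraction of crisis flow into CMHC
    connectedness_coverage: float = 0.0  # [0,1]
    aftercare_cmhc_cost: float = 0.0  # CMHC contacts/week per post-attempt person

    max_wait_weeks: float = 52.0
    shock: ShockParams = field(default_factory=ShockParams)

    def __post_init__(self) -> None:
        for name in (
            "attempt_case_fatality",
            "hospitalised_fraction",
            "safe_space_diversion",
            "acute_care_diversion",
            "connectedness_coverage",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.attempt_hazard_in_care > self.attempt_hazard_untreated:
            raise ConfigurationError(
                "in-care attempt hazard must not exceed the untreated hazard"
            )

    # -- parameter-path plumbing (used by interventions & calibration) -----

    def get_path(self, path: str) -> float:
        """Read a parameter by dotted path, e.g. ``treatment_success.gp``."""
        obj: object = self
        for part in path.split("."):
            if isinstance(obj, dict):
                obj = obj[part]
            else:
                obj = getattr(obj, part)
        return float(obj)  # type: ignore[arg-type]

    def set_path(self, path: str, value: float) -> None:
        parts = path.split(".")
        obj: object = self
        for part in parts[:-1]:
            obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
        if isinstance(obj, dict):
            if parts[-1] not in obj:
                raise KeyError(path)
            obj[parts[-1]] = value
        else:
            if not hasattr(obj, parts[-1]):
                raise AttributeError(path)
            setattr(obj, parts[-1], value)

    def copy(self) -> "ModelParams":
        return replace(
            self,
            treatment_success=dict(self.treatment_success),
            contacts_per_year=dict(self.contacts_per_year),
            shock=replace(self.shock),
        )


@dataclass
class CapacityModifiers:
    """Policy settings acting on service capacity growth.

    ``growth_multiplier`` scales each service's annual capacity growth rate
    from ``start_t`` onward (default 1 = business as usual);
    ``cmhc_increment_per_10k`` adds CMHC contacts per 10,000 population per
    week, accruing annually from ``start_t`` (default 0 = no growth).
    """

    growth_multiplier: dict[str, float] = field(
        default_factory=lambda: {sid: 1.0 for sid in SERVICES}
    )
    cmhc_increment_per_10k: float = 0.0
    start_t: float = 0.0

    def copy(self) -> "CapacityModifiers":
        return CapacityModifiers(
            dict(self.growth_multiplier), self.cmhc_increment_per_10k, self.start_t
        )


# --------------------------------------------------------------------------
# State containers
# --------------------------------------------------------------------------


@dataclass
class RegionState:
    """All stock values and cumulative counters at one time point."""

    t: float
    stocks: dict[str, float]
    cumulatives: dict[str, float]

    @property
    def population(self) -> float:
        return sum(self.stocks.values())

    def to_vector(self) -> np.ndarray:
        y = np.empty(N_STATE)
        for name, i in _IDX.items():
            y[i] = (
                self.stocks[name] if name in self.stocks else self.cumulatives[name]
            )
        return y

    @classmethod
    def from_vector(cls, t: float, y: np.ndarray | list[float]) -> "RegionState":
        return cls(
            t=t,
            stocks={name: float(y[_IDX[name]]) for name in STOCKS},
            cumulatives={name: float(y[_IDX[name]]) for name in CUMULATIVES},
        )


@dataclass
class Trajectory:
    """A simulated run on a fixed grid, with derived output series.

    ``states`` has one row per grid point, columns in ``STOCKS`` then
    ``CUMULATIVES`` order.  ``derived`` holds instantaneous output series:
    annual-rate event flows, distress prevalence, per-service wait times
    (weeks) and utilisations.
    """

    region_id: str
    times: np.ndarray
    states: np.ndarray
    derived: dict[str, np.ndarray]
    dt: float

    def state_at(self, t: float) -> RegionState:
        """State at the grid point nearest to time ``t``."""
        i = int(round((t - self.times[0]) / self.dt))
        if i < 0 or i >= len(self.times):
            raise ValueError(f"t={t} outside trajectory span")
        return RegionState.from_vector(float(self.times[i]), self.states[i])

    def series(self, name: str) -> np.ndarray:
        if name in _IDX:
            return self.states[:, _IDX[name]]
        return self.derived[name]

    def to_frame(self):
        """Tidy long-format DataFrame (time, variable, value)."""
        import pandas as pd

        cols = {name: self.states[:, i] for name, i in _IDX.items()}
        cols.update(self.derived)
        wide = pd.DataFrame({"time": self.times, **cols})
        return wide.melt(id_vars="time", var_name="variable", value_name="value")


@dataclass
class ScenarioOutcome:
    """Cumulative outcome triplet over a window, for one region."""

    scenario_id: str
    region_id: str
    window: tuple[float, float]
    suicides: float
    ed_presentations: float
    disengagements: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.suicides, self.ed_presentations, self.disengagements)


# --------------------------------------------------------------------------
# Elementary operations
# --------------------------------------------------------------------------


def wait_time(queue: float, throughput_per_week: float, cap: float = 52.0) -> float:
    """Expected wait (weeks) for a queue served at a weekly throughput.

    Little's-law estimate queue/throughput, zero for an empty queue and
    capped at ``cap`` weeks; a saturated service (zero throughput with a
    non-empty queue) returns the cap.
    """
    if queue <= 0.0:
        return 0.0
    if throughput_per_week <= 0.0:
        return cap
    w = queue / throughput_per_week
    return w if w < cap else cap


def shock_multiplier(t: float, shock: ShockParams) -> float:
    """Distress-onset multiplier at time ``t`` (rectangular pulse)."""
    if shock.start <= t < shock.start + shock.duration:
        return shock.onset_multiplier
    return 1.0


def capacity_at(
    service_id: str,
    t: float,
    config: RegionConfig,
    modifiers: CapacityModifiers | None = None,
) -> float:
    """Service capacity (events/week) at time ``t``.

    Baseline capacity compounds at the region's annual growth rate; a
    capacity lever multiplies that growth rate from the lever's start time.
    The CMHC lever instead adds a constant annual increment in contacts per
    10,000 population per week.
    """
    if service_id not in config.service_capacities:
        raise KeyError(f"unknown service {service_id!r}")
    base = config.service_capacities[service_id]
    g = config.capacity_growth.get(service_id, 0.0)
    if modifiers is None:
        return base * (1.0 + g) ** t
    ts = modifiers.start_t
    m = modifiers.growth_multiplier.get(service_id, 1.0)
    pre = min(t, ts)
    post = max(0.0, t - ts)
    cap = base * (1.0 + g) ** max(pre, 0.0) * (1.0 + m * g) ** post
    if service_id == "cmhc" and modifiers.cmhc_increment_per_10k:
        cap += (
            modifiers.cmhc_increment_per_10k
            * (config.initial_population / 1e4)
            * post
        )
    return cap


# --------------------------------------------------------------------------
# Initial state
# --------------------------------------------------------------------------


def init_state(config: RegionConfig, params: ModelParams) -> RegionState:
    """Initial state with the population split by the initial prevalence.

    The distressed total ``P*prev`` is allocated across the pathway stocks
    with an approximate flow-balance closed form: the untreated/engaged split
    follows help-seeking vs untreated-recovery propensities, engaged persons
    are spread over the service stocks in proportion to (referral share x
    mean episode duration), and queues are seeded at a two-week wait.
    Cumulative counters start at zero.  The allocation is heuristic — the
    simulator relaxes to its own quasi-steady state within a year or two —
    but keeps early-history transients small.
    """
    p = params
    pop = config.initial_population
    prev = config.initial_distress_prevalence
    distressed_total = pop * prev

    y = [0.0] * N_STATE
    y[_IDX["well"]] = pop - distressed_total
    if distressed_total <= 0:
        return RegionState.from_vector(0.0, y)

    # untreated vs on-pathway split
    hs = p.help_seeking_rate * p.help_seeking_multiplier
    exit_unt = p.recovery_untreated + hs + p.attempt_hazard_untreated
    frac_engaged = hs / exit_unt if exit_unt > 0 else 0.0

    # mean residence times (yr) in each care state
    bd = p.base_disengagement_rate
    out_gp = (
        p.treatment_success["gp"]
        + p.refer_specialist
        + p.refer_cmhc
        + p.refer_online
        + p.refer_inpatient
        + bd
        + p.attempt_hazard_in_care
    )
    tau_gp = 1.0 / max(out_gp, 1e-9)
    tau_sp = 1.0 / max(
        p.treatment_success["specialist"] + bd + p.attempt_hazard_in_care, 1e-9
    )
    tau_cm = 1.0 / max(
        p.treatment_success["cmhc"] + bd + p.attempt_hazard_in_care, 1e-9
    )
    tau_on = 1.0 / max(
        p.treatment_success["online"] + bd + p.attempt_hazard_in_care, 1e-9
    )
    tau_in = 1.0 / max(p.inpatient_discharge_rate, 1e-9)

    # steady-state occupancy weights: every engaged person passes through GP
    # care; downstream weights are branch probability x duration.
    w_gp = tau_gp
    w_sp = p.refer_specialist * tau_gp * tau_sp
    w_on = p.refer_online * tau_gp * tau_on
    w_in = p.refer_inpatient * tau_gp * tau_in
    w_cm = (p.refer_cmhc + p.refer_inpatient) * tau_gp * tau_cm  # inpatients step down
    # disengaged pool fed by all care states
    w_dis = bd * (w_gp + w_sp + w_cm + w_on) / max(
        p.re_engagement_rate + p.recovery_untreated, 1e-9
    )
    w_q = 2.0 / WEEKS_PER_YEAR  # two-week GP queue

    weights = {
        "in_gp_care": w_gp,
        "in_specialist_care": w_sp,
        "in_cmhc_care": w_cm,
        "inpatient": w_in,
        "online_services": w_on,
        "disengaged": w_dis,
        "awaiting_gp": w_q,
    }
    total_w = sum(weights.values())
    engaged = distressed_total * frac_engaged
    for name, w in weights.items():
        y[_IDX[name]] = engaged * w / total_w

    # cap seeded care stocks at the caseload the week-0 capacity supports;
    # overflow returns to the untreated pool
    overflow = 0.0
    for name, sid in (
        ("in_gp_care", "gp"),
        ("in_specialist_care", "specialist"),
        ("in_cmhc_care", "cmhc"),
    ):
        nmax = (
            config.service_capacities[sid]
            * WEEKS_PER_YEAR
            / p.contacts_per_year[sid]
        )
        if y[_IDX[name]] > 0.95 * nmax:
            overflow += y[_IDX[name]] - 0.95 * nmax
            y[_IDX[name]] = 0.95 * nmax
    y[_IDX["distressed_not_in_care"]] = (
        distressed_total * (1.0 - frac_engaged) + overflow
    )
    return RegionState.from_vector(0.0, y)


# --------------------------------------------------------------------------
# The Euler step
# --------------------------------------------------------------------------

# indices hoisted to module level for the inner loop
(
    I_WELL,
    I_DIST,
    I_AWGP,
    I_GP,
    I_AWSP,
    I_SP,
    I_CMHC,
    I_INP,
    I_ONL,
    I_DIS,
    I_POST,
    I_CSUI,
    I_CSH,
    I_CED,
    I_CDIS,
    I_CBGD,
) = range(N_STATE)

#: names of the derived per-step diagnostics, in order
DERIVED_NAMES = (
    "suicides_per_yr",
    "self_harm_hospitalisations_per_yr",
    "ed_presentations_per_yr",
    "disengagements_per_yr",
    "attempts_per_yr",
    "distress_prevalence",
    "wait_gp_weeks",
    "wait_specialist_weeks",
    "wait_cmhc_weeks",
    "util_gp",
    "util_specialist",
    "util_cmhc",
    "gp_consultations_per_yr",
    "allied_services_per_yr",
    "psych_bed_occupancy",
)


def make_stepper(
    config: RegionConfig,
    params: ModelParams,
    modifiers: CapacityModifiers | None = None,
) -> Callable[[list[float], float, float], tuple[list[float], tuple]]:
    """Compile a fast single-step closure for fixed config/params/modifiers.

    The returned function maps ``(y, t, dt) -> (y_next, derived)`` where
    ``y`` is the flat state vector and ``derived`` the diagnostics tuple in
    :data:`DERIVED_NAMES` order.  All parameters are captured as locals so
    the inner loop does no attribute lookups.
    """
    p = params
    mods = modifiers if modifiers is not None else CapacityModifiers()

    demo_in = config.births_rate + config.net_migration
    mu = config.background_mortality
    pop0 = config.initial_population

    onset = p.distress_onset_rate
    rec_u = p.recovery_untreated
    seek = p.help_seeking_rate * p.help_seeking_multiplier
    ir = p.intake_rate
    ref_sp = p.refer_specialist
    ref_cm = p.refer_cmhc
    ref_on = p.refer_online
    ref_in = p.refer_inpatient
    s_gp = p.treatment_success["gp"]
    s_sp = p.treatment_success["specialist"]
    s_cm = p.treatment_success["cmhc"]
    s_on = p.treatment_success["online"]
    disch = p.inpatient_discharge_rate
    bd = p.base_disengagement_rate
    dws = p.disengagement_wait_sensitivity
    re_eng = p.re_engagement_rate
    post_eng = p.post_attempt_engage_rate
    post_ret = p.post_attempt_return_rate
    h_u = p.attempt_hazard_untreated
    h_c = p.attempt_hazard_in_care
    h_p = p.attempt_hazard_post_attempt
    cf = p.attempt_case_fatality
    hf = p.hospitalised_fraction
    ed_u = p.ed_rate_untreated
    ed_p = p.ed_rate_post_attempt
    cpy_gp = p.contacts_per_year["gp"]
    cpy_sp = p.contacts_per_year["specialist"]
    cpy_cm = p.contacts_per_year["cmhc"]
    safe_frac = p.safe_space_diversion
    acute_frac = p.acute_care_diversion
    aftercare_cost = p.aftercare_cmhc_cost
    wcap = p.max_wait_weeks
    sh_start = p.shock.start
    sh_end = p.shock.start + p.shock.duration
    sh_mult = p.shock.onset_multiplier

    cap_gp0 = config.service_capacities["gp"]
    cap_sp0 = config.service_capacities["specialist"]
    cap_in0 = config.service_capacities["inpatient"]
    cap_cm0 = config.service_capacities["cmhc"]
    g_gp = config.capacity_growth.get("gp", 0.0)
    g_sp = config.capacity_growth.get("specialist", 0.0)
    g_in = config.capacity_growth.get("inpatient", 0.0)
    g_cm = config.capacity_growth.get("cmhc", 0.0)
    m_gp = mods.growth_multiplier.get("gp", 1.0)
    m_sp = mods.growth_multiplier.get("specialist", 1.0)
    m_in = mods.growth_multiplier.get("inpatient", 1.0)
    m_cm = mods.growth_multiplier.get("cmhc", 1.0)
    cm_inc = mods.cmhc_increment_per_10k * (pop0 / 1e4)
    ts = mods.start_t
    W = WEEKS_PER_YEAR

    def _step(y: list[float], t: float, dt: float) -> tuple[list[float], tuple]:
        (
            well, dist, awgp, gp, awsp, sp, cmhc, inp, onl, dis, post,
            c_sui, c_sh, c_ed, c_dis, c_bgd,
        ) = y

        msh = sh_mult if sh_start <= t < sh_end else 1.0

        pre = t if t < ts else ts
        pst = t - ts if t > ts else 0.0
        capw_gp = cap_gp0 * (1.0 + g_gp) ** pre * (1.0 + m_gp * g_gp) ** pst
        capw_sp = cap_sp0 * (1.0 + g_sp) ** pre * (1.0 + m_sp * g_sp) ** pst
        capw_in = cap_in0 * (1.0 + g_in) ** pre * (1.0 + m_in * g_in) ** pst
        capw_cm = cap_cm0 * (1.0 + g_cm) ** pre * (1.0 + m_cm * g_cm) ** pst
        if cm_inc and pst > 0.0:
            capw_cm += cm_inc * pst
        # aftercare consumes CMHC contacts for everyone in the post-attempt state
        capw_cm_free = capw_cm - aftercare_cost * post
        if capw_cm_free < 0.0:
            capw_cm_free = 0.0

        # maximum caseloads implied by weekly capacity & per-person intensity
        nmax_gp = capw_gp * W / cpy_gp
        nmax_sp = capw_sp * W / cpy_sp
        nmax_cm = capw_cm_free * W / cpy_cm

        # ---- intake flows (capacity-limited), /yr
        room = nmax_gp - gp
        f_intake_gp = awgp * ir
        lim = room * ir if room > 0.0 else 0.0
        if f_intake_gp > lim:
            f_intake_gp = lim
        room = nmax_sp - sp
        f_intake_sp = awsp * ir
        lim = room * ir if room > 0.0 else 0.0
        if f_intake_sp > lim:
            f_intake_sp = lim
        # CMHC admissions share remaining room among its feeders
        room_cm = nmax_cm - cmhc
        lim_cm = room_cm * ir if room_cm > 0.0 else 0.0

        # waits (weeks): queue / realised weekly intake
        thr = f_intake_gp / W
        w_gp = 0.0 if awgp <= 0.0 else (awgp / thr if thr > 0.0 else wcap)
        if w_gp > wcap:
            w_gp = wcap
        thr = f_intake_sp / W
        w_sp = 0.0 if awsp <= 0.0 else (awsp / thr if thr > 0.0 else wcap)
        if w_sp > wcap:
            w_sp = wcap
        # CMHC congestion signal: fractional caseload overload mapped onto a
        # weeks-of-backlog scale (10% overload ~ 5.2 weeks of extra wait)
        w_cm = 0.0
        if nmax_cm > 0.0:
            excess = cmhc / nmax_cm - 1.0
            if excess > 0.0:
                w_cm = excess * 52.0
        elif cmhc > 0.0:
            w_cm = wcap
        if w_cm > wcap:
            w_cm = wcap

        # ---- per-stock outflow rates (/yr)
        # well
        f_onset = well * onset * msh
        # distressed, not in care
        f_rec_u = dist * rec_u
        f_seek = dist * seek
        f_att_dist = dist * h_u
        f_acute = dist * ed_u * acute_frac  # crisis contacts diverted into CMHC care
        # GP queue
        f_dis_awgp = awgp * (bd + dws * w_gp)
        f_att_awgp = awgp * h_u
        # GP care
        f_succ_gp = gp * s_gp
        f_ref_sp = gp * ref_sp
        f_ref_cm = gp * ref_cm
        f_ref_on = gp * ref_on
        f_ref_in = gp * ref_in
        inp_adm_cap = capw_in * W
        if f_ref_in > inp_adm_cap:
            f_ref_in = inp_adm_cap
        f_dis_gp = gp * bd
        f_att_gp = gp * h_c
        # specialist queue
        f_dis_awsp = awsp * (bd + dws * w_sp)
        f_att_awsp = awsp * h_u
        # specialist care
        f_succ_sp = sp * s_sp
        f_dis_sp = sp * bd
        f_att_sp = sp * h_c
        # CMHC care
        f_succ_cm = cmhc * s_cm
        f_dis_cm = cmhc * (bd + dws * w_cm)
        f_att_cm = cmhc * h_c
        # inpatient
        f_disch = inp * disch
        f_att_inp = inp * h_c
        # online
        f_succ_on = onl * s_on
        f_dis_on = onl * bd
        f_att_on = onl * h_c
        # disengaged
        f_re = dis * re_eng
        f_rec_dis = dis * rec_u
        f_att_dis2 = dis * h_u
        # post-attempt
        f_post_eng = post * post_eng
        f_post_ret = post * post_ret
        f_att_post = post * h_p

        # CMHC inflow rationing against free capacity
        cm_in = f_ref_cm + f_disch + f_post_eng + f_acute
        if cm_in > lim_cm:
            scale_cm = lim_cm / cm_in if cm_in > 0.0 else 0.0
            f_ref_cm *= scale_cm
            f_post_eng *= scale_cm
            f_acute *= scale_cm
            f_disch_cm = f_disch * scale_cm
        else:
            f_disch_cm = f_disch
        f_disch_dist = f_disch - f_disch_cm  # no CMHC room: step down to community

        # ---- joint non-negativity rationing per source stock
        def _scale(stock: float, out: float) -> float:
            lim = out * dt
            if lim <= stock or lim <= 0.0:
                return 1.0
            return stock / lim

        sc_well = _scale(well, f_onset + well * mu)
        sc_dist = _scale(
            dist, f_rec_u + f_seek + f_att_dist + f_acute + dist * mu
        )
        sc_awgp = _scale(awgp, f_intake_gp + f_dis_awgp + f_att_awgp + awgp * mu)
        sc_gp = _scale(
            gp,
            f_succ_gp + f_ref_sp + f_ref_cm + f_ref_on + f_ref_in + f_dis_gp
            + f_att_gp + gp * mu,
        )
        sc_awsp = _scale(awsp, f_intake_sp + f_dis_awsp + f_att_awsp + awsp * mu)
        sc_sp = _scale(sp, f_succ_sp + f_dis_sp + f_att_sp + sp * mu)
        sc_cm = _scale(cmhc, f_succ_cm + f_dis_cm + f_att_cm + cmhc * mu)
        sc_inp = _scale(inp, f_disch + f_att_inp + inp * mu)
        sc_onl = _scale(onl, f_succ_on + f_dis_on + f_att_on + onl * mu)
        sc_dis = _scale(dis, f_re + f_rec_dis + f_att_dis2 + dis * mu)
        # post-attempt: attempt survivors stay, only fatalities leave
        sc_post = _scale(
            post, f_post_eng + f_post_ret + f_att_post * cf + post * mu
        )

        f_onset *= sc_well
        f_rec_u *= sc_dist
        f_seek *= sc_dist
        f_att_dist *= sc_dist
        f_acute *= sc_dist
        f_intake_gp *= sc_awgp
        f_dis_awgp *= sc_awgp
        f_att_awgp *= sc_awgp
        f_succ_gp *= sc_gp
        f_ref_sp *= sc_gp
        f_ref_cm *= sc_gp
        f_ref_on *= sc_gp
        f_ref_in *= sc_gp
        f_dis_gp *= sc_gp
        f_att_gp *= sc_gp
        f_intake_sp *= sc_awsp
        f_dis_awsp *= sc_awsp
        f_att_awsp *= sc_awsp
        f_succ_sp *= sc_sp
        f_dis_sp *= sc_sp
        f_att_sp *= sc_sp
        f_succ_cm *= sc_cm
        f_dis_cm *= sc_cm
        f_att_cm *= sc_cm
        f_disch_cm *= sc_inp
        f_disch_dist *= sc_inp
        f_att_inp *= sc_inp
        f_succ_on *= sc_onl
        f_dis_on *= sc_onl
        f_att_on *= sc_onl
        f_re *= sc_dis
        f_rec_dis *= sc_dis
        f_att_dis2 *= sc_dis
        f_post_eng *= sc_post
        f_post_ret *= sc_post
        f_att_post *= sc_post

        # attempts & their consequences
        att_move = (
            f_att_dist + f_att_awgp + f_att_gp + f_att_awsp + f_att_sp
            + f_att_cm + f_att_inp + f_att_on + f_att_dis2
        )
        attempts = att_move + f_att_post
        f_suicide = attempts * cf
        f_to_post = att_move * (1.0 - cf)

        # background deaths (scaled where a stock was rationed)
        bgd = mu * (
            well * sc_well + dist * sc_dist + awgp * sc_awgp + gp * sc_gp
            + awsp * sc_awsp + sp * sc_sp + cmhc * sc_cm + inp * sc_inp
            + onl * sc_onl + dis * sc_dis + post * sc_post
        )

        # event flows
        f_diseng = (
            f_dis_awgp + f_dis_gp + f_dis_awsp + f_dis_sp + f_dis_cm + f_dis_on
        )
        ed_raw = (dist + dis + awgp + awsp) * ed_u + post * ed_p + attempts
        divert = safe_frac + acute_frac
        if divert > 1.0:
            divert = 1.0
        f_ed = ed_raw * (1.0 - divert)

        # ---- Euler update
        y2 = [
            well + dt * (demo_in + f_rec_u + f_rec_dis + f_succ_gp + f_succ_sp
                         + f_succ_cm + f_succ_on - f_onset - well * mu * sc_well),
            dist + dt * (f_onset + f_post_ret + f_disch_dist
                         - f_rec_u - f_seek - f_att_dist - f_acute
                         - dist * mu * sc_dist),
            awgp + dt * (f_seek + f_re - f_intake_gp - f_dis_awgp - f_att_awgp
                         - awgp * mu * sc_awgp),
            gp + dt * (f_intake_gp - f_succ_gp - f_ref_sp - f_ref_cm - f_ref_on
                       - f_ref_in - f_dis_gp - f_att_gp - gp * mu * sc_gp),
            awsp + dt * (f_ref_sp - f_intake_sp - f_dis_awsp - f_att_awsp
                         - awsp * mu * sc_awsp),
            sp + dt * (f_intake_sp - f_succ_sp - f_dis_sp - f_att_sp
                       - sp * mu * sc_sp),
            cmhc + dt * (f_ref_cm + f_disch_cm + f_post_eng + f_acute
                         - f_succ_cm - f_dis_cm - f_att_cm - cmhc * mu * sc_cm),
            inp + dt * (f_ref_in - f_disch_cm - f_disch_dist - f_att_inp
                        - inp * mu * sc_inp),
            onl + dt * (f_ref_on - f_succ_on - f_dis_on - f_att_on
                        - onl * mu * sc_onl),
            dis + dt * (f_diseng - f_re - f_rec_dis - f_att_dis2
                        - dis * mu * sc_dis),
            post + dt * (f_to_post - f_post_eng - f_post_ret - f_att_post * cf
                         - post * mu * sc_post),
            c_sui + dt * f_suicide,
            c_sh + dt * attempts * hf,
            c_ed + dt * f_ed,
            c_dis + dt * f_diseng,
            c_bgd + dt * bgd,
        ]

        pop_now = (well + dist + awgp + gp + awsp + sp + cmhc + inp + onl
                   + dis + post)
        prevalence = 1.0 - well / pop_now if pop_now > 0.0 else 0.0
        derived = (
            f_suicide,
            attempts * hf,
            f_ed,
            f_diseng,
            attempts,
            prevalence,
            w_gp,
            w_sp,
            w_cm,
            gp / nmax_gp if nmax_gp > 0.0 else 0.0,
            sp / nmax_sp if nmax_sp > 0.0 else 0.0,
            cmhc / nmax_cm if nmax_cm > 0.0 else 0.0,
            gp * cpy_gp,
            sp * cpy_sp,
            inp,
        )
        return y2, derived

    return _step


def step(
    state: RegionState,
    params: ModelParams,
    config: RegionConfig,
    modifiers: CapacityModifiers | None = None,
    dt: float = DEFAULT_DT_DAYS / DAYS_PER_YEAR,
) -> RegionState:
    """Advance one Euler step of length ``dt`` (years)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    stepper = make_stepper(config, params, modifiers)
    y2, _ = stepper(list(state.to_vector()), state.t, dt)
    _check_state(y2, state.t + dt)
    return RegionState.from_vector(state.t + dt, y2)


def _check_state(y: list[float], t: float) -> None:
    for i, v in enumerate(y):
        if not np.isfinite(v) or (i < N_PERSON and v < -1e-9):
            name = (STOCKS + CUMULATIVES)[i]
            raise IntegrationError(
                f"invalid value {v!r} in {name!r} at t={t:.4f}"
            )


def simulate(
    config: RegionConfig,
    params: ModelParams,
    modifiers: CapacityModifiers | None = None,
    t_end: float = 28.0,
    dt_days: float = DEFAULT_DT_DAYS,
    t0: float = 0.0,
    init: RegionState | None = None,
    switch: tuple[float, ModelParams, CapacityModifiers] | None = None,
    record: bool = True,
) -> Trajectory:
    """Integrate the model from ``t0`` to ``t_end`` on a fixed grid.

    ``switch=(t_s, params2, modifiers2)`` swaps in a second parameter set at
    the first grid point >= ``t_s`` (used to activate intervention scenarios
    mid-run).  The run is fully deterministic.  With ``record=False`` only
    the first and last grid states are kept (derived series empty), which is
    the fast path for scenario sweeps.
    """
    if t_end <= t0:
        raise ValueError("t_end must exceed t0")
    dt = dt_days / DAYS_PER_YEAR
    n_steps = int(round((t_end - t0) / dt))
    state0 = init if init is not None else init_state(config, params)
    y = list(state0.to_vector())

    stepper = make_stepper(config, params, modifiers)
    switched = switch is None
    t_switch = switch[0] if switch is not None else np.inf

    times = np.empty(n_steps + 1)
    if record:
        states = np.empty((n_steps + 1, N_STATE))
        deriv = np.empty((n_steps + 1, len(DERIVED_NAMES)))
        states[0] = y
    else:
        states = np.empty((2, N_STATE))
        deriv = np.zeros((2, len(DERIVED_NAMES)))
        states[0] = y
    times[0] = t0

    t = t0
    last_d: tuple = ()
    check_every = max(1, n_steps // 64)
    for k in range(1, n_steps + 1):
        if not switched and t >= t_switch - 1e-12:
            stepper = make_stepper(config, switch[1], switch[2])
            switched = True
        y, d = stepper(y, t, dt)
        t = t0 + k * dt
        times[k] = t
        if record:
            states[k] = y
            deriv[k] = d
        if k % check_every == 0 or k == n_steps:
            _check_state(y, t)
        last_d = d

    if record:
        deriv[0] = deriv[1]  # derived series undefined at t0; repeat first step
        derived = {
            name: deriv[:, j] for j, name in enumerate(DERIVED_NAMES)
        }
        return Trajectory(config.region_id, times, states, derived, dt)

    states[1] = y
    times_min = np.array([t0, t])
    derived = {name: deriv[:, j] for j, name in enumerate(DERIVED_NAMES)}
    return Trajectory(config.region_id, times_min, states[:2], derived, t - t0)


# --------------------------------------------------------------------------
# Outcome extraction
# --------------------------------------------------------------------------


def cumulative_outcomes(
    traj: Trajectory,
    window: tuple[float, float],
    scenario_id: str = "baseline",
) -> ScenarioOutcome:
    """Outcome triplet over ``window``: counter at end minus counter at start."""
    t_lo, t_hi = window
    if t_lo > t_hi:
        raise ValueError("window start must not exceed its end")
    eps = traj.dt / 2
    if t_lo < traj.times[0] - eps or t_hi > traj.times[-1] + eps:
        raise ValueError(
            f"window {window} outside trajectory span "
            f"[{traj.times[0]}, {traj.times[-1]}]"
        )
    a = traj.state_at(t_lo).cumulatives
    b = traj.state_at(t_hi).cumulatives
    return ScenarioOutcome(
        scenario_id=scenario_id,
        region_id=traj.region_id,
        window=(t_lo, t_hi),
        suicides=b["suicide_deaths"] - a["suicide_deaths"],
        ed_presentations=b["ed_presentations"] - a["ed_presentations"],
        disengagements=b["disengagement_events"] - a["disengagement_events"],
    )


def aggregate_regions(outcomes: list[ScenarioOutcome]) -> ScenarioOutcome:
    """Component-wise sum over regions (PHN-level outcome)."""
    if not outcomes:
        raise ValueError("no outcomes to aggregate")
    first = outcomes[0]
    for o in outcomes[1:]:
        if o.scenario_id != first.scenario_id or o.window != first.window:
            raise ValueError("mismatched scenario_id or window in aggregation")
    return ScenarioOutcome(
        scenario_id=first.scenario_id,
        region_id="PHN",
        window=first.window,
        suicides=sum(o.suicides for o in outcomes),
        ed_presentations=sum(o.ed_presentations for o in outcomes),
        disengagements=sum(o.disengagements for o in outcomes),
    )
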