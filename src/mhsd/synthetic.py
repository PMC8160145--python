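"""Synthetic region profiles and generated "historical" calibration series.

The study region — a coastal/rural Australian Primary Health Network (PHN)
of ~1.27 million people served by two Local Health Districts (LHDs) — has no
public microdata, so this module generates region configurations and noisy
annual 2011–2017 observation series with the same statistical structure:
a large LHD carrying roughly 74% of the burden and a smaller one carrying
26%, adult high/very-high psychological distress around 13.5 per 100, and a
suicide rate near 13.7 per 100,000 per year.  The generated series drive the
calibration, scenario-search and sensitivity machinery end to end and
support generate-and-refit parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationTargets, TARGET_SERIES
from .engine import (
    ModelParams,
    RegionConfig,
    Trajectory,
    simulate,
)

__all__ = [
    "TOTAL_POPULATION",
    "SyntheticRegionProfile",
    "SyntheticTruth",
    "default_profiles",
    "profile_to_config",
    "default_configs",
    "default_params",
    "generate_history",
    "recovery_fixture",
]

#: 2018 estimated resident population of the modelled PHN catchment.
TOTAL_POPULATION = 1_269_782

#: Share of the regional burden carried by the larger (Hunter New England
#: -like) district, from the 1307 : 471 split of baseline suicides.
_HNE_SHARE = 1307.0 / 1778.0

# Reference demography and service supply per 1,000,000 population; regional
# configs scale these by population.  Capacities are service events/week.
_PER_1M = {
    "births_rate": 12_000.0,
    "net_migration": 1_500.0,
    "service_capacities": {
        "gp": 3_300.0,  # GP mental-health consultations/week
        "specialist": 1_700.0,  # psychiatrist + allied sessions/week
        "inpatient": 50.0,  # admissions/week
        "cmhc": 2_000.0,  # community mental-health contacts/week
    },
}
_BACKGROUND_MORTALITY = 0.0065  # fraction/yr
_CAPACITY_GROWTH = {"gp": 0.022, "specialist": 0.018, "inpatient": 0.010, "cmhc": 0.0}


@dataclass
class SyntheticRegionProfile:
    """Summary statistics a synthetic region is built to match."""

    name: str
    population: float
    distress_rate_per_100: float = 13.5
    suicide_rate_per_100k: float = 13.7
    burden_share: float = 1.0
    noise_cv: float = 0.03


def default_profiles() -> list[SyntheticRegionProfile]:
    """Two district profiles splitting the PHN by burden share (~74%/26%)."""
    pop_hne = round(TOTAL_POPULATION * _HNE_SHARE)
    return [
        SyntheticRegionProfile(
            name="HNE", population=pop_hne, burden_share=_HNE_SHARE
        ),
        SyntheticRegionProfile(
            name="CC",
            population=TOTAL_POPULATION - pop_hne,
            burden_share=1.0 - _HNE_SHARE,
        ),
    ]


def profile_to_config(profile: SyntheticRegionProfile) -> RegionConfig:
    """Region configuration scaled from the per-million reference supply."""
    scale = profile.population / 1e6
    return RegionConfig(
        region_id=profile.name,
        initial_population=float(profile.population),
        births_rate=_PER_1M["births_rate"] * scale,
        net_migration=_PER_1M["net_migration"] * scale,
        background_mortality=_BACKGROUND_MORTALITY,
        initial_distress_prevalence=profile.distress_rate_per_100 / 100.0,
        service_capacities={
            sid: cap * scale for sid, cap in _PER_1M["service_capacities"].items()
        },
        capacity_growth=dict(_CAPACITY_GROWTH),
        burden_share=profile.burden_share,
    )


def default_configs() -> list[RegionConfig]:
    return [profile_to_config(p) for p in default_profiles()]


def default_params() -> ModelParams:
    """The documented default parameterisation (see ModelParams docstring)."""
    return ModelParams()


# --------------------------------------------------------------------------
# History generation
# --------------------------------------------------------------------------


def _sample_series(traj: Trajectory, times: np.ndarray) -> dict[str, np.ndarray]:
    """Model counterparts of the six observed series, at given times."""
    pop = traj.states[:, : len(traj.states[0]) - 5].sum(axis=1)  # person stocks
    per100k = 1e5 / pop
    model = {
        "distress_prevalence": traj.derived["distress_prevalence"],
        "self_harm_hospitalisation_rate": (
            traj.derived["self_harm_hospitalisations_per_yr"] * per100k
        ),
        "suicide_rate": traj.derived["suicides_per_yr"] * per100k,
        "gp_mh_consultations_per_yr": traj.derived["gp_consultations_per_yr"],
        "allied_services_per_yr": traj.derived["allied_services_per_yr"],
        "psych_bed_occupancy": traj.derived["psych_bed_occupancy"],
    }
    return {
        name: np.interp(times, traj.times, series) for name, series in model.items()
    }


def generate_history(
    params: ModelParams,
    config: RegionConfig,
    noise_cv: float = 0.03,
    seed: int = 0,
    t_end: float = 7.0,
    dt_days: float | None = None,
) -> CalibrationTargets:
    """Simulate 2011–2018 and sample noisy annual observation series.

    Observations are taken at the end of each simulated year and multiplied
    by mean-one lognormal noise with coefficient of variation ``noise_cv``
    (multiplicative noise keeps every series strictly positive, as the MAPE
    objective requires).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    kwargs = {} if dt_days is None else {"dt_days": dt_days}
    traj = simulate(config, params, t_end=t_end, **kwargs)
    times = np.arange(1.0, t_end + 1e-9)
    clean = _sample_series(traj, times)

    rng = np.random.default_rng(seed)
    series = {}
    for name in TARGET_SERIES:
        vals = clean[name]
        if noise_cv > 0:
            sigma = float(np.sqrt(np.log1p(noise_cv**2)))
            noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(vals))
            vals = vals * noise
        series[name] = (times.copy(), np.asarray(vals, dtype=float))
    return CalibrationTargets(series=series)


# --------------------------------------------------------------------------
# Parameter-recovery fixture
# --------------------------------------------------------------------------

#: Default free-parameter list for calibration (the least-evidenced rates).
FREE_PARAMS = (
    "distress_onset_rate",
    "recovery_untreated",
    "attempt_hazard_untreated",
    "refer_specialist",
    "attempt_case_fatality",
    "base_disengagement_rate",
)


@dataclass
class SyntheticTruth:
    """A packaged generate-and-refit bundle with known ground truth."""

    params: ModelParams
    configs: list[RegionConfig]
    targets_noiseless: CalibrationTargets
    targets_noisy: CalibrationTargets
    free: tuple[str, ...]
    bounds: list[tuple[float, float]]
    seed: int
    noise_cv: float = 0.05
    #: free parameters that the six observed series pin down individually;
    #: distress onset and untreated recovery form a sloppy pair (the data
    #: constrain their ratio via the prevalence level, not their scale)
    identifiable: tuple[str, ...] = (
        "attempt_hazard_untreated",
        "refer_specialist",
        "attempt_case_fatality",
        "base_disengagement_rate",
    )


def recovery_fixture(seed: int = 0, noise_cv: float = 0.05) -> SyntheticTruth:
    """Truth params + noiseless and noisy targets for the larger region.

    Bounds are deliberately asymmetric around the truth ([0.7x, 1.5x]) so a
    midpoint start does not coincide with the true values.  Targets are
    generated on the same coarsened grid the calibration objective uses
    (annual samples are insensitive to the sub-weekly step), so the
    noiseless objective has an exact zero at the truth.
    """
    params = default_params()
    configs = default_configs()
    cfg = configs[0]
    bounds = [
        (0.7 * params.get_path(p), 1.5 * params.get_path(p)) for p in FREE_PARAMS
    ]
    return SyntheticTruth(
        params=params,
        configs=configs,
        targets_noiseless=generate_history(
            params, cfg, noise_cv=0.0, seed=seed, dt_days=1.75
        ),
        targets_noisy=generate_history(
            params, cfg, noise_cv=noise_cv, seed=seed, dt_days=1.75
        ),
        free=FREE_PARAMS,
        bounds=bounds,
        seed=seed,
        noise_cv=noise_cv,
    )
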