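"""Latin-hypercube propagation of intervention-effect uncertainty.

Draws stratified samples of the direct effect of each of the eight
prevention programs (±20% of its default magnitude) and the duration of the
pandemic distress-onset pulse (±50% of its default), pushes each draw
through the scenario pipeline, and summarises the resulting percent
reductions with means and 50%/95% empirical intervals.  The intervals
measure the impact of parameter uncertainty on the projections; they are
not confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .engine import CapacityModifiers, ModelParams, RegionConfig
from .interventions import InterventionSet, InterventionSpec, catalogue
from .scenarios import DEFAULT_WINDOW, OUTCOMES, evaluate_scenarios
from .interventions import DEFAULT_START

__all__ = [
    "LHSDesign",
    "SummaryInterval",
    "default_dims",
    "lhs_sample",
    "run_sensitivity",
    "summarise",
]


@dataclass
class LHSDesign:
    """A Latin hypercube design in parameter units.

    ``dims`` lists ``(parameter_path, low, high)``; ``samples`` is an
    ``n x d`` array with exactly one sample per equal-probability stratum in
    every one-dimensional margin.  Effect dimensions use the path form
    ``effect:<intervention_id>`` (a scale factor on that intervention's
    direct effect); other paths address :class:`ModelParams` directly.
    """

    n_samples: int
    dims: list[tuple[str, float, float]]
    seed: int
    samples: np.ndarray


@dataclass
class SummaryInterval:
    scenario_id: str
    region_id: str
    outcome: str
    mean: float
    interval_50: tuple[float, float]
    interval_95: tuple[float, float]
    n_draws: int


def default_dims(
    specs: list[InterventionSpec] | None = None,
    params: ModelParams | None = None,
) -> list[tuple[str, float, float]]:
    """One dimension per program's direct effect (scale factor in
    [0.8, 1.2]) plus the pandemic-pulse duration (±50% of default).
    Capacity levers are policy settings, not uncertain effects, and carry
    no dimension."""
    if specs is None:
        specs = catalogue()
    if params is None:
        params = ModelParams()
    dims: list[tuple[str, float, float]] = [
        (f"effect:{s.id}", 0.8, 1.2) for s in specs if s.kind == "program"
    ]
    d = params.shock.duration
    dims.append(("shock.duration", 0.5 * d, 1.5 * d))
    return dims


def lhs_sample(
    dims: list[tuple[str, float, float]], n: int = 100, seed: int = 0
) -> LHSDesign:
    """Stratified uniform Latin hypercube sample, reproducible under seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    for path, lo, hi in dims:
        if not lo < hi:
            raise ValueError(f"degenerate range for {path!r}: [{lo}, {hi}]")
    sampler = qmc.LatinHypercube(d=len(dims), seed=seed)
    unit = sampler.random(n=n)
    lo = np.array([d[1] for d in dims])
    hi = np.array([d[2] for d in dims])
    return LHSDesign(
        n_samples=n, dims=list(dims), seed=seed, samples=qmc.scale(unit, lo, hi)
    )


def _apply_draw(
    specs: list[InterventionSpec],
    params: ModelParams,
    dims: list[tuple[str, float, float]],
    x: np.ndarray,
) -> tuple[list[InterventionSpec], ModelParams]:
    """Rebuild the catalogue and params for one sample row."""
    scale = {
        path.split(":", 1)[1]: float(v)
        for (path, _, _), v in zip(dims, x)
        if path.startswith("effect:")
    }
    new_specs = [s.scaled(scale[s.id]) if s.id in scale else s for s in specs]
    p = params.copy()
    for (path, _, _), v in zip(dims, x):
        if not path.startswith("effect:"):
            p.set_path(path, float(v))
    return new_specs, p


def run_sensitivity(
    design: LHSDesign,
    scenarios: list[InterventionSet],
    configs: list[RegionConfig],
    params: ModelParams | None = None,
    modifiers: CapacityModifiers | None = None,
    window: tuple[float, float] = DEFAULT_WINDOW,
    start_t: float = DEFAULT_START,
    dt_days: float | None = None,
    specs: list[InterventionSpec] | None = None,
) -> pd.DataFrame:
    """Percent reductions for every draw x scenario x region x outcome.

    Returns a tidy DataFrame (draw, scenario_id, region_id, outcome, value);
    a failed draw is recorded with NaN values rather than aborting the
    sweep.  Deterministic given the design (which is seeded).
    """
    if params is None:
        params = ModelParams()
    if specs is None:
        specs = catalogue()
    records = []
    for i, x in enumerate(design.samples):
        try:
            draw_specs, draw_params = _apply_draw(specs, params, design.dims, x)
            table = evaluate_scenarios(
                configs, draw_params, modifiers, sets=scenarios,
                specs=draw_specs, window=window, start_t=start_t,
                dt_days=dt_days,
            )
            df = table.df
            for _, row in df[df["scenario_id"] != "baseline"].iterrows():
                for outcome in OUTCOMES:
                    records.append(
                        {
                            "draw": i,
                            "scenario_id": row["scenario_id"],
                            "region_id": row["region_id"],
                            "outcome": outcome,
                            "value": row[f"{outcome}_reduction_pct"],
                        }
                    )
        except Exception:
            for iset in scenarios:
                if not iset.ids:
                    continue
                for config in configs:
                    for outcome in OUTCOMES:
                        records.append(
                            {
                                "draw": i,
                                "scenario_id": iset.label(),
                                "region_id": config.region_id,
                                "outcome": outcome,
                                "value": np.nan,
                            }
                        )
    return pd.DataFrame.from_records(records)


def summarise(draws: pd.DataFrame) -> list[SummaryInterval]:
    """Mean and 50%/95% empirical intervals per scenario/region/outcome.

    Quantiles use linear interpolation between order statistics (numpy's
    default rule).  A cell with no finite draws raises."""
    out = []
    for (sid, rid, outcome), grp in draws.groupby(
        ["scenario_id", "region_id", "outcome"], sort=True
    ):
        vals = grp["value"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            raise ValueError(
                f"no finite draws for ({sid}, {rid}, {outcome})"
            )
        q = np.quantile(vals, [0.025, 0.25, 0.75, 0.975])
        out.append(
            SummaryInterval(
                scenario_id=sid,
                region_id=rid,
                outcome=outcome,
                mean=float(np.mean(vals)),
                interval_50=(float(q[1]), float(q[2])),
                interval_95=(float(q[0]), float(q[3])),
                n_draws=len(vals),
            )
        )
    return out
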