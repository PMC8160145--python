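"""Exhaustive k-of-12 scenario evaluation and Pareto filtering.

Every size-k subset of the intervention catalogue is simulated over the
forecast window (default 2021–2031) for each region, cumulative outcomes
(suicides, ED presentations, disengagements) are compared against the
business-as-usual baseline, and the best-per-outcome and non-dominated
(Pareto-optimal, minimisation sense) scenarios are extracted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import (
    CapacityModifiers,
    ModelParams,
    RegionConfig,
    ScenarioOutcome,
    aggregate_regions,
    cumulative_outcomes,
    date_to_t,
    simulate,
)
from .interventions import (
    DEFAULT_START,
    InterventionSet,
    InterventionSpec,
    apply_interventions,
    catalogue,
)

__all__ = [
    "OUTCOMES",
    "OutcomeTable",
    "ParetoResult",
    "enumerate_sets",
    "percent_reduction",
    "dominates",
    "pareto_front",
    "best_per_outcome",
    "evaluate_scenarios",
    "assign_scenario_labels",
]

#: The three minimised outcomes, in canonical column order.
OUTCOMES = ("suicides", "ed_presentations", "disengagements")

DEFAULT_WINDOW = (date_to_t("2021-01-01"), date_to_t("2031-01-01"))


@dataclass
class OutcomeTable:
    """Per-scenario, per-region outcome counts and reductions vs baseline.

    ``df`` columns: scenario_id, region_id, suicides, ed_presentations,
    disengagements, plus ``*_reduction_pct`` for each outcome.  Exactly one
    ``baseline`` row per region, whose reductions are zero.
    """

    df: pd.DataFrame
    window: tuple[float, float]
    members: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def region(self, region_id: str) -> pd.DataFrame:
        sub = self.df[self.df["region_id"] == region_id]
        if sub.empty:
            raise KeyError(f"no rows for region {region_id!r}")
        return sub.reset_index(drop=True)


@dataclass
class ParetoResult:
    """Non-dominated scenarios with a dominating witness for the rest."""

    non_dominated: list[str]
    dominated: list[tuple[str, str]]  # (scenario_id, witness id)
    objectives: tuple[str, str, str] = OUTCOMES
    sense: str = "minimise"


def enumerate_sets(
    specs: list[InterventionSpec] | list[str] | None = None, k: int = 4
) -> list[InterventionSet]:
    """All C(n, k) unordered intervention subsets, lexicographically ordered."""
    if specs is None:
        specs = catalogue()
    ids = sorted(s if isinstance(s, str) else s.id for s in specs)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate intervention ids")
    if not 0 <= k <= len(ids):
        raise ValueError(f"k must be in [0, {len(ids)}], got {k}")
    return [InterventionSet(combo) for combo in itertools.combinations(ids, k)]


def percent_reduction(baseline_count: float, scenario_count: float) -> float:
    """Percent reduction of a scenario count relative to the baseline."""
    if baseline_count <= 0:
        raise ValueError("baseline count must be > 0")
    return 100.0 * (baseline_count - scenario_count) / baseline_count


def dominates(a: ScenarioOutcome, b: ScenarioOutcome) -> bool:
    """True iff ``a`` is no worse than ``b`` on all three outcomes and
    strictly better on at least one (minimisation)."""
    if a.region_id != b.region_id or a.window != b.window:
        raise ValueError("outcomes must share region and window")
    ta, tb = a.as_tuple(), b.as_tuple()
    return all(x <= y for x, y in zip(ta, tb)) and any(
        x < y for x, y in zip(ta, tb)
    )


def _pareto_mask(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Boolean non-dominated mask + index of a dominating witness (-1 if none).

    Vectorised all-pairs domination test; ties (identical rows) are all
    retained on the front.
    """
    n = len(values)
    le = (values[:, None, :] <= values[None, :, :]).all(axis=2)
    lt = (values[:, None, :] < values[None, :, :]).any(axis=2)
    dom = le & lt  # dom[i, j]: i dominates j
    dominated_by = dom.any(axis=0)
    witness = np.full(n, -1)
    for j in np.flatnonzero(dominated_by):
        witness[j] = int(np.flatnonzero(dom[:, j])[0])
    return ~dominated_by, witness


def pareto_front(table: OutcomeTable, region_id: str = "PHN") -> ParetoResult:
    """Non-dominated scenarios for one region (baseline row included as a
    candidate; it is dominated whenever any scenario improves on it)."""
    sub = table.region(region_id)
    if sub.empty:
        raise ValueError("empty outcome table")
    values = sub[list(OUTCOMES)].to_numpy(dtype=float)
    mask, witness = _pareto_mask(values)
    ids = sub["scenario_id"].tolist()
    non_dom = [ids[i] for i in np.flatnonzero(mask)]
    dominated = [
        (ids[j], ids[witness[j]]) for j in np.flatnonzero(~mask)
    ]
    return ParetoResult(non_dominated=non_dom, dominated=dominated)


def best_per_outcome(
    table: OutcomeTable, region_id: str, outcome: str
) -> str:
    """Scenario id minimising one outcome; ties broken lexicographically."""
    if outcome not in OUTCOMES:
        raise KeyError(f"unknown outcome {outcome!r}")
    sub = table.region(region_id)
    sub = sub[sub["scenario_id"] != "baseline"]
    if sub.empty:
        raise ValueError("no scenario rows")
    best = sub.loc[sub[outcome] == sub[outcome].min(), "scenario_id"]
    return sorted(best)[0]


# --------------------------------------------------------------------------
# Scenario evaluation
# --------------------------------------------------------------------------


def _region_outcome(
    config: RegionConfig,
    params: ModelParams,
    modifiers: CapacityModifiers,
    iset: InterventionSet,
    specs: list[InterventionSpec],
    window: tuple[float, float],
    start_t: float,
    shared_init,
    dt_days: float,
    scenario_id: str,
) -> ScenarioOutcome:
    p2, m2 = apply_interventions(params, modifiers, iset, specs)
    traj = simulate(
        config, params, modifiers,
        t0=start_t, t_end=window[1], init=shared_init,
        switch=(start_t, p2, m2) if iset.ids else None,
        dt_days=dt_days, record=False,
    )
    return cumulative_outcomes(traj, (start_t, window[1]), scenario_id)


def evaluate_scenarios(
    configs: list[RegionConfig],
    params: ModelParams,
    modifiers: CapacityModifiers | None = None,
    sets: list[InterventionSet] | None = None,
    specs: list[InterventionSpec] | None = None,
    window: tuple[float, float] = DEFAULT_WINDOW,
    start_t: float = DEFAULT_START,
    dt_days: float | None = None,
    k: int = 4,
) -> OutcomeTable:
    """Simulate baseline plus every intervention set for every region.

    The pre-rollout segment (model start to ``start_t``) is simulated once
    per region and shared by all scenarios, which is exact because
    interventions only act from ``start_t`` onward.  Returns an
    :class:`OutcomeTable` with per-region rows and the PHN aggregate.
    """
    from .engine import DEFAULT_DT_DAYS

    if dt_days is None:
        dt_days = DEFAULT_DT_DAYS
    if specs is None:
        specs = catalogue()
    if sets is None:
        sets = enumerate_sets(specs, k)
    mods = modifiers if modifiers is not None else CapacityModifiers(
        start_t=start_t
    )

    rows = []
    members: dict[str, tuple[str, ...]] = {"baseline": ()}
    per_scenario: dict[str, list[ScenarioOutcome]] = {}

    for config in configs:
        warm = simulate(
            config, params, mods, t0=0.0, t_end=start_t,
            dt_days=dt_days, record=False,
        )
        shared_init = warm.state_at(start_t)
        base = _region_outcome(
            config, params, mods, InterventionSet(), specs, window, start_t,
            shared_init, dt_days, "baseline",
        )
        per_scenario.setdefault("baseline", []).append(base)
        for iset in sets:
            if not iset.ids:
                continue
            sid = iset.label()
            members[sid] = tuple(sorted(iset.ids))
            out = _region_outcome(
                config, params, mods, iset, specs, window, start_t,
                shared_init, dt_days, sid,
            )
            per_scenario.setdefault(sid, []).append(out)

    # append PHN aggregates and percent reductions
    baselines: dict[str, ScenarioOutcome] = {}
    all_outcomes: list[ScenarioOutcome] = []
    for sid, outs in per_scenario.items():
        outs = list(outs)
        if len(configs) > 1:
            outs.append(aggregate_regions(outs))
        for o in outs:
            all_outcomes.append(o)
            if sid == "baseline":
                baselines[o.region_id] = o

    for o in all_outcomes:
        b = baselines[o.region_id]
        rows.append(
            {
                "scenario_id": o.scenario_id,
                "region_id": o.region_id,
                "suicides": o.suicides,
                "ed_presentations": o.ed_presentations,
                "disengagements": o.disengagements,
                "suicides_reduction_pct": percent_reduction(
                    b.suicides, o.suicides
                ),
                "ed_presentations_reduction_pct": percent_reduction(
                    b.ed_presentations, o.ed_presentations
                ),
                "disengagements_reduction_pct": percent_reduction(
                    b.disengagements, o.disengagements
                ),
            }
        )
    df = pd.DataFrame(rows)
    return OutcomeTable(df=df, window=(start_t, window[1]), members=members)


def assign_scenario_labels(
    table: OutcomeTable, front: ParetoResult, region_id: str = "PHN"
) -> dict[str, str]:
    """Letter labels (a, b, c, ...) for the non-dominated scenarios, ordered
    by descending suicide reduction; the baseline keeps label '0'."""
    sub = table.region(region_id).set_index("scenario_id")
    ids = [s for s in front.non_dominated if s != "baseline"]
    ordered = sorted(
        ids, key=lambda s: (-sub.loc[s, "suicides_reduction_pct"], s)
    )
    labels = {"baseline": "0"}
    for i, sid in enumerate(ordered):
        labels[sid] = chr(ord("a") + i) if i < 26 else f"z{i}"
    return labels
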