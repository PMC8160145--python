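"""Historical calibration by Powell's method on a summed-MAPE objective.

Free model parameters are fitted to annual observation series (distress
prevalence, self-harm hospitalisation and suicide rates, GP mental-health
consultations, allied services, psychiatric bed occupancy) by minimising the
sum over series of the mean absolute percent error (MAPE) between observed
values and the model output sampled at the observation timestamps.  Powell's
derivative-free conjugate-direction search runs in coordinates normalised to
the parameter box, with bounds enforced natively plus a finite penalty for
any excursion, and a small number of jittered restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from .engine import ModelParams, RegionConfig, simulate, t_to_date, date_to_t

__all__ = [
    "TARGET_SERIES",
    "CalibrationTargets",
    "CalibrationResult",
    "mape",
    "model_series",
    "objective",
    "powell_fit",
    "fit",
]

#: The six observed series the objective compares against.
TARGET_SERIES = (
    "distress_prevalence",
    "self_harm_hospitalisation_rate",
    "suicide_rate",
    "gp_mh_consultations_per_yr",
    "allied_services_per_yr",
    "psych_bed_occupancy",
)

#: Penalty returned when a simulation fails inside the objective.
FAILURE_PENALTY = 1e6


@dataclass
class CalibrationTargets:
    """Named historical series: name -> (timestamps in model years, values)."""

    series: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        for name, (t, v) in self.series.items():
            t = np.asarray(t, dtype=float)
            v = np.asarray(v, dtype=float)
            if len(t) != len(v) or len(t) == 0:
                raise ValueError(f"series {name!r}: mismatched or empty arrays")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"series {name!r}: timestamps must increase")
            if np.any(v <= 0):
                bad = t[v <= 0][0]
                raise ValueError(
                    f"series {name!r}: non-positive observation at t={bad} "
                    "(MAPE requires positive denominators)"
                )
            self.series[name] = (t, v)

    def to_csv(self, path: str) -> None:
        import pandas as pd

        rows = [
            {"series": name, "date": t_to_date(t).isoformat(), "value": val}
            for name, (ts, vs) in self.series.items()
            for t, val in zip(ts, vs)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "CalibrationTargets":
        import pandas as pd

        df = pd.read_csv(path)
        series = {}
        for name, grp in df.groupby("series", sort=False):
            grp = grp.sort_values("date")
            ts = np.array([date_to_t(d) for d in grp["date"]])
            series[name] = (ts, grp["value"].to_numpy(dtype=float))
        return cls(series=series)


@dataclass
class CalibrationResult:
    params: ModelParams
    objective_value: float  # summed MAPE, percent
    per_series_mape: dict[str, float]
    iterations: int
    n_evaluations: int
    converged: bool
    bounds_active: list[str] = field(default_factory=list)
    x: np.ndarray | None = None


# --------------------------------------------------------------------------
# The loss
# --------------------------------------------------------------------------


def mape(observed: Sequence[float], simulated: Sequence[float]) -> float:
    """Mean absolute percent error of ``simulated`` against ``observed``.

    Each absolute difference is expressed as a percentage of the observed
    value; the mean over time points is returned.
    """
    obs = np.asarray(observed, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if obs.shape != sim.shape or obs.size == 0:
        raise ValueError("observed and simulated must be equal-length, non-empty")
    if np.any(obs == 0):
        i = int(np.flatnonzero(obs == 0)[0])
        raise ValueError(f"observed value is zero at index {i}; MAPE undefined")
    return float(100.0 * np.mean(np.abs(obs - sim) / np.abs(obs)))


def model_series(
    config: RegionConfig,
    params: ModelParams,
    targets: CalibrationTargets,
    dt_days: float | None = None,
) -> dict[str, np.ndarray]:
    """Simulate over the target span and interpolate outputs to timestamps."""
    from .synthetic import _sample_series  # shared output mapping

    t_max = max(ts[-1] for ts, _ in targets.series.values())
    kwargs = {} if dt_days is None else {"dt_days": dt_days}
    traj = simulate(config, params, t_end=float(np.ceil(t_max)), **kwargs)
    out = {}
    for name, (ts, _) in targets.series.items():
        sampled = _sample_series(traj, ts)
        if name not in sampled:
            raise KeyError(f"no model output mapped to series {name!r}")
        out[name] = sampled[name]
    return out


def _decode(
    x: Sequence[float], free: Sequence[str], base: ModelParams
) -> ModelParams:
    p = base.copy()
    for path, val in zip(free, x):
        p.set_path(path, float(val))
    return p


def objective(
    x: Sequence[float],
    free: Sequence[str],
    targets: CalibrationTargets,
    config: RegionConfig,
    base_params: ModelParams,
    dt_days: float | None = None,
) -> float:
    """Summed per-series MAPE (percent) at parameter vector ``x``.

    Simulation failures return a large finite penalty rather than raising,
    so derivative-free search can continue past a pathological corner.
    """
    if len(x) != len(free):
        raise ValueError("parameter vector length must match the free list")
    try:
        params = _decode(x, free, base_params)
        sim = model_series(config, params, targets, dt_days=dt_days)
    except Exception:
        return FAILURE_PENALTY
    total = 0.0
    for name, (_, obs) in targets.series.items():
        total += mape(obs, sim[name])
    if not np.isfinite(total):
        return FAILURE_PENALTY
    return total


# --------------------------------------------------------------------------
# Powell search
# --------------------------------------------------------------------------


def powell_fit(
    fun: Callable[[np.ndarray], float],
    x0: Sequence[float],
    bounds: Sequence[tuple[float, float]],
    xtol: float = 1e-4,
    ftol: float = 1e-6,
    max_iter: int = 200,
    seed: int = 0,
    restarts: int = 3,
) -> CalibrationResult:
    """Minimise ``fun`` with Powell's method under box constraints.

    The search runs in unit-box-normalised coordinates (``xtol`` applies
    there).  Out-of-box proposals are clipped to the box with a quadratic
    penalty, keeping the objective finite everywhere.  ``restarts`` jittered
    starting points (seeded) are tried and the best result kept.  The
    returned ``params`` field is unset; use :func:`fit` for the full
    model-fitting pipeline.
    """
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.any(hi <= lo):
        raise ValueError("each bound must satisfy low < high")
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < lo) or np.any(x0 > hi):
        raise ValueError("x0 must lie within bounds")

    span = hi - lo
    n_eval = 0

    def wrapped(u: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        uc = np.clip(u, 0.0, 1.0)
        penalty = float(np.sum((u - uc) ** 2)) * 1e4
        val = fun(lo + uc * span)
        if not np.isfinite(val):
            return FAILURE_PENALTY + penalty
        return val + penalty

    f0 = wrapped((x0 - lo) / span)
    n_eval = 0
    if not np.isfinite(f0):
        raise ValueError("objective is non-finite at x0")

    rng = np.random.default_rng(seed)
    starts = [(x0 - lo) / span]
    for _ in range(max(0, restarts - 1)):
        u = starts[0] + rng.uniform(-0.15, 0.15, size=len(x0))
        starts.append(np.clip(u, 0.0, 1.0))

    best = None
    total_iters = 0
    for u0 in starts:
        res = optimize.minimize(
            wrapped,
            u0,
            method="Powell",
            bounds=[(0.0, 1.0)] * len(x0),
            options={"xtol": xtol, "ftol": ftol, "maxiter": max_iter},
        )
        total_iters += int(res.nit)
        if best is None or res.fun < best.fun:
            best = res

    assert best is not None
    u = np.clip(best.x, 0.0, 1.0)
    x = lo + u * span
    active = [
        str(i) for i in range(len(x)) if u[i] < 1e-6 or u[i] > 1.0 - 1e-6
    ]
    return CalibrationResult(
        params=None,  # type: ignore[arg-type]
        objective_value=float(best.fun),
        per_series_mape={},
        iterations=total_iters,
        n_evaluations=n_eval,
        converged=bool(best.success),
        bounds_active=active,
        x=x,
    )


def fit(
    config: RegionConfig,
    base_params: ModelParams,
    targets: CalibrationTargets,
    free: Sequence[str],
    bounds: Sequence[tuple[float, float]],
    x0: Sequence[float] | None = None,
    xtol: float = 1e-4,
    ftol: float = 1e-6,
    max_iter: int = 200,
    seed: int = 0,
    restarts: int = 3,
    dt_days: float | None = 1.75,
) -> CalibrationResult:
    """Fit the free parameters of the model to historical targets.

    ``x0`` defaults to the midpoint of the bounds.  Returns the fitted
    parameter set, the summed-MAPE objective and its per-series breakdown.
    """
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if x0 is None:
        x0 = 0.5 * (lo + hi)

    def fun(x: np.ndarray) -> float:
        return objective(x, free, targets, config, base_params, dt_days=dt_days)

    result = powell_fit(
        fun, x0, bounds, xtol=xtol, ftol=ftol, max_iter=max_iter, seed=seed,
        restarts=restarts,
    )
    fitted = _decode(result.x, free, base_params)
    sim = model_series(config, fitted, targets, dt_days=dt_days)
    per_series = {
        name: mape(obs, sim[name]) for name, (_, obs) in targets.series.items()
    }
    result.params = fitted
    result.per_series_mape = per_series
    result.objective_value = float(sum(per_series.values()))
    result.bounds_active = [free[int(i)] for i in result.bounds_active]
    return result
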