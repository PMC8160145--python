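"""Intervention catalogue and its mapping onto model parameters.

Twelve entries: eight mental-health / suicide-prevention programs acting on
model rates and hazards, and four service-capacity levers acting on capacity
growth.  An unordered subset of entries (an intervention set / scenario) is
translated into a modified parameter set and capacity modifiers, applied
instantaneously at the scenario start date (default 1 Jan 2021).

Program effects combine multiplicatively on shared parameters, which makes
application order-independent and preserves positivity; non-additive
interaction between interventions emerges structurally through shared
service capacity rather than bespoke interaction terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import yaml

from .engine import CapacityModifiers, ModelParams, date_to_t

__all__ = [
    "InterventionSpec",
    "InterventionSet",
    "catalogue",
    "catalogue_ids",
    "apply_interventions",
    "community_support_factor",
    "DEFAULT_START",
]

#: Scenario start: interventions roll out instantaneously at 1 Jan 2021.
DEFAULT_START = date_to_t("2021-01-01")

# parameters constrained to [0, 1]; effects are clamped there with a warning
_FRACTION_PARAMS = {
    "attempt_case_fatality",
    "hospitalised_fraction",
    "safe_space_diversion",
    "acute_care_diversion",
    "connectedness_coverage",
}


@dataclass(frozen=True)
class InterventionSpec:
    """One catalogue entry: a program or a capacity lever."""

    id: str
    kind: str  # "program" | "capacity_lever"
    label: str
    note: str = ""
    targets: tuple[dict, ...] = ()
    capacity_cost: dict | None = None
    lever: dict | None = None
    start_t: float = DEFAULT_START

    def scaled(self, factor: float) -> "InterventionSpec":
        """Copy with every effect's distance from identity scaled.

        Multiplicative effects e become 1 + (e-1)*factor, additive and
        overwrite effects are scaled directly; used by the sensitivity
        analysis to vary an intervention's direct effect.
        """
        new_targets = []
        for tgt in self.targets:
            t = dict(tgt)
            if not t.get("vary", True):
                new_targets.append(t)
                continue
            if t["transform"] == "mul":
                t["effect"] = 1.0 + (t["effect"] - 1.0) * factor
            else:
                t["effect"] = t["effect"] * factor
            new_targets.append(t)
        return InterventionSpec(
            id=self.id, kind=self.kind, label=self.label, note=self.note,
            targets=tuple(new_targets), capacity_cost=self.capacity_cost,
            lever=self.lever, start_t=self.start_t,
        )


@dataclass(frozen=True)
class InterventionSet:
    """An unordered, duplicate-free subset of catalogue ids."""

    ids: frozenset[str] = field(default_factory=frozenset)

    def __init__(self, ids=()):  # accept any iterable
        object.__setattr__(self, "ids", frozenset(ids))
        unknown = self.ids - set(catalogue_ids())
        if unknown:
            raise KeyError(f"unknown intervention id(s): {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(sorted(self.ids))

    def label(self) -> str:
        return "+".join(sorted(self.ids)) if self.ids else "baseline"


@lru_cache(maxsize=1)
def _load_catalogue() -> tuple[InterventionSpec, ...]:
    text = resources.files("mhsd").joinpath("catalogue.yaml").read_text()
    raw = yaml.safe_load(text)
    specs = []
    for entry in raw:
        specs.append(
            InterventionSpec(
                id=entry["id"],
                kind=entry["kind"],
                label=entry["label"],
                note=entry.get("note", ""),
                targets=tuple(entry.get("targets", ())),
                capacity_cost=entry.get("capacity_cost"),
                lever=entry.get("lever"),
            )
        )
    ids = [s.id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate intervention ids in catalogue")
    return tuple(specs)


def catalogue() -> list[InterventionSpec]:
    """The 12 modelled programs, services and capacity levers."""
    return list(_load_catalogue())


def catalogue_ids() -> list[str]:
    return [s.id for s in _load_catalogue()]


def community_support_factor(coverage: float) -> float:
    """Multiplier on support-sensitive effects, linear in connectedness
    coverage: 1.0 with no social-connectedness program, 1.5 at full
    coverage (bounded within [0.5, 1.5])."""
    f = 1.0 + 0.5 * coverage
    return min(max(f, 0.5), 1.5)


def apply_interventions(
    params: ModelParams,
    modifiers: CapacityModifiers,
    iset: InterventionSet,
    specs: list[InterventionSpec] | None = None,
) -> tuple[ModelParams, CapacityModifiers]:
    """Translate an intervention set into modified params and modifiers.

    Inputs are not mutated.  Effects on shared parameters combine
    multiplicatively, so the result is independent of application order.
    An effect pushing a [0,1]-constrained fraction outside its range is
    clamped with a warning.
    """
    by_id = {s.id: s for s in (specs if specs is not None else _load_catalogue())}
    unknown = iset.ids - set(by_id)
    if unknown:
        raise KeyError(f"unknown intervention id(s): {sorted(unknown)}")
    if not iset.ids:
        return params, modifiers

    p = params.copy()
    mods = modifiers.copy()
    active = [by_id[i] for i in sorted(iset.ids)]

    # community-support coverage is resolved first so support-scaled effects
    # see the final coverage regardless of set order
    coverage = p.connectedness_coverage
    for spec in active:
        for tgt in spec.targets:
            if tgt["path"] == "connectedness_coverage" and tgt["transform"] == "set":
                coverage = max(coverage, float(tgt["effect"]))
    csf = community_support_factor(coverage)

    for spec in active:
        if spec.kind == "capacity_lever":
            lever = spec.lever or {}
            sid = lever["service_id"]
            if "growth_multiplier" in lever:
                mods.growth_multiplier[sid] = float(lever["growth_multiplier"])
            if "cmhc_increment_per_10k" in lever:
                mods.cmhc_increment_per_10k = float(lever["cmhc_increment_per_10k"])
            continue
        for tgt in spec.targets:
            path, transform = tgt["path"], tgt["transform"]
            effect = float(tgt["effect"])
            if tgt.get("scaled_by_support") and transform == "mul":
                effect = 1.0 + (effect - 1.0) * csf
            old = p.get_path(path)
            if transform == "mul":
                new = old * effect
            elif transform == "add":
                new = old + effect
            elif transform == "set":
                new = effect
            else:
                raise ValueError(f"unknown transform {transform!r}")
            leaf = path.split(".")[-1]
            if leaf in _FRACTION_PARAMS and not 0.0 <= new <= 1.0:
                clamped = min(max(new, 0.0), 1.0)
                warnings.warn(
                    f"effect on {path} pushed value to {new:.3f}; "
                    f"clamped to {clamped:.3f}",
                    stacklevel=2,
                )
                new = clamped
            p.set_path(path, new)

    # re-validate cross-parameter constraints after combination
    if p.attempt_hazard_in_care > p.attempt_hazard_untreated:
        p.attempt_hazard_in_care = p.attempt_hazard_untreated
    return p, mods
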