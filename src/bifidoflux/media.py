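"""Growth media as nutrient sets and their translation to exchange bounds.

A :class:`Medium` names the nutrients available to the cell; concentrations
are carried as documentation only.  For flux balance analysis a batch
medium is encoded as uptake-rate *availability*: every supplied nutrient's
exchange lower bound is opened (to ``-uptake_bound``, or an effectively
unconstrained -1000 mmol gCDW^-1 h^-1), all other exchange lower bounds are
closed, and secretion stays unrestricted.  The mapping from nutrient names
to exchange reaction ids is an explicit, editable table; nutrients without
a mapped exchange (e.g. trace salts absent from the model) are
documentation-only and flagged at application time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import yaml

from .fba import RatioConstraint
from .model import DEFAULT_UB, MetabolicModel

__all__ = ["MediumComponent", "Medium", "Scenario", "apply_medium", "omit",
           "load_medium", "save_medium"]

#: Marker for a component whose uptake is not rate-limited.
UNCONSTRAINED = "unconstrained"


@dataclass
class MediumComponent:
    """One nutrient: documentation concentration plus an uptake bound."""

    concentration: float = 0.0
    unit: str = "g/L"
    uptake_bound: Union[float, str] = UNCONSTRAINED  # mmol/gCDW/h or marker

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if not isinstance(self.uptake_bound, str) and self.uptake_bound < 0:
            raise ValueError("uptake bound must be non-negative "
                             "(it is a magnitude, applied as -bound)")

    @property
    def bound_value(self) -> float:
        if isinstance(self.uptake_bound, str):
            return DEFAULT_UB
        return float(self.uptake_bound)


@dataclass
class Medium:
    """A named nutrient set.

    ``exchange_map`` maps each nutrient name to the id of the exchange
    reaction that supplies it; a ``None`` entry declares the nutrient as
    documentation-only (not represented in the model).
    """

    name: str
    components: Dict[str, MediumComponent] = field(default_factory=dict)
    exchange_map: Dict[str, Optional[str]] = field(default_factory=dict)

    def __contains__(self, nutrient: str) -> bool:
        return nutrient in self.components

    def __len__(self) -> int:
        return len(self.components)

    def copy(self) -> "Medium":
        return Medium(
            self.name,
            {k: MediumComponent(v.concentration, v.unit, v.uptake_bound)
             for k, v in self.components.items()},
            dict(self.exchange_map))

    def add(self, nutrient: str,
            component: Optional[MediumComponent] = None,
            exchange_id: Optional[str] = None) -> "Medium":
        """Return a copy with one nutrient added (or re-added)."""
        new = self.copy()
        new.components[nutrient] = component or MediumComponent()
        if exchange_id is not None or nutrient not in new.exchange_map:
            new.exchange_map[nutrient] = exchange_id
        return new

    def exchange_id(self, nutrient: str) -> Optional[str]:
        return self.exchange_map.get(nutrient)


def omit(medium: Medium, nutrient: str) -> Medium:
    """Copy of the medium without one nutrient; the original is untouched."""
    if nutrient not in medium.components:
        raise KeyError(f"nutrient {nutrient!r} is not in medium "
                       f"{medium.name!r}")
    new = medium.copy()
    del new.components[nutrient]
    return new


def apply_medium(model: MetabolicModel, medium: Medium,
                 strict: bool = True) -> Tuple[MetabolicModel, List[str]]:
    """Constrain a model's exchange bounds to a medium.

    Returns ``(constrained_copy, documentation_only)`` where the second item
    lists components not represented by any exchange reaction.  With
    ``strict=True`` a component that is *mapped* to a missing exchange
    reaction raises an error listing it; unmapped (``None``) components are
    always tolerated and reported.  Idempotent and order-independent over
    components.
    """
    constrained = model.copy()
    for rxn in constrained.exchanges:
        rxn.lower_bound = 0.0
        rxn.upper_bound = max(rxn.upper_bound, 0.0) or DEFAULT_UB

    documentation_only: List[str] = []
    missing: List[str] = []
    for nutrient in sorted(medium.components):
        component = medium.components[nutrient]
        ex_id = medium.exchange_id(nutrient)
        if ex_id is None:
            documentation_only.append(nutrient)
            continue
        if ex_id not in constrained.reactions:
            missing.append(f"{nutrient} -> {ex_id}")
            continue
        constrained.set_bounds(ex_id, lower=-component.bound_value)
    if missing and strict:
        raise KeyError(
            "medium components mapped to exchanges absent from model "
            f"{model.id!r}: {missing}")
    documentation_only.extend(missing)
    return constrained, documentation_only


@dataclass
class Scenario:
    """A named constraint recipe on top of a medium.

    ``fixed_uptakes`` pins an exchange flux to an exact uptake magnitude
    (applied as lower == upper == -value); ``closed_exchanges`` forbids both
    uptake and secretion of the listed exchanges; ``ratio_constraints`` are
    homogeneous flux-ratio equalities (e.g. acetate:lactate).
    """

    name: str
    medium: Medium
    objective_id: Optional[str] = None
    ratio_constraints: List[RatioConstraint] = field(default_factory=list)
    closed_exchanges: List[str] = field(default_factory=list)
    fixed_uptakes: Dict[str, float] = field(default_factory=dict)
    uptake_caps: Dict[str, float] = field(default_factory=dict)

    def apply(self, model: MetabolicModel) -> MetabolicModel:
        constrained, _ = apply_medium(model, self.medium)
        for rxn_id in self.closed_exchanges:
            constrained.set_bounds(rxn_id, 0.0, 0.0)
        for rxn_id, uptake in self.fixed_uptakes.items():
            constrained.set_bounds(rxn_id, -uptake, -uptake)
        for rxn_id, cap in self.uptake_caps.items():
            constrained.set_bounds(rxn_id, lower=-cap)
        if self.objective_id is not None:
            if self.objective_id not in constrained.reactions:
                raise KeyError(f"scenario objective {self.objective_id!r} "
                               "not in model")
            constrained.objective_id = self.objective_id
        return constrained


# ---------------------------------------------------------------------------
# structured-text serialization
# ---------------------------------------------------------------------------

def load_medium(path: Union[str, Path]) -> Medium:
    """Load a medium table from YAML: name, components, exchange_map."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    components = {}
    for nutrient, spec in raw.get("components", {}).items():
        spec = spec or {}
        components[nutrient] = MediumComponent(
            concentration=float(spec.get("concentration", 0.0)),
            unit=spec.get("unit", "g/L"),
            uptake_bound=(spec.get("uptake_bound", UNCONSTRAINED)))
    return Medium(name=raw.get("name", Path(path).stem),
                  components=components,
                  exchange_map=raw.get("exchange_map", {}) or {})


def save_medium(medium: Medium, path: Union[str, Path]) -> None:
    payload = {
        "name": medium.name,
        "components": {
            n: {"concentration": c.concentration, "unit": c.unit,
                "uptake_bound": c.uptake_bound}
            for n, c in sorted(medium.components.items())},
        "exchange_map": dict(sorted(medium.exchange_map.items())),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
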