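"""Structural model audits: mass/charge balance and model comparison.

Every internal reaction of a reconstruction must conserve each chemical
element and the net charge.  Boundary pseudo-reactions (exchanges, demands,
sinks, the biomass reaction) are exempt by construction but are reported as
such rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

from .model import MetabolicModel

__all__ = ["BalanceReport", "check_mass_charge_balance",
           "ModelComparison", "compare_models"]

#: Absolute per-element residual below which a reaction counts as balanced.
BALANCE_TOLERANCE = 1e-6


@dataclass
class BalanceReport:
    """Outcome of an element/charge conservation audit.

    ``residuals`` maps reaction id -> {element or "charge" -> signed
    residual}; only audited (non-exempt, auditable) reactions appear.
    ``unauditable`` lists reactions containing a metabolite without a
    formula, which cannot be audited and must not be reported as balanced.
    """

    residuals: Dict[str, Dict[str, float]] = field(default_factory=dict)
    exempt: List[str] = field(default_factory=list)
    unauditable: List[str] = field(default_factory=list)
    tolerance: float = BALANCE_TOLERANCE

    @property
    def unbalanced(self) -> Dict[str, Dict[str, float]]:
        """Audited reactions with at least one residual above tolerance."""
        return {
            rxn: {k: v for k, v in res.items() if abs(v) > self.tolerance}
            for rxn, res in self.residuals.items()
            if any(abs(v) > self.tolerance for v in res.values())
        }

    @property
    def balanced(self) -> bool:
        return not self.unbalanced and not self.unauditable


def check_mass_charge_balance(model: MetabolicModel,
                              tolerance: float = BALANCE_TOLERANCE,
                              ) -> BalanceReport:
    """Audit elemental and charge conservation of every internal reaction.

    The residual of element ``e`` in reaction ``j`` is
    ``sum_i S[i, j] * formula_i[e]`` and analogously for charge; a balanced
    reaction has every |residual| below ``tolerance``.  Exchanges,
    demands/sinks and the objective (biomass) reaction are exempt.  A
    non-exempt reaction touching a metabolite with no formula is listed as
    unauditable instead of passing silently.
    """
    report = BalanceReport(tolerance=tolerance)
    exempt_ids = model.boundary_like()
    for rxn_id, rxn in model.reactions.items():
        if rxn_id in exempt_ids:
            report.exempt.append(rxn_id)
            continue
        mets = [model.metabolite(m) for m in rxn.stoichiometry]
        if any(not m.formula for m in mets):
            report.unauditable.append(rxn_id)
            continue
        residual: Dict[str, float] = {}
        charge = 0.0
        for met_id, coef in rxn.stoichiometry.items():
            met = model.metabolite(met_id)
            for el, count in met.formula.items():
                residual[el] = residual.get(el, 0.0) + coef * count
            charge += coef * met.charge
        residual["charge"] = charge
        report.residuals[rxn_id] = residual
    return report


@dataclass
class ModelComparison:
    """Shared/unique reaction keys between two models.

    ``key_mode`` is ``"identifier"`` (reaction ids) or ``"ec"`` (individual
    EC numbers).  The three sets are pairwise disjoint and their union is
    the union of both models' key sets.
    """

    shared: Set[str]
    unique_to_a: Set[str]
    unique_to_b: Set[str]
    key_mode: str
    model_a: str = ""
    model_b: str = ""

    @property
    def n_not_shared(self) -> int:
        return len(self.unique_to_a) + len(self.unique_to_b)


def _keys(model: MetabolicModel, key_mode: str,
          exclude_exchanges: bool) -> Set[str]:
    keys: Set[str] = set()
    for rxn in model.reactions.values():
        if exclude_exchanges and rxn.is_exchange:
            continue
        if key_mode == "identifier":
            keys.add(rxn.id)
        else:
            keys.update(rxn.ec_numbers)
    return keys


def compare_models(a: MetabolicModel, b: MetabolicModel,
                   key_mode: str = "identifier",
                   exclude_exchanges: bool = True) -> ModelComparison:
    """Set comparison of two reconstructions by reaction key.

    With ``key_mode="identifier"`` the keys are reaction identifiers; with
    ``"ec"`` they are the individual EC numbers annotated on reactions.
    Exchange reactions are excluded by default, matching the usual
    convention for comparing reconstructions of different organisms.
    """
    if key_mode not in ("identifier", "ec"):
        raise ValueError(f"unknown key_mode {key_mode!r}; "
                         "expected 'identifier' or 'ec'")
    keys_a = _keys(a, key_mode, exclude_exchanges)
    keys_b = _keys(b, key_mode, exclude_exchanges)
    return ModelComparison(
        shared=keys_a & keys_b,
        unique_to_a=keys_a - keys_b,
        unique_to_b=keys_b - keys_a,
        key_mode=key_mode, model_a=a.id, model_b=b.id)
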