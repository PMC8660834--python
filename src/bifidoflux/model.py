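"""Core containers for stoichiometric metabolic models.

A :class:`MetabolicModel` is a plain in-memory network: metabolites with
chemical formulas and charges, reactions with flux bounds and gene rules,
and one designated objective reaction.  The model is the source of the
stoichiometric matrix ``S`` used by flux balance analysis, where steady
state means ``S @ v == 0`` for the flux vector ``v``.

Conventions
-----------
* Compartments are short tokens, ``"c"`` (cytosol) and ``"e"``
  (extracellular) by default.
* Exchange reactions touch exactly one extracellular metabolite; negative
  flux means uptake, positive means secretion.
* Flux units are mmol per gram cell dry weight per hour
  (mmol gCDW^-1 h^-1); the biomass reaction carries h^-1.
* Formulas map element symbols to non-negative real counts.  Fractional
  subscripts are allowed so that pooled pseudo-species such as biomass
  ("CH1.57N0.23O0.43P0.01") can be represented.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "parse_formula",
    "format_formula",
    "formula_weight",
    "stoichiometric_matrix",
    "ATOMIC_MASSES",
    "DEFAULT_UB",
]

#: Default magnitude for an effectively unconstrained flux bound.
DEFAULT_UB = 1000.0

# Monoisotopic-free standard atomic weights for the elements that occur in
# metabolic reconstructions (g/mol).
ATOMIC_MASSES: Dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "K": 39.098, "Na": 22.990, "Mg": 24.305, "Ca": 40.078,
    "Fe": 55.845, "Cl": 35.45, "Mn": 54.938, "Zn": 65.38, "Cu": 63.546,
    "Co": 58.933, "Ni": 58.693, "Mo": 95.95, "Se": 78.971, "B": 10.81,
    "F": 18.998, "I": 126.904, "W": 183.84, "R": 0.0, "X": 0.0,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def parse_formula(text: str) -> Dict[str, float]:
    """Parse a Hill-style formula string into an element->count mapping.

    Fractional subscripts are accepted ("CH1.57N0.23O0.43P0.01").
    """
    if text is None:
        return {}
    text = text.strip()
    if not text:
        return {}
    out: Dict[str, float] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
        pos = match.end()
        element, count = match.group(1), match.group(2)
        if element not in ATOMIC_MASSES:
            raise ValueError(f"unknown element symbol {element!r} in {text!r}")
        out[element] = out.get(element, 0.0) + (float(count) if count else 1.0)
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
    return out


def format_formula(formula: Mapping[str, float]) -> str:
    """Format an element mapping as a Hill-ordered formula string."""
    def fmt(x: float) -> str:
        if abs(x - round(x)) < 1e-9:
            n = int(round(x))
            return "" if n == 1 else str(n)
        return f"{x:.12g}"

    symbols = sorted(formula, key=lambda s: (s != "C", s != "H", s))
    return "".join(f"{s}{fmt(formula[s])}" for s in symbols if formula[s] != 0)


def formula_weight(formula: Mapping[str, float]) -> float:
    """Molecular weight in g/mol of an element mapping."""
    return sum(ATOMIC_MASSES[el] * n for el, n in formula.items())


@dataclass
class Metabolite:
    """A chemical species in one compartment."""

    id: str
    name: str = ""
    compartment: str = "c"
    formula: Dict[str, float] = field(default_factory=dict)
    charge: float = 0.0

    def validate(self) -> None:
        if not self.id:
            raise ValueError("metabolite id must be non-empty")
        for el, n in self.formula.items():
            if el not in ATOMIC_MASSES:
                raise ValueError(f"{self.id}: unknown element symbol {el!r}")
            if n < 0:
                raise ValueError(f"{self.id}: negative count for {el}")

    @property
    def formula_string(self) -> str:
        return format_formula(self.formula)

    def copy(self) -> "Metabolite":
        return Metabolite(self.id, self.name, self.compartment,
                          dict(self.formula), self.charge)


_GENE_TOKEN = re.compile(r"[A-Za-z0-9_.\-]+")


def genes_in_rule(gene_rule: str) -> Set[str]:
    """Extract gene identifiers from a boolean AND/OR gene rule."""
    if not gene_rule:
        return set()
    return {tok for tok in _GENE_TOKEN.findall(gene_rule)
            if tok.lower() not in {"and", "or"}}


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds.

    ``stoichiometry`` maps metabolite ids to signed coefficients; negative
    means consumed, positive means produced.
    """

    id: str
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_UB
    gene_rule: str = ""
    name: str = ""
    subsystem: str = ""
    ec_numbers: List[str] = field(default_factory=list)
    is_exchange: bool = False

    def validate(self) -> None:
        if not self.id:
            raise ValueError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ValueError(f"{self.id}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"{self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}")

    @property
    def genes(self) -> Set[str]:
        return genes_in_rule(self.gene_rule)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        return Reaction(self.id, dict(self.stoichiometry), self.lower_bound,
                        self.upper_bound, self.gene_rule, self.name,
                        self.subsystem, list(self.ec_numbers), self.is_exchange)

    def equation(self, arrow: Optional[str] = None) -> str:
        """Human-readable reaction string, e.g. ``glc_c + atp_c --> g6p_c``."""
        if arrow is None:
            arrow = "<=>" if self.reversible else "-->"
        def side(sign: int) -> str:
            terms = []
            for met, coef in sorted(self.stoichiometry.items()):
                if math.copysign(1, coef) == sign and coef != 0:
                    c = abs(coef)
                    terms.append(met if abs(c - 1) < 1e-12 else f"{c:g} {met}")
            return " + ".join(terms)
        return f"{side(-1)} {arrow} {side(1)}".strip()


class MetabolicModel:
    """A stoichiometric model: metabolites, reactions, one objective."""

    def __init__(self, id: str, metabolites: Iterable[Metabolite] = (),
                 reactions: Iterable[Reaction] = (),
                 objective_id: Optional[str] = None,
                 gene_ids: Optional[Set[str]] = None,
                 name: str = ""):
        self.id = id
        self.name = name or id
        self.metabolites: Dict[str, Metabolite] = {}
        self.reactions: Dict[str, Reaction] = {}
        self.gene_ids: Set[str] = set(gene_ids or set())
        for met in metabolites:
            self.add_metabolite(met)
        for rxn in reactions:
            self.add_reaction(rxn)
        self.objective_id = objective_id

    # -- construction -----------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ValueError(f"duplicate metabolite id {met.id!r}")
        met.validate()
        self.metabolites[met.id] = met
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        rxn.validate()
        missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
        if missing:
            raise ValueError(
                f"reaction {rxn.id!r} references undeclared metabolites "
                f"{sorted(missing)}")
        self.reactions[rxn.id] = rxn
        self.gene_ids |= rxn.genes
        return rxn

    def remove_reaction(self, rxn_id: str) -> Reaction:
        return self.reactions.pop(rxn_id)

    # -- accessors --------------------------------------------------------
    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self.reactions[rxn_id]
        except KeyError:
            raise KeyError(f"no reaction {rxn_id!r} in model {self.id!r}") from None

    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self.metabolites[met_id]
        except KeyError:
            raise KeyError(f"no metabolite {met_id!r} in model {self.id!r}") from None

    @property
    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    def boundary_like(self) -> Set[str]:
        """Reaction ids exempt from elemental audits.

        Exchanges, demand/sink reactions (single-metabolite pseudo
        reactions regardless of compartment) and the objective/biomass
        reaction do not conserve mass by design.
        """
        out: Set[str] = set()
        for rxn in self.reactions.values():
            if rxn.is_exchange or len(rxn.stoichiometry) == 1:
                out.add(rxn.id)
            elif rxn.id.startswith(("DM_", "SK_", "sink_")):
                out.add(rxn.id)
        if self.objective_id:
            out.add(self.objective_id)
        return out

    def genes_in_rules(self) -> Set[str]:
        out: Set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.genes
        return out

    def set_bounds(self, rxn_id: str, lower: Optional[float] = None,
                   upper: Optional[float] = None) -> None:
        rxn = self.reaction(rxn_id)
        if lower is not None:
            rxn.lower_bound = lower
        if upper is not None:
            rxn.upper_bound = upper
        rxn.validate()

    # -- integrity --------------------------------------------------------
    def validate(self) -> None:
        for met in self.metabolites.values():
            met.validate()
        for rxn in self.reactions.values():
            rxn.validate()
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ValueError(
                        f"{rxn.id}: unresolved metabolite {met_id!r}")
            if rxn.is_exchange:
                if len(rxn.stoichiometry) != 1:
                    raise ValueError(
                        f"exchange {rxn.id} touches "
                        f"{len(rxn.stoichiometry)} metabolites")
                (met_id,) = rxn.stoichiometry
                if self.metabolites[met_id].compartment != "e":
                    raise ValueError(
                        f"exchange {rxn.id} metabolite {met_id} is not "
                        "extracellular")
        if self.objective_id is not None and \
                self.objective_id not in self.reactions:
            raise ValueError(
                f"objective {self.objective_id!r} not among reactions")
        if not self.gene_ids >= self.genes_in_rules():
            raise ValueError("gene_ids does not cover genes in gene rules")

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            self.id,
            (m.copy() for m in self.metabolites.values()),
            (r.copy() for r in self.reactions.values()),
            objective_id=self.objective_id,
            gene_ids=set(self.gene_ids),
            name=self.name,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<MetabolicModel {self.id}: {len(self.metabolites)} "
                f"metabolites, {len(self.reactions)} reactions, "
                f"{len(self.gene_ids)} genes>")


def stoichiometric_matrix(
    model: MetabolicModel,
) -> Tuple[np.ndarray, Dict[str, int], Dict[str, int]]:
    """Dense stoichiometric matrix ``S`` (metabolites x reactions).

    Returns ``(S, met_index, rxn_index)`` where ``S[i, j]`` is the
    coefficient of metabolite ``i`` in reaction ``j`` and the index maps
    give row/column positions by identifier.  Ordering follows insertion
    order of the model and is therefore deterministic.
    """
    met_index = {m: i for i, m in enumerate(model.metabolites)}
    rxn_index = {r: j for j, r in enumerate(model.reactions)}
    S = np.zeros((len(met_index), len(rxn_index)))
    for rxn_id, rxn in model.reactions.items():
        j = rxn_index[rxn_id]
        for met_id, coef in rxn.stoichiometry.items():
            S[met_index[met_id], j] = coef
    return S, met_index, rxn_index
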