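"""Internal helper for assembling elementally balanced synthetic models."""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

from ..model import MetabolicModel, Metabolite, Reaction
from .species import SPECIES, met

__all__ = ["ModelBuilder"]

#: Elements tracked by the closure solver (S must balance from the mains).
_ELEMENTS = ("C", "H", "N", "O", "P")

# Free balancing species available to `balanced`: columns of the closure
# system, each given as its element/charge vector when *produced*.
_FREE = {
    "co2_c": {"C": 1, "O": 2, "charge": 0},
    "nh4_c": {"N": 1, "H": 4, "charge": 1},
    "pi_c": {"H": 1, "O": 4, "P": 1, "charge": -2},
    "h2o_c": {"H": 2, "O": 1, "charge": 0},
    "h_c": {"H": 1, "charge": 1},
    # one net redox step: NAD+ produced, NADH consumed
    "redox": {"H": -1, "charge": 1},
}


class ModelBuilder:
    """Accumulates metabolites and reactions into a MetabolicModel.

    Species are drawn from the registry by ``<species>_<compartment>`` id;
    the builder instantiates them on first use.  ``balanced`` closes the
    element/charge books of a lumped reaction by solving for CO2, NH4+,
    phosphate, water, protons and one NADH/NAD+ redox step, so every
    generated internal reaction passes the mass/charge audit by
    construction.
    """

    def __init__(self, model_id: str, name: str = ""):
        self.model = MetabolicModel(model_id, name=name or model_id)

    # -- species ----------------------------------------------------------
    def ensure(self, full_id: str) -> Metabolite:
        if full_id in self.model.metabolites:
            return self.model.metabolites[full_id]
        species_id, _, comp = full_id.rpartition("_")
        if species_id not in SPECIES:
            raise KeyError(f"unknown species {species_id!r} (from {full_id!r})")
        return self.model.add_metabolite(met(species_id, comp))

    def pseudo(self, full_id: str, name: str, formula: Dict[str, float],
               charge: float, compartment: str = "c") -> Metabolite:
        """Register a pseudo-species with an explicit composite formula."""
        if full_id in self.model.metabolites:
            return self.model.metabolites[full_id]
        return self.model.add_metabolite(Metabolite(
            id=full_id, name=name, compartment=compartment,
            formula={k: v for k, v in formula.items() if abs(v) > 1e-12},
            charge=charge))

    # -- reactions ----------------------------------------------------------
    def rxn(self, rxn_id: str, stoich: Dict[str, float],
            lb: float = 0.0, ub: float = 1000.0, name: str = "",
            subsystem: str = "", gene_rule: str = "", ec: tuple = (),
            is_exchange: bool = False) -> Reaction:
        for full_id in stoich:
            self.ensure(full_id)
        return self.model.add_reaction(Reaction(
            id=rxn_id, stoichiometry=dict(stoich), lower_bound=lb,
            upper_bound=ub, name=name or rxn_id, subsystem=subsystem,
            gene_rule=gene_rule, ec_numbers=list(ec),
            is_exchange=is_exchange))

    def exchange(self, species_id: str, lb: float = 0.0,
                 ub: float = 1000.0) -> Reaction:
        full_id = f"{species_id}_e"
        self.ensure(full_id)
        return self.rxn(f"EX_{species_id}_e", {full_id: -1.0}, lb=lb, ub=ub,
                        name=f"{SPECIES[species_id][0]} exchange",
                        subsystem="Exchange", is_exchange=True)

    def balanced(self, rxn_id: str, mains: Dict[str, float],
                 atp_cost: float = 0.0, **kwargs) -> Reaction:
        """Add a lumped reaction, auto-closing element and charge balances.

        ``mains`` holds the fixed part of the stoichiometry (negative =
        consumed).  The solver determines the co-substrate coefficients of
        CO2, NH4+, Pi, H2O, H+ and one NADH/NAD+ couple so that C, H, N, O,
        P and charge all balance exactly; sulfur must already balance in
        the mains.  ``atp_cost`` adds n * (ATP + H2O -> ADP + Pi + H+),
        which is element-neutral.
        """
        residual = {el: 0.0 for el in _ELEMENTS}
        residual["charge"] = 0.0
        s_resid = 0.0
        for full_id, coef in mains.items():
            species = self.ensure(full_id)
            for el, count in species.formula.items():
                if el == "S":
                    s_resid += coef * count
                elif el in residual:
                    residual[el] += coef * count
                else:
                    raise ValueError(
                        f"{rxn_id}: element {el} not closable by the lump "
                        "solver")
            residual["charge"] += coef * species.charge
        if abs(s_resid) > 1e-9:
            raise ValueError(f"{rxn_id}: sulfur does not balance in mains "
                             f"(residual {s_resid:g})")

        keys = ("C", "H", "N", "O", "P", "charge")
        A = np.array([[_FREE[sp].get(k, 0.0) for sp in _FREE] for k in keys])
        b = -np.array([residual[k] for k in keys])
        x = np.linalg.solve(A, b)

        stoich = dict(mains)

        def add(full_id: str, coef: float) -> None:
            stoich[full_id] = stoich.get(full_id, 0.0) + coef

        for sp, coef in zip(_FREE, x):
            if sp == "redox":
                add("nad_c", coef)
                add("nadh_c", -coef)
            else:
                add(sp, coef)
        if atp_cost:
            add("atp_c", -atp_cost)
            add("h2o_c", -atp_cost)
            add("adp_c", atp_cost)
            add("pi_c", atp_cost)
            add("h_c", atp_cost)
        stoich = {m: round(c, 9) for m, c in stoich.items()
                  if abs(c) > 1e-9}
        return self.rxn(rxn_id, stoich, **kwargs)

    def recipe_pseudo(self, full_id: str, name: str,
                      consumed: Dict[str, float],
                      released: Dict[str, float]) -> Metabolite:
        """Define a pseudo-species as an exact element sum of a recipe.

        The species' formula and charge are set to
        ``sum(consumed) - sum(released)`` so the synthesis reaction
        ``consumed -> pseudo + released`` balances by construction.
        """
        formula: Dict[str, float] = {}
        charge = 0.0
        for table, sign in ((consumed, 1.0), (released, -1.0)):
            for mid, coef in table.items():
                species = self.ensure(mid)
                for el, count in species.formula.items():
                    formula[el] = formula.get(el, 0.0) + sign * coef * count
                charge += sign * coef * species.charge
        negative = {el: n for el, n in formula.items() if n < -1e-9}
        if negative:
            raise ValueError(f"recipe for {full_id!r} implies negative "
                             f"element counts: {negative}")
        return self.pseudo(full_id, name,
                           {el: round(n, 9) for el, n in formula.items()
                            if n > 1e-9},
                           round(charge, 9))

    def recipe_synthesis(self, rxn_id: str, product_id: str,
                         consumed: Dict[str, float],
                         released: Dict[str, float],
                         atp_cost: float = 0.0, **kwargs) -> Reaction:
        """Synthesis reaction matching a `recipe_pseudo` definition."""
        stoich = {mid: -coef for mid, coef in consumed.items()}
        for mid, coef in released.items():
            stoich[mid] = stoich.get(mid, 0.0) + coef
        stoich[product_id] = stoich.get(product_id, 0.0) + 1.0
        if atp_cost:
            for mid, sign in (("atp_c", -1), ("h2o_c", -1), ("adp_c", 1),
                              ("pi_c", 1), ("h_c", 1)):
                self.ensure(mid)
                stoich[mid] = stoich.get(mid, 0.0) + sign * atp_cost
        stoich = {m: c for m, c in stoich.items() if abs(c) > 1e-10}
        return self.rxn(rxn_id, stoich, **kwargs)

    def build(self, objective_id: Optional[str] = None) -> MetabolicModel:
        if objective_id is not None:
            self.model.objective_id = objective_id
        self.model.validate()
        return self.model
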