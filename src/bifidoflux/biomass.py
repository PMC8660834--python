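"""Compile a biomass objective function (BOF) from cell composition.

The BOF is a pseudo-reaction draining biosynthetic monomers in the molar
proportions needed to form one gram of cell dry weight (CDW), plus the
growth-associated maintenance (GAM) ATP hydrolysis.  Its flux therefore has
units of h^-1 (grams of biomass per gram of biomass per hour), and each
monomer coefficient is mmol gCDW^-1.

Composition input follows common bacterial BOF practice: macromolecular
mass fractions (protein, DNA, RNA, carbohydrate, cell-wall polymers,
lipids, ions, soluble pool) that sum to one gram per gram CDW, and per
category a monomer table of mole fractions.  Polymer categories use
polymerized (water-subtracted) residue masses; condensation water is
released stoichiometrically so that the reaction consumes exactly 1.000 g
of monomer mass per unit flux.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Union

import yaml

from .model import (ATOMIC_MASSES, MetabolicModel, Metabolite, Reaction,
                    formula_weight)

__all__ = ["BiomassComposition", "ElementalSummary", "build_bof", "set_gam",
           "elemental_summary", "load_composition", "save_composition"]

_WATER_MW = 2 * ATOMIC_MASSES["H"] + ATOMIC_MASSES["O"]

#: Species taking part in GAM hydrolysis (ATP + H2O -> ADP + Pi + H+).
GAM_SPECIES = ("atp_c", "h2o_c", "adp_c", "pi_c", "h_c")


@dataclass
class BiomassComposition:
    """Macromolecular composition of one gram of cell dry weight.

    Attributes
    ----------
    fractions : mass fraction (g/gCDW) per macro-category; must sum to 1.
    monomer_tables : per category, metabolite id -> mole fraction
        (each table sums to 1).
    monomer_masses : metabolite id -> mass used for the category weighting
        (g/mol); polymerized residue mass for polymers, free mass for the
        soluble pool and ions.
    gam : growth-associated maintenance, mmol ATP hydrolyzed per gCDW.
    name : free-text label.
    """

    fractions: Dict[str, float]
    monomer_tables: Dict[str, Dict[str, float]]
    monomer_masses: Dict[str, float]
    gam: float = 0.0
    name: str = ""

    def validate(self, tol: float = 1e-6) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > tol:
            raise ValueError(
                f"mass fractions sum to {total:.8f}, expected 1 +/- {tol}")
        for cat, frac in self.fractions.items():
            if frac < 0:
                raise ValueError(f"negative mass fraction for {cat!r}")
            if frac > 0 and cat not in self.monomer_tables:
                raise ValueError(f"category {cat!r} has no monomer table")
        for cat, table in self.monomer_tables.items():
            ssum = sum(table.values())
            if abs(ssum - 1.0) > tol:
                raise ValueError(
                    f"mole fractions of {cat!r} sum to {ssum:.8f}, expected 1")
            for met in table:
                mass = self.monomer_masses.get(met)
                if mass is None:
                    raise ValueError(f"no monomer mass for {met!r} ({cat})")
                if mass <= 0:
                    raise ValueError(f"non-positive mass for {met!r}")
        if self.gam < 0:
            raise ValueError("GAM must be non-negative")

    def category_residue_mass(self, category: str) -> float:
        """Mole-fraction weighted residue mass of a category (g/mol)."""
        table = self.monomer_tables[category]
        return sum(frac * self.monomer_masses[met]
                   for met, frac in table.items())


@dataclass
class ElementalSummary:
    """Per-carbon-mole elemental formula and weight of biomass."""

    formula: Dict[str, float]
    molecular_weight: float  # g per C-mol

    def __post_init__(self) -> None:
        if abs(self.formula.get("C", 0.0) - 1.0) > 1e-9:
            raise ValueError("formula must be normalized to one carbon")
        if self.molecular_weight <= 0:
            raise ValueError("molecular weight must be positive")


def build_bof(composition: BiomassComposition,
              catalogue: Mapping[str, Metabolite],
              biomass_met: str = "biomass_c",
              reaction_id: str = "BIOMASS",
              water_id: str = "h2o_c") -> Reaction:
    """Compile the biomass reaction from a composition.

    The coefficient of monomer ``m`` in category ``cat`` is
    ``1000 * fraction(cat) * molefrac(m) / weighted_residue_mass(cat)``
    (mmol/gCDW, consumed).  Condensation water is released per polymerized
    residue, GAM hydrolysis species are added at the GAM stoichiometry, and
    one unit of the biomass pseudo-metabolite is produced.  The net consumed
    monomer mass is 1 g per unit flux to within 1e-4.
    """
    composition.validate()
    stoich: Dict[str, float] = {}

    def add(met: str, coef: float) -> None:
        stoich[met] = stoich.get(met, 0.0) + coef

    for cat, frac in composition.fractions.items():
        if frac == 0:
            continue
        residue_mass = composition.category_residue_mass(cat)
        for met, molefrac in composition.monomer_tables[cat].items():
            if molefrac == 0:
                continue
            if met not in catalogue:
                raise KeyError(
                    f"monomer {met!r} (category {cat!r}) is not in the "
                    "metabolite catalogue")
            coef = 1000.0 * frac * molefrac / residue_mass
            add(met, -coef)
            free_mass = formula_weight(catalogue[met].formula)
            if free_mass <= 0:
                raise ValueError(f"monomer {met!r} carries no usable formula")
            water = (free_mass - composition.monomer_masses[met]) / _WATER_MW
            if water > 1e-9:
                add(water_id, coef * water)

    if composition.gam > 0:
        for met, sign in (("atp_c", -1), (water_id, -1), ("adp_c", 1),
                          ("pi_c", 1), ("h_c", 1)):
            if met not in catalogue:
                raise KeyError(f"GAM species {met!r} missing from catalogue")
            add(met, sign * composition.gam)

    if biomass_met not in catalogue:
        raise KeyError(f"biomass pseudo-metabolite {biomass_met!r} missing "
                       "from catalogue")
    add(biomass_met, 1.0)
    # 12-decimal rounding keeps coefficients exactly serializable
    stoich = {m: round(c, 12) for m, c in stoich.items() if abs(c) > 1e-12}

    rxn = Reaction(id=reaction_id, stoichiometry=stoich,
                   lower_bound=0.0, upper_bound=1000.0,
                   name=f"Biomass formation ({composition.name})".strip(),
                   subsystem="Biomass and maintenance")

    consumed_mass = -sum(
        coef * formula_weight(catalogue[met].formula)
        for met, coef in stoich.items() if met != biomass_met) / 1000.0
    if abs(consumed_mass - 1.0) > 1e-4:
        raise ValueError(
            f"biomass reaction consumes {consumed_mass:.6f} g per unit flux; "
            "expected 1.0000 (check formulas and residue masses)")
    return rxn


def set_gam(model: MetabolicModel, gam: float,
            biomass_id: Optional[str] = None) -> MetabolicModel:
    """Return a copy of the model with GAM set to ``gam`` mmol ATP/gCDW.

    The hydrolysis component of the biomass reaction is identified by its
    ADP production (monomer drains never produce ADP); ATP, ADP, Pi, H2O
    and H+ coefficients are shifted accordingly and all other coefficients
    stay untouched.  Idempotent.
    """
    if gam < 0:
        raise ValueError("GAM must be non-negative")
    biomass_id = biomass_id or model.objective_id
    if biomass_id is None or biomass_id not in model.reactions:
        raise ValueError("no biomass reaction identified on the model")
    new = model.copy()
    rxn = new.reaction(biomass_id)
    current = rxn.stoichiometry.get("adp_c", 0.0)
    delta = gam - current
    for met, sign in (("atp_c", -1), ("h2o_c", -1), ("adp_c", 1),
                      ("pi_c", 1), ("h_c", 1)):
        rxn.stoichiometry[met] = round(
            rxn.stoichiometry.get(met, 0.0) + sign * delta, 12)
    rxn.stoichiometry = {m: c for m, c in rxn.stoichiometry.items()
                         if abs(c) > 1e-12}
    return new


def elemental_summary(bof: Reaction, catalogue: Mapping[str, Metabolite],
                      biomass_met: str = "biomass_c") -> ElementalSummary:
    """Elemental formula per C-mol and weight (g/C-mol) of the biomass.

    Element flows into biomass are the net consumption over the BOF
    (consumed monomers minus released water/ADP/Pi); GAM hydrolysis is
    element-neutral and cancels.  The formula is normalized to one carbon;
    the weight is the per-C-mol mass of that formula.
    """
    flows: Dict[str, float] = {}
    charge = 0.0
    for met, coef in bof.stoichiometry.items():
        if met == biomass_met:
            continue
        species = catalogue.get(met)
        if species is None:
            raise KeyError(f"species {met!r} missing from catalogue")
        if not species.formula:
            raise ValueError(f"species {met!r} carries no formula; cannot "
                             "summarize biomass elementally")
        for el, count in species.formula.items():
            flows[el] = flows.get(el, 0.0) - coef * count
        charge -= coef * species.charge
    carbon = flows.get("C", 0.0)
    if carbon <= 0:
        raise ValueError("biomass contains no net carbon")
    formula = {el: n / carbon for el, n in flows.items() if abs(n) > 1e-9}
    formula["C"] = 1.0
    weight = sum(ATOMIC_MASSES[el] * n for el, n in formula.items())
    return ElementalSummary(formula=formula, molecular_weight=weight)


# ---------------------------------------------------------------------------
# structured-text serialization
# ---------------------------------------------------------------------------

def load_composition(path: Union[str, Path]) -> BiomassComposition:
    """Load a composition from YAML (or JSON, a YAML subset)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    comp = BiomassComposition(
        fractions={k: float(v) for k, v in raw["fractions"].items()},
        monomer_tables={c: {m: float(x) for m, x in t.items()}
                        for c, t in raw["monomer_tables"].items()},
        monomer_masses={m: float(x)
                        for m, x in raw["monomer_masses"].items()},
        gam=float(raw.get("gam", 0.0)),
        name=raw.get("name", ""))
    comp.validate()
    return comp


def save_composition(composition: BiomassComposition,
                     path: Union[str, Path]) -> None:
    composition.validate()
    payload = {
        "name": composition.name,
        "gam": composition.gam,
        "fractions": composition.fractions,
        "monomer_tables": composition.monomer_tables,
        "monomer_masses": composition.monomer_masses,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
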