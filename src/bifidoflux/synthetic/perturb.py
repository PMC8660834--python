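"""Deliberately broken models for QC testing.

Each injector takes a healthy base model and plants exactly one labeled
defect, returning the modified copy together with the ground truth, so that
the structural audits (balance check, gap finder, loop finder) can be
scored against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ..model import MetabolicModel, Metabolite, Reaction

__all__ = ["Defect", "make_broken_model", "DEFECT_KINDS"]

DEFECT_KINDS = ("unbalance", "dead_end", "loop")


@dataclass
class Defect:
    """Ground-truth label of one injected defect."""

    kind: str
    reaction_id: Optional[str] = None   # unbalance / loop
    metabolite_id: Optional[str] = None  # dead_end


def _internal_reactions(model: MetabolicModel):
    exempt = model.boundary_like()
    return [r for r in model.reactions.values() if r.id not in exempt]


def make_broken_model(base: MetabolicModel, defect: str,
                      seed: int = 0) -> tuple[MetabolicModel, Defect]:
    """Copy of ``base`` with exactly one labeled defect injected.

    * ``unbalance``: perturbs one stoichiometric coefficient of a random
      internal reaction, breaking its element balance.
    * ``dead_end``: adds a new metabolite produced by one new reaction and
      consumed by nothing (a no-consumption dead end; it is also blocked).
    * ``loop``: adds a reversed duplicate of a random irreversible internal
      reaction, creating a two-reaction internal cycle.
    """
    if defect not in DEFECT_KINDS:
        raise ValueError(f"unsupported defect {defect!r}; "
                         f"choose from {DEFECT_KINDS}")
    rng = np.random.default_rng(seed)
    model = base.copy()

    if defect == "unbalance":
        candidates = [r for r in _internal_reactions(model)
                      if all(model.metabolite(m).formula
                             for m in r.stoichiometry)]
        rxn = candidates[rng.integers(len(candidates))]
        met_id = sorted(rxn.stoichiometry)[
            rng.integers(len(rxn.stoichiometry))]
        # shifting one coefficient by a non-integer offset cannot be
        # compensated by any other species in the reaction
        rxn.stoichiometry[met_id] += 0.5
        if abs(rxn.stoichiometry[met_id]) < 1e-9:
            rxn.stoichiometry[met_id] += 0.5
        return model, Defect(kind="unbalance", reaction_id=rxn.id)

    if defect == "dead_end":
        donors = [m for m in model.metabolites.values()
                  if m.compartment == "c" and m.formula]
        donor = donors[rng.integers(len(donors))]
        orphan = Metabolite(id="orphan_defect_c",
                            name="dead-end metabolite (injected)",
                            compartment="c", formula=dict(donor.formula),
                            charge=donor.charge)
        model.add_metabolite(orphan)
        model.add_reaction(Reaction(
            id="ORPHANS", stoichiometry={donor.id: -1.0, orphan.id: 1.0},
            lower_bound=0.0, upper_bound=1000.0,
            name="orphan-producing reaction (injected)"))
        return model, Defect(kind="dead_end", metabolite_id=orphan.id)

    # loop: reversed duplicate of an irreversible internal reaction
    candidates = [r for r in _internal_reactions(model)
                  if r.lower_bound >= 0 and r.upper_bound > 0]
    rxn = candidates[rng.integers(len(candidates))]
    dup = Reaction(
        id=f"{rxn.id}_rev_dup",
        stoichiometry={m: -c for m, c in rxn.stoichiometry.items()},
        lower_bound=0.0, upper_bound=rxn.upper_bound,
        name=f"reversed duplicate of {rxn.id} (injected)")
    model.add_reaction(dup)
    return model, Defect(kind="loop", reaction_id=rxn.id)
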