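"""Shared fixtures: generated models and random-model helpers."""

from __future__ import annotations

import numpy as np
import pytest

from bifidoflux.model import MetabolicModel, Metabolite, Reaction
from bifidoflux.synthetic import (CoreModelSpec, make_core_model,
                                  make_strain_model)


@pytest.fixture(scope="session")
def core_model():
    return make_core_model()


@pytest.fixture(scope="session")
def core_biomass_model():
    return make_core_model(CoreModelSpec(include_pts_and_symport=True,
                                         include_biomass_drain=True))


@pytest.fixture(scope="session")
def bb12():
    return make_strain_model("BB-12")


@pytest.fixture(scope="session")
def bb46():
    return make_strain_model("BB-46")


def random_model(rng: np.random.Generator, n_mets: int = 4,
                 n_rxns: int = 5, with_formulas: bool = True,
                 bounded: bool = True) -> MetabolicModel:
    """Small random connected network with finite bounds.

    Metabolite formulas are built so arbitrary stoichiometries remain
    representable (elements C and H only); exchanges are attached to a
    random subset of metabolites placed extracellularly.
    """
    mets = []
    n_ext = max(1, n_mets // 3)
    for i in range(n_mets):
        comp = "e" if i < n_ext else "c"
        formula = {"C": int(rng.integers(1, 5)),
                   "H": int(rng.integers(1, 9))} if with_formulas else {}
        mets.append(Metabolite(id=f"m{i}_{comp}", compartment=comp,
                               formula=formula,
                               charge=float(rng.integers(-2, 3))))
    rxns = []
    for j in range(n_rxns):
        size = int(rng.integers(2, min(4, n_mets) + 1))
        chosen = rng.choice(n_mets, size=size, replace=False)
        stoich = {}
        for k, idx in enumerate(chosen):
            coef = float(rng.integers(1, 3))
            stoich[mets[idx].id] = -coef if k % 2 == 0 else coef
        lb = float(rng.choice([-10.0, 0.0]))
        ub = float(rng.choice([5.0, 10.0])) if bounded else 1000.0
        rxns.append(Reaction(id=f"r{j}", stoichiometry=stoich,
                             lower_bound=lb, upper_bound=ub,
                             gene_rule=("gA and gB" if j % 3 == 0 else ""),
                             subsystem=f"sub{j % 2}",
                             ec_numbers=["1.1.1.1"] if j % 2 else []))
    for i in range(n_ext):
        rxns.append(Reaction(id=f"EX_m{i}_e",
                             stoichiometry={f"m{i}_e": -1.0},
                             lower_bound=float(rng.choice([-10.0, 0.0])),
                             upper_bound=10.0, is_exchange=True))
    return MetabolicModel(f"random_{rng.integers(1 << 30)}", mets, rxns,
                          objective_id=rxns[0].id)
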