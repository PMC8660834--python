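"""Flux balance analysis over stoichiometric models.

FBA finds a steady-state flux vector ``v`` (``S @ v == 0``) within the flux
bounds that maximizes (or minimizes) the flux of an objective reaction,
solved as a linear program with the HiGHS solver.  On top of plain FBA this
module provides:

* homogeneous ratio constraints (``v_num - r * v_den == 0``), used to pin
  fermentation product ratios such as acetate:lactate;
* parsimonious FBA (pFBA): total absolute flux minimization at a fixed
  optimal objective, giving reproducible secretion profiles among the
  usually degenerate alternate optima;
* structural sanity analyses: energy/matter generation from nothing,
  internal (type III) flux loops, and dead-end / blocked metabolite
  detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel, stoichiometric_matrix

__all__ = [
    "FBAResult", "RatioConstraint", "LoopReport", "GapReport",
    "solve_fba", "parsimonious_fluxes", "flux_variability",
    "find_internal_loops", "find_gaps", "atp_yield",
]

#: Solver feasibility/optimality tolerance handed to HiGHS.
SOLVER_TOL = 1e-9
#: Tolerance at which a reported flux is considered non-zero.
FLUX_TOL = 1e-6

_HIGHS_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": SOLVER_TOL,
    "dual_feasibility_tolerance": SOLVER_TOL,
}

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible",
           3: "unbounded", 4: "numerical"}


@dataclass
class RatioConstraint:
    """Fix the flux ratio ``v_numerator / v_denominator`` to ``ratio``.

    Encoded as the homogeneous equality ``v_num - ratio * v_den = 0`` so it
    also admits the all-zero solution.
    """

    numerator_rxn: str
    denominator_rxn: str
    ratio: float

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")


@dataclass
class FBAResult:
    """Solver status, objective value and the full flux vector."""

    status: str
    objective_value: Optional[float]
    fluxes: Dict[str, float] = field(default_factory=dict)
    objective_id: Optional[str] = None
    degenerate: bool = False

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    def nonzero(self, tol: float = FLUX_TOL) -> Dict[str, float]:
        return {r: v for r, v in self.fluxes.items() if abs(v) > tol}


@dataclass
class LoopReport:
    """Reactions able to carry flux with every boundary reaction closed."""

    looped_reactions: Set[str] = field(default_factory=set)


@dataclass
class GapReport:
    """Dead-end and blocked metabolites.

    ``no_production`` / ``no_consumption`` are structural verdicts from the
    sign pattern of ``S`` and the bound directions; ``blocked`` collects
    metabolites whose maximal production flux through a temporary sink is
    (numerically) zero.
    """

    no_production: Set[str] = field(default_factory=set)
    no_consumption: Set[str] = field(default_factory=set)
    blocked: Set[str] = field(default_factory=set)


def _assemble(model: MetabolicModel,
              extra_constraints: Sequence[RatioConstraint] = ()):
    S, met_index, rxn_index = stoichiometric_matrix(model)
    rows = [S]
    for rc in extra_constraints:
        row = np.zeros((1, S.shape[1]))
        row[0, rxn_index[rc.numerator_rxn]] = 1.0
        row[0, rxn_index[rc.denominator_rxn]] = -rc.ratio
        rows.append(row)
    A_eq = np.vstack(rows)
    b_eq = np.zeros(A_eq.shape[0])
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions.values()]
    return A_eq, b_eq, bounds, rxn_index


def solve_fba(model: MetabolicModel,
              objective_id: Optional[str] = None,
              sense: str = "max",
              extra_constraints: Sequence[RatioConstraint] = ()) -> FBAResult:
    """Optimize one reaction flux subject to steady state and bounds.

    Parameters
    ----------
    model : the stoichiometric model (not modified).
    objective_id : reaction to optimize; defaults to ``model.objective_id``.
    sense : ``"max"`` or ``"min"``.
    extra_constraints : homogeneous flux-ratio equalities.

    A numerically failed solve is propagated via ``status``; an optimum is
    never fabricated.
    """
    objective_id = objective_id or model.objective_id
    if objective_id is None:
        raise ValueError("no objective reaction given and none set on model")
    if objective_id not in model.reactions:
        raise KeyError(f"objective {objective_id!r} not in model {model.id!r}")
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")

    A_eq, b_eq, bounds, rxn_index = _assemble(model, extra_constraints)
    c = np.zeros(A_eq.shape[1])
    c[rxn_index[objective_id]] = -1.0 if sense == "max" else 1.0
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs",
                  options=_HIGHS_OPTIONS)
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FBAResult(status=status, objective_value=None,
                         objective_id=objective_id)
    fluxes = {rid: float(res.x[j]) for rid, j in rxn_index.items()}
    return FBAResult(status="optimal",
                     objective_value=float(fluxes[objective_id]),
                     fluxes=fluxes, objective_id=objective_id)


def parsimonious_fluxes(model: MetabolicModel,
                        objective_id: Optional[str] = None,
                        sense: str = "max",
                        extra_constraints: Sequence[RatioConstraint] = (),
                        ) -> FBAResult:
    """Parsimonious FBA: fix the FBA optimum, minimize total absolute flux.

    The primary objective is first optimized; its value is then fixed (as a
    two-sided bound at the optimum) and ``sum_j |v_j|`` is minimized by
    splitting each flux into forward/backward non-negative parts.  The
    returned flux vector is unique up to residual degeneracy; a cheap
    two-solve probe sets ``degenerate=True`` when distinct minimizers are
    detected.
    """
    primary = solve_fba(model, objective_id, sense, extra_constraints)
    if not primary.optimal:
        return primary
    objective_id = primary.objective_id
    opt = primary.objective_value

    A_eq, b_eq, bounds, rxn_index = _assemble(model, extra_constraints)
    n = A_eq.shape[1]
    j_obj = rxn_index[objective_id]
    # Split v = p - q with p, q >= 0; objective min sum(p + q).
    A_split = np.hstack([A_eq, -A_eq])
    split_bounds = []
    for lb, ub in bounds:
        split_bounds.append((max(lb, 0.0), max(ub, 0.0)))
    for lb, ub in bounds:
        split_bounds.append((max(-ub, 0.0), max(-lb, 0.0)))
    # Fix the objective flux at its optimum (tiny slack for LP round-off).
    slack = 1e-9 * max(1.0, abs(opt))
    lo, hi = opt - slack, opt + slack
    split_bounds[j_obj] = (max(split_bounds[j_obj][0], 0.0),
                           split_bounds[j_obj][1])
    row = np.zeros((1, 2 * n))
    row[0, j_obj], row[0, n + j_obj] = 1.0, -1.0
    A_ub = np.vstack([row, -row])
    b_ub = np.array([hi, -lo])

    def _solve(weights: np.ndarray):
        res = linprog(weights, A_ub=A_ub, b_ub=b_ub, A_eq=A_split, b_eq=b_eq,
                      bounds=split_bounds, method="highs",
                      options=_HIGHS_OPTIONS)
        return res

    w = np.ones(2 * n)
    res = _solve(w)
    if res.status != 0:
        return FBAResult(status=_STATUS.get(res.status, "numerical"),
                         objective_value=None, objective_id=objective_id)
    v = res.x[:n] - res.x[n:]

    # Degeneracy probe: re-solve with deterministically perturbed weights at
    # the same total-flux optimum; a different flux vector flags ties.
    total = float(res.x.sum())
    rng = np.random.default_rng(0)
    w2 = 1.0 + 1e-6 * rng.random(2 * n)
    A_ub2 = np.vstack([A_ub, np.ones((1, 2 * n))])
    b_ub2 = np.append(b_ub, total + 1e-7 * max(1.0, total))
    res2 = linprog(w2, A_ub=A_ub2, b_ub=b_ub2, A_eq=A_split, b_eq=b_eq,
                   bounds=split_bounds, method="highs",
                   options=_HIGHS_OPTIONS)
    degenerate = False
    if res2.status == 0:
        v2 = res2.x[:n] - res2.x[n:]
        degenerate = bool(np.max(np.abs(v2 - v)) > 1e-4)

    fluxes = {rid: float(v[j]) for rid, j in rxn_index.items()}
    return FBAResult(status="optimal",
                     objective_value=float(fluxes[objective_id]),
                     fluxes=fluxes, objective_id=objective_id,
                     degenerate=degenerate)


def flux_variability(model: MetabolicModel, reaction_ids: Iterable[str],
                     extra_constraints: Sequence[RatioConstraint] = (),
                     ) -> Dict[str, Tuple[float, float]]:
    """Minimal FVA: per reaction, the feasible flux minimum and maximum."""
    A_eq, b_eq, bounds, rxn_index = _assemble(model, extra_constraints)
    out: Dict[str, Tuple[float, float]] = {}
    for rid in reaction_ids:
        c = np.zeros(A_eq.shape[1])
        c[rxn_index[rid]] = 1.0
        lohi = []
        for sign in (1.0, -1.0):
            res = linprog(sign * c, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
                          method="highs", options=_HIGHS_OPTIONS)
            lohi.append(float(sign * res.fun) if res.status == 0 else np.nan)
        out[rid] = (lohi[0], lohi[1])
    return out


def _closed_copy(model: MetabolicModel) -> MetabolicModel:
    closed = model.copy()
    for rid in closed.boundary_like():
        closed.set_bounds(rid, 0.0, 0.0)
    return closed


def find_internal_loops(model: MetabolicModel,
                        tol: float = FLUX_TOL) -> LoopReport:
    """Detect internal (type III) flux cycles.

    All boundary reactions (exchanges, demands/sinks, biomass) are closed
    and each remaining reaction's flux is maximized and minimized; any
    reaction attaining ``|v| > tol`` participates in a cycle that performs
    no net conversion.
    """
    closed = _closed_copy(model)
    internal = [r.id for r in closed.reactions.values()
                if r.id not in closed.boundary_like()]
    report = LoopReport()
    for rid, (lo, hi) in flux_variability(closed, internal).items():
        if max(abs(lo), abs(hi)) > tol:
            report.looped_reactions.add(rid)
    return report


def find_gaps(model: MetabolicModel, medium_exchanges_open: bool = True,
              tol: float = FLUX_TOL, flux_test: bool = True) -> GapReport:
    """Dead-end (no production / no consumption) and blocked metabolites.

    Structural verdicts consider reaction directionality: a reaction can
    produce metabolite ``i`` if its coefficient is positive and the upper
    bound allows forward flux, or negative with a negative lower bound.
    With ``medium_exchanges_open`` every exchange is treated as reversible
    (any extracellular species may be supplied or removed); otherwise
    current bounds apply.  The flux test adds a temporary sink per
    metabolite and maximizes its flux; a metabolite is blocked iff the
    optimum is below ``tol``.  Note that conserved cofactor moieties
    without a synthesis route (e.g. the adenylate pool of a catabolism-only
    network) are blocked under this definition even though their reactions
    carry flux.  ``flux_test=False`` skips the per-metabolite LPs and
    returns only the structural sets.
    """
    probe = model.copy()
    if medium_exchanges_open:
        for rxn in probe.exchanges:
            rxn.lower_bound, rxn.upper_bound = -abs(1000.0), abs(1000.0)

    report = GapReport()
    producers: Dict[str, int] = {m: 0 for m in probe.metabolites}
    consumers: Dict[str, int] = {m: 0 for m in probe.metabolites}
    for rxn in probe.reactions.values():
        fwd = rxn.upper_bound > tol
        rev = rxn.lower_bound < -tol
        for met_id, coef in rxn.stoichiometry.items():
            if (coef > 0 and fwd) or (coef < 0 and rev):
                producers[met_id] += 1
            if (coef < 0 and fwd) or (coef > 0 and rev):
                consumers[met_id] += 1
    report.no_production = {m for m, k in producers.items() if k == 0}
    report.no_consumption = {m for m, k in consumers.items() if k == 0}

    if not flux_test:
        return report
    from .model import Reaction  # local import avoids cycle at module load
    for met_id in probe.metabolites:
        sink_id = "__probe_sink__"
        probe.reactions[sink_id] = Reaction(
            id=sink_id, stoichiometry={met_id: -1.0},
            lower_bound=0.0, upper_bound=1000.0)
        result = solve_fba(probe, objective_id=sink_id, sense="max")
        del probe.reactions[sink_id]
        if not result.optimal or result.objective_value <= tol:
            report.blocked.add(met_id)
    return report


def atp_yield(model: MetabolicModel, result: FBAResult,
              hexose_uptake_flux: float,
              atp_id: str = "atp_c",
              maintenance_ids: Sequence[str] = ("ATPM",)) -> float:
    """Net ATP formed per hexose equivalent consumed.

    Sums ``S[atp, j] * v_j`` over all reactions except the maintenance
    drains, then divides by the hexose-equivalent uptake flux (a
    disaccharide of two hexoses counts twice).  Requires an optimal result
    and a non-zero uptake.
    """
    if not result.optimal:
        raise ValueError("atp_yield requires an optimal FBA result")
    if abs(hexose_uptake_flux) < FLUX_TOL:
        raise ValueError("hexose uptake flux is zero; ATP yield undefined")
    net = 0.0
    for rxn_id, rxn in model.reactions.items():
        if rxn_id in maintenance_ids:
            continue
        coef = rxn.stoichiometry.get(atp_id)
        if coef:
            net += coef * result.fluxes[rxn_id]
    return net / abs(hexose_uptake_flux)
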