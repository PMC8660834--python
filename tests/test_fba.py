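"""FBA engine: LP correctness, ratio constraints, pFBA, loops, gaps, ATP
yield.  The LP optimum is cross-checked against exhaustive vertex
enumeration on small instances."""

import itertools

import numpy as np
import pytest
from scipy.linalg import null_space

from bifidoflux import (RatioConstraint, atp_yield, find_gaps,
                        find_internal_loops, parsimonious_fluxes, solve_fba,
                        stoichiometric_matrix)
from bifidoflux.model import MetabolicModel, Metabolite, Reaction

from conftest import random_model


def chain_model():
    """A -> B -> C with A supply limited to 3."""
    mets = [Metabolite(id=f"{x}_e" if x == "a" else f"{x}_c",
                       compartment="e" if x == "a" else "c")
            for x in "abc"] + [Metabolite(id="c_e", compartment="e")]
    rxns = [
        Reaction("EX_a_e", {"a_e": -1}, lower_bound=-3, upper_bound=0,
                 is_exchange=True),
        Reaction("AB", {"a_e": -1, "b_c": 1}),
        Reaction("BC", {"b_c": -1, "c_c": 1}),
        Reaction("Ct", {"c_c": -1, "c_e": 1}),
        Reaction("EX_c_e", {"c_e": -1}, is_exchange=True),
    ]
    return MetabolicModel("chain", mets, rxns, objective_id="EX_c_e")


def vertex_optimum(model, objective_id, sense="max"):
    """Brute-force LP oracle: enumerate vertices of {S v = 0, lb<=v<=ub}.

    Works on instances with finite bounds.  Returns the optimal objective
    value, or None if no feasible vertex exists.
    """
    S, _, rxn_idx = stoichiometric_matrix(model)
    n = S.shape[1]
    lb = np.array([r.lower_bound for r in model.reactions.values()])
    ub = np.array([r.upper_bound for r in model.reactions.values()])
    N = null_space(S, rcond=1e-10)
    k = N.shape[1]
    j = rxn_idx[objective_id]
    candidates = []
    if k == 0:
        candidates.append(np.zeros(n))
    else:
        # vertices: k active bound constraints among the 2n rows +/-N
        rows = np.vstack([N, -N])          # rows i: v_i <= ub; n+i: -v_i <= -lb
        rhs = np.concatenate([ub, -lb])
        for combo in itertools.combinations(range(2 * n), k):
            A = rows[list(combo)]
            if np.linalg.matrix_rank(A, tol=1e-10) < k:
                continue
            z, *_ = np.linalg.lstsq(A, rhs[list(combo)], rcond=None)
            v = N @ z
            if np.all(v <= ub + 1e-7) and np.all(v >= lb - 1e-7):
                candidates.append(v)
    if not candidates:
        return None
    values = [v[j] for v in candidates]
    return max(values) if sense == "max" else min(values)


class TestSolveFBA:
    def test_chain_optimum_is_supply_limit(self):
        result = solve_fba(chain_model(), "EX_c_e", "max")
        assert result.optimal
        assert result.objective_value == pytest.approx(3.0)

    def test_steady_state_and_bounds_invariants(self, core_model):
        model = core_model.copy()
        model.set_bounds("EX_glc__D_e", -10, 0)
        result = solve_fba(model, "ATPM", "max")
        S, met_idx, rxn_idx = stoichiometric_matrix(model)
        v = np.array([result.fluxes[r] for r in rxn_idx])
        assert np.max(np.abs(S @ v)) <= 1e-6
        for rid, rxn in model.reactions.items():
            assert rxn.lower_bound - 1e-6 <= result.fluxes[rid] \
                <= rxn.upper_bound + 1e-6

    def test_ratio_constraint_exact(self, core_model):
        model = core_model.copy()
        model.set_bounds("EX_glc__D_e", -10, 0)
        rc = RatioConstraint("EX_ac_e", "EX_lac__L_e", 2.5)
        result = solve_fba(model, "ATPM", "max", extra_constraints=[rc])
        assert result.optimal
        assert abs(result.fluxes["EX_ac_e"]
                   - 2.5 * result.fluxes["EX_lac__L_e"]) <= 1e-8

    def test_infeasible_status_propagated(self):
        model = chain_model()
        model.set_bounds("AB", 5, 10)  # demands more A than supply allows
        result = solve_fba(model, "EX_c_e", "max")
        assert result.status == "infeasible"
        assert result.objective_value is None

    def test_missing_objective_raises(self, core_model):
        with pytest.raises(KeyError):
            solve_fba(core_model, "NOPE", "max")
        with pytest.raises(ValueError):
            solve_fba(core_model, "ATPM", "upward")

    def test_relaxing_a_bound_never_decreases_optimum(self, core_model):
        model = core_model.copy()
        model.set_bounds("EX_glc__D_e", -5, 0)
        base = solve_fba(model, "ATPM", "max").objective_value
        for rid in ("EX_glc__D_e", "EX_for_e", "PFL"):
            relaxed = model.copy()
            rxn = relaxed.reaction(rid)
            relaxed.set_bounds(rid, rxn.lower_bound - 5,
                               rxn.upper_bound + 5)
            new = solve_fba(relaxed, "ATPM", "max").objective_value
            assert new >= base - 1e-9

    @pytest.mark.parametrize("seed", range(12))
    def test_lp_matches_vertex_enumeration_oracle(self, seed):
        """On <= 6-reaction finite-bound instances the LP optimum equals
        the exhaustive polytope-vertex optimum."""
        rng = np.random.default_rng(100 + seed)
        model = random_model(rng, n_mets=int(rng.integers(2, 5)),
                             n_rxns=int(rng.integers(2, 5)), bounded=True)
        assert len(model.reactions) <= 6
        target = list(model.reactions)[int(rng.integers(len(model.reactions)))]
        expected = vertex_optimum(model, target, "max")
        result = solve_fba(model, target, "max")
        if expected is None:
            assert not result.optimal
        else:
            assert result.optimal
            assert result.objective_value == pytest.approx(expected,
                                                           abs=1e-6)


class TestParsimoniousFBA:
    def test_futile_loop_carries_no_flux(self, core_model):
        model = core_model.copy()
        model.set_bounds("EX_glc__D_e", -10, 0)
        # add a two-reaction futile cycle
        model.add_reaction(Reaction("LOOP_F", {"g6p_c": -1, "f6p_c": 1}))
        model.add_reaction(Reaction("LOOP_R", {"f6p_c": -1, "g6p_c": 1}))
        result = parsimonious_fluxes(model, "ATPM")
        assert result.optimal
        assert min(abs(result.fluxes["LOOP_F"]),
                   abs(result.fluxes["LOOP_R"])) <= 1e-9

    def test_objective_value_preserved(self, core_model):
        model = core_model.copy()
        model.set_bounds("EX_glc__D_e", -10, 0)
        plain = solve_fba(model, "ATPM", "max")
        pfba = parsimonious_fluxes(model, "ATPM")
        assert pfba.objective_value == pytest.approx(plain.objective_value,
                                                     rel=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_total_flux_not_above_any_feasible_optimum(self, seed):
        """pFBA's total |v| is minimal among vertex optima of the same LP."""
        rng = np.random.default_rng(300 + seed)
        model = random_model(rng, n_mets=3, n_rxns=3, bounded=True)
        target = list(model.reactions)[0]
        plain = solve_fba(model, target, "max")
        if not plain.optimal:
            pytest.skip("instance infeasible")
        pfba = parsimonious_fluxes(model, target)
        S, _, rxn_idx = stoichiometric_matrix(model)
        lb = np.array([r.lower_bound for r in model.reactions.values()])
        ub = np.array([r.upper_bound for r in model.reactions.values()])
        N = null_space(S, rcond=1e-10)
        total_pfba = sum(abs(v) for v in pfba.fluxes.values())
        # sample feasible points at the objective optimum; none may have a
        # smaller total absolute flux
        j = rxn_idx[target]
        found = 0
        for _ in range(300):
            z = rng.normal(size=N.shape[1]) if N.shape[1] else np.zeros(0)
            v = N @ z if N.shape[1] else np.zeros(len(lb))
            if np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9) and \
                    abs(v[j] - plain.objective_value) <= 1e-6:
                found += 1
                assert total_pfba <= np.sum(np.abs(v)) + 1e-6
        assert found >= 0  # sampling is best-effort


class TestLoopsAndGaps:
    def test_two_reaction_cycle_reported(self):
        mets = [Metabolite(id="a_c"), Metabolite(id="b_c")]
        rxns = [Reaction("f", {"a_c": -1, "b_c": 1}),
                Reaction("r", {"b_c": -1, "a_c": 1})]
        model = MetabolicModel("loopy", mets, rxns)
        report = find_internal_loops(model)
        assert report.looped_reactions == {"f", "r"}

    def test_core_model_is_loop_free(self, core_model):
        assert find_internal_loops(core_model).looped_reactions == set()

    def test_reversible_duplicate_creates_loop(self, core_model):
        model = core_model.copy()
        hex1 = model.reaction("HEX1")
        model.add_reaction(Reaction(
            "HEX1_dup",
            {m: -c for m, c in hex1.stoichiometry.items()},
            lower_bound=0, upper_bound=1000))
        looped = find_internal_loops(model).looped_reactions
        assert {"HEX1", "HEX1_dup"} <= looped

    def test_only_consumed_metabolite_in_no_production(self):
        mets = [Metabolite(id="a_e", compartment="e"),
                Metabolite(id="a_c"), Metabolite(id="b_c")]
        rxns = [Reaction("EX_a_e", {"a_e": -1}, lower_bound=-10,
                         is_exchange=True),
                Reaction("At", {"a_e": -1, "a_c": 1}),
                Reaction("AB", {"a_c": -1, "b_c": 1})]
        model = MetabolicModel("gappy", mets, rxns)
        report = find_gaps(model)
        assert "b_c" in report.no_consumption
        assert "b_c" in report.blocked or "b_c" in report.no_consumption
        assert "a_c" not in report.no_production

    def test_open_linear_chain_has_no_gaps(self):
        model = chain_model()
        report = find_gaps(model, medium_exchanges_open=True)
        assert not report.no_production
        assert not report.no_consumption
        assert not report.blocked

    @pytest.mark.parametrize("victim", ["PGI", "TALA", "PGK", "ENO"])
    def test_deleting_interior_reaction_blocks_metabolites(self, core_model,
                                                           victim):
        model = core_model.copy()
        del model.reactions[victim]
        report = find_gaps(model, medium_exchanges_open=True)
        assert report.blocked, f"removing {victim} should block something"

    def test_core_blocked_set_is_exactly_the_conserved_moieties(self,
                                                                core_model):
        """With every exchange open, the only metabolites that cannot be
        net-produced in the core are the conserved cofactor moieties (the
        adenylate, NAD and CoA pools have no synthesis route there)."""
        report = find_gaps(core_model, medium_exchanges_open=True)
        moieties = {"atp_c", "adp_c", "nad_c", "nadh_c", "coa_c", "accoa_c"}
        assert report.blocked == moieties


class TestATPYield:
    def test_theoretical_shunt_yield(self, core_model):
        """3:2 split without biomass drain gives 2.5 ATP per hexose:
        -2 at the kinases, +4 at PGK/PYK, +3 at acetate kinase per two
        hexoses."""
        model = core_model.copy()
        model.set_bounds("EX_glc__D_e", -10, 0)
        model.set_bounds("EX_for_e", 0, 0)
        model.set_bounds("EX_etoh_e", 0, 0)
        result = solve_fba(model, "ATPM", "max")
        assert atp_yield(model, result, 10.0) == pytest.approx(2.5,
                                                               abs=1e-6)

    def test_zero_uptake_is_an_error(self, core_model):
        result = solve_fba(core_model, "ATPM", "max")
        with pytest.raises(ValueError):
            atp_yield(core_model, result, 0.0)

    def test_homolactic_bypass_absent(self, core_model):
        """All carbon to lactate is infeasible: the phosphoketolase split
        forces acetyl phosphate production alongside every triose."""
        model = core_model.copy()
        model.set_bounds("EX_glc__D_e", -10, -10)
        model.set_bounds("EX_for_e", 0, 0)
        model.set_bounds("EX_etoh_e", 0, 0)
        model.set_bounds("EX_ac_e", 0, 0)
        result = solve_fba(model, "ATPM", "max")
        assert result.status == "infeasible"
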