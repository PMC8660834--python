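"""Rate estimation, carbon recovery, maintenance fitting, validation."""

import numpy as np
import pytest

from bifidoflux import (apply_medium, carbon_recovery,
                        estimate_specific_rates, fit_maintenance, solve_fba,
                        validate_against_rates)
from bifidoflux.biomass import set_gam
from bifidoflux.media import Scenario
from bifidoflux.model import MetabolicModel, Metabolite, Reaction
from bifidoflux.physiology import FermentationTimeSeries, SpecificRates
from bifidoflux.reference import (CARBON_COUNTS, EXCHANGE_OF,
                                  measured_rates)
from bifidoflux.synthetic import (BatchSimSpec, CoreModelSpec,
                                  make_core_model, simulate_batch,
                                  cdm_medium, make_strain_model,
                                  table2_scenario)


class TestSpecificRates:
    def test_exact_recovery_on_noiseless_exponential(self):
        """On exact exponential data q = mu * Y holds with zero residual:
        mu 0.45 and Y 26.2 mmol/g give q = 11.79 exactly."""
        spec = BatchSimSpec(mu=0.45, yields={"acetate": 26.2},
                            noise_sd=0.0)
        rates = estimate_specific_rates(simulate_batch(spec))
        assert rates.mu == pytest.approx(0.45, abs=1e-12)
        assert rates.q["acetate"] == pytest.approx(0.45 * 26.2, rel=1e-12)

    def test_constant_concentration_gives_zero_rate(self):
        t = np.linspace(0, 5, 11)
        series = FermentationTimeSeries(
            time=t, biomass=0.02 * np.exp(0.4 * t),
            concentrations={"acetate": np.full(11, 7.0)})
        rates = estimate_specific_rates(series)
        assert rates.q["acetate"] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points_is_an_error(self):
        series = FermentationTimeSeries(
            time=np.array([0.0, 1.0]), biomass=np.array([0.1, 0.2]),
            concentrations={})
        with pytest.raises(ValueError, match="3 points"):
            estimate_specific_rates(series)

    def test_non_monotone_biomass_warns_but_fits(self):
        t = np.linspace(0, 4, 9)
        x = 0.05 * np.exp(0.5 * t)
        x[4] *= 0.5  # one dip below the previous point
        series = FermentationTimeSeries(time=t, biomass=x,
                                        concentrations={})
        with pytest.warns(UserWarning, match="not strictly increasing"):
            estimate_specific_rates(series)

    def test_benchmark_series_reproduces_measured_rates(self):
        """A series regenerated at the benchmark parameters (mu 0.45,
        yields q/mu) returns the printed rates: sucrose uptake 3.9,
        acetate secretion 11.8."""
        bench = measured_rates("BB-12")
        spec = BatchSimSpec(mu=bench.mu,
                            yields={m: q / bench.mu
                                    for m, q in bench.q.items()},
                            noise_sd=0.0)
        rates = estimate_specific_rates(simulate_batch(spec))
        assert rates.mu == pytest.approx(0.45, abs=1e-9)
        assert rates.q["sucrose"] == pytest.approx(-3.9, rel=1e-9)
        assert rates.q["acetate"] == pytest.approx(11.8, rel=1e-9)
        assert rates.acetate_lactate_ratio == pytest.approx(2.51, abs=0.01)

    def test_estimator_bias_vanishes_with_noise_averaging(self):
        """Under multiplicative Gaussian noise the mean estimate over many
        replicates stays close to the true rates (n = 50 points, 1000
        replicates)."""
        import warnings as _warnings
        mus, qs = [], []
        for rep in range(1000):
            spec = BatchSimSpec(mu=0.45, yields={"acetate": 26.2},
                                duration=4.9, sampling_interval=0.1,
                                noise_sd=0.02, seed=rep)
            series = simulate_batch(spec)
            assert len(series.time) == 50
            with _warnings.catch_warnings():
                # noisy trajectories may dip locally; that is the point
                _warnings.simplefilter("ignore", UserWarning)
                rates = estimate_specific_rates(series)
            mus.append(rates.mu)
            qs.append(rates.q["acetate"])
        assert np.mean(mus) == pytest.approx(0.45, rel=0.01)
        assert np.mean(qs) == pytest.approx(0.45 * 26.2, rel=0.02)

    def test_od600_conversion(self):
        t = np.linspace(0, 3, 7)
        frame = simulate_batch(BatchSimSpec(mu=0.4, yields={})).to_frame()
        frame["od600"] = frame.pop("cdw_g_per_L") / 0.30
        series = FermentationTimeSeries.from_frame(frame, od_to_cdw=0.30)
        rates = estimate_specific_rates(series)
        assert rates.mu == pytest.approx(0.4, abs=1e-9)


class TestCarbonRecovery:
    def test_printed_bb46_rates_give_106_percent(self):
        recovery = carbon_recovery(measured_rates("BB-46"), CARBON_COUNTS)
        assert recovery == pytest.approx(106.25, abs=0.01)

    def test_printed_bb12_rates_give_about_83_percent(self):
        recovery = carbon_recovery(measured_rates("BB-12"), CARBON_COUNTS)
        assert recovery == pytest.approx(82.9, abs=0.2)

    def test_zero_products_zero_percent(self):
        rates = SpecificRates(mu=0.1, q={"sucrose": -2.0, "acetate": 0.0})
        assert carbon_recovery(rates, CARBON_COUNTS) == 0.0

    def test_zero_substrate_is_an_error(self):
        rates = SpecificRates(mu=0.1, q={"sucrose": 0.0, "acetate": 1.0})
        with pytest.raises(ValueError):
            carbon_recovery(rates, CARBON_COUNTS, substrate="sucrose")

    def test_mass_balanced_flux_solution_recovers_100_percent(self,
                                                              core_model):
        """Any steady-state solution of the carbon-balanced core (no
        biomass drain) must return exactly 100% carbon recovery."""
        model = core_model.copy()
        model.set_bounds("EX_glc__D_e", -10, 0)
        result = solve_fba(model, "ATPM", "max")
        mu = 0.37  # arbitrary positive growth rate for scaling
        q = {"glucose": result.fluxes["EX_glc__D_e"],
             "acetate": result.fluxes["EX_ac_e"],
             "lactate": result.fluxes["EX_lac__L_e"],
             "formate": result.fluxes["EX_for_e"],
             "ethanol": result.fluxes["EX_etoh_e"]}
        counts = {"glucose": 6, "acetate": 2, "lactate": 3, "formate": 1,
                  "ethanol": 2}
        recovery = carbon_recovery(SpecificRates(mu=mu, q=q), counts,
                                   substrate="glucose")
        assert recovery == pytest.approx(100.0, abs=1e-6)


def two_toy_strains(gam_true, ngam_true):
    """Two little chemostat-like models generated at known maintenance
    parameters, with slightly different catabolic capacity."""
    models, mus = [], []
    for rate in (10.0, 7.0):
        mets = [Metabolite(id="s_e", compartment="e"),
                Metabolite(id="s_c"), Metabolite(id="atp_c"),
                Metabolite(id="adp_c"), Metabolite(id="pi_c"),
                Metabolite(id="h2o_c"), Metabolite(id="h_c"),
                Metabolite(id="biomass_c")]
        rxns = [
            Reaction("EX_s_e", {"s_e": -1}, lower_bound=-rate,
                     is_exchange=True),
            Reaction("St", {"s_e": -1, "s_c": 1}),
            # catabolism: 2 ATP per substrate
            Reaction("CAT", {"s_c": -1, "adp_c": -2, "pi_c": -2,
                             "atp_c": 2, "h2o_c": 2, "h_c": -2}),
            Reaction("ATPM", {"atp_c": -1, "h2o_c": -1, "adp_c": 1,
                              "pi_c": 1, "h_c": 1}),
            Reaction("BIOMASS", {"atp_c": -gam_true, "h2o_c": -gam_true,
                                 "adp_c": gam_true, "pi_c": gam_true,
                                 "h_c": gam_true, "biomass_c": 1.0}),
            Reaction("DM_biomass", {"biomass_c": -1}),
        ]
        model = MetabolicModel(f"toy{rate}", mets, rxns,
                               objective_id="BIOMASS")
        models.append(model)
        mus.append((2 * rate - ngam_true) / gam_true)
    return models, mus


class TestFitMaintenance:
    def test_parameter_recovery_on_generated_pair(self):
        """A model pair generated at known (GAM*, NGAM*) is recovered."""
        models, mus = two_toy_strains(gam_true=20.0, ngam_true=1.0)
        params = fit_maintenance(models, mus, gam_max=60.0, ngam_max=10.0)
        assert params.converged
        assert params.gam == pytest.approx(20.0, abs=1e-3)
        assert params.ngam == pytest.approx(1.0, abs=1e-3)

    def test_zero_maintenance_fixed_point(self):
        models, _ = two_toy_strains(gam_true=10.0, ngam_true=0.0)
        # measured mu produced by the models at (10, 0); at gam=10 the fit
        # should return ngam 0
        mus = [2 * 10.0 / 10.0, 2 * 7.0 / 10.0]
        params = fit_maintenance(models, mus, gam_max=40.0, ngam_max=5.0)
        assert params.gam == pytest.approx(10.0, abs=1e-3)
        assert params.ngam == pytest.approx(0.0, abs=1e-3)

    def test_unreachable_growth_rates_warn(self):
        models, _ = two_toy_strains(gam_true=20.0, ngam_true=1.0)
        with pytest.warns(UserWarning):
            params = fit_maintenance(models, [100.0, 90.0], gam_max=50.0)
        assert not params.converged

    def test_mu_monotone_in_gam_and_ngam(self):
        """The property the nested bisection relies on: predicted growth
        is non-increasing in both maintenance parameters."""
        model = table2_scenario("BB-12", 3.9, 2.5).apply(
            make_strain_model("BB-12"))
        rc = table2_scenario("BB-12", 3.9, 2.5).ratio_constraints

        def mu(g, n):
            probe = set_gam(model, g)
            probe.set_bounds("ATPM", lower=n)
            res = solve_fba(probe, extra_constraints=rc)
            return res.objective_value if res.optimal else 0.0

        tol = 1e-9  # non-strict: growth may be carbon-limited, not ATP-
        assert mu(10, 0) >= mu(20, 0) - tol >= mu(40, 0) - 2 * tol
        assert mu(20, 0) >= mu(20, 2) - tol >= mu(20, 6) - 2 * tol
        assert mu(40, 0) < mu(10, 0)  # GAM eventually binds


@pytest.fixture(scope="module")
def fitted_bb12():
    model = set_gam(make_strain_model("BB-12"), 20.0)
    model.set_bounds("ATPM", lower=1.0)
    return model


class TestValidateAgainstRates:
    def test_side_by_side_table(self, fitted_bb12):
        scenario = table2_scenario("BB-12", 3.9, 2.5)
        out = validate_against_rates(fitted_bb12, scenario,
                                     measured_rates("BB-12"), EXCHANGE_OF)
        assert out.feasible
        table = out.table.set_index("quantity")
        assert table.loc["growth_rate", "in_vitro"] == 0.45
        assert table.loc["acetate", "in_silico"] == pytest.approx(
            2.5 * table.loc["lactate", "in_silico"], rel=1e-6)
        assert table.loc["sucrose", "in_silico"] == pytest.approx(-3.9,
                                                                  abs=1e-6)

    def test_all_rates_pinned_is_infeasible(self, fitted_bb12):
        """Constraining every measured secretion rate simultaneously
        over-determines the network and FBA finds no feasible solution."""
        scenario = table2_scenario("BB-12", 3.9, 2.5)
        pinned = scenario.apply(fitted_bb12)
        for met, q in measured_rates("BB-12").q.items():
            if met == "sucrose":
                continue
            pinned.set_bounds(EXCHANGE_OF[met], q, q)
        result = solve_fba(pinned, "BIOMASS", "max")
        assert result.status == "infeasible"

    def test_self_consistency_on_own_optimum(self, fitted_bb12):
        """Re-constraining a model to its own parsimonious optimum's rates
        stays feasible and reproduces the fluxes."""
        scenario = table2_scenario("BB-12", 3.9, 2.5)
        out = validate_against_rates(fitted_bb12, scenario,
                                     measured_rates("BB-12"), EXCHANGE_OF)
        constrained = scenario.apply(fitted_bb12)
        for met in ("acetate", "lactate", "formate"):
            v = out.result.fluxes[EXCHANGE_OF[met]]
            constrained.set_bounds(EXCHANGE_OF[met], v - 1e-6, v + 1e-6)
        again = solve_fba(constrained, "BIOMASS", "max")
        assert again.optimal
        assert again.objective_value == pytest.approx(
            out.result.objective_value, abs=1e-4)
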