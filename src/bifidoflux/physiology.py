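"""Batch-fermentation physiology: specific rates, carbon recovery, and
maintenance-energy fitting.

From a batch time series the maximum specific growth rate mu (h^-1) is the
least-squares slope of ln(biomass) versus time over the exponential window,
and the specific rate of a metabolite (mmol gCDW^-1 h^-1) is mu times the
regression slope of its concentration (mmol/L) versus biomass concentration
(gCDW/L) over the same window — positive for secreted products, negative
for consumed substrates.

Maintenance energetics split into growth-associated maintenance (GAM, mmol
ATP per gram biomass, part of the biomass reaction) and non-growth
associated maintenance (NGAM, mmol ATP gCDW^-1 h^-1, the lower bound of a
standalone ATP hydrolysis reaction).  Both are fitted jointly across
strains by matching predicted to measured growth rates, exploiting that the
predicted optimum is non-increasing in either parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .biomass import set_gam
from .fba import FBAResult, parsimonious_fluxes, solve_fba
from .media import Scenario
from .model import MetabolicModel

__all__ = [
    "OD_TO_CDW", "FermentationTimeSeries", "SpecificRates",
    "MaintenanceParams", "ValidationTable", "estimate_specific_rates",
    "carbon_recovery", "fit_maintenance", "validate_against_rates",
]

#: Default OD600 -> gCDW/L conversion factors per strain.
OD_TO_CDW: Dict[str, float] = {"BB-12": 0.30, "BB-46": 0.32}


@dataclass
class FermentationTimeSeries:
    """Timed biomass and metabolite concentrations from one batch culture.

    ``exponential_window`` is a half-open index range ``(start, stop)``
    selecting the points used for rate estimation; window choice is
    explicit user input, not auto-detected.
    """

    time: np.ndarray                      # h, strictly increasing
    biomass: np.ndarray                   # gCDW/L
    concentrations: Dict[str, np.ndarray]  # mmol/L per time point
    exponential_window: Tuple[int, int] = (0, 0)
    name: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.biomass = np.asarray(self.biomass, dtype=float)
        self.concentrations = {m: np.asarray(c, dtype=float)
                               for m, c in self.concentrations.items()}
        if self.exponential_window == (0, 0):
            self.exponential_window = (0, len(self.time))
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        for met, conc in self.concentrations.items():
            if conc.shape != self.time.shape:
                raise ValueError(f"concentration series {met!r} length "
                                 "mismatch")
        lo, hi = self.exponential_window
        if np.any(self.biomass[lo:hi] <= 0):
            raise ValueError("biomass must be positive inside the "
                             "exponential window")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   exponential_window: Optional[Tuple[int, int]] = None,
                   od_to_cdw: Optional[float] = None,
                   name: str = "") -> "FermentationTimeSeries":
        """Build from a table with ``time_h`` and either ``cdw_g_per_L`` or
        ``od600`` (converted with ``od_to_cdw``), all other columns being
        metabolite concentrations in mmol/L."""
        if "cdw_g_per_L" in frame.columns:
            biomass = frame["cdw_g_per_L"].to_numpy(float)
        elif "od600" in frame.columns:
            if od_to_cdw is None:
                raise ValueError("od600 input needs an od_to_cdw factor")
            biomass = frame["od600"].to_numpy(float) * od_to_cdw
        else:
            raise ValueError("need a cdw_g_per_L or od600 column")
        mets = [c for c in frame.columns
                if c not in ("time_h", "cdw_g_per_L", "od600")]
        return cls(time=frame["time_h"].to_numpy(float), biomass=biomass,
                   concentrations={m: frame[m].to_numpy(float) for m in mets},
                   exponential_window=exponential_window or (0, len(frame)),
                   name=name)

    def to_frame(self) -> pd.DataFrame:
        data = {"time_h": self.time, "cdw_g_per_L": self.biomass}
        data.update(self.concentrations)
        return pd.DataFrame(data)


@dataclass
class SpecificRates:
    """Exponential-phase specific rates of one culture."""

    mu: float                             # h^-1
    q: Dict[str, float]                   # mmol/gCDW/h, negative = consumed
    name: str = ""

    @property
    def acetate_lactate_ratio(self) -> float:
        q_lac = self.q.get("lactate", 0.0)
        if q_lac <= 0:
            return float("nan")
        return self.q.get("acetate", 0.0) / q_lac


@dataclass
class MaintenanceParams:
    """Fitted maintenance energies with the fit residual."""

    gam: float                            # mmol ATP / gCDW
    ngam: float                           # mmol ATP / gCDW / h
    residual: float = 0.0                 # sum of squared mu deviations
    converged: bool = True

    def __post_init__(self) -> None:
        if self.gam < 0 or self.ngam < 0:
            raise ValueError("maintenance parameters must be non-negative")


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        raise ValueError("degenerate regressor (zero variance)")
    return float(xc @ (y - y.mean())) / denom


def estimate_specific_rates(series: FermentationTimeSeries) -> SpecificRates:
    """Estimate mu and per-metabolite specific rates from the window.

    mu is the OLS slope of ln(biomass) on time; q_m = mu * slope of
    concentration on biomass.  On exact exponential data this recovers
    q = mu * Y exactly, Y being the yield in mmol per gCDW.  Fewer than
    three window points is an error; non-monotone biomass inside the window
    triggers a warning but the fit proceeds.
    """
    lo, hi = series.exponential_window
    t = series.time[lo:hi]
    x = series.biomass[lo:hi]
    if len(t) < 3:
        raise ValueError("need at least 3 points in the exponential window")
    if np.any(np.diff(x) <= 0):
        warnings.warn(f"biomass not strictly increasing inside the "
                      f"exponential window of {series.name or 'series'}; "
                      "fitting anyway", stacklevel=2)
    mu = _ols_slope(t, np.log(x))
    q = {met: mu * _ols_slope(x, conc[lo:hi])
         for met, conc in series.concentrations.items()}
    return SpecificRates(mu=mu, q=q, name=series.name)


def carbon_recovery(rates: SpecificRates,
                    carbon_counts: Mapping[str, int],
                    substrate: Optional[str] = None) -> float:
    """Percent of consumed substrate carbon recovered in secreted products.

    ``100 * sum_products(q_p * C_p) / (|q_substrate| * C_substrate)``.
    Biomass formation is not included.  ``carbon_counts`` maps metabolite
    name to carbon atoms per molecule (sucrose = 12) and must cover every
    secreted species considered.
    """
    consumed = [m for m in carbon_counts
                if rates.q.get(m, 0.0) < 0]
    if substrate is None:
        if len(consumed) != 1:
            raise ValueError(
                f"cannot identify a unique substrate among {consumed}; "
                "pass substrate= explicitly")
        substrate = consumed[0]
    q_s = rates.q.get(substrate, 0.0)
    if q_s >= 0:
        raise ValueError(f"substrate {substrate!r} is not consumed "
                         f"(q = {q_s})")
    produced = sum(rates.q[m] * carbon_counts[m]
                   for m in carbon_counts
                   if m != substrate and rates.q.get(m, 0.0) > 0)
    return 100.0 * produced / (abs(q_s) * carbon_counts[substrate])


# ---------------------------------------------------------------------------
# maintenance fitting
# ---------------------------------------------------------------------------

def _predict_mu(model: MetabolicModel, gam: float, ngam: float,
                ngam_reaction: str, cache: Dict,
                constraints: Sequence = ()) -> float:
    key = (id(model), round(gam, 9), round(ngam, 9))
    if key in cache:
        return cache[key]
    probe = set_gam(model, gam)
    probe.set_bounds(ngam_reaction, lower=ngam)
    if probe.reaction(ngam_reaction).upper_bound < ngam:
        probe.set_bounds(ngam_reaction, upper=ngam)
    result = solve_fba(probe, sense="max", extra_constraints=constraints)
    mu = result.objective_value if result.optimal else 0.0
    cache[key] = max(mu, 0.0)
    return cache[key]


def fit_maintenance(models: Sequence[MetabolicModel],
                    measured_mu: Sequence[float],
                    ngam_reaction: str = "ATPM",
                    gam_max: float = 200.0,
                    ngam_max: float = 50.0,
                    tol: float = 1e-6,
                    constraints_per_model: Optional[Sequence] = None,
                    ) -> MaintenanceParams:
    """Fit one (GAM, NGAM) pair shared across constrained models.

    Each model must already carry its scenario constraints (fixed substrate
    uptake, product-ratio constraint, amino-acid caps) and a biomass
    objective.  The fit minimizes ``sum_i (mu_pred_i - mu_meas_i)^2`` by
    nested bisection: for a trial GAM the NGAM reproducing each measured mu
    is found by bisection (mu_pred is non-increasing in NGAM), and GAM is
    then bisected on the difference of the per-model NGAM requirements.
    When no non-negative pair can reach every measured mu, the closest
    feasible pair is returned with ``converged=False``.
    """
    if len(models) != len(measured_mu) or not models:
        raise ValueError("need one measured growth rate per model")
    for model in models:
        if ngam_reaction not in model.reactions:
            raise KeyError(f"model {model.id!r} lacks the NGAM reaction "
                           f"{ngam_reaction!r}")
    if constraints_per_model is None:
        constraints_per_model = [() for _ in models]
    caches = [dict() for _ in models]

    def mu_at(i: int, gam: float, ngam: float) -> float:
        return _predict_mu(models[i], gam, ngam, ngam_reaction, caches[i],
                           constraints_per_model[i])

    def ngam_for(i: int, gam: float) -> Optional[float]:
        """NGAM making model i hit its measured mu at this GAM, or None."""
        target = measured_mu[i]
        if mu_at(i, gam, 0.0) < target - tol:
            return None
        lo, hi = 0.0, ngam_max
        if mu_at(i, gam, hi) > target:
            return hi
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if mu_at(i, gam, mid) >= target:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def residual(gam: float, ngam: float) -> float:
        return sum((mu_at(i, gam, ngam) - m) ** 2
                   for i, m in enumerate(measured_mu))

    if len(models) == 1:
        # Degenerate single-model case: fix NGAM at 0, bisect GAM.
        n0 = None
        lo, hi = 0.0, gam_max
        if mu_at(0, 0.0, 0.0) < measured_mu[0] - tol:
            return MaintenanceParams(0.0, 0.0,
                                     residual(0.0, 0.0), converged=False)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if mu_at(0, mid, 0.0) >= measured_mu[0]:
                lo = mid
            else:
                hi = mid
        gam = 0.5 * (lo + hi)
        return MaintenanceParams(gam, 0.0, residual(gam, 0.0))

    def gap(gam: float) -> Optional[float]:
        ns = [ngam_for(i, gam) for i in range(len(models))]
        if any(n is None for n in ns):
            return None
        return max(ns) - min(ns)

    def signed_gap(gam: float) -> Optional[float]:
        ns = [ngam_for(i, gam) for i in range(len(models))]
        if any(n is None for n in ns):
            return None
        return ns[0] - ns[-1]

    # Coarse scan for a bracket of signed_gap's sign change.
    grid = np.linspace(0.0, gam_max, 41)
    best: Optional[Tuple[float, float, float]] = None  # (res, gam, ngam)
    bracket = None
    prev = None
    for g in grid:
        sg = signed_gap(g)
        if sg is None:
            continue
        ns = [ngam_for(i, g) for i in range(len(models))]
        n_mid = float(np.mean(ns))
        res = residual(g, max(n_mid, 0.0))
        if best is None or res < best[0]:
            best = (res, g, max(n_mid, 0.0))
        if prev is not None and np.sign(sg) != np.sign(prev[1]) != 0:
            bracket = (prev[0], g)
        prev = (g, sg)

    if bracket is not None:
        lo, hi = bracket
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            sg = signed_gap(mid)
            if sg is None:
                break
            if np.sign(sg) == np.sign(signed_gap(lo) or 0.0):
                lo = mid
            else:
                hi = mid
        gam = 0.5 * (lo + hi)
        ns = [ngam_for(i, gam) for i in range(len(models))]
        if all(n is not None for n in ns):
            ngam = float(np.mean(ns))
            res = residual(gam, ngam)
            if best is None or res < best[0]:
                best = (res, gam, ngam)

    # Local refinement around the incumbent when the NGAM-requirement
    # curves never cross (or to polish the bisection result).
    if best is not None:
        step = float(grid[1] - grid[0])
        for _ in range(4):
            _, g0, _ = best
            for g in np.linspace(max(g0 - step, 0.0),
                                 min(g0 + step, gam_max), 9):
                ns = [ngam_for(i, g) for i in range(len(models))]
                if any(n is None for n in ns):
                    continue
                n_mid = max(float(np.mean(ns)), 0.0)
                res = residual(g, n_mid)
                if res < best[0]:
                    best = (res, g, n_mid)
            step /= 4.0

    if best is None:
        warnings.warn("no non-negative (GAM, NGAM) reproduces the measured "
                      "growth rates; returning (0, 0)", stacklevel=2)
        return MaintenanceParams(0.0, 0.0, residual(0.0, 0.0),
                                 converged=False)
    res, gam, ngam = best
    mu_tol = max(1e-3, tol)
    converged = res <= len(models) * mu_tol ** 2
    if not converged:
        warnings.warn(
            f"maintenance fit residual {res:.3e} exceeds tolerance; "
            "reporting the best feasible pair", stacklevel=2)
    return MaintenanceParams(float(gam), float(ngam), float(res), converged)


# ---------------------------------------------------------------------------
# model-versus-measurement confrontation
# ---------------------------------------------------------------------------

@dataclass
class ValidationTable:
    """Side-by-side in-vitro/in-silico rates."""

    feasible: bool
    table: pd.DataFrame
    result: Optional[FBAResult] = None


def validate_against_rates(model: MetabolicModel, scenario: Scenario,
                           measured: SpecificRates,
                           exchange_of: Mapping[str, str],
                           ) -> ValidationTable:
    """Confront model predictions with measured specific rates.

    The scenario (substrate uptake fixed, product-ratio constraint,
    amino-acid caps) is applied, biomass is maximized and the secretion
    profile is taken from parsimonious FBA.  ``exchange_of`` maps measured
    metabolite names to exchange reaction ids.  An infeasible scenario is
    reported as such, not raised.
    """
    constrained = scenario.apply(model)
    result = parsimonious_fluxes(
        constrained, extra_constraints=scenario.ratio_constraints)
    if not result.optimal:
        return ValidationTable(feasible=False,
                               table=pd.DataFrame(), result=result)

    rows = [{"quantity": "growth_rate", "in_vitro": measured.mu,
             "in_silico": result.objective_value}]
    for met, q_meas in measured.q.items():
        ex_id = exchange_of.get(met)
        q_pred = result.fluxes.get(ex_id, float("nan")) if ex_id else float("nan")
        rows.append({"quantity": met, "in_vitro": q_meas,
                     "in_silico": q_pred})
    table = pd.DataFrame(rows)
    with np.errstate(divide="ignore", invalid="ignore"):
        table["relative_deviation"] = (
            (table["in_silico"] - table["in_vitro"])
            / table["in_vitro"].abs())
    return ValidationTable(feasible=True, table=table, result=result)
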