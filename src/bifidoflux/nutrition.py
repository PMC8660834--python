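"""In-silico nutrition experiments: omission scans, sugar screens, and the
glucose transporter flux-split scan.

Single-omission essentiality removes one nutrient at a time from a medium
and re-optimizes biomass formation; a nutrient is *essential* when growth
collapses below ``GROWTH_EPSILON`` without it while the complete medium
supports growth.  The carbohydrate screen asks which sugars can serve as
the sole carbon source.  The transporter split scan divides a fixed sugar
uptake between a PEP-dependent phosphotransferase system (PTS) and an
alternative permease/symporter route and records the biomass optimum along
the split fraction grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fba import solve_fba
from .media import Medium, apply_medium, omit
from .model import MetabolicModel

__all__ = ["GROWTH_EPSILON", "NutrientVerdict", "EssentialityReport",
           "SplitScanResult", "single_omission_scan", "carbohydrate_screen",
           "pts_split_scan"]

#: Growth rate (h^-1) below which a prediction counts as "no growth".
GROWTH_EPSILON = 1e-6


@dataclass
class NutrientVerdict:
    nutrient: str
    max_growth_with: float
    max_growth_without: float
    verdict: str  # "essential" | "dispensable" | "growth-promoting"


@dataclass
class EssentialityReport:
    """Per-nutrient omission outcomes, in deterministic (input) order."""

    verdicts: Dict[str, NutrientVerdict] = field(default_factory=dict)

    def essential(self) -> List[str]:
        return [n for n, v in self.verdicts.items() if v.verdict == "essential"]

    def dispensable(self) -> List[str]:
        return [n for n, v in self.verdicts.items()
                if v.verdict != "essential"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"nutrient": v.nutrient, "max_growth_with": v.max_growth_with,
              "max_growth_without": v.max_growth_without,
              "verdict": v.verdict} for v in self.verdicts.values()])


def _max_growth(model: MetabolicModel, medium: Medium,
                objective_id: Optional[str]) -> float:
    constrained, _ = apply_medium(model, medium)
    result = solve_fba(constrained, objective_id=objective_id, sense="max")
    if not result.optimal:
        return 0.0
    return max(result.objective_value, 0.0)


def single_omission_scan(model: MetabolicModel, medium: Medium,
                         nutrients: Optional[Sequence[str]] = None,
                         objective_id: Optional[str] = None,
                         growth_epsilon: float = GROWTH_EPSILON,
                         ) -> EssentialityReport:
    """Omit one nutrient at a time and re-optimize biomass formation.

    A nutrient is *essential* when the complete medium supports growth
    (>= epsilon) but its omission abolishes it (< epsilon);
    *growth-promoting* when both runs grow but omission reduces the
    optimum by more than 1%; otherwise *dispensable*.
    """
    if nutrients is None:
        nutrients = sorted(medium.components)
    missing = [n for n in nutrients if n not in medium]
    if missing:
        raise KeyError(f"nutrients not in medium {medium.name!r}: {missing}")

    reference = _max_growth(model, medium, objective_id)
    report = EssentialityReport()
    for nutrient in nutrients:
        without = _max_growth(model, omit(medium, nutrient), objective_id)
        if reference >= growth_epsilon and without < growth_epsilon:
            verdict = "essential"
        elif (without >= growth_epsilon
              and without < reference * (1 - 1e-2)):
            verdict = "growth-promoting"
        else:
            verdict = "dispensable"
        report.verdicts[nutrient] = NutrientVerdict(
            nutrient=nutrient, max_growth_with=reference,
            max_growth_without=without, verdict=verdict)
    return report


def carbohydrate_screen(model: MetabolicModel, base_medium: Medium,
                        sugars: Sequence[str],
                        uptake: float = 10.0,
                        objective_id: Optional[str] = None,
                        growth_epsilon: float = GROWTH_EPSILON,
                        ) -> pd.DataFrame:
    """Maximal growth with each sugar as the sole carbon source.

    ``base_medium`` should contain no carbohydrate; each candidate sugar is
    added alone with the given molar uptake bound (the same rate for every
    sugar, irrespective of its carbon count).  A sugar without a mapped,
    model-resident exchange reaction yields an annotated no-growth row
    rather than an error.
    """
    rows = []
    for sugar in sugars:
        medium = base_medium.add(sugar)
        ex_id = medium.exchange_id(sugar)
        if ex_id is None or ex_id not in model.reactions:
            rows.append({"sugar": sugar, "max_growth": 0.0, "grows": False,
                         "note": "no transporter/exchange in model"})
            continue
        medium.components[sugar].uptake_bound = uptake
        growth = _max_growth(model, medium, objective_id)
        rows.append({"sugar": sugar, "max_growth": growth,
                     "grows": bool(growth >= growth_epsilon), "note": ""})
    return pd.DataFrame(rows)


@dataclass
class SplitScanResult:
    """Biomass optimum along the PTS share of a fixed total sugar uptake.

    ``fractions`` holds the grid of PTS shares f in [0, 1]; ``growth``
    the biomass optimum at each f (NaN where infeasible); ``argmax`` every
    grid fraction attaining the maximum within a tolerance (ties are
    reported, not broken).
    """

    fractions: np.ndarray
    growth: np.ndarray
    argmax: List[float]
    pts_rxn: str
    alt_rxn: str

    @property
    def best_fraction(self) -> float:
        return self.argmax[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pts_fraction": self.fractions,
                             "growth": self.growth})


def pts_split_scan(model: MetabolicModel,
                   pts_rxn: str, alt_rxn: str,
                   exchange_id: str,
                   total_uptake: float = 10.0,
                   steps: int = 21,
                   objective_id: Optional[str] = None) -> SplitScanResult:
    """Scan the PTS share of a fixed sugar uptake.

    The sugar exchange is fixed at ``-total_uptake``; at each grid fraction
    ``f`` the PTS route is fixed to ``f * total`` and the alternative route
    to ``(1 - f) * total`` so the two transporter fluxes always sum to the
    total uptake.  Biomass is maximized at every point.  A model lacking
    either route is an error.
    """
    for rxn_id in (pts_rxn, alt_rxn, exchange_id):
        if rxn_id not in model.reactions:
            raise KeyError(f"reaction {rxn_id!r} not in model {model.id!r}")
    if steps < 2:
        raise ValueError("need at least 2 grid points")

    fractions = np.linspace(0.0, 1.0, steps)
    growth = np.full(steps, np.nan)
    for i, f in enumerate(fractions):
        probe = model.copy()
        probe.set_bounds(exchange_id, -total_uptake, -total_uptake)
        probe.set_bounds(pts_rxn, f * total_uptake, f * total_uptake)
        probe.set_bounds(alt_rxn, (1 - f) * total_uptake,
                         (1 - f) * total_uptake)
        result = solve_fba(probe, objective_id=objective_id, sense="max")
        if result.optimal:
            growth[i] = result.objective_value

    finite = np.nan_to_num(growth, nan=-np.inf)
    best = float(np.max(finite))
    if not np.isfinite(best):
        argmax: List[float] = []
    else:
        tol = max(1e-9, 1e-6 * abs(best))
        argmax = [float(f) for f, g in zip(fractions, finite)
                  if g >= best - tol]
    return SplitScanResult(fractions=fractions, growth=growth, argmax=argmax,
                           pts_rxn=pts_rxn, alt_rxn=alt_rxn)
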