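"""Benchmark batch-fermentation dataset for the two strains.

In-vitro maximum specific growth rates and exponential-phase specific
rates (mmol gCDW^-1 h^-1; negative = consumption) measured in the
chemically defined medium with 10 g/L sucrose, used to constrain and
confront the models.  OD600-to-CDW conversion factors are 0.30 (BB-12) and
0.32 (BB-46) gCDW/L per OD unit.
"""

from __future__ import annotations

from typing import Dict

from .physiology import SpecificRates

__all__ = ["MEASURED_RATES", "CARBON_COUNTS", "measured_rates",
           "EXCHANGE_OF"]

#: strain -> (mu, {metabolite: q})
MEASURED_RATES: Dict[str, Dict] = {
    "BB-12": {
        "mu": 0.45,
        "q": {"sucrose": -3.9, "acetate": 11.8, "lactate": 4.7,
              "formate": 0.3, "succinate": 0.2, "ethanol": 0.0},
    },
    "BB-46": {
        "mu": 0.35,
        "q": {"sucrose": -2.8, "acetate": 11.9, "lactate": 0.7,
              "formate": 4.0, "succinate": 0.2, "ethanol": 2.5},
    },
}

#: Carbon atoms per molecule of the measured species.
CARBON_COUNTS: Dict[str, int] = {
    "sucrose": 12, "acetate": 2, "lactate": 3, "formate": 1,
    "succinate": 4, "ethanol": 2,
}

#: Measured metabolite name -> exchange reaction id in the strain models.
EXCHANGE_OF: Dict[str, str] = {
    "sucrose": "EX_sucr_e", "acetate": "EX_ac_e", "lactate": "EX_lac__L_e",
    "formate": "EX_for_e", "succinate": "EX_succ_e", "ethanol": "EX_etoh_e",
}


def measured_rates(strain: str) -> SpecificRates:
    """The benchmark in-vitro rates of one strain as a SpecificRates."""
    entry = MEASURED_RATES[strain]
    return SpecificRates(mu=entry["mu"], q=dict(entry["q"]), name=strain)
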