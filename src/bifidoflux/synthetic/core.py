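"""The self-contained core model of bifidobacterial central carbon
metabolism (the "bifid shunt").

Bifidobacteria lack 6-phosphofructokinase and dissimilate hexoses through
the fructose-6-phosphate phosphoketolase pathway: the dual-specificity
phosphoketolase cleaves fructose-6-phosphate (F6PPK) and
xylulose-5-phosphate (PK) into acetyl phosphate plus the corresponding
aldose phosphate.  Per two hexoses the pathway yields three acetyl
phosphates and two glyceraldehyde-3-phosphates, hence the theoretical
3 acetate : 2 lactate split and 2.5 ATP per hexose when all reducing
equivalents go to lactate.  Pentoses enter directly at
xylulose-5-phosphate, so only a 1:1 acetate:lactate split is possible.

The generated model is elementally and charge balanced throughout
(explicit protons and water), carries a reversible pyruvate formate-lyase,
the acetaldehyde/ethanol branch, an ATP-drain (maintenance) reaction, and
optionally a PEP:PTS + proton-symport pair of glucose uptake routes and a
small biomass drain with PEP/G6P precursor coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..model import MetabolicModel
from ._builder import ModelBuilder

__all__ = ["CoreModelSpec", "make_core_model"]


@dataclass
class CoreModelSpec:
    """Switches for the generated core network.

    ``biomass_pep`` / ``biomass_g6p`` are the precursor coefficients (mmol
    per unit drain flux) of the optional biomass drain; ``biomass_atp`` its
    ATP hydrolysis cost.  ``maintenance_lb`` is the lower bound of the
    ATP-drain reaction (a non-growth maintenance flux).
    """

    include_pentose_route: bool = True
    include_pts_and_symport: bool = False
    include_biomass_drain: bool = False
    biomass_pep: float = 0.5
    biomass_g6p: float = 0.5
    biomass_atp: float = 2.0
    maintenance_lb: float = 0.0
    model_id: str = "bifid_core"


def add_central_carbon(builder: ModelBuilder,
                       include_pentose_entry: bool = True) -> None:
    """Bifid shunt + lower glycolysis + fermentation branches (internal)."""
    B = builder
    B.rxn("HEX1", {"glc__D_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1,
                   "h_c": 1},
          name="hexokinase", subsystem="Bifid shunt", ec=("2.7.1.2",))
    B.rxn("PGI", {"g6p_c": -1, "f6p_c": 1}, lb=-1000,
          name="glucose-6-phosphate isomerase", subsystem="Bifid shunt",
          ec=("5.3.1.9",))
    B.rxn("PGMT", {"g1p_c": -1, "g6p_c": 1}, lb=-1000,
          name="phosphoglucomutase", subsystem="Bifid shunt",
          ec=("5.4.2.2",))
    B.rxn("F6PPK", {"f6p_c": -1, "pi_c": -1, "actp_c": 1, "e4p_c": 1,
                    "h2o_c": 1},
          name="fructose-6-phosphate phosphoketolase",
          subsystem="Bifid shunt", ec=("4.1.2.22",))
    B.rxn("PK", {"xu5p__D_c": -1, "pi_c": -1, "actp_c": 1, "g3p_c": 1,
                 "h2o_c": 1},
          name="xylulose-5-phosphate phosphoketolase",
          subsystem="Bifid shunt", ec=("4.1.2.9",))
    B.rxn("TALA", {"g3p_c": -1, "s7p_c": -1, "e4p_c": 1, "f6p_c": 1},
          lb=-1000, name="transaldolase", subsystem="Pentose phosphate",
          ec=("2.2.1.2",))
    B.rxn("TKT1", {"r5p_c": -1, "xu5p__D_c": -1, "g3p_c": 1, "s7p_c": 1},
          lb=-1000, name="transketolase (C5+C5)",
          subsystem="Pentose phosphate", ec=("2.2.1.1",))
    B.rxn("TKT2", {"e4p_c": -1, "xu5p__D_c": -1, "f6p_c": 1, "g3p_c": 1},
          lb=-1000, name="transketolase (C4+C5)",
          subsystem="Pentose phosphate", ec=("2.2.1.1",))
    B.rxn("RPE", {"ru5p__D_c": -1, "xu5p__D_c": 1}, lb=-1000,
          name="ribulose-5-phosphate 3-epimerase",
          subsystem="Pentose phosphate", ec=("5.1.3.1",))
    B.rxn("RPI", {"r5p_c": -1, "ru5p__D_c": 1}, lb=-1000,
          name="ribose-5-phosphate isomerase",
          subsystem="Pentose phosphate", ec=("5.3.1.6",))
    B.rxn("GAPD", {"g3p_c": -1, "nad_c": -1, "pi_c": -1, "13dpg_c": 1,
                   "h_c": 1, "nadh_c": 1}, lb=-1000,
          name="glyceraldehyde-3-phosphate dehydrogenase",
          subsystem="Lower glycolysis", ec=("1.2.1.12",))
    B.rxn("PGK", {"13dpg_c": -1, "adp_c": -1, "3pg_c": 1, "atp_c": 1},
          lb=-1000, name="phosphoglycerate kinase",
          subsystem="Lower glycolysis", ec=("2.7.2.3",))
    B.rxn("PGM", {"3pg_c": -1, "2pg_c": 1}, lb=-1000,
          name="phosphoglycerate mutase", subsystem="Lower glycolysis",
          ec=("5.4.2.11",))
    B.rxn("ENO", {"2pg_c": -1, "pep_c": 1, "h2o_c": 1}, lb=-1000,
          name="enolase", subsystem="Lower glycolysis", ec=("4.2.1.11",))
    B.rxn("PYK", {"pep_c": -1, "adp_c": -1, "h_c": -1, "pyr_c": 1,
                  "atp_c": 1},
          name="pyruvate kinase", subsystem="Lower glycolysis",
          ec=("2.7.1.40",))
    B.rxn("LDH_L", {"pyr_c": -1, "nadh_c": -1, "h_c": -1, "lac__L_c": 1,
                    "nad_c": 1}, lb=-1000,
          name="L-lactate dehydrogenase", subsystem="Fermentation",
          ec=("1.1.1.27",))
    # reversible by curation: acetyl-CoA + formate <-> pyruvate + CoA
    B.rxn("PFL", {"pyr_c": -1, "coa_c": -1, "accoa_c": 1, "for_c": 1},
          lb=-1000, name="pyruvate formate-lyase (reversible)",
          subsystem="Fermentation", ec=("2.3.1.54",))
    B.rxn("PTAr", {"accoa_c": -1, "pi_c": -1, "actp_c": 1, "coa_c": 1},
          lb=-1000, name="phosphotransacetylase", subsystem="Fermentation",
          ec=("2.3.1.8",))
    B.rxn("ACKr", {"actp_c": -1, "adp_c": -1, "ac_c": 1, "atp_c": 1},
          lb=-1000, name="acetate kinase", subsystem="Fermentation",
          ec=("2.7.2.1",))
    B.rxn("ACALD", {"acald_c": -1, "coa_c": -1, "nad_c": -1, "accoa_c": 1,
                    "h_c": 1, "nadh_c": 1}, lb=-1000,
          name="acetaldehyde dehydrogenase (acylating)",
          subsystem="Fermentation", ec=("1.2.1.10",))
    B.rxn("ALCD2x", {"etoh_c": -1, "nad_c": -1, "acald_c": 1, "h_c": 1,
                     "nadh_c": 1}, lb=-1000,
          name="alcohol dehydrogenase", subsystem="Fermentation",
          ec=("1.1.1.1",))
    if include_pentose_entry:
        B.rxn("XYLI", {"xyl__D_c": -1, "xylu__D_c": 1}, lb=-1000,
              name="xylose isomerase", subsystem="Pentose entry",
              ec=("5.3.1.5",))
        B.rxn("XYLK", {"xylu__D_c": -1, "atp_c": -1, "xu5p__D_c": 1,
                       "adp_c": 1, "h_c": 1},
              name="xylulokinase", subsystem="Pentose entry",
              ec=("2.7.1.17",))


def make_core_model(spec: CoreModelSpec = CoreModelSpec()) -> MetabolicModel:
    """Generate the core bifid-shunt model.

    Defaults produce a hexose-fed network whose ATP-drain optimum secretes
    acetate and lactate at the theoretical 3:2 ratio when formate and
    ethanol routes are closed, and 1:1 on a pentose.  The optional biomass
    drain consumes PEP (among other precursors), which renders exclusive
    PEP:PTS hexose uptake infeasible whenever the drain is active.
    """
    B = ModelBuilder(spec.model_id, name="bifid shunt core model")
    add_central_carbon(B, include_pentose_entry=spec.include_pentose_route)

    # transport
    B.rxn("GLCt", {"glc__D_e": -1, "glc__D_c": 1}, lb=-1000,
          name="glucose permease (facilitated diffusion)",
          subsystem="Transport")
    if spec.include_pts_and_symport:
        B.rxn("GLCpts", {"glc__D_e": -1, "pep_c": -1, "g6p_c": 1,
                         "pyr_c": 1},
              name="glucose PEP:PTS", subsystem="Transport",
              ec=("2.7.1.199",))
        B.rxn("GLCt2", {"glc__D_e": -1, "h_e": -1, "glc__D_c": 1, "h_c": 1},
              name="glucose proton symporter", subsystem="Transport")
    if spec.include_pentose_route:
        B.rxn("XYLt", {"xyl__D_e": -1, "xyl__D_c": 1}, lb=-1000,
              name="xylose transport", subsystem="Transport")
    for sid in ("lac__L", "ac", "for", "etoh"):
        B.rxn(f"{sid.upper().replace('__', '_')}t",
              {f"{sid}_c": -1, f"{sid}_e": 1}, lb=-1000,
              name=f"{sid} transport", subsystem="Transport")
    B.rxn("H2Ot", {"h2o_e": -1, "h2o_c": 1}, lb=-1000,
          name="water transport", subsystem="Transport")
    B.rxn("Ht", {"h_e": -1, "h_c": 1}, lb=-1000,
          name="proton diffusion", subsystem="Transport")
    B.rxn("PIt", {"pi_e": -1, "pi_c": 1}, lb=-1000,
          name="phosphate transport", subsystem="Transport")

    # exchanges: water and protons freely exchangeable, everything else
    # closed for uptake until a medium or scenario opens it
    B.exchange("glc__D")
    if spec.include_pentose_route:
        B.exchange("xyl__D")
    for sid in ("lac__L", "ac", "for", "etoh"):
        B.exchange(sid)
    B.exchange("h", lb=-1000)
    B.exchange("h2o", lb=-1000)
    B.exchange("pi")

    B.rxn("ATPM", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1,
                   "h_c": 1}, lb=spec.maintenance_lb,
          name="ATP drain (maintenance)", subsystem="Biomass and maintenance")

    objective = "ATPM"
    if spec.include_biomass_drain:
        consumed = {"pep_c": spec.biomass_pep, "g6p_c": spec.biomass_g6p}
        released = {"pi_c": spec.biomass_pep + spec.biomass_g6p}
        B.recipe_pseudo("biomass_c", "biomass (core pseudo-species)",
                        consumed, released)
        B.recipe_synthesis("BIOMASS_core", "biomass_c", consumed, released,
                           atp_cost=spec.biomass_atp,
                           name="biomass drain (PEP/G6P precursors)",
                           subsystem="Biomass and maintenance")
        B.rxn("DM_biomass", {"biomass_c": -1},
              name="biomass sink", subsystem="Biomass and maintenance")
        objective = "BIOMASS_core"
    return B.build(objective_id=objective)
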