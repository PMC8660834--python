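"""Synthetic strain reconstructions of the two model bifidobacteria.

These are *synthetic stand-ins*, not the published genome-scale models:
compact, fully balanced networks that encode the documented strain-specific
physiology on top of the shared bifid-shunt core —

* carbohydrate transport/utilization complements (BB-12 grows on 6 of the
  12 panel sugars, BB-46 on all but mannose; BB-12 has only a PEP:PTS for
  fructose, BB-46 has both a glucose proton symporter and a glucose
  PEP:PTS);
* vitamin dependencies: both strains need pantethine for coenzyme A
  biosynthesis (no route from pantothenate); BB-12 needs nicotinate
  (no nicotinamidase, no aspartate route to NAD) and folate (no
  dihydropteroate-synthase route from 4-aminobenzoate), while BB-46 can use
  nicotinamide or aspartate and can build tetrahydrofolate from
  4-aminobenzoate; menaquinone-4 is a biomass requirement of BB-46 only;
* sulfur: cysteine and methionine are interconvertible (lumped routes), so
  either serves as the sole organic sulfur source;
* a biomass objective compiled from the strain composition table, a
  standalone ATP-hydrolysis maintenance reaction, and an F1F0 ATPase
  exporting three protons per ATP for transport energetics.

Biosynthesis of nucleotides, cell-wall polymers and lipids is represented
by elementally balanced lumped reactions (documented ATP and NADH costs),
not by the full pathways.
"""

from __future__ import annotations

from typing import Dict, Optional

from ..biomass import build_bof
from ..fba import RatioConstraint
from ..media import Medium, MediumComponent, Scenario, UNCONSTRAINED
from ..model import MetabolicModel, formula_weight
from ._builder import ModelBuilder
from .compositions import strain_composition
from .core import add_central_carbon
from .species import AMINO_ACIDS

__all__ = ["make_strain_model", "cdm_medium", "table2_scenario",
           "SUGAR_PANEL", "STRAIN_SUGAR_GROWTH"]

#: The twelve-carbohydrate utilization panel.
SUGAR_PANEL = ["glucose", "fructose", "sucrose", "raffinose", "melibiose",
               "lactose", "galactose", "mannose", "xylose", "arabinose",
               "lacto-N-biose", "galacto-N-biose"]

#: Observed growth/no-growth calls per strain (validated panel).
STRAIN_SUGAR_GROWTH = {
    "BB-12": {"glucose": True, "fructose": False, "sucrose": True,
              "raffinose": True, "melibiose": True, "lactose": True,
              "galactose": True, "mannose": False, "xylose": False,
              "arabinose": False, "lacto-N-biose": False,
              "galacto-N-biose": False},
    "BB-46": {s: (s != "mannose") for s in SUGAR_PANEL},
}

_SUGAR_EXCHANGE = {
    "glucose": "EX_glc__D_e", "fructose": "EX_fru_e", "sucrose": "EX_sucr_e",
    "raffinose": "EX_raffin_e", "melibiose": "EX_melib_e",
    "lactose": "EX_lcts_e", "galactose": "EX_gal_e", "mannose": "EX_man_e",
    "xylose": "EX_xyl__D_e", "arabinose": "EX_arab__L_e",
    "lacto-N-biose": "EX_lnb_e", "galacto-N-biose": "EX_gnb_e",
}


def _abc_import(B: ModelBuilder, rid: str, species: str, name: str) -> None:
    B.rxn(rid, {f"{species}_e": -1, "atp_c": -1, "h2o_c": -1,
                f"{species}_c": 1, "adp_c": 1, "pi_c": 1, "h_c": 1},
          name=name, subsystem="Transport")


def _symport(B: ModelBuilder, rid: str, species: str, name: str,
             reversible: bool = False) -> None:
    B.rxn(rid, {f"{species}_e": -1, "h_e": -1, f"{species}_c": 1, "h_c": 1},
          lb=-1000 if reversible else 0.0, name=name, subsystem="Transport")


def _passive(B: ModelBuilder, rid: str, species: str, name: str) -> None:
    B.rxn(rid, {f"{species}_e": -1, f"{species}_c": 1}, lb=-1000,
          name=name, subsystem="Transport")


def _add_sugar_machinery(B: ModelBuilder, strain: str) -> None:
    bb46 = strain == "BB-46"

    # glucose: BB-12 permease only; BB-46 proton symporter + PEP:PTS
    if bb46:
        _symport(B, "GLCt2", "glc__D", "glucose proton symporter")
        B.rxn("GLCpts", {"glc__D_e": -1, "pep_c": -1, "g6p_c": 1, "pyr_c": 1},
              name="glucose PEP:PTS", subsystem="Transport",
              ec=("2.7.1.199",))
    else:
        _passive(B, "GLCt", "glc__D", "glucose permease")
    B.exchange("glc__D")

    # fructose: BB-12 PEP:PTS only (hexose PTS alone cannot support growth);
    # BB-46 ABC importer; both carry an intracellular fructokinase
    if bb46:
        _abc_import(B, "FRUabc", "fru", "fructose ABC transporter")
    else:
        B.rxn("FRUpts", {"fru_e": -1, "pep_c": -1, "f6p_c": 1, "pyr_c": 1},
              name="fructose PEP:PTS", subsystem="Transport",
              ec=("2.7.1.202",))
    B.rxn("FRUK", {"fru_c": -1, "atp_c": -1, "f6p_c": 1, "adp_c": 1,
                   "h_c": 1},
          name="fructokinase", subsystem="Bifid shunt", ec=("2.7.1.4",))
    B.exchange("fru")

    # sucrose: proton symport; hydrolase (SUCR) and phosphorylase (SUCPHOS)
    _symport(B, "SUCRt2", "sucr", "sucrose proton symporter")
    B.rxn("SUCR", {"sucr_c": -1, "h2o_c": -1, "glc__D_c": 1, "fru_c": 1},
          name="sucrase", subsystem="Oligosaccharide catabolism",
          ec=("3.2.1.26",))
    B.rxn("SUCPHOS", {"sucr_c": -1, "pi_c": -1, "g1p_c": 1, "fru_c": 1},
          name="sucrose phosphorylase",
          subsystem="Oligosaccharide catabolism", ec=("2.4.1.7",))
    B.exchange("sucr")

    # raffinose and melibiose share the ABC transporter genes; raffinose
    # galactohydrolase yields galactose + sucrose
    _abc_import(B, "RAFFabc", "raffin", "raffinose ABC transporter")
    B.rxn("RAFGH", {"raffin_c": -1, "h2o_c": -1, "gal_c": 1, "sucr_c": 1},
          name="raffinose galactohydrolase",
          subsystem="Oligosaccharide catabolism", ec=("3.2.1.22",))
    B.exchange("raffin")
    _abc_import(B, "MELIBabc", "melib", "melibiose ABC transporter")
    B.rxn("MELIBGH", {"melib_c": -1, "h2o_c": -1, "gal_c": 1, "glc__D_c": 1},
          name="melibiose galactohydrolase",
          subsystem="Oligosaccharide catabolism", ec=("3.2.1.22",))
    B.exchange("melib")

    # lactose permease + beta-galactosidase
    _symport(B, "LCTSt2", "lcts", "lactose proton symporter")
    B.rxn("LCTSGH", {"lcts_c": -1, "h2o_c": -1, "gal_c": 1, "glc__D_c": 1},
          name="beta-galactosidase",
          subsystem="Oligosaccharide catabolism", ec=("3.2.1.23",))
    B.exchange("lcts")

    # galactose: symporter + Leloir entry (lumped epimerase/uridylyl step)
    _symport(B, "GALt2", "gal", "galactose proton symporter")
    B.rxn("GALK", {"gal_c": -1, "atp_c": -1, "gal1p_c": 1, "adp_c": 1,
                   "h_c": 1},
          name="galactokinase", subsystem="Leloir pathway", ec=("2.7.1.6",))
    B.rxn("GAL1PUT", {"gal1p_c": -1, "g1p_c": 1},
          name="galactose-1-phosphate uridylyltransferase + epimerase "
               "(lumped)", subsystem="Leloir pathway", ec=("2.7.7.12",))
    B.exchange("gal")

    # mannose: exchange only — neither strain transports or degrades it
    B.exchange("man")

    # pentoses (transport is BB-46 specific; isomerase/kinase in the core)
    if bb46:
        _symport(B, "XYLt2", "xyl__D", "xylose proton symporter")
        _symport(B, "ARBt2", "arab__L", "arabinose proton symporter")
        B.rxn("ARAI", {"arab__L_c": -1, "rbl__L_c": 1}, lb=-1000,
              name="arabinose isomerase", subsystem="Pentose entry",
              ec=("5.3.1.4",))
        B.rxn("RBK", {"rbl__L_c": -1, "atp_c": -1, "ru5p__D_c": 1,
                      "adp_c": 1, "h_c": 1},
              name="ribulokinase", subsystem="Pentose entry",
              ec=("2.7.1.16",))
    B.exchange("xyl__D")
    B.exchange("arab__L")

    # lacto-/galacto-N-biose: BB-46 gene cluster only
    if bb46:
        _abc_import(B, "LNBabc", "lnb", "lacto-N-biose ABC transporter")
        B.rxn("LNBP", {"lnb_c": -1, "pi_c": -1, "gal1p_c": 1, "acgam_c": 1},
              name="lacto-N-biose phosphorylase",
              subsystem="Oligosaccharide catabolism", ec=("2.4.1.211",))
        _abc_import(B, "GNBabc", "gnb", "galacto-N-biose ABC transporter")
        B.rxn("GNBP", {"gnb_c": -1, "pi_c": -1, "gal1p_c": 1, "acgam_c": 1},
              name="galacto-N-biose phosphorylase",
              subsystem="Oligosaccharide catabolism", ec=("2.4.1.211",))
        # N-acetylhexosamine catabolism (kinase/deacetylase/deaminase lump)
        B.rxn("ACGAMCAT", {"acgam_c": -1, "atp_c": -1, "h2o_c": -2,
                           "f6p_c": 1, "ac_c": 1, "nh4_c": 1, "adp_c": 1,
                           "h_c": 1},
              name="N-acetylhexosamine catabolism (lumped)",
              subsystem="Oligosaccharide catabolism")
    B.exchange("lnb")
    B.exchange("gnb")


def _add_vitamin_pathways(B: ModelBuilder, strain: str) -> None:
    bb46 = strain == "BB-46"

    # pantethine -> pantetheine -> 4'-phosphopantetheine -> CoA; the
    # pantothenate branch (PPNCL3/PPCDC) is absent in both strains, so the
    # pantothenate importer leads nowhere.
    _symport(B, "PTTt", "ptth", "pantethine proton symporter")
    B.exchange("ptth")
    B.rxn("PTTR", {"ptth_c": -1, "nadh_c": -1, "h_c": -1, "pan4p_c": 2,
                   "nad_c": 1},
          name="pantethine reductase", subsystem="Cofactor biosynthesis")
    B.rxn("PTTK", {"pan4p_c": -1, "atp_c": -1, "ppant_c": 1, "adp_c": 1,
                   "h_c": 1},
          name="pantetheine kinase", subsystem="Cofactor biosynthesis",
          ec=("2.7.1.33",))
    B.rxn("PPCOAS", {"ppant_c": -1, "atp_c": -2, "coa_c": 1, "ppi_c": 1,
                     "adp_c": 1},
          name="phosphopantetheine adenylyltransferase + dephospho-CoA "
               "kinase (lumped)", subsystem="Cofactor biosynthesis",
          ec=("2.7.7.3", "2.7.1.24"))
    B.rxn("PPA", {"ppi_c": -1, "h2o_c": -1, "pi_c": 2, "h_c": 1},
          name="inorganic pyrophosphatase", subsystem="Cofactor biosynthesis",
          ec=("3.6.1.1",))
    _symport(B, "PNTOt2", "pnto__R", "pantothenate proton symporter")
    B.exchange("pnto__R")

    # NAD+: nicotinate salvage in both; nicotinamidase and the
    # aspartate/quinolinate de-novo route only in BB-46
    _passive(B, "NACt", "nac", "nicotinate transport")
    B.exchange("nac")
    _passive(B, "NCAMt", "ncam", "nicotinamide transport")
    B.exchange("ncam")
    B.balanced("NADS", {"nac_c": -1, "r5p_c": -1, "amp_c": -1, "nad_c": 1},
               atp_cost=2, name="NAD+ salvage from nicotinate (lumped)",
               subsystem="Cofactor biosynthesis", ec=("6.3.4.21",))
    if bb46:
        B.rxn("NNAM", {"ncam_c": -1, "h2o_c": -1, "nac_c": 1, "nh4_c": 1},
              name="nicotinamidase", subsystem="Cofactor biosynthesis",
              ec=("3.5.1.19",))
        B.balanced("NADS_ASP", {"asp__L_c": -1, "g3p_c": -1, "amp_c": -1,
                                "nad_c": 1},
                   atp_cost=2,
                   name="NAD+ de novo from aspartate (lumped quinolinate "
                        "route)", subsystem="Cofactor biosynthesis")

    # folate: reduction to THF in both; 4-aminobenzoate route (DHPS2 and
    # downstream, lumped) only in BB-46
    _passive(B, "FOLt", "fol", "folate transport")
    B.exchange("fol")
    B.rxn("THFR", {"fol_c": -1, "nadh_c": -2, "h_c": -2, "thf_c": 1,
                   "nad_c": 2},
          name="folate reduction to tetrahydrofolate",
          subsystem="Cofactor biosynthesis", ec=("1.5.1.3",))
    _passive(B, "4ABZt", "4abz", "4-aminobenzoate transport")
    B.exchange("4abz")
    if bb46:
        B.balanced("THFS_ABZ", {"4abz_c": -1, "glu__L_c": -1, "amp_c": -1,
                                "thf_c": 1},
                   atp_cost=3,
                   name="tetrahydrofolate synthesis from 4-aminobenzoate "
                        "(lumped, dihydropteroate synthase route)",
                   subsystem="Cofactor biosynthesis", ec=("2.5.1.15",))

    # menaquinone-4, thiamine, riboflavin, biotin: uptake only (no
    # biosynthesis in either strain)
    for vit in ("mqn4", "thm", "ribflv", "btn"):
        _passive(B, f"{vit.upper()}t", vit, f"{vit} transport")
        B.exchange(vit)

    # polyamines: transportable, never synthesized
    for pa in ("ptrc", "spmd"):
        _symport(B, f"{pa.upper()}t2", pa, f"{pa} proton symporter")
        B.exchange(pa)


def _add_nucleotide_synthesis(B: ModelBuilder) -> None:
    B.balanced("AMPS", {"r5p_c": -1, "amp_c": 1}, atp_cost=6,
               name="AMP de novo synthesis (lumped purine pathway)",
               subsystem="Nucleotide biosynthesis")
    # adenylate kinase links de-novo AMP into the ATP/ADP pool
    B.rxn("ADK1", {"amp_c": -1, "atp_c": -1, "adp_c": 2}, lb=-1000,
          name="adenylate kinase", subsystem="Nucleotide biosynthesis",
          ec=("2.7.4.3",))
    B.balanced("GMPS", {"amp_c": -1, "gmp_c": 1}, atp_cost=1,
               name="GMP from AMP (lumped)",
               subsystem="Nucleotide biosynthesis")
    B.balanced("UMPS", {"r5p_c": -1, "asp__L_c": -1, "ump_c": 1}, atp_cost=2,
               name="UMP de novo synthesis (lumped orotate pathway)",
               subsystem="Nucleotide biosynthesis")
    B.balanced("CMPS", {"ump_c": -1, "cmp_c": 1}, atp_cost=1,
               name="CMP from UMP (lumped amination)",
               subsystem="Nucleotide biosynthesis")
    for nmp, dnmp in (("amp", "damp"), ("gmp", "dgmp"), ("cmp", "dcmp")):
        B.balanced(f"RNDR_{nmp}", {f"{nmp}_c": -1, f"{dnmp}_c": 1},
                   name=f"ribonucleotide reduction ({nmp} -> {dnmp}, lumped)",
                   subsystem="Nucleotide biosynthesis", ec=("1.17.4.1",))
    B.balanced("DTMPS", {"ump_c": -1, "dtmp_c": 1},
               name="dTMP from UMP (lumped reduction + methylation)",
               subsystem="Nucleotide biosynthesis")


def _add_macromolecule_recipes(B: ModelBuilder, strain: str) -> Dict[str, float]:
    """Recipe-defined pseudo-monomers; returns their molar masses."""
    interpeptide = "orn__L_c" if strain == "BB-46" else "lys__L_c"
    recipes = {
        "glycogen_c": ("glycogen residue (glucan)",
                       {"g6p_c": 1}, {"pi_c": 1}, "GLYCS", 1,
                       "glycogen synthesis (residue, lumped)"),
        "cps_c": ("capsular polysaccharide residue",
                  {"g6p_c": 1}, {"pi_c": 1}, "CPSS", 2,
                  "capsular polysaccharide synthesis (residue, lumped)"),
        "lta_c": ("lipoteichoic acid residue (glycerophosphate)",
                  {"g3p_c": 1, "nadh_c": 1, "h_c": 1}, {"nad_c": 1},
                  "LTAS", 1, "lipoteichoic acid synthesis (residue, lumped)"),
        "lipid_c": ("membrane lipid (average phospholipid)",
                    {"accoa_c": 16, "g3p_c": 1, "nadh_c": 28, "h_c": 28},
                    {"coa_c": 16, "nad_c": 28, "h2o_c": 14},
                    "LIPS", 2, "phospholipid synthesis (lumped)"),
        "peptidoglycan_c": (
            f"peptidoglycan residue "
            f"({'A3beta, ornithine' if strain == 'BB-46' else 'A3alpha, lysine'})",
            {"g6p_c": 2, "pep_c": 1, "accoa_c": 2, "ala__L_c": 2,
             "glu__L_c": 1, interpeptide: 1, "nh4_c": 2},
            {"coa_c": 2, "pi_c": 2, "h2o_c": 6},
            "PGS", 4, "peptidoglycan subunit synthesis (lumped)"),
    }
    masses: Dict[str, float] = {}
    for pid, (pname, consumed, released, rid, atp, rname) in recipes.items():
        species = B.recipe_pseudo(pid, pname, consumed, released)
        B.recipe_synthesis(rid, pid, consumed, released, atp_cost=atp,
                           name=rname, subsystem="Macromolecule synthesis")
        masses[pid] = formula_weight(species.formula)
    # pooled inorganic ions: imported, not synthesized
    _passive(B, "IONSt", "ions", "pooled ion transport")
    B.exchange("ions")
    masses["ions_c"] = formula_weight(B.ensure("ions_c").formula)
    return masses


def make_strain_model(strain: str, gam: float = 39.31, ngam: float = 5.0,
                      include_polyamines: bool = False) -> MetabolicModel:
    """Build the synthetic reconstruction of one strain.

    ``gam``/``ngam`` default to the customary anaerobe initialization
    (39.31 mmol ATP/gCDW and 5 mmol ATP/gCDW/h) used before fitting.
    ``include_polyamines`` restores putrescine/spermidine to the biomass
    (the pre-curation state).
    """
    if strain not in ("BB-12", "BB-46"):
        raise ValueError(f"unknown strain {strain!r}; use 'BB-12' or 'BB-46'")
    tag = strain.replace("-", "")
    B = ModelBuilder(f"{tag}_synthetic",
                     name=f"{strain} synthetic strain reconstruction")

    add_central_carbon(B, include_pentose_entry=True)
    _add_sugar_machinery(B, strain)

    # fermentation product export: proton-coupled acid efflux (electro-
    # neutral), passive ethanol/CO2/water diffusion
    for acid in ("lac__L", "ac", "for", "succ"):
        B.rxn(f"{acid.upper().replace('__', '_')}t2r",
              {f"{acid}_c": -1, "h_c": -1, f"{acid}_e": 1, "h_e": 1},
              lb=-1000, name=f"{acid} proton-coupled efflux",
              subsystem="Transport")
        B.exchange(acid)
    _passive(B, "ETOHt", "etoh", "ethanol diffusion")
    B.exchange("etoh")
    _passive(B, "CO2t", "co2", "CO2 diffusion")
    B.exchange("co2")
    _passive(B, "H2Ot", "h2o", "water diffusion")
    B.exchange("h2o", lb=-1000)
    B.exchange("h", lb=-1000)

    # nitrogen, phosphate, pooled ions
    _passive(B, "NH4t", "nh4", "ammonium transport")
    B.exchange("nh4")
    _symport(B, "PIt2", "pi", "phosphate proton symporter")
    B.exchange("pi")

    # amino acid uptake (proton symport)
    for aa in AMINO_ACIDS:
        _symport(B, f"{aa.split('__')[0].upper()}t2", aa,
                 f"{aa} proton symporter")
        B.exchange(aa)

    # F1F0 ATPase: exports 3 H+ per ATP (one scalar chemical proton plus
    # two translocated) — the only primary proton pump of the anaerobe
    B.rxn("ATPS3r", {"atp_c": -1, "h2o_c": -1, "h_c": -2, "adp_c": 1,
                     "pi_c": 1, "h_e": 3},
          name="F1F0 ATPase (proton export, 3 H+/ATP)",
          subsystem="Energy metabolism", ec=("7.1.2.2",))
    # inward-only membrane proton leak: dissipates the gradient, can never
    # act as a pump, so it cannot create energy
    B.rxn("Hleak", {"h_e": -1, "h_c": 1},
          name="proton leak (inward)", subsystem="Energy metabolism")

    # sulfur amino-acid interconversion (lumped both directions; the
    # methionine->cysteine route lets methionine serve as sole S source)
    B.balanced("CYSMET", {"cys__L_c": -1, "met__L_c": 1}, atp_cost=1,
               name="methionine synthesis from cysteine (lumped "
                    "transsulfuration + methylation)",
               subsystem="Amino acid metabolism")
    B.balanced("METCYS", {"met__L_c": -1, "cys__L_c": 1}, atp_cost=1,
               name="cysteine synthesis from methionine (lumped "
                    "S-adenosylmethionine route)",
               subsystem="Amino acid metabolism")
    if strain == "BB-46":
        B.balanced("ORNS", {"glu__L_c": -1, "orn__L_c": 1}, atp_cost=1,
                   name="ornithine synthesis from glutamate (lumped)",
                   subsystem="Amino acid metabolism")

    # minor succinate branch: aspartate deamination to fumarate, then
    # fumarate reduction (low capacity keeps the headline ratios clean)
    B.rxn("ASPFUM", {"asp__L_c": -1, "fum_c": 1, "nh4_c": 1},
          name="aspartate ammonia-lyase", subsystem="Fermentation",
          ec=("4.3.1.1",))
    B.rxn("FRD", {"fum_c": -1, "nadh_c": -1, "h_c": -1, "succ_c": 1,
                  "nad_c": 1}, ub=0.5,
          name="fumarate reductase (low capacity)",
          subsystem="Fermentation", ec=("1.3.5.4",))

    _add_vitamin_pathways(B, strain)
    _add_nucleotide_synthesis(B)
    pseudo_masses = _add_macromolecule_recipes(B, strain)

    # biomass objective from the composition table
    composition = strain_composition(strain, gam=gam,
                                     include_polyamines=include_polyamines,
                                     pseudo_masses=pseudo_masses)
    B.pseudo("biomass_c", "biomass", {}, 0.0)
    bof = build_bof(composition, B.model.metabolites,
                    biomass_met="biomass_c", reaction_id="BIOMASS")
    # give the biomass pseudo-species the exact element content implied by
    # the drain so even the BOF itself is elementally closed
    flows: Dict[str, float] = {}
    charge = 0.0
    for met_id, coef in bof.stoichiometry.items():
        if met_id == "biomass_c":
            continue
        species = B.model.metabolites[met_id]
        for el, count in species.formula.items():
            flows[el] = flows.get(el, 0.0) - coef * count
        charge -= coef * species.charge
    bm = B.model.metabolites["biomass_c"]
    bm.formula = {el: round(n, 9) for el, n in flows.items()
                  if abs(n) > 1e-9}
    bm.charge = round(charge, 9)
    B.model.add_reaction(bof)
    B.rxn("DM_biomass", {"biomass_c": -1}, name="biomass sink",
          subsystem="Biomass and maintenance")

    B.rxn("ATPM", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1,
                   "h_c": 1}, lb=ngam,
          name="non-growth maintenance ATP hydrolysis",
          subsystem="Biomass and maintenance")

    # plausible GPR assignments (synthetic locus tags); pantethine
    # transport/reduction stay gene-free, mirroring their unresolved basis
    prefix = "Balat" if strain == "BB-12" else "BL46"
    gprs = {
        "HEX1": "0127", "PGI": "0214", "PGMT": "0295",
        "F6PPK": "0576", "PK": "0576",      # one dual-specificity enzyme
        "TALA": "0801", "TKT1": "0802", "RPE": "0803", "RPI": "0804",
        "GAPD": "0911", "PGK": "0912", "PGM": "0913", "ENO": "0914",
        "PYK": "0920", "LDH_L": "1034", "PFL": "1101 and 1102",
        "PTAr": "1190", "ACKr": "1191",
        "ACALD": "1230", "ALCD2x": "1230",  # bifunctional adhE
        "SUCR": "0310 or 0311", "SUCPHOS": "0312",
        "GALK": "0420", "GAL1PUT": "0421 and 0422", "FRUK": "0515",
        "PTTK": "0640",                      # broad-spectrum PanK
        "THFR": "0712", "ADK1": "0055",
        "ATPS3r": "1501 and 1502 and 1503",
        "RAFFabc": "0960 and 0961", "MELIBabc": "0960 and 0961",
        "UMPS": "1310", "AMPS": "1320",
    }
    if strain == "BB-46":
        gprs.update({"NNAM": "0733", "NADS_ASP": "0734 and 0735",
                     "THFS_ABZ": "0740", "XYLt2": "0850", "XYLI": "0851",
                     "XYLK": "0852", "ARBt2": "0860", "ARAI": "0861",
                     "RBK": "0862", "LNBP": "0875", "GNBP": "0875",
                     "GLCpts": "0880", "FRUabc": "0890 and 0891",
                     "ORNS": "0930"})
    else:
        gprs.update({"FRUpts": "0880"})
    import re as _re
    for rid, rule in gprs.items():
        if rid in B.model.reactions:
            B.model.reactions[rid].gene_rule = _re.sub(
                r"(\d{4})", rf"{prefix}_\1", rule)
    B.model.gene_ids |= B.model.genes_in_rules()
    return B.build(objective_id="BIOMASS")


# ---------------------------------------------------------------------------
# the chemically defined medium and the quantitative-validation scenario
# ---------------------------------------------------------------------------

#: nutrient -> (concentration, unit, exchange id or None).  ``None`` marks
#: documentation-only components with no counterpart in the models.
_CDM_TABLE = {
    "sucrose": (10.0, "g/L", "EX_sucr_e"),
    "NH4Cl": (1.0, "g/L", "EX_nh4_e"),
    "citrate": (0.6, "g/L", None),
    "NaHCO3": (0.42, "g/L", "EX_co2_e"),
    "FeCl2 4H2O": (6.5e-3, "g/L", "EX_ions_e"),
    "MnCl2 4H2O": (23.1e-3, "g/L", "EX_ions_e"),
    "ZnCl2": (7e-5, "g/L", "EX_ions_e"),
    "H3BO3": (6e-6, "g/L", "EX_ions_e"),
    "CoCl2 6H2O": (1.9e-4, "g/L", "EX_ions_e"),
    "CuCl2 2H2O": (2e-6, "g/L", "EX_ions_e"),
    "NiCl2 6H2O": (2.4e-5, "g/L", "EX_ions_e"),
    "MgCl2 6H2O": (0.4, "g/L", "EX_ions_e"),
    "CaCl2 2H2O": (0.05, "g/L", "EX_ions_e"),
    "cysteine-HCl": (0.5, "g/L", "EX_cys__L_e"),
    "K2HPO4": (8.7, "g/L", "EX_pi_e"),
    "KH2PO4": (6.1, "g/L", "EX_pi_e"),
    "para-aminobenzoic acid": (5e-4, "g/L", "EX_4abz_e"),
    "calcium pantothenate": (4e-3, "g/L", "EX_pnto__R_e"),
    "pantethine": (1e-2, "g/L", "EX_ptth_e"),
    "biotin": (2e-4, "g/L", "EX_btn_e"),
    "folic acid": (2e-4, "g/L", "EX_fol_e"),
    "nicotinamide": (5e-4, "g/L", "EX_ncam_e"),
    "nicotinic acid": (5e-3, "g/L", "EX_nac_e"),
    "pyridoxal-HCl": (2e-3, "g/L", None),
    "riboflavin": (5e-4, "g/L", "EX_ribflv_e"),
    "thiamine-HCl": (5e-4, "g/L", "EX_thm_e"),
    "cobalamin": (5e-4, "g/L", None),
    "thioctic acid": (5e-4, "g/L", None),
    "menaquinone-4": (1e-3, "g/L", "EX_mqn4_e"),
    "Tween 80": (1.0, "mL/L", None),
    # solvent and buffered protons, implicit in any aqueous medium
    "water": (0.0, "", "EX_h2o_e"),
    "protons": (0.0, "", "EX_h_e"),
}

_AA_NAMES = {
    "ala__L": "L-alanine", "arg__L": "L-arginine", "asn__L": "L-asparagine",
    "asp__L": "L-aspartic acid", "gln__L": "L-glutamine",
    "glu__L": "L-glutamic acid", "gly": "glycine", "his__L": "L-histidine",
    "ile__L": "L-isoleucine", "leu__L": "L-leucine", "lys__L": "L-lysine",
    "met__L": "L-methionine", "phe__L": "L-phenylalanine",
    "pro__L": "L-proline", "ser__L": "L-serine", "thr__L": "DL-threonine",
    "trp__L": "L-tryptophan", "tyr__L": "L-tyrosine", "val__L": "L-valine",
}


def cdm_medium(carbon_source: str = "sucrose",
               name: str = "CDM") -> Medium:
    """The chemically defined medium as a Medium object.

    All nutrients are supplied with unconstrained uptake (batch
    availability); ``carbon_source`` picks the carbohydrate from the
    twelve-sugar panel (or ``None`` for the carbohydrate-free base).
    """
    components = {}
    exchange_map = {}
    for nutrient, (conc, unit, ex) in _CDM_TABLE.items():
        if nutrient == "sucrose":
            continue
        components[nutrient] = MediumComponent(conc, unit, UNCONSTRAINED)
        exchange_map[nutrient] = ex
    for aa, aa_name in _AA_NAMES.items():
        components[aa_name] = MediumComponent(0.04, "g/L", UNCONSTRAINED)
        exchange_map[aa_name] = f"EX_{aa}_e"
    # the full sugar-panel mapping ships with the medium so that screens
    # can add any panel carbohydrate by name
    exchange_map.update(_SUGAR_EXCHANGE)
    if carbon_source is not None:
        if carbon_source not in _SUGAR_EXCHANGE:
            raise KeyError(f"unknown carbohydrate {carbon_source!r}")
        components[carbon_source] = MediumComponent(10.0, "g/L",
                                                    UNCONSTRAINED)
    return Medium(name=name, components=components,
                  exchange_map=exchange_map)


def table2_scenario(strain: str, sucrose_uptake: float,
                    acetate_lactate_ratio: float,
                    amino_acid_cap: float = 1.0) -> Scenario:
    """The quantitative-validation constraint recipe for one strain:
    sucrose uptake fixed, acetate:lactate pinned, amino-acid uptake capped.
    """
    medium = cdm_medium("sucrose", name=f"CDM ({strain})")
    caps = {f"EX_{aa}_e": amino_acid_cap for aa in AMINO_ACIDS}
    return Scenario(
        name=f"{strain} quantitative validation",
        medium=medium,
        objective_id="BIOMASS",
        ratio_constraints=[RatioConstraint("EX_ac_e", "EX_lac__L_e",
                                           acetate_lactate_ratio)],
        fixed_uptakes={"EX_sucr_e": sucrose_uptake},
        uptake_caps=caps)
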