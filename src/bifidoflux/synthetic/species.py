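"""Chemical species registry for the generated models.

Formulas and charges follow the usual charged (pH 7) reconstruction
conventions so that every generated internal reaction passes the
element/charge audit.  Pseudo-species (biomass, macromolecular residues,
the pooled ion species) carry composite formulas; their docstrings in the
builder modules say how they were derived.
"""

from __future__ import annotations

from typing import Dict, Tuple

from ..model import Metabolite, parse_formula

__all__ = ["SPECIES", "met", "AMINO_ACIDS"]

# id -> (name, formula, charge)
SPECIES: Dict[str, Tuple[str, str, float]] = {
    # central carbon
    "glc__D": ("D-glucose", "C6H12O6", 0),
    "fru": ("D-fructose", "C6H12O6", 0),
    "gal": ("D-galactose", "C6H12O6", 0),
    "man": ("D-mannose", "C6H12O6", 0),
    "sucr": ("sucrose", "C12H22O11", 0),
    "lcts": ("lactose", "C12H22O11", 0),
    "melib": ("melibiose", "C12H22O11", 0),
    "raffin": ("raffinose", "C18H32O16", 0),
    "lnb": ("lacto-N-biose", "C14H25NO11", 0),
    "gnb": ("galacto-N-biose", "C14H25NO11", 0),
    "acgam": ("N-acetyl-D-hexosamine", "C8H15NO6", 0),
    "xyl__D": ("D-xylose", "C5H10O5", 0),
    "xylu__D": ("D-xylulose", "C5H10O5", 0),
    "arab__L": ("L-arabinose", "C5H10O5", 0),
    "rbl__L": ("L-ribulose", "C5H10O5", 0),
    "g6p": ("D-glucose 6-phosphate", "C6H11O9P", -2),
    "g1p": ("D-glucose 1-phosphate", "C6H11O9P", -2),
    "gal1p": ("D-galactose 1-phosphate", "C6H11O9P", -2),
    "f6p": ("D-fructose 6-phosphate", "C6H11O9P", -2),
    "e4p": ("D-erythrose 4-phosphate", "C4H7O7P", -2),
    "xu5p__D": ("D-xylulose 5-phosphate", "C5H9O8P", -2),
    "ru5p__D": ("D-ribulose 5-phosphate", "C5H9O8P", -2),
    "r5p": ("D-ribose 5-phosphate", "C5H9O8P", -2),
    "s7p": ("sedoheptulose 7-phosphate", "C7H13O10P", -2),
    "g3p": ("glyceraldehyde 3-phosphate", "C3H5O6P", -2),
    "13dpg": ("1,3-bisphospho-D-glycerate", "C3H4O10P2", -4),
    "3pg": ("3-phospho-D-glycerate", "C3H4O7P", -3),
    "2pg": ("2-phospho-D-glycerate", "C3H4O7P", -3),
    "pep": ("phosphoenolpyruvate", "C3H2O6P", -3),
    "pyr": ("pyruvate", "C3H3O3", -1),
    "lac__L": ("L-lactate", "C3H5O3", -1),
    "actp": ("acetyl phosphate", "C2H3O5P", -2),
    "ac": ("acetate", "C2H3O2", -1),
    "accoa": ("acetyl-CoA", "C23H34N7O17P3S", -4),
    "coa": ("coenzyme A", "C21H32N7O16P3S", -4),
    "for": ("formate", "CHO2", -1),
    "acald": ("acetaldehyde", "C2H4O", 0),
    "etoh": ("ethanol", "C2H6O", 0),
    "succ": ("succinate", "C4H4O4", -2),
    "fum": ("fumarate", "C4H2O4", -2),
    # energy / redox / inorganics
    "atp": ("ATP", "C10H12N5O13P3", -4),
    "adp": ("ADP", "C10H12N5O10P2", -3),
    "pi": ("phosphate", "HO4P", -2),
    "ppi": ("diphosphate", "HO7P2", -3),
    "nad": ("NAD+", "C21H26N7O14P2", -1),
    "nadh": ("NADH", "C21H27N7O14P2", -2),
    "h": ("proton", "H", 1),
    "h2o": ("water", "H2O", 0),
    "co2": ("carbon dioxide", "CO2", 0),
    "nh4": ("ammonium", "H4N", 1),
    "ions": ("pooled inorganic ions", "K1Mg0.2Cl1O1.2P0.3H0.1S0.05Fe0.02", 0),
    # amino acids
    "ala__L": ("L-alanine", "C3H7NO2", 0),
    "arg__L": ("L-arginine", "C6H15N4O2", 1),
    "asn__L": ("L-asparagine", "C4H8N2O3", 0),
    "asp__L": ("L-aspartate", "C4H6NO4", -1),
    "cys__L": ("L-cysteine", "C3H7NO2S", 0),
    "gln__L": ("L-glutamine", "C5H10N2O3", 0),
    "glu__L": ("L-glutamate", "C5H8NO4", -1),
    "gly": ("glycine", "C2H5NO2", 0),
    "his__L": ("L-histidine", "C6H9N3O2", 0),
    "ile__L": ("L-isoleucine", "C6H13NO2", 0),
    "leu__L": ("L-leucine", "C6H13NO2", 0),
    "lys__L": ("L-lysine", "C6H15N2O2", 1),
    "met__L": ("L-methionine", "C5H11NO2S", 0),
    "orn__L": ("L-ornithine", "C5H13N2O2", 1),
    "phe__L": ("L-phenylalanine", "C9H11NO2", 0),
    "pro__L": ("L-proline", "C5H9NO2", 0),
    "ser__L": ("L-serine", "C3H7NO3", 0),
    "thr__L": ("L-threonine", "C4H9NO3", 0),
    "trp__L": ("L-tryptophan", "C11H12N2O2", 0),
    "tyr__L": ("L-tyrosine", "C9H11NO3", 0),
    "val__L": ("L-valine", "C5H11NO2", 0),
    # nucleotides (monophosphates are the polymer residues' free forms)
    "amp": ("AMP", "C10H12N5O7P", -2),
    "gmp": ("GMP", "C10H12N5O8P", -2),
    "cmp": ("CMP", "C9H12N3O8P", -2),
    "ump": ("UMP", "C9H11N2O9P", -2),
    "damp": ("dAMP", "C10H12N5O6P", -2),
    "dgmp": ("dGMP", "C10H12N5O7P", -2),
    "dcmp": ("dCMP", "C9H12N3O7P", -2),
    "dtmp": ("dTMP", "C10H13N2O8P", -2),
    # vitamins and cofactors
    "ptth": ("pantethine", "C22H42N4O8S2", 0),
    "pan4p": ("pantetheine", "C11H22N2O4S", 0),
    "ppant": ("4'-phosphopantetheine", "C11H21N2O7PS", -2),
    "pnto__R": ("(R)-pantothenate", "C9H16NO5", -1),
    "nac": ("nicotinate", "C6H4NO2", -1),
    "ncam": ("nicotinamide", "C6H6N2O", 0),
    "fol": ("folate", "C19H19N7O6", -2),
    "thf": ("tetrahydrofolate", "C19H23N7O6", -2),
    "4abz": ("4-aminobenzoate", "C7H6NO2", -1),
    "mqn4": ("menaquinone-4", "C31H40O2", 0),
    "thm": ("thiamine", "C12H17N4OS", 1),
    "ribflv": ("riboflavin", "C17H20N4O6", 0),
    "btn": ("biotin", "C10H15N2O3S", -1),
    "ptrc": ("putrescine", "C4H14N2", 2),
    "spmd": ("spermidine", "C7H22N3", 3),
}

#: The 20 proteinogenic amino-acid metabolite ids.
AMINO_ACIDS = [
    "ala__L", "arg__L", "asn__L", "asp__L", "cys__L", "gln__L", "glu__L",
    "gly", "his__L", "ile__L", "leu__L", "lys__L", "met__L", "phe__L",
    "pro__L", "ser__L", "thr__L", "trp__L", "tyr__L", "val__L",
]


def met(species_id: str, compartment: str = "c") -> Metabolite:
    """Instantiate a registry species in a compartment (id gets ``_c``/``_e``)."""
    name, formula, charge = SPECIES[species_id]
    return Metabolite(id=f"{species_id}_{compartment}", name=name,
                      compartment=compartment,
                      formula=parse_formula(formula), charge=float(charge))
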