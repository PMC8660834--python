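"""Biomass compositions of the two synthetic strain reconstructions.

The measured macromolecular fractions of *B. animalis* subsp. *lactis*
BB-12 anchor the table: protein 52.2%, DNA 3.77% and RNA 4.9% (w/w).  The
remaining 39.13% is distributed over cell-wall polymers, lipids, inorganic
ions and the soluble pool using ratios typical of Gram-positive bacteria;
these splits, the codon-usage-style amino-acid table and the ion/soluble
pool species are literature-informed reconstructions, not measured values.

The BB-46 variant differs in its peptidoglycan interpeptide residue
(L-ornithine, cell-wall type A3beta, versus L-lysine, A3alpha) and carries
menaquinone-4 in the soluble pool, reflecting its absolute requirement for
the vitamin.
"""

from __future__ import annotations

from typing import Dict

from ..biomass import BiomassComposition
from ..model import formula_weight, parse_formula
from .species import SPECIES, AMINO_ACIDS

__all__ = ["strain_composition", "MACRO_FRACTIONS", "PROTEIN_MOLE_FRACTIONS"]

_WATER = 18.015

#: Mass fractions g/gCDW.  Protein/DNA/RNA are the measured values; the
#: rest is the reconstructed remainder (sums to 1).
MACRO_FRACTIONS: Dict[str, float] = {
    "protein": 0.522,
    "dna": 0.0377,
    "rna": 0.049,
    "carbohydrate": 0.08,
    "peptidoglycan": 0.10,
    "capsular_polysaccharide": 0.06,
    "lipoteichoic_acid": 0.02,
    "lipids": 0.07,
    "ions": 0.03,
    "soluble_pool": 0.0313,
}

#: Codon-usage-style average amino-acid mole fractions (normalized below).
PROTEIN_MOLE_FRACTIONS: Dict[str, float] = {
    "ala__L": 0.102, "arg__L": 0.057, "asn__L": 0.036, "asp__L": 0.055,
    "cys__L": 0.009, "gln__L": 0.036, "glu__L": 0.061, "gly": 0.084,
    "his__L": 0.019, "ile__L": 0.053, "leu__L": 0.094, "lys__L": 0.051,
    "met__L": 0.022, "phe__L": 0.036, "pro__L": 0.046, "ser__L": 0.057,
    "thr__L": 0.058, "trp__L": 0.012, "tyr__L": 0.027, "val__L": 0.075,
}

#: RNA NMP mole fractions (high-GC genome).
_RNA = {"amp_c": 0.26, "gmp_c": 0.32, "cmp_c": 0.22, "ump_c": 0.20}
#: DNA dNMP mole fractions at ~60% G+C.
_DNA = {"damp_c": 0.20, "dgmp_c": 0.30, "dcmp_c": 0.30, "dtmp_c": 0.20}

#: Soluble pool (mole fractions); glutamate dominates as the major
#: intracellular anion, cofactors at trace levels.
_SOLUBLE = {
    "glu__L_c": 0.40, "gly_c": 0.20, "amp_c": 0.12, "nad_c": 0.12,
    "coa_c": 0.05, "thf_c": 0.03, "thm_c": 0.03, "ribflv_c": 0.03,
    "btn_c": 0.02,
}


def _normalize(table: Dict[str, float]) -> Dict[str, float]:
    total = sum(table.values())
    return {k: v / total for k, v in table.items()}


def _free_mass(met_full_id: str) -> float:
    species_id = met_full_id.rsplit("_", 1)[0]
    return formula_weight(parse_formula(SPECIES[species_id][1]))


def strain_composition(strain: str, gam: float = 39.31,
                       include_polyamines: bool = False,
                       pseudo_masses: Dict[str, float] = None,
                       ) -> BiomassComposition:
    """Composition table for one strain ("BB-12" or "BB-46").

    ``pseudo_masses`` supplies the molar masses of the recipe-defined
    pseudo-monomers (peptidoglycan, polysaccharides, lipoteichoic acid,
    lipid, pooled ions), which depend on the strain builder's recipes.
    ``include_polyamines`` restores putrescine and spermidine to the
    soluble pool (the pre-curation state; both were removed after omission
    experiments showed no requirement).
    """
    if strain not in ("BB-12", "BB-46"):
        raise ValueError(f"unknown strain {strain!r}")
    pseudo_masses = pseudo_masses or {}

    protein = _normalize({f"{aa}_c": x
                          for aa, x in PROTEIN_MOLE_FRACTIONS.items()})
    soluble = dict(_SOLUBLE)
    if strain == "BB-46":
        soluble["mqn4_c"] = 0.02
        soluble["glu__L_c"] -= 0.02
    if include_polyamines:
        soluble["ptrc_c"] = 0.05
        soluble["spmd_c"] = 0.03
        soluble["glu__L_c"] -= 0.08
    soluble = _normalize(soluble)

    monomer_tables = {
        "protein": protein,
        "dna": dict(_DNA),
        "rna": dict(_RNA),
        "carbohydrate": {"glycogen_c": 1.0},
        "peptidoglycan": {"peptidoglycan_c": 1.0},
        "capsular_polysaccharide": {"cps_c": 1.0},
        "lipoteichoic_acid": {"lta_c": 1.0},
        "lipids": {"lipid_c": 1.0},
        "ions": {"ions_c": 1.0},
        "soluble_pool": soluble,
    }

    masses: Dict[str, float] = {}
    for met in protein:
        masses[met] = _free_mass(met) - _WATER        # peptide residue
    for met in list(_RNA) + list(_DNA):
        masses[met] = _free_mass(met) - _WATER        # phosphodiester residue
    for met in soluble:
        masses.setdefault(met, _free_mass(met))       # free metabolites
    masses["ions_c"] = formula_weight(parse_formula(SPECIES["ions"][1]))
    for pseudo, mass in pseudo_masses.items():
        masses[pseudo] = mass

    comp = BiomassComposition(
        fractions=dict(MACRO_FRACTIONS),
        monomer_tables=monomer_tables,
        monomer_masses=masses,
        gam=gam,
        name=f"{strain} (synthetic reconstruction)")
    return comp
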