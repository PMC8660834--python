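# Methods

## The modeling framework

A metabolic model is a set of metabolites (with chemical formula and
charge) and reactions (signed stoichiometries, flux bounds in
mmol gCDW⁻¹ h⁻¹, optional gene rules), with one designated objective
reaction. Flux balance analysis solves the linear program

    max c'v   s.t.  S v = 0,  lb <= v <= ub

with HiGHS (dual simplex; feasibility/optimality tolerances 1e-9). A
reported solution is checked against a looser 1e-6 tolerance: steady state
means ‖S v‖∞ ≤ 1e-6 and a flux counts as non-zero above 1e-6. Solver
failures propagate as a status; an optimum is never fabricated.

Exchange reactions follow the community sign convention: negative flux is
uptake, positive is secretion. Irreversibility is encoded purely in the
bounds (default internal reversible [−1000, 1000], irreversible [0, 1000],
exchange lower bounds 0 until a medium opens them). Only parsimonious FBA
splits fluxes into forward/backward parts, to linearize |v|.

**Ratio constraints.** A product ratio such as acetate:lactate = r is the
homogeneous equality v_ac − r·v_lac = 0, appended to the equality block.
It admits the zero solution, so it never renders a resting model
infeasible by itself.

**Parsimonious FBA.** Plain FBA secretion profiles are generally
non-unique. All headline secretion profiles therefore come from
parsimonious FBA: the objective flux is fixed at its optimum (two-sided
bound with 1e-9 relative slack) and total absolute flux is minimized.
Residual degeneracy is probed by re-solving with a deterministic 1e-6
perturbation of the minimization weights at the same total flux; a
disagreement above 1e-4 sets the `degenerate` flag.

**Structural audits.** The balance audit computes per-reaction residuals
Σᵢ S[i,j]·formulaᵢ[e] for every element e and for charge; the default
pass tolerance is 1e-6 absolute. Exchanges, demands/sinks and the biomass
reaction are exempt but listed; a reaction containing a formula-less
metabolite is reported "unauditable" rather than passed. Internal (type
III) loops are found by closing every boundary reaction and running flux
variability over the rest; any reaction attaining |v| > 1e-6 participates
in a cycle with no net conversion. Gap finding reports structural
no-production/no-consumption sets from the sign pattern of S and the bound
directions, plus a flux-based "blocked" set (temporary sink per
metabolite, maximize its flux, blocked iff ≤ 1e-6). Under this definition
conserved cofactor moieties with no synthesis route (the adenylate, NAD
and CoA pools of the catabolism-only core) are blocked even though their
reactions carry flux — a property of the production test, documented and
asserted in the tests.

## Biomass objective construction

One gram of cell dry weight is decomposed into macromolecular mass
fractions (protein, DNA, RNA, carbohydrate, peptidoglycan, capsular
polysaccharide, lipoteichoic acid, lipids, inorganic ions, soluble pool;
they must sum to 1 ± 1e-6). Each category carries a monomer table of mole
fractions and per-monomer masses: polymerized (water-subtracted) residue
masses for protein/DNA/RNA, formula weights for the recipe-defined
cell-wall/lipid pseudo-residues, free masses for the soluble pool. The
coefficient of monomer m in category cat is

    1000 · fraction(cat) · molefrac(m) / weighted-residue-mass(cat)   [mmol/gCDW]

with condensation water released per polymerized residue, so one unit of
biomass flux consumes exactly 1.000 g (verified to 1e-4 at build time; GAM
hydrolysis ATP + H₂O → ADP + Pi + H⁺ is mass-neutral). Growth-associated
maintenance (GAM, mmol ATP/gCDW) lives inside the biomass reaction and is
retargeted by `set_gam`, which identifies the hydrolysis component by the
ADP coefficient (monomer drains never produce ADP) — idempotent and blind
to the other coefficients. Non-growth maintenance (NGAM,
mmol ATP gCDW⁻¹ h⁻¹) is deliberately *not* part of the biomass reaction:
it is the lower bound of a standalone ATP-hydrolysis reaction (`ATPM`),
keeping the two fitted parameters orthogonal.

The elemental summary sums net element flows into biomass over the
reaction (GAM cancels), normalizes carbon to 1 and reports the weight in
g C-mol⁻¹; by mass closure this equals 1000 divided by the carbon flow,
and the tests assert both accounting routes agree.

### The strain composition tables

Measured anchors: protein 52.2%, DNA 3.77%, RNA 4.9% (w/w). The remaining
39.13% is a reconstruction using Gram-positive literature-typical splits —
peptidoglycan 10%, capsular polysaccharide 6%, other carbohydrate 8%,
lipoteichoic acid 2%, lipids 7%, inorganic ions 3%, soluble pool 3.13% —
fixed once, a priori. The amino-acid mole fractions are a codon-usage-style
average table shipped as data (computing them from a genome is out of
scope); RNA is A/G/C/U = 0.26/0.32/0.22/0.20 and DNA reflects ~60% G+C.
The soluble pool (glutamate-dominated, with AMP, NAD, CoA, THF, thiamine,
riboflavin, biotin at trace mole fractions) stands in for the unpublished
ion/metabolite inventory; the BB-46 variant adds menaquinone-4 and swaps
the peptidoglycan interpeptide residue (L-ornithine, wall type A3β, vs
L-lysine, A3α). Putrescine and spermidine are excluded by default —
omission experiments showed no requirement — but
`include_polyamines=True` restores the pre-curation state for testing.

With these choices the compiled biomass computes to CH₁.₅₉N₀.₂₂O₀.₄₅P₀.₀₂
at 25.0 g C-mol⁻¹, against the published cell formula
CH₁.₅₇N₀.₂₃O₀.₄₃P₀.₀₁ at 24.7 g C-mol⁻¹. The ~1% weight gap sits in the
reconstructed sulfur/ion remainder (a CHONP-only reading of the published
formula gives ≈24.0, so the published 24.7 itself hinges on the
unpublished ion inventory). The fractions were not adjusted to close this
gap.

## Media and scenarios

A medium is a named nutrient set; concentrations are documentation. For
batch FBA every supplied nutrient is availability, not a rate: its
exchange lower bound opens to −1000 (or −bound if one is set), all other
exchange lower bounds close, secretion stays free. The nutrient→exchange
mapping is an explicit editable table; trace salts and other components
without a model counterpart are documentation-only and reported at
application time. Water and protons appear as implicit components of any
aqueous medium. The shipped chemically defined medium (CDM) mirrors the
published recipe (sucrose 10 g/L, salts, 20 amino acids, the vitamin set
including both pantothenate and pantethine, nicotinamide and nicotinic
acid, folate and 4-aminobenzoate, menaquinone-4); the nine trace-salt rows
map onto one pooled-ion exchange. Scenarios add ratio constraints, closed
exchanges, fixed uptakes (lower = upper = −value) and uptake caps on top
of a medium; the quantitative-validation scenario fixes sucrose uptake,
pins acetate:lactate, and caps every amino-acid uptake at
1 mmol gCDW⁻¹ h⁻¹.

## Nutrition analyses

Single-omission essentiality re-optimizes biomass once per omitted
nutrient. "No growth" means µ < 1e-6 h⁻¹ (`GROWTH_EPSILON`; FBA gives no
natural threshold, so this is a numerical choice). A nutrient is
*essential* when the full medium grows and the omission does not;
*growth-promoting* when both grow but omission costs more than 1% of the
optimum — a reporting-layer verdict only, since FBA cannot encode the
irreproducible-growth phenotype seen in vivo for menaquinone in one
strain. The carbohydrate screen gives each sugar the same molar uptake
(default 10 mmol gCDW⁻¹ h⁻¹, not hexose-equivalent-normalized — matching
how disaccharide simulations are usually constrained); a sugar without a
mapped exchange is an annotated no-growth row, not an error. The
transporter split scan fixes total sugar uptake, sweeps the PTS share f
over an even grid (default 21 points) fixing PTS flux to f·total and the
alternative route to (1−f)·total, and reports the growth curve plus the
argmax as a tie *set* — ties are never broken silently.

## Batch physiology

µ is the least-squares slope of ln(biomass) versus time over an explicit,
user-chosen exponential window (auto-detection is deliberately out of
scope); the specific rate of metabolite m is µ times the least-squares
slope of its concentration against biomass over the same window, negative
for consumption. On exact exponential data this recovers q = µ·Y with zero
residual, which the simulator round-trip asserts. Carbon recovery is
100·Σ_products q_p·C_p / (|q_s|·C_s) on the substrate's carbon (sucrose
= 12), excluding biomass. OD600→CDW factors 0.30 and 0.32 g L⁻¹ per OD
unit ship as named defaults.

Maintenance fitting searches one (GAM, NGAM) pair shared across the
strain models, each pre-constrained by its validation scenario. Predicted
µ is non-increasing in both parameters (verified as a test), so for a
trial GAM the NGAM reproducing each measured µ is found by bisection, and
GAM is bisected on the difference of the per-model NGAM requirements, with
a local grid refinement when the requirement curves never cross. Bounds:
GAM ∈ [0, 200] mmol/gCDW, NGAM ∈ [0, 50] mmol/gCDW/h, 60 bisection
iterations; the sum of squared µ deviations is reported and `converged`
reflects whether every measured µ was matched to ~1e-3. Initialization
values before fitting are GAM 39.31 and NGAM 5, the customary anaerobe
starting point.

## The synthetic generators

`make_core_model` emits the ~40-reaction bifid-shunt network: hexose entry
(kinase, optional PEP:PTS + proton symporter), both phosphoketolase
cleavages, the full transketolase/transaldolase shuffle (including the
C4+C5 transketolase, needed to run the pentose pool up to hexose
phosphates), GAP→pyruvate with explicit NAD/ATP bookkeeping, lactate
dehydrogenase, *reversible* pyruvate formate-lyase, the
phosphotransacetylase/acetate-kinase and acetaldehyde/ethanol branches, an
ATP drain, optional pentose entry at xylulose-5-phosphate and an optional
biomass drain with PEP/G6P precursor coefficients. Explicit protons and
water make every internal reaction element- and charge-balanced even
though pathway diagrams omit them.

`make_strain_model` builds the two strain reconstructions on that core.
These are *synthetic stand-ins* for the published genome-scale models —
compact networks encoding the documented strain biology, not the
reconstructions themselves:

* carbohydrate complements: the BB-12-like model has a glucose permease, a
  fructose PEP:PTS only, sucrose/raffinose/melibiose/lactose/galactose
  machinery, and no xylose/arabinose/amino-sugar routes; the BB-46-like
  model adds the glucose proton symporter *and* glucose PEP:PTS, a
  fructose ABC importer, pentose transporters, and the
  lacto-/galacto-N-biose cluster. Neither transports mannose.
* vitamin logic: CoA is reachable only from pantethine (symport,
  reduction, pantetheine kinase, lumped adenylylation) — pantothenate
  imports but leads nowhere; NAD comes from nicotinate in both, plus
  nicotinamidase and a lumped aspartate route only in the BB-46-like
  model; tetrahydrofolate comes from folate in both, from 4-aminobenzoate
  only in the BB-46-like model; menaquinone-4, thiamine, riboflavin and
  biotin are uptake-only.
* sulfur: lumped cysteine↔methionine interconversions in both directions,
  so either amino acid serves as sole organic sulfur source.
* energetics: proton-coupled (electroneutral) acid efflux, proton-symport
  uptake of sugars/amino acids/phosphate, a 3 H⁺/ATP F1F0 ATPase as the
  only pump, and an inward-only membrane leak (dissipative; it can never
  generate energy, which the closed-exchange tests confirm).
* biosynthesis: nucleotide monophosphates, cell-wall polymers and lipids
  are lumped, elementally exact reactions. A generic closure solver
  determines the CO₂/NH₄⁺/Pi/H₂O/H⁺ and NADH co-substrate coefficients of
  each lump by solving the 6×6 element/charge system, so the whole model
  passes the balance audit by construction. ATP costs of the lumps (e.g.
  6 per purine, 4 per peptidoglycan subunit) are literature-scale choices.
  Peptidoglycan synthesis consumes PEP (the MurNAc lactyl ether), which is
  what makes exclusive PEP:PTS hexose uptake infeasible for growth: each
  hexose yields a single PEP and the PTS consumes exactly one per hexose.

`make_broken_model` injects exactly one labeled defect — a non-integer
coefficient shift (unbalance), an orphan metabolite with a producing
reaction (dead end), or a reversed duplicate of an irreversible reaction
(loop) — and returns the ground truth for scoring the audits. Note a loop
injection can legitimately create further cycles through the reversible
pentose-phosphate shuffle; the no-false-positive check is therefore that
deleting the injected duplicate restores a loop-free network.

`simulate_batch` produces x(t) = x₀e^{µt} with growth-coupled metabolite
balances c(t) = c₀ + Y·(x − x₀), multiplicative Gaussian noise of given
relative SD, and bit-reproducibility per seed (one named generator, no
global state). Defaults (x₀ = 0.015 gCDW/L ≈ OD 0.05, 0.5 h sampling over
8 h) emulate exponential-phase serum-bottle batch cultures. It does not
emulate lag or stationary phases, substrate depletion kinetics, pH drift
or autocorrelated sensor error — so passing estimator tests demonstrate
correctness of the exponential-window estimator, not robustness to
real-world departures from exponential balanced growth.

## What the reconstructions reproduce, and what they cannot

Reproduced quantitatively (test suite): the 3:2 hexose and 1:1 pentose
acetate:lactate splits and 2.5 ATP/hexose of the shunt; zero
matter/energy from nothing; the full 12-sugar utilization panel of both
strains; the strain-resolved essentiality pattern (pantethine essential in
both, pantothenate unusable, nicotinate and folate essential only in the
BB-12-like model, menaquinone-4 only in the BB-46-like model, cysteine or
methionine interchangeable as sulfur source); the glucose-uptake optimum
at an 80% PTS share with no growth at 100%; carbon recoveries of 106% and
≈83% from the measured exponential-phase rates; and exact recovery of
generated maintenance parameters and specific rates.

Not reproduced, by construction: bookkeeping statistics of the published
genome-scale files (731/771 reactions, 480/520 genes, 84 unshared
reactions) — the synthetic models are an order of magnitude smaller; and
the absolute growth-rate scale under the quantitative-validation
constraints. With GAM 20/NGAM 1 the reconstructions predict µ ≈ 0.58/0.56
against the published in-silico 0.44/0.34, and the joint maintenance fit
to measured µ 0.45/0.35 lands at GAM ≈ 38, NGAM ≈ 1.1 rather than the
published (20, 1): lumped biosynthesis omits much of a genome-scale
network's distributed ATP/redox overhead, and the fitted GAM absorbs the
difference. The *secretion structure* under those constraints (acetate ≈
11.6 vs 12.0 and lactate ≈ 4.6 vs 4.8 for one strain; formate-dominated
ethanol-positive fermentation for the other; infeasibility when every
measured rate is pinned simultaneously) does carry over, as does the NGAM
scale. Conclusions about absolute energetics should therefore be drawn
from genome-scale reconstructions, not from these stand-ins.

## Numerical conventions

* LP tolerances 1e-9 (solver), 1e-6 (reported solutions and flux
  thresholds); ratio constraints satisfied to 1e-8 at optima.
* Balance audit tolerance 1e-6 absolute per element.
* growth_epsilon 1e-6 h⁻¹.
* Generated stoichiometric coefficients rounded to 9–12 decimals so SBML
  round-trips are bit-exact.
* Degenerate inputs: zero-variance regressors, zero substrate uptake,
  zero hexose uptake and empty windows raise; non-monotone biomass inside
  a window warns and proceeds.
* Split-scan argmax ties are reported as the full tie set; pFBA reports a
  degeneracy flag instead of pretending uniqueness.
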