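# Methods

`spheromet` simulates the early, avascular growth of a pancreatic tumor
spheroid as three coupled layers: a quasi-static extracellular
reaction-diffusion environment, a Cellular Potts (Glazier-Graner-Hogeweg)
lattice of discrete cells, and a per-cell kinetic model of central carbon
metabolism.  This note records the model, its assumptions, the parameters
that matter, and the design choices made where the design was genuinely
open.

## Lattice and energies

Cells are spatially extended domains on a periodic 2-D lattice (default
400x400; the desk-scale configuration uses 120x120 or smaller).  A cell is
the set of sites carrying its id; id 0 is the continuous stromal Medium.
The configuration evolves by Metropolis voxel-copy attempts: a source site
is drawn uniformly, a Moore (8-)neighbor is the target, and the source id
is copied onto the target with probability 1 if the total energy change
dH <= 0, else exp(-dH/Tm).  One Monte Carlo step (MCS) is width x height
attempts — the standard GGH convention.

The effective energy collects:

* **adhesion** — J(tau_i, tau_j) summed over Moore neighbor pairs of
  unlike cells.  The contact matrix is a surrogate; it is ordered so tumor cells cohere
  (J(tumor,tumor)=4 < J(tumor,Medium)=12) and necrotic cells are strongly
  repelled by stroma and epithelium (J=25), which confines necrosis to the
  core;
* **volume and surface constraints** — lambda_v (V-Vt)^2 +
  lambda_s (S-St)^2.  The quadratic form is used (configurable to the
  linear form via `energy.volume_form`): a linear penalty is unbounded
  below for shrinking cells and cannot constrain them.  Surface is the
  exposed-edge count in the 4-neighborhood.  Tm=10 and
  lambda_v = lambda_s = 2 for tumor cells (10 for the stiffer epithelium)
  follow the conventional CompuCell3D parameterization;
* **chemotaxis** — dH_chem = -lambda (C(dest) - C(src)) summed over the
  three nutrient fields with a single strength lambda (default 20),
  applied when the cell gaining the site is of a proliferating type;
* **focal-point plasticity** — sum lambda_ij (l_ij - L_ij)^2 over springs
  linking neighboring epithelial (ECM/Basal) cell centers; links longer
  than `fpp_max_distance` break, and under-connected cells re-link to the
  nearest unlinked neighbor once per MCS.

No connectivity constraint is imposed (cells may fragment; a diagnostic
counts fragmented cells).  The engine keeps volume, surface and
center-of-mass caches incrementally; the test suite proves the
incremental energies equal a brute-force recomputation of the full
Hamiltonian and that caches equal a from-scratch recount.

## Nutrient fields

Glucose, glutamine, oxygen and lactate diffuse much faster than cells
move, so each field is held at the steady state of

    D lap(C) - eps C + alpha(x) - sink(x) = 0

on the periodic grid (5-point Laplacian; preconditioned conjugate
gradients warm-started between MCS, with a dense direct solve as the
small-grid oracle).  Secretion is uniform over the stromal and epithelial
compartments at alpha = eps G, so the tumor-free field equals the
physiological baseline G everywhere; sites occupied by tumor cells do not
secrete, which is what carves nutrient gradients around the growing
spheroid.  Baselines are blood values: glucose 5 mM, glutamine 0.65 mM,
oxygen 0.056 mM (5 mM = 0.32 fmol/voxel anchors all unit conversions).
Extracellular lactate starts at zero and receives only tumor export and
necrotic bursts.

Each viable cell samples the fields at its center-of-mass site and
deposits its integrated uptake there as a linearized sink conductance
(g = uptake/(C+delta)), which keeps the discrete operator an M-matrix and
the solution non-negative.  D and eps are surrogate defaults.  They were chosen once, by the criterion that the
nutrient penetration depth sqrt(D/eps) must separate the two regimes the
biology requires: larger than the initial 9-cell cluster radius (~8
voxels), so the seed cluster is well fed and grows, and smaller than the
day-25 spheroid radius (~25 voxels), so a substrate-starved core forms.
Defaults: glucose and glutamine D=100, eps=1.2 (penetration ~9 voxels);
oxygen D=400, eps=1 (deep penetration: oxygen is not the limiting
species — starvation is driven by glucose+glutamine, matching the
starvation rule); lactate D=100, eps=0.1.

## Intracellular network

Each viable cell carries a 10-species concentration vector (fmol/voxel):
Glc_in, Gln_in, ATP, Lac_in, PEP, fumarate, malate, alpha-ketoglutarate,
R5P, S7P.  The default network is a reduced surrogate for a detailed (53-species
class) kinetic model of central carbon metabolism, keeping the pathway
skeleton — GLUT1 uptake,
lumped glycolysis (GAPDH: Glc -> 2 PEP + 2 ATP), LDH/MCT lactate exchange,
oxidative and non-oxidative pentose phosphate branches (PPP_in, PPP_ret,
PPP_out), ASCT2 glutamine uptake, glutaminolysis (GLS), a three-step TCA
chain, OXPHOS (malate + O2 -> 30 ATP) and an ATPase maintenance drain —
with three regulatory couplings that make the reported compensation
behaviors mechanistically reachable:

* ATP inhibits GAPDH (Pasteur/Warburg-type respiratory feedback): when
  respiration fails, glycolytic flux rises, elevating PEP and lactate;
* malate product-inhibits the TCA steps and alpha-ketoglutarate inhibits
  GLS: an OXPHOS block backs the chain up and intracellular glutamine
  accumulates;
* lactate import and oxidation are gated strictly on extracellular
  glucose exhaustion (< 1e-6 fmol/voxel): at normal glucose the lactate
  uptake flux is null.

Rate laws are irreversible Michaelis-Menten products over substrates with
hyperbolic inhibition factors.  The rate constants are surrogates, fixed
by four conditions evaluated at the nutrient regimes the fields produce:
(1) a well-fed cell holds ATP well above the starvation gate atpD and an
ATP+glucose+glutamine pool above the growth threshold; (2) a cell in the
core of a grown spheroid (glucose and glutamine at ~10-15% of baseline)
falls below atpD; (3) complete OXPHOS or ASCT2 knockdown drives ATP below
atpD at full nutrients, while GAPDH knockdown does not (the PPP and TCA
routes compensate); (4) a glucose-starved cell supplied with lactate
stays viable.  Transporter Km values sit at ~15-20% of the baseline
concentrations so the rim of a spheroid runs near saturation while the
core collapses.  The ATPase drain runs near capacity (Vf only ~30% above
control production, Km = 0.05), which makes steady-state ATP a steep
function of production — the switch that converts graded nutrient
depletion into a sharp viable/necrotic boundary.

Integration uses a fixed-step RK4 with adaptive substepping (nominal 0.5
min; a substep shrinks whenever a pool would lose more than ~90% in one
step, which handles the stiffness of small fast pools near depletion)
and non-negativity clipping; one call advances a cell by one MCS (6 min),
and the final state seeds the next call.  scipy's implicit BDF solver is
the cross-check oracle in tests (agreement to ~1e-4 relative in smooth
regimes, ~1e-9 at a finer substep).  Per-cell integration is independent
given the sampled inputs, so results do not depend on cell order.

Networks can be exported to and imported from SBML (libsbml).  Models
written by the package round-trip exactly; foreign kinetic laws are
compiled from the SBML math AST into generic rate callables and
integrated on the scipy path; an alias table reconciles foreign species
ids with the canonical state vector, and unmapped species are carried as
extra state entries.

## Cell decisions

Decisions run every 50 MCS (5 h).  Accruals use the saturating fitness
factor F(x, Vmax, k) = Vmax x^a/(x^a + k^a) (Hill exponent a=1 and
k = atpD by default; both are surrogate choices).  With ATP >= atpD the
cell gains Health (times exp(C), C=6); below it, Starvation; extracellular
lactate above LacDeath adds Acidity; more than N distinct neighbors adds
StressIncrement (consecutive crowding only: relief resets the
accumulator, configurable).  Quiescent cells run all amplitudes at 75%.

Thresholds follow the saturating forms
QCPThr = QSSThr = Total_time Vatpmax Pos_conc/(Pos_conc+atpK) (quiescent
-> proliferating), PNeThr (starvation necrosis) and PNeThra (acid
necrosis); quiescent and stem cells carry 1.5x the necrosis thresholds
(only the ordering is fixed; the multiplier is configurable).
Necrosis is irreversible, zeroes the accumulators, marks whether the cell
touches Medium (periphery) at transition time, and dumps the cell's
entire intracellular lactate into the extracellular field, split evenly
over its sites.

Proliferating cells above their growth threshold increase their target
volume by incvol (ATP+Glc+Gln - threshold) per decision step; at the
doubling volume 2 Vo (Vo = 25 voxels), with Health above QCPThr and the
senescence budget unspent, the cell divides: voxels split by a random
plane through the center of mass (equal halves, odd voxel to the parent),
the daughter inherits the parent's concentrations, both become quiescent
(a PStem daughter is QStem with probability probstem, else QCancer), and
all attributes reset.  The senescence limit `temp` is one rounded
Gaussian(maxdiv, 2) draw per cell at creation; a cell at its limit turns
necrotic instead of dividing.  Necrotic cells shrink by decvol per step:
periphery cells to zero (cleared to Medium), core cells to a quarter of
Vo.  All decision parameters default to the calibrated baseline values.

## Timescales and the driver

6 minutes per MCS; 6000 MCS = 25 days; decisions every 50 MCS.  Within an
MCS the driver (1) re-solves the fields against the current sinks,
(2) samples each cell's environment at its center of mass, (3) integrates
each cell's ODEs for 6 min, (4) performs one lattice Monte Carlo step,
and (5) at 50-MCS boundaries runs the decision rules.  The ordering within a step is a free choice; fields-then-ODE-then-lattice keeps the
environment and intracellular state consistent within the step.  All
randomness flows from one seeded generator, so (config, seed) determines
a run bitwise.

The world starts with two epithelial bands (ECM along the lower edge,
Basal along the upper, 40 voxels deep at full scale) tiled into ~8x8
cells connected by focal-point springs, fields pre-solved to their
tumor-free steady state, and nine 25-voxel tumor cells at the lattice
center with types drawn from the chosen scenario (I: all four viable
types ... V: PStem only).

## Problem sizes

The package distinguishes full scale (400x400, 6000 MCS, the reference
geometry) from desk scale (`SimulationParameters.desk()`, default
120x120).  The test suite and the acceptance script run desk-scale worlds
of 60-72 voxels a side — chosen so a complete 25-day trajectory with its
emergent structure (rim growth, quiescence, necrotic core, knockdown
contrasts) computes in about two minutes — with reduced replicate counts.
At these sizes a baseline run grows quasi-exponentially to about 10-fold
by day 10, saturates near 18-fold as the avascular supply is exhausted,
and develops a substantial necrotic core from about day 12 onward; the
knockdown orderings are well separated.  Emergent numbers quoted anywhere
in this repository are desk-scale numbers produced by these runs.

## Known limitations

* The surrogate network reproduces the *gated and directional* behaviors
  of the full 53-species model (knockdown orderings, compensation
  routes, lactate gating), not its quantitative trajectories; spatial
  metabolite profiles are qualitative.
* Partial (90%) knockdowns draw the residual activity once per replicate
  from Normal(0.1, 0.2) truncated at zero, as specified; with ~31% of
  draws truncated the effective mean residual activity is higher than
  0.1.
* Lactate-driven acidosis is weak within 25 days at desk scale (as at
  full scale: the acid threshold is rarely reached), so the acidity
  pathway is exercised by unit tests rather than emergent runs.
* The stress (crowding) necrosis route with the baseline N=6 and
  strict consecutive-step accounting rarely fires in desk-scale runs;
  core necrosis is carried by substrate starvation.
* The atpD sensitivity is one-sided in this parameterization: raising
  the starvation gate tenfold collapses growth to ~1x, but lowering it
  tenfold leaves the fold-change nearly unchanged (it rescues interior
  cells from necrosis without adding volume).  Total volume growth here
  is limited by nutrient supply at the rim — the cells that a lower gate
  keeps alive sit where the growth sum is below its threshold anyway —
  so only the growth-suppression side of the sensitivity is reproduced
  at desk scale.
* 2-D lattice only; no vasculature, immune or fibroblast compartments,
  no metastasis — all outside the model's scope.
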