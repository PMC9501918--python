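# Methods

This note records the scientific model implemented by `pegkin`, the
numerical and design choices that were genuinely open, and what the test
suite does and does not demonstrate.

## Model overview and assumptions

The package treats amine PEGylation as a two-layer process:

1. a **site layer** that decides *which* amine reacts next and at what
   intrinsic rate, from the protein's tertiary structure; and
2. a **bulk kinetic layer** that integrates the concentrations of the
   PEGmer populations, the active reagent, and its hydrolysis product.

The key assumptions, inherited from the modelled regime:

- the protein structure does not change upon PEGylation;
- the mixture is dilute enough that a well-mixed mass-action description
  holds and diffusion enters only through the attenuation modifier φ_j;
- attached chains (≲10 kDa PEG) adopt a dumbbell rather than shroud
  conformation, so their steric effect is local and radial;
- shielding is permanent: a site blocked by a nearby attached chain is
  never re-exposed (re-exposure is never observed within the modelled
  reaction times, and a permanent rule keeps the state machine simple);
- the models are valid near pH 7–8; pKa and Coulombic charge inputs are
  pH-specific and no Arrhenius temperature dependence is modelled.

## Site layer

**Amine sites.** One site per lysine with a resolved NZ atom, plus
optionally the backbone N of each chain's first resolved residue for the
α-amine. The N atom is used for the terminus because the coordinate of
the free α-amine nitrogen is what the shielding metric needs; lysines
with unresolved side chains are skipped with a warning, which reproduces
the reduced site counts of structures with missing residues. Author
residue numbering is kept throughout. For NMR ensembles only the first
model is used; alternate locations resolve to the highest-occupancy
conformer. On multimers a residue-number reference matches all chains and
distances take the minimum over chain pairings — the conservative choice
for shielding. These conventions are deliberate fixed points: the
alternatives (average over chains, last altloc) change distances by
fractions of an Å but make results irreproducible across tools.

**Descriptors.**

- *ESA*: Shrake–Rupley with a deterministic Fibonacci sphere lattice
  (default 960 points — the analytic-sphere error is ≪1% and results are
  bit-stable across runs) and a fixed heavy-atom van der Waals table
  (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, Se 1.90 Å). The probe radius
  mimics the reagent: 4.2 Å for a small-molecule initiator, 12/17/24 Å
  for 5/10/20 kDa PEG (freely-jointed-chain radii of gyration; 12 and
  24 Å are the endpoints of the published 12–24 Å range, with only the
  10 kDa value printed explicitly — flagged as a convention). Proteins of
  ≥60 kDa cap the probe at 8.8 Å. ESA is summed per residue; whether the
  original per-site values were per-residue or per-amine-group is not
  documented, and the per-residue sum is adopted.
- *pKa and Coulombic charge* are ingested from delimited tables produced
  by external electrostatics tools (H++, PROPKA, Chimera); computing them
  is explicitly out of scope and the table format is the contract.
- *Hydrophobicity/helicity*: Kyte–Doolittle and Levitt scales through a
  ProtScale-style sliding window (width 7, centre weight 1.0 decreasing
  linearly to 0.1; truncated windows at the termini are renormalized over
  the residues present — terminus handling is not otherwise specified).
  These two descriptors are computed and attachable but excluded from the
  default feature set, since adding them does not improve categorical
  prediction accuracy; a flag includes them.
- *Secondary structure* comes from HELIX/SHEET records; helix wins on
  overlapping annotations (arbitrary but fixed). No geometric (DSSP-style)
  assignment is attempted.

**Reactivity models.** The linear and structure-based models are affine
in the descriptors; the structure-based model's sheet/coil branch adds a
charge term (sheet/coil lysines sit closer to ionizable groups). The
published coefficient sets are exposed as ready-made model objects and are
applied to raw (unstandardized) descriptor units, since nothing indicates
the printed coefficients were fitted on standardized inputs. Fitting
linear kinds solves the least-squares problem exactly in closed form — a
multi-restart protocol cannot improve on the convex optimum, so restarts
are accepted for interface compatibility but not needed. The
machine-learned model is a feed-forward network with two hidden layers of
four nodes; "positive linear" activation is implemented as the
rectified-linear unit and the output is linear. Training standardizes
features to zero mean/unit variance (constants stored with the model),
minimizes mean squared error with seeded multi-restart L-BFGS, and the
best network's weights are extracted so that prediction is an explicit,
deterministic forward pass independent of the training library. A
helix-restricted leave-one-out hold-out is available for training sets
whose lysines are predominantly helical. Categorization sorts predicted
rates descending into fast/slow/nonreacting bins of prescribed sizes,
breaking ties by input order, with any site below the reactivity cutoff
(3.9 M⁻¹·min⁻¹ by default) forced to nonreacting.

## Kinetic layer

**Site selection** is Gillespie-like: with reactive-set rates k_v, the
cumulative probabilities partition [0, 1] and a single uniform draw picks
the site; a draw landing exactly on a boundary belongs to the left
(lower-cumulative) site. **Shielding** then removes every reactive site
within the radius R (nitrogen-to-nitrogen) of the chosen site. Iterating
until the reactive set empties yields the modification sequence, its
length N_eff, and the per-step averaged rate constants k_j,avg (the mean
over the current reactive set; raw per-site constants are available via a
flag, the average being the cheaper and equally physical choice).

**Attenuation.** The per-step modifier defaults to
φ_j = exp(−κ·(j−1)·π·R²): the first reaction is unattenuated and each
attached chain reduces the next step in proportion to the surface area
π·R² it covers. This covered-area form is adopted because κ is tabulated
in Å⁻²-compatible units and the shielded area is the only
Å²-dimensioned quantity in the model; the functional form is nonetheless
a modelling choice, documented as provisional and isolated behind a
strategy hook (`phi_strategy`) so a mass-based or other attenuation is a
one-line substitution.

**ODE system.** N+3 equations (P_0…P_N, PEG, PEG_d) with observed step
rates ε·k_j,avg·φ_j and parallel first-order reagent hydrolysis
(0.21 min⁻¹ for mPEG-NHS, 0.01 min⁻¹ for mPEG-SPA/SMB; other linkers
require an explicit k_d, and an explicit k_d always wins over a linker
default). Integration uses LSODA at relative tolerance 1e-8 with
absolute tolerances scaled to the initial concentrations; the right-hand
side clamps the tiny negative undershoots inherent to any tolerance-bound
integrator so they cannot act as spurious sources, and the solution is
rejected if any concentration falls below −1e-12. Distribution queries
use the integrator's dense output, not linear resampling. Relative
concentrations are molar PEGmer concentrations normalized by the initial
native-protein concentration; because the protein moiety's mass is
constant across PEGmers this equals the initial-mass-normalized basis for
the protein species.

**Conformation diagnostic.** R_f = a·N^(3/5) with monomer length
a = 3.5 Å and N = PEG mass / 44 g·mol⁻¹ ethylene-oxide units; D is the
mean nearest-neighbour nitrogen distance among grafted sites (the
original spacing convention is in supporting material not available here;
mean nearest-neighbour spacing is the adopted convention). R_f/D > 2 is
classified brush, otherwise dumbbell.

## Parameter fitting

The free parameters are κ, ε, and R. The objective pools every
experimental point of every supplied curve into one RMSE,
sqrt(Σ(C_ex−C_calc)²/n) (whether the original n pooled species or
averaged per-species RMSEs is unstated; pooling is adopted). Because R
acts through a discrete blocking rule the objective is piecewise constant
in R, so R is scanned on an explicit grid (include the 11 Å floor — the
smallest lysine spacing in a compact ~14 kDa protein, below which
shielding is ineffective) while (log κ, log ε) are minimized with
Nelder-Mead from seeded log-uniform restarts, followed by a longer polish
run from the incumbent. The modification sequence is generated once per
candidate R from the fit's sequence seed, making the objective
deterministic. Curves on a relative basis are compared on the simulated
relative basis; molar curves absolutely. ε is per (protein, linker, MW)
dataset; sharing ε across datasets for multi-MW experiments is a config
choice on the model object.

**Confidence intervals** use the F criterion
D(p)² ≤ D(p*)²·(1 + n_p/(n−n_p)·F_{1−q}(n_p, n−n_p)) — the standard
squared-RMSE F-ratio form, adopted because the exact printed inequality
is not available. Random multiplicative perturbations of p* at log-scales
from ×1.001 up to ×3 map the acceptance region; a second phase resamples
along the accepted set's empirical covariance (inflated 4×) so the
extremes of the elongated, κ–ε-correlated region are reached; the
per-parameter min/max of accepted points (always including p*) form the
intervals. This sampling construction approximates the profile interval
from the inside, so it errs narrow, never wide.

## Synthetic data

The toy-structure generator places lysine NZ atoms at exact line, ring,
or helix geometry (ring `spacing` is the nearest-neighbour chord; for a
hexagon the radius equals the spacing) with an idealized backbone, HELIX
records over a leading fraction of residues, and standard PDB formatting.
It emulates exactly the properties the models consume — inter-amine
distances, annotations, exposure patterns — and nothing else: no
stereochemistry, rotamers, or realistic packing, so passing tests
demonstrate correctness of the geometric and kinetic machinery, not
predictive accuracy on real proteins (which the published-data worked
examples and the external descriptor inputs address). Synthetic progress
curves are simulator output sampled at requested times plus seeded
Gaussian noise with standard deviation proportional to the initial
protein concentration, clipped at zero — matching the noise model assumed
by the recovery tests. PDB coordinates carry the format's fixed 0.001 Å
precision, so geometric identities asserted at 1e-6 are checked on the
generator's analytic coordinates and at 2e-3 Å after a file round-trip.

## Problem sizes and determinism

Test and acceptance-script problem sizes are chosen so every check runs
on a laptop in minutes: 4–8 site fixtures, 15–25 time points per curve,
50 randomized conservation simulations, 10⁵ selection draws, 10⁴
label shuffles, and 20 noisy replicates (restarts 4, ≤150 simplex
iterations, 300 interval perturbations) for the recovery experiment.
One seed governs each entry point; the Gillespie draws and fitting
restarts consume independent derived streams, so sub-components are
individually reproducible and repeated runs are bit-identical.

## Known limitations

- The φ_j functional form and its parameter units are provisional (see
  above); fitted κ values are only comparable between runs using the same
  strategy.
- Branched PEG geometry, shroud conformations, and structural change upon
  PEGylation are out of scope.
- The machine-learned model extrapolates poorly beyond its descriptor
  training range; the published training corpus is small.
- pKa/charge ingestion trusts the external tool; no sanity model is
  applied beyond table validation.
- The F-test intervals assume approximately Gaussian, homoscedastic
  residuals; heteroscedastic channels (e.g. a reagent curve measured on a
  different scale) make them approximate.
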