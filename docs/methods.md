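# Methods

## The model

`sidechaindbn` models the joint distribution of a residue's dihedral angles
(φ, ψ, χ1…χn) with a dynamic Bayesian network that is a small input-driven
hidden Markov model. One slice per angle: a discrete *input* node carries a
bookkeeping index identifying (amino-acid type, angle label); a discrete
*hidden* node of size H mediates all dependencies; a von Mises output node
emits the angle, its (μ, κ) selected by the hidden value. All amino acids
and all angles share one emission table, while the initial and transition
CPDs are indexed per (amino acid, angle) — multitask sharing that keeps the
parameter count low and lets rare residue types borrow statistical strength
from common ones.

Because the hidden chain connects the backbone slices to the χ slices, the
same parameterization supports both use modes:

* **backbone-dependent**: condition on observed φ, ψ; χ sampling uses the
  forward-backtrack algorithm (forward pass with φ, ψ observed, hidden
  states drawn backwards through the lattice, emissions drawn last).
* **backbone-independent**: φ, ψ slices are kept but marked unobserved in
  the evidence mask — the chain never changes length — and sampling is
  plain ancestral sampling.

All likelihood values are log *densities* in nats per radian, not
probabilities: comparing them with discrete rotamer-library probabilities
requires evaluating the library as a density too (see below).

### Numerical choices

* Scaled forward recursions (normalized α vectors, log scale factors
  accumulated) rather than log-space matrix products; exact to ~1e−15
  against brute-force enumeration on toy models and robust for κ up to the
  cap.
* κ is capped at 700: beyond that the circular sd is below 0.04° and I₀
  overflows double precision; log-space Bessel evaluation
  (`scipy.special.ive`) is used throughout.
* Weighted von Mises MLE inverts A(κ) = I₁/I₀ with the Best–Fisher
  closed-form start plus ≤ 50 Newton steps to |A(κ) − R̄| < 1e−10.
* Angles are radians in [−π, π) internally; degrees appear only in TSV/CLI
  boundaries and rotamer-library files.
* Missing angles are evidence-mask entries, never sentinel values.

## Training

Exact EM is the default: the E-step computes posterior hidden-state and
transition expectations by forward–backward (vectorized over all residues
of an amino-acid type, which share a slice sequence), the M-step
re-estimates CPD rows from expected counts plus a pseudocount (default
1e−3 per cell; a pseudocount of 0 leaves never-visited rows unchanged
instead of producing NaNs) and refits emissions from the three weighted
circular sufficient statistics. The log-likelihood trace is monotone
non-decreasing; convergence is declared when the per-residue improvement
drops below 1e−6 nats (default cap 300 iterations). Stochastic EM replaces
the expectations with one exact posterior draw of the hidden sequence per
residue (forward-backtrack over hidden nodes given *all* observed angles)
and hard counts; it converges to the same held-out likelihood within ~0.1
nats/residue on the synthetic study data and is retained because sampled
E-steps scale better when H is large. Restarts use Dirichlet(1) CPD rows
and emission means spread over the circle with jitter, κ = 1; per-restart
seeds derive from the master seed.

Hidden-node size is chosen by AIC = 2k − 2 log L over a user-given size
list with several restarts per size. k defaults to the dense free-parameter
count K(H−1) + K·H(H−1) + 2H; a non-zero count (entries > 1e−8) is
available because trained CPDs in this architecture go structurally sparse.

## Rotamer-library comparison

A backbone-independent rotamer library defines the mixture density
q_R(χ⃗) = Σ_R P(R) Π_n N(χ_n; μ_{R,n}, σ_{R,n}), with every Gaussian
evaluated on the *wrapped* difference folded to (−π, π] — unwrapped
evaluation misassigns density for means near ±180°. Model vs library is
scored by the relative KL divergence
D(p‖q_R) − D(p‖q_B) ≈ (1/n) Σ_i [log q_B(x_i) − log q_R(x_i)] over test
observations; positive values favour the model. Units are nats and all
outputs say so. Records where either density is non-finite are excluded
and reported, not silently dropped.

## Geometry

Side chains are rebuilt from χ alone: bond lengths and angles are ideal
(Engh–Huber-type values in the packaged topology table), and each atom is
placed by NeRF internal-to-Cartesian construction from three reference
atoms. Dihedrals follow the IUPAC sign convention (cis = 0), half-open
range [−π, π). The CB improper (N–C–CA–CB ≈ 122.6°) fixes L-chirality;
branch offsets (e.g. Leu CD2 at χ2 + 122°) and ring atoms past the last
rotatable bond use fixed dihedrals, so five- and six-membered rings close
only approximately — irrelevant to χ extraction, which round-trips at
1e−6 rad over all 18 residue types. PDB reading/writing goes through
Bio.PDB; altlocs resolve to highest occupancy; hydrogens are never kept;
chain breaks are flagged at CA–CA > 4.5 Å.

## Packing

The energy is an unmodified Lennard-Jones 6-12 sum,
4ε[(σ/d)¹² − (σ/d)⁶], heavy atoms only, geometric-mean combination, σ read
as the zero-crossing (OPLS convention; the minimum −ε sits at 2^{1/6}σ).
The packaged atom-type table maps atom classes (aliphatic/aromatic/carbonyl
C, N, carbonyl/hydroxyl O, S) to OPLS-like (ε, σ); 1-2 and 1-3 bonded pairs
are excluded, 1-4 kept at full weight. Energies become probabilities via
Boltzmann's law at T = 298.15 K (RT computed from R·T ≈ 0.5925 kcal/mol,
not hard-coded). A cap at 1e6 kcal/mol guards against overflow only; the
potential is otherwise unsoftened, so clashes are genuinely catastrophic.

Metropolis–Hastings modes:

* `proposal_only` — target is the LJ Boltzmann distribution; the model is
  the proposal and its density is corrected for:
  α = min(1, p_LJ(x′) q(x) / [p_LJ(x) q(x′)]). This samples the physical
  distribution without bias (verified against exhaustive Boltzmann
  probabilities on a 9-state enumerable toy).
* `pseudo_energy` — the model density multiplies the target *and* is the
  proposal; the four-term MH ratio reduces exactly to the LJ ratio
  (asserted to 1e−12 in the tests).
* `pseudo_energy_bbdep` — as above with backbone-conditional proposals and
  densities.

Each iteration resamples the side chains at `residues_per_move` (default
3, the study protocol) *random* sequence positions jointly with one
accept/reject. Positions are drawn with replacement: on protein-sized
inputs they are almost always distinct, while on few-residue fixtures this
naturally mixes cheaper single-residue moves with the joint moves that let
clashing side chains swap — without it, short chains on tight fixtures
accept almost nothing. The final prediction is the visited state minimizing
E_LJ (`proposal_only`) or E_LJ − RT log q (pseudo-energy modes).

Accuracy uses the ±20° criterion on the wrapped difference; χ2 is scored
only among residues whose χ1 is already correct (the conditional column
convention). Folding of two-fold terminal symmetries (Asp χ2, Glu χ3,
Phe/Tyr χ2) is opt-in and off by default. Burial can come from a
user-supplied mask or the built-in Shrake–Rupley surface area (Bio.PDB);
the default threshold marks residues with < 1 Å² accessible area buried.

## Synthetic study data

The generator defines the study conditions for every test:

* `make_ground_truth(seed, hidden_size=3)` — menu {SER (1χ), HIS (2χ),
  LYS (4χ)} so model and geometry layers share fixtures; Dirichlet(1)
  CPDs; emission means spread over the circle, κ ~ U[2, 20]. Draws are
  rejected (seed advanced) until the conditional and marginal χ densities
  differ by total variation > 0.05 at some probe backbone, so
  backbone-coupling tests cannot pass vacuously.
* `sample_dataset(truth, n, seed, missing_backbone_fraction)` — i.i.d.
  residues by ancestral sampling, uniform over the menu; training uses
  n = 2×10⁴ (recovery) and 8×10³ (AIC scans), held-out sets 5×10³.
* `make_toy_protein("helix_clash")` — a 5-mer whose tight turn points the
  two terminal LYS CB vectors at each other (CB–CB < 4 Å). Individually
  optimal rotamers collide (< 2.5 Å heavy-atom contact); only a
  coordinated pair avoids the clash. The planted native is found by
  scoring a 100×100 candidate grid (truth-model draws) with the
  pseudo-energy objective, refining one representative per distinct χ1
  basin by Nelder–Mead, and keeping the global optimum.
  `make_clash_scenario` additionally rejects truth draws whose landscape
  is ill-posed for recovery: the native basin must lead every distinct
  basin by ≥ 1.5 kcal/mol (refined and crude scores) and hold ≥ 8% of the
  per-residue proposal mass, so a finite chain can actually reach it.

What the synthetic data does *not* emulate: real rotamer populations and
their backbone dependence, experimental coordinate error, hydrogen
bonding/electrostatics/solvation (absent from the energy by design), and
crystallographic artefacts. Passing tests therefore demonstrate that the
machinery is correct — exact inference, consistent training, unbiased
sampling, convergent packing — not that the defaults reproduce
distributions of real proteins; training on a real angle table is required
for that.

## Problem sizes and known limitations

Test problem sizes (H ≤ 5, 2×10⁴ residues, 1.5–2×10⁴ MCMC iterations per
packing run, 2×10⁵ iterations for stationary-distribution checks) were
chosen so the whole suite runs on a single CPU in minutes while keeping
every statistical assertion well-powered; the packing protocol of the
original study (500,000 iterations, 43 crystal structures) is supported by
the same code path but not exercised in the tests. The MCMC best-state
selection on near-degenerate energy landscapes is inherently stochastic —
the end-to-end recovery criterion is therefore stated over seeds (≥ 4/5).
Ring closure in built side chains is approximate (construction is a tree);
proline's χ is treated as free rather than ring-constrained. The LJ table
is class-based, not a full per-atom OPLS extraction.
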