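# Methods

## The model

`flexsaxs` samples conformations of multi-protein complexes that combine
folded domains with long intrinsically disordered linkers, and confronts
the sampled ensembles with small-angle X-ray scattering (SAXS) data.  The
representation is coarse-grained at one bead per residue, placed at the
Calpha position.  Crystallised portions are *rigid bodies*: their internal
bead geometry is frozen and only the pose (unit quaternion + translation)
evolves.  Disordered segments are *linker chains* of beads connected at
the consecutive-Calpha spacing of 3.8 A, optionally bonded at either end
to a bead of a rigid body.  Internal units are Angstrom and kcal/mol
throughout; membrane geometry stated in nm elsewhere is converted (the
membrane surface sits at z = 20 A).

### Energy function

* **Bonded (linkers only).** Harmonic stretching ½k_b(b−b₀)² between
  consecutive beads and between chain ends and their anchors
  (k_b = 10 kcal/mol/A², b₀ = 3.8 A); harmonic bending ½k_θ(θ−θ₀)²
  (k_θ = 2 kcal/mol/rad², θ₀ = 120°, a typical Calpha pseudo-angle); a
  cosine torsion term A(1+cos φ) with A = 0.5 kcal/mol.  Rigid-body
  internal pairs contribute nothing.
* **Nonbonded contacts.** A square well of depth ε_ij between the
  excluded-volume radius (4.0 A) and the contact range (6.5 A), with
  harmonic repulsion k_rep(r_ex−r)² below the excluded radius
  (k_rep = 10 kcal/mol/A²).  Separations are floored at 0.1 A, so
  overlapping beads get a large but finite energy.  ε_ij belongs to the
  family of statistical residue–residue contact potentials; because no
  single parameter set is canonical at this resolution the shipped
  default is a transparent hydrophobicity rule, ε_ij = ε₀ h_i h_j with
  h the Kyte–Doolittle scale rescaled to [0,1] and ε₀ = 0.6 kcal/mol, and
  the full 20×20 matrix is replaceable from a whitespace-delimited text
  table.  Results should always be reported together with the matrix
  used.
* **Electrostatics.** Screened Debye–Hückel between integer formal
  charges at pH 7 (Asp/Glu −1, Lys/Arg +1, His neutral by default and
  configurable): E = 332.0637 q_iq_j exp(−r/λ_D)/(ε_r r) with
  λ_D = 10 A (≈150 mM monovalent salt) and ε_r = 80.  Pairs inside one
  rigid body and bonded neighbours are excluded from all nonbonded terms.
* **Membrane mode.** Three terms: (i) soft harmonic z-restraints
  ½k(z−z₀)² on designated anchor beads, default k = 0.1 kcal/mol/A² — at
  300 K this permits z fluctuations of ≈2.4 A (rms), which is what "soft"
  is taken to mean; (ii) a per-residue-type attraction that ramps
  linearly from −w_i at the membrane surface to 0 at 6 A above it, with
  w_i largest for hydrophobic and interfacial (Trp/Tyr/Arg/Lys) residues;
  (iii) impenetrability, a steep half-space repulsion 100(z_m−z)² below
  the plane.  The functional form and all parameters of the attraction
  are config-exposed rather than fixed, since only the existence of
  residue-type-dependent membrane potentials, not their shape, is pinned
  down by the modelling literature this follows.

### Sampling

Metropolis Monte Carlo: one *sweep* attempts one move per mobile degree
of freedom — for each rigid body a random Gaussian translation
(amplitude 1.0 A) or rotation about its centroid (0.1 rad), for each
linker bead a local Gaussian displacement (1.5 A) or a pivot of the
shorter chain arm about that bead (0.2 rad).  All proposals are
symmetric, so acceptance is min(1, exp(−ΔE/k_BT)).  Rigid-body
coordinates are always reconstructed from the reference frame and the
current quaternion, so internal distances cannot drift.  Amplitudes were
chosen once to give 20–40% acceptance on the toy dumbbell at 300 K.

Temperature replica exchange wraps the sampler: replicas populate a
geometric ladder between t_min and t_max (solution default 16 replicas,
300–500 K; membrane default 8 replicas over the same span — the count is
documented for membrane runs but not the range, so the solution span is
reused).  Every 10 sweeps one random adjacent pair attempts a
configuration exchange with probability min(1, exp((β_i−β_j)(E_i−E_j)));
the swap period is not documented either and 10 sweeps is this package's
choice.  Structures are recorded every `save_interval` sweeps — at all
temperatures for solution runs (the published 2·16 = 32-trajectory
arithmetic implies all replicas are kept) and at the lowest temperature
only for membrane runs; both defaults are overridable.  Independent runs
start from seed-randomised poses.  One global seed spawns per-run RNG
streams; identical configs reproduce bit-identical pools.

The incremental energy evaluation (only pairs crossing the moved bead
set change for rigid and single-bead moves) and the sweep loop are
compiled with numba.  A Python sweep path with identical physics (but a
different RNG consumption order) handles models with a user-supplied
external potential; the toy Boltzmann validation systems use it.

### SAXS

Model intensities use the orientation-averaged Debye double sum over
beads, I(q) = Σ_ij f_i f_j sin(qr_ij)/(qr_ij), with the q→0 and r→0
limits taken as 1.  The default form factor is a single constant per
residue (a per-type table can be supplied); excluded-volume and
hydration-shell corrections are deliberately omitted — a documented
limitation that matters for absolute comparisons with experimental
curves but cancels in the synthetic closed-loop experiments here, where
data and models share the same forward operator.

Discrepancy against a target curve is
χ² = Σ_i (I_exp(q_i) − a I_mod(q_i))²/σ²(q_i) with the scale a from
∂χ²/∂a = 0, i.e. a = Σ I_exp I_mod/σ² / Σ I_mod²/σ².  Reported χ² values
are the reduced statistic (raw sum / N_q); the raw sum is kept alongside.
Models are linearly interpolated onto the target grid; extrapolation is
refused.

Guinier analysis fits ln I = ln I₀ − q²R_g²/3 by σ-weighted linear
regression, starting from the widest usable window and shrinking it until
q_max·R_g ≤ 1.3 at a fixed point.  Non-positive intensities are dropped
with a warning; a profile whose first point already violates the limit is
an error.  On an exactly Gaussian profile any window returns the true
R_g; on a homogeneous sphere the qR_g ≤ 1.3 window carries an inherent
bias of ≈ +1.5%, which is why the sphere-recovery check uses a 2% band.

### Selection and clustering

Structures are ranked by reduced χ² (ties broken by pool id).  The
minimum-ensemble search looks for the smallest equal-weight set of
structures whose mean intensity, jointly rescaled, reaches an acceptance
χ² (default 1.5, between the published accept/reject values of ≈1.2–1.3
and 1.8).  Sizes are tried in order 1, 2, …, max_size (default 2,
capped at 4) exhaustively over a candidate pool pruned to the best 200
singles; the published search strategy is not described, so exhaustive
enumeration over the pruned pool is this package's choice.  For an
equal-weight mixture the optimal scale and χ² reduce to expressions in
the candidates' cross vector and Gram matrix, so the pair search needs no
per-combination refitting.  A non-negative-least-squares weight fit is
available as an extension but the default, matching the published
minimal ensembles, is equal weights.

Accepted structures are grouped by QT (quality-threshold) clustering
under a DRMS metric: DRMS(a,b) = sqrt(mean over a pair set of
(d_ij^a − d_ij^b)²), computed over all bead pairs that span two different
rigid bodies (seeded-subsampled to ≤5000 pairs for large complexes).
This groups conformations by relative domain placement and is invariant
to global rotation/translation.  The QT quality measure is the cluster
diameter (max pairwise DRMS); growth ties break to the lowest id and
commit ties to the lowest seed id, so the procedure is deterministic.

## Synthetic data

No public SAXS curve exists for the complexes that motivated this
pipeline, so end-to-end validation runs against synthetic experiments
with known ground truth.  The toy complex is a "dumbbell": two globular
bead clusters (protein-like density, 110 A³/residue) joined by a
flexible linker, with a compact and an extended geometry preset.  In
anchored (membrane) variants each body carries a 5-bead disordered tail
whose terminal bead is z-restrained — lipid anchors such as
geranylgeranylated cysteines sit on flexible termini, so the tether acts
on a mobile bead rather than rigidly dragging a domain.

Synthetic targets add Gaussian noise of sd σ(q) = α + β·I(q) to a known
mixture intensity and record that sd truthfully in the error column;
the default β = 0.01 (1% multiplicative noise, α = 0) reproduces the
statistical structure the χ² assumes (known per-point errors) without
emulating beamline-specific effects.

The two-state fixture designates one compact and one extended
conformation as a 50/50 generating pair inside a 200-structure pool of
pose-kick decoys (Gaussian rotations of sd 0.3 rad and translations with
a 2 A floor).  Because some pose changes are almost scattering-invariant
(rotations about the inter-body axis, transverse translations), raw
kicks can produce decoys that are structurally distinct yet
profile-degenerate with a parent; such decoys would make exact-pair
recovery ill-posed rather than hard.  Candidate decoys are therefore
rejection-sampled: one is kept only if substituting it for its parent in
the generating mixture shifts the reduced χ² against the noiseless
target by at least 3 at the generating noise level — every decoy is a
structure the experiment could actually reject.  What passing recovery
tests show is that the search identifies the generating pair whenever
the data can distinguish it; they do not show that real SAXS data
determine ensembles uniquely (they generally do not).

## Problem sizes

The validation suite runs deliberately scaled-down versions of the
production protocols: dumbbells of 40–75 beads, replica-exchange runs of
10⁵ sweeps with 8 replicas (membrane check), 200-structure recovery
pools, and 20–50 seed repetitions.  The bookkeeping checks
(160,000-structure solution pool, 32 trajectories, 50,000-structure
membrane pool) evaluate the protocol arithmetic exactly without running
the full simulations.

## Known limitations

* The default contact matrix and membrane well depths are transparent
  stand-ins, not fitted potentials; quantitative energetics require a
  user-supplied parameter set.
* Constant per-residue form factors omit solvent contrast and
  excluded-volume corrections, so absolute fits to experimental curves
  are systematically imperfect at high q.
* Equal-weight minimum ensembles cap the expressiveness of the ensemble
  model by design; full-pool reweighting is out of scope.
* The membrane is a flat, featureless plane: no curvature, leaflets or
  lipid species.
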