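# Methods

`transit` re-creates, at desk scale, a protocol for driving a membrane
transporter from its outward-facing (OF) to its inward-facing (IF)
conformation: a hybrid conformational target is built by threading the
subject's Cα trace onto a template in the other state; short screening runs
identify which transmembrane (TM) helix subsets can be driven without
artefacts; a targeted-MD (TMD) run biases those helices toward the target
while the rest of the system responds freely; and a trajectory-analysis
suite quantifies the transition (contact-map differences, pore-radius
profiles, SASA, lumen water counts, salt-bridge distances, RMSD series).
All-atom force fields, membranes and solvent are out of scope: dynamics run
on a coarse-grained Cα elastic network, and every input is generated
synthetically.

## The biasing potential

The bias is the standard TMD harmonic penalty on the best-fit RMSD between
the current and target coordinates of the N targeted atoms, with a target
value RMSD\*(t) scheduled linearly from the initial RMSD to a final value
(0 for a complete transition).  Two normalisations of the same penalty
appear in the literature, differing in whether the printed deviation is the
RMS-normalised coordinate or the plain Euclidean norm over targeted atoms.
They differ by a factor N in the stiffness felt per atom:

* **per-atom convention** (default; the convention of the reference MD
  engine's TMD module): U = (k/2)(RMSD − RMSD\*)², forces
  F_i = −(k/N)(1 − RMSD\*/RMSD)(x_i − x̂_i), where x̂ is the optimally
  superposed target.  Each targeted atom effectively carries a spring of
  stiffness k/N; the canonical run configurations (k = N, e.g. 141
  kcal/mol/Å² on 141 Cα) give exactly the quoted effective per-atom
  constant of 1 kcal/mol/Å².
* **rms convention**: U = (k/2N)(RMSD − RMSD\*)² taken literally, whose
  per-atom forces are N-fold weaker.

Both are exposed (`TMDParams.convention`); both are exact
energy–gradient-consistent potentials.  Runs default to the per-atom
convention because it is the one under which the canonical force constants
actually drive a transition: under the rms reading the whole RMSD
coordinate is held by a 1 kcal/mol/Å² spring, which thermal fluctuation at
310 K (σ = √(k_BT/κ) ≈ 0.8 Å) and any realistic network resistance
overwhelm.

The RMSD inside the potential is the best-fit (Kabsch) value, recomputed
every step with the fit over the targeted set itself; the gradient treats
the optimal rotation as stationary (envelope theorem), giving
∂RMSD/∂x_i = (x_i − x̂_i)/(N·RMSD).  Net force and net torque from the bias
vanish identically.  At RMSD below 10⁻⁶ Å the gradient is undefined and is
reported as zero with an "at target" flag.

## The coarse-grained engine

Nodes are Cα atoms; springs connect pairs within a 10 Å cutoff with rest
lengths at their build-time distances and a uniform spring constant of
1 kcal/mol/Å² (standard anisotropic-network territory).  Dynamics are
overdamped (Brownian) Euler–Maruyama steps,

    x ← x + (dt/(mγ)) F + √(2 k_B T dt/(mγ)) ξ,

with dt = 5 fs, T = 310 K, friction γ = 0.5 ps⁻¹ and bead mass 110 amu (an
average residue).  These defaults keep the integrator stable
(mobility × max node stiffness ≈ 0.7 < 2), reproduce equipartition in a
harmonic well to ~2 %, and hold an undriven bundle within 3 Å Cα RMSD of
its start over 10⁴ steps.  Temperature and friction are the simulation
conditions of the protocol this engine stands in for.  Side-chain
pseudo-atoms and other non-node atoms are convected rigidly with their
residue's Cα; waters are analysis-time particles only.

**Transition networks.**  A single-basin network built on the OF state
makes a large-amplitude transition strain-prohibitive (hundreds of
kcal/mol at the IF state for the standard fixture), which real transporters
are not: contacts that the transition breaks are not permanent springs.
`build_transition_enm` therefore drops springs whose length changes by more
than `rest_tol` (default 1.0 Å) between the two endpoint conformations.
The retained moderate strain (≈ 20 kcal/mol at IF on the standard fixture)
is deliberate: it keeps the OF basin stiff enough that the *unbiased*
control run stays put (σ along the transition mode ≈ 0.3 Å), while the
biased run affords the crossing with a modest scheduled lag.  Tightening
`rest_tol` to ~0.35 Å flattens the path almost completely — the clean
tracking regime used when measuring schedule-following.  Elastic networks
are state-specific, so post-TMD relaxation runs under a network rebuilt
around the arrived conformation.

**Quenched snapshots.**  Single-frame structural analyses (contact maps in
particular) are sensitive to thermal jitter: residue pairs whose closest
heavy atoms sit near the 3.5 Å threshold flicker in instantaneous frames.
`quench_frame` minimises the network with the driven atoms held in place,
the coarse-grained analogue of analysing a relaxed final model rather than
a thermal snapshot; remaining sub-0.5 Å distance changes are
threshold-hover, while genuine opening moves contacts by several Å.

## Target construction

Threading is Cα-level: paired residues (from a gapped two-sequence
alignment, editable by gap-removal, segment-start shifts and
retain-subject additions, each edit logged and monotonicity-checked) take
the template Cα position after the template is globally best-fitted onto
the subject — so the product lives in the subject's membrane frame — and
each residue's remaining atoms ride with its Cα.  Retain-subject segments
keep the subject's internal geometry exactly and are stitched in by
superposing on up to three paired anchor residues per side (fewer at
termini, with a warning; a translation-only fallback covers degenerate
anchor sets).  `regularize_target` smooths stitching artefacts by a short
restrained minimisation (restraint 0.1 kcal/mol/Å² toward the threaded
positions) under the subject-topology network and warns when consecutive
Cα distances within a segment remain outside 3.4–4.2 Å.  Side-chain
placement and stereochemical validation are beyond this resolution.

## Analysis definitions

* **Contacts**: residues are in contact when any heavy-atom pair is within
  3.5 Å (inclusive — "within" is read as ≤), excluding pairs separated by
  ≤ 3 in sequence within one chain; inter-chain pairs are always eligible;
  waters and hydrogens never participate.  Differential maps are plain set
  differences (broken/formed) between two structures on the same roster.
* **SASA**: Shrake–Rupley with probe 1.4 Å and 960 Fibonacci points per
  atom; all structure atoms occlude.  Exact surface ties between
  coincident atoms are assigned to the lower-indexed atom so degenerate
  surface is counted once.  Totals change < 0.5 % on doubling the point
  count.
* **Pore profile**: at each height z (default ±15 Å in 0.5 Å slices, the
  lumen window), the radius of the largest clearance sphere centred in
  that plane, found by Nelder–Mead searches seeded from the previous
  slice's centre plus random restarts (seeded, deterministic); candidates
  that run off into open space are discarded, and a slice with no bounded
  optimum is reported as NaN and excluded from means; radii are clamped
  at 0.
* **Lumen waters**: a water oxygen counts toward a half-lumen when its z
  lies in the half's window (defaults 2 ≤ z ≤ 15 extracellular,
  −15 ≤ z ≤ −2 intracellular) and it is within 10 Å of the half's anchor
  atoms.  Whole-molecule counting reduces to oxygen counting at this
  resolution.
* **Salt bridges**: per-frame minimum distance between the acidic
  partner's side-chain oxygens (Asp OD1/OD2, Glu OE1/OE2) and the basic
  partner's side-chain nitrogens (Arg NE/NH1/NH2, Lys NZ).
* **RMSD series**: best-fit RMSD per frame over a selection; invariant to
  global rigid motion of the frames.
* **Subset screening**: each candidate helix subset gets a short biased
  run (default 2 × 10³ steps; the full TMD default is 2 × 10⁴ and
  relaxation 10⁴, preserving the protocol's ~1:50:20 ratio at step
  resolution — the coarse engine has no literal nanosecond mapping); the
  opening score is Δ(mean IC-half pore radius) − Δ(mean EC-half radius)
  between first and last frame, and subsets that widen the EC half by
  more than 0.2 Å are flagged as artefactual extracellular opening.

## Synthetic fixtures

The generators emulate the structural situations the analyses assume — a
TM bundle around a z-axial lumen with an EC/IC two-state transition — not
any real fold or sequence.  The standard bundle is 10 ideal α-helices
(24 residues; rise 1.5 Å, twist 100°, helix radius 2.3 Å; Cα plus a
pseudo-Cβ 1.5 Å along the outward normal) on a ring of radius 12.5 Å,
chosen so neighbouring helices form ~3 Å heavy-atom contacts and the Cα
network is densely connected (~20 springs/node).  The IF state bends
helices TM2 and TM5 outward by 25° below the mid-plane about tangential
per-helix hinge axes (echoing intracellular opening by individual helix
splay); a rigid-block mode is also available for bundle-tilt motions.
Atoms at or above the hinge are bitwise identical between states; the
residue roster and annotation are preserved exactly.  Pseudo-waters are
rejection-sampled (uniform within 8 Å of the half's anchors, inside its
z-window, ≥ 2.4 Å clearance).  Cylindrical cages of stacked atom rings
provide analytic pore-radius oracles (radius exactly ring radius − vdW).
Everything is bitwise deterministic under its seed.

Passing tests on these fixtures demonstrate the mechanics of the method —
bias correctness, schedule tracking, transition convergence against an
unbiased control, analysis-operator correctness against analytic and
brute-force oracles.  They do not demonstrate biological accuracy: there
are no side chains, no membrane, no solvent, no electrostatics, and the
transition landscape is the pruned-network construction, not a free-energy
surface.

## Numerical choices and limitations

* Kabsch via SVD with reflection correction; collinear point sets raise an
  explicit degeneracy error (rotation not unique).  A quaternion-based
  optimiser exists only as a test oracle.
* vdW radii from a Bondi-style element table (C 1.70, N 1.55, O 1.52,
  S 1.80, H 1.20 Å), default 1.70 for unknown elements.
* z is the membrane normal, extracellular side positive; the origin is a
  reference-selection centroid (default whole structure).  Residue
  indexing is 1-based per chain; altlocs and insertion codes are rejected
  outright rather than silently dropped.
* Energy minimisation is L-BFGS on the network energy with optional
  (per-node) harmonic restraints; accepted iterates never increase the
  objective.
* A biased run warns "bias too weak" when RMSD lags RMSD\* by more than
  2 Å for over 10 % of the run.
* The pipeline fans one global seed out to per-stage seeds by fixed
  offsets; reruns with the same config are byte-identical on logs.
* Known limitations: no excluded volume during dynamics (the network is
  the only structure-keeper), harmonic springs cannot encode genuinely
  bistable landscapes along monotone distance paths, and the Cα-resolution
  threading delegates all side-chain realism to downstream (out-of-scope)
  refinement.
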