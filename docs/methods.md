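# Methods

## Model overview

driftfold treats folding as near-equilibrium drift and diffusion of
coarse protein substructures in superimposed energy fields.  Three forces
act explicitly between Cα-level sites; a fourth contribution, global
entropy change, enters as a modifier of the drift mobility rather than as
a force.  Secondary structure is not simulated: it is predicted by a
deterministic rule engine operating on per-residue charge and
hydrophobicity, inserted as immutable ideal geometry, and coarse-grained
away before the tertiary simulation starts.

## Per-residue properties

Each residue contributes exactly two numbers: a hydrophobicity `h`
(Kyte–Doolittle hydropathy by default; the table is a versioned JSON data
file and any scale with the same layout can be loaded) and a fractional
side-chain charge `q(pH)` from Henderson–Hasselbalch titration with
standard pKa values (D 3.9, E 4.1, H 6.0, C 8.4, K 10.5, R 12.5, Y 10.5).
Acids run from 0 to −1 e as pH rises through the pKa; bases from +1 to 0;
every titratable residue carries ±0.5 e exactly at its pKa.  Terminal
(backbone) charges are ignored.  The binary hydropathy class uses a
threshold of 0 on the bundled scale — boundary values count as
hydrophilic — and is configurable because only the relative
hydrophobic/hydrophilic split enters the scan.

## Secondary-structure rules

The helix pass opens a scan bracket at each hydrophilic residue `n_i`,
closing at the first hydrophilic residue among the following six
positions; openers with no partner in the window leave the region
unstructured.  (Ending the bracket at the next *hydrophilic* residue —
rather than at the next hydrophobic one — is the operational choice; it
is what gives the six-position cutoff its meaning.)  A closed bracket
with `n` intervening residues is classified by a declarative rule file,
`data/helix_rules.yaml`.  The load-bearing encoding choices, documented
in the file itself:

* explicit cases exist for n = 1, 3, 5 only; even n fall back to the
  nearest smaller case;
* Σq and Σh run over the *whole bracket* (endpoints included), while the
  charge product Πq and the individual-charge conditions cover the
  *intervening* residues.  The bracket-wide sum is what makes the rules
  live under the titration charge model: intervening residues are
  hydrophobic and hence essentially neutral at physiologic pH, so
  intervening-only sums could never reach any rule threshold and no
  helix would ever form.  The summation domain is a config switch
  (`sum_domain`) so the narrow reading remains testable;
* the fourth n = 1 row pairs a negative charge product with the sum
  window 0.1 < a < 0.5.

The beta pass slides a 5-residue window over runs that are still
unstructured after the helix pass and accepts a window as sheet when
strictly Σ|q| − Σh < 0.3 and Σh > 0.1 (both sums over the window;
a narrower leading-pair variant of the h-sum is selectable).  Accepted
windows are labelled and the scan resumes after them.  One consequence
worth stating plainly: a purely hydrophobic run satisfies both
inequalities on any positive hydropathy scale, so poly-hydrophobic
stretches classify as sheet, not coil.

## Force field

Internal units are nm, elementary charge, eV (so 1 eV/nm ≈ 1.6 × 10⁻¹⁰ N;
the Coulomb prefactor e²/4πε₀ = 1.439964 eV·nm).

* **Coulomb**: `q_i q_j / (4π ε_w r²)` with a uniform water dielectric
  ε_w = 78 ε₀ everywhere.  Local-dielectric refinement is out of scope.
* **Dielectric displacement**: `β q² / r⁵`, acting on hydrophobic
  (`h > 0`) sites, always directed away from the charge: polar water
  drawn toward a strong field sweeps nonpolar matter out of it.  β is not
  a measured constant; the default is calibrated so the displacement
  force at 0.1 nm from a unit charge equals the screened Coulomb force
  between unit charges at that distance (β = 1.846 × 10⁻⁵ eV·nm⁵/e²).
* **Thermal**: an isotropic random force of magnitude exactly γkT
  (direction uniform on the sphere, drawn from the run's single seeded
  generator).  γ defaults to 0.286 nm⁻¹, calibrated so γkT at 300 K is
  10 % of the screened unit-charge Coulomb force at 0.5 nm — close pairs
  must dominate thermal noise early in a fold, distant ones must not.
* **Mobility**: `μ(sign) = D / (kT − sign · dST)`, where `sign` is the
  global-entropy sign of the proposed move and `dST` (default 0.005 eV,
  required < kT) is a lumped entropy–temperature energy scale.  The
  entropy sign of a move is the sign of its radius-of-gyration change
  (compaction = entropy decrease = lower mobility), evaluated with a
  small probe rotation.  `dST = 0` recovers the Einstein relation
  μ = D/kT.  `dST` is an opaque magnitude knob, not a tabulated constant.
  D defaults to 1 nm² per simulation time unit, which fixes the (arbitrary)
  time scale.

Self-interactions and nearest bonded neighbours are excluded from all
pairwise sums.

## Chain geometry

One site per residue at a 0.38 nm virtual bond (canonical Cα–Cα).
Helix template: 0.15 nm rise, 100°/residue, 0.23 nm radius (consecutive
Cα distance then ≈ 0.38 nm); strand template: straight at 0.35 nm rise.
Predicted regions are spliced into the extended chain as rigid groups
with interior pivots frozen, then each region collapses to one effective
site at its centroid carrying the summed charge and hydrophobicity.  The
member geometry is kept in a body frame that accumulates subsequent
rotations, so the full Cα trace re-expands exactly after folding.

A pivot move rotates the smaller flank (ties: the C-terminal side)
rigidly about the pivot-bond axis.  A perfectly collinear chain is a
fixed point of such moves — every site lies on every axis, so no torque
can act — and the extended starting structure is exactly collinear.
Folding therefore starts from a gentle deterministic 3-D curl
(`initial_curl`, default 0.15 rad per pivot about alternating
perpendicular axes), an arbitrary physically permissible starting
conformation that preserves all bond lengths and template geometry.

No steric exclusion is applied by default (thermal plus repulsive
electrostatic forces suffice to prevent unrealistic collapse at these
scales); a hard-core rejection of moves bringing non-bonded sites within
0.36 nm is available via `FoldConfig(clash_rejection=True)`.

## The Markov step

Per step: (1) census — for every unfrozen pivot, net force on each
mobile-flank site (pairwise table plus one thermal draw per site, drawn
per pivot per census) is resolved into a signed torque about the
pivot-bond axis; (2) the largest torque magnitude wins, ties to the
lowest pivot index; (3) the rotation angle is
`θ = min(μ F Δt / r₀, θ_max)` in the torque's direction, where F is the
flank's net-force magnitude and r₀ the mean pivot-to-site lever arm of
this step (a per-step average, chosen over a whole-run average for
locality); (4) the winner's consecutive-win counter increments, all
other counters reset (the "sequential" reading; a no-reset variant is a
config switch), and a pivot reaching five consecutive wins freezes
permanently; (5) the work F·θ·r₀ is appended to the energy trace, with
arbitrary initial energy E₀ = 0 and E_t = E₀ − ΣΔE maintained as an
exact bookkeeping identity.

Δt defaults to 0.25 time units, set so that a typical early-fold step on
the 60-mer amphipathic fixture is ≈ 0.05 rad; θ_max = 0.1 rad caps the
step.  Runs end at `max_steps` or when every pivot is frozen; since
thermal draws keep acting, complete cessation of motion otherwise never
occurs.  All randomness flows through one `numpy` generator seeded from
`FoldConfig.seed`, so traces are bit-identical on seed repeat.

## Synthetic fixtures

`generate_fixture` produces the test surface: `helix_former` (a D-A-E
bracket, accepted through the strongly-negative-sum helix row, inside
hydrophobic padding), `blocked_helix` (the same with the bracket
interior mutated to K or D — the mutation both charges the bracket and,
because K/D are hydrophilic, dissolves it), `sheet_former` (an uncharged
hydrophobic run accepted by every beta window), `amphipathic` (a basic
head, hydrophobic core and acidic tail, so the oppositely charged
flexible ends attract across the chain and drive compaction), and
`random` (weighted draws from a stated hydrophobic-rich composition).
All are deterministic per seed.

What the fixtures do *not* emulate: real sequence statistics, turns and
irregular structure, disulfides, solvent structure, or any experimentally
assigned reference labels.  Tests passing on fixtures demonstrate that
the rules and the simulator implement their stated mechanics, not that
predictions on real proteins reach any particular accuracy — reproducing
published per-protein benchmark figures would additionally require
external reference structures and property tables this package does not
bundle.

## Evaluation

Per-residue label accuracy uses recall-style per-class denominators
(reference-positive residues) by default, with a precision-style switch;
"core" accuracy drops the two edge residues of each reference run.  RMSD
is classic Kabsch (SVD with a propriety flip, superposition applied
explicitly to avoid cancellation near zero) over Cα sites only.

## Problem sizes and numerical tolerances

The test and acceptance workloads use a 60-mer amphipathic fixture,
five seeds, ≤ 2000 steps per fold; rule-engine equivalence against an
independent direct-scan oracle is exhaustive over the reduced 4-letter
alphabet to length 9 (~350 k sequences) and sampled at lengths 10–12.
Force/torque oracle agreement is checked to 10⁻¹⁰ relative; rigid-motion
isometries to 10⁻⁹ relative; Kabsch RMSD against a quaternion-search
minimiser to 10⁻⁶.  Strict inequalities in the rule engine are evaluated
exactly (no epsilons); the Πq = 0 test uses |Πq| ≤ 10⁻¹² because the
product of floating charges is compared against an exact zero.

## Known limitations

* The tertiary dynamics on desk-scale fixtures compact modestly; there is
  no attractive hydrophobic-pair term, so collapse is driven entirely by
  Coulomb attraction between oppositely charged segments.
* The helix rule file encodes one defensible reading of rules that
  admit several; alternative readings drop in as data without code
  changes.
* Templates are ideal and immutable; no backbone dihedral realism, no
  all-atom refinement stage.
* The entropy model is a single scalar bias on mobility, signed by the
  radius-of-gyration change of the proposed move.
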