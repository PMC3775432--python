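# driftfold

Coarse-grained, all-physical protein folding by drift and diffusion:
a rule-based secondary-structure predictor driven by per-residue charge
and hydrophobicity, a three-force field with an entropy-modified drift
mobility, and a Markov pivot-torque simulator that folds a Cα-level
chain toward lower energy while logging the work done each step.

The package is aimed at people who want an inspectable, template-free
folding model — every force, rule and move is a few lines of physics you
can read — rather than a statistical predictor.  Everything runs on a
desktop in seconds.

## The model in brief

Between Cα sites carrying side-chain charge `q` (Henderson–Hasselbalch
titration at the ambient pH) and hydrophobicity `h` (Kyte–Doolittle),
three forces act:

```
F = q₁q₂/(4π ε_w r²)  +  β|q|²/r⁵  +  γkT
    Coulomb (ε_w=78ε₀)   displacement    thermal (isotropic, random)
```

The displacement term is the dielectric displacement force: polar water
drawn toward a strong field sweeps nonpolar matter away from charges.
Global entropy change is not a force but rescales the drift mobility,
`μ = D/(kT − sign·dST)`, so compacting (entropy-lowering) moves proceed
more slowly; drift speed is `μF`.

Secondary structure comes first, from a deterministic scan: a bracket
opens at each hydrophilic residue and closes at the next one within six
positions, and the balance of Σq, Πq and Σh over the bracket decides
helix formation (a declarative, editable rule file); remaining 5-residue
windows are sheets when strictly Σ|q| − Σh < 0.3 and Σh > 0.1.  Regions
are inserted as immutable ideal templates and coarse-grained to single
tagged sites.  Each simulation step then rotates the pivot bond with the
largest net torque by `θ = min(μFΔt/r₀, θ_max)`; a pivot winning five
consecutive steps freezes permanently; the energy trace records
`ΔE = F·θ·r₀` against an arbitrary initial energy.

## Worked example

```python
from driftfold import FixtureSpec, FoldConfig, generate_fixture, run_fold

seq = generate_fixture(FixtureSpec(60, "amphipathic"))
result = run_fold(seq, config=FoldConfig(seed=0, max_steps=2000))
print(result.annotation.labels)
print(f"Rg {result.rg:.2f} nm, energy removed {-result.trace.E[-1]:.2f} eV")
```

prints (exactly, for this seed):

```
CEEEEECEEEEECEEEEEEEEEEEEEEEEEEEEEEEEECCCCHHHHCCHHHHCCHHHHCC
Rg 5.71 nm, energy removed 11.56 eV
```

The charged head of the fixture stays flexible while its hydrophobic
stretches become rigid strands and the acidic tail forms short helices;
after 2000 steps the folded radius of gyration (5.71 nm) sits below the
extended chain's 6.58 nm, and 11.56 eV of field energy has been removed
as work.  `examples/` contains one narrative script per capability
(annotation, secondary-structure prediction with a charge-mutation flip,
folding with the energy trace, structure scoring); each prints the
numbers it computes and a line on what they mean.

A thin CLI wraps the same calls:

```
driftfold make-fixture amphipathic --length 60 --out amp.fasta
driftfold predict-ss amp.fasta --ph 7
driftfold fold amp.fasta --seed 0 --trace-csv trace.csv
driftfold evaluate --pred-labels HHHCC --ref-labels HHCCC
```

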