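# pbflex

Protein Block flexibility analysis for conformational ensembles of
multi-chain membrane proteins.

## The problem

Molecular-dynamics trajectories of polytopic membrane proteins — the
motivating case is trimers of the erythrocyte Rh proteins (RhD/RhAG, the
ammonium-transporter superfamily carriers of the RH blood group) — raise a
recurring analysis question: *where* is a subunit conformationally rigid,
flexible or disordered, and does the oligomer's subunit composition change
the local conformational sampling? `pbflex` implements the standard
structural-alphabet answer as a reusable, tested pipeline:

1. **Discretization.** Every residue of every frame is assigned one of the
   16 **Protein Blocks** (PBs, letters *a*–*p*): canonical 5-residue
   backbone prototypes defined by 8 reference dihedrals
   (ψ(i−2), φ(i−1), ψ(i−1), φ(i), ψ(i), φ(i+1), ψ(i+1), φ(i+2)).
   The assigned PB minimizes the RMSDA — the root mean square of
   circularly wrapped angle differences — over the window. PB *m* is the
   α-helix prototype, *d* the central β-strand. The first/last two
   residues of each chain are unassignable (`Z`).

2. **Local flexibility.** Per position, the PB frequencies *f_x* over
   frames give

   *N*<sub>eq</sub> = exp(−Σ<sub>x=1..16</sub> *f_x* ln *f_x*),

   the "equivalent number of PBs": 1 means a single local conformation
   (rigid), 16 a uniform spread over the whole alphabet. Positions
   classify as rigid (*N*<sub>eq</sub> ≤ 1), flexible (around 4, band
   [3, 8)), disordered (≥ 8), intermediate otherwise.

3. **Ensemble comparison.** Two samplings of the same subunit are compared
   per position by ΔPB = Σ<sub>x</sub> |*f_x*¹ − *f_x*²| ∈ [0, 2], with
   descriptive levels ≤ 0.2 (unremarkable), > 0.6 (notable), > 1.0
   (maximum variability).

4. **Global mobility.** Cα RMSD against a reference frame (equilibration
   check), per-residue RMSF about the iteratively refined mean structure
   after Kabsch superposition, per-chain z-score ("normalized RMSF"), and
   Pearson correlation between per-residue descriptors.

5. **Composition study.** Monomer chains from trimers of identical
   composition are pooled (trajectories concatenated after truncating the
   equilibration segment) into composition groups; groups of the same
   subunit are compared pairwise by ΔPB.

Because public trajectories for such systems are rarely available, the
package includes a first-class synthetic generator
(`pbflex.synthetic`): per-position PB targets, Markov frame-to-frame
persistence, conformer-switching segments, angular noise, and NeRF-style
reconstruction of Cartesian backbones from dihedrals — every statistic
above can be validated against analytic ground truth.

## Worked example

```python
import numpy as np
import pbflex as pf

# a 60-residue membrane-protein-like chain: helices, loops and a
# conformer-switching N-terminal tail; 5 deg angular noise
spec = pf.subunit_spec("A", n_frames=1000)
ens, states, truth = pf.generate_ensemble(spec, np.random.default_rng(1))

pbs  = pf.assign_pb(pf.compute_dihedrals(ens))   # frames x residues letters
neq  = pf.neq(pf.pb_frequencies(pbs))            # per-position N_eq
print(np.round(neq.values[2:10], 3))
print(pf.classify(neq)[2:10])
```

prints

```
[1.833 1.833 1.833 1.833 1.833 1.833 1.833 1.833]
['intermediate' 'intermediate' 'intermediate' 'intermediate'
 'intermediate' 'intermediate' 'intermediate' 'intermediate']
```

— the switching tail (residues 1–8) samples two conformations at
probabilities 0.7/0.3, so its measured *N*<sub>eq</sub> of 1.833 sits at
the analytic value exp(H(0.7, 0.3)) ≈ 1.842 up to sampling error, and the
switching also reaches the two flanking helix windows (positions 9–10).
Helix cores further in sit at *N*<sub>eq</sub> = 1.000 exactly (rigid).

The full study lives in the numbered drivers:

```
python analysis/01_simulate_study.py        # the eight-system trimer study
python analysis/02_flexibility_profiles.py  # pooled N_eq + classification
python analysis/03_global_metrics.py        # RMSD, normalized RMSF, correlations
python analysis/04_composition_comparison.py# pairwise delta-PB + flags
```

Each prints what it found and writes TSV reports under `results/`; e.g.
the composition comparison ends with

```
composition null holds: no position reaches the maximum-variability level
```

as expected when all compositions share one generator recipe.

## Layout

```
src/pbflex/
  ensemble_io.py    multi-model PDB / dihedral-TSV / annotation / report I/O
  pb_alphabet.py    dihedrals, the 16 PB prototypes, RMSDA assignment
  flexibility.py    PB frequencies, N_eq, classification, delta-PB, regions
  global_metrics.py Kabsch superposition, RMSD, RMSF, correlations
  composition.py    manifests, composition groups, pooling, run_study
  synthetic.py      generator: Markov PB sampling + NeRF backbone rebuild
analysis/           the numbered study drivers
tests/              unit, property and acceptance suites
```
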