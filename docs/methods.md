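# Methods

This note documents the models, conventions and numerical choices behind
`pbflex`, and what the synthetic validation does and does not demonstrate.

## Protein Block assignment

A Protein Block (PB) is one of 16 canonical 5-residue backbone prototypes,
labelled *a*–*p*, each defined by 8 reference dihedrals in window order
ψ(i−2), φ(i−1), ψ(i−1), φ(i), ψ(i), φ(i+1), ψ(i+1), φ(i+2). The prototype
table shipped in `src/pbflex/data/pb_prototypes.tsv` is the canonical
reference set of the structural-alphabet literature (the same angles used
by the standard PB assignment tools); it is stored as a read-only asset and
validated by geometric self-consistency tests: a chain built from PB *m*'s
central angles re-assigns to *m* everywhere (the α-helix is self-similar
under the 5-residue window), likewise PB *d* (β-strand), and every
prototype window assigns to itself at zero deviation.

Backbone dihedrals use the IUPAC sign convention, computed by the
projection (praxeolitic) formulation; results live in (−180°, 180°].
φ of each chain's first residue and ψ of its last are undefined, so the
first two and last two positions of every chain carry the undefined marker
`Z`, as does any window touching an undefined angle. Windows never span
chain boundaries. Assignment minimizes the RMSDA

RMSDA(w, p) = sqrt( (1/8) Σ_k wrap(w_k − p_k)² ),

with wrap(·) the signed minimal circular difference; exact ties (measure
zero, but constructible) resolve to the alphabetically first letter, making
assignment a pure function of the window.

Degenerate geometry (collinear atom quadruples) yields an undefined angle
with a warning rather than an error: a single bad frame should not abort a
trajectory-scale analysis.

## Flexibility statistics

Per position, PB frequencies are tallied over frames with `Z` excluded
from the denominator (the alphabet has 16 states; treating `Z` as a 17th
would break the [1, 16] range of N_eq). Then

N_eq = exp(−Σ_x f_x ln f_x),  0·ln 0 := 0,

so N_eq = 1 iff one PB is ever observed and N_eq = 16 iff all 16 are
equally frequent. Classification bands (all configurable via
`FlexibilityThresholds`): rigid N_eq ≤ 1 + 1e−9 (the epsilon absorbs
floating-point dust at the analytic boundary), flexible [3, 8) — a band
around the descriptive value 4, since only a point value is conventional —
disordered ≥ 8, intermediate otherwise. Segment summaries classify a
helix/loop by its **maximum** N_eq: a loop counts as disordered as soon as
any position in it is, which is how whole-loop disorder is convention-
ally reported.

ΔPB between two frequency profiles is Σ_x |f_x¹ − f_x²| ∈ [0, 2] (0 =
identical sampling, 2 = disjoint). The absolute values matter: the signed
sum is identically zero for normalized frequencies. No significance
machinery is attached — the descriptive levels 0.2 / 0.6 / 1.0 are named
constants (`DEFAULT_FLAG_LEVELS`), not test statistics.

Pooling replicate members weights frequencies by observation counts,
which is exactly equivalent to tallying the concatenated trajectories,
and is order-invariant.

## Global metrics

Superposition is the Kabsch SVD optimum restricted to proper rotations
(det = +1; a mirrored cloud is never matched by a reflection). RMSD is
computed on Cα after superposition onto a designated reference frame.
RMSF uses the iterative-mean reference: superpose onto the current mean,
recompute the mean, repeat until the mean moves < 1e−6 Å (max 10 rounds);
this is the standard fluctuation-about-the-average definition, not
fluctuation about the first frame. Equilibration handling is a fixed
truncation count from config — 500 frames by default, i.e. 50 ns at a
100 ps saving interval — with the RMSD series available for choosing a
different cutoff by inspection; no automatic plateau detector is included.

Normalized RMSF is the per-chain z-score (RMSF − chain mean)/chain SD,
undefined (NA) for a zero-variance chain. When pooling a composition
group, RMSF is computed per member, normalized per member, then averaged
position-wise; normalizing before averaging keeps chains from different
replicates on a common scale, though averaging first and normalizing
after would be an equally defensible convention.

## The synthetic generator

The generator is a statistical null model, not an MD surrogate: no
sterics, no energetics, no lipids. It emulates exactly the features the
statistics consume:

* **Per-position PB targets** sampled by stationary first-order Markov
  chains (keep the previous state with probability ρ, else redraw from
  the target), so the marginal is exactly the target and the lag-1
  autocorrelation is ρ. The effective sample size of n correlated frames
  is n(1−ρ)/(1+ρ), which the validation uses for its standard errors.
* **Conformer blocks**: a run of residues switching as a unit between
  complete PB strings under one Markov chain. This is the only mechanism
  by which specified per-position variability survives the coordinate
  channel (below) intact.
* **Coordinates** rebuilt from dihedrals by sequential NeRF extension
  with ideal geometry (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, standard
  bond angles, ω = 180°; generator conventions — the analysis only ever
  uses dihedrals and relative positions). Each residue's φ/ψ are its
  current PB's central prototype angles plus Gaussian noise of σ degrees,
  rejection-truncated at ±3σ so that a noisy window can never leave its
  generating prototype's basin when the margin to the runner-up exceeds
  the worst-case noise displacement.
* **Rigid drift** (removable by superposition), **Cartesian jitter** (for
  RMSF's √3·σ closed-form limit) and a **noisy burn-in segment** (for
  truncation tests) are optional additives.

Randomness derives from one root seed via `SeedSequence` spawn keys per
(ensemble, chain), so fixtures are reproducible independently of
evaluation order.

### Why segment switching, not per-position mixing

The PB window spans 5 residues, so the assignment of position i depends on
the states of i−2…i+2. If positions sampled their letters independently,
an isolated letter flip would be low-pass filtered away (the window is
dominated by the neighbours' dihedrals) *and* would contaminate up to four
flanking windows — the generator's nominal per-position distribution would
not be what the pipeline can measure, at any sample size. Whole-segment
conformer switching keeps windows internally coherent: interior block
positions are recovered letter-for-letter, and block-edge positions are
recovered up to a relabelling that N_eq (a label-permutation-invariant
statistic) does not see. The residual, irreducible distortion is confined
to the ≤ 2 flanking helix windows adjacent to a block — these are rigid in
the nominal target but visibly switch in the measured ensemble — and this
is a property of the window definition itself, not an implementation
artifact. The study fixture therefore reports ~96% of positions in exact
agreement with analytic ground truth, with the known flanks accounting for
the remainder.

### The study fixture

`make_study_fixture` mirrors the trimer design at toy scale: two 60-residue
subunit types (A: three m-helices joined by two d-loops; B: two longer
helices, two loops), each with an 8-residue N-terminal conformer block
switching helix ↔ extended at probabilities 0.7/0.3 (A) and 0.6/0.4 (B),
persistence ρ = 0.9, angular noise σ = 5°. Eight systems (3:0, 2:1, 1:2,
0:3 with the odd subunit at each chain position), 3 replicates for pure
trimers and 2 for mixed — 18 trajectories, 54 chains. The block sits at
the chain terminus so that its left flank falls on unassignable positions,
minimizing channel distortion; its probabilities are asymmetric because
the first-order standard error of the plug-in N_eq estimator vanishes at
a symmetric two-state distribution (dH/dp = 0 at p = ½), which would make
"within k standard errors" ill-posed — and because a dominant loop
conformation is the realistic situation. Default depth is 5,000 frames per
replicate (500 of which are truncated as equilibration), chosen so the
effective sample size per pooled group (n(1−ρ)/(1+ρ) per member, summed
over members) resolves the block's N_eq to a few percent; analysis drivers
use 1,000 frames to keep the narrative runs short.

### What passing tests do and do not show

The generator validates the *statistics*: counting, entropy, pooling,
comparison, superposition and normalization are checked against analytic
values and independent brute-force implementations. It does not validate
scientific conclusions about real membrane proteins: real trajectories
have correlated inter-residue motion, anharmonic noise, slow modes longer
than any ρ, and genuinely disordered loops whose N_eq the coordinate
channel can measure but for which no analytic truth exists. The
composition-null property (between-composition ΔPB indistinguishable from
between-replicate ΔPB when one recipe generates everything) demonstrates
that the pipeline does not *invent* composition effects; it cannot show
that a real system lacks them.

## Numerical conventions

* Angles in degrees, (−180, 180]; residues 0-based in memory, 1-based in
  every file; reports are UTF-8 TSV, floats at 6 decimals, NA for
  undefined.
* N_eq is clipped to [1, 16] after exponentiation to absorb roundoff at
  the analytic boundaries.
* Ties in RMSDA break alphabetically; altloc ties keep the first
  encountered highest-occupancy location; insertion codes are rejected
  outright (they make 5-residue window arithmetic ambiguous).
* The report bundle contains no timestamps or environment state, so a
  rerun with identical manifest, data and seed is byte-identical.

## Known limitations

* Cross-subunit comparison (e.g. A-type vs B-type chains) is out of
  scope: ΔPB requires a shared roster, and aligning different sequences
  is a modelling decision this package does not make.
* No automatic equilibration detection; the truncation count is config.
* The PB-sequence FASTA writer and dihedral-TSV dialect are conveniences
  for interoperability, not attempts to match any external tool's exact
  file layout.
* `region_summary` classifies flanking helix windows adjacent to a
  switching block as non-rigid (see the channel discussion above); on
  synthetic data this is expected, and on real data it is the correct
  behaviour (the window genuinely moves).
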