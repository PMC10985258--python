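"""Synthetic backbone ensembles with known statistical structure.

This is a statistical null generator, not an MD surrogate: it emulates the
*shape* of a membrane-protein trajectory — rigid helix cores, strand-like
loops, a conformer-switching disordered segment, frame-to-frame
correlation, angular noise, optional rigid-body drift — with fully known
per-position PB distributions, so that every downstream statistic (N_eq,
delta-PB, RMSF) can be checked against analytic ground truth.

Two sampling mechanisms are provided:

* independent per-position Markov chains over the 16 PB letters, with
  stationary distribution equal to the per-position target and
  self-transition (persistence) probability rho;
* *conformer blocks*: a run of residues that switches as a unit between
  complete PB strings under one Markov chain. Only whole-segment switching
  survives the 5-residue assignment window intact (an isolated letter flip
  is averaged away by its neighbours' dihedrals), so blocks are how the
  study fixture realizes measurable flexibility with exact ground truth.

Cartesian coordinates are rebuilt from the sampled states by an
internal-to-Cartesian (NeRF-style) chain extension with ideal backbone
geometry; each residue's phi/psi are its current PB's central prototype
angles plus truncated Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .ensemble_io import BackboneEnsemble, write_ensemble_pdb, write_report
from .pb_alphabet import N_PB, PB_LABELS, load_prototypes

__all__ = [
    "ConformerBlock",
    "GeneratorSpec",
    "GroundTruth",
    "IDEAL_GEOMETRY",
    "sample_pb_trajectory",
    "build_coordinates",
    "generate_ensemble",
    "analytic_target",
    "analytic_neq",
    "make_study_fixture",
    "subunit_spec",
    "subunit_annotation",
]

_LETTER_INDEX = {lab: i for i, lab in enumerate(PB_LABELS)}

# Ideal backbone geometry (generator convention; analysis only ever uses
# dihedrals and relative coordinates, so any consistent geometry works).
IDEAL_GEOMETRY = {
    "r_n_ca": 1.458,
    "r_ca_c": 1.525,
    "r_c_n": 1.329,
    "theta_n_ca_c": 111.0,
    "theta_ca_c_n": 116.6,
    "theta_c_n_ca": 121.9,
    "omega": 180.0,
}


@dataclass(frozen=True)
class ConformerBlock:
    """Residues ``start..stop`` (0-based, inclusive) switch together
    between complete PB strings under one Markov chain with stationary
    probabilities ``probs`` and self-transition ``rho``."""

    start: int
    stop: int
    strings: tuple[str, ...]
    probs: tuple[float, ...]
    rho: float = 0.9

    def __post_init__(self) -> None:
        width = self.stop - self.start + 1
        if width < 1:
            raise ValueError("empty conformer block")
        for s in self.strings:
            if len(s) != width:
                raise ValueError(f"conformer string {s!r} does not span the block")
            if not set(s) <= set(PB_LABELS):
                raise ValueError(f"conformer string {s!r} has non-PB letters")
        p = np.asarray(self.probs, dtype=float)
        if len(p) != len(self.strings) or abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
            raise ValueError("probs must be a distribution over the conformer strings")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic chain.

    ``base_letters`` gives the deterministic backbone letter per residue
    (e.g. ``"m"`` runs for helices, ``"d"`` runs for extended loops);
    ``position_target`` optionally overrides any position with an explicit
    16-vector distribution sampled by an independent per-position Markov
    chain; ``blocks`` carve out conformer-switching segments. ``sigma`` is
    the angular noise (degrees, truncated at 3 sigma) around prototype
    dihedrals; ``rho`` the per-position self-transition probability;
    ``coord_noise`` adds isotropic Cartesian jitter (Angstrom) after the
    build; ``burn_in_frames`` receive ``burn_in_coord_noise`` jitter
    instead, emulating an unequilibrated leading segment. ``drift_step``
    translates frame f by f * drift_step (rigid, removable by
    superposition).
    """

    n_residues: int
    n_frames: int
    base_letters: str = ""
    position_target: Optional[np.ndarray] = None
    blocks: tuple[ConformerBlock, ...] = ()
    sigma: float = 0.0
    rho: float = 0.0
    coord_noise: float = 0.0
    burn_in_frames: int = 0
    burn_in_coord_noise: float = 0.0
    drift_step: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.n_residues < 1:
            raise ValueError("need at least one frame and one residue")
        if self.sigma < 0 or self.coord_noise < 0 or self.burn_in_coord_noise < 0:
            raise ValueError("noise levels must be non-negative")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        letters = self.base_letters or "m" * self.n_residues
        if len(letters) != self.n_residues or not set(letters) <= set(PB_LABELS):
            raise ValueError("base_letters must give one PB letter per residue")
        object.__setattr__(self, "base_letters", letters)
        if self.position_target is not None:
            t = np.asarray(self.position_target, dtype=float)
            if t.shape != (self.n_residues, N_PB):
                raise ValueError("position_target must have shape (n_residues, 16)")
            rows = t[np.isfinite(t).all(axis=1)]
            if rows.size and np.any(np.abs(rows.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError("each defined target row must sum to 1")
            object.__setattr__(self, "position_target", t)
        for blk in self.blocks:
            if blk.stop >= self.n_residues:
                raise ValueError("conformer block exceeds the chain")


@dataclass
class GroundTruth:
    """What the generator actually did: the analytic per-position target
    distribution, its N_eq, the sampled letter counts, and the rigid
    transform applied per frame."""

    target: np.ndarray  # (n_residues, 16)
    analytic_neq: np.ndarray  # (n_residues,)
    counts: np.ndarray  # (n_residues, 16)
    drift: np.ndarray  # (n_frames, 3) translation applied per frame


def analytic_target(spec: GeneratorSpec) -> np.ndarray:
    """Per-position marginal PB distribution implied by the spec."""
    target = np.zeros((spec.n_residues, N_PB))
    for i, lab in enumerate(spec.base_letters):
        target[i, _LETTER_INDEX[lab]] = 1.0
    if spec.position_target is not None:
        override = np.isfinite(spec.position_target).all(axis=1)
        target[override] = spec.position_target[override]
    for blk in spec.blocks:
        target[blk.start: blk.stop + 1] = 0.0
        for s, p in zip(blk.strings, blk.probs):
            for off, lab in enumerate(s):
                target[blk.start + off, _LETTER_INDEX[lab]] += p
    return target


def analytic_neq(target: np.ndarray) -> np.ndarray:
    """exp(Shannon entropy) of each row of a distribution matrix."""
    t = np.asarray(target, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(t > 0, t * np.log(t), 0.0)
    return np.exp(-terms.sum(axis=1))


def _markov_sample(rng: np.random.Generator, probs: np.ndarray, n_frames: int,
                   n_chains: int, rho: float) -> np.ndarray:
    """Stationary first-order Markov sampling, vectorized over chains.

    Each step keeps the previous state with probability rho, otherwise
    redraws i.i.d. from ``probs`` (per chain); the stationary distribution
    is exactly ``probs`` and the lag-1 autocorrelation is rho.
    ``probs``: (n_chains, n_states). Returns (n_frames, n_chains) ints.
    """
    cum = np.cumsum(probs, axis=1)
    r = rng.random((n_frames, n_chains))
    innov = (r[:, :, None] >= cum[None, :, :]).sum(axis=2)
    persist = rng.random((n_frames, n_chains)) < rho
    persist[0] = False
    t_innov = np.where(persist, -1, np.arange(n_frames)[:, None])
    last = np.maximum.accumulate(t_innov, axis=0)
    return np.take_along_axis(innov, last, axis=0)


def sample_pb_trajectory(spec: GeneratorSpec, rng: np.random.Generator):
    """Sample the frames x residues PB state matrix and its ground truth.

    Returns ``(states, truth)`` where ``states`` holds integer PB codes
    0..15 and ``truth`` is a :class:`GroundTruth` (drift is filled by
    :func:`build_coordinates`; zero here).
    """
    F, L = spec.n_frames, spec.n_residues
    states = np.empty((F, L), dtype=np.int8)
    base = np.array([_LETTER_INDEX[c] for c in spec.base_letters], dtype=np.int8)
    states[:] = base[None, :]

    if spec.position_target is not None:
        override = np.nonzero(np.isfinite(spec.position_target).all(axis=1))[0]
        if override.size:
            probs = spec.position_target[override]
            states[:, override] = _markov_sample(rng, probs, F, len(override), spec.rho)

    in_block = np.zeros(L, dtype=bool)
    for blk in spec.blocks:
        in_block[blk.start: blk.stop + 1] = True
        strings = np.array(
            [[_LETTER_INDEX[c] for c in s] for s in blk.strings], dtype=np.int8
        )
        conf = _markov_sample(
            rng, np.asarray(blk.probs)[None, :], F, 1, blk.rho
        )[:, 0]
        states[:, blk.start: blk.stop + 1] = strings[conf]

    counts = np.zeros((L, N_PB), dtype=np.int64)
    for x in range(N_PB):
        counts[:, x] = (states == x).sum(axis=0)
    target = analytic_target(spec)
    truth = GroundTruth(target, analytic_neq(target), counts, np.zeros((F, 3)))
    return states, truth


# ---------------------------------------------------------------------------
# internal-to-Cartesian reconstruction


def _truncated_normal(rng: np.random.Generator, sigma: float, shape) -> np.ndarray:
    """Gaussian noise truncated (by rejection) to +/- 3 sigma, keeping every
    noisy window near its generating prototype."""
    if sigma == 0:
        return np.zeros(shape)
    x = rng.normal(0.0, sigma, shape)
    for _ in range(8):
        bad = np.abs(x) > 3 * sigma
        if not bad.any():
            break
        x[bad] = rng.normal(0.0, sigma, int(bad.sum()))
    return np.clip(x, -3 * sigma, 3 * sigma)


def _place_atom(a, b, c, r, theta_deg, chi_deg):
    """NeRF atom placement: position D with bond length |CD| = r, bond
    angle B-C-D = theta and torsion A-B-C-D = chi (vectorized over frames).
    """
    bc = c - b
    bc = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    theta = np.radians(theta_deg)
    chi = np.radians(np.asarray(chi_deg, dtype=float))
    d_local = (
        -np.cos(theta) * bc
        + (np.sin(theta) * np.cos(chi))[..., None] * m
        + (np.sin(theta) * np.sin(chi))[..., None] * n
    )
    return c + r * d_local


def build_coordinates(
    states: np.ndarray,
    spec: GeneratorSpec,
    rng: np.random.Generator,
    truth: Optional[GroundTruth] = None,
    chain_id: str = "A",
) -> BackboneEnsemble:
    """Rebuild Cartesian backbone coordinates from sampled PB states.

    Each residue's (phi, psi) are its current PB's central prototype angles
    plus truncated Gaussian noise of ``spec.sigma`` degrees; bonds and
    angles are ideal, omega = 180. Optional rigid drift and Cartesian
    jitter are applied after the build; the applied drift is recorded in
    ``truth`` when given.
    """
    F, L = states.shape
    proto = load_prototypes()
    phi_c = proto[:, 3]
    psi_c = proto[:, 4]
    phi = phi_c[states] + _truncated_normal(rng, spec.sigma, (F, L))
    psi = psi_c[states] + _truncated_normal(rng, spec.sigma, (F, L))
    # wrap into (-180, 180]
    phi = -((-phi + 180.0) % 360.0 - 180.0)
    psi = -((-psi + 180.0) % 360.0 - 180.0)

    g = IDEAL_GEOMETRY
    coords = np.empty((F, L, 3, 3))
    coords[:, 0, 0] = [0.0, 0.0, 0.0]
    coords[:, 0, 1] = [g["r_n_ca"], 0.0, 0.0]
    t = np.radians(g["theta_n_ca_c"])
    coords[:, 0, 2] = coords[:, 0, 1] + g["r_ca_c"] * np.array([np.cos(np.pi - t), np.sin(np.pi - t), 0.0])
    for i in range(1, L):
        n_prev, ca_prev, c_prev = coords[:, i - 1, 0], coords[:, i - 1, 1], coords[:, i - 1, 2]
        n_i = _place_atom(n_prev, ca_prev, c_prev, g["r_c_n"], g["theta_ca_c_n"], psi[:, i - 1])
        ca_i = _place_atom(ca_prev, c_prev, n_i, g["r_n_ca"], g["theta_c_n_ca"],
                           np.full(F, g["omega"]))
        c_i = _place_atom(c_prev, n_i, ca_i, g["r_ca_c"], g["theta_n_ca_c"], phi[:, i])
        coords[:, i, 0], coords[:, i, 1], coords[:, i, 2] = n_i, ca_i, c_i

    drift = np.arange(F)[:, None] * np.asarray(spec.drift_step)[None, :]
    coords += drift[:, None, None, :]
    if spec.burn_in_frames and spec.burn_in_coord_noise > 0:
        nb = min(spec.burn_in_frames, F)
        coords[:nb] += rng.normal(0.0, spec.burn_in_coord_noise, (nb, L, 3, 3))
    if spec.coord_noise > 0:
        coords += rng.normal(0.0, spec.coord_noise, coords.shape)
    if truth is not None:
        truth.drift = drift
    times = 0.1 * np.arange(F)  # 100 ps saving interval, in ns
    return BackboneEnsemble(
        coords,
        np.full(L, chain_id, dtype="U4"),
        np.arange(L),
        frame_times=times,
    )


def generate_ensemble(spec: GeneratorSpec, rng: np.random.Generator,
                      chain_id: str = "A"):
    """Sample states and rebuild coordinates in one step.

    Returns ``(ensemble, states, truth)``.
    """
    states, truth = sample_pb_trajectory(spec, rng)
    ens = build_coordinates(states, spec, rng, truth, chain_id)
    return ens, states, truth


# ---------------------------------------------------------------------------
# the miniature eight-system study


def subunit_spec(kind: str, n_frames: int, sigma: float = 5.0, rho: float = 0.9) -> GeneratorSpec:
    """Generator recipe for one of the two synthetic subunit types.

    Both are 60-residue chains shaped like a miniature polytopic membrane
    protein: three alpha-helical m-runs joined by extended d-run loops,
    plus an N-terminal conformer-switching block (the 'disordered tail')
    that flips between a helical and an extended conformation under a
    persistent Markov chain. The two types differ in segment layout and in
    the tail's conformer probabilities (0.7/0.3 for A, 0.6/0.4 for B); the
    asymmetric probabilities are the dominant-conformation situation real
    loops show.
    """
    if kind == "A":
        letters = "m" * 8 + "m" * 16 + "d" * 6 + "m" * 16 + "d" * 6 + "m" * 8
        block = ConformerBlock(0, 7, ("mmmmmmmm", "dddddddd"), (0.7, 0.3), rho)
    elif kind == "B":
        letters = "m" * 8 + "m" * 18 + "d" * 8 + "m" * 18 + "d" * 8
        block = ConformerBlock(0, 7, ("mmmmmmmm", "dddddddd"), (0.6, 0.4), rho)
    else:
        raise ValueError(f"unknown subunit kind {kind!r}")
    return GeneratorSpec(
        n_residues=60,
        n_frames=n_frames,
        base_letters=letters,
        blocks=(block,),
        sigma=sigma,
        rho=rho,
    )


def subunit_annotation(kind: str):
    """Annotation track matching :func:`subunit_spec`'s segment layout:
    the N-terminal switching tail, the helices (TM) and the connecting
    loops (EC/IC alternating)."""
    import pandas as pd

    from .ensemble_io import AnnotationTrack

    if kind == "A":
        segments = [("tail", 0, 7, "IC", "coil"), ("helix1", 8, 23, "TM", "alpha"),
                    ("loop1", 24, 29, "EC", "coil"), ("helix2", 30, 45, "TM", "alpha"),
                    ("loop2", 46, 51, "IC", "coil"), ("helix3", 52, 59, "TM", "alpha")]
    elif kind == "B":
        segments = [("tail", 0, 7, "IC", "coil"), ("helix1", 8, 25, "TM", "alpha"),
                    ("loop1", 26, 33, "EC", "coil"), ("helix2", 34, 51, "TM", "alpha"),
                    ("loop2", 52, 59, "IC", "coil")]
    else:
        raise ValueError(f"unknown subunit kind {kind!r}")
    rows = [
        {"chain": kind, "residue": r, "topology": topo, "ss": ss,
         "segment": seg, "exon": i + 1}
        for i, (seg, start, stop, topo, ss) in enumerate(segments)
        for r in range(start, stop + 1)
    ]
    return AnnotationTrack(pd.DataFrame(rows))


#: the eight trimer systems: subunit type per chain position, with the odd
#: subunit cycled through each position, and replicate counts (3 for the
#: pure systems, 2 for the mixed ones).
STUDY_SYSTEMS: tuple[tuple[str, int], ...] = (
    ("AAA", 3),
    ("AAB", 2), ("ABA", 2), ("BAA", 2),
    ("ABB", 2), ("BAB", 2), ("BBA", 2),
    ("BBB", 3),
)

CHAIN_IDS = ("P", "Q", "R")


def make_study_fixture(
    seed: int,
    n_frames: int = 5000,
    sigma: float = 5.0,
    rho: float = 0.9,
    out_dir=None,
):
    """Build the miniature eight-system study mirrored on the trimer design.

    Returns ``(manifest, data, truths)`` where ``data`` maps ensemble id to
    :class:`BackboneEnsemble` (three chains each) and ``truths`` maps
    (ensemble id, chain id) to :class:`GroundTruth`. With ``out_dir`` the
    ensembles are also written as multi-model PDB plus per-chain
    ground-truth TSVs and a manifest JSON (use small ``n_frames`` there).
    Deterministic per seed: every (ensemble, chain) gets its own counter-
    derived stream, so evaluation order never matters.
    """
    from .composition import (
        AnalysisConfig, CompositionGroup, EnsembleRecord, StudyManifest,
    )

    specs = {k: subunit_spec(k, n_frames, sigma, rho) for k in ("A", "B")}
    data: dict[str, BackboneEnsemble] = {}
    truths: dict[tuple[str, str], GroundTruth] = {}
    records: dict[str, EnsembleRecord] = {}
    ens_counter = 0
    for composition, n_reps in STUDY_SYSTEMS:
        for rep in range(n_reps):
            ens_id = f"{composition}_r{rep + 1}"
            chains = []
            for c_idx, (chain_id, kind) in enumerate(zip(CHAIN_IDS, composition)):
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=seed, spawn_key=(ens_counter, c_idx))
                )
                ens, _states, truth = generate_ensemble(specs[kind], rng, chain_id)
                chains.append(ens)
                truths[(ens_id, chain_id)] = truth
            data[ens_id] = _concat_chains(chains)
            records[ens_id] = EnsembleRecord(
                composition=composition,
                replicate=rep + 1,
                chain_subunits={c: k for c, k in zip(CHAIN_IDS, composition)},
            )
            ens_counter += 1

    groups = []
    comparisons = []
    for kind in ("A", "B"):
        kind_groups = []
        for count in (3, 2, 1):
            members = [
                (ens_id, chain)
                for ens_id, rec in records.items()
                for chain, k in rec.chain_subunits.items()
                if k == kind and rec.composition.count(kind) == count
            ]
            if members:
                name = f"{kind}_in_{count}{kind}"
                kind_groups.append(CompositionGroup(name, tuple(members)))
        groups.extend(kind_groups)
        names = [grp.name for grp in kind_groups]
        comparisons.extend(
            (names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))
        )

    manifest = StudyManifest(
        ensembles=records,
        groups=tuple(groups),
        comparisons=tuple(comparisons),
        # 500 frames = 50 ns at a 100 ps interval; scaled to a tenth of the
        # trajectory for toy-sized fixtures
        config=AnalysisConfig(
            truncate_frames=500 if n_frames > 2500 else n_frames // 10, seed=seed
        ),
    )
    if out_dir is not None:
        _write_fixture(out_dir, manifest, data, truths)
    return manifest, data, truths


def _concat_chains(chains: Sequence[BackboneEnsemble]) -> BackboneEnsemble:
    # separate the chains in space (a rigid offset, invisible to every
    # statistic) so the trimer is not three superimposed monomers
    chains = [
        BackboneEnsemble(c.coords + np.array([0.0, 60.0 * i, 0.0]),
                         c.chain_ids, c.residue_indices, c.frame_times)
        for i, c in enumerate(chains)
    ]
    coords = np.concatenate([c.coords for c in chains], axis=1)
    chain_ids = np.concatenate([c.chain_ids for c in chains])
    residues = np.concatenate([c.residue_indices for c in chains])
    return BackboneEnsemble(coords, chain_ids, residues, chains[0].frame_times)


def _write_fixture(out_dir, manifest, data, truths) -> None:
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ens_id, ens in sorted(data.items()):
        write_ensemble_pdb(ens, out / f"{ens_id}.pdb")
    for (ens_id, chain_id), truth in sorted(truths.items()):
        df = pd.DataFrame(truth.target, columns=[f"p_{lab}" for lab in PB_LABELS])
        df.insert(0, "residue", np.arange(len(truth.analytic_neq)))
        df["analytic_neq"] = truth.analytic_neq
        write_report(df, out / f"{ens_id}_{chain_id}_truth.tsv")
    (out / "manifest.json").write_text(manifest.to_json())
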