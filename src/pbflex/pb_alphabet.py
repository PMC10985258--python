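"""Protein Block (PB) assignment.

The 16 Protein Blocks *a*–*p* are canonical 5-residue backbone prototypes,
each defined by 8 reference dihedrals ordered
psi(i-2), phi(i-1), psi(i-1), phi(i), psi(i), phi(i+1), psi(i+1), phi(i+2).
A residue's local conformation is discretized by building the same 8-angle
window around it and assigning the prototype with minimal RMSDA (root mean
square deviation over circularly wrapped angle differences). PB *m* is the
alpha-helix prototype, PB *d* the central beta-strand; *a*–*j* describe
coils and caps.

The first two and last two residues of every chain have incomplete windows
and carry the undefined marker ``Z``; windows never span chain boundaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .ensemble_io import BackboneEnsemble, DihedralEnsemble

logger = logging.getLogger(__name__)

PB_LABELS = tuple("abcdefghijklmnop")
UNDEFINED = "Z"
N_PB = 16

__all__ = [
    "PB_LABELS",
    "UNDEFINED",
    "PBEnsemble",
    "load_prototypes",
    "prototype_central_angles",
    "circular_diff",
    "dihedral",
    "compute_dihedrals",
    "assign_pb",
    "rmsda",
    "write_pb_fasta",
]


@dataclass
class PBEnsemble:
    """Frames x residues PB letters; ``Z`` marks unassignable positions."""

    labels: np.ndarray  # (frames, residues) of single characters
    chain_ids: np.ndarray
    residue_indices: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="U1")
        self.chain_ids = np.asarray(self.chain_ids, dtype="U4")
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        valid = set(PB_LABELS) | {UNDEFINED}
        found = set(np.unique(self.labels))
        if not found <= valid:
            raise ValueError(f"invalid PB letters: {sorted(found - valid)}")

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    @property
    def n_residues(self) -> int:
        return self.labels.shape[1]

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c))
        return list(seen)


def load_prototypes() -> np.ndarray:
    """Return the canonical 16 x 8 prototype dihedral matrix, rows ordered
    a..p, columns in window order (see module docstring)."""
    with resources.files("pbflex.data").joinpath("pb_prototypes.tsv").open() as fh:
        header = fh.readline().split()
        assert header[0] == "pb"
        rows = {}
        for line in fh:
            parts = line.split()
            rows[parts[0]] = [float(x) for x in parts[1:]]
    mat = np.array([rows[lab] for lab in PB_LABELS], dtype=float)
    if mat.shape != (N_PB, 8):
        raise ValueError("prototype asset corrupt: expected 16 x 8 angles")
    return mat


def prototype_central_angles() -> dict[str, tuple[float, float]]:
    """Per PB letter, the (phi, psi) of the window's central residue —
    columns phi_0 and psi_0 of the prototype table."""
    mat = load_prototypes()
    return {lab: (float(mat[i, 3]), float(mat[i, 4])) for i, lab in enumerate(PB_LABELS)}


def circular_diff(a, b):
    """Signed minimal angular difference a - b, wrapped into [-180, 180)."""
    return (np.asarray(a, dtype=float) - np.asarray(b, dtype=float) + 180.0) % 360.0 - 180.0


def dihedral(p0, p1, p2, p3):
    """Torsion angle (degrees, IUPAC sign convention) of the four points,
    vectorized over leading axes. Degenerate (collinear) quadruples give NaN.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    norm = np.linalg.norm(b1, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        b1u = b1 / norm
        v = b0 - np.sum(b0 * b1u, axis=-1, keepdims=True) * b1u
        w = b2 - np.sum(b2 * b1u, axis=-1, keepdims=True) * b1u
        x = np.sum(v * w, axis=-1)
        y = np.sum(np.cross(b1u, v) * w, axis=-1)
        ang = np.degrees(np.arctan2(y, x))
    vnorm = np.linalg.norm(v, axis=-1)
    wnorm = np.linalg.norm(w, axis=-1)
    degenerate = (norm[..., 0] < 1e-9) | (vnorm < 1e-9) | (wnorm < 1e-9)
    ang = np.where(degenerate, np.nan, ang)
    # map -180 -> 180 so results live in (-180, 180]
    ang = np.where(ang == -180.0, 180.0, ang)
    return ang


def compute_dihedrals(ens: BackboneEnsemble) -> DihedralEnsemble:
    """phi/psi per frame per residue; phi of each chain's first and psi of
    each chain's last residue are undefined (NaN), as are angles from
    degenerate geometry (with a warning)."""
    F, R = ens.n_frames, ens.n_residues
    phi = np.full((F, R), np.nan)
    psi = np.full((F, R), np.nan)
    for chain in ens.chains:
        idx = np.nonzero(ens.chain_mask(chain))[0]
        c = ens.coords[:, idx]  # (F, L, 3, 3); atoms N, CA, C
        N, CA, C = c[:, :, 0], c[:, :, 1], c[:, :, 2]
        if len(idx) >= 2:
            # phi(i) = C(i-1)-N(i)-CA(i)-C(i), i >= 1
            phi[:, idx[1:]] = dihedral(C[:, :-1], N[:, 1:], CA[:, 1:], C[:, 1:])
            # psi(i) = N(i)-CA(i)-C(i)-N(i+1), i <= L-2
            psi[:, idx[:-1]] = dihedral(N[:, :-1], CA[:, :-1], C[:, :-1], N[:, 1:])
    n_bad = int(np.isnan(phi[:, ens.residue_indices > 0]).sum()
                + np.isnan(psi[:, _not_last_mask(ens)]).sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} dihedral(s) undefined from degenerate geometry", stacklevel=2
        )
    return DihedralEnsemble(phi, psi, ens.chain_ids, ens.residue_indices)


def _not_last_mask(ens: BackboneEnsemble) -> np.ndarray:
    mask = np.zeros(ens.n_residues, dtype=bool)
    for chain in ens.chains:
        idx = np.nonzero(ens.chain_mask(chain))[0]
        mask[idx[:-1]] = True
    return mask


def _windows(dih: DihedralEnsemble, chain_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """8-angle windows for the assignable positions of one chain.

    Returns (windows, positions): windows has shape (F, L-4, 8), positions
    the global residue-axis indices of the window centres.
    """
    phi = dih.phi[:, chain_idx]
    psi = dih.psi[:, chain_idx]
    L = len(chain_idx)
    centres = np.arange(2, L - 2)
    win = np.stack(
        [
            psi[:, centres - 2],
            phi[:, centres - 1],
            psi[:, centres - 1],
            phi[:, centres],
            psi[:, centres],
            phi[:, centres + 1],
            psi[:, centres + 1],
            phi[:, centres + 2],
        ],
        axis=-1,
    )
    return win, chain_idx[centres]


def rmsda(window, prototype):
    """Root mean square circular deviation between an 8-angle window and a
    prototype (vectorized over leading axes)."""
    d = circular_diff(window, prototype)
    return np.sqrt(np.mean(d * d, axis=-1))


def assign_pb(dih: DihedralEnsemble, prototypes: np.ndarray | None = None) -> PBEnsemble:
    """Assign every residue of every frame to its nearest Protein Block.

    The assigned PB minimizes the RMSDA over the 8 wrapped angle
    differences of the 5-residue window; ties break to the alphabetically
    first letter. The first/last two residues of each chain and any window
    touching an undefined dihedral are ``Z``. Windows never span chains.
    """
    if prototypes is None:
        prototypes = load_prototypes()
    prototypes = np.asarray(prototypes, dtype=float)
    if prototypes.shape != (N_PB, 8):
        raise ValueError("prototypes must be a 16 x 8 angle matrix")
    F, R = dih.n_frames, dih.n_residues
    labels = np.full((F, R), UNDEFINED, dtype="U1")
    letters = np.array(PB_LABELS, dtype="U1")
    for chain in dih.chains:
        idx = np.nonzero(dih.chain_ids == chain)[0]
        if len(idx) < 5:
            continue
        win, centres = _windows(dih, idx)
        ok = ~np.isnan(win).any(axis=-1)  # (F, n_centres)
        # mean squared wrapped deviation to each prototype; per-prototype
        # loop keeps the intermediates at (F, n_centres, 8)
        score = np.empty(win.shape[:2] + (N_PB,))
        for p in range(N_PB):
            d = win - prototypes[p]
            d = np.where(d > 180.0, d - 360.0, d)
            d = np.where(d <= -180.0, d + 360.0, d)
            score[:, :, p] = np.einsum("fcw,fcw->fc", d, d)
        best = np.argmin(score, axis=-1)  # first minimum = alphabetical tie-break
        assigned = letters[best]
        assigned[~ok] = UNDEFINED
        labels[:, centres] = assigned
    return PBEnsemble(labels, dih.chain_ids, dih.residue_indices)


def write_pb_fasta(pbs: PBEnsemble, path, per: str = "frame") -> None:
    """Write PB sequences as FASTA-like records.

    ``per="frame"`` emits one record per frame with all chains concatenated
    in roster order; ``per="chain"`` emits one record per (chain, frame).
    """
    with open(path, "w", encoding="utf-8") as fh:
        if per == "frame":
            for f in range(pbs.n_frames):
                fh.write(f">frame_{f}\n{''.join(pbs.labels[f])}\n")
        elif per == "chain":
            for chain in pbs.chains:
                idx = pbs.chain_ids == chain
                for f in range(pbs.n_frames):
                    fh.write(f">chain_{chain}_frame_{f}\n{''.join(pbs.labels[f, idx])}\n")
        else:
            raise ValueError(f"per must be 'frame' or 'chain', got {per!r}")
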