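"""Superposition-based global descriptors: C-alpha RMSD, RMSF, per-chain
normalized RMSF, and correlation between flexibility descriptors.

RMSD measures a frame's overall deviation from a reference conformation
after optimal rigid-body superposition (Kabsch); RMSF measures each
residue's fluctuation about the iteratively refined mean structure.
Normalized RMSF is the per-chain z-score, making profiles comparable
across chains and systems. These are "global" descriptors, complementary
to the local, dihedral-based N_eq: a residue can be rigid locally
(N_eq = 1) yet ride on a mobile region (high RMSF), and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .ensemble_io import BackboneEnsemble

__all__ = [
    "SuperpositionError",
    "RMSDSeries",
    "RMSFProfile",
    "superpose",
    "rmsd_series",
    "rmsf",
    "descriptor_correlation",
]


class SuperpositionError(ValueError):
    """Fewer than 3 points or degenerate geometry."""


@dataclass
class RMSDSeries:
    """Per-frame C-alpha RMSD (Angstrom) versus a reference conformation."""

    values: np.ndarray
    reference_frame: int
    frame_times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise ValueError("RMSD must be non-negative")


@dataclass
class RMSFProfile:
    """Per-residue RMSF (Angstrom) and its per-chain z-score.

    ``normalized`` is NaN for chains with zero RMSF variance (e.g. a static
    ensemble), where a z-score is undefined.
    """

    rmsf: np.ndarray
    normalized: np.ndarray
    chain_ids: np.ndarray
    residue_indices: np.ndarray

    def __post_init__(self) -> None:
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        self.normalized = np.asarray(self.normalized, dtype=float)
        if np.any(self.rmsf < -1e-12):
            raise ValueError("RMSF must be non-negative")


def superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Kabsch algorithm with the proper-rotation branch (det = +1). Returns
    ``(rotation, translation, fitted)`` with ``fitted = mobile @ R.T + t``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise SuperpositionError("mobile and reference must be equal (N, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise SuperpositionError("need at least 3 points to superpose")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    m = mobile - mc
    r = reference - rc
    h = m.T @ r
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10:  # rank < 2: collinear/coincident points
        raise SuperpositionError("degenerate geometry: points are (near-)collinear")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    trans = rc - rot @ mc
    fitted = mobile @ rot.T + trans
    return rot, trans, fitted


def _superpose_batch(frames: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Kabsch-fit every frame of ``frames`` (F, N, 3) onto ``reference``
    (N, 3) at once; returns the fitted coordinates."""
    mc = frames.mean(axis=1, keepdims=True)
    rc = reference.mean(axis=0)
    m = frames - mc
    r = reference - rc
    h = np.einsum("fni,nj->fij", m, r)
    u, s, vt = np.linalg.svd(h)
    v = vt.transpose(0, 2, 1)
    ut = u.transpose(0, 2, 1)
    det = np.linalg.det(v @ ut)
    flip = np.broadcast_to(np.eye(3), (len(frames), 3, 3)).copy()
    flip[:, 2, 2] = np.sign(det)
    rot = v @ flip @ ut
    return np.einsum("fij,fnj->fni", rot, m) + rc


def rmsd_series(ens: BackboneEnsemble, reference: int = 0) -> RMSDSeries:
    """C-alpha RMSD of every frame against frame ``reference`` after
    optimal superposition."""
    if not 0 <= reference < ens.n_frames:
        raise IndexError(f"reference frame {reference} out of range")
    ca = ens.calpha
    if ca.shape[1] < 3:
        raise SuperpositionError("need at least 3 C-alpha atoms")
    ref = ca[reference]
    fitted = _superpose_batch(ca, ref)
    values = np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=2), axis=1))
    values[reference] = 0.0  # exact by definition; avoid roundoff dust
    return RMSDSeries(values, reference, ens.frame_times)


def rmsf(
    ens: BackboneEnsemble,
    truncate_frames: int = 0,
    do_superpose: bool = True,
    tol: float = 1e-6,
    max_iter: int = 10,
) -> RMSFProfile:
    """Per-residue C-alpha RMSF about the mean structure.

    The first ``truncate_frames`` frames are discarded (equilibration);
    remaining frames are superposed onto an iteratively refined mean
    structure (superpose -> mean -> re-superpose, until the mean moves less
    than ``tol`` Angstrom or ``max_iter`` rounds). RMSF(i) is the root mean
    square displacement of residue i about its average position, followed
    by per-chain z-score normalization. ``do_superpose=False`` computes raw
    fluctuations in the laboratory frame.
    """
    if truncate_frames >= ens.n_frames:
        raise ValueError("truncation leaves no frames")
    ca = ens.calpha[truncate_frames:]
    if ca.shape[0] < 2:
        raise ValueError("need at least 2 retained frames for fluctuations")
    if do_superpose:
        if ca.shape[1] < 3:
            raise SuperpositionError("need at least 3 C-alpha atoms")
        ref = ca[0]
        fitted = ca
        for _ in range(max_iter):
            fitted = _superpose_batch(ca, ref)
            mean = fitted.mean(axis=0)
            shift = np.sqrt(np.mean(np.sum((mean - ref) ** 2, axis=1)))
            ref = mean
            if shift < tol:
                break
        ca = fitted
    mean = ca.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((ca - mean) ** 2, axis=2), axis=0))
    normalized = np.full_like(fluct, np.nan)
    for chain in dict.fromkeys(ens.chain_ids):
        m = ens.chain_ids == chain
        sd = fluct[m].std()
        if m.sum() >= 2 and sd > 0:
            normalized[m] = (fluct[m] - fluct[m].mean()) / sd
    return RMSFProfile(fluct, normalized, ens.chain_ids, ens.residue_indices)


def descriptor_correlation(a, b, mask=None) -> float:
    """Pearson correlation between two per-residue descriptors over an
    optional position mask; NaN if either side has zero variance or fewer
    than 3 usable positions."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("descriptor arrays must have equal shape")
    keep = np.isfinite(a) & np.isfinite(b)
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    x, y = a[keep], b[keep]
    if x.size < 3 or x.std() == 0 or y.std() == 0:
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
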