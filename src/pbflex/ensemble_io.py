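"""Reading and writing conformational ensembles, annotation tracks and reports.

The in-memory currency of the package is :class:`BackboneEnsemble`: a
frames x residues array of backbone (N, CA, C) coordinates with chain and
residue identity. Multi-model PDB is the canonical on-disk ensemble format;
a plain dihedral table (TSV) is accepted as an already-reduced alternative.

Conventions used throughout the package:

* residue indexing is 0-based in memory and 1-based in every file written;
* all report tables are UTF-8 TSV, ``NA`` for undefined, floats with 6
  decimals;
* angles are degrees in (-180, 180].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C")

__all__ = [
    "BackboneEnsemble",
    "DihedralEnsemble",
    "AnnotationTrack",
    "EnsembleFormatError",
    "EnsembleStructureError",
    "read_ensemble",
    "write_ensemble_pdb",
    "read_dihedral_tsv",
    "write_dihedral_tsv",
    "read_annotation",
    "write_report",
]


class EnsembleFormatError(ValueError):
    """The file could not be parsed in the requested format."""


class EnsembleStructureError(ValueError):
    """The file parsed but violates an ensemble invariant (e.g. diverging
    residue rosters between models)."""


@dataclass
class BackboneEnsemble:
    """Frames x residues backbone coordinates.

    Parameters
    ----------
    coords
        Array of shape ``(n_frames, n_residues, 3, 3)``; axis 2 is the atom
        (N, CA, C), axis 3 is x/y/z in Angstrom.
    chain_ids
        Chain label per residue, shape ``(n_residues,)``.
    residue_indices
        0-based integer per residue, contiguous within each chain.
    frame_times
        Optional strictly increasing time stamps in ns, one per frame.
    """

    coords: np.ndarray
    chain_ids: np.ndarray
    residue_indices: np.ndarray
    frame_times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.chain_ids = np.asarray(self.chain_ids, dtype="U4")
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        if self.coords.ndim != 4 or self.coords.shape[2:] != (3, 3):
            raise ValueError(
                f"coords must have shape (frames, residues, 3, 3), got {self.coords.shape}"
            )
        n_res = self.coords.shape[1]
        if self.chain_ids.shape != (n_res,) or self.residue_indices.shape != (n_res,):
            raise ValueError("chain_ids / residue_indices must match the residue axis")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("all backbone coordinates must be finite")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (self.coords.shape[0],):
                raise ValueError("frame_times must have one entry per frame")
            if np.any(np.diff(self.frame_times) <= 0):
                raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    @property
    def chains(self) -> list[str]:
        """Chain labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c))
        return list(seen)

    def chain_mask(self, chain_id: str) -> np.ndarray:
        return self.chain_ids == chain_id

    def select_chain(self, chain_id: str) -> "BackboneEnsemble":
        m = self.chain_mask(chain_id)
        if not m.any():
            raise KeyError(f"no chain {chain_id!r} in ensemble")
        return BackboneEnsemble(
            self.coords[:, m], self.chain_ids[m], self.residue_indices[m], self.frame_times
        )

    def truncate(self, n_frames: int) -> "BackboneEnsemble":
        """Drop the first ``n_frames`` frames (equilibration truncation)."""
        if n_frames >= self.n_frames:
            raise ValueError(
                f"cannot truncate {n_frames} of {self.n_frames} frames"
            )
        times = None if self.frame_times is None else self.frame_times[n_frames:]
        return BackboneEnsemble(
            self.coords[n_frames:], self.chain_ids, self.residue_indices, times
        )

    @property
    def calpha(self) -> np.ndarray:
        """C-alpha coordinates, shape (n_frames, n_residues, 3)."""
        return self.coords[:, :, 1, :]


@dataclass
class DihedralEnsemble:
    """Frames x residues phi/psi table; NaN marks undefined angles
    (phi of the first and psi of the last residue of each chain)."""

    phi: np.ndarray
    psi: np.ndarray
    chain_ids: np.ndarray
    residue_indices: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.chain_ids = np.asarray(self.chain_ids, dtype="U4")
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        if self.phi.shape != self.psi.shape or self.phi.ndim != 2:
            raise ValueError("phi and psi must be equal-shape (frames, residues) arrays")
        for angles in (self.phi, self.psi):
            defined = angles[np.isfinite(angles)]
            if defined.size and (np.any(defined <= -180.0) or np.any(defined > 180.0)):
                raise ValueError("defined dihedrals must lie in (-180, 180]")

    @property
    def n_frames(self) -> int:
        return self.phi.shape[0]

    @property
    def n_residues(self) -> int:
        return self.phi.shape[1]

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c))
        return list(seen)


@dataclass
class AnnotationTrack:
    """Per-residue annotation: membrane topology, secondary structure,
    helix/loop segment label and (optionally) exon index.

    Stored as a DataFrame with columns chain, residue (0-based), topology,
    ss, segment, exon; covers any subset of the roster.
    """

    table: pd.DataFrame

    REQUIRED = ("chain", "residue", "topology", "ss", "segment")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation table lacks columns: {missing}")
        dup = self.table.duplicated(subset=["chain", "residue"])
        if dup.any():
            raise ValueError(
                "segment labels must partition residues: duplicate annotation for "
                f"{self.table.loc[dup, ['chain', 'residue']].iloc[0].tolist()}"
            )

    def segments(self) -> dict[str, pd.DataFrame]:
        """Mapping segment label -> annotated rows, in label order of appearance."""
        out: dict[str, pd.DataFrame] = {}
        for label, sub in self.table.groupby("segment", sort=False):
            out[str(label)] = sub
        return out


# ---------------------------------------------------------------------------
# multi-model PDB


def read_ensemble(path, fmt: str = "pdb"):
    """Read a conformational ensemble.

    ``fmt="pdb"`` reads a multi-model PDB and returns a
    :class:`BackboneEnsemble`; ``fmt="dihedral_tsv"`` reads the reduced
    dihedral table and returns a :class:`DihedralEnsemble`.

    Residues missing any of N/CA/C in any model are dropped from the roster
    with a warning. Insertion codes are rejected (ambiguous position
    arithmetic for the 5-residue PB windows). Altloc conflicts keep the
    highest-occupancy location, ties resolved to the first encountered.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "pdb":
        return _read_pdb_ensemble(path)
    if fmt == "dihedral_tsv":
        return read_dihedral_tsv(path)
    raise ValueError(f"unknown ensemble format {fmt!r}")


def _read_pdb_ensemble(path: Path) -> BackboneEnsemble:
    try:
        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
    except Exception as exc:  # biotite raises several parse error types
        raise EnsembleFormatError(f"cannot parse {path} as PDB: {exc}") from exc
    if n_models == 0:
        raise EnsembleFormatError(f"{path} contains no coordinate models")

    # parse each model separately: models may disagree on which atoms they
    # resolve, and the roster rules below reconcile them
    per_model: list[dict[tuple[str, int], dict[str, np.ndarray]]] = []
    roster: list[tuple[str, int]] = []
    for m in range(1, n_models + 1):
        try:
            atoms = pdb.get_structure(model=m, altloc="occupancy")
        except Exception as exc:
            raise EnsembleFormatError(
                f"cannot parse model {m} of {path}: {exc}"
            ) from exc
        if np.any(atoms.ins_code != ""):
            bad = np.nonzero(atoms.ins_code != "")[0][0]
            raise EnsembleStructureError(
                f"insertion codes are not supported (model {m}, chain "
                f"{atoms.chain_id[bad]} residue {atoms.res_id[bad]})"
            )
        is_bb = np.isin(atoms.atom_name, BACKBONE_ATOMS) & ~atoms.hetero
        bb = atoms[is_bb]
        table: dict[tuple[str, int], dict[str, np.ndarray]] = {}
        for i in range(bb.array_length()):
            key = (str(bb.chain_id[i]), int(bb.res_id[i]))
            table.setdefault(key, {})[str(bb.atom_name[i])] = bb.coord[i]
        if m == 1:
            roster = list(table)
        else:
            extra = [k for k in table if k not in set(roster)]
            if extra:
                raise EnsembleStructureError(
                    f"model {m} of {path} introduces residue chain {extra[0][0]} "
                    f"{extra[0][1]} absent from model 1: diverging rosters"
                )
        per_model.append(table)

    kept, dropped = [], []
    for key in roster:
        complete = all(
            all(a in tab.get(key, {}) for a in BACKBONE_ATOMS) for tab in per_model
        )
        (kept if complete else dropped).append(key)
    if dropped:
        warnings.warn(
            f"{len(dropped)} residue(s) lack a complete N/CA/C backbone in some "
            f"model and were dropped from the roster (first: chain "
            f"{dropped[0][0]} residue {dropped[0][1]})",
            stacklevel=2,
        )
    if not kept:
        raise EnsembleStructureError(f"{path}: no residue has a complete backbone")

    n_res = len(kept)
    coords = np.empty((n_models, n_res, 3, 3), dtype=float)
    for m, tab in enumerate(per_model):
        for r, key in enumerate(kept):
            for a, name in enumerate(BACKBONE_ATOMS):
                coords[m, r, a, :] = tab[key][name]
    if not np.all(np.isfinite(coords)):
        raise EnsembleStructureError(f"{path}: non-finite backbone coordinates")

    chain_ids = np.array([k[0] for k in kept], dtype="U4")
    # re-base residue numbering to a 0-based contiguous index per chain
    residue_indices = np.empty(n_res, dtype=int)
    counter: dict[str, int] = {}
    for r, (c, _rid) in enumerate(kept):
        residue_indices[r] = counter.get(c, 0)
        counter[c] = residue_indices[r] + 1
    return BackboneEnsemble(coords, chain_ids, residue_indices)


def write_ensemble_pdb(ens: BackboneEnsemble, path) -> None:
    """Write a :class:`BackboneEnsemble` as a multi-model PDB (poly-ALA
    backbone; the analysis uses geometry only, never residue identity)."""
    n_atoms = ens.n_residues * 3
    template = struc.AtomArray(n_atoms)
    template.chain_id = np.repeat(ens.chain_ids, 3)
    template.res_id = np.repeat(ens.residue_indices + 1, 3)  # 1-based on disk
    template.res_name = np.full(n_atoms, "ALA")
    template.atom_name = np.tile(np.array(BACKBONE_ATOMS), ens.n_residues)
    template.element = np.tile(np.array(["N", "C", "C"]), ens.n_residues)
    template.hetero = np.zeros(n_atoms, dtype=bool)
    stack = struc.AtomArrayStack(ens.n_frames, n_atoms)
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = ens.coords.reshape(ens.n_frames, n_atoms, 3)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# dihedral TSV dialect: columns frame, chain, residue, phi_deg, psi_deg


def write_dihedral_tsv(dih: DihedralEnsemble, path) -> None:
    """Serialize a dihedral ensemble; residues reported 1-based, angles with
    6 decimals, undefined angles as NA."""
    frames = np.repeat(np.arange(dih.n_frames), dih.n_residues)
    chains = np.tile(dih.chain_ids, dih.n_frames)
    residues = np.tile(dih.residue_indices + 1, dih.n_frames)
    df = pd.DataFrame(
        {
            "frame": frames,
            "chain": chains,
            "residue": residues,
            "phi_deg": dih.phi.ravel(),
            "psi_deg": dih.psi.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6f")


def read_dihedral_tsv(path) -> DihedralEnsemble:
    try:
        df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False,
                         dtype={"chain": str})
    except Exception as exc:
        raise EnsembleFormatError(f"cannot parse {path} as dihedral TSV: {exc}") from exc
    required = ["frame", "chain", "residue", "phi_deg", "psi_deg"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise EnsembleFormatError(f"{path}: dihedral TSV lacks columns {missing}")
    frames = np.sort(df["frame"].unique())
    first = df[df["frame"] == frames[0]]
    roster = list(zip(first["chain"], first["residue"]))
    n_res = len(roster)
    phi = np.full((len(frames), n_res), np.nan)
    psi = np.full((len(frames), n_res), np.nan)
    pos_of = {key: i for i, key in enumerate(roster)}
    frame_of = {f: i for i, f in enumerate(frames)}
    for f, sub in df.groupby("frame", sort=True):
        rows = list(zip(sub["chain"], sub["residue"]))
        if rows != roster:
            raise EnsembleStructureError(
                f"{path}: frame {f} roster diverges from frame {frames[0]}"
            )
        phi[frame_of[f]] = sub["phi_deg"].to_numpy()
        psi[frame_of[f]] = sub["psi_deg"].to_numpy()
    chain_ids = np.array([c for c, _ in roster], dtype="U4")
    residue_indices = np.array([int(r) - 1 for _, r in roster], dtype=int)
    return DihedralEnsemble(phi, psi, chain_ids, residue_indices)


# ---------------------------------------------------------------------------
# annotation and report tables


def read_annotation(path) -> AnnotationTrack:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False,
                     dtype={"chain": str})
    if "residue" in df.columns:
        df["residue"] = df["residue"].astype(int) - 1  # file is 1-based
    if "exon" not in df.columns:
        df["exon"] = pd.NA
    return AnnotationTrack(df)


def write_report(table: pd.DataFrame, path) -> None:
    """Write any per-position report as UTF-8 TSV with a header row, NA for
    undefined values and 6-decimal floats. 0-based ``residue`` columns are
    shifted to the 1-based convention of the files."""
    out = table.copy()
    if "residue" in out.columns:
        out["residue"] = out["residue"].astype(int) + 1
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6f")


def read_report(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    if "chain" in df.columns:
        df["chain"] = df["chain"].astype(str)
    if "residue" in df.columns:
        df["residue"] = df["residue"].astype(int) - 1
    return df
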