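"""Per-position flexibility statistics on Protein Block ensembles.

From a discretized trajectory (frames x positions PB letters) this module
derives:

* per-position PB frequency vectors f_x over the 16 letters;
* N_eq = exp(-sum f_x ln f_x), the "equivalent number of PBs" — the
  exponential Shannon entropy of the local conformational distribution,
  ranging from 1 (a single conformation, rigid) to 16 (uniform over the
  alphabet, maximally disordered);
* the rigid / intermediate / flexible / disordered classification by N_eq
  thresholds (rigid at 1.0, flexible around 4.0, disordered at 8.0+);
* delta-PB = sum_x |f_x^1 - f_x^2|, the total per-position difference
  between two sampling distributions, bounded by [0, 2];
* per-segment (helix/loop) summaries against an annotation track.

Undefined positions (no non-Z observation) propagate as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ensemble_io import AnnotationTrack
from .pb_alphabet import N_PB, PB_LABELS, PBEnsemble, UNDEFINED

__all__ = [
    "PBFrequencyProfile",
    "NeqProfile",
    "FlexibilityThresholds",
    "DeltaPBProfile",
    "pb_frequencies",
    "pool_frequencies",
    "neq",
    "classify",
    "delta_pb",
    "region_summary",
    "frequency_table",
    "pb_logo_table",
]

_LETTER_INDEX = {lab: i for i, lab in enumerate(PB_LABELS)}


@dataclass
class PBFrequencyProfile:
    """Per-position frequencies over the 16 PBs.

    ``freq`` has shape (n_positions, 16); rows of undefined positions
    (``n_obs == 0``) are NaN. Defined rows are non-negative and sum to 1.
    """

    freq: np.ndarray
    n_obs: np.ndarray
    chain_ids: np.ndarray
    residue_indices: np.ndarray

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.n_obs = np.asarray(self.n_obs, dtype=int)
        self.chain_ids = np.asarray(self.chain_ids, dtype="U4")
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        if self.freq.ndim != 2 or self.freq.shape[1] != N_PB:
            raise ValueError("freq must have shape (positions, 16)")
        defined = self.n_obs > 0
        rows = self.freq[defined]
        if rows.size:
            if np.any(rows < -1e-12):
                raise ValueError("frequencies must be non-negative")
            if np.any(np.abs(rows.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError("defined frequency rows must sum to 1")
        if np.any(np.isfinite(self.freq[~defined])):
            raise ValueError("undefined positions must be NaN rows")

    @property
    def n_positions(self) -> int:
        return self.freq.shape[0]

    @property
    def defined(self) -> np.ndarray:
        return self.n_obs > 0


@dataclass
class NeqProfile:
    """Per-position N_eq; NaN where the frequency profile is undefined."""

    values: np.ndarray
    chain_ids: np.ndarray
    residue_indices: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        defined = self.values[np.isfinite(self.values)]
        if defined.size and (np.any(defined < 1.0 - 1e-9) or np.any(defined > 16.0 + 1e-9)):
            raise ValueError("defined N_eq values must lie in [1, 16]")


@dataclass(frozen=True)
class FlexibilityThresholds:
    """N_eq cut points for the rigid/intermediate/flexible/disordered bands.

    Defaults: rigid at N_eq <= 1 (+ epsilon), flexible band [3, 8) around
    the descriptive value of 4, disordered at N_eq >= 8.
    """

    rigid_max: float = 1.0 + 1e-9
    flexible_lo: float = 3.0
    flexible_hi: float = 8.0
    disordered_min: float = 8.0

    def __post_init__(self) -> None:
        if not (self.rigid_max <= self.flexible_lo <= self.flexible_hi <= self.disordered_min):
            raise ValueError(
                "inconsistent thresholds: require rigid_max <= flexible_lo "
                "<= flexible_hi <= disordered_min"
            )


@dataclass
class DeltaPBProfile:
    """Per-position delta-PB between two frequency profiles; NaN where
    either side is undefined. Defined values lie in [0, 2]."""

    values: np.ndarray
    chain_ids: np.ndarray
    residue_indices: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        defined = self.values[np.isfinite(self.values)]
        if defined.size and (np.any(defined < -1e-12) or np.any(defined > 2.0 + 1e-9)):
            raise ValueError("defined delta-PB values must lie in [0, 2]")


def pb_frequencies(pbs: PBEnsemble) -> PBFrequencyProfile:
    """Tally per-position PB frequencies over frames, excluding Z.

    A position observed only as Z (chain termini) is undefined (NaN row).
    """
    if pbs.n_frames < 1:
        raise ValueError("need at least one frame")
    counts = np.zeros((pbs.n_residues, N_PB), dtype=np.int64)
    codes = _codes(pbs.labels)
    for x in range(N_PB):
        counts[:, x] = (codes == x).sum(axis=0)
    n_obs = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = counts / n_obs[:, None]
    freq[n_obs == 0] = np.nan
    return PBFrequencyProfile(freq, n_obs, pbs.chain_ids, pbs.residue_indices)


def _codes(labels: np.ndarray) -> np.ndarray:
    """PB letters -> integer codes 0..15, Z -> -1."""
    codes = np.full(labels.shape, -1, dtype=np.int8)
    for lab, i in _LETTER_INDEX.items():
        codes[labels == lab] = i
    return codes


def pool_frequencies(profiles: Sequence[PBFrequencyProfile]) -> PBFrequencyProfile:
    """Pool profiles over the same roster with observation-count weights —
    equivalent to tallying the concatenated trajectories."""
    if not profiles:
        raise ValueError("nothing to pool")
    first = profiles[0]
    for p in profiles[1:]:
        if p.freq.shape != first.freq.shape or np.any(p.chain_ids != first.chain_ids) \
                or np.any(p.residue_indices != first.residue_indices):
            raise ValueError("pooled profiles must share one residue roster")
    counts = np.zeros_like(first.freq)
    for p in profiles:
        c = p.freq * p.n_obs[:, None]
        counts += np.where(np.isfinite(c), c, 0.0)
    n_obs = np.sum([p.n_obs for p in profiles], axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = counts / n_obs[:, None]
    freq[n_obs == 0] = np.nan
    return PBFrequencyProfile(freq, n_obs, first.chain_ids, first.residue_indices)


def neq(freq: PBFrequencyProfile) -> NeqProfile:
    """N_eq = exp(-sum_x f_x ln f_x), with 0 ln 0 = 0.

    1 means a single PB is ever observed; 16 means all PBs equally likely.
    """
    f = freq.freq
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(f > 0, f * np.log(f), 0.0)
    values = np.exp(-np.nansum(terms, axis=1))
    values = np.clip(values, 1.0, 16.0)  # guard roundoff at the boundaries
    values[~freq.defined] = np.nan
    return NeqProfile(values, freq.chain_ids, freq.residue_indices)


def classify(neqp: NeqProfile, thresholds: FlexibilityThresholds | None = None) -> np.ndarray:
    """Map per-position N_eq to {rigid, intermediate, flexible, disordered}.

    Monotone in N_eq; undefined positions map to the empty string.
    """
    t = thresholds or FlexibilityThresholds()
    return classify_values(neqp.values, t)


def classify_values(values: np.ndarray, thresholds: FlexibilityThresholds | None = None) -> np.ndarray:
    t = thresholds or FlexibilityThresholds()
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, "", dtype="U12")
    defined = np.isfinite(v)
    out[defined] = "intermediate"
    out[defined & (v <= t.rigid_max)] = "rigid"
    out[defined & (v >= t.flexible_lo) & (v < t.flexible_hi)] = "flexible"
    out[defined & (v >= t.disordered_min)] = "disordered"
    return out


def delta_pb(a: PBFrequencyProfile, b: PBFrequencyProfile) -> DeltaPBProfile:
    """Per-position total difference between two PB frequency profiles,
    sum_x |f_x^1 - f_x^2| in [0, 2]."""
    if a.freq.shape != b.freq.shape:
        raise ValueError(
            f"profile rosters differ in length: {a.n_positions} vs {b.n_positions}"
        )
    mismatch = (a.chain_ids != b.chain_ids) | (a.residue_indices != b.residue_indices)
    if np.any(mismatch):
        pos = int(np.nonzero(mismatch)[0][0])
        raise ValueError(
            f"profile rosters diverge first at position {pos}: "
            f"{a.chain_ids[pos]}/{a.residue_indices[pos]} vs "
            f"{b.chain_ids[pos]}/{b.residue_indices[pos]}"
        )
    values = np.abs(a.freq - b.freq).sum(axis=1)
    values[~(a.defined & b.defined)] = np.nan
    return DeltaPBProfile(values, a.chain_ids, a.residue_indices)


def region_summary(
    neqp: NeqProfile,
    annotation: AnnotationTrack,
    thresholds: FlexibilityThresholds | None = None,
) -> pd.DataFrame:
    """Per-segment (helix/loop) flexibility summary.

    For each segment label: max N_eq, mean N_eq, and the segment class from
    its maximum N_eq — a loop counts as disordered as soon as any of its
    positions is. Segments without any defined position are omitted with a
    warning.
    """
    import warnings

    t = thresholds or FlexibilityThresholds()
    pos_of = {
        (str(c), int(r)): i
        for i, (c, r) in enumerate(zip(neqp.chain_ids, neqp.residue_indices))
    }
    rows = []
    for label, sub in annotation.segments().items():
        vals = []
        for _, arow in sub.iterrows():
            key = (str(arow["chain"]), int(arow["residue"]))
            if key in pos_of:
                v = neqp.values[pos_of[key]]
                if np.isfinite(v):
                    vals.append(v)
        if not vals:
            warnings.warn(f"segment {label!r} has no defined N_eq position; omitted",
                          stacklevel=2)
            continue
        vmax = float(np.max(vals))
        rows.append(
            {
                "segment": label,
                "n_positions": len(vals),
                "max_neq": vmax,
                "mean_neq": float(np.mean(vals)),
                "class": classify_values(np.array([vmax]), t)[0],
            }
        )
    return pd.DataFrame(rows, columns=["segment", "n_positions", "max_neq", "mean_neq", "class"])


# ---------------------------------------------------------------------------
# tabular exports


def frequency_table(freq: PBFrequencyProfile) -> pd.DataFrame:
    """Position x 16 PB frequency table plus observation counts."""
    df = pd.DataFrame(freq.freq, columns=[f"f_{lab}" for lab in PB_LABELS])
    df.insert(0, "chain", freq.chain_ids)
    df.insert(1, "residue", freq.residue_indices)
    df["n_obs"] = freq.n_obs
    return df


def pb_logo_table(freq: PBFrequencyProfile, top: int = 5) -> pd.DataFrame:
    """Ranked-PB text 'logo': per position the top PB letters with their
    frequencies, a data mirror of graphical logo panels."""
    rows = []
    for i in range(freq.n_positions):
        row = {"chain": freq.chain_ids[i], "residue": freq.residue_indices[i]}
        if freq.n_obs[i] == 0:
            for r in range(top):
                row[f"pb_{r + 1}"] = UNDEFINED
                row[f"freq_{r + 1}"] = np.nan
        else:
            order = np.argsort(-freq.freq[i], kind="stable")[:top]
            for r, x in enumerate(order):
                row[f"pb_{r + 1}"] = PB_LABELS[x]
                row[f"freq_{r + 1}"] = freq.freq[i, x]
        rows.append(row)
    return pd.DataFrame(rows)
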