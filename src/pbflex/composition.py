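"""Composition-wise grouping and comparison of trimer trajectories.

The top-level experiment: monomer chains coming from trimers of identical
subunit composition are pooled (their trajectories concatenated, after
equilibration truncation) into one conformational sample per
(subunit, composition) group; groups of the same subunit are then compared
pairwise by per-position delta-PB, and positions are flagged at the
descriptive levels used for the trimer study (> 1.0 maximum variability,
> 0.6 notable, <= 0.2 unremarkable).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ensemble_io import AnnotationTrack, BackboneEnsemble, write_report
from .flexibility import (
    DeltaPBProfile,
    FlexibilityThresholds,
    NeqProfile,
    PBFrequencyProfile,
    classify,
    delta_pb,
    frequency_table,
    neq,
    pb_frequencies,
    pool_frequencies,
    region_summary,
)
from .global_metrics import rmsf
from .pb_alphabet import PB_LABELS, assign_pb, compute_dihedrals

__all__ = [
    "CompositionGroup",
    "EnsembleRecord",
    "AnalysisConfig",
    "StudyManifest",
    "GroupProfile",
    "StudyResult",
    "pool_group",
    "compare_groups",
    "run_study",
]

#: descriptive delta-PB flag levels: unremarkable / notable / maximum
DEFAULT_FLAG_LEVELS = (0.2, 0.6, 1.0)


@dataclass(frozen=True)
class CompositionGroup:
    """A named set of (ensemble id, chain id) members analysed together.

    All members must carry the same subunit (identical residue rosters).
    """

    name: str
    members: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group {self.name!r} has no members")


@dataclass(frozen=True)
class EnsembleRecord:
    """Metadata for one declared trajectory: its trimer composition string,
    replicate index and the subunit type of each chain. ``path`` points to
    the on-disk ensemble for file-based studies."""

    composition: str
    replicate: int
    chain_subunits: Mapping[str, str]
    path: Optional[str] = None


@dataclass(frozen=True)
class AnalysisConfig:
    """Study-wide analysis settings.

    ``truncate_frames`` drops the leading frames of every member before any
    statistic (the 50 ns equilibration at a 100 ps saving interval = 500
    frames by default); thresholds and flag levels are the N_eq bands and
    delta-PB descriptive levels.
    """

    truncate_frames: int = 500
    thresholds: FlexibilityThresholds = field(default_factory=FlexibilityThresholds)
    flag_levels: tuple[float, float, float] = DEFAULT_FLAG_LEVELS
    seed: int = 0


@dataclass(frozen=True)
class StudyManifest:
    """Declarative description of a study: ensembles, groups, pairwise
    comparisons and the analysis config."""

    ensembles: Mapping[str, EnsembleRecord]
    groups: tuple[CompositionGroup, ...]
    comparisons: tuple[tuple[str, str], ...]
    config: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        by_name = {g.name: g for g in self.groups}
        for g in self.groups:
            for ens_id, chain in g.members:
                if ens_id not in self.ensembles:
                    raise ValueError(
                        f"group {g.name!r} references undeclared ensemble {ens_id!r}"
                    )
                if chain not in self.ensembles[ens_id].chain_subunits:
                    raise ValueError(
                        f"group {g.name!r} references unknown chain {chain!r} "
                        f"of ensemble {ens_id!r}"
                    )
        for a, b in self.comparisons:
            for name in (a, b):
                if name not in by_name:
                    raise ValueError(f"comparison references unknown group {name!r}")

    def to_json(self) -> str:
        doc = {
            "ensembles": {
                k: {
                    "composition": r.composition,
                    "replicate": r.replicate,
                    "chain_subunits": dict(r.chain_subunits),
                    "path": r.path,
                }
                for k, r in sorted(self.ensembles.items())
            },
            "groups": [
                {"name": g.name, "members": [list(m) for m in g.members]}
                for g in self.groups
            ],
            "comparisons": [list(c) for c in self.comparisons],
            "config": {
                "truncate_frames": self.config.truncate_frames,
                "thresholds": asdict(self.config.thresholds),
                "flag_levels": list(self.config.flag_levels),
                "seed": self.config.seed,
            },
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StudyManifest":
        doc = json.loads(text)
        ensembles = {
            k: EnsembleRecord(
                composition=v["composition"],
                replicate=v["replicate"],
                chain_subunits=v["chain_subunits"],
                path=v.get("path"),
            )
            for k, v in doc["ensembles"].items()
        }
        groups = tuple(
            CompositionGroup(g["name"], tuple(tuple(m) for m in g["members"]))
            for g in doc["groups"]
        )
        comparisons = tuple(tuple(c) for c in doc["comparisons"])
        cfg = doc["config"]
        config = AnalysisConfig(
            truncate_frames=cfg["truncate_frames"],
            thresholds=FlexibilityThresholds(**cfg["thresholds"]),
            flag_levels=tuple(cfg["flag_levels"]),
            seed=cfg["seed"],
        )
        return cls(ensembles, groups, comparisons, config)


@dataclass
class GroupProfile:
    """Pooled statistics of one composition group."""

    name: str
    frequencies: PBFrequencyProfile
    neq: NeqProfile
    classes: np.ndarray
    rmsf_mean: np.ndarray  # position-wise mean of per-member RMSF (A)
    rmsf_norm_mean: np.ndarray  # position-wise mean of per-member normalized RMSF
    n_members: int
    n_frames_pooled: int


@dataclass
class StudyResult:
    groups: dict[str, GroupProfile]
    comparisons: dict[tuple[str, str], pd.DataFrame]
    region_summaries: dict[str, pd.DataFrame]


def _member_statistics(ens: BackboneEnsemble, chain: str, truncate_frames: int):
    """Truncate, discretize and profile one (ensemble, chain) member."""
    sub = ens.select_chain(chain)
    if truncate_frames:
        sub = sub.truncate(truncate_frames)
    dih = compute_dihedrals(sub)
    pbs = assign_pb(dih)
    freq = pb_frequencies(pbs)
    prof = rmsf(sub)
    return freq, prof


def _relabel(freq: PBFrequencyProfile, label: str) -> PBFrequencyProfile:
    """Replace the chain id so that members from different chain positions
    pool over one canonical roster."""
    return PBFrequencyProfile(
        freq.freq,
        freq.n_obs,
        np.full(freq.n_positions, label, dtype="U4"),
        freq.residue_indices,
    )


def pool_group(
    group: CompositionGroup,
    data: Mapping[str, BackboneEnsemble],
    config: AnalysisConfig | None = None,
    _cache: Optional[dict] = None,
) -> GroupProfile:
    """Pool a group's members: PB frequencies by concatenation (observation-
    count weights), N_eq from the pooled frequencies, RMSF per member then
    averaged position-wise (normalized per member first, then averaged).
    """
    config = config or AnalysisConfig()
    freqs, rmsfs, rmsf_norms = [], [], []
    roster = None
    for ens_id, chain in group.members:
        key = (ens_id, chain)
        if _cache is not None and key in _cache:
            freq, prof = _cache[key]
        else:
            freq, prof = _member_statistics(data[ens_id], chain, config.truncate_frames)
            if _cache is not None:
                _cache[key] = (freq, prof)
        if roster is None:
            roster = freq.residue_indices
        elif len(roster) != freq.n_positions or np.any(roster != freq.residue_indices):
            raise ValueError(
                f"group {group.name!r}: member {key} has a diverging residue roster"
            )
        freqs.append(_relabel(freq, group.name.split("_")[0][:4]))
        rmsfs.append(prof.rmsf)
        rmsf_norms.append(prof.normalized)
    pooled = pool_frequencies(freqs)
    pooled_neq = neq(pooled)
    classes = classify(pooled_neq, config.thresholds)
    return GroupProfile(
        name=group.name,
        frequencies=pooled,
        neq=pooled_neq,
        classes=classes,
        rmsf_mean=np.mean(rmsfs, axis=0),
        rmsf_norm_mean=np.nanmean(rmsf_norms, axis=0) if rmsf_norms else np.array([]),
        n_members=len(group.members),
        n_frames_pooled=int(pooled.n_obs.max()) if pooled.n_obs.size else 0,
    )


def compare_groups(
    a: GroupProfile | PBFrequencyProfile,
    b: GroupProfile | PBFrequencyProfile,
    flag_levels: Sequence[float] = DEFAULT_FLAG_LEVELS,
) -> pd.DataFrame:
    """Per-position delta-PB between two pooled profiles with descriptive
    flags: 'maximum' above the top level, 'notable' above the middle,
    'low' at or below the bottom, 'moderate' between."""
    fa = a.frequencies if isinstance(a, GroupProfile) else a
    fb = b.frequencies if isinstance(b, GroupProfile) else b
    lo, mid, hi = sorted(flag_levels)
    profile = delta_pb(fa, fb)
    v = profile.values
    flags = np.full(v.shape, "", dtype="U12")
    defined = np.isfinite(v)
    flags[defined] = "moderate"
    flags[defined & (v <= lo)] = "low"
    flags[defined & (v > mid)] = "notable"
    flags[defined & (v > hi)] = "maximum"
    return pd.DataFrame(
        {
            "residue": profile.residue_indices,
            "delta_pb": v,
            "flag": flags,
        }
    )


def run_study(
    manifest: StudyManifest,
    data: Mapping[str, BackboneEnsemble] | None = None,
    out_dir=None,
    annotations: Mapping[str, AnnotationTrack] | None = None,
) -> StudyResult:
    """Execute a whole study: pool every group, run every declared pairwise
    comparison, join region summaries where an annotation is given, and
    (optionally) write a deterministic report bundle.

    ``data`` may be omitted for file-based manifests whose records carry
    paths. The report bundle contains only content derived from manifest +
    data + seed (no timestamps), so re-running with the same inputs gives
    byte-identical files.
    """
    from .ensemble_io import read_ensemble

    if data is None:
        data = {}
    data = dict(data)
    for ens_id, rec in manifest.ensembles.items():
        if ens_id not in data:
            if rec.path is None:
                raise ValueError(f"ensemble {ens_id!r} has neither data nor path")
            data[ens_id] = read_ensemble(rec.path)

    cache: dict = {}
    groups: dict[str, GroupProfile] = {}
    for group in manifest.groups:
        try:
            groups[group.name] = pool_group(group, data, manifest.config, cache)
        except Exception as exc:
            raise RuntimeError(f"pooling failed for group {group.name!r}: {exc}") from exc

    comparisons: dict[tuple[str, str], pd.DataFrame] = {}
    for a, b in manifest.comparisons:
        try:
            comparisons[(a, b)] = compare_groups(
                groups[a], groups[b], manifest.config.flag_levels
            )
        except Exception as exc:
            raise RuntimeError(f"comparison {a!r} vs {b!r} failed: {exc}") from exc

    region_summaries: dict[str, pd.DataFrame] = {}
    if annotations:
        for name, profile in groups.items():
            subunit = name.split("_")[0]
            if subunit in annotations:
                region_summaries[name] = region_summary(
                    profile.neq, annotations[subunit], manifest.config.thresholds
                )

    result = StudyResult(groups, comparisons, region_summaries)
    if out_dir is not None:
        _write_bundle(out_dir, manifest, result)
    return result


def _write_bundle(out_dir, manifest: StudyManifest, result: StudyResult) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in sorted(result.groups):
        g = result.groups[name]
        freq_df = frequency_table(g.frequencies)
        write_report(freq_df, out / f"group_{name}_pb_frequencies.tsv")
        prof_df = pd.DataFrame(
            {
                "chain": g.neq.chain_ids,
                "residue": g.neq.residue_indices,
                "neq": g.neq.values,
                "class": g.classes,
                "rmsf_A": g.rmsf_mean,
                "rmsf_norm": g.rmsf_norm_mean,
            }
        )
        write_report(prof_df, out / f"group_{name}_profile.tsv")
    for (a, b) in sorted(result.comparisons):
        write_report(result.comparisons[(a, b)], out / f"delta_pb_{a}_vs_{b}.tsv")
    for name in sorted(result.region_summaries):
        write_report(result.region_summaries[name], out / f"regions_{name}.tsv")
    log = {
        "manifest": json.loads(manifest.to_json()),
        "n_groups": len(result.groups),
        "n_comparisons": len(result.comparisons),
        "package": "pbflex 0.1.0",
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
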