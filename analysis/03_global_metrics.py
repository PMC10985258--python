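#!/usr/bin/env python
"""Global descriptors: RMSD equilibration check, normalized RMSF, and the
local-vs-global flexibility relation.

For one replicate trajectory the C-alpha RMSD series against the first
frame verifies the steady state (the generator is stationary, so the
series should plateau immediately). Per-chain normalized RMSF is then
averaged within each composition group and correlated with both the
group's N_eq profile and the generator's analytic N_eq — the synthetic
analogue of comparing a global mobility measure with an external
per-residue reference profile.

Writes results/global_metrics/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

import pbflex as pf
from pbflex.composition import pool_group

OUT = Path(__file__).resolve().parent.parent / "results" / "global_metrics"
SEED = 1
N_FRAMES = 1000


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    manifest, data, truths = pf.make_study_fixture(seed=SEED, n_frames=N_FRAMES)

    ens = data["AAA_r1"]
    series = pf.rmsd_series(ens)
    pf.write_report(
        pd.DataFrame({"frame": np.arange(ens.n_frames),
                      "time_ns": series.frame_times,
                      "rmsd_A": series.values}),
        OUT / "rmsd_AAA_r1.tsv",
    )
    half = ens.n_frames // 2
    print(f"AAA_r1 C-alpha RMSD: mean {series.values[1:].mean():.3f} A, "
          f"first-half {series.values[1:half].mean():.3f} vs "
          f"second-half {series.values[half:].mean():.3f} A (stationary)")

    cache = {}
    rows = []
    for group in manifest.groups:
        gp = pool_group(group, data, manifest.config, cache)
        truth = truths[group.members[0]]
        r_neq = pf.descriptor_correlation(gp.rmsf_norm_mean, gp.neq.values)
        r_truth = pf.descriptor_correlation(gp.rmsf_norm_mean, truth.analytic_neq)
        rows.append({"group": group.name, "n_members": gp.n_members,
                     "r_rmsf_neq": r_neq, "r_rmsf_analytic_neq": r_truth})
        pf.write_report(
            pd.DataFrame({"chain": gp.neq.chain_ids,
                          "residue": gp.neq.residue_indices,
                          "rmsf_A": gp.rmsf_mean,
                          "rmsf_norm": gp.rmsf_norm_mean}),
            OUT / f"rmsf_{group.name}.tsv",
        )
        print(f"{group.name}: normalized RMSF vs N_eq r = {r_neq:.3f}, "
              f"vs analytic N_eq r = {r_truth:.3f}")

    pf.write_report(pd.DataFrame(rows), OUT / "correlations.tsv")
    print("high correlations are expected here: the generator's only "
          "mobility mechanism is the conformer-switching tail, so local "
          "and global descriptors agree; real proteins decouple them")
    print(f"wrote RMSD series, RMSF profiles and correlations under {OUT}")


if __name__ == "__main__":
    sys.exit(main())
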