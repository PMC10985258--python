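#!/usr/bin/env python
"""Does trimer composition change local conformational sampling?

Runs the declared pairwise delta-PB comparisons between composition
groups of the same subunit and flags positions at the descriptive levels
(<= 0.2 unremarkable, > 0.6 notable, > 1.0 maximum variability). Because
every composition is generated from the same subunit recipe, the expected
answer is the null: delta-PB stays at sampling-noise level everywhere,
concentrated in the conformer-switching tail.

Writes the full report bundle under results/composition/.
"""

import sys
from pathlib import Path

import numpy as np

import pbflex as pf

OUT = Path(__file__).resolve().parent.parent / "results" / "composition"
SEED = 1
N_FRAMES = 1000


def main() -> None:
    manifest, data, truths = pf.make_study_fixture(seed=SEED, n_frames=N_FRAMES)
    annotations = {k: pf.subunit_annotation(k) for k in ("A", "B")}
    result = pf.run_study(manifest, data, out_dir=OUT, annotations=annotations)

    print(f"{len(result.comparisons)} pairwise group comparisons:")
    worst = 0.0
    for (a, b), table in result.comparisons.items():
        d = table["delta_pb"].to_numpy()
        peak = np.nanmax(d)
        worst = max(worst, peak)
        n_notable = int((table["flag"] == "notable").sum()
                        + (table["flag"] == "maximum").sum())
        peak_pos = int(table.loc[np.nanargmax(d), "residue"]) + 1
        print(f"  {a} vs {b}: max delta-PB {peak:.3f} at residue {peak_pos}, "
              f"{n_notable} positions above the notable level")
    if worst <= 1.0:
        print(f"composition null holds: no position reaches the maximum-"
              f"variability level (worst {worst:.3f} <= 1.0)")
    else:
        print(f"composition effect detected: max delta-PB {worst:.3f} > 1.0")
    print(f"report bundle written under {OUT}")


if __name__ == "__main__":
    sys.exit(main())
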