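#!/usr/bin/env python
"""Exact blockage-to-convergence window distributions by enumeration.

Enumerates all 2^8 origin-firing subsets of the barrier locus (and of the
same locus with ori-1253, the dominant converging-side origin, deleted) and
aggregates the arrest-window outcomes.  The deletion shifts probability mass
from ~22-min windows to ~40+-min and censored (never-converged within 90 min)
outcomes — the quantitative basis for the extended recombination intervals
seen in the origin-deleted strain.

Writes results/window_distribution_{AO,AO_ori1253d}.{tsv,json}.
"""

import json
from pathlib import Path

from rfbsim.locus import TimingParams, delete_origin, packaged_origin_map, window_distribution_enumerate

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    amap = packaged_origin_map("AO")
    for tag, m in (("AO", amap), ("AO_ori1253d", delete_origin(amap, "ori-1253"))):
        dist = window_distribution_enumerate(m, TimingParams())
        dist.write(OUT / f"window_distribution_{tag}.tsv",
                   OUT / f"window_distribution_{tag}.json")
        s = dist.summary()
        print(f"{tag}: P(arrest window opens) = {s['p_defined']:.3f}, "
              f"mean window {s['mean_min']:.1f} min over resolved outcomes, "
              f"P(unresolved at {s['horizon_min']:.0f} min) = {s['p_censored']:.3f}")


if __name__ == "__main__":
    main()
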