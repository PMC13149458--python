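#!/usr/bin/env python
"""Per-subject weighted graph measures for every simulated cohort.

Computes node strength, betweenness centrality, Onnela clustering and
assortativity for each (metric, filtering) cell and writes the long-format
node and whole-brain tables consumed by the group comparisons.
"""

from pathlib import Path

import pandas as pd

from connectogroup.atlas import generic_atlas
from connectogroup.core import read_cohort
from connectogroup.graph_metrics import compute_cohort_metrics

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    labels = generic_atlas(30)
    for scenario in ("null", "node_effect", "removal", "emergence"):
        cohort = read_cohort(ROOT / "cohorts" / scenario,
                             ROOT / "cohorts" / scenario / "manifest.csv", labels)
        nodes, globals_ = [], []
        for metric in cohort.available_metrics():
            for filtering in ("unfiltered", "filtered"):
                nt, gt = compute_cohort_metrics(cohort, metric, filtering)
                nodes.append(nt)
                globals_.append(gt)
        out_n = ROOT / f"metrics_{scenario}_nodes.csv"
        out_g = ROOT / f"metrics_{scenario}_global.csv"
        pd.concat(nodes, ignore_index=True).to_csv(out_n, index=False)
        pd.concat(globals_, ignore_index=True).to_csv(out_g, index=False)
        print(f"{scenario}: wrote {out_n.name} and {out_g.name}")


if __name__ == "__main__":
    main()
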