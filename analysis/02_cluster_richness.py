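#!/usr/bin/env python
"""Cluster richness and rarefaction of the two simulated viromes.

Reads the deduplicated viromes from 01, normalises them to equal-size
100-bp subsamples, clusters at 75% identity and draws rarefaction curves.
The richer lake should show both more clusters and a steeper, less
saturating curve.
"""

import os

from viromekit import clusterdiv, seqio

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
SCRATCH = os.path.join(os.path.dirname(__file__), "..", "scratch")
SEED = 20120314
SUBSAMPLE_N = 5000
TRIM_LEN = 100
THRESHOLD = 0.75
STEP = 500


def main() -> None:
    rows = ["virome\tn_reads\tn_clusters"]
    for name in ("lake_rich", "lake_poor"):
        rs = seqio.read_sequences(os.path.join(SCRATCH, f"{name}.fasta"),
                                  name=name, biome="freshwater")
        sub = seqio.subsample(rs, n=SUBSAMPLE_N, trim_len=TRIM_LEN, seed=SEED)
        sol = clusterdiv.greedy_cluster(sub, THRESHOLD)
        curve = clusterdiv.rarefy(sub, THRESHOLD, step=STEP, seed=SEED + 1)
        clusterdiv.write_curve_tsv(
            curve, os.path.join(OUT, f"{name}.rarefaction.tsv"))
        rows.append(f"{name}\t{len(sub)}\t{sol.n_clusters}")
        print(f"{name}: {sol.n_clusters} clusters from {len(sub)} reads at "
              f"{THRESHOLD:.0%} identity; curve endpoint "
              f"{curve.points[-1]}")
    with open(os.path.join(OUT, "cluster_richness.tsv"), "w") as fh:
        fh.write("\n".join(rows) + "\n")


if __name__ == "__main__":
    main()
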