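#!/usr/bin/env python
"""Species richness of the two simulated viromes from their contig spectra.

Subsamples each deduplicated virome to 100-bp reads, assembles at 98%
identity over >= 35 bp, and fits all rank-abundance families to the
contig spectrum.  The known true richness values from 01 (800 vs 200
virotypes) let us see how well the estimates order and scale.
"""

import json
import os

from viromekit import seqio, specrich

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
SCRATCH = os.path.join(os.path.dirname(__file__), "..", "scratch")
SEED = 20120314
SUBSAMPLE_N = 20000
TRIM_LEN = 100
AVG_GENOME_LEN = 5000  # known input for the synthetic communities


def main() -> None:
    results = {}
    for name in ("lake_rich", "lake_poor"):
        rs = seqio.read_sequences(os.path.join(SCRATCH, f"{name}.fasta"),
                                  name=name, biome="freshwater")
        sub = seqio.subsample(rs, n=min(SUBSAMPLE_N, len(rs)),
                              trim_len=TRIM_LEN, seed=SEED)
        _, spectrum = specrich.assemble_strict(sub)
        specrich.write_spectrum_tsv(
            spectrum, os.path.join(OUT, f"{name}.spectrum.tsv"))
        lw = specrich.LWParams(read_len=TRIM_LEN, min_overlap=35,
                               avg_genome_len=AVG_GENOME_LEN)
        est = specrich.fit_richness(spectrum, lw)
        results[name] = {
            "S_hat": est.S_hat, "family": est.best_model.family,
            "params": est.best_model.params, "shannon": round(est.shannon, 4),
            "evenness": round(est.evenness, 4),
            "fit_table": est.fit_table,
        }
        print(f"{name}: S_hat = {est.S_hat} ({est.best_model.family}), "
              f"H = {est.shannon:.3f} nats, J = {est.evenness:.3f}")
    with open(os.path.join(OUT, "species_richness.json"), "w") as fh:
        json.dump(results, fh, indent=1)
    ordered = results["lake_rich"]["S_hat"] > results["lake_poor"]["S_hat"]
    print(f"richness ordering matches the simulated truth: {ordered}")


if __name__ == "__main__":
    main()
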