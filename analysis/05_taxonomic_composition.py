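#!/usr/bin/env python
"""Taxonomic decision logic on the worked hit-table example.

Runs the known/unknown calls, domain breakdown, viral rescue and
genome-length-normalised family affiliation on the hand-crafted hit
tables (the full decision tree in miniature), and writes the composition
report.  With real data the tables would come from protein-database and
viral-genome searches of the virome reads.
"""

import json
import os

from viromekit.experiments import taxonomy_example_results

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    res = taxonomy_example_results()
    print(f"known fraction: {res['known_fraction']:.0%}")
    print("domain breakdown of known reads:")
    for dom, frac in res["domain_fractions"].items():
        print(f"  {dom}: {frac:.1%}")
    print(f"reads similar to at least one viral sequence: "
          f"{len(res['viral_like'])} of {len(res['known'])} known")
    print(f"family composition (1/genome-length weighted): "
          f"{res['composition']}")
    with open(os.path.join(OUT, "taxonomy.json"), "w") as fh:
        json.dump(res, fh, indent=1)


if __name__ == "__main__":
    main()
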