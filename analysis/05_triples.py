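#!/usr/bin/env python
"""Validate miRNA/protein/taxon triple formation against ORF ground truth.

Plants target sites inside annotated ORFs, runs the translated protein
search with the 90% identity / 80% coverage / 25-hit rules and the
intersect-then-bitscore best-hit selection, and checks that each triple's
protein label names an ORF the read pair actually overlaps.
"""

import json
from pathlib import Path

from mirbact.formats import write_table
from mirbact.studies import triple_recovery_study

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    result = triple_recovery_study(seed=1)
    with open(RESULTS / "05_triple_precision.json", "w") as fh:
        json.dump(
            {
                "protein_label_precision": result["precision"],
                "n_pairs_with_protein_hit": result["n_pairs_with_protein"],
                "n_distinct_triples": len(result["triples"]),
            },
            fh, indent=2,
        )
    write_table(RESULTS / "05_triples.tsv", result["triples"])
    print(f"protein label precision: {result['precision']:.3f} "
          f"over {result['n_pairs_with_protein']} pairs")
    print(f"{len(result['triples'])} distinct triples → "
          f"{RESULTS / '05_triples.tsv'}")


if __name__ == "__main__":
    main()
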