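#!/usr/bin/env python
"""Intra-protein co-occurrence of the anchor protein's own phosphosites.

Tallies direction concordance for every ordered pair of anchor-protein sites
across the differential corpus and writes the long-format pair table
(counts plus positive/negative co-modulation ratios) to
results/cooccurrence.tsv, printing the pairs most strongly co-occurring with
the predominant site.
"""

import argparse
from pathlib import Path

from comodnet import cooccurrence_matrix, read_corpus
from comodnet.corpus import write_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--fixture", type=Path, default=ROOT / "results" / "fixture")
    parser.add_argument("--protein", default="P07947")
    parser.add_argument("--anchor-site", default="Y426")
    args = parser.parse_args()

    corpus = read_corpus(None, args.fixture / "differential.tsv")
    matrix = cooccurrence_matrix(corpus, args.protein)
    out = ROOT / "results" / "cooccurrence.tsv"
    write_table(matrix, out)

    anchored = matrix[matrix["site_a"] == args.anchor_site].sort_values(
        "total", ascending=False)
    print(f"{len(matrix)} ordered site pairs on {args.protein}; "
          f"pairs with {args.anchor_site} by shared callable datasets:")
    print(anchored.to_string(index=False))
    print(f"table written to {out}")


if __name__ == "__main__":
    main()
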