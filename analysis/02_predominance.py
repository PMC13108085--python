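#!/usr/bin/env python
"""Rank the anchor protein's phosphosites and nominate the predominant one.

Reads the corpus from results/fixture/ (run 01_simulate_corpus.py first),
counts each anchor-protein site's Class-1 detections across the profiling
and differential corpora, combines the two dense frequency ranks by their
product, and writes results/predominance.tsv.
"""

import argparse
from pathlib import Path

from comodnet import rank_predominance, read_corpus, site_frequencies
from comodnet.corpus import write_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--fixture", type=Path, default=ROOT / "results" / "fixture")
    parser.add_argument("--protein", default="P07947")
    args = parser.parse_args()

    corpus = read_corpus(args.fixture / "profiling.tsv", args.fixture / "differential.tsv")
    ranked = rank_predominance(site_frequencies(corpus, args.protein))
    out = ROOT / "results" / "predominance.tsv"
    write_table(ranked, out)

    top = ranked.iloc[0]
    print(ranked.to_string(index=False))
    print(f"\npredominant phosphosite: {top['gene']} {top['residue']}{top['position']} "
          f"(profile rank {top['profile_rank']}, differential rank "
          f"{top['differential_rank']}, score {top['predominance_score']})")
    print(f"table written to {out}")


if __name__ == "__main__":
    main()
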