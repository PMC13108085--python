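#!/usr/bin/env python
"""Overlay interaction, kinase-substrate, enzyme and biomarker annotations.

Uses the deterministic demonstration corpus (perfectly concordant/discordant
named partners) together with the curated annotation fixtures to produce the
site-resolved network views: binary interactors with their co-modulation
sign, site-specific upstream regulators and candidate downstream substrates
of the anchor site, kinase/phosphatase partners with functional-effect
labels, and per-disease biomarker overlaps.  Writes the overlay tables and a
merged SIF edge list under results/overlays/.
"""

import argparse
from pathlib import Path

from comodnet import demo_corpus, run_comodulation
from comodnet.annotations import (biomarker_overlap, classify_enzyme_partners,
                                  identify_downstream_substrates,
                                  identify_upstream_regulators,
                                  read_biomarkers, read_enzyme_classes,
                                  read_interactions, read_kinase_substrate,
                                  read_site_effects, tag_binary_interactors)
from comodnet.corpus import write_sif, write_table
from comodnet.simulate import ANCHOR, write_annotation_fixtures

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--annotations", type=Path,
                        default=ROOT / "results" / "fixture" / "annotations")
    args = parser.parse_args()

    ann = args.annotations
    if not ann.exists():
        write_annotation_fixtures(ann)

    result = run_comodulation(demo_corpus(), ANCHOR)
    hc = result.table
    out = ROOT / "results" / "overlays"

    interactors = tag_binary_interactors(hc, read_interactions(ann / "interactions.tsv"),
                                         ANCHOR.accession)
    ks = read_kinase_substrate(ann / "kinase_substrate.tsv")
    upstream = identify_upstream_regulators(hc, ks, ANCHOR)
    substrates = identify_downstream_substrates(hc, ks, ANCHOR)
    enzymes = classify_enzyme_partners(hc, read_enzyme_classes(ann / "enzyme_class.tsv"),
                                       read_site_effects(ann / "site_effects.tsv"))
    biomarkers = read_biomarkers(ann / "biomarkers.tsv")

    def fmt(df):
        return ", ".join(f"{r.gene} {r.residue}{r.position}" for r in df.itertuples(index=False))

    pos_int = interactors[interactors["sign_class"] == "positive"]
    neg_int = interactors[interactors["sign_class"] == "negative"]
    print(f"binary interactors: {interactors['accession'].nunique()} proteins, "
          f"{len(pos_int)} positively and {len(neg_int)} negatively co-modulated sites")
    print(f"  negative interactor site(s): {fmt(neg_int)}")
    print(f"upstream regulators of {ANCHOR.label}: {fmt(upstream)}")
    print(f"candidate downstream substrates: {fmt(substrates)}")
    kin = enzymes[enzymes["enzyme_class"] == "kinase"]
    pho = enzymes[enzymes["enzyme_class"] == "phosphatase"]
    print(f"kinase partners: {kin['accession'].nunique()} "
          f"({int((kin['sign_class'] == 'positive').sum())} positive sites); "
          f"phosphatase partners: {pho['accession'].nunique()}")
    both = enzymes[enzymes["site_effect"] == "both"]
    print(f"  sites with dual activity effect: {fmt(both)}")
    for sign in ("positive", "negative"):
        ov = biomarker_overlap(hc, biomarkers, sign)
        for disease, grp in ov.groupby("disease"):
            print(f"biomarker overlap ({sign}, {disease}): {fmt(grp)}")

    edges = []
    anchor_node = ANCHOR.label.replace(" ", "_")
    for df, rel in ((interactors, "interacts"), (substrates, "phosphorylates")):
        for r in df.itertuples(index=False):
            edges.append((anchor_node, rel, f"{r.gene}_{r.residue}{r.position}"))
    for r in upstream.itertuples(index=False):
        edges.append((f"{r.gene}_{r.residue}{r.position}", "phosphorylates", anchor_node))

    for name, df in (("interactors", interactors), ("upstream", upstream),
                     ("substrates", substrates), ("enzymes", enzymes)):
        write_table(df, out / f"{name}.tsv")
    write_sif(edges, out / "network.sif")
    print(f"overlay tables and network.sif written to {out}")


if __name__ == "__main__":
    main()
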