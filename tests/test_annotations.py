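"""Annotation overlays: pure joins over the high-confidence result rows."""

import pandas as pd
import pytest

from comodnet.annotations import (biomarker_overlap, classify_enzyme_partners,
                                  identify_downstream_substrates,
                                  identify_upstream_regulators,
                                  read_biomarkers, read_enzyme_classes,
                                  read_interactions, read_kinase_substrate,
                                  read_site_effects, tag_binary_interactors)
from comodnet.comodulation import run_comodulation
from comodnet.corpus import SiteKey

ANCHOR = SiteKey("P07947", "YES1", "Y", 426)


@pytest.fixture(scope="module")
def results(demo):
    """Co-modulation table of the deterministic demonstration corpus: 50
    perfectly concordant and 10 perfectly discordant partners."""
    return run_comodulation(demo, ANCHOR).table


@pytest.fixture(scope="module")
def tables(annotation_paths):
    return {
        "interactions": read_interactions(annotation_paths["interactions"]),
        "ks": read_kinase_substrate(annotation_paths["kinase_substrate"]),
        "enzymes": read_enzyme_classes(annotation_paths["enzyme_class"]),
        "effects": read_site_effects(annotation_paths["site_effects"]),
        "biomarkers": read_biomarkers(annotation_paths["biomarkers"]),
    }


def _site_set(df):
    return {(r.accession, r.residue, int(r.position)) for r in df.itertuples(index=False)}


class TestBinaryInteractors:
    def test_empty_interaction_table_empty_subset(self, results):
        empty = pd.DataFrame(columns=["anchor_accession", "partner_accession",
                                      "source", "evidence"])
        assert len(tag_binary_interactors(results, empty, ANCHOR.accession)) == 0

    def test_negatively_comodulated_interactor_tagged(self, results, tables):
        tagged = tag_binary_interactors(results, tables["interactions"], ANCHOR.accession)
        erbb2 = tagged[(tagged["gene"] == "ERBB2") & (tagged["position"] == 1054)]
        assert len(erbb2) == 1
        assert erbb2.iloc[0]["sign_class"] == "negative"

    def test_multi_site_interactor_fully_tagged(self, results, tables):
        tagged = tag_binary_interactors(results, tables["interactions"], ANCHOR.accession)
        lyn_sites = tagged[tagged["gene"] == "LYN"]
        assert {(r, p) for r, p in lyn_sites[["residue", "position"]].itertuples(index=False)} \
            == {("Y", 397), ("S", 11), ("T", 398)}

    def test_unordered_pair_semantics(self, results):
        reversed_rec = pd.DataFrame([{"anchor_accession": "P04626",
                                      "partner_accession": ANCHOR.accession,
                                      "source": "x", "evidence": "binary"}])
        tagged = tag_binary_interactors(results, reversed_rec, ANCHOR.accession)
        assert set(tagged["gene"]) == {"ERBB2"}

    def test_only_high_confidence_rows_tagged(self, results, tables):
        weakened = results.copy()
        weakened.loc[weakened["gene"] == "ERBB2", "high_confidence"] = False
        tagged = tag_binary_interactors(weakened, tables["interactions"], ANCHOR.accession)
        assert "ERBB2" not in set(tagged["gene"])


class TestUpstreamDownstream:
    def test_upstream_regulator_site_specific_join(self, results, tables):
        upstream = identify_upstream_regulators(results, tables["ks"], ANCHOR)
        genes = set(upstream["gene"])
        assert {"LCK", "LYN", "ERBB2"} <= genes
        lck = upstream[upstream["gene"] == "LCK"].iloc[0]
        assert (lck["residue"], lck["position"]) == ("Y", 394)
        assert lck["sign_class"] == "positive"
        assert "screen" in lck["evidence_class"]
        # MAPK3 targets a different anchor-protein site (S40), never Y426
        assert "MAPK3" not in genes

    def test_no_record_for_anchor_site_empty(self, results, tables):
        other_anchor = SiteKey("P07947", "YES1", "T", 427)
        assert len(identify_upstream_regulators(results, tables["ks"], other_anchor)) == 0

    def test_downstream_substrates_site_specific(self, results, tables):
        subs = identify_downstream_substrates(results, tables["ks"], ANCHOR)
        assert ("P07948", "Y", 397) in _site_set(subs)     # LYN Y397
        assert ("P06239", "Y", 394) in _site_set(subs)     # LCK Y394
        # LYN S11 is high-confidence but not an annotated substrate site
        assert ("P07948", "S", 11) not in _site_set(subs)

    def test_empty_results_empty(self, results, tables):
        empty = results.iloc[0:0]
        assert len(identify_downstream_substrates(empty, tables["ks"], ANCHOR)) == 0


class TestEnzymePartition:
    def test_partition_and_site_effects(self, results, tables):
        enz = classify_enzyme_partners(results, tables["enzymes"], tables["effects"])
        by_site = enz.set_index(["gene", "residue", "position"])
        assert by_site.loc[("PNKP", "S", 114)]["enzyme_class"] == "phosphatase"
        assert by_site.loc[("PNKP", "S", 114)]["site_effect"] == "both"
        assert by_site.loc[("LYN", "Y", 397)]["site_effect"] == "induces"
        assert by_site.loc[("MAPK3", "T", 207)]["site_effect"] == "inhibits"
        # annotated kinase, unannotated site
        assert by_site.loc[("LYN", "S", 11)]["enzyme_class"] == "kinase"
        assert by_site.loc[("LYN", "S", 11)]["site_effect"] == "unknown"
        # partner absent from the enzyme table
        assert by_site.loc[("YBX1", "S", 209)]["enzyme_class"] == "none"

    def test_phosphatase_counts_by_sign(self, results, tables):
        enz = classify_enzyme_partners(results, tables["enzymes"], tables["effects"])
        pos_ph = enz[(enz["enzyme_class"] == "phosphatase") & (enz["sign_class"] == "positive")]
        neg_ph = enz[(enz["enzyme_class"] == "phosphatase") & (enz["sign_class"] == "negative")]
        assert set(pos_ph["gene"]) == {"PGAM1", "MTMR12", "PPM1G", "PTPN12", "PNKP"}
        assert set(neg_ph["gene"]) == {"LPIN2"}


class TestBiomarkers:
    def test_breast_cancer_site_resolved_overlap(self, results, tables):
        overlap = biomarker_overlap(results, tables["biomarkers"], "positive")
        breast = overlap[overlap["disease"] == "breast_cancer"]
        assert {("YBX1", "S", 209), ("CRK", "S", 41)} <= {
            (r.gene, r.residue, int(r.position)) for r in breast.itertuples(index=False)}
        # ERBB2 is a breast-cancer biomarker but negatively co-modulated
        assert "ERBB2" not in set(breast["gene"])

    def test_case_folded_gene_match(self, results, tables):
        bm = tables["biomarkers"].copy()
        bm["gene"] = bm["gene"].str.lower()
        overlap = biomarker_overlap(results, bm, "positive")
        assert "YBX1" in set(overlap["gene"])

    def test_disjoint_gene_sets_empty(self, results):
        bm = pd.DataFrame([{"disease": "x", "gene": "NOSUCHGENE", "source": "s"}])
        assert len(biomarker_overlap(results, bm, "positive")) == 0


class TestOverlayContracts:
    def test_outputs_are_row_subsets_without_mutation(self, results, tables):
        for overlay in (
            tag_binary_interactors(results, tables["interactions"], ANCHOR.accession),
            identify_upstream_regulators(results, tables["ks"], ANCHOR),
            identify_downstream_substrates(results, tables["ks"], ANCHOR),
            biomarker_overlap(results, tables["biomarkers"], "positive"),
        ):
            assert _site_set(overlay) <= _site_set(results)
            merged = overlay.merge(results, on=["accession", "residue", "position"],
                                   suffixes=("", "_orig"))
            for col in ("p_positive", "ratio_positive", "n_cc"):
                assert (merged[col] == merged[f"{col}_orig"]).all()

    def test_annotation_row_order_irrelevant(self, results, tables):
        shuffled = tables["ks"].iloc[::-1].reset_index(drop=True)
        a = identify_upstream_regulators(results, tables["ks"], ANCHOR)
        b = identify_upstream_regulators(results, shuffled, ANCHOR)
        pd.testing.assert_frame_equal(a, b)
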