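"""Annotation overlays: interactors, kinase-substrate links, enzymes, biomarkers.

All operations here are pure filters/joins over the high-confidence rows of a
co-modulation table: they never alter counts, p-values or ratios, and their
outputs are row subsets of the input (with added annotation columns).

Annotation tables are TSVs:

* ``interactions.tsv``    — anchor_accession, partner_accession, source, evidence
  (unordered pair semantics: either column may hold the anchor)
* ``kinase_substrate.tsv``— kinase_accession, substrate_accession,
  substrate_residue, substrate_position, evidence_class, source
* ``enzyme_class.tsv``    — accession, gene, enzyme_class (kinase/phosphatase/none)
* ``site_effects.tsv``    — accession, residue, position, effect
  (induces/inhibits/both/unknown; effect of phosphorylation at that site on
  the protein's own enzymatic activity)
* ``biomarkers.tsv``      — disease, gene, source

Gene-symbol matching is case-folded exact match; accession matching is exact.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .corpus import SiteKey
from .cooccurrence import POSITIVE

EVIDENCE_CLASSES = {"experimental", "predicted", "screen"}
ENZYME_CLASSES = {"kinase", "phosphatase", "none"}
SITE_EFFECTS = {"induces", "inhibits", "both", "unknown"}


def _read(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def read_interactions(path: str | Path) -> pd.DataFrame:
    return _read(path, ["anchor_accession", "partner_accession", "source", "evidence"])


def read_kinase_substrate(path: str | Path) -> pd.DataFrame:
    df = _read(path, ["kinase_accession", "substrate_accession",
                      "substrate_residue", "substrate_position", "evidence_class", "source"])
    df["substrate_position"] = df["substrate_position"].astype(int)
    bad = set(df["evidence_class"]) - EVIDENCE_CLASSES
    if bad:
        raise ValueError(f"{path}: unknown evidence_class {sorted(bad)}")
    return df


def read_enzyme_classes(path: str | Path) -> pd.DataFrame:
    df = _read(path, ["accession", "gene", "enzyme_class"])
    bad = set(df["enzyme_class"]) - ENZYME_CLASSES
    if bad:
        raise ValueError(f"{path}: unknown enzyme_class {sorted(bad)}")
    return df


def read_site_effects(path: str | Path) -> pd.DataFrame:
    df = _read(path, ["accession", "residue", "position", "effect"])
    df["position"] = df["position"].astype(int)
    bad = set(df["effect"]) - SITE_EFFECTS
    if bad:
        raise ValueError(f"{path}: unknown effect {sorted(bad)}")
    return df


def read_biomarkers(path: str | Path) -> pd.DataFrame:
    return _read(path, ["disease", "gene", "source"])


def _hc(results: pd.DataFrame) -> pd.DataFrame:
    if "high_confidence" in results.columns:
        return results[results["high_confidence"].astype(bool)]
    return results


def tag_binary_interactors(results: pd.DataFrame, interactions: pd.DataFrame,
                           anchor_accession: str) -> pd.DataFrame:
    """High-confidence partners that are direct interactors of the anchor protein.

    Pair records are unordered: a row qualifies if it links the anchor's
    accession with the partner's in either orientation.  All sites of a
    tagged interactor are kept (coordinated multi-site modulation), grouped
    by accession.
    """
    hc = _hc(results)
    fwd = interactions[interactions["anchor_accession"] == anchor_accession]["partner_accession"]
    rev = interactions[interactions["partner_accession"] == anchor_accession]["anchor_accession"]
    partners = set(fwd) | set(rev)
    tagged = hc[hc["accession"].isin(partners)].copy()
    return tagged.sort_values(["accession", "position"]).reset_index(drop=True)


def identify_upstream_regulators(results: pd.DataFrame, ks_records: pd.DataFrame,
                                 anchor: SiteKey) -> pd.DataFrame:
    """High-confidence partners annotated as kinases of the anchor *site*.

    The join is site-specific: the kinase-substrate record must target the
    anchor protein at exactly the anchor's residue and position (kinase-of-
    the-protein alone does not qualify).  ``evidence_class``/``source`` of the
    matching records are propagated (joined with ``;`` when several agree).
    """
    hc = _hc(results)
    hits = ks_records[
        (ks_records["substrate_accession"] == anchor.accession)
        & (ks_records["substrate_residue"] == anchor.residue)
        & (ks_records["substrate_position"] == int(anchor.position))
    ]
    evidence = (hits.groupby("kinase_accession")
                    .agg(evidence_class=("evidence_class", lambda s: ";".join(sorted(set(s)))),
                         evidence_source=("source", lambda s: ";".join(sorted(set(s)))))
                    .reset_index())
    tagged = hc.merge(evidence, left_on="accession", right_on="kinase_accession")
    return (tagged.drop(columns="kinase_accession")
                  .sort_values(["accession", "position"]).reset_index(drop=True))


def identify_downstream_substrates(results: pd.DataFrame, ks_records: pd.DataFrame,
                                   anchor: SiteKey) -> pd.DataFrame:
    """High-confidence partner sites annotated as substrates of the anchor kinase.

    Site-specific in the other direction: the partner's own (accession,
    residue, position) must appear as the substrate site of a record whose
    kinase is the anchor protein.
    """
    hc = _hc(results)
    hits = ks_records[ks_records["kinase_accession"] == anchor.accession]
    evidence = (hits.groupby(["substrate_accession", "substrate_residue", "substrate_position"])
                    .agg(evidence_class=("evidence_class", lambda s: ";".join(sorted(set(s)))),
                         evidence_source=("source", lambda s: ";".join(sorted(set(s)))))
                    .reset_index())
    tagged = hc.merge(
        evidence,
        left_on=["accession", "residue", "position"],
        right_on=["substrate_accession", "substrate_residue", "substrate_position"],
    )
    return (tagged.drop(columns=["substrate_accession", "substrate_residue", "substrate_position"])
                  .sort_values(["accession", "position"]).reset_index(drop=True))


def classify_enzyme_partners(results: pd.DataFrame, enzyme_classes: pd.DataFrame,
                             site_effects: pd.DataFrame | None = None) -> pd.DataFrame:
    """Partition high-confidence partners by enzyme class, with site effects.

    Partners absent from the enzyme table get class ``none``.  When a
    site-effect table is given, each partner site annotated there carries its
    effect (induces/inhibits/both); annotated enzymes with unannotated sites
    get ``unknown``.
    """
    hc = _hc(results).copy()
    cls = enzyme_classes.set_index("accession")["enzyme_class"]
    hc["enzyme_class"] = hc["accession"].map(cls).fillna("none")
    hc["site_effect"] = "unknown"
    if site_effects is not None and len(site_effects):
        eff = site_effects.set_index(["accession", "residue", "position"])["effect"]
        idx = pd.MultiIndex.from_frame(hc[["accession", "residue", "position"]])
        mapped = pd.Series(eff.reindex(idx).to_numpy(), index=hc.index)
        hc["site_effect"] = mapped.fillna("unknown")
    hc.loc[hc["enzyme_class"] == "none", "site_effect"] = "unknown"
    return hc.sort_values(["enzyme_class", "accession", "position"]).reset_index(drop=True)


def biomarker_overlap(results: pd.DataFrame, biomarkers: pd.DataFrame,
                      sign: str = POSITIVE) -> pd.DataFrame:
    """Per-disease intersection of biomarker genes with one sign's partners.

    Gene symbols are matched case-insensitively; the partner's specific
    phosphosites are retained so the overlap is site-resolved.  Diseases with
    no shared gene contribute no rows.
    """
    hc = _hc(results)
    hc = hc[hc["sign_class"] == sign].copy()
    hc["_gene_cf"] = hc["gene"].str.casefold()
    bm = biomarkers.copy()
    bm["_gene_cf"] = bm["gene"].str.casefold()
    merged = hc.merge(bm[["disease", "_gene_cf", "source"]], on="_gene_cf")
    merged = merged.drop(columns="_gene_cf").rename(columns={"source": "biomarker_source"})
    return merged.sort_values(["disease", "gene", "position"]).reset_index(drop=True)
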