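"""End-to-end run: filter → predominance → co-occurrence → co-modulation → overlays.

``run_pipeline`` composes the module operations exactly as one would by hand
(the integration contract: pipeline output equals manual composition with
the same configuration) and writes every stage's table plus a
machine-readable manifest (software version, configuration echo, input
checksums, stage record counts).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotations import (biomarker_overlap, classify_enzyme_partners,
                          identify_downstream_substrates,
                          identify_upstream_regulators, read_biomarkers,
                          read_enzyme_classes, read_interactions,
                          read_kinase_substrate, read_site_effects,
                          tag_binary_interactors)
from .comodulation import (ComodConfig, ComodulationResult, run_comodulation)
from .cooccurrence import NEGATIVE, POSITIVE, cooccurrence_matrix
from .corpus import Corpus, SiteKey, read_corpus, validate_corpus, write_sif, write_table
from .predominance import rank_predominance, site_frequencies
from .qc import FilterThresholds

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``anchor_site`` is a compact site spec such as ``"Y426"``; when omitted
    the top predominance-ranked site of ``protein`` is selected
    automatically.  ``seed`` is recorded in the manifest for provenance; the
    core pipeline itself is deterministic.
    """

    differential_path: str
    out_dir: str
    protein: str
    profile_path: str | None = None
    anchor_site: str | None = None
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    comod: ComodConfig = field(default_factory=ComodConfig)
    annotations_dir: str | None = None
    condition_subsets: list[list[str]] = field(default_factory=list)
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        thr = FilterThresholds(**raw.pop("thresholds", {}))
        com = ComodConfig(**raw.pop("comod", {}))
        return cls(thresholds=thr, comod=com, **raw)


def _parse_site(spec: str) -> tuple[str, int]:
    residue, pos = spec[0].upper(), spec[1:]
    return residue, int(pos)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _select_anchor(corpus: Corpus, config: RunConfig) -> SiteKey:
    freqs = site_frequencies(corpus, config.protein, config.thresholds)
    if not len(freqs):
        raise ValueError(f"protein {config.protein!r} not present in corpus")
    ranked = rank_predominance(freqs)
    if config.anchor_site:
        residue, position = _parse_site(config.anchor_site)
        match = ranked[(ranked["residue"] == residue) & (ranked["position"] == position)]
        if not len(match):
            raise ValueError(
                f"anchor site {config.anchor_site} not found on {config.protein}")
        row = match.iloc[0]
    else:
        row = ranked.iloc[0]
    return SiteKey(row["accession"], row["gene"], row["residue"], int(row["position"]))


def _comod_edges(result: ComodulationResult):
    anchor = result.anchor.label.replace(" ", "_")
    for row in result.high_confidence.itertuples(index=False):
        partner = f"{row.gene or row.accession}_{row.residue}{row.position}"
        yield anchor, f"comod_{row.sign_class}", partner


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest dictionary.

    Outputs (TSV/SIF/JSON) land in ``config.out_dir``.  Deterministic for
    fixed inputs and configuration; raises on missing anchors or malformed
    inputs (the CLI maps exception types to distinct exit codes).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out_dir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("comodnet")
    root.addHandler(log_handler)
    try:
        corpus = read_corpus(config.profile_path, config.differential_path)
        report = validate_corpus(corpus)
        logger.info("corpus: %d datasets (%d profile / %d differential), %d sites",
                    report.n_datasets, report.n_profile_datasets,
                    report.n_differential_datasets, report.n_sites)

        ranked = rank_predominance(site_frequencies(corpus, config.protein, config.thresholds))
        write_table(ranked, out_dir / "predominance.tsv")
        anchor = _select_anchor(corpus, config)
        logger.info("anchor site: %s", anchor.label)

        matrix = cooccurrence_matrix(corpus, config.protein, config.thresholds)
        write_table(matrix, out_dir / "cooccurrence.tsv")

        result = run_comodulation(corpus, anchor, config.thresholds, config.comod)
        write_table(result.table, out_dir / "comodulation.tsv")
        logger.info("co-modulation: %d partners, %d high-confidence (cutoff %.3g)",
                    len(result.table), len(result.high_confidence), result.cutoff)

        edges = list(_comod_edges(result))
        overlay_counts: dict[str, int] = {}
        if config.annotations_dir:
            ann = Path(config.annotations_dir)
            hc = result.table
            interactors = tag_binary_interactors(
                hc, read_interactions(ann / "interactions.tsv"), anchor.accession)
            ks = read_kinase_substrate(ann / "kinase_substrate.tsv")
            upstream = identify_upstream_regulators(hc, ks, anchor)
            substrates = identify_downstream_substrates(hc, ks, anchor)
            enzymes = classify_enzyme_partners(
                hc, read_enzyme_classes(ann / "enzyme_class.tsv"),
                read_site_effects(ann / "site_effects.tsv"))
            biomarkers = read_biomarkers(ann / "biomarkers.tsv")
            bm_pos = biomarker_overlap(hc, biomarkers, POSITIVE)
            bm_neg = biomarker_overlap(hc, biomarkers, NEGATIVE)
            for name, df in [("interactors", interactors), ("upstream", upstream),
                             ("substrates", substrates), ("enzymes", enzymes)]:
                write_table(df, out_dir / f"{name}.tsv")
                overlay_counts[name] = len(df)
            import pandas as pd
            bm = pd.concat([bm_pos.assign(overlap_sign=POSITIVE),
                            bm_neg.assign(overlap_sign=NEGATIVE)], ignore_index=True)
            write_table(bm, out_dir / "biomarker_overlap.tsv")
            overlay_counts["biomarker_overlap"] = len(bm)
            anchor_node = anchor.label.replace(" ", "_")
            for row in interactors.itertuples(index=False):
                edges.append((anchor_node, "interacts",
                              f"{row.gene or row.accession}_{row.residue}{row.position}"))
            for row in upstream.itertuples(index=False):
                edges.append((f"{row.gene or row.accession}_{row.residue}{row.position}",
                              "phosphorylates", anchor_node))
            for row in substrates.itertuples(index=False):
                edges.append((anchor_node, "phosphorylates",
                              f"{row.gene or row.accession}_{row.residue}{row.position}"))
        write_sif(edges, out_dir / "network.sif")

        if config.condition_subsets:
            from .comodulation import condition_set_overlap
            overlap = condition_set_overlap(result, corpus, config.condition_subsets,
                                            config.thresholds)
            write_table(overlap, out_dir / "condition_overlap.tsv")

        checksums = {}
        for p in (config.profile_path, config.differential_path):
            if p:
                checksums[str(p)] = _sha256(p)

        manifest = {
            "software": {"name": "comodnet", "version": __version__},
            "config": {
                "protein": config.protein,
                "anchor_site": config.anchor_site,
                "thresholds": dataclasses.asdict(config.thresholds),
                "comod": dataclasses.asdict(config.comod),
                "seed": config.seed,
            },
            "inputs": checksums,
            "anchor": {"accession": anchor.accession, "gene": anchor.gene,
                       "residue": anchor.residue, "position": anchor.position},
            "n_anchor_datasets": result.n_anchor_datasets,
            "cutoff": result.cutoff,
            "counts": {
                "datasets": report.n_datasets,
                "differential_datasets": report.n_differential_datasets,
                "profile_datasets": report.n_profile_datasets,
                "sites": report.n_sites,
                "partners_tested": len(result.table),
                "high_confidence": int(result.table["high_confidence"].sum()) if len(result.table) else 0,
                "high_confidence_positive": int(((result.table["sign_class"] == POSITIVE)
                                                 & result.table["high_confidence"]).sum()) if len(result.table) else 0,
                "high_confidence_negative": int(((result.table["sign_class"] == NEGATIVE)
                                                 & result.table["high_confidence"]).sum()) if len(result.table) else 0,
                **overlay_counts,
            },
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8")
        return manifest
    finally:
        root.removeHandler(log_handler)
        log_handler.close()
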