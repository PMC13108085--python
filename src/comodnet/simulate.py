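"""Seeded synthetic phosphoproteomic corpora with a machine-readable truth record.

The generator emulates the structure the analysis assumes: many small
datasets, each covering a random subset of sites; an anchor site carrying
direction calls in a controlled number of differential datasets; partner
sites whose direction matches the anchor's with a tunable concordance;
independent background sites; and missingness (sites simply absent from most
datasets).  Directions are drawn first and the measurement values (fold
change, p-value, localization probability, A-score) are then sampled
*conditionally on the drawn direction*, so that every emitted row classifies
back to its planted direction under the default thresholds — boundary noise
is deliberately excluded because the tests target the analysis, not the
thresholds.

What it does **not** emulate: raw spectra, peptide-level evidence, realistic
intensity distributions, or inter-dataset batch structure.

A small fully deterministic :func:`demo_corpus` (no randomness at all) is
also provided for the annotation-overlay demonstrations, where named partner
sites must be perfectly concordant or discordant with the anchor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import (Corpus, SiteKey, write_differential_table,
                     write_profile_table, write_table)
from .cooccurrence import POSITIVE, NEGATIVE
from .qc import INCREASED, DECREASED, NOT_CALLABLE

ANCHOR = SiteKey("P07947", "YES1", "Y", 426)

#: experimental-condition vocabulary used by the default fixture
CONDITION_CODES = ["metformin", "il-33", "caffeine", "egf", "her2", "serum"]


@dataclass(frozen=True)
class PlantedPartner:
    """A partner site with controlled concordance to the anchor.

    ``concordance`` is the probability that, in a dataset where both the
    partner and the anchor are callable, the partner's direction equals the
    anchor's.  ``coobservation_probability`` is the chance the partner is
    observed (and callable) in any given differential dataset.
    """

    site: SiteKey
    concordance: float = 0.9
    coobservation_probability: float = 0.7
    profile_probability: float = 0.4

    @property
    def planted_sign(self) -> str:
        if self.concordance > 0.5:
            return POSITIVE
        if self.concordance < 0.5:
            return NEGATIVE
        return "none"


@dataclass
class GeneratorConfig:
    """Full description of one synthetic corpus.

    The anchor is callable in exactly ``round(anchor_callable_fraction *
    n_differential_datasets)`` datasets (an exact count, so fixtures hit
    their stated anchor frequency deterministically), with direction
    Bernoulli(``anchor_up_probability``).  Fold changes for callable rows are
    the threshold times a log-space exponential excess, p-values are uniform
    below the significance bound, and localization probabilities are uniform
    on [0.75, 1].
    """

    n_differential_datasets: int = 90
    n_profile_datasets: int = 40
    anchor: SiteKey = ANCHOR
    anchor_callable_fraction: float = 0.8
    anchor_up_probability: float = 0.5
    anchor_profile_probability: float = 0.85
    planted_partners: list[PlantedPartner] = field(default_factory=list)
    anchor_siblings: list[PlantedPartner] = field(default_factory=list)
    n_background_sites: int = 500
    background_observation_probability: float = 0.3
    background_not_callable_fraction: float = 0.2
    background_profile_probability: float = 0.15
    n_studies: int = 5
    n_conditions: int = 6
    fc_log_scale: float = 0.4
    p_callable_max: float = 0.049
    seed: int = 17

    def __post_init__(self) -> None:
        for name in ("anchor_callable_fraction", "anchor_up_probability",
                     "anchor_profile_probability", "background_observation_probability",
                     "background_not_callable_fraction", "background_profile_probability"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_differential_datasets < 1 or self.n_studies < 1 or self.n_conditions < 1:
            raise ValueError("dataset/study/condition counts must be positive")
        seen = {(self.anchor.accession, self.anchor.residue, self.anchor.position)}
        for p in self.planted_partners + self.anchor_siblings:
            key = (p.site.accession, p.site.residue, p.site.position)
            if key in seen:
                raise ValueError(f"planted site {p.site} duplicates the anchor or another plant")
            seen.add(key)
            if not (0 <= p.concordance <= 1 and 0 <= p.coobservation_probability <= 1):
                raise ValueError(f"probabilities out of range for {p.site}")


@dataclass
class TruthRecord:
    """Ground truth of one generated corpus, recomputable from the files."""

    anchor: str
    anchor_directions: dict[str, str]                 # dataset_id -> direction
    site_directions: dict[str, dict[str, str]]        # site -> dataset_id -> direction
    expected_pair_counts: dict[str, list[int]]        # site -> [n_cc, n_cd, n_dc, n_dd]
    planted_sign: dict[str, str]                      # planted partner site -> sign
    n_anchor_callable: int

    def to_json(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = asdict(self)
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


def _site_str(site: SiteKey) -> str:
    return f"{site.accession}:{site.residue}{site.position}"


def _values(rng: np.random.Generator, direction: str, cfg: GeneratorConfig):
    """Sample (fold_change, p_value, loc_prob, a_score) consistent with a direction."""
    loc_prob = rng.uniform(0.75, 1.0)
    a_score = rng.uniform(13.0, 40.0) if rng.random() < 0.7 else np.nan
    if direction == INCREASED:
        fc = 1.3 * float(np.exp(rng.exponential(cfg.fc_log_scale)))
        p = rng.uniform(1e-5, cfg.p_callable_max)
    elif direction == DECREASED:
        fc = 0.76 * float(np.exp(-rng.exponential(cfg.fc_log_scale)))
        p = rng.uniform(1e-5, cfg.p_callable_max)
    else:  # not callable: Class-1 but neutral fold change
        fc = rng.uniform(0.80, 1.25)
        p = rng.uniform(0.0, 1.0)
    return round(fc, 6), round(p, 6), round(loc_prob, 4), (np.nan if np.isnan(a_score) else round(a_score, 2))


def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, TruthRecord]:
    """Generate a corpus and its truth record; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    n_diff = config.n_differential_datasets

    diff_meta = pd.DataFrame({
        "dataset_id": [f"d{i + 1:03d}" for i in range(n_diff)],
        "study_id": [f"PMID{1000 + i % config.n_studies}" for i in range(n_diff)],
        "condition_code": [CONDITION_CODES[i % config.n_conditions]
                           if config.n_conditions <= len(CONDITION_CODES)
                           else f"cond{i % config.n_conditions + 1:02d}"
                           for i in range(n_diff)],
        "kind": "differential",
        "enrichment": [("STY", "ST", "Y")[i % 3] for i in range(n_diff)],
    })
    prof_meta = pd.DataFrame({
        "dataset_id": [f"p{i + 1:03d}" for i in range(config.n_profile_datasets)],
        "study_id": [f"PMID{2000 + i % config.n_studies}" for i in range(config.n_profile_datasets)],
        "condition_code": [CONDITION_CODES[i % config.n_conditions]
                           if config.n_conditions <= len(CONDITION_CODES)
                           else f"cond{i % config.n_conditions + 1:02d}"
                           for i in range(config.n_profile_datasets)],
        "kind": "profile",
        "enrichment": [("STY", "ST", "Y")[i % 3] for i in range(config.n_profile_datasets)],
    })
    diff_ids = diff_meta["dataset_id"].tolist()
    prof_ids = prof_meta["dataset_id"].tolist()

    # anchor: exact callable count, random subset of datasets
    n_callable = int(round(config.anchor_callable_fraction * n_diff))
    callable_ids = sorted(rng.choice(diff_ids, size=n_callable, replace=False).tolist())
    anchor_dir = {ds: (INCREASED if rng.random() < config.anchor_up_probability else DECREASED)
                  for ds in callable_ids}

    diff_rows: list[dict] = []
    site_directions: dict[str, dict[str, str]] = {}
    expected_counts: dict[str, list[int]] = {}
    planted_sign: dict[str, str] = {}

    def emit(ds: str, site: SiteKey, direction: str) -> None:
        fc, p, lp, asc = _values(rng, direction, config)
        diff_rows.append({
            "dataset_id": ds, "accession": site.accession, "gene": site.gene,
            "residue": site.residue, "position": site.position,
            "loc_prob": lp, "a_score": asc, "fold_change": fc, "p_value": p,
        })

    for ds in callable_ids:
        emit(ds, config.anchor, anchor_dir[ds])

    def plant(partner: PlantedPartner, record_sign: bool) -> None:
        key = _site_str(partner.site)
        dirs: dict[str, str] = {}
        counts = [0, 0, 0, 0]  # n_cc, n_cd, n_dc, n_dd
        for ds in diff_ids:
            if rng.random() >= partner.coobservation_probability:
                continue
            if ds in anchor_dir:
                a_dir = anchor_dir[ds]
                concordant = rng.random() < partner.concordance
                direction = a_dir if concordant else (DECREASED if a_dir == INCREASED else INCREASED)
                a_up = a_dir == INCREASED
                p_up = direction == INCREASED
                idx = 0 if (a_up and p_up) else 1 if (a_up and not p_up) \
                    else 2 if (not a_up and p_up) else 3
                counts[idx] += 1
            else:
                direction = INCREASED if rng.random() < 0.5 else DECREASED
            dirs[ds] = direction
            emit(ds, partner.site, direction)
        site_directions[key] = dirs
        expected_counts[key] = counts
        if record_sign:
            planted_sign[key] = partner.planted_sign

    for partner in config.planted_partners:
        plant(partner, record_sign=True)
    for sibling in config.anchor_siblings:
        plant(sibling, record_sign=False)

    residues = np.array(["S", "T", "Y"])
    background_sites: list[SiteKey] = []
    for j in range(config.n_background_sites):
        site = SiteKey(f"B{j + 1:05d}", f"BG{j + 1}", str(rng.choice(residues)),
                       int(rng.integers(1, 2000)))
        background_sites.append(site)
        key = _site_str(site)
        dirs = {}
        for ds in diff_ids:
            if rng.random() >= config.background_observation_probability:
                continue
            if rng.random() < config.background_not_callable_fraction:
                direction = NOT_CALLABLE
            else:
                direction = INCREASED if rng.random() < 0.5 else DECREASED
            dirs[ds] = direction
            emit(ds, site, direction)
        site_directions[key] = dirs

    # profile observations: qualitative detections with Class-1 confidence
    prof_rows: list[dict] = []

    def emit_profile(site: SiteKey, prob: float) -> None:
        for ds in prof_ids:
            if rng.random() < prob:
                lp = round(rng.uniform(0.75, 1.0), 4)
                asc = round(rng.uniform(13.0, 40.0), 2) if rng.random() < 0.7 else np.nan
                prof_rows.append({"dataset_id": ds, "accession": site.accession,
                                  "gene": site.gene, "residue": site.residue,
                                  "position": site.position, "loc_prob": lp, "a_score": asc})

    emit_profile(config.anchor, config.anchor_profile_probability)
    for sibling in config.anchor_siblings:
        emit_profile(sibling.site, sibling.profile_probability)
    for partner in config.planted_partners:
        emit_profile(partner.site, partner.profile_probability)
    for site in background_sites:
        if rng.random() < config.background_profile_probability:
            emit_profile(site, 0.3)

    diff_cols = ["dataset_id", "accession", "gene", "residue", "position",
                 "loc_prob", "a_score", "fold_change", "p_value"]
    prof_cols = diff_cols[:-2]
    corpus = Corpus(
        datasets=pd.concat([prof_meta, diff_meta], ignore_index=True),
        profile_obs=pd.DataFrame(prof_rows, columns=prof_cols),
        differential_obs=pd.DataFrame(diff_rows, columns=diff_cols),
    )
    truth = TruthRecord(
        anchor=_site_str(config.anchor),
        anchor_directions=anchor_dir,
        site_directions=site_directions,
        expected_pair_counts=expected_counts,
        planted_sign=planted_sign,
        n_anchor_callable=n_callable,
    )
    return corpus, truth


# ---------------------------------------------------------------------------
# default fixture: the documented study conditions
# ---------------------------------------------------------------------------

_POSITIVE_PARTNERS: list[tuple[str, str, str, int]] = [
    ("P06239", "LCK", "Y", 394), ("P07948", "LYN", "Y", 397),
    ("P07948", "LYN", "S", 11), ("P07948", "LYN", "T", 398),
    ("P67809", "YBX1", "S", 209), ("P46108", "CRK", "S", 41),
    ("Q96T60", "PNKP", "S", 114), ("P18669", "PGAM1", "S", 14),
    ("Q9C0I1", "MTMR12", "S", 564), ("O15355", "PPM1G", "S", 183),
    ("Q05209", "PTPN12", "S", 435), ("P15056", "BRAF", "S", 729),
    ("P27361", "MAPK3", "T", 207), ("Q13131", "PRKAA1", "S", 496),
    ("P35269", "GTF2F1", "S", 385), ("Q05655", "PRKCD", "S", 645),
    ("P26651", "ZFP36", "S", 60), ("Q92934", "BAD", "S", 99),
    ("P49736", "MCM2", "S", 108), ("Q13263", "TRIM28", "S", 501),
    ("Q13263", "TRIM28", "S", 683), ("Q13435", "SF3B2", "S", 861),
    ("Q13435", "SF3B2", "T", 780), ("P15311", "EZR", "S", 535),
    ("Q9UHB6", "LIMA1", "S", 686), ("P17987", "TCP1", "S", 544),
    ("P55196", "AFDN", "S", 216), ("O15042", "U2SURP", "S", 485),
    ("P22681", "CBL", "S", 669), ("P04792", "HSPB1", "S", 199),
    ("Q4G0J3", "LARP7", "T", 257), ("P40227", "CCT6A", "S", 205),
    ("Q96I25", "RBM17", "T", 71), ("P02794", "FTH1", "S", 179),
    ("P17302", "GJA1", "S", 296), ("Q13480", "GAB1", "S", 266),
    ("Q13177", "PAK2", "S", 197), ("Q9UPQ0", "LIMCH1", "S", 493),
    ("Q13443", "ADAM9", "Y", 769), ("Q9NWQ8", "PAG1", "Y", 227),
    ("P68104", "EEF1A1", "Y", 141), ("P10398", "ARAF", "Y", 155),
    ("P52799", "EFNB2", "Y", 304), ("Q6NZI2", "CAVIN1", "Y", 308),
    ("O43684", "BUB3", "S", 211), ("O94885", "SASH1", "S", 407),
    ("Q9UPN4", "CEP131", "S", 78), ("Q05086", "UBE3A", "S", 218),
    ("Q9UQ84", "EXO1", "S", 714), ("P21796", "VDAC1", "S", 104),
]

_NEGATIVE_PARTNERS: list[tuple[str, str, str, int]] = [
    ("P04626", "ERBB2", "S", 1054), ("Q9H792", "PEAK1", "T", 1151),
    ("Q96GX5", "MASTL", "S", 370), ("Q86YV5", "PRAG1", "S", 712),
    ("O00750", "PIK3C2B", "S", 155), ("Q13233", "MAP3K1", "S", 1157),
    ("Q92539", "LPIN2", "S", 106), ("P06400", "RB1", "S", 811),
    ("P07737", "PFN1", "Y", 129), ("P19105", "MYL12A", "S", 19),
]

#: anchor-protein sibling sites: (site, profile_prob, coobs_prob, concordance)
_SIBLINGS = [
    (("P07947", "YES1", "S", 40), 0.98, 0.15, 0.6),
    (("P07947", "YES1", "Y", 194), 0.90, 0.10, 0.5),
    (("P07947", "YES1", "T", 427), 0.50, 0.50, 0.9),
    (("P07947", "YES1", "S", 111), 0.40, 0.45, 0.85),
    (("P07947", "YES1", "S", 195), 0.35, 0.40, 0.85),
    (("P07947", "YES1", "S", 197), 0.30, 0.10, 0.5),
]


def default_generator_config(seed: int = 17) -> GeneratorConfig:
    """The documented default fixture: 72 anchor-callable differential
    datasets (0.8 of 90), 5 studies, 6 condition codes, 50 planted positive
    partners at concordance 0.9, 10 planted negative partners at concordance
    0.1, 500 independent background sites, 40 profile datasets."""
    positives = [PlantedPartner(SiteKey(a, g, r, p), concordance=0.9,
                                coobservation_probability=0.7)
                 for a, g, r, p in _POSITIVE_PARTNERS]
    negatives = [PlantedPartner(SiteKey(a, g, r, p), concordance=0.1,
                                coobservation_probability=0.7)
                 for a, g, r, p in _NEGATIVE_PARTNERS]
    siblings = [PlantedPartner(SiteKey(*s), concordance=conc,
                               coobservation_probability=coobs,
                               profile_probability=prof)
                for s, prof, coobs, conc in _SIBLINGS]
    return GeneratorConfig(planted_partners=positives + negatives,
                           anchor_siblings=siblings, seed=seed)


def write_annotation_fixtures(out_dir: str | Path) -> dict[str, Path]:
    """Write the curated annotation tables used by the overlay analyses.

    These are synthetic stand-ins assembled for the fixture corpus: small
    hand-curated tables mirroring the kind of content a practitioner would
    export from interaction, kinase-substrate, enzyme-classification and
    disease-biomarker databases for one anchor kinase.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    anchor_acc = ANCHOR.accession

    interactor_genes = ["LIMA1", "LYN", "TCP1", "AFDN", "SF3B2", "EZR", "TRIM28",
                        "U2SURP", "CBL", "HSPB1", "LARP7", "CCT6A", "RBM17", "FTH1",
                        "GJA1", "GAB1", "LCK", "PAK2", "LIMCH1", "ERBB2"]
    acc_by_gene = {g: a for a, g, _, _ in _POSITIVE_PARTNERS + _NEGATIVE_PARTNERS}
    interactions = pd.DataFrame([
        {"anchor_accession": anchor_acc, "partner_accession": acc_by_gene[g],
         "source": "biogrid" if i % 2 == 0 else "hprd", "evidence": "binary"}
        for i, g in enumerate(interactor_genes)
    ])

    ks = pd.DataFrame([
        # kinases acting on the anchor site (upstream regulators)
        {"kinase_accession": "P06239", "substrate_accession": anchor_acc,
         "substrate_residue": "Y", "substrate_position": 426,
         "evidence_class": "screen", "source": "synthetic-peptide-screen"},
        {"kinase_accession": "P06239", "substrate_accession": anchor_acc,
         "substrate_residue": "Y", "substrate_position": 426,
         "evidence_class": "predicted", "source": "networkin"},
        {"kinase_accession": "P07948", "substrate_accession": anchor_acc,
         "substrate_residue": "Y", "substrate_position": 426,
         "evidence_class": "predicted", "source": "networkin"},
        {"kinase_accession": "P04626", "substrate_accession": anchor_acc,
         "substrate_residue": "Y", "substrate_position": 426,
         "evidence_class": "predicted", "source": "networkin"},
        # a record on a *different* anchor-protein site: must never match Y426
        {"kinase_accession": "P27361", "substrate_accession": anchor_acc,
         "substrate_residue": "S", "substrate_position": 40,
         "evidence_class": "predicted", "source": "networkin"},
        # anchor kinase acting on partner sites (candidate downstream substrates)
        *[{"kinase_accession": anchor_acc, "substrate_accession": acc,
           "substrate_residue": res, "substrate_position": pos,
           "evidence_class": "predicted", "source": "networkin"}
          for acc, res, pos in [("P06239", "Y", 394), ("Q13443", "Y", 769),
                                ("P07948", "Y", 397), ("Q9NWQ8", "Y", 227),
                                ("P68104", "Y", 141), ("P10398", "Y", 155),
                                ("P52799", "Y", 304), ("Q6NZI2", "Y", 308)]],
    ])

    enzyme_rows = [
        ("P06239", "LCK", "kinase"), ("P07948", "LYN", "kinase"),
        ("P15056", "BRAF", "kinase"), ("P27361", "MAPK3", "kinase"),
        ("Q13131", "PRKAA1", "kinase"), ("P35269", "GTF2F1", "kinase"),
        ("Q05655", "PRKCD", "kinase"), ("Q13177", "PAK2", "kinase"),
        ("P10398", "ARAF", "kinase"), ("P04626", "ERBB2", "kinase"),
        ("Q9H792", "PEAK1", "kinase"), ("Q96GX5", "MASTL", "kinase"),
        ("Q13233", "MAP3K1", "kinase"),
        ("P18669", "PGAM1", "phosphatase"), ("Q9C0I1", "MTMR12", "phosphatase"),
        ("O15355", "PPM1G", "phosphatase"), ("Q05209", "PTPN12", "phosphatase"),
        ("Q96T60", "PNKP", "phosphatase"), ("Q92539", "LPIN2", "phosphatase"),
    ]
    enzymes = pd.DataFrame(enzyme_rows, columns=["accession", "gene", "enzyme_class"])

    effects = pd.DataFrame([
        ("P06239", "Y", 394, "induces"), ("P07948", "Y", 397, "induces"),
        ("P15056", "S", 729, "induces"), ("P27361", "T", 207, "inhibits"),
        ("Q13131", "S", 496, "inhibits"), ("P35269", "S", 385, "inhibits"),
        ("Q96T60", "S", 114, "both"),
    ], columns=["accession", "residue", "position", "effect"])

    biomarkers = pd.DataFrame([
        ("breast_cancer", "YBX1"), ("breast_cancer", "CRK"), ("breast_cancer", "ERBB2"),
        ("leukemia", "LYN"), ("leukemia", "PRKCD"), ("leukemia", "ZFP36"),
        ("colorectal_cancer", "BRAF"), ("colorectal_cancer", "EXO1"),
        ("lung_cancer", "VDAC1"), ("lung_cancer", "MAPK3"),
        ("melanoma", "BRAF"),
    ], columns=["disease", "gene"]).assign(source="disgenet")

    paths = {}
    for name, df in [("interactions", interactions), ("kinase_substrate", ks),
                     ("enzyme_class", enzymes), ("site_effects", effects),
                     ("biomarkers", biomarkers)]:
        path = out_dir / f"{name}.tsv"
        write_table(df, path)
        paths[name] = path
    return paths


def write_default_fixture(out_dir: str | Path, seed: int = 17
                          ) -> tuple[dict[str, Path], TruthRecord, GeneratorConfig]:
    """Emit the documented fixture bundle: corpus TSVs, truth JSON, annotations."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = default_generator_config(seed=seed)
    corpus, truth = generate_corpus(config)
    paths = {
        "profiling": out_dir / "profiling.tsv",
        "differential": out_dir / "differential.tsv",
        "truth": out_dir / "truth.json",
    }
    write_profile_table(corpus, paths["profiling"])
    write_differential_table(corpus, paths["differential"])
    truth.to_json(paths["truth"])
    paths.update(write_annotation_fixtures(out_dir / "annotations"))
    return paths, truth, config


# ---------------------------------------------------------------------------
# deterministic demonstration corpus (no randomness)
# ---------------------------------------------------------------------------

def demo_corpus() -> Corpus:
    """Small fully deterministic corpus for the annotation-overlay demos.

    Twelve differential datasets over four studies and five condition codes;
    the anchor is callable in all twelve (seven increased, five decreased).
    Every planted positive partner matches the anchor's direction in every
    dataset and every negative partner opposes it, so each partner's
    classification is exact: positives tally (7,0,0,5) with one-sided
    concordant p = 1/C(12,7) ≈ 0.00126 and ratio +inf; negatives mirror it.
    """
    n = 12
    ids = [f"ds{i + 1:02d}" for i in range(n)]
    meta = pd.DataFrame({
        "dataset_id": ids,
        "study_id": [f"PMID{9000 + i % 4}" for i in range(n)],
        "condition_code": [CONDITION_CODES[i % 5] for i in range(n)],
        "kind": "differential",
        "enrichment": "STY",
    })
    anchor_up = [True] * 7 + [False] * 5

    rows = []

    def emit(ds: str, acc: str, gene: str, res: str, pos: int, up: bool) -> None:
        rows.append({
            "dataset_id": ds, "accession": acc, "gene": gene, "residue": res,
            "position": pos, "loc_prob": 0.95, "a_score": 20.0,
            "fold_change": 2.0 if up else 0.5, "p_value": 0.01,
        })

    for ds, up in zip(ids, anchor_up):
        emit(ds, ANCHOR.accession, ANCHOR.gene, ANCHOR.residue, ANCHOR.position, up)
        for acc, gene, res, pos in _POSITIVE_PARTNERS:
            emit(ds, acc, gene, res, pos, up)
        for acc, gene, res, pos in _NEGATIVE_PARTNERS:
            emit(ds, acc, gene, res, pos, not up)

    cols = ["dataset_id", "accession", "gene", "residue", "position",
            "loc_prob", "a_score", "fold_change", "p_value"]
    return Corpus(datasets=meta,
                  profile_obs=pd.DataFrame(columns=cols[:-2]),
                  differential_obs=pd.DataFrame(rows, columns=cols))
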