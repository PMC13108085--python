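"""Anchor-site co-modulation analysis across other proteins' phosphosites.

Given an anchor phosphosite (e.g. the predominant activation-loop site of a
kinase), every phosphosite on *other* proteins (PsOP) that is ever callable
in the same differential dataset as the anchor is tabulated into the four
direction-concordance cells (ItIo, ItDo, DtIo, DtDo), tested with one-sided
Fisher's exact tests in both orientations, and summarized by the
co-modulation ratio.  A partner is *high-confidence* when

1. its concordant (or discordant) one-sided exact test has p < alpha,
2. the corresponding ratio strictly exceeds ``cutoff_fraction`` times the
   number of datasets in which the anchor carries a direction call (the
   field's 10%-of-anchor-dataset-count rule; note this compares a
   dimensionless ratio against a fraction of a count — implemented literally
   as stated), and
3. it is supported by at least ``min_studies`` distinct studies and
   ``min_conditions`` distinct experimental conditions (redundancy filter
   against multi-time-point or replicated-condition over-representation).

Benjamini–Hochberg q-values are emitted per tail family as an auxiliary
column only; classification uses raw p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .corpus import Corpus, SiteKey
from .cooccurrence import (PairCounts, cooccur_ratio, tally_pair,
                           POSITIVE, NEGATIVE)
from .qc import (FilterThresholds, INCREASED, callable_mask, direction_matrix,
                 site_directions)

SIGN_NONE = "none"

CONCORDANT = "concordant"
DISCORDANT = "discordant"


class AnchorNotFoundError(ValueError):
    """The requested anchor site is absent (or never callable) in the corpus."""


@dataclass(frozen=True)
class ComodConfig:
    """Significance and filtering settings; defaults are the standard ones."""

    alpha: float = 0.05
    cutoff_fraction: float = 0.10
    min_studies: int = 3
    min_conditions: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if not (0 < self.cutoff_fraction <= 1):
            raise ValueError("cutoff_fraction must be in (0, 1]")
        if self.min_studies < 1 or self.min_conditions < 1:
            raise ValueError("min_studies/min_conditions must be >= 1")


def fisher_one_sided(counts: PairCounts, alternative: str) -> float:
    """One-sided exact test on the 2x2 anchor-direction x partner-direction table.

    Rows are (anchor increased, anchor decreased), columns (partner
    increased, partner decreased).  ``concordant`` tests enrichment of the
    (I,I) cell given the margins (upper hypergeometric tail, equivalent to
    Fisher's exact test with the greater alternative); ``discordant`` tests
    the lower tail.  Any zero margin gives p = 1.
    """
    a, b, c, d = counts
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if alternative not in (CONCORDANT, DISCORDANT):
        raise ValueError(f"alternative must be concordant/discordant, got {alternative!r}")
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        return 1.0
    if alternative == CONCORDANT:
        return float(hypergeom.sf(a - 1, n, row1, col1))
    # discordant tail == upper tail of the (I,D) cell given the same margins
    # (P[X_II <= a] = P[X_ID >= b]); computing both tails as upper tails keeps
    # tiny p-values accurate and makes the partner-label-flip swap bit-exact
    return float(hypergeom.sf(b - 1, n, row1, n - col1))


def comod_ratio(counts: PairCounts, sign: str) -> float:
    """Co-modulation ratio; identical semantics to the intra-protein ratio."""
    return cooccur_ratio(counts, sign)


def high_confidence_cutoff(n_anchor_datasets: int, cutoff_fraction: float = 0.10) -> float:
    """Ratio cutoff: ``cutoff_fraction`` x anchor's callable-dataset count.

    E.g. an anchor with direction calls in 72 differential datasets and the
    default 10% fraction yields 7.2; the downstream comparison is strict
    (the ratio must *exceed* the cutoff).
    """
    if n_anchor_datasets < 1:
        raise ValueError("n_anchor_datasets must be >= 1")
    if cutoff_fraction <= 0:
        raise ValueError("cutoff_fraction must be positive")
    return cutoff_fraction * n_anchor_datasets


def categorize_partner(anchor: SiteKey, partner: SiteKey,
                       directions: pd.DataFrame) -> PairCounts:
    """ItIo/ItDo/DtIo/DtDo tallies with the anchor as first member.

    Partners on the anchor's own protein are rejected; intra-protein pairs
    belong to the co-occurrence analysis.
    """
    if partner.accession == anchor.accession:
        raise ValueError("partner is on the anchor protein; use the co-occurrence analysis")
    a_rows = site_directions(directions, anchor.accession, anchor.residue, anchor.position)
    p_rows = site_directions(directions, partner.accession, partner.residue, partner.position)
    return tally_pair(a_rows, p_rows)


def redundancy_support(partner: SiteKey, anchor: SiteKey,
                       directions: pd.DataFrame) -> tuple[int, int]:
    """Distinct (studies, conditions) among datasets contributing to the tally.

    Every dataset in which both anchor and partner are callable contributes
    to exactly one cell, so the support is counted over the co-callable
    dataset set.
    """
    a_rows = site_directions(directions, anchor.accession, anchor.residue, anchor.position)
    p_rows = site_directions(directions, partner.accession, partner.residue, partner.position)
    shared = a_rows.merge(p_rows[["dataset_id"]], on="dataset_id")
    return int(shared["study_id"].nunique()), int(shared["condition_code"].nunique())


RESULT_COLUMNS = [
    "accession", "gene", "residue", "position",
    "n_cc", "n_cd", "n_dc", "n_dd",
    "p_positive", "p_negative", "bh_q_value",
    "ratio_positive", "ratio_negative",
    "sign_class", "n_studies", "n_conditions",
    "passes_redundancy", "high_confidence",
]


@dataclass
class ComodulationResult:
    """Output bundle of :func:`run_comodulation`.

    ``table`` has one row per partner site (columns :data:`RESULT_COLUMNS`);
    ``n_anchor_datasets`` is the anchor's callable-dataset count that sets
    the ratio ``cutoff``.
    """

    table: pd.DataFrame
    anchor: SiteKey
    n_anchor_datasets: int
    cutoff: float
    config: ComodConfig

    @property
    def high_confidence(self) -> pd.DataFrame:
        return self.table[self.table["high_confidence"]]

    def high_confidence_sites(self, sign: str | None = None) -> set[tuple[str, str, int]]:
        hc = self.high_confidence
        if sign is not None:
            hc = hc[hc["sign_class"] == sign]
        return {(r.accession, r.residue, int(r.position))
                for r in hc.itertuples(index=False)}


def _bh(p: np.ndarray) -> np.ndarray:
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def run_comodulation(corpus: Corpus, anchor: SiteKey,
                     thresholds: FilterThresholds = FilterThresholds(),
                     config: ComodConfig = ComodConfig()) -> ComodulationResult:
    """Full anchor-vs-all-PsOP co-modulation analysis.

    One result row per phosphosite on another protein that is callable in at
    least one dataset together with the anchor.  Deterministic given inputs.
    """
    directions = direction_matrix(corpus, thresholds)
    a_rows = site_directions(directions, anchor.accession, anchor.residue, anchor.position)
    if not len(a_rows):
        raise AnchorNotFoundError(
            f"anchor {anchor.label} has no callable differential dataset")
    n_anchor = int(a_rows["dataset_id"].nunique())
    cutoff = high_confidence_cutoff(n_anchor, config.cutoff_fraction)

    partners = directions[(directions["accession"] != anchor.accession)
                          & callable_mask(directions)]
    merged = partners.merge(
        a_rows[["dataset_id", "direction"]].rename(columns={"direction": "anchor_direction"}),
        on="dataset_id",
    )
    if not len(merged):
        empty = pd.DataFrame(columns=RESULT_COLUMNS)
        return ComodulationResult(empty, anchor, n_anchor, cutoff, config)

    anchor_up = merged["anchor_direction"] == INCREASED
    partner_up = merged["direction"] == INCREASED
    merged = merged.assign(
        _cc=(anchor_up & partner_up),
        _cd=(anchor_up & ~partner_up),
        _dc=(~anchor_up & partner_up),
        _dd=(~anchor_up & ~partner_up),
    )
    keys = ["accession", "gene", "residue", "position"]
    grouped = merged.groupby(keys, sort=True)
    counts = grouped[["_cc", "_cd", "_dc", "_dd"]].sum().astype(int)
    counts.columns = ["n_cc", "n_cd", "n_dc", "n_dd"]
    support = grouped.agg(n_studies=("study_id", "nunique"),
                          n_conditions=("condition_code", "nunique"))
    table = counts.join(support).reset_index()

    pair_list = [PairCounts(*row) for row in
                 table[["n_cc", "n_cd", "n_dc", "n_dd"]].itertuples(index=False)]
    table["p_positive"] = [fisher_one_sided(pc, CONCORDANT) for pc in pair_list]
    table["p_negative"] = [fisher_one_sided(pc, DISCORDANT) for pc in pair_list]
    table["ratio_positive"] = [comod_ratio(pc, POSITIVE) for pc in pair_list]
    table["ratio_negative"] = [comod_ratio(pc, NEGATIVE) for pc in pair_list]

    q_pos = _bh(table["p_positive"].to_numpy())
    q_neg = _bh(table["p_negative"].to_numpy())

    pos = table["p_positive"] < config.alpha
    neg = table["p_negative"] < config.alpha
    # one-sided tails of the same table satisfy p_pos + p_neg >= 1, so both
    # can never be below any alpha <= 0.5
    both = pos & neg
    if both.any():
        raise AssertionError("both one-sided tails significant — impossible table")
    table["sign_class"] = np.select([pos, neg], [POSITIVE, NEGATIVE], default=SIGN_NONE)
    table["bh_q_value"] = np.select([pos, neg], [q_pos, q_neg],
                                    default=np.minimum(q_pos, q_neg))

    table["passes_redundancy"] = ((table["n_studies"] >= config.min_studies)
                                  & (table["n_conditions"] >= config.min_conditions))
    signed_ratio = np.select(
        [table["sign_class"] == POSITIVE, table["sign_class"] == NEGATIVE],
        [table["ratio_positive"], table["ratio_negative"]],
        default=np.nan,
    )
    with np.errstate(invalid="ignore"):
        exceeds = signed_ratio > cutoff  # nan compares False; inf passes
    table["high_confidence"] = ((table["sign_class"] != SIGN_NONE)
                                & exceeds & table["passes_redundancy"])

    table = (table[RESULT_COLUMNS]
             .sort_values(["sign_class", "p_positive", "accession", "position"])
             .reset_index(drop=True))
    return ComodulationResult(table, anchor, n_anchor, cutoff, config)


def condition_set_overlap(result: ComodulationResult, corpus: Corpus,
                          subsets: list[list[str]],
                          thresholds: FilterThresholds = FilterThresholds()) -> pd.DataFrame:
    """High-confidence partners supported under every condition of a subset.

    A partner *supports* a condition code when at least one dataset with that
    (normalized) code contributes to its tally, i.e. both the partner and the
    anchor are callable there.  For each requested subset of codes the number
    of high-confidence partners supporting all of them is returned.
    """
    directions = direction_matrix(corpus, thresholds)
    known_codes = set(directions["condition_code"].unique())
    anchor = result.anchor
    a_rows = site_directions(directions, anchor.accession, anchor.residue, anchor.position)
    partners = directions[(directions["accession"] != anchor.accession)
                          & callable_mask(directions)]
    merged = partners.merge(a_rows[["dataset_id"]], on="dataset_id")
    support: dict[tuple[str, str, int], set[str]] = {}
    for row in merged.itertuples(index=False):
        support.setdefault((row.accession, row.residue, int(row.position)),
                           set()).add(row.condition_code)

    hc_sites = result.high_confidence_sites()
    records = []
    for subset in subsets:
        codes = {str(c).strip().casefold() for c in subset}
        unknown = codes - known_codes
        if unknown:
            raise ValueError(
                f"unknown condition code(s) {sorted(unknown)}; known: {sorted(known_codes)}")
        n = sum(1 for site in hc_sites if codes <= support.get(site, set()))
        records.append({"conditions": ";".join(sorted(codes)), "n_codes": len(codes),
                        "n_common_partners": n})
    return pd.DataFrame.from_records(
        records, columns=["conditions", "n_codes", "n_common_partners"])
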