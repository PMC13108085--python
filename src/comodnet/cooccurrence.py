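"""Intra-protein pairwise co-occurrence of direction calls.

For an ordered pair of sites (a, b) on the same protein, every differential
dataset in which *both* sites carry a direction call contributes to exactly
one of four cells: II (both increased), ID (a up, b down), DI, DD.  The
positive co-modulation ratio is (nII + nDD)/(nID + nDI) and the negative
ratio its reciprocal.

Zero denominators are kept distinguishable downstream: a ratio with zero
denominator but nonzero numerator is ``+inf`` (all-concordant — passes any
finite cutoff), while an all-zero table yields ``nan`` (no shared data —
never passes anything).
"""

from __future__ import annotations

import math
from itertools import permutations
from typing import NamedTuple

import numpy as np
import pandas as pd

from .corpus import Corpus
from .qc import FilterThresholds, INCREASED, DECREASED, callable_mask, direction_matrix

POSITIVE = "positive"
NEGATIVE = "negative"


class PairCounts(NamedTuple):
    """Four direction-concordance counts for an ordered site pair.

    ``n_cc``/``n_dd`` are the concordant cells (both increased / both
    decreased), ``n_cd``/``n_dc`` the discordant ones (first member's
    direction written first).  For an anchor/partner pair these are the
    ItIo, ItDo, DtIo, DtDo tallies.
    """

    n_cc: int
    n_cd: int
    n_dc: int
    n_dd: int

    @property
    def total(self) -> int:
        return self.n_cc + self.n_cd + self.n_dc + self.n_dd

    @property
    def concordant(self) -> int:
        return self.n_cc + self.n_dd

    @property
    def discordant(self) -> int:
        return self.n_cd + self.n_dc


def tally_pair(dirs_a: pd.DataFrame, dirs_b: pd.DataFrame) -> PairCounts:
    """Tally concordance over datasets where both sites are callable.

    Inputs are direction-matrix slices (one row per dataset) for the two
    sites; rows are joined on ``dataset_id``.
    """
    a = dirs_a[callable_mask(dirs_a)][["dataset_id", "direction"]]
    b = dirs_b[callable_mask(dirs_b)][["dataset_id", "direction"]]
    merged = a.merge(b, on="dataset_id", suffixes=("_a", "_b"))
    up_a = merged["direction_a"] == INCREASED
    up_b = merged["direction_b"] == INCREASED
    return PairCounts(
        n_cc=int((up_a & up_b).sum()),
        n_cd=int((up_a & ~up_b).sum()),
        n_dc=int((~up_a & up_b).sum()),
        n_dd=int((~up_a & ~up_b).sum()),
    )


def pair_counts(site_a: tuple[str, str, int], site_b: tuple[str, str, int],
                directions: pd.DataFrame) -> PairCounts:
    """Concordance counts for two sites given a direction matrix.

    Sites are (accession, residue, position) triples and must differ.
    """
    if site_a == site_b:
        raise ValueError("pair_counts requires two distinct sites")

    def rows(site):
        acc, res, pos = site
        return directions[(directions["accession"] == acc)
                          & (directions["residue"] == res)
                          & (directions["position"] == int(pos))]

    return tally_pair(rows(site_a), rows(site_b))


def cooccur_ratio(counts: PairCounts, sign: str) -> float:
    """Concordant/discordant count ratio (``positive``) or its reciprocal.

    Returns ``+inf`` when the denominator is zero with a nonzero numerator
    and ``nan`` when all four cells are zero.
    """
    if sign not in (POSITIVE, NEGATIVE):
        raise ValueError(f"sign must be positive/negative, got {sign!r}")
    num, den = counts.concordant, counts.discordant
    if sign == NEGATIVE:
        num, den = den, num
    if num == 0 and den == 0:
        return math.nan
    if den == 0:
        return math.inf
    return num / den


PAIR_COLUMNS = ["site_a", "site_b", "n_cc", "n_cd", "n_dc", "n_dd",
                "total", "pos_ratio", "neg_ratio"]


def cooccurrence_matrix(corpus: Corpus, protein: str,
                        thresholds: FilterThresholds = FilterThresholds()) -> pd.DataFrame:
    """All ordered site pairs of ``protein`` with counts and both ratios.

    Long format, one row per ordered pair; suitable for a heat-map layout
    with the positive ratio on one triangle and the negative on the other.
    A protein with fewer than two callable sites yields an empty frame.
    """
    dirs = direction_matrix(corpus, thresholds)
    dirs = dirs[(dirs["accession"] == protein) & callable_mask(dirs)]
    sites = sorted(
        {(r, int(p)) for r, p in dirs[["residue", "position"]].itertuples(index=False)},
        key=lambda rp: (rp[1], rp[0]),
    )
    by_site = {rp: grp for rp, grp in dirs.groupby(["residue", "position"])}
    records = []
    for (ra, pa), (rb, pb) in permutations(sites, 2):
        counts = tally_pair(by_site[(ra, pa)], by_site[(rb, pb)])
        records.append({
            "site_a": f"{ra}{pa}", "site_b": f"{rb}{pb}",
            "n_cc": counts.n_cc, "n_cd": counts.n_cd,
            "n_dc": counts.n_dc, "n_dd": counts.n_dd,
            "total": counts.total,
            "pos_ratio": cooccur_ratio(counts, POSITIVE),
            "neg_ratio": cooccur_ratio(counts, NEGATIVE),
        })
    if not records:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    return pd.DataFrame.from_records(records, columns=PAIR_COLUMNS)
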