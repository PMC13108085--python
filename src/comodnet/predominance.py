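"""Predominant-phosphosite ranking for one protein.

Each of a protein's phosphosites is scored by how often it is detected as a
Class-1 site across the profiling corpus and across the differential corpus
(distinct datasets, not rows).  A site that ranks highly on *both* lists is
"predominant"; we combine the two dense ranks by their product (rank product:
lower is better), which is scale-free across corpora of different sizes.

Two differential counts are emitted because detection and direction-calling
differ: ``differential_count`` is datasets reporting the site as Class-1 at
all, ``callable_count`` those where it additionally receives an
increased/decreased call.
"""

from __future__ import annotations

import pandas as pd

from .corpus import Corpus
from .qc import FilterThresholds, class1_mask, callable_mask, direction_matrix

FREQ_COLUMNS = ["accession", "gene", "residue", "position",
                "profile_count", "differential_count", "callable_count"]
RANK_COLUMNS = FREQ_COLUMNS + ["profile_rank", "differential_rank", "predominance_score"]


def _distinct_dataset_counts(obs: pd.DataFrame, name: str) -> pd.DataFrame:
    if not len(obs):
        return pd.DataFrame(columns=["accession", "gene", "residue", "position", name])
    counts = (obs.groupby(["accession", "gene", "residue", "position"], as_index=False)
                 ["dataset_id"].nunique().rename(columns={"dataset_id": name}))
    return counts


def site_frequencies(corpus: Corpus, protein: str,
                     thresholds: FilterThresholds = FilterThresholds()) -> pd.DataFrame:
    """Per-site detection counts for ``protein`` (unknown protein → empty)."""
    pobs = corpus.profile_obs
    if len(pobs):
        pobs = pobs[pobs["accession"] == protein]
        pobs = pobs[class1_mask(pobs, thresholds)]
    pcounts = _distinct_dataset_counts(pobs, "profile_count")

    dobs = corpus.differential_obs
    if len(dobs):
        dobs = dobs[dobs["accession"] == protein]
        dobs = dobs[class1_mask(dobs, thresholds)]
    dcounts = _distinct_dataset_counts(dobs, "differential_count")

    dirs = direction_matrix(corpus, thresholds)
    if len(dirs):
        dirs = dirs[(dirs["accession"] == protein) & callable_mask(dirs)]
    ccounts = _distinct_dataset_counts(dirs, "callable_count")

    keys = ["accession", "gene", "residue", "position"]
    freqs = pcounts.merge(dcounts, on=keys, how="outer").merge(ccounts, on=keys, how="outer")
    if not len(freqs):
        return pd.DataFrame(columns=FREQ_COLUMNS)
    for col in ("profile_count", "differential_count", "callable_count"):
        freqs[col] = pd.to_numeric(freqs[col], errors="coerce").fillna(0).astype(int)
    return freqs[FREQ_COLUMNS].sort_values(["position", "residue"]).reset_index(drop=True)


def rank_predominance(freqs: pd.DataFrame) -> pd.DataFrame:
    """Rank sites by the product of their two frequency ranks.

    Ranks are dense and 1-based, higher count → better (smaller) rank.  The
    output is sorted ascending by ``predominance_score`` with ties broken by
    larger ``differential_count`` and then by position; row 0 is the nominated
    predominant phosphosite.
    """
    if not len(freqs):
        raise ValueError("rank_predominance needs at least one site")
    out = freqs.copy()
    out["profile_rank"] = out["profile_count"].rank(method="dense", ascending=False).astype(int)
    out["differential_rank"] = out["differential_count"].rank(method="dense", ascending=False).astype(int)
    out["predominance_score"] = out["profile_rank"] * out["differential_rank"]
    out = out.sort_values(
        by=["predominance_score", "differential_count", "position", "residue"],
        ascending=[True, False, True, True],
    ).reset_index(drop=True)
    return out[RANK_COLUMNS]


def predominant_site(corpus: Corpus, protein: str,
                     thresholds: FilterThresholds = FilterThresholds()) -> pd.Series:
    """Convenience: the top-ranked site row for ``protein``."""
    freqs = site_frequencies(corpus, protein, thresholds)
    if not len(freqs):
        raise ValueError(f"protein {protein!r} not present in corpus")
    return rank_predominance(freqs).iloc[0]
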