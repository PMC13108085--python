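"""Shared builders for hand-crafted corpora used across the test modules."""

from __future__ import annotations

import pandas as pd

from comodnet.corpus import Corpus

# deterministic measurement values that classify to each direction under the
# default thresholds
VALUES = {
    "increased": {"fold_change": 2.0, "p_value": 0.01, "loc_prob": 0.9, "a_score": 20.0},
    "decreased": {"fold_change": 0.5, "p_value": 0.01, "loc_prob": 0.9, "a_score": 20.0},
    "not_callable": {"fold_change": 1.0, "p_value": 0.5, "loc_prob": 0.9, "a_score": 20.0},
}

DIFF_COLS = ["dataset_id", "accession", "gene", "residue", "position",
             "loc_prob", "a_score", "fold_change", "p_value"]


def make_corpus(site_dirs: dict[tuple[str, str, str, int], dict[str, str]],
                studies: dict[str, str] | None = None,
                conditions: dict[str, str] | None = None) -> Corpus:
    """Build a differential-only corpus from planned direction calls.

    ``site_dirs`` maps (accession, gene, residue, position) to a
    {dataset_id: direction} plan; measurement values are filled in
    deterministically so each row classifies exactly to its planned
    direction.  Studies/conditions default to one per dataset.
    """
    dataset_ids = sorted({ds for dirs in site_dirs.values() for ds in dirs})
    studies = studies or {ds: f"study_{ds}" for ds in dataset_ids}
    conditions = conditions or {ds: f"cond_{ds}" for ds in dataset_ids}
    meta = pd.DataFrame({
        "dataset_id": dataset_ids,
        "study_id": [studies[ds] for ds in dataset_ids],
        "condition_code": [conditions[ds] for ds in dataset_ids],
        "kind": "differential",
        "enrichment": "STY",
    })
    rows = []
    for (acc, gene, res, pos), dirs in site_dirs.items():
        for ds, direction in dirs.items():
            rows.append({"dataset_id": ds, "accession": acc, "gene": gene,
                         "residue": res, "position": pos, **VALUES[direction]})
    return Corpus(datasets=meta,
                  profile_obs=pd.DataFrame(columns=DIFF_COLS[:-2]),
                  differential_obs=pd.DataFrame(rows, columns=DIFF_COLS))


def flip_site_calls(corpus: Corpus, accessions: set[str] | None = None,
                    exclude: set[str] = frozenset()) -> Corpus:
    """Return a corpus whose callable rows for selected sites are inverted.

    Increased rows (fc >= 1.3) become decreased and vice versa by swapping in
    fixed values well clear of the thresholds, so call inversion is exact;
    not-callable rows are untouched.
    """
    obs = corpus.differential_obs.copy()
    mask = pd.Series(True, index=obs.index)
    if accessions is not None:
        mask &= obs["accession"].isin(accessions)
    if exclude:
        mask &= ~obs["accession"].isin(exclude)
    callable_ = (obs["p_value"] < 0.05) & ((obs["fold_change"] >= 1.3)
                                           | (obs["fold_change"] <= 0.76))
    up = mask & callable_ & (obs["fold_change"] >= 1.3)
    down = mask & callable_ & (obs["fold_change"] <= 0.76)
    obs.loc[up, "fold_change"] = 0.5
    obs.loc[down, "fold_change"] = 2.0
    return Corpus(datasets=corpus.datasets.copy(),
                  profile_obs=corpus.profile_obs.copy(),
                  differential_obs=obs)
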