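"""Site-level quality filters and the three-way abundance classification.

A differential observation yields a direction call only when the site's
peptide-level localization is confident (a *Class-1* site), the comparison is
significant, and the linear fold change crosses one of the two bounds:

* ``increased``   — Class-1, p < 0.05, fold change ≥ 1.3
* ``decreased``   — Class-1, p < 0.05, fold change ≤ 0.76
* ``not_callable``— everything else (including sites between the bounds)

Class-1 means localization probability ≥ 0.75 **or** A-score ≥ 13 (a missing
metric fails its own clause).  An AND combination is available by
configuration for stricter reading of mixed corpora.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus import Corpus

INCREASED = "increased"
DECREASED = "decreased"
NOT_CALLABLE = "not_callable"

#: direction-matrix column layout
DIRECTION_COLUMNS = ["dataset_id", "study_id", "condition_code", "accession",
                     "gene", "residue", "position", "direction"]


@dataclass(frozen=True)
class FilterThresholds:
    """Quality and significance thresholds, defaulting to the standard values.

    ``fc_up_min``/``fc_down_max`` are linear test/control fold-change bounds
    (no log transform is applied anywhere); ``class1_mode`` selects whether
    Class-1 status requires either ("or", the usual convention) or both
    ("and") localization metrics to pass.
    """

    loc_prob_min: float = 0.75
    a_score_min: float = 13.0
    p_max: float = 0.05
    fc_up_min: float = 1.3
    fc_down_max: float = 0.76
    class1_mode: str = "or"

    def __post_init__(self) -> None:
        if not (0 < self.fc_down_max < 1 < self.fc_up_min):
            raise ValueError("need 0 < fc_down_max < 1 < fc_up_min")
        if not (0 < self.p_max <= 1):
            raise ValueError("need 0 < p_max <= 1")
        if not (0 <= self.loc_prob_min <= 1):
            raise ValueError("loc_prob_min must be a probability")
        if self.class1_mode not in ("or", "and"):
            raise ValueError("class1_mode must be 'or' or 'and'")


def is_class1(loc_prob: float | None, a_score: float | None,
              thresholds: FilterThresholds = FilterThresholds()) -> bool:
    """Confident-localization test; missing metrics fail their own clause."""
    lp_ok = loc_prob is not None and not pd.isna(loc_prob) and loc_prob >= thresholds.loc_prob_min
    as_ok = a_score is not None and not pd.isna(a_score) and a_score >= thresholds.a_score_min
    return (lp_ok and as_ok) if thresholds.class1_mode == "and" else (lp_ok or as_ok)


def classify_abundance(fold_change: float, p_value: float,
                       loc_prob: float | None = None, a_score: float | None = None,
                       thresholds: FilterThresholds = FilterThresholds()) -> str:
    """Classify one differential observation into increased/decreased/not_callable."""
    if fold_change <= 0:
        raise ValueError("fold_change must be positive (linear ratio)")
    if not is_class1(loc_prob, a_score, thresholds) or not (p_value < thresholds.p_max):
        return NOT_CALLABLE
    if fold_change >= thresholds.fc_up_min:
        return INCREASED
    if fold_change <= thresholds.fc_down_max:
        return DECREASED
    return NOT_CALLABLE


def class1_mask(frame: pd.DataFrame, thresholds: FilterThresholds) -> pd.Series:
    """Vectorized Class-1 test over a frame with loc_prob / a_score columns."""
    lp = frame["loc_prob"].astype(float)
    asc = frame["a_score"].astype(float)
    lp_ok = lp.notna() & (lp >= thresholds.loc_prob_min)
    as_ok = asc.notna() & (asc >= thresholds.a_score_min)
    return (lp_ok & as_ok) if thresholds.class1_mode == "and" else (lp_ok | as_ok)


def classify_frame(frame: pd.DataFrame, thresholds: FilterThresholds) -> pd.Series:
    """Vectorized :func:`classify_abundance` over a differential frame."""
    c1 = class1_mask(frame, thresholds)
    sig = frame["p_value"].astype(float) < thresholds.p_max
    fc = frame["fold_change"].astype(float)
    out = pd.Series(NOT_CALLABLE, index=frame.index, dtype=object)
    out[c1 & sig & (fc >= thresholds.fc_up_min)] = INCREASED
    out[c1 & sig & (fc <= thresholds.fc_down_max)] = DECREASED
    return out


def direction_matrix(corpus: Corpus,
                     thresholds: FilterThresholds = FilterThresholds()) -> pd.DataFrame:
    """Direction call for every retained (dataset, site) differential pair.

    Returns a long-format frame (:data:`DIRECTION_COLUMNS`) carrying the
    dataset's study and condition labels so downstream redundancy filtering
    needs no further joins.  Deterministic given corpus and thresholds.
    """
    obs = corpus.differential_obs
    if not len(obs):
        return pd.DataFrame(columns=DIRECTION_COLUMNS)
    out = obs[["dataset_id", "accession", "gene", "residue", "position"]].copy()
    out["direction"] = classify_frame(obs, thresholds)
    meta = corpus.datasets.set_index("dataset_id")
    out["study_id"] = out["dataset_id"].map(meta["study_id"])
    out["condition_code"] = out["dataset_id"].map(meta["condition_code"])
    return out[DIRECTION_COLUMNS].reset_index(drop=True)


def callable_mask(directions: pd.DataFrame) -> pd.Series:
    return directions["direction"].isin([INCREASED, DECREASED])


def site_directions(directions: pd.DataFrame, accession: str, residue: str,
                    position: int, callable_only: bool = True) -> pd.DataFrame:
    """Rows of the direction matrix for one site (optionally callable only)."""
    rows = directions[(directions["accession"] == accession)
                      & (directions["residue"] == residue)
                      & (directions["position"] == int(position))]
    if callable_only:
        rows = rows[callable_mask(rows)]
    return rows
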