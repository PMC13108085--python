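"""Corpus data model and TSV I/O.

A *corpus* is a compilation of many small phosphoproteomic datasets, each of
which reports a subset of phosphosites.  Datasets come in two kinds:

* **profile** datasets — qualitative detection only (site seen or not, with a
  localization confidence), and
* **differential** datasets — a test condition compared against a control,
  yielding a linear fold change and a p-value per site.

Tables are tab-separated UTF-8 with a mandatory header row; a ``.`` or an
empty cell denotes a missing value.  Phosphosite identity is the triple
(protein accession, residue letter, 1-based position); the gene symbol is
carried for reporting but does not participate in identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_RESIDUES = frozenset({"S", "T", "Y"})
VALID_KINDS = frozenset({"profile", "differential"})
VALID_ENRICHMENTS = frozenset({"STY", "ST", "Y"})

#: canonical column order of the two corpus tables
PROFILE_COLUMNS = [
    "dataset_id", "study_id", "condition_code", "enrichment",
    "accession", "gene", "residue", "position", "loc_prob", "a_score",
]
DIFFERENTIAL_COLUMNS = PROFILE_COLUMNS + ["fold_change", "p_value"]

MISSING_TOKENS = {"", "."}


class CorpusError(Exception):
    """Base class for corpus I/O and validation failures."""


class TableFormatError(CorpusError):
    """A table is structurally malformed (missing columns, bad header)."""


class RowValidationError(CorpusError):
    """One or more rows violate a field invariant.

    ``rows`` holds 1-based data-row indices (header excluded) for error
    reporting back to the table's author.
    """

    def __init__(self, message: str, rows: list[int]):
        super().__init__(message)
        self.rows = rows


@dataclass(frozen=True)
class SiteKey:
    """Identity of one phosphosite.

    Equality and hashing use (accession, residue, position) only; ``gene`` is
    display metadata (HGNC-style symbol) and may differ between records that
    denote the same site.
    """

    accession: str
    gene: str = field(compare=False, default="")
    residue: str = "S"
    position: int = 1

    def __post_init__(self) -> None:
        if self.residue not in VALID_RESIDUES:
            raise ValueError(f"residue must be one of S/T/Y, got {self.residue!r}")
        if int(self.position) < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    @property
    def label(self) -> str:
        """Field-standard site notation, e.g. ``YES1 Y426``."""
        name = self.gene or self.accession
        return f"{name} {self.residue}{self.position}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.accession}:{self.residue}{self.position}"


@dataclass(frozen=True)
class DatasetMeta:
    dataset_id: str
    study_id: str
    condition_code: str
    kind: str
    enrichment: str = "STY"

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"kind must be profile/differential, got {self.kind!r}")
        if self.enrichment not in VALID_ENRICHMENTS:
            raise ValueError(f"enrichment must be STY/ST/Y, got {self.enrichment!r}")
        if not normalize_condition(self.condition_code):
            raise ValueError("condition_code empty after normalization")


def normalize_condition(code: str) -> str:
    """Normalize an experimental-condition label: trim + case-fold.

    Condition uniqueness (for the redundancy filter) is exact string match
    after this normalization.
    """
    return str(code).strip().casefold()


@dataclass
class Corpus:
    """In-memory corpus: dataset metadata plus long-format observation tables.

    ``datasets`` has one row per dataset (columns ``dataset_id, study_id,
    condition_code, kind, enrichment``); ``profile_obs`` and
    ``differential_obs`` are long-format site observation tables keyed by
    ``dataset_id`` and the site triple.
    """

    datasets: pd.DataFrame
    profile_obs: pd.DataFrame
    differential_obs: pd.DataFrame

    def site_key(self, row: Mapping) -> SiteKey:
        return SiteKey(row["accession"], row.get("gene", ""), row["residue"], int(row["position"]))

    @property
    def n_differential_datasets(self) -> int:
        return int((self.datasets["kind"] == "differential").sum())

    @property
    def n_profile_datasets(self) -> int:
        return int((self.datasets["kind"] == "profile").sum())


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _apply_dialect(df: pd.DataFrame, dialect: Mapping[str, str] | None) -> pd.DataFrame:
    """Rename file columns to canonical names; dialect maps canonical -> file."""
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    return df


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def _parse_numeric(df: pd.DataFrame, col: str, bad_rows: dict[str, list[int]]) -> pd.Series:
    raw = df[col].astype("string").str.strip()
    missing = raw.isna() | raw.isin(MISSING_TOKENS)
    parsed = pd.to_numeric(raw.where(~missing), errors="coerce")
    bad = (~missing) & parsed.isna()
    if bad.any():
        bad_rows.setdefault(col, []).extend((np.flatnonzero(bad.to_numpy()) + 1).tolist())
    return parsed.astype(float)


def _read_table(path: str | Path, columns: list[str], dialect: Mapping[str, str] | None,
                kind: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shared reader for the two corpus dialects.

    Returns ``(observations, datasets)``; raises on structural or row-level
    problems, naming the offending column and 1-based data-row indices.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype="string", keep_default_na=False)
    df = _apply_dialect(df, dialect)
    _require_columns(df, columns, path)
    df = df[columns].copy()
    if df.empty:
        obs_cols = [c for c in columns if c not in ("study_id", "condition_code", "enrichment")]
        return (pd.DataFrame(columns=obs_cols + ["loc_prob", "a_score"]).iloc[:, :0],
                pd.DataFrame(columns=["dataset_id", "study_id", "condition_code", "kind", "enrichment"]))

    bad: dict[str, list[int]] = {}

    df["residue"] = df["residue"].str.strip().str.upper()
    bad_res = ~df["residue"].isin(list(VALID_RESIDUES))
    if bad_res.any():
        bad["residue"] = (np.flatnonzero(bad_res.to_numpy()) + 1).tolist()

    pos = pd.to_numeric(df["position"].str.strip(), errors="coerce")
    bad_pos = pos.isna() | (pos < 1) | (pos != pos.round())
    if bad_pos.any():
        bad["position"] = (np.flatnonzero(bad_pos.to_numpy()) + 1).tolist()
    df["position"] = pos.fillna(-1).astype(int)

    df["loc_prob"] = _parse_numeric(df, "loc_prob", bad)
    out_of_range = (df["loc_prob"] < 0) | (df["loc_prob"] > 1)
    if out_of_range.any():
        bad.setdefault("loc_prob", []).extend((np.flatnonzero(out_of_range.to_numpy()) + 1).tolist())
    df["a_score"] = _parse_numeric(df, "a_score", bad)
    neg = df["a_score"] < 0
    if neg.any():
        bad.setdefault("a_score", []).extend((np.flatnonzero(neg.to_numpy()) + 1).tolist())

    if kind == "differential":
        for col in ("fold_change", "p_value"):
            vals = _parse_numeric(df, col, bad)
            missing = vals.isna()
            if missing.any():
                bad.setdefault(col, []).extend((np.flatnonzero(missing.to_numpy()) + 1).tolist())
            df[col] = vals
        bad_fc = df["fold_change"] <= 0
        if bad_fc.any():
            bad.setdefault("fold_change", []).extend((np.flatnonzero(bad_fc.to_numpy()) + 1).tolist())
        bad_p = (df["p_value"] < 0) | (df["p_value"] > 1)
        if bad_p.any():
            bad.setdefault("p_value", []).extend((np.flatnonzero(bad_p.to_numpy()) + 1).tolist())

    df["enrichment"] = df["enrichment"].str.strip().str.upper()
    bad_enr = ~df["enrichment"].isin(list(VALID_ENRICHMENTS))
    if bad_enr.any():
        bad["enrichment"] = (np.flatnonzero(bad_enr.to_numpy()) + 1).tolist()

    df["condition_code"] = df["condition_code"].map(normalize_condition)
    empty_cond = df["condition_code"] == ""
    if empty_cond.any():
        bad["condition_code"] = (np.flatnonzero(empty_cond.to_numpy()) + 1).tolist()

    if bad:
        rows = sorted({r for rr in bad.values() for r in rr})
        detail = "; ".join(f"{col}: rows {sorted(set(rr))}" for col, rr in sorted(bad.items()))
        raise RowValidationError(f"{path}: invalid values ({detail})", rows)

    datasets = (
        df[["dataset_id", "study_id", "condition_code", "enrichment"]]
        .drop_duplicates(subset="dataset_id")
        .assign(kind=kind)
        [["dataset_id", "study_id", "condition_code", "kind", "enrichment"]]
        .reset_index(drop=True)
    )
    obs_cols = ["dataset_id", "accession", "gene", "residue", "position", "loc_prob", "a_score"]
    if kind == "differential":
        obs_cols += ["fold_change", "p_value"]
    obs = df[obs_cols].copy()
    obs["gene"] = obs["gene"].astype(str)
    obs["accession"] = obs["accession"].astype(str)
    obs["dataset_id"] = obs["dataset_id"].astype(str)
    return obs, datasets


_SITE_COLS = ["dataset_id", "accession", "residue", "position"]


def _dedup_profile(obs: pd.DataFrame) -> pd.DataFrame:
    """Keep one row per (dataset, site): best loc_prob, then best a_score."""
    dup = obs.duplicated(subset=_SITE_COLS, keep=False)
    if dup.any():
        logger.warning("collapsing %d duplicate profile rows", int(dup.sum()))
        obs = (obs.sort_values(["loc_prob", "a_score"], ascending=False, na_position="last")
                  .drop_duplicates(subset=_SITE_COLS, keep="first"))
    return obs.reset_index(drop=True)


def _dedup_differential(obs: pd.DataFrame) -> pd.DataFrame:
    """Keep the smallest-p row per (dataset, site); drop on direction conflict.

    Duplicates whose classified directions (default thresholds) disagree are
    dropped from that dataset entirely — a conservative resolution, since the
    data offer no basis for picking one.
    """
    dup_mask = obs.duplicated(subset=_SITE_COLS, keep=False)
    if not dup_mask.any():
        return obs.reset_index(drop=True)
    from .qc import FilterThresholds, classify_frame  # local import: avoid cycle

    dups = obs[dup_mask].copy()
    dups["_dir"] = classify_frame(dups, FilterThresholds())
    conflict_keys = (
        dups[dups["_dir"] != "not_callable"]
        .groupby(_SITE_COLS)["_dir"].nunique()
        .pipe(lambda s: s[s > 1])
        .index
    )
    if len(conflict_keys):
        logger.warning("dropping %d (dataset, site) groups with conflicting duplicate directions",
                       len(conflict_keys))
    keep = (obs.sort_values("p_value", ascending=True)
               .drop_duplicates(subset=_SITE_COLS, keep="first"))
    idx = pd.MultiIndex.from_frame(keep[_SITE_COLS])
    keep = keep[~idx.isin(conflict_keys)]
    logger.warning("collapsed duplicate differential rows: %d -> %d", len(obs), len(keep))
    return keep.reset_index(drop=True)


def read_profile_table(path: str | Path, dialect: Mapping[str, str] | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a profiling TSV; returns ``(observations, dataset_meta)``."""
    obs, datasets = _read_table(path, PROFILE_COLUMNS, dialect, "profile")
    return _dedup_profile(obs) if len(obs) else obs, datasets


def read_differential_table(path: str | Path, dialect: Mapping[str, str] | None = None
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a differential TSV; returns ``(observations, dataset_meta)``."""
    obs, datasets = _read_table(path, DIFFERENTIAL_COLUMNS, dialect, "differential")
    return _dedup_differential(obs) if len(obs) else obs, datasets


def read_corpus(profile_path: str | Path | None, differential_path: str | Path | None,
                dialect: Mapping[str, str] | None = None) -> Corpus:
    """Assemble a :class:`Corpus` from one or both corpus tables."""
    frames, metas = [], []
    empty_meta = pd.DataFrame(columns=["dataset_id", "study_id", "condition_code", "kind", "enrichment"])
    if profile_path is not None:
        pobs, pmeta = read_profile_table(profile_path, dialect)
    else:
        pobs, pmeta = pd.DataFrame(columns=PROFILE_COLUMNS[:1]), empty_meta
    if differential_path is not None:
        dobs, dmeta = read_differential_table(differential_path, dialect)
    else:
        dobs, dmeta = pd.DataFrame(columns=DIFFERENTIAL_COLUMNS[:1]), empty_meta
    non_empty = [m for m in (pmeta, dmeta) if len(m)]
    datasets = (pd.concat(non_empty, ignore_index=True) if non_empty else empty_meta)
    return Corpus(datasets=datasets, profile_obs=pobs, differential_obs=dobs)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return "."
    if isinstance(v, float):
        if np.isinf(v):
            return "Inf" if v > 0 else "-Inf"
        if v == int(v) and abs(v) < 1e15:
            return str(int(v))
        return format(v, ".10g")
    return str(v)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any result table as TSV with ``.`` for missing, ``Inf`` markers."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in out.columns:
        out[col] = out[col].map(_fmt)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _meta_lookup(datasets: pd.DataFrame) -> pd.DataFrame:
    return datasets.set_index("dataset_id")


def write_profile_table(corpus: Corpus, path: str | Path) -> None:
    meta = _meta_lookup(corpus.datasets)
    obs = corpus.profile_obs.copy()
    for col in ("study_id", "condition_code", "enrichment"):
        obs[col] = obs["dataset_id"].map(meta[col])
    write_table(obs[PROFILE_COLUMNS], path)


def write_differential_table(corpus: Corpus, path: str | Path) -> None:
    meta = _meta_lookup(corpus.datasets)
    obs = corpus.differential_obs.copy()
    for col in ("study_id", "condition_code", "enrichment"):
        obs[col] = obs["dataset_id"].map(meta[col])
    write_table(obs[DIFFERENTIAL_COLUMNS], path)


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_table`.

    ``.`` becomes NaN and ``Inf`` the float infinity, so a write→read
    round-trip is the identity on the numeric content.
    """
    df = pd.read_csv(path, sep="\t", na_values=["."], keep_default_na=False)
    return df.replace({"Inf": np.inf, "-Inf": -np.inf})


def write_sif(edges: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Write a SIF edge list (``source<TAB>relation<TAB>target``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for source, relation, target in edges:
            fh.write(f"{source}\t{relation}\t{target}\n")


# ---------------------------------------------------------------------------
# validation report
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    n_datasets: int
    n_profile_datasets: int
    n_differential_datasets: int
    n_profile_obs: int
    n_differential_obs: int
    n_sites: int
    n_orphan_obs: int
    n_duplicate_obs: int

    @property
    def ok(self) -> bool:
        return self.n_orphan_obs == 0 and self.n_duplicate_obs == 0


def validate_corpus(corpus: Corpus) -> ValidationReport:
    """Side-effect-free consistency report: orphan references and duplicates."""
    known = set(corpus.datasets["dataset_id"]) if len(corpus.datasets) else set()
    orphans = dups = 0
    sites: set[tuple] = set()
    for obs in (corpus.profile_obs, corpus.differential_obs):
        if not len(obs) or "dataset_id" not in obs.columns:
            continue
        orphans += int((~obs["dataset_id"].isin(known)).sum())
        dups += int(obs.duplicated(subset=_SITE_COLS).sum())
        sites.update(map(tuple, obs[["accession", "residue", "position"]].itertuples(index=False)))
    return ValidationReport(
        n_datasets=len(corpus.datasets),
        n_profile_datasets=corpus.n_profile_datasets,
        n_differential_datasets=corpus.n_differential_datasets,
        n_profile_obs=len(corpus.profile_obs),
        n_differential_obs=len(corpus.differential_obs),
        n_sites=len(sites),
        n_orphan_obs=orphans,
        n_duplicate_obs=dups,
    )
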