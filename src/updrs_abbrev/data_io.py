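"""Reading assessment tables, completeness filtering, scoring, cohort comparison.

Assessments arrive as wide CSV, one row per (subject, visit), one column
per rating field, 0-4 integers, empty or ``NA`` for missing. A column map
translates source export codes (e.g. PPMI-style column names) onto the
registry's canonical rating-field names. Only assessments with every one
of the instrument's rating fields present enter the analysis; covariates
(Hoehn & Yahr stage, age, gender) may be missing without penalty.

Cohorts are compared on their total-score distributions with a two-sided
Mann-Whitney U test. Orientation convention: U counts pairs in which the
first table's total exceeds the second's (ties contribute one half), so
0 <= U <= n_a * n_b and identical samples give U = n_a * n_b / 2. The
p-value uses the tie-corrected normal approximation with continuity
correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .scale_model import ItemRegistry, ItemSet

__all__ = [
    "AssessmentTable",
    "ComparisonStats",
    "LoadError",
    "load_assessments",
    "write_assessments",
    "completeness_filter",
    "total_score",
    "subset_sum",
    "compare_datasets",
]

logger = logging.getLogger(__name__)

#: Optional per-assessment covariates recognised in input files.
COVARIATE_COLUMNS = ("hy_stage", "age", "gender")
KEY_COLUMNS = ("subject_id", "visit_id")

_MISSING_TOKENS = {"", "na", "nan", "none"}


class LoadError(ValueError):
    """Raised on malformed assessment input, with row/column context."""


@dataclass(frozen=True)
class AssessmentTable:
    """Per-visit ratings for one cohort, aligned to an item registry.

    ``df`` holds one row per assessment with columns ``subject_id``,
    ``visit_id``, every registry rating field (float, NaN = missing) and
    any covariates present.
    """

    df: pd.DataFrame
    registry: ItemRegistry
    provenance: str = "unlabelled"

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_records(self) -> int:
        return len(self.df)

    def rating_matrix(self) -> pd.DataFrame:
        """Just the rating-field columns, in registry order."""
        return self.df.loc[:, list(self.registry.rating_fields)]

    def is_complete(self) -> pd.Series:
        """Per-record indicator: every rating field present."""
        return self.rating_matrix().notna().all(axis=1)

    def item_scores(self) -> pd.DataFrame:
        """Per-record item scores: each item's rating fields summed.

        Undefined (NaN) for records missing any field of that item.
        """
        cols = {}
        for it in self.registry.items:
            block = self.df.loc[:, list(it.rating_fields)]
            cols[it.item_id] = block.sum(axis=1, skipna=False)
        return pd.DataFrame(cols, index=self.df.index)

    def total_scores(self) -> pd.Series:
        """Sum of all rating fields per record (NaN if incomplete)."""
        return self.rating_matrix().sum(axis=1, skipna=False)

    def subset_sums(self, subset: ItemSet) -> pd.Series:
        """Sum of the subset's rating fields per record."""
        fields = self.registry.rating_fields_of(subset)
        if not fields:
            return pd.Series(0.0, index=self.df.index)
        return self.df.loc[:, list(fields)].sum(axis=1, skipna=False)

    def records(self):
        """Iterate records as (index, row-mapping) pairs."""
        return self.df.iterrows()


@dataclass(frozen=True)
class ComparisonStats:
    """Two-cohort comparison: Mann-Whitney U on totals, plus medians."""

    u_statistic: float
    p_value: float
    median_total_a: float
    median_total_b: float
    n_a: int
    n_b: int
    median_hy_a: float | None = None
    median_hy_b: float | None = None


def _read_mapping(mapping: str | Path | Mapping[str, str] | None) -> dict[str, str]:
    if mapping is None:
        return {}
    if isinstance(mapping, Mapping):
        cfg = dict(mapping)
    else:
        with open(mapping, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh) or {}
    # accept either a flat {source: canonical} map or one nested under "columns"
    if "columns" in cfg and isinstance(cfg["columns"], Mapping):
        cfg = dict(cfg["columns"])
    return {str(k): str(v) for k, v in cfg.items()}


def _coerce_rating(value, row_label, column: str) -> float:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    text = str(value).strip()
    if text.lower() in _MISSING_TOKENS:
        return np.nan
    try:
        num = float(text)
    except ValueError:
        raise LoadError(
            f"row {row_label}, column {column!r}: non-numeric rating {value!r}"
        ) from None
    if num != int(num) or not (0 <= num <= 4):
        raise LoadError(
            f"row {row_label}, column {column!r}: rating {value!r} "
            "outside the integer range 0-4"
        )
    return float(int(num))


def load_assessments(
    path: str | Path,
    registry: ItemRegistry,
    mapping: str | Path | Mapping[str, str] | None = None,
    provenance: str | None = None,
    strict: bool = False,
) -> AssessmentTable:
    """Load a wide CSV of assessments against the registry.

    Parameters
    ----------
    path:
        CSV file, UTF-8, header row required, one row per assessment.
    mapping:
        Optional column map (dict, or YAML file of ``source: canonical``
        pairs, optionally nested under a ``columns:`` key) renaming source
        columns to registry rating fields or to the reserved names
        ``subject_id``/``visit_id``/``hy_stage``/``age``/``gender``.
    strict:
        If true, any column that is neither a key, a covariate nor a
        registry rating field after mapping is an error; otherwise such
        columns are dropped with a log message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.rename(columns=_read_mapping(mapping))

    known = set(KEY_COLUMNS) | set(COVARIATE_COLUMNS) | set(registry.rating_fields)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        if strict:
            raise LoadError(f"unknown columns after mapping: {unknown}")
        logger.info("dropping %d unrecognised columns: %s", len(unknown), unknown)
        df = df.drop(columns=unknown)

    for key in KEY_COLUMNS:
        if key not in df.columns:
            df[key] = [f"r{i}" for i in range(len(df))] if key == "subject_id" else "v1"

    dupes = df.duplicated(subset=list(KEY_COLUMNS))
    if dupes.any():
        first = df.loc[dupes, list(KEY_COLUMNS)].iloc[0]
        raise LoadError(
            f"duplicate (subject_id, visit_id) key: "
            f"({first['subject_id']!r}, {first['visit_id']!r})"
        )

    out = pd.DataFrame(index=df.index)
    for key in KEY_COLUMNS:
        out[key] = df[key].astype(str)
    for rf in registry.rating_fields:
        if rf in df.columns:
            col = df[rf]
            out[rf] = [
                _coerce_rating(v, lab, rf) for lab, v in zip(df.index + 2, col)
            ]
        else:
            out[rf] = np.nan
    for cov in COVARIATE_COLUMNS:
        if cov in df.columns:
            if cov == "gender":
                out[cov] = df[cov].replace("", pd.NA)
            else:
                out[cov] = pd.to_numeric(df[cov].replace("", np.nan), errors="coerce")

    table = AssessmentTable(
        df=out.reset_index(drop=True),
        registry=registry,
        provenance=provenance or path.stem,
    )
    logger.info("loaded %d assessments from %s", len(table), path)
    return table


def write_assessments(table: AssessmentTable, path: str | Path) -> None:
    """Re-emit a table as canonical CSV (keys, rating fields, covariates)."""
    df = table.df.copy()
    for rf in table.registry.rating_fields:
        df[rf] = df[rf].astype("Int64")  # integers with empty cells for missing
    df.to_csv(path, index=False)


def completeness_filter(table: AssessmentTable) -> AssessmentTable:
    """Retain exactly the records with all rating fields present.

    Idempotent. Covariate missingness never drops a record. Logs the
    retention count and covariate medians before/after so selection bias
    with respect to age or gender can be eyeballed.
    """
    mask = table.is_complete()
    kept = table.df.loc[mask].reset_index(drop=True)
    logger.info(
        "completeness filter (%s): retained %d of %d assessments",
        table.provenance, int(mask.sum()), len(table),
    )
    for cov in ("age",):
        if cov in table.df.columns:
            logger.info(
                "  median %s before=%.1f after=%.1f", cov,
                table.df[cov].median(), kept[cov].median(),
            )
    if not mask.any():
        logger.warning("completeness filter left zero records (%s)", table.provenance)
    return replace(table, df=kept)


def _require_complete(record: Mapping[str, object], fields: tuple[str, ...]):
    vals = np.array([record[f] for f in fields], dtype=float)
    if np.isnan(vals).any():
        missing = [f for f, v in zip(fields, vals) if np.isnan(v)]
        raise ValueError(f"record is missing ratings for fields {missing}")
    return vals


def total_score(record: Mapping[str, object], registry: ItemRegistry) -> int:
    """Sum of all of a record's ratings (0-260 for the MDS-UPDRS)."""
    return int(_require_complete(record, registry.rating_fields).sum())


def subset_sum(
    record: Mapping[str, object], subset: ItemSet, registry: ItemRegistry
) -> int:
    """Sum of a record's ratings over the subset's rating fields.

    Multi-rating items (e.g. lateralised part-III items) contribute the
    sum of all their fields.
    """
    fields = registry.rating_fields_of(subset)
    if not fields:
        return 0
    return int(_require_complete(record, fields).sum())


def compare_datasets(a: AssessmentTable, b: AssessmentTable) -> ComparisonStats:
    """Mann-Whitney U comparison of two cohorts' total-score distributions.

    U is oriented to table ``a`` (pairs where a's total exceeds b's, ties
    half); the two-sided p-value uses the tie-corrected normal
    approximation with continuity correction.
    """
    ta = a.total_scores().to_numpy(dtype=float)
    tb = b.total_scores().to_numpy(dtype=float)
    if np.isnan(ta).any() or np.isnan(tb).any():
        raise ValueError("both tables must be complete; run completeness_filter")
    if len(ta) < 2 or len(tb) < 2:
        raise ValueError("need at least 2 records per table to compare")
    res = stats.mannwhitneyu(
        ta, tb, alternative="two-sided", method="asymptotic", use_continuity=True
    )

    def _median_hy(t: AssessmentTable) -> float | None:
        if "hy_stage" in t.df.columns and t.df["hy_stage"].notna().any():
            return float(t.df["hy_stage"].median())
        return None

    return ComparisonStats(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_total_a=float(np.median(ta)),
        median_total_b=float(np.median(tb)),
        n_a=len(ta),
        n_b=len(tb),
        median_hy_a=_median_hy(a),
        median_hy_b=_median_hy(b),
    )
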