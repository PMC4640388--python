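"""Reading and writing cohort tables and packaged reference fixtures.

The single interchange format is UTF-8 comma-delimited text with a header
row.  A cohort table has one row per subject with at least ``subject_id``,
``age``, one column per risk factor (level ids; blanks where a factor does
not apply) and, for validation, a binary ``chd_10yr`` outcome.  Unknown
columns are carried through untouched.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .errors import SchemaError
from .model import RiskModel
from .params import _data_path, params_checksum  # noqa: F401  (re-exported)

__all__ = [
    "example_cohort_path",
    "read_cohort",
    "read_published_category_counts",
    "read_published_cstats",
    "write_cohort",
]

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("subject_id", "age")


def read_cohort(
    path: str | Path,
    model: RiskModel | None = None,
    require_outcome: bool = False,
) -> pd.DataFrame:
    """Read a cohort table, validating the declared schema.

    When a ``model`` is given, a column per model factor is required.  Row
    and null counts are logged.  Raises :class:`SchemaError` naming every
    missing mandatory column; unparseable ages or outcomes raise with the
    offending row index.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = list(MANDATORY_COLUMNS)
    if model is not None:
        required += list(model.factor_ids)
    if require_outcome:
        required.append("chd_10yr")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file {path} missing column(s): {missing}")
    for col in ("age", "chd_10yr"):
        if col not in df.columns:
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            raise SchemaError(
                f"cohort file {path}: unparseable {col!r} at row(s) "
                f"{df.index[bad][:5].tolist()}"
            )
        df[col] = parsed
    logger.info(
        "read %d rows from %s (%d null cells)", len(df), path, int(df.isna().sum().sum())
    )
    return df


def write_cohort(df: pd.DataFrame, path: str | Path, **meta: object) -> None:
    """Write a cohort (or scored cohort) table as CSV.

    The data file stays plain CSV so any reader round-trips it; keyword
    metadata (seed, parameter checksum ...) goes to a ``<path>.meta``
    sidecar, one ``key: value`` per line, so reruns are auditable without
    perturbing the table bytes.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        df.to_csv(fh, index=False)
    if meta:
        side = path.with_suffix(path.suffix + ".meta")
        side.write_text(
            "".join(f"{k}: {v}\n" for k, v in sorted(meta.items())), encoding="utf-8"
        )


def example_cohort_path() -> Path:
    """Path of the packaged 20-row synthetic example cohort."""
    return _data_path("example_cohort.csv")


def read_published_category_counts(stratum: str | None = None) -> pd.DataFrame:
    """The packaged published per-category count table (all strata or one).

    Columns: ``stratum, category, n, cases`` plus the published odds-ratio
    columns for diffing.
    """
    df = pd.read_csv(_data_path("table2_counts.csv"))
    if stratum is not None:
        sub = df[df["stratum"] == stratum]
        if sub.empty:
            raise SchemaError(
                f"unknown stratum {stratum!r}; have {sorted(df['stratum'].unique())}"
            )
        return sub.reset_index(drop=True)
    return df


def read_published_cstats() -> pd.DataFrame:
    """The packaged published c-statistics (overall, age-adjusted, age bands)."""
    return pd.read_csv(_data_path("table3_cstats.csv"))
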