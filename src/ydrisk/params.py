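"""Loading and validating factor-parameter files.

The package ships a default parameter file encoding the YDR consensus
relative risks together with two prevalence columns: the estimated U.S.
population prevalences the tool's denominator uses, and the prevalences
observed in the Nurses' Health Study validation cohort.  Two further columns
carry the cohort-observed (unadjusted and multivariate-adjusted) relative
risks so that sensitivity analyses can swap effect sources without touching
code.

Schema (delimited text, header row, prevalences in percent):

    factor_id,level_id,is_reference,consensus_rr,us_prevalence,
    nhs_prevalence,applicability[,extra columns carried through]
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import ParameterError, SchemaError
from .model import FactorDefinition, FactorLevel, RiskModel

__all__ = [
    "default_params_path",
    "load_effect_rrs",
    "params_checksum",
    "read_params",
    "read_params_table",
]

_CORE_COLUMNS = [
    "factor_id",
    "level_id",
    "is_reference",
    "consensus_rr",
    "us_prevalence",
    "nhs_prevalence",
    "applicability",
]

#: Tolerance for the printed reference prevalence vs 100 - sum(exposed),
#: absorbing rounding of the published percentages.
_PRINTED_REF_TOL = 0.5  # percentage points

PREVALENCE_SOURCES = ("us", "nhs")
EFFECT_SOURCES = ("consensus", "observed_unadjusted", "observed_multivariate")

_EFFECT_COLUMN = {
    "consensus": "consensus_rr",
    "observed_unadjusted": "nhs_unadjusted_rr",
    "observed_multivariate": "nhs_multivariate_rr",
}


def default_params_path() -> Path:
    """Path of the packaged default factor-parameter file."""
    return Path(resources.files("ydrisk.data") / "params_table1.csv")


def _data_path(name: str) -> Path:
    return Path(resources.files("ydrisk.data") / name)


def params_checksum(path: str | Path | None = None) -> str:
    """SHA-256 of a parameter file, recorded in every output for provenance."""
    p = Path(path) if path is not None else default_params_path()
    return hashlib.sha256(p.read_bytes()).hexdigest()


def read_params_table(path: str | Path | None = None) -> pd.DataFrame:
    """Read a factor-parameter file into a validated flat table."""
    p = Path(path) if path is not None else default_params_path()
    df = pd.read_csv(p, dtype={"factor_id": str, "level_id": str})
    missing = [c for c in _CORE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"parameter file {p} missing column(s): {missing}")
    if df.duplicated(subset=["factor_id", "level_id"]).any():
        raise ParameterError(f"parameter file {p} has duplicate factor/level rows")
    return df


def _build_factor(
    factor_id: str, block: pd.DataFrame, prevalence_column: str
) -> FactorDefinition:
    refs = block[block["is_reference"].astype(int) == 1]
    if len(refs) != 1:
        raise ParameterError(
            f"factor {factor_id!r}: expected exactly one reference level, "
            f"found {len(refs)}"
        )
    ref_row = refs.iloc[0]
    rules = block["applicability"].unique()
    if len(rules) != 1:
        raise ParameterError(
            f"factor {factor_id!r}: conflicting applicability rules {list(rules)}"
        )
    exposed = block[block["is_reference"].astype(int) == 0]
    exposed_pct = exposed[prevalence_column].astype(float)
    if (exposed_pct < 0).any() or exposed_pct.sum() > 100.0 + 1e-9:
        raise ParameterError(
            f"factor {factor_id!r}: exposed prevalences in column "
            f"{prevalence_column!r} must be >= 0 and sum to <= 100%"
        )
    # reference prevalence is recomputed so levels sum to exactly 1;
    # the printed value is only checked for consistency
    ref_pct = 100.0 - exposed_pct.sum()
    printed = float(ref_row[prevalence_column])
    if abs(printed - ref_pct) > _PRINTED_REF_TOL:
        raise ParameterError(
            f"factor {factor_id!r}: reference prevalence {printed}% inconsistent "
            f"with 100 - sum(exposed) = {ref_pct}%"
        )
    levels = []
    for _, row in block.iterrows():
        is_ref = int(row["is_reference"]) == 1
        pct = ref_pct if is_ref else float(row[prevalence_column])
        levels.append(
            FactorLevel(
                level_id=str(row["level_id"]),
                consensus_rr=float(row["consensus_rr"]),
                population_prevalence=pct / 100.0,
            )
        )
    return FactorDefinition(
        factor_id=factor_id,
        levels=tuple(levels),
        reference_level=str(ref_row["level_id"]),
        applicability=str(rules[0]),
    )


def read_params(
    path: str | Path | None = None, prevalence_source: str = "us"
) -> RiskModel:
    """Load a :class:`~ydrisk.model.RiskModel` from a parameter file.

    ``prevalence_source`` selects which prevalence column feeds the score
    denominator: ``"us"`` (the tool's definition) or ``"nhs"`` (the cohort's
    observed prevalences, for sensitivity analyses).
    """
    if prevalence_source not in PREVALENCE_SOURCES:
        raise ParameterError(
            f"prevalence_source must be one of {PREVALENCE_SOURCES}, "
            f"got {prevalence_source!r}"
        )
    df = read_params_table(path)
    column = f"{prevalence_source}_prevalence"
    factors = tuple(
        _build_factor(fid, block, column)
        for fid, block in df.groupby("factor_id", sort=False)
    )
    return RiskModel(factors=factors)


def load_effect_rrs(
    path: str | Path | None = None, source: str = "consensus"
) -> dict[str, dict[str, float]]:
    """Per-factor, per-level relative risks for simulating outcomes.

    ``source`` is ``"consensus"`` (the YDR parameters), or
    ``"observed_unadjusted"`` / ``"observed_multivariate"`` (the cohort
    estimates shipped alongside them).  Returns ``{factor_id: {level_id: rr}}``.
    """
    if source not in _EFFECT_COLUMN:
        raise ParameterError(
            f"effect source must be one of {tuple(_EFFECT_COLUMN)}, got {source!r}"
        )
    df = read_params_table(path)
    col = _EFFECT_COLUMN[source]
    if col not in df.columns:
        raise SchemaError(f"parameter file lacks column {col!r} for source {source!r}")
    out: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        rr = float(row[col])
        if not rr > 0:
            raise ParameterError(
                f"{row['factor_id']}/{row['level_id']}: RR must be positive, got {rr}"
            )
        out.setdefault(str(row["factor_id"]), {})[str(row["level_id"])] = rr
    return out
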