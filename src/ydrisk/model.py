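"""The Your Disease Risk (YDR) relative-risk scoring engine for CHD.

YDR estimates a person's 10-year risk of coronary heart disease *relative to
an average person of the same age and sex*.  Each risk factor contributes a
consensus relative risk ``RR_l`` for the person's own level (numerator) and a
population-average relative risk (denominator), so that

    RR = prod_f RR_l(f)  /  prod_f sum_k P_k(f) * RR_k(f)

where ``P_k`` is the population prevalence of level ``k`` of factor ``f``.
The denominator anchors the score: a person whose factor levels are drawn at
the population prevalences scores 1.0 on average.  The score is then binned
into seven ordered categories from "very much below average" (RR <= 0.2) to
"very much above average" (RR > 5.1).

Factors may be age-gated (adiposity is measured as BMI under age 60 and as
waist circumference at 60 and over) or conditional on another factor
(secondhand-smoke exposure is defined only for people who are not current
smokers); inapplicable factors contribute to neither the numerator nor the
denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import MissingFactorError, ParameterError, SchemaError

__all__ = [
    "CATEGORY_LABELS",
    "CATEGORY_UPPER_BOUNDS",
    "FactorLevel",
    "FactorDefinition",
    "RiskModel",
    "RiskProfile",
    "ScoreResult",
    "categorize",
    "population_average_rr",
    "score",
    "score_cohort",
    "score_denominator",
    "select_adiposity_factor",
]

#: Ordered category identifiers, lowest relative risk first.
CATEGORY_LABELS: tuple[str, ...] = (
    "very_much_below_average",
    "much_below_average",
    "below_average",
    "about_average",
    "above_average",
    "much_above_average",
    "very_much_above_average",
)

#: Human-readable names for reports.
CATEGORY_TITLES: dict[str, str] = {
    "very_much_below_average": "Very much below average (RR <= 0.2)",
    "much_below_average": "Much below average (0.2 < RR <= 0.5)",
    "below_average": "Below average (0.5 < RR <= 0.9)",
    "about_average": "About average (0.9 < RR <= 1.1)",
    "above_average": "Above average (1.1 < RR <= 2.1)",
    "much_above_average": "Much above average (2.1 < RR <= 5.1)",
    "very_much_above_average": "Very much above average (RR > 5.1)",
}

#: Inclusive upper bounds of the first six categories; the seventh is open.
CATEGORY_UPPER_BOUNDS: tuple[float, ...] = (0.2, 0.5, 0.9, 1.1, 2.1, 5.1)

#: Applicability rules understood by the factor-parameter file.
APPLICABILITY_RULES = ("always", "age<60", "age>=60", "not_current_smoker")

#: Canonical factor ids for the age-gated adiposity pair and smoking.
BMI_FACTOR = "bmi"
WAIST_FACTOR = "waist"
SMOKING_FACTOR = "smoking"
#: Smoking level ids beginning with this prefix denote current smokers.
CURRENT_SMOKER_PREFIX = "current"

_PREV_TOL = 1e-9


def categorize(relative_risk: float) -> str:
    """Map a relative risk to its YDR category (upper bounds inclusive)."""
    if not relative_risk > 0:
        raise ParameterError(f"relative risk must be positive, got {relative_risk}")
    idx = int(np.searchsorted(CATEGORY_UPPER_BOUNDS, relative_risk, side="left"))
    return CATEGORY_LABELS[idx]


@dataclass(frozen=True)
class FactorLevel:
    """One level of a risk factor.

    ``consensus_rr`` is the expert-panel relative risk versus the factor's
    reference level; ``population_prevalence`` is the proportion of the
    reference population at this level (in [0, 1]).
    """

    level_id: str
    consensus_rr: float
    population_prevalence: float

    def __post_init__(self) -> None:
        if not self.consensus_rr > 0:
            raise ParameterError(
                f"level {self.level_id!r}: consensus RR must be positive, "
                f"got {self.consensus_rr}"
            )
        if not 0.0 <= self.population_prevalence <= 1.0:
            raise ParameterError(
                f"level {self.level_id!r}: prevalence {self.population_prevalence} "
                "outside [0, 1]"
            )


@dataclass(frozen=True)
class FactorDefinition:
    """A risk factor: ordered levels, exactly one reference, applicability rule."""

    factor_id: str
    levels: tuple[FactorLevel, ...]
    reference_level: str
    applicability: str = "always"

    def __post_init__(self) -> None:
        ids = [lv.level_id for lv in self.levels]
        if len(set(ids)) != len(ids):
            raise ParameterError(f"factor {self.factor_id!r}: duplicate level ids")
        if self.reference_level not in ids:
            raise ParameterError(
                f"factor {self.factor_id!r}: reference level "
                f"{self.reference_level!r} not among levels"
            )
        ref = self.level(self.reference_level)
        if ref.consensus_rr != 1.0:
            raise ParameterError(
                f"factor {self.factor_id!r}: reference level must have RR 1.0"
            )
        total = sum(lv.population_prevalence for lv in self.levels)
        if abs(total - 1.0) > _PREV_TOL:
            raise ParameterError(
                f"factor {self.factor_id!r}: level prevalences sum to {total}, not 1"
            )
        if self.applicability not in APPLICABILITY_RULES:
            raise ParameterError(
                f"factor {self.factor_id!r}: unknown applicability rule "
                f"{self.applicability!r}; expected one of {APPLICABILITY_RULES}"
            )

    def level(self, level_id: str) -> FactorLevel:
        for lv in self.levels:
            if lv.level_id == level_id:
                return lv
        raise SchemaError(
            f"factor {self.factor_id!r}: unknown level {level_id!r} "
            f"(known: {[lv.level_id for lv in self.levels]})"
        )

    @property
    def level_ids(self) -> tuple[str, ...]:
        return tuple(lv.level_id for lv in self.levels)

    def rr(self, level_id: str) -> float:
        return self.level(level_id).consensus_rr

    def applies(self, age: float, factor_levels: Mapping[str, str]) -> bool:
        """Whether this factor enters the score for a subject."""
        rule = self.applicability
        if rule == "always":
            return True
        if rule == "age<60":
            return age < 60
        if rule == "age>=60":
            return age >= 60
        # not_current_smoker: needs the smoking assignment of the profile
        smoking = factor_levels.get(SMOKING_FACTOR)
        if smoking is None:
            raise MissingFactorError(
                f"factor {self.factor_id!r} is conditional on smoking status, "
                "but the profile has no smoking level"
            )
        return not str(smoking).startswith(CURRENT_SMOKER_PREFIX)


@dataclass(frozen=True)
class RiskModel:
    """A full YDR parameterisation: factors plus the seven category cutpoints."""

    factors: tuple[FactorDefinition, ...]
    category_upper_bounds: tuple[float, ...] = CATEGORY_UPPER_BOUNDS

    def __post_init__(self) -> None:
        ids = [f.factor_id for f in self.factors]
        if len(set(ids)) != len(ids):
            raise ParameterError("duplicate factor ids in model")
        ups = self.category_upper_bounds
        if len(ups) != len(CATEGORY_LABELS) - 1 or any(
            b >= a for a, b in zip(ups[1:], ups[:-1])
        ) or ups[0] <= 0:
            raise ParameterError(
                "category cutpoints must be positive and strictly increasing, "
                "one fewer than the number of categories"
            )

    @property
    def factor_ids(self) -> tuple[str, ...]:
        return tuple(f.factor_id for f in self.factors)

    def factor(self, factor_id: str) -> FactorDefinition:
        for f in self.factors:
            if f.factor_id == factor_id:
                return f
        raise SchemaError(f"unknown factor {factor_id!r}")

    def applicable_factors(
        self, age: float, factor_levels: Mapping[str, str]
    ) -> tuple[FactorDefinition, ...]:
        return tuple(f for f in self.factors if f.applies(age, factor_levels))


@dataclass(frozen=True)
class RiskProfile:
    """One subject: age in years plus a level assignment per factor."""

    subject_id: str
    age: int
    factor_levels: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class ScoreResult:
    """A scored profile: equation numerator, denominator, RR, category."""

    numerator: float
    denominator: float
    relative_risk: float
    category: str


def select_adiposity_factor(age: float) -> str:
    """Return the adiposity factor id used at a given age.

    Adiposity is assessed as BMI below age 60 and as waist circumference at
    age 60 and above.
    """
    if age < 0:
        raise ParameterError(f"age must be non-negative, got {age}")
    return BMI_FACTOR if age < 60 else WAIST_FACTOR


def population_average_rr(factor: FactorDefinition) -> float:
    """Prevalence-weighted mean RR of a factor over the reference population.

    This is the factor's term in the score denominator,
    ``sum_k P_k * RR_k`` with the reference contributing ``P_ref * 1.0``.
    Equals 1.0 when no one is exposed.
    """
    return float(
        sum(lv.population_prevalence * lv.consensus_rr for lv in factor.levels)
    )


def score_denominator(model: RiskModel, profile: RiskProfile) -> float:
    """Product of population-average RRs over the factors applicable to a profile."""
    den = 1.0
    for f in model.applicable_factors(profile.age, profile.factor_levels):
        den *= population_average_rr(f)
    return den


def score(
    profile: RiskProfile, model: RiskModel, impute_reference: bool = False
) -> ScoreResult:
    """Score one profile: numerator, denominator, relative risk and category.

    Raises :class:`MissingFactorError` if an applicable factor has no level,
    unless ``impute_reference`` is set, in which case the reference level
    (RR 1.0) is assumed for the missing factor.
    """
    num = 1.0
    den = 1.0
    for f in model.applicable_factors(profile.age, profile.factor_levels):
        level_id = profile.factor_levels.get(f.factor_id)
        if level_id is None or (isinstance(level_id, float) and math.isnan(level_id)):
            if not impute_reference:
                raise MissingFactorError(
                    f"subject {profile.subject_id!r}: no level for applicable "
                    f"factor {f.factor_id!r}"
                )
            level_id = f.reference_level
        num *= f.rr(str(level_id))
        den *= population_average_rr(f)
    rr = num / den
    return ScoreResult(num, den, rr, categorize(rr))


def _applicability_mask(
    factor: FactorDefinition, age: pd.Series, cohort: pd.DataFrame
) -> np.ndarray:
    rule = factor.applicability
    if rule == "always":
        return np.ones(len(cohort), dtype=bool)
    if rule == "age<60":
        return (age < 60).to_numpy()
    if rule == "age>=60":
        return (age >= 60).to_numpy()
    if SMOKING_FACTOR not in cohort.columns:
        raise SchemaError(
            f"factor {factor.factor_id!r} is conditional on smoking status, "
            f"but the cohort has no {SMOKING_FACTOR!r} column"
        )
    smoking = cohort[SMOKING_FACTOR].astype("string")
    return ~(smoking.str.startswith(CURRENT_SMOKER_PREFIX).fillna(False)).to_numpy()


def score_cohort(
    model: RiskModel, cohort: pd.DataFrame, impute_reference: bool = False
) -> pd.DataFrame:
    """Score every row of a cohort table (vectorised).

    ``cohort`` must have an ``age`` column and one column per factor holding
    level ids; inapplicable factors may be empty.  Returns a copy with
    ``ydr_numerator``, ``ydr_denominator``, ``ydr_rr`` and ``ydr_category``
    appended; all other columns are carried through unchanged.
    """
    if "age" not in cohort.columns:
        raise SchemaError("cohort table has no 'age' column")
    age = pd.to_numeric(cohort["age"])
    n = len(cohort)
    num = np.ones(n)
    den = np.ones(n)
    for f in model.factors:
        if f.factor_id not in cohort.columns:
            raise SchemaError(f"cohort table has no column for factor {f.factor_id!r}")
        mask = _applicability_mask(f, age, cohort)
        levels = cohort[f.factor_id].where(pd.notna(cohort[f.factor_id]), None)
        rr_map = {lv.level_id: lv.consensus_rr for lv in f.levels}
        rr = levels.map(rr_map).to_numpy(dtype=float, na_value=np.nan)
        missing = mask & np.isnan(rr)
        if missing.any():
            # distinguish unknown level ids from genuinely absent values
            present = levels.notna().to_numpy() & missing
            if present.any():
                bad = sorted(set(levels.to_numpy()[present]))
                raise SchemaError(
                    f"factor {f.factor_id!r}: unknown level id(s) {bad}"
                )
            if not impute_reference:
                idx = cohort.index[missing][:5].tolist()
                raise MissingFactorError(
                    f"{int(missing.sum())} subject(s) missing a level for "
                    f"applicable factor {f.factor_id!r} (e.g. rows {idx}); "
                    "exclude them or pass impute_reference=True"
                )
            rr = np.where(missing, 1.0, rr)
        num = np.where(mask, num * np.where(np.isnan(rr), 1.0, rr), num)
        den = np.where(mask, den * population_average_rr(f), den)
    rr_score = num / den
    cat_idx = np.searchsorted(
        np.asarray(model.category_upper_bounds), rr_score, side="left"
    )
    out = cohort.copy()
    out["ydr_numerator"] = num
    out["ydr_denominator"] = den
    out["ydr_rr"] = rr_score
    out["ydr_category"] = pd.Categorical.from_codes(
        cat_idx, categories=list(CATEGORY_LABELS), ordered=True
    )
    return out
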