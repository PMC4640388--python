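"""Calibration and discrimination statistics for the YDR score.

Everything the validation battery needs reduces to logistic-regression
category models and concordance statistics:

* per-category odds ratios against the "about average" reference, crude and
  age-adjusted (calibration by risk category);
* per-factor odds ratios, unadjusted and multivariate (how the cohort's own
  effect estimates compare to the consensus parameters);
* the c-statistic of the category model, overall, age-adjusted and within
  age bands (discrimination), with Hanley-McNeil (default) or DeLong
  confidence intervals, and a normal-approximation z-test for comparing the
  c-statistics of two independent strata.

For a model whose only predictors are category indicators, the fitted MLE
odds ratios equal the empirical cell odds ratios and the fitted risk ranking
equals the category event-rate ranking; the closed-form routines here exploit
that both as fast paths on published count tables and as independent oracles
for the regression-based routines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .errors import ParameterError, SchemaError
from .model import (
    CATEGORY_LABELS,
    CATEGORY_TITLES,
    RiskModel,
    _applicability_mask,
)

__all__ = [
    "CStatResult",
    "ValidationReport",
    "build_report",
    "c_statistic_from_counts",
    "c_statistic_pairwise",
    "category_counts",
    "closed_form_category_or",
    "compare_c_statistics",
    "factor_association_models",
    "logistic_category_model",
    "report_from_counts",
]

REFERENCE_CATEGORY = "about_average"

#: Age bands used for age-specific discrimination.
AGE_BANDS = (
    ("le55", None, 55),
    ("56_60", 56, 60),
    ("61_65", 61, 65),
    ("66_70", 66, 70),
    ("gt70", 71, None),
)


# ---------------------------------------------------------------------------
# tabulation


def category_counts(scored: pd.DataFrame) -> pd.DataFrame:
    """Subjects and cases per YDR category (all seven rows, zeros allowed)."""
    for col in ("ydr_category", "chd_10yr"):
        if col not in scored.columns:
            raise SchemaError(f"scored cohort lacks column {col!r}")
    cat = pd.Categorical(
        scored["ydr_category"], categories=list(CATEGORY_LABELS), ordered=True
    )
    grp = scored.groupby(cat, observed=False)["chd_10yr"]
    out = pd.DataFrame(
        {"n": grp.size(), "cases": grp.sum().astype(int)},
        index=pd.Index(CATEGORY_LABELS, name="category"),
    )
    out["n"] = out["n"].fillna(0).astype(int)
    out["pct"] = 100.0 * out["n"] / max(out["n"].sum(), 1)
    return out


def _check_counts(counts: pd.DataFrame) -> pd.DataFrame:
    for col in ("n", "cases"):
        if col not in counts.columns:
            raise SchemaError(f"count table lacks column {col!r}")
    if ((counts["cases"] < 0) | (counts["cases"] > counts["n"])).any():
        raise ParameterError("cases must lie in [0, n] for every category")
    n1 = int(counts["cases"].sum())
    n0 = int(counts["n"].sum()) - n1
    if n1 == 0 or n0 == 0:
        raise ParameterError("count table needs at least one case and one non-case")
    return counts


# ---------------------------------------------------------------------------
# odds ratios


def closed_form_category_or(
    counts: pd.DataFrame, reference: str = REFERENCE_CATEGORY
) -> pd.DataFrame:
    """Empirical per-category odds ratios versus a reference category.

    For a logistic model with only category indicators these equal the MLE.
    Wald 95% CIs on the log scale use the sum of the four reciprocal cell
    counts; a zero cell yields an infinite or zero bound and sets the
    ``zero_cell`` flag instead of raising.
    """
    _check_counts(counts)
    if reference not in counts.index:
        raise ParameterError(f"reference category {reference!r} not in table")
    a_ref = float(counts.loc[reference, "cases"])
    b_ref = float(counts.loc[reference, "n"] - counts.loc[reference, "cases"])
    if a_ref == 0 or b_ref == 0:
        raise ParameterError(
            "reference category must contain at least one case and one non-case"
        )
    rows = []
    z = scipy.stats.norm.ppf(0.975)
    for cat, row in counts.iterrows():
        a = float(row["cases"])
        b = float(row["n"] - row["cases"])
        zero = (a == 0.0) or (b == 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            point = (a / b) / (a_ref / b_ref) if b > 0 else np.inf
            if cat == reference:
                lo = hi = point = 1.0
                zero = False
            elif zero:
                lo, hi = (0.0, np.inf)
                point = 0.0 if a == 0 else np.inf
            else:
                se = np.sqrt(1 / a + 1 / b + 1 / a_ref + 1 / b_ref)
                lo = point * np.exp(-z * se)
                hi = point * np.exp(z * se)
        rows.append((cat, point, lo, hi, zero))
    return pd.DataFrame(
        rows, columns=["category", "point", "ci_low", "ci_high", "zero_cell"]
    ).set_index("category")


def _category_design(
    scored: pd.DataFrame, reference: str, adjust_age: bool
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    cats = [
        c
        for c in CATEGORY_LABELS
        if (scored["ydr_category"] == c).any()
    ]
    if reference not in cats:
        raise ParameterError(f"reference category {reference!r} has no subjects")
    if len(cats) < 2:
        raise ParameterError("cohort occupies a single category: no contrast to fit")
    X = pd.DataFrame(index=scored.index)
    for c in cats:
        if c != reference:
            X[c] = (scored["ydr_category"] == c).astype(float)
    if adjust_age:
        X["age"] = pd.to_numeric(scored["age"]).astype(float)
    X = sm.add_constant(X, prepend=True)
    y = pd.to_numeric(scored["chd_10yr"]).to_numpy(dtype=float)
    return X, y, [c for c in cats if c != reference]


def logistic_category_model(
    scored: pd.DataFrame,
    adjust_age: bool = False,
    reference: str = REFERENCE_CATEGORY,
):
    """ML logistic fit of the category-indicator model.

    Returns ``(or_table, result)`` where ``or_table`` has the exponentiated
    coefficients with Wald 95% CIs (reference row fixed at 1.0) and
    ``result`` is the fitted statsmodels GLM, whose fitted probabilities
    feed the (age-adjusted) concordance statistic.
    """
    X, y, terms = _category_design(scored, reference, adjust_age)
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    if not res.converged:
        raise ParameterError("logistic category model failed to converge")
    params, ci = res.params, res.conf_int()
    rows = [(reference, 1.0, 1.0, 1.0)]
    for t in terms:
        rows.append(
            (t, float(np.exp(params[t])), float(np.exp(ci.loc[t, 0])),
             float(np.exp(ci.loc[t, 1])))
        )
    order = [c for c in CATEGORY_LABELS if c in {r[0] for r in rows}]
    table = (
        pd.DataFrame(rows, columns=["category", "point", "ci_low", "ci_high"])
        .set_index("category")
        .loc[order]
    )
    return table, res


def factor_association_models(
    scored: pd.DataFrame, model: RiskModel, adjust_age: bool = False
) -> pd.DataFrame:
    """Per-factor odds ratios, unadjusted and mutually adjusted.

    Each factor's non-reference levels enter as indicators; the unadjusted
    estimate fits that factor alone among the subjects it applies to, the
    multivariate estimate fits all factors jointly (age-gated adiposity
    indicators are zero outside their age stratum, so BMI and waist share
    one joint model).  Factors constant in the cohort are flagged and
    dropped from the joint fit.

    ``adjust_age`` adds continuous age to every fit.  The default (off)
    mirrors the published factor table, but note that the age-gated
    adiposity indicators then also carry the age-outcome gradient: their
    dummies identify the age stratum, so whenever age affects the outcome
    the unadjusted-for-age estimates of BMI and waist are confounded by
    design.  Parameter-recovery checks against a simulation with an age
    effect must set ``adjust_age=True``.
    """
    age = pd.to_numeric(scored["age"])
    y_all = pd.to_numeric(scored["chd_10yr"]).to_numpy(dtype=float)
    dummies: dict[tuple[str, str], pd.Series] = {}
    masks: dict[str, np.ndarray] = {}
    constant: set[str] = set()
    for f in model.factors:
        if f.factor_id not in scored.columns:
            raise SchemaError(f"cohort lacks column for factor {f.factor_id!r}")
        mask = _applicability_mask(f, age, scored)
        masks[f.factor_id] = mask
        observed = scored.loc[mask, f.factor_id].dropna().unique()
        if len(observed) < 2:
            constant.add(f.factor_id)
            continue
        for lv in f.levels:
            if lv.level_id == f.reference_level:
                continue
            dummies[(f.factor_id, lv.level_id)] = (
                (scored[f.factor_id] == lv.level_id).astype(float)
            )
    rows = []
    z = scipy.stats.norm.ppf(0.975)

    def fit(X: pd.DataFrame, y: np.ndarray, age_col: pd.Series | None):
        if adjust_age and age_col is not None:
            X = X.assign(age=age_col.to_numpy(dtype=float))
        res = sm.GLM(y, sm.add_constant(X, prepend=True),
                     family=sm.families.Binomial()).fit()
        return res

    # joint multivariate fit over the full cohort
    Xj = pd.DataFrame({f"{fid}::{lvl}": s for (fid, lvl), s in dummies.items()})
    joint = fit(Xj, y_all, age) if len(Xj.columns) else None

    for f in model.factors:
        if f.factor_id in constant:
            for lv in f.levels:
                if lv.level_id != f.reference_level:
                    rows.append((f.factor_id, lv.level_id, *(np.nan,) * 6, True))
            continue
        mask = masks[f.factor_id]
        cols = [
            f"{f.factor_id}::{lv.level_id}"
            for lv in f.levels
            if lv.level_id != f.reference_level
        ]
        Xu = pd.DataFrame(
            {c: dummies[(f.factor_id, c.split("::")[1])][mask] for c in cols}
        )
        single = fit(Xu, y_all[mask], age[mask])
        for lv in f.levels:
            if lv.level_id == f.reference_level:
                continue
            c = f"{f.factor_id}::{lv.level_id}"
            b, se = single.params[c], single.bse[c]
            bj, sej = joint.params[c], joint.bse[c]
            # huge standard errors (separation on tiny cohorts) overflow to
            # inf bounds, which downstream code treats as flagged output
            with np.errstate(over="ignore"):
                rows.append(
                    (
                        f.factor_id,
                        lv.level_id,
                        float(np.exp(b)),
                        float(np.exp(b - z * se)),
                        float(np.exp(b + z * se)),
                        float(np.exp(bj)),
                        float(np.exp(bj - z * sej)),
                        float(np.exp(bj + z * sej)),
                        False,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "factor_id",
            "level_id",
            "or_unadjusted",
            "or_unadjusted_low",
            "or_unadjusted_high",
            "or_multivariate",
            "or_multivariate_low",
            "or_multivariate_high",
            "constant_factor",
        ],
    ).set_index(["factor_id", "level_id"])


# ---------------------------------------------------------------------------
# concordance


@dataclass(frozen=True)
class CStatResult:
    """A concordance statistic with its standard error and 95% CI."""

    c: float
    se: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_noncases: int
    ci_method: str = "hanley-mcneil"
    degenerate: bool = False


def _hanley_mcneil_se(c: float, n1: int, n0: int) -> float:
    q1 = c / (2.0 - c)
    q2 = 2.0 * c * c / (1.0 + c)
    var = (
        c * (1 - c) + (n1 - 1) * (q1 - c * c) + (n0 - 1) * (q2 - c * c)
    ) / (n1 * n0)
    return float(np.sqrt(max(var, 0.0)))


def _delong_se(scores: np.ndarray, outcomes: np.ndarray) -> float:
    cases = scores[outcomes == 1]
    ctrls = scores[outcomes == 0]
    n1, n0 = len(cases), len(ctrls)
    order = np.sort(ctrls)
    # placement of each case among controls (fraction below + half ties)
    v10 = (
        np.searchsorted(order, cases, side="left")
        + 0.5 * (np.searchsorted(order, cases, side="right")
                 - np.searchsorted(order, cases, side="left"))
    ) / n0
    order1 = np.sort(cases)
    v01 = (
        (n1 - np.searchsorted(order1, ctrls, side="right"))
        + 0.5 * (np.searchsorted(order1, ctrls, side="right")
                 - np.searchsorted(order1, ctrls, side="left"))
    ) / n1
    s10 = np.var(v10, ddof=1) if n1 > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n0 > 1 else 0.0
    return float(np.sqrt(s10 / n1 + s01 / n0))


def _finish(c: float, se: float, n1: int, n0: int, method: str,
            degenerate: bool = False) -> CStatResult:
    z = scipy.stats.norm.ppf(0.975)
    return CStatResult(
        c=float(c),
        se=float(se),
        ci_low=float(max(0.0, c - z * se)),
        ci_high=float(min(1.0, c + z * se)),
        n_cases=n1,
        n_noncases=n0,
        ci_method=method,
        degenerate=degenerate,
    )


def c_statistic_from_counts(
    counts: pd.DataFrame, ci_method: str = "hanley-mcneil"
) -> CStatResult:
    """Tie-corrected concordance of the category model, from counts alone.

    All subjects in one category share a fitted risk (the category event
    rate), so concordance reduces to a sum over category pairs: pairs whose
    case sits in a higher-rate category count 1, equal-rate pairs count 1/2.
    """
    _check_counts(counts)
    cases = counts["cases"].to_numpy(dtype=float)
    noncases = (counts["n"] - counts["cases"]).to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        rates = np.where(counts["n"] > 0, cases / counts["n"], np.nan)
    n1, n0 = cases.sum(), noncases.sum()
    num = 0.0
    for j in range(len(cases)):
        if cases[j] == 0 or np.isnan(rates[j]):
            continue
        below = noncases[(rates < rates[j]) & ~np.isnan(rates)].sum()
        tied = noncases[(rates == rates[j])].sum()
        num += cases[j] * (below + 0.5 * tied)
    c = num / (n1 * n0)
    occupied = counts["n"][counts["n"] > 0]
    degenerate = len(occupied) < 2 or len(np.unique(rates[~np.isnan(rates)])) < 2
    se = _hanley_mcneil_se(c, int(n1), int(n0))
    return _finish(c, se, int(n1), int(n0), "hanley-mcneil", degenerate)


def c_statistic_pairwise(
    scores, outcomes, ci_method: str = "hanley-mcneil"
) -> CStatResult:
    """Tie-corrected Mann-Whitney concordance of arbitrary risk scores.

    ``c`` is the probability a random case outscores a random non-case,
    ties counting one half; computed from midranks, so it equals the
    trapezoidal area under the ROC curve.  ``ci_method`` is
    ``"hanley-mcneil"`` (default) or ``"delong"``.
    """
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    if scores.shape != outcomes.shape:
        raise ParameterError("scores and outcomes must have equal length")
    if not np.isin(outcomes, (0, 1)).all():
        raise ParameterError("outcomes must be binary 0/1")
    n1 = int(outcomes.sum())
    n0 = int(len(outcomes) - n1)
    if n1 == 0 or n0 == 0:
        raise ParameterError("need at least one case and one non-case")
    ranks = scipy.stats.rankdata(scores)
    c = (ranks[outcomes == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    if ci_method == "hanley-mcneil":
        se = _hanley_mcneil_se(c, n1, n0)
    elif ci_method == "delong":
        se = _delong_se(scores, outcomes)
    else:
        raise ParameterError(f"unknown ci_method {ci_method!r}")
    degenerate = len(np.unique(scores)) < 2
    return _finish(c, se, n1, n0, ci_method, degenerate)


def compare_c_statistics(a: CStatResult, b: CStatResult) -> tuple[float, float]:
    """Two-sided z-test of equal concordance in two independent strata.

    ``z = (c_A - c_B) / sqrt(var_A + var_B)`` with the same variance
    estimator used for the CIs; valid when the strata are disjoint subject
    sets.  Returns ``(z, p)``.
    """
    var = a.se**2 + b.se**2
    if var <= 0.0:
        raise ParameterError("degenerate strata: zero variance in both c-statistics")
    z = (a.c - b.c) / np.sqrt(var)
    p = 2.0 * scipy.stats.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# report


@dataclass
class ValidationReport:
    """Machine-readable validation battery for one scored cohort."""

    n: int
    n_cases: int
    incidence: float
    category_tables: dict[str, pd.DataFrame]
    cstats: dict[str, CStatResult]
    age_comparison: dict[str, float] | None
    factor_table: pd.DataFrame | None
    flags: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = [
            "YDR validation report",
            f"subjects: {self.n}   cases: {self.n_cases}   "
            f"10-year incidence: {100 * self.incidence:.1f}%",
            "",
        ]
        for stratum, table in self.category_tables.items():
            lines.append(f"[{stratum}] category calibration "
                         "(OR vs 'about average')")
            lines.append(table.round(2).to_string())
            lines.append("")
        lines.append("discrimination (c-statistics):")
        for name, cs in self.cstats.items():
            lines.append(
                f"  {name}: {cs.c:.2f} ({cs.ci_low:.2f}-{cs.ci_high:.2f})"
                + ("  [degenerate]" if cs.degenerate else "")
            )
        if self.age_comparison is not None:
            ac = self.age_comparison
            lines.append(
                f"  age<60 vs age>=60: z={ac['z']:.2f}, p={ac['p']:.4f}"
            )
        if self.factor_table is not None:
            lines += ["", "per-factor odds ratios:",
                      self.factor_table.round(2).to_string()]
        if self.flags:
            lines += ["", "flags:"] + [f"  - {f}" for f in self.flags]
        return "\n".join(lines) + "\n"

    def to_files(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for stratum, table in self.category_tables.items():
            table.to_csv(out / f"category_{stratum}.csv")
        pd.DataFrame(
            [
                {
                    "name": name,
                    "c": cs.c,
                    "se": cs.se,
                    "ci_low": cs.ci_low,
                    "ci_high": cs.ci_high,
                    "n_cases": cs.n_cases,
                    "n_noncases": cs.n_noncases,
                    "ci_method": cs.ci_method,
                    "degenerate": cs.degenerate,
                }
                for name, cs in self.cstats.items()
            ]
        ).to_csv(out / "cstatistics.csv", index=False)
        if self.factor_table is not None:
            self.factor_table.to_csv(out / "factor_associations.csv")
        (out / "summary.txt").write_text(self.to_text())


def _stratum_table(scored: pd.DataFrame, flags: list[str], label: str) -> pd.DataFrame:
    counts = category_counts(scored)
    try:
        table = counts.join(
            closed_form_category_or(counts).rename(
                columns={
                    "point": "or_crude",
                    "ci_low": "or_crude_low",
                    "ci_high": "or_crude_high",
                }
            )
        )
        if table["zero_cell"].any():
            flags.append(f"{label}: zero cell(s) in crude odds ratios")
    except ParameterError as exc:
        flags.append(f"{label}: crude odds ratios not computed ({exc})")
        return counts
    try:
        adj, _ = logistic_category_model(scored, adjust_age=True)
        table = table.join(
            adj.rename(
                columns={
                    "point": "or_age_adjusted",
                    "ci_low": "or_age_adjusted_low",
                    "ci_high": "or_age_adjusted_high",
                }
            )
        )
    except (ParameterError, ValueError) as exc:
        flags.append(f"{label}: age-adjusted model not fitted ({exc})")
    return table


def build_report(
    scored: pd.DataFrame,
    model: RiskModel | None = None,
    include_factor_models: bool = True,
) -> ValidationReport:
    """Run the full battery on a scored cohort with outcome and age.

    Produces category calibration tables (overall and within the <60 / >=60
    age strata, refit per stratum), c-statistics (crude, age-adjusted via
    the fitted probabilities of the age-plus-categories model, and per age
    band) and, when ``model`` is given, the per-factor association models.
    Fragile fits on tiny cohorts degrade to flags instead of crashing.
    """
    flags: list[str] = []
    n = len(scored)
    n_cases = int(pd.to_numeric(scored["chd_10yr"]).sum())
    age = pd.to_numeric(scored["age"])

    strata = {
        "overall": scored,
        "age_lt60": scored[age < 60],
        "age_ge60": scored[age >= 60],
    }
    tables = {
        name: _stratum_table(part, flags, name)
        for name, part in strata.items()
        if len(part)
    }

    cstats: dict[str, CStatResult] = {}
    try:
        cstats["overall"] = c_statistic_from_counts(category_counts(scored))
    except ParameterError as exc:
        flags.append(f"overall c-statistic not computed ({exc})")
    try:
        _, res = logistic_category_model(scored, adjust_age=True)
        cstats["overall_age_adjusted"] = c_statistic_pairwise(
            np.asarray(res.fittedvalues), pd.to_numeric(scored["chd_10yr"])
        )
    except (ParameterError, ValueError) as exc:
        flags.append(f"age-adjusted c-statistic not computed ({exc})")
    for band, lo, hi in AGE_BANDS:
        sel = pd.Series(True, index=scored.index)
        if lo is not None:
            sel &= age >= lo
        if hi is not None:
            sel &= age <= hi
        part = scored[sel]
        try:
            cstats[band] = c_statistic_from_counts(category_counts(part))
        except ParameterError as exc:
            flags.append(f"band {band}: c-statistic not computed ({exc})")

    age_comparison = None
    try:
        c_lt = c_statistic_from_counts(category_counts(strata["age_lt60"]))
        c_ge = c_statistic_from_counts(category_counts(strata["age_ge60"]))
        z, p = compare_c_statistics(c_lt, c_ge)
        age_comparison = {"c_lt60": c_lt.c, "c_ge60": c_ge.c, "z": z, "p": p}
    except ParameterError as exc:
        flags.append(f"age-strata c comparison not computed ({exc})")

    factor_table = None
    if model is not None and include_factor_models:
        try:
            factor_table = factor_association_models(scored, model)
            if factor_table["constant_factor"].any():
                flags.append("constant factor(s) dropped from joint model")
        except (ParameterError, ValueError, KeyError) as exc:
            flags.append(f"factor association models not fitted ({exc})")

    return ValidationReport(
        n=n,
        n_cases=n_cases,
        incidence=n_cases / n if n else float("nan"),
        category_tables=tables,
        cstats=cstats,
        age_comparison=age_comparison,
        factor_table=factor_table,
        flags=flags,
    )


def report_from_counts(counts: pd.DataFrame) -> dict[str, object]:
    """Validation quantities computable from published count tables alone.

    ``counts`` has columns ``stratum, category, n, cases`` (one row per
    category per stratum).  Returns per-stratum crude odds-ratio tables, the
    overall count-based c-statistic, and the overall incidence in percent.
    """
    out: dict[str, object] = {"or_tables": {}}
    for stratum, block in counts.groupby("stratum", sort=False):
        tab = block.set_index("category")[["n", "cases"]]
        out["or_tables"][stratum] = closed_form_category_or(tab)
        if stratum == "overall":
            out["c_statistic"] = c_statistic_from_counts(tab)
            out["n"] = int(tab["n"].sum())
            out["n_cases"] = int(tab["cases"].sum())
            out["incidence_pct"] = 100.0 * tab["cases"].sum() / tab["n"].sum()
    return out
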