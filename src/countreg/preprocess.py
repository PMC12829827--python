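"""Data-quality filtering, imputation, encoding and monthly aggregation.

The cleaning pipeline for patient-level records runs in a fixed order:

1. :func:`drop_high_missing` — drop covariates with more than 90% missing;
2. :func:`drop_low_variance` — drop covariates where at least 90% of
   patients share one value;
3. record exclusion (age >= 20, inside the study window, not mostly empty);
4. :func:`impute` — column mean for numerical gaps, column mode for
   categorical ones.

:func:`encode_covariates` then turns everything numeric (0/1 for binary
variables, ordered integer scores for graded clinical categories) and
:func:`aggregate_monthly` collapses patients into one row per calendar
month: the case count y, monthly means of numerical covariates and monthly
positive-class proportions of binary ones.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Optional

import pandas as pd

__all__ = [
    "DEFAULT_ENCODING",
    "drop_high_missing",
    "drop_low_variance",
    "impute",
    "encode_covariates",
    "aggregate_monthly",
    "clean_patients",
]

logger = logging.getLogger(__name__)

#: columns that are identifiers/outcome bookkeeping, never filtered or encoded
PROTECTED_COLUMNS = ("patient_id", "diagnosis_date")

# Default encoding scheme.  Binary variables map their positive class to 1;
# graded numeric variables are cut at the clinical thresholds used by the
# generator and enter as ordered integer scores (one coefficient each).
DEFAULT_ENCODING: dict[str, dict] = {
    "gender": {"binary": {"Male": 1, "Female": 0}},
    "marital_status": {"binary": {"Married": 1, "Not Married": 0}},
    "nationality": {"binary": {"Saudi": 1, "Not Saudi": 0}},
    "occupation": {"binary": {"Employed": 1, "Not Employed": 0}},
    "smoking": {"binary": {"Yes": 1, "No": 0}},
    "physical_activity": {"binary": {"Yes": 1, "No": 0}},
    "food_type": {"binary": {"Healthy": 1, "Non healthy": 0}},
    "hypertension": {"binary": {"Yes": 1, "No": 0}},
    "age": {"bins": (20.0, 40.0, 60.0, 80.0, 105.0),
            "labels": {"20-39": 0, "40-59": 1, "60-79": 2, "80+": 3}},
    "bmi": {"bins": (12.0, 18.5, 25.0, 30.0, 60.0),
            "labels": {"Underweight": 0, "Normal weight": 1, "Overweight": 2, "Obese": 3}},
    "tc": {"bins": (2.0, 5.2, 6.2, 12.0),
           "labels": {"Normal": 0, "Moderately": 1, "High": 2}},
    "tg": {"bins": (0.3, 1.7, 2.2, 9.0),
           "labels": {"Normal": 0, "Moderately": 1, "High": 2}},
    "hdl": {"bins": (0.3, 1.0, 1.55, 3.5),
            "labels": {"Low": 0, "Good": 1, "High": 2}},
    "wbc": {"bins": (1.0, 4.0, 11.0, 30.0),
            "labels": {"Low": 0, "Good": 1, "High": 2}},
    "sbp": {"bins": (80.0, 120.0, 140.0, 220.0),
            "labels": {"Low": 0, "Good": 1, "High": 2}},
    "dbp": {"bins": (40.0, 80.0, 90.0, 130.0),
            "labels": {"Low": 0, "Good": 1, "High": 2}},
    "vitamin_d": {"bins": (3.0, 20.0, 30.0, 90.0),
                  "labels": {"Deficient": 0, "Insufficient": 1, "Sufficient": 2}},
    "ferritin": {"bins": (1.0, 30.0, 100.0, 700.0),
                 "labels": {"Deficient": 0, "Insufficient": 1, "Sufficient": 2}},
    # HbA1c stays continuous: the published design carries it as a plain
    # numeric predictor with no category bins.
    "hba1c": {"numeric": True},
}


def _covariate_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in PROTECTED_COLUMNS]


def drop_high_missing(table: pd.DataFrame, threshold: float = 0.90) -> pd.DataFrame:
    """Drop covariate columns whose missing fraction exceeds ``threshold``.

    The rule is strictly "over": a column missing exactly 90% is retained.
    """
    if table.empty:
        raise ValueError("empty table")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    frac = table[_covariate_columns(table)].isna().mean()
    dropped = list(frac.index[frac > threshold])
    for col in dropped:
        logger.info("dropping %r: %.1f%% missing", col, 100 * frac[col])
    return table.drop(columns=dropped)


def drop_low_variance(table: pd.DataFrame, threshold: float = 0.90) -> pd.DataFrame:
    """Drop covariate columns whose modal-value share reaches ``threshold``.

    The modal share is computed among observed (non-missing) values; a
    column where at least 90% of patients share one value is removed.
    """
    if table.empty:
        raise ValueError("empty table")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    dropped = []
    for col in _covariate_columns(table):
        observed = table[col].dropna()
        if observed.empty:
            continue
        share = observed.value_counts(normalize=True).iloc[0]
        if share >= threshold:
            dropped.append(col)
            logger.info("dropping %r: modal share %.1f%%", col, 100 * share)
    return table.drop(columns=dropped)


def impute(table: pd.DataFrame) -> pd.DataFrame:
    """Fill gaps: column mean for numeric columns, column mode for the rest.

    Mode ties are broken toward the lexicographically smallest category,
    with a warning.  A retained column with no observed value at all cannot
    be imputed and raises.
    """
    out = table.copy()
    for col in _covariate_columns(out):
        s = out[col]
        if not s.isna().any():
            continue
        if s.notna().sum() == 0:
            raise ValueError(f"column {col!r} has no observed values to impute from")
        if pd.api.types.is_numeric_dtype(s):
            out[col] = s.fillna(s.mean())
        else:
            counts = s.value_counts()
            top = counts[counts == counts.iloc[0]]
            if len(top) > 1:
                warnings.warn(
                    f"mode tie in {col!r} among {sorted(top.index)}; "
                    "using the lexicographically smallest",
                    stacklevel=2,
                )
            out[col] = s.fillna(sorted(top.index)[0])
    return out


def encode_covariates(
    records: pd.DataFrame, scheme: Optional[Mapping[str, Mapping]] = None
) -> pd.DataFrame:
    """Make every covariate numeric under ``scheme`` (default: study coding).

    Binary variables map to 0/1; graded variables map category labels (or
    raw numeric values, cut at the scheme's bin edges) to ordered integer
    scores.  An unseen category raises, naming the variable and the value.
    """
    scheme = DEFAULT_ENCODING if scheme is None else scheme
    out = records.copy()
    for col in _covariate_columns(out):
        if col not in scheme:
            raise ValueError(f"no encoding rule for variable {col!r}")
        rule = scheme[col]
        s = out[col]
        if rule.get("numeric"):
            out[col] = pd.to_numeric(s)
            continue
        if "binary" in rule:
            mapping = rule["binary"]
        else:
            mapping = rule["labels"]
            if pd.api.types.is_numeric_dtype(s):
                edges = rule["bins"]
                out[col] = pd.cut(
                    s, bins=edges, labels=False, right=False, include_lowest=True
                ).astype(float)
                oob = s.notna() & out[col].isna()
                if oob.any():
                    raise ValueError(
                        f"value {s[oob].iloc[0]!r} of variable {col!r} falls outside "
                        f"the bin range {edges[0]}..{edges[-1]}"
                    )
                continue
        mapped = s.map(mapping)
        bad = s.notna() & mapped.isna()
        if bad.any():
            raise ValueError(
                f"unseen category {s[bad].iloc[0]!r} for variable {col!r}"
            )
        out[col] = mapped.astype(float)
    return out


def aggregate_monthly(
    records: pd.DataFrame, window: tuple[str, str]
) -> pd.DataFrame:
    """Collapse encoded patient records to one row per calendar month.

    y is the number of diagnoses in the month; covariates are monthly means
    (which for 0/1 variables are exactly the positive-class proportions).
    Every month of ``window`` appears, including empty ones, whose y is 0
    and whose covariates carry the across-months mean so the design matrix
    stays complete.  Records outside the window raise.
    """
    if "diagnosis_date" not in records.columns:
        raise ValueError("records need a 'diagnosis_date' column")
    start = pd.Period(window[0], freq="M")
    end = pd.Period(window[1], freq="M")
    months = pd.period_range(start, end, freq="M")
    per = pd.PeriodIndex(pd.to_datetime(records["diagnosis_date"]), freq="M")
    if len(records) and (per.min() < start or per.max() > end):
        raise ValueError(
            f"window {window} does not cover all diagnosis dates "
            f"({per.min()}..{per.max()})"
        )
    covs = [c for c in _covariate_columns(records) if c != "diagnosis_date"]
    grouped = records[covs].groupby(per).mean()
    counts = pd.Series(per).value_counts().reindex(months, fill_value=0)
    agg = grouped.reindex(months)
    agg = agg.fillna(agg.mean())
    out = pd.DataFrame({"month": months.astype(str), "y": counts.to_numpy(dtype=int)})
    return pd.concat([out.reset_index(drop=True), agg.reset_index(drop=True)], axis=1)


def clean_patients(
    table: pd.DataFrame,
    window: Optional[tuple[str, str]] = None,
    missing_threshold: float = 0.90,
    variance_threshold: float = 0.90,
    record_missing_threshold: float = 0.5,
) -> pd.DataFrame:
    """Full cleaning pipeline: drop columns, exclude records, impute.

    Record exclusion drops patients younger than 20 (when age is observed),
    outside the study window (when one is given), or with more than
    ``record_missing_threshold`` of their covariates missing.
    """
    out = drop_high_missing(table, missing_threshold)
    out = drop_low_variance(out, variance_threshold)

    keep = pd.Series(True, index=out.index)
    if "age" in out.columns:
        keep &= out["age"].isna() | (out["age"] >= 20)
    if window is not None and "diagnosis_date" in out.columns:
        per = pd.PeriodIndex(pd.to_datetime(out["diagnosis_date"]), freq="M")
        keep &= (per >= pd.Period(window[0], freq="M")) & (
            per <= pd.Period(window[1], freq="M")
        )
    covs = _covariate_columns(out)
    keep &= out[covs].isna().mean(axis=1) <= record_missing_threshold
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("excluding %d records", n_dropped)
    return impute(out.loc[keep].reset_index(drop=True))
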