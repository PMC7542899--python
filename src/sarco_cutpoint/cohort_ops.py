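"""Cohort container, CSV I/O, matched splitting, descriptives and event rates.

A cohort is a pandas DataFrame with one row per patient and a fixed schema:
``id,sex,age,dm,cvd,albumin,height,weight,hgs,lmi,dialysis_duration,time,cause``.
Sex is coded ``M``/``F``; ``dm`` and ``cvd`` are 0/1; follow-up ``time`` is in
months and ``cause`` is the first event ending follow-up: ``death``,
``hd_transfer`` (transfer to hemodialysis), ``transplant``, ``lost`` (lost to
follow-up) or ``admin_censor`` (administratively censored at study end).
Unknown extra columns are carried through reads, writes and splits untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "REQUIRED_COLUMNS",
    "CAUSES",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "matched_split",
    "describe",
    "event_rates",
]

REQUIRED_COLUMNS = [
    "id",
    "sex",
    "age",
    "dm",
    "cvd",
    "albumin",
    "height",
    "weight",
    "hgs",
    "lmi",
    "dialysis_duration",
    "time",
    "cause",
]

CAUSES = ["death", "hd_transfer", "transplant", "lost", "admin_censor"]

_NUMERIC_COLUMNS = [
    "age",
    "dm",
    "cvd",
    "albumin",
    "height",
    "weight",
    "hgs",
    "lmi",
    "dialysis_duration",
    "time",
]

#: Model covariates that must be complete for Cox fitting.
MODEL_COVARIATES = ["age", "dm", "cvd", "albumin"]


@dataclass
class Cohort:
    """An ordered patient table plus a provenance label.

    ``data`` holds one row per patient with the schema above; ``label`` records
    where the cohort came from (``full``, ``development``, ``validation`` or
    ``synthetic``).
    """

    data: pd.DataFrame
    label: str = "full"

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing column: {', '.join(missing)}")
        if self.data["id"].duplicated().any():
            dupes = self.data.loc[self.data["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate patient ids: {dupes[:5]}")
        bad = set(self.data["cause"].dropna()) - set(CAUSES)
        if bad:
            raise ValueError(f"unknown cause values: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.data)

    def complete_cases(self, columns: list[str] | None = None) -> "Cohort":
        """Drop rows missing any of ``columns`` (default: model covariates),
        logging the excluded count."""
        cols = MODEL_COVARIATES if columns is None else columns
        keep = self.data[cols].notna().all(axis=1)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info(
                "excluded %d record(s) with missing values in %s", n_dropped, cols
            )
        return Cohort(self.data.loc[keep].reset_index(drop=True), self.label)


def read_cohort(path, label: str = "full") -> Cohort:
    """Read a cohort CSV, validating the schema.

    Missing values are empty fields.  An unparsable numeric cell raises a
    ``ValueError`` naming the row; a missing required column raises naming it.
    """
    df = pd.read_csv(path, dtype={"id": str, "sex": str, "cause": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column: {', '.join(missing)}")
    for col in _NUMERIC_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"unparsable value {df.loc[row, col]!r} in column {col!r}, row {row + 2}"
            )
        df[col] = coerced
    return Cohort(df, label)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to CSV (deterministic byte output for a given cohort)."""
    cohort.data.to_csv(path, index=False)


def matched_split(
    cohort: Cohort,
    dev_frac: float = 0.70,
    seed: int = 0,
) -> tuple[Cohort, Cohort]:
    """Random development/validation split matched on sex and diabetes.

    Within each of the four sex x DM strata, ``round(dev_frac * stratum size)``
    patients (round-half-up) go to the development cohort and the rest to the
    validation cohort, so both cohorts keep the sex and DM mix of the input.
    Membership is randomised by ``seed``; the per-stratum counts are not.
    """
    if not 0 < dev_frac < 1:
        raise ValueError(f"dev_frac must be in (0, 1), got {dev_frac}")
    df = cohort.data
    if df["sex"].isna().any() or df["dm"].isna().any():
        raise ValueError("matched_split requires non-missing sex and dm")
    rng = np.random.default_rng(seed)
    dev_idx: list[np.ndarray] = []
    val_idx: list[np.ndarray] = []
    # sorted group keys => deterministic stratum order regardless of row order
    for _, idx in sorted(df.groupby(["sex", "dm"]).groups.items()):
        idx = np.sort(np.asarray(idx))
        n_dev = int(np.floor(dev_frac * len(idx) + 0.5))  # round half up
        perm = rng.permutation(len(idx))
        dev_idx.append(idx[perm[:n_dev]])
        val_idx.append(idx[perm[n_dev:]])
    dev = df.loc[np.sort(np.concatenate(dev_idx))].reset_index(drop=True)
    val = df.loc[np.sort(np.concatenate(val_idx))].reset_index(drop=True)
    return Cohort(dev, "development"), Cohort(val, "validation")


#: Default variable typing for descriptive comparison, mirroring the usual
#: baseline table: normal continuous -> t test, skewed -> rank-sum,
#: categorical -> chi-square.
DEFAULT_VARIABLE_TYPES = {
    "age": "normal",
    "sex": "categorical",
    "dm": "categorical",
    "cvd": "categorical",
    "albumin": "normal",
    "height": "normal",
    "weight": "normal",
    "hgs": "normal",
    "lmi": "normal",
    "dialysis_duration": "skewed",
}


def describe(
    cohort_a: Cohort,
    cohort_b: Cohort,
    variable_types: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-variable summaries of two cohorts with between-cohort tests.

    Returns a table with one row per variable: summary strings per cohort
    (mean +/- SD, median (IQR) or n (%)) and the two-sided p-value from the
    t test, Wilcoxon rank-sum or Pearson chi-square as appropriate.
    An all-missing variable is summarised as missing with no test (p = NaN).
    """
    vtypes = DEFAULT_VARIABLE_TYPES if variable_types is None else variable_types
    rows = []
    for var, vtype in vtypes.items():
        a = cohort_a.data[var].dropna()
        b = cohort_b.data[var].dropna()
        if a.empty or b.empty:
            rows.append((var, vtype, "missing", "missing", np.nan))
            continue
        if vtype == "categorical":
            levels = sorted(set(a) | set(b))
            ca = a.value_counts().reindex(levels, fill_value=0)
            cb = b.value_counts().reindex(levels, fill_value=0)
            table = np.vstack([ca.to_numpy(), cb.to_numpy()])
            table = table[:, table.sum(axis=0) > 0]
            if table.shape[1] < 2:
                p = 1.0  # single level in both cohorts: no difference testable
            else:
                _, p, _, _ = stats.chi2_contingency(table, correction=False)
            top = levels[-1]
            sa = f"{int((a == top).sum())} ({100 * (a == top).mean():.1f}%)"
            sb = f"{int((b == top).sum())} ({100 * (b == top).mean():.1f}%)"
        elif vtype == "normal":
            _, p = stats.ttest_ind(a, b, equal_var=True)
            sa = f"{a.mean():.1f} ± {a.std(ddof=1):.1f}"
            sb = f"{b.mean():.1f} ± {b.std(ddof=1):.1f}"
        elif vtype == "skewed":
            _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            qa, qb = a.quantile([0.25, 0.5, 0.75]), b.quantile([0.25, 0.5, 0.75])
            sa = f"{qa[0.5]:.1f} ({qa[0.25]:.1f}, {qa[0.75]:.1f})"
            sb = f"{qb[0.5]:.1f} ({qb[0.25]:.1f}, {qb[0.75]:.1f})"
        else:
            raise ValueError(f"unknown variable type {vtype!r} for {var!r}")
        rows.append((var, vtype, sa, sb, float(p)))
    return pd.DataFrame(
        rows,
        columns=["variable", "type", cohort_a.label, cohort_b.label, "p_value"],
    )


def event_rates(cohort: Cohort) -> pd.DataFrame:
    """Per-cause event counts and rates per 100 person-years.

    Follow-up is stored in months; person-years are total months / 12.  The
    denominator for every cause is the full cohort person-time, the standard
    cause-specific incidence-rate convention.
    """
    total_months = cohort.data["time"].sum()
    if not total_months > 0:
        raise ValueError("total follow-up time is zero")
    person_years = total_months / 12.0
    counts = cohort.data["cause"].value_counts()
    rows = [
        (
            cause,
            int(counts.get(cause, 0)),
            100.0 * counts.get(cause, 0) / person_years,
        )
        for cause in CAUSES
    ]
    out = pd.DataFrame(rows, columns=["cause", "events", "rate_per_100py"])
    out.attrs["person_years"] = person_years
    return out
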