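"""Validation of derived cut-offs on a held-out cohort.

Patients are dichotomized at sex-specific exposure cut-offs (strictly below =
low), low-vs-high and four-group (HGS x LMI) cause-specific Cox models are
fitted unadjusted (Model 1) and adjusted for age, DM, CVD and albumin
(Model 2), and each patient's vital status is predicted from their fitted
survival function S_i(t_i) evaluated at their own follow-up time (predict
death when S_i(t_i) <= 0.5).  Predicted and observed status are compared by
absolute agreement and Cohen's kappa, for the derived cut-offs and for the
handgrip cut-offs published by the sarcopenia consensus groups (EWGSOP 2010
and 2019, AWGS, FNIH).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_ops import MODEL_COVARIATES, Cohort
from .spline_cox import CoxModel, CutoffPair, fit_cox

logger = logging.getLogger(__name__)

__all__ = [
    "GuidelineSet",
    "GUIDELINES",
    "AgreementReport",
    "dichotomize",
    "four_group_labels",
    "group_cox",
    "classify_outcomes",
    "agreement_kappa",
    "compare_cutoff_sets",
]

_Z = 1.959963984540054


@dataclass(frozen=True)
class GuidelineSet:
    """A consensus-guideline pair of handgrip-strength cut-offs (kg, male/female)."""

    name: str
    male: float
    female: float
    exposure: str = "hgs"

    def __post_init__(self) -> None:
        if not (self.male > 0 and self.female > 0):
            raise ValueError("guideline cutoffs must be positive")

    def for_sex(self, sex: str) -> float:
        return self.male if sex == "M" else self.female


#: Published HGS cut-offs (kg male / kg female) from sarcopenia guidelines.
GUIDELINES = [
    GuidelineSet("EWGSOP2019", 27.0, 16.0),
    GuidelineSet("AWGS", 26.0, 18.0),
    GuidelineSet("FNIH", 26.0, 16.0),
    GuidelineSet("EWGSOP2010", 30.0, 20.0),
]


def dichotomize(cohort: Cohort, cutoffs: CutoffPair | GuidelineSet) -> pd.Series:
    """Label each patient ``low``/``high`` at the sex-specific cut-off.

    Low means exposure strictly below the cut-off for the patient's sex (the
    reference group is defined as >= cut-off).  Patients missing the exposure
    are excluded (NaN label) with a logged count; a null cut-off for a sex
    labels that whole sex NaN.
    """
    exposure = cutoffs.exposure
    df = cohort.data
    cut = df["sex"].map(
        {"M": cutoffs.for_sex("M"), "F": cutoffs.for_sex("F")}
    ).astype(float)
    x = df[exposure]
    n_missing = int((x.isna() | cut.isna()).sum())
    if n_missing:
        logger.info("dichotomize: excluded %d record(s) without %s", n_missing, exposure)
    labels = pd.Series(
        np.where(x < cut, "low", "high"), index=df.index, dtype="object"
    )
    labels[x.isna() | cut.isna()] = np.nan
    return labels


def four_group_labels(
    cohort: Cohort, hgs_cutoffs: CutoffPair, lmi_cutoffs: CutoffPair
) -> pd.Series:
    """Joint HGS x LMI groups: both_high (reference), lmi_low_only,
    hgs_low_only, both_low."""
    hgs_labels = dichotomize(cohort, hgs_cutoffs)
    lmi_labels = dichotomize(cohort, lmi_cutoffs)
    hgs_low, lmi_low = hgs_labels == "low", lmi_labels == "low"
    out = pd.Series(np.nan, index=cohort.data.index, dtype="object")
    valid = hgs_labels.notna() & lmi_labels.notna()
    out[valid & ~hgs_low & ~lmi_low] = "both_high"
    out[valid & ~hgs_low & lmi_low] = "lmi_low_only"
    out[valid & hgs_low & ~lmi_low] = "hgs_low_only"
    out[valid & hgs_low & lmi_low] = "both_low"
    return out


def _design(df: pd.DataFrame, labels: pd.Series, reference: str, adjusters):
    groups = [g for g in pd.unique(labels.dropna()) if g != reference]
    X = pd.DataFrame(index=df.index)
    for g in sorted(groups):
        X[f"group_{g}"] = (labels == g).astype(float)
    for a in adjusters:
        X[a] = df[a].astype(float)
    return X


def group_cox(
    cohort: Cohort,
    labels: pd.Series,
    reference: str = "high",
    adjusters: list[str] | None = None,
    ties: str = "breslow",
) -> pd.DataFrame:
    """Low-vs-high (or multi-group) cause-specific Cox models for death.

    Fits Model 1 (group indicators only) and Model 2 (plus adjusters,
    default age/DM/CVD/albumin) and returns HR with Wald 95% CI per
    non-reference group.  Groups with no members are dropped with a warning;
    the reference group must be non-empty with at least one death.
    """
    adjusters = MODEL_COVARIATES if adjusters is None else list(adjusters)
    keep = labels.notna()
    df = cohort.data.loc[keep]
    labels = labels.loc[keep]
    ref_mask = labels == reference
    if not ref_mask.any():
        raise ValueError(f"reference group {reference!r} is empty")
    if (df.loc[ref_mask, "cause"] == "death").sum() < 1:
        raise ValueError(f"reference group {reference!r} has no deaths")
    events = (df["cause"] == "death").to_numpy(dtype=int)
    rows = []
    for model_name, cols in (("model1", []), ("model2", adjusters)):
        X = _design(df, labels, reference, cols)
        fitted = fit_cox(df["time"], events, X, ties=ties)
        hrs = fitted.hazard_ratios()
        for col in X.columns:
            if not col.startswith("group_"):
                continue
            rows.append(
                {
                    "group": col.removeprefix("group_"),
                    "model": model_name,
                    "n": int((labels == col.removeprefix("group_")).sum()),
                    "hr": float(hrs.loc[col, "hr"]),
                    "hr_lo": float(hrs.loc[col, "hr_lo"]),
                    "hr_hi": float(hrs.loc[col, "hr_hi"]),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["reference"] = reference
    out.attrs["n_reference"] = int(ref_mask.sum())
    return out


def classify_outcomes(
    model: CoxModel,
    X: pd.DataFrame,
    times,
    threshold: float = 0.5,
) -> pd.Series:
    """Predict each patient's vital status from their fitted survival function.

    Evaluates S_i(t_i) = exp(-H0(t_i) exp(x_i' beta)) at the patient's own
    follow-up time (baseline hazard carried forward beyond the last event
    time) and predicts ``death`` when S_i(t_i) <= ``threshold``, else
    ``survive``.
    """
    surv = model.survival_at(X, np.asarray(times, dtype=float))
    return pd.Series(
        np.where(surv <= threshold, "death", "survive"), index=X.index, dtype="object"
    )


@dataclass
class AgreementReport:
    """Predicted-vs-observed agreement for binary death/survive labels.

    ``a`` counts predicted-death & observed-death, ``b`` predicted-death &
    observed-survive, ``c`` predicted-survive & observed-death, ``d`` both
    survive.  ``kappa_se`` uses the Fleiss–Cohen–Everitt asymptotic variance;
    a degenerate chance agreement (p_e = 1) leaves kappa NaN.
    """

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def agreement_pct(self) -> float:
        return 100.0 * (self.a + self.d) / self.n

    @property
    def kappa(self) -> float:
        po, pe = self._po_pe()
        if pe == 1.0:
            return float("nan")
        return (po - pe) / (1.0 - pe)

    def _po_pe(self) -> tuple[float, float]:
        n = self.n
        po = (self.a + self.d) / n
        row1, row2 = (self.a + self.b) / n, (self.c + self.d) / n
        col1, col2 = (self.a + self.c) / n, (self.b + self.d) / n
        return po, row1 * col1 + row2 * col2

    @property
    def kappa_se(self) -> float:
        # Fleiss, Cohen & Everitt (1969) large-sample variance of kappa
        n = self.n
        _, pe = self._po_pe()
        if pe == 1.0:
            return float("nan")
        k = self.kappa
        p = np.array([[self.a, self.b], [self.c, self.d]], dtype=float) / n
        prow = p.sum(axis=1)
        pcol = p.sum(axis=0)
        term_a = sum(
            p[i, i] * (1.0 - (prow[i] + pcol[i]) * (1.0 - k)) ** 2 for i in range(2)
        )
        term_b = (1.0 - k) ** 2 * sum(
            p[i, j] * (pcol[i] + prow[j]) ** 2
            for i in range(2)
            for j in range(2)
            if i != j
        )
        term_c = (k - pe * (1.0 - k)) ** 2
        var = (term_a + term_b - term_c) / (n * (1.0 - pe) ** 2)
        return float(np.sqrt(max(var, 0.0)))

    @property
    def kappa_ci(self) -> tuple[float, float]:
        k, se = self.kappa, self.kappa_se
        return (k - _Z * se, k + _Z * se)

    def to_dict(self) -> dict:
        lo, hi = self.kappa_ci
        return {
            "n": self.n,
            "confusion": {"a": self.a, "b": self.b, "c": self.c, "d": self.d},
            "agreement_pct": self.agreement_pct,
            "kappa": self.kappa,
            "kappa_ci": [lo, hi],
        }


def agreement_kappa(predicted, observed) -> AgreementReport:
    """Absolute agreement and Cohen's kappa between predicted and observed
    death/survive labels (same length, labels in {'death', 'survive'})."""
    predicted = np.asarray(predicted, dtype=object)
    observed = np.asarray(observed, dtype=object)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have the same length")
    valid = {"death", "survive"}
    bad = (set(predicted) | set(observed)) - valid
    if bad:
        raise ValueError(f"labels must be in {sorted(valid)}, got {sorted(bad)}")
    pd_, od = predicted == "death", observed == "death"
    return AgreementReport(
        a=int((pd_ & od).sum()),
        b=int((pd_ & ~od).sum()),
        c=int((~pd_ & od).sum()),
        d=int((~pd_ & ~od).sum()),
    )


def _agreement_for_labels(
    cohort: Cohort,
    low: pd.Series,
    adjusters: list[str],
    ties: str,
    threshold: float,
) -> AgreementReport:
    keep = low.notna()
    df = cohort.data.loc[keep]
    events = (df["cause"] == "death").to_numpy(dtype=int)
    X = pd.DataFrame({"low": (low.loc[keep] == "low").astype(float)}, index=df.index)
    X[adjusters] = df[adjusters].astype(float)
    model = fit_cox(df["time"], events, X, ties=ties)
    predicted = classify_outcomes(model, X, df["time"], threshold=threshold)
    observed = pd.Series(
        np.where(df["cause"] == "death", "death", "survive"),
        index=df.index,
        dtype="object",
    )
    return agreement_kappa(predicted, observed)


def compare_cutoff_sets(
    validation: Cohort,
    sets: list[tuple[str, CutoffPair | GuidelineSet]],
    adjusters: list[str] | None = None,
    ties: str = "breslow",
    threshold: float = 0.5,
    combined: tuple[CutoffPair, CutoffPair] | None = None,
) -> pd.DataFrame:
    """Agreement-rate comparison across cut-off sets on the validation cohort.

    For each named set: dichotomize, fit the adjusted (Model 2) cause-specific
    Cox model on the low indicator, classify outcomes from the fitted survival
    functions and score agreement/kappa against observed status.  Rows keep
    the supplied order.  ``combined`` adds a final row in which low means
    below both the HGS and the LMI cut-off.  Deterministic given the cohort.
    """
    adjusters = MODEL_COVARIATES if adjusters is None else list(adjusters)
    cohort = validation.complete_cases(["time", "cause", *adjusters])
    rows = []

    def add_row(name: str, low: pd.Series) -> None:
        rep = _agreement_for_labels(cohort, low, adjusters, ties, threshold)
        lo, hi = rep.kappa_ci
        rows.append(
            {
                "name": name,
                "percent_low": 100.0 * float((low == "low").mean()),
                "agreement_pct": rep.agreement_pct,
                "kappa": rep.kappa,
                "kappa_lo": lo,
                "kappa_hi": hi,
            }
        )

    for name, cutoffs in sets:
        add_row(name, dichotomize(cohort, cutoffs))
    if combined is not None:
        hgs_pair, lmi_pair = combined
        both_low = (dichotomize(cohort, hgs_pair) == "low") & (
            dichotomize(cohort, lmi_pair) == "low"
        )
        add_row(
            "combined_hgs_lmi",
            pd.Series(
                np.where(both_low, "low", "high"), index=cohort.data.index,
                dtype="object",
            ),
        )
    return pd.DataFrame(rows)
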