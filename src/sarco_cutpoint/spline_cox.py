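"""Restricted cubic spline Cox models and prognostic cut-off derivation.

The exposure–mortality relationship is modelled with a Cox proportional-
hazards model whose exposure term is a restricted (natural) cubic spline:
piecewise cubic between the knots, constrained to be linear beyond the outer
knots.  Four knots at the 20/40/60/80th percentiles of the fitting sample give
a 3-column basis (one linear plus two constrained-cubic terms).  The fitted
spline block yields a hazard-ratio curve over the central 5–95% of the
exposure distribution, relative to a reference exposure (the sample median),
with pointwise delta-method confidence bands.  The prognostic cut-off is read
off this curve (see :func:`find_cutoff`): after confirming the hazard is
significantly elevated somewhere at low exposure, the default read-out is the
exposure at which the excess log hazard falls to half its low-exposure
plateau — the midpoint of the smoothed risk transition; a pure
loss-of-significance read-out is available as an alternative method.

Cox fitting is delegated to :class:`statsmodels.duration.hazard_regression.PHReg`
(Breslow or Efron ties; covariance from the inverse observed information);
the right-continuous Breslow baseline cumulative hazard is computed from the
fitted coefficients so per-patient survival functions include the jump at the
patient's own event time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.duration.hazard_regression import PHReg

from .cohort_ops import MODEL_COVARIATES, Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "SplineSpec",
    "CoxModel",
    "HazardCurve",
    "CutoffPair",
    "ConvergenceError",
    "rcs_basis",
    "fit_cox",
    "hazard_curve",
    "find_cutoff",
    "derive_cutoffs",
]


class ConvergenceError(RuntimeError):
    """Partial-likelihood maximisation failed (e.g. monotone likelihood)."""


@dataclass(frozen=True)
class SplineSpec:
    """Knot placement and evaluation window for a restricted cubic spline.

    ``knots`` are the complete knot set (default: 20/40/60/80th percentiles of
    the fitting sample); ``window`` is the exposure range over which hazard
    curves are evaluated (default 5th–95th percentile, avoiding extrapolation
    from extreme values); ``grid_step`` is the curve resolution in exposure
    units (0.1 matches the precision at which cut-offs are reported).
    """

    knots: tuple[float, ...]
    window: tuple[float, float]
    grid_step: float = 0.1

    def __post_init__(self) -> None:
        k = np.asarray(self.knots, dtype=float)
        if k.size < 3:
            raise ValueError("need at least 3 knots")
        if not np.all(np.diff(k) > 0):
            raise ValueError(f"knots must be strictly increasing, got {self.knots}")
        lo, hi = self.window
        if not (lo <= k[0] and k[-1] <= hi):
            raise ValueError("window must contain all knots")
        if not self.grid_step > 0:
            raise ValueError("grid_step must be positive")

    @classmethod
    def from_sample(
        cls,
        x,
        knot_quantiles: tuple[float, ...] = (0.20, 0.40, 0.60, 0.80),
        window_quantiles: tuple[float, float] = (0.05, 0.95),
        grid_step: float = 0.1,
    ) -> "SplineSpec":
        x = np.asarray(x, dtype=float)
        x = x[np.isfinite(x)]
        knots = tuple(np.quantile(x, knot_quantiles))
        window = tuple(np.quantile(x, window_quantiles))
        return cls(knots=knots, window=window, grid_step=grid_step)

    @property
    def n_basis(self) -> int:
        return len(self.knots) - 1


def rcs_basis(x, spec: SplineSpec) -> np.ndarray:
    """Restricted-cubic-spline basis matrix (k-1 columns for k knots).

    Column 0 is the identity; column j (j >= 1) is the standard natural-spline
    construction: truncated cubics combined so the function is linear beyond
    both outer knots, scaled by the squared knot span for numeric balance.
    Values outside the knot range extrapolate linearly.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(spec.knots, dtype=float)
    k = t.size
    scale = (t[-1] - t[0]) ** 2

    def pos3(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        c = (
            pos3(x - t[j])
            - pos3(x - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
            + pos3(x - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2])
        ) / scale
        cols.append(c)
    return np.column_stack(cols)


@dataclass
class CoxModel:
    """A fitted Cox proportional-hazards model.

    ``coef``/``cov`` are indexed by design-column name; ``baseline_times`` and
    ``baseline_cumhaz`` hold the Breslow baseline cumulative-hazard step
    function (0 before the first event time, last value carried forward).
    """

    coef: pd.Series
    cov: pd.DataFrame
    ties: str
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    n: int
    n_events: int

    @property
    def columns(self) -> list[str]:
        return list(self.coef.index)

    def cumulative_baseline_hazard(self, times) -> np.ndarray:
        """Baseline cumulative hazard at arbitrary times (step interpolation)."""
        times = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.baseline_times, times, side="right") - 1
        out = np.where(idx >= 0, self.baseline_cumhaz[np.clip(idx, 0, None)], 0.0)
        return out

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        return X[self.columns].to_numpy(dtype=float) @ self.coef.to_numpy()

    def survival_at(self, X: pd.DataFrame, times) -> np.ndarray:
        """Per-subject survival probability S_i(t_i) = exp(-H0(t_i) e^{x_i b})."""
        h0 = self.cumulative_baseline_hazard(times)
        return np.exp(-h0 * np.exp(self.linear_predictor(X)))

    def hazard_ratios(self) -> pd.DataFrame:
        """exp(coef) with Wald 95% CI per design column."""
        se = np.sqrt(np.diag(self.cov.to_numpy()))
        return pd.DataFrame(
            {
                "coef": self.coef,
                "hr": np.exp(self.coef),
                "hr_lo": np.exp(self.coef - 1.959963984540054 * se),
                "hr_hi": np.exp(self.coef + 1.959963984540054 * se),
                "se": se,
            }
        )


def fit_cox(
    times,
    events,
    X: pd.DataFrame,
    ties: str = "breslow",
) -> CoxModel:
    """Fit a Cox model by partial-likelihood maximisation.

    ``times`` are follow-up durations, ``events`` the event indicator (1 =
    event, 0 = censored), ``X`` the design matrix (named columns).  Ties are
    handled by Breslow's (default) or Efron's approximation.  Raises
    :class:`ConvergenceError` on monotone likelihood (perfect separation),
    naming the offending column, and ``ValueError`` for a constant column or a
    dataset with no events.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError(f"ties must be 'breslow' or 'efron', got {ties!r}")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 1:
        raise ValueError("need at least one event to fit a Cox model")
    Xv = X.to_numpy(dtype=float)
    const = [c for c, v in zip(X.columns, Xv.T) if np.ptp(v) == 0]
    if const:
        raise ValueError(f"constant column(s) in design: {const}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # PHReg warns en route to our own check
        model = PHReg(times, Xv, status=events, ties=ties)
        try:
            res = model.fit(disp=False)
        except Exception as exc:  # singular information etc.
            raise ConvergenceError(f"Cox fit failed: {exc}") from exc

    params = np.asarray(res.params, dtype=float)
    cov = np.asarray(res.cov_params(), dtype=float)
    sds = Xv.std(axis=0)
    standardized = np.abs(params) * np.where(sds > 0, sds, 1.0)
    if (not np.all(np.isfinite(params))) or (not np.all(np.isfinite(cov))) or np.any(
        standardized > 50
    ):
        worst = X.columns[int(np.nanargmax(standardized))]
        raise ConvergenceError(
            f"monotone partial likelihood (perfect separation) in column {worst!r}"
        )

    # Breslow baseline cumulative hazard, right-continuous (jumps included at
    # their own event time): H0(t) = sum_{t_j <= t} d_j / sum_{i in R(t_j)} e^eta_i
    eta = Xv @ params
    order = np.argsort(times, kind="stable")
    st = times[order]
    suffix = np.cumsum(np.exp(eta[order])[::-1])[::-1]  # sum over risk set at st[i]
    bt, d = np.unique(times[events == 1], return_counts=True)
    denom = suffix[np.searchsorted(st, bt, side="left")]
    bch = np.cumsum(d / denom)
    return CoxModel(
        coef=pd.Series(params, index=list(X.columns)),
        cov=pd.DataFrame(cov, index=list(X.columns), columns=list(X.columns)),
        ties=ties,
        baseline_times=bt,
        baseline_cumhaz=bch,
        n=len(times),
        n_events=int(events.sum()),
    )


@dataclass
class HazardCurve:
    """Hazard-ratio curve over an exposure grid, relative to a reference.

    ``hr`` and the pointwise 95% bounds are relative to ``reference`` (where
    HR = 1 exactly with zero standard error).
    """

    grid: np.ndarray
    log_hr: np.ndarray
    se: np.ndarray
    reference: float
    sex: str | None = None

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.log_hr)

    @property
    def lower(self) -> np.ndarray:
        return np.exp(self.log_hr - 1.959963984540054 * self.se)

    @property
    def upper(self) -> np.ndarray:
        return np.exp(self.log_hr + 1.959963984540054 * self.se)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "exposure": self.grid,
                "hr": self.hr,
                "hr_lo": self.lower,
                "hr_hi": self.upper,
            }
        )


def hazard_curve(
    model: CoxModel,
    spec: SplineSpec,
    reference: float,
    spline_columns: list[str] | None = None,
    sex: str | None = None,
) -> HazardCurve:
    """Hazard-ratio curve of a spline Cox model over the evaluation window.

    For each grid exposure x, log HR = (basis(x) - basis(reference)) . beta
    over the spline block; the pointwise variance follows by the delta method
    from the spline-block covariance.  The reference must lie inside the
    window and is inserted into the grid so HR(reference) = 1 appears exactly.
    """
    lo, hi = spec.window
    if not lo <= reference <= hi:
        raise ValueError(
            f"reference {reference} outside evaluation window [{lo}, {hi}]"
        )
    if spline_columns is None:
        spline_columns = model.columns[: spec.n_basis]
    grid = np.arange(lo, hi + spec.grid_step / 2, spec.grid_step)
    grid = np.unique(np.append(grid, reference))
    beta = model.coef[spline_columns].to_numpy()
    sigma = model.cov.loc[spline_columns, spline_columns].to_numpy()
    d = rcs_basis(grid, spec) - rcs_basis(np.array([reference]), spec)
    log_hr = d @ beta
    var = np.einsum("ij,jk,ik->i", d, sigma, d)
    se = np.sqrt(np.clip(var, 0.0, None))
    return HazardCurve(grid=grid, log_hr=log_hr, se=se, reference=reference, sex=sex)


def find_cutoff(
    curve: HazardCurve,
    method: str = "half_height",
    plateau_frac: float = 0.10,
) -> float | None:
    """Prognostic cut-off from a hazard-ratio curve.

    Both methods first require a significantly elevated low-exposure region:
    if no grid point has its pointwise lower 95% bound above 1, there is no
    cut-off and None is returned (a flat null curve yields None).

    ``half_height`` (default) locates the exposure at which the fitted
    log hazard ratio first drops below half its low-exposure plateau value
    (the mean log HR over the lowest ``plateau_frac`` of the grid).  For a
    threshold-like risk profile the half-height crossing sits at the middle
    of the smoothed transition, so it estimates the underlying threshold
    without the power-dependent drift of a significance-based read-out.

    ``significance`` returns the largest grid exposure x* such that every
    grid point below x* has its lower 95% bound above 1 — the point where
    the significantly elevated hazard stops being significant, scanning
    upward.  Because HR(reference) = 1 exactly, this read-out can never
    exceed the reference and, as power grows, migrates toward it.
    """
    sig = curve.lower > 1.0
    if not sig.any():
        return None
    if method == "significance":
        run_end = int(np.argmin(sig)) if not sig.all() else len(sig)
        if run_end == 0:
            # lowest grid point already non-significant: vacuous prefix only
            return float(curve.grid[0])
        if run_end == len(sig):
            return float(curve.grid[-1])
        return float(curve.grid[run_end])
    if method != "half_height":
        raise ValueError(f"unknown cut-off method {method!r}")
    k = max(3, int(round(plateau_frac * len(curve.grid))))
    plateau = float(curve.log_hr[:k].mean())
    if plateau <= 0:
        return None  # hazard not elevated at low exposure
    below = curve.log_hr < 0.5 * plateau
    if not below.any():
        return float(curve.grid[-1])  # elevation persists to the window edge
    return float(curve.grid[int(np.argmax(below))])


@dataclass
class CutoffPair:
    """Sex-specific prognostic thresholds for one exposure."""

    exposure: str
    male: float | None
    female: float | None
    units: str
    provenance: dict = field(default_factory=dict)

    def for_sex(self, sex: str) -> float | None:
        return self.male if sex == "M" else self.female


_UNITS = {"hgs": "kg", "lmi": "kg/m^2"}


def derive_cutoffs(
    development: Cohort,
    exposure: str,
    adjusters: list[str] | None = None,
    ties: str = "breslow",
    grid_step: float = 0.1,
    min_events: int = 30,
    cutoff_method: str = "half_height",
) -> CutoffPair:
    """Derive sex-specific mortality cut-offs for an exposure.

    Per sex: place spline knots on that sex's exposure distribution, fit a
    cause-specific Cox model (death is the event; all other causes censor)
    with the exposure spline plus the adjustment covariates, compute the
    adjusted hazard-ratio curve relative to the sex-specific median, and read
    the cut-off off the curve with :func:`find_cutoff`.  A sex stratum with
    fewer than ``min_events`` deaths yields a null cut-off with a warning.
    Deterministic given the cohort and grid step.
    """
    if exposure not in _UNITS:
        raise ValueError(f"exposure must be one of {sorted(_UNITS)}, got {exposure!r}")
    adjusters = MODEL_COVARIATES if adjusters is None else list(adjusters)
    cohort = development.complete_cases([exposure, "sex", "time", "cause", *adjusters])
    cutoffs: dict[str, float | None] = {}
    provenance: dict = {
        "exposure": exposure,
        "ties": ties,
        "grid_step": grid_step,
        "cutoff_method": cutoff_method,
    }
    for sex in ("M", "F"):
        sub = cohort.data[cohort.data["sex"] == sex]
        events = (sub["cause"] == "death").to_numpy(dtype=int)
        if events.sum() < min_events:
            warnings.warn(
                f"only {events.sum()} death(s) among sex={sex}; "
                f"need >= {min_events} for a cut-off",
                stacklevel=2,
            )
            cutoffs[sex] = None
            provenance[sex] = {"n": len(sub), "events": int(events.sum())}
            continue
        x = sub[exposure].to_numpy(dtype=float)
        spec = SplineSpec.from_sample(x, grid_step=grid_step)
        basis = rcs_basis(x, spec)
        spline_cols = [f"{exposure}_rcs{j}" for j in range(spec.n_basis)]
        X = pd.DataFrame(basis, columns=spline_cols, index=sub.index)
        X[adjusters] = sub[adjusters]
        model = fit_cox(sub["time"], events, X, ties=ties)
        reference = float(np.median(x))
        curve = hazard_curve(model, spec, reference, spline_cols, sex=sex)
        cutoffs[sex] = find_cutoff(curve, method=cutoff_method)
        provenance[sex] = {
            "n": len(sub),
            "events": int(events.sum()),
            "knots": list(spec.knots),
            "window": list(spec.window),
            "reference": reference,
        }
    return CutoffPair(
        exposure=exposure,
        male=cutoffs["M"],
        female=cutoffs["F"],
        units=_UNITS[exposure],
        provenance=provenance,
    )
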