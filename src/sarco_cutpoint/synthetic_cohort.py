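"""Synthetic peritoneal-dialysis cohorts with covariate-dependent mortality.

No patient-level data accompany the published cohort, so this module generates
cohorts that reproduce its aggregate structure: the baseline covariate
distributions (sex mix, age, diabetes, cardiovascular disease, albumin,
anthropometry, handgrip strength and lean mass index), a death hazard driven
by the published adjusted log-hazard coefficients, and competing events
(transfer to hemodialysis, transplantation, loss to follow-up) at the
published constant rates per 100 person-years.

Two death-hazard modes are supported:

* proportional — log-linear in the covariates (age, DM, CVD, albumin and one
  exposure, HGS or LMI), the data-generating analogue of the adjusted Cox
  model used for derivation;
* step — a known-threshold ground truth: the hazard is a constant multiplied
  by ``hr_below`` whenever the exposure is below a sex-specific cut-off.
  This mode is the test bed for cut-off recovery studies.

Event times per cause are independent exponentials (constant cause-specific
hazards match the published constant event rates with minimal assumptions);
the earliest time wins, with administrative censoring at a fixed horizon.
The baseline death hazard is calibrated numerically on the realised
covariates so the marginal death rate matches the target (11.1 per 100
person-years by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort_ops import Cohort

__all__ = [
    "SexStats",
    "SimulationParams",
    "StepHazardSpec",
    "generate_covariates",
    "generate_outcomes",
    "generate_cohort",
]


@dataclass(frozen=True)
class SexStats:
    """Mean/SD of a continuous covariate conditional on sex."""

    male_mean: float
    male_sd: float
    female_mean: float
    female_sd: float


@dataclass(frozen=True)
class StepHazardSpec:
    """Known-threshold death hazard: HR ``hr_below`` when exposure < cut-off."""

    exposure: str = "hgs"
    cutoff_male: float = 24.5
    cutoff_female: float = 14.0
    hr_below: float = 2.0

    def __post_init__(self) -> None:
        if self.exposure not in ("hgs", "lmi"):
            raise ValueError(f"exposure must be 'hgs' or 'lmi', got {self.exposure!r}")
        if not self.hr_below > 0:
            raise ValueError(f"hr_below must be positive, got {self.hr_below}")


@dataclass(frozen=True)
class SimulationParams:
    """Generating parameters for a synthetic PD cohort.

    Covariate moments follow the published development-cohort baseline table;
    sex-conditional means for height, weight, HGS and LMI are chosen so the
    pooled moments match the published pooled ones (only pooled values are
    reported, but the sexes must differ for sex-specific cut-offs to exist).
    Log-hazard coefficients are the published adjusted Cox estimates; event
    rates are per 100 person-years.
    """

    n: int = 1000
    seed: int = 0
    male_frac: float = 0.508
    dm_frac: float = 0.389
    cvd_frac: float = 0.395
    age_mean: float = 56.5
    age_sd: float = 15.2
    age_bounds: tuple[float, float] = (18.0, 95.0)
    albumin_mean: float = 35.6
    albumin_sd: float = 4.6
    albumin_bounds: tuple[float, float] = (15.0, 55.0)
    height: SexStats = SexStats(170.3, 6.0, 158.0, 6.0)
    weight: SexStats = SexStats(67.0, 11.0, 57.0, 11.0)
    hgs: SexStats = SexStats(29.0, 8.0, 15.0, 8.0)  # pooled ~22.0 +/- 10.6
    lmi: SexStats = SexStats(16.6, 1.5, 14.6, 1.5)  # pooled ~15.6 +/- 1.8
    duration_mean: float = 2.0
    duration_sd: float = 0.8
    # adjusted log-hazard coefficients for death
    beta_age: float = 0.039
    beta_dm: float = 0.395
    beta_cvd: float = 0.454
    beta_albumin: float = -0.002
    beta_hgs: float = -0.027
    beta_lmi: float = -0.093
    exposure: str = "hgs"  # which exposure drives the proportional hazard
    death_rate_target: float = 11.1  # per 100 person-years, marginal
    hd_transfer_rate: float = 4.3
    transplant_rate: float = 3.1
    lost_rate: float = 0.7
    admin_horizon: float = 120.0  # months

    def __post_init__(self) -> None:
        for name in ("male_frac", "dm_frac", "cvd_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("age_sd", "albumin_sd", "duration_sd"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("death_rate_target", "hd_transfer_rate", "transplant_rate",
                     "lost_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.exposure not in ("hgs", "lmi"):
            raise ValueError(f"exposure must be 'hgs' or 'lmi', got {self.exposure!r}")
        if not self.admin_horizon > 0:
            raise ValueError("admin_horizon must be positive")


def _truncnorm(rng, mean, sd, lower=-np.inf, upper=np.inf, size=1):
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _by_sex(rng, male, ss: SexStats, lower=-np.inf, upper=np.inf):
    out = np.empty(male.size)
    out[male] = _truncnorm(rng, ss.male_mean, ss.male_sd, lower, upper, male.sum())
    out[~male] = _truncnorm(
        rng, ss.female_mean, ss.female_sd, lower, upper, (~male).sum()
    )
    return out


def generate_covariates(params: SimulationParams) -> Cohort:
    """Draw baseline covariates for ``params.n`` patients.

    Sex, DM and CVD are Bernoulli; continuous covariates are truncated
    normals (physiologic floors prevent impossible draws); height, weight,
    HGS and LMI are drawn conditional on sex.  Follow-up ``time`` and
    ``cause`` are left empty — fill them with :func:`generate_outcomes`.
    Identical params give bit-identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 1)))
    n = params.n
    male = rng.random(n) < params.male_frac
    df = pd.DataFrame(
        {
            "id": [f"S{i:06d}" for i in range(n)],
            "sex": np.where(male, "M", "F"),
            "age": _truncnorm(
                rng, params.age_mean, params.age_sd, *params.age_bounds, size=n
            ),
            "dm": (rng.random(n) < params.dm_frac).astype(int),
            "cvd": (rng.random(n) < params.cvd_frac).astype(int),
            "albumin": _truncnorm(
                rng, params.albumin_mean, params.albumin_sd,
                *params.albumin_bounds, size=n
            ),
            "height": _by_sex(rng, male, params.height, 130.0, 200.0),
            "weight": _by_sex(rng, male, params.weight, 30.0, 150.0),
            "hgs": _by_sex(rng, male, params.hgs, 0.0, np.inf),
            "lmi": _by_sex(rng, male, params.lmi, 5.0, np.inf),
            "dialysis_duration": _truncnorm(
                rng, params.duration_mean, params.duration_sd, 0.0, np.inf, size=n
            ),
            "time": np.nan,
            "cause": pd.Series([pd.NA] * n, dtype="object"),
        }
    )
    return Cohort(df, "synthetic")


def _death_log_relative_hazard(
    df: pd.DataFrame, params: SimulationParams, step: StepHazardSpec | None
) -> np.ndarray:
    """Per-patient log hazard relative to the calibrated baseline."""
    if step is not None:
        cutoff = np.where(
            df["sex"].to_numpy() == "M", step.cutoff_male, step.cutoff_female
        )
        below = df[step.exposure].to_numpy() < cutoff
        return np.log(step.hr_below) * below
    beta_exp = params.beta_hgs if params.exposure == "hgs" else params.beta_lmi
    exp_mean = (
        params.male_frac * getattr(params, params.exposure).male_mean
        + (1 - params.male_frac) * getattr(params, params.exposure).female_mean
    )
    # centred at the population means so the baseline is a typical patient
    return (
        params.beta_age * (df["age"].to_numpy() - params.age_mean)
        + params.beta_dm * (df["dm"].to_numpy() - params.dm_frac)
        + params.beta_cvd * (df["cvd"].to_numpy() - params.cvd_frac)
        + params.beta_albumin * (df["albumin"].to_numpy() - params.albumin_mean)
        + beta_exp * (df[params.exposure].to_numpy() - exp_mean)
    )


def _calibrate_baseline(
    log_rel_hazard: np.ndarray, params: SimulationParams
) -> float:
    """Baseline death hazard (per month) matching the marginal rate target.

    Solves, on the realised covariates, for the baseline hazard at which the
    expected number of deaths divided by expected person-years under the
    competing-exponentials model equals ``death_rate_target`` / 100 py.
    """
    target = params.death_rate_target / 100.0 / 12.0  # deaths per person-month
    competing = (
        params.hd_transfer_rate + params.transplant_rate + params.lost_rate
    ) / 100.0 / 12.0
    rel = np.exp(log_rel_hazard)
    horizon = params.admin_horizon

    def expected_rate(lam0: float) -> float:
        lam_d = lam0 * rel
        lam_tot = lam_d + competing
        p_any = -np.expm1(-lam_tot * horizon)
        exp_time = p_any / lam_tot  # E[min(T_event, horizon)] months
        exp_deaths = (lam_d / lam_tot) * p_any
        return exp_deaths.sum() / exp_time.sum()

    if target == 0:
        return 0.0
    return optimize.brentq(
        lambda lam0: expected_rate(lam0) - target, 1e-10, 1.0, xtol=1e-12
    )


def generate_outcomes(
    cohort: Cohort,
    params: SimulationParams,
    step: StepHazardSpec | None = None,
) -> Cohort:
    """Draw follow-up time and cause for every patient.

    Each patient gets independent exponential latent times for death, HD
    transfer, transplantation and loss to follow-up; the earliest within the
    administrative horizon determines (``time``, ``cause``), otherwise the
    patient is administratively censored at the horizon.  The death hazard is
    proportional (covariate-driven) unless a :class:`StepHazardSpec` is given.
    """
    if cohort.data[["sex", "age", "dm", "cvd", "albumin"]].isna().any().any():
        raise ValueError("covariates must be populated before generating outcomes")
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 2)))
    df = cohort.data.copy()
    n = len(df)
    log_rel = _death_log_relative_hazard(df, params, step)
    lam0 = _calibrate_baseline(log_rel, params)
    lam_death = lam0 * np.exp(log_rel)
    per_month = 1.0 / 1200.0  # rate per 100 py -> per person-month
    cause_rates = {
        "death": lam_death,
        "hd_transfer": np.full(n, params.hd_transfer_rate * per_month),
        "transplant": np.full(n, params.transplant_rate * per_month),
        "lost": np.full(n, params.lost_rate * per_month),
    }
    latent = np.full((len(cause_rates), n), np.inf)
    for k, rates in enumerate(cause_rates.values()):
        positive = rates > 0
        latent[k, positive] = rng.exponential(1.0 / rates[positive])
    first = latent.argmin(axis=0)
    t_event = latent.min(axis=0)
    causes = np.array(list(cause_rates.keys()), dtype=object)
    admin = t_event >= params.admin_horizon
    df["time"] = np.where(admin, params.admin_horizon, t_event)
    df["cause"] = np.where(admin, "admin_censor", causes[first])
    return Cohort(df, cohort.label)


def generate_cohort(
    params: SimulationParams, step: StepHazardSpec | None = None
) -> Cohort:
    """Covariates plus outcomes in one call."""
    return generate_outcomes(generate_covariates(params), params, step)
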