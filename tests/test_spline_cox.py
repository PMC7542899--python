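import numpy as np
import pandas as pd
import pytest

from sarco_cutpoint.cohort_ops import MODEL_COVARIATES
from sarco_cutpoint.spline_cox import (
    ConvergenceError,
    CoxModel,
    HazardCurve,
    SplineSpec,
    derive_cutoffs,
    find_cutoff,
    fit_cox,
    hazard_curve,
    rcs_basis,
)
from sarco_cutpoint.synthetic_cohort import SimulationParams, generate_cohort

SPEC = SplineSpec(knots=(2.0, 4.0, 6.0, 8.0), window=(0.0, 12.0))


class TestRcsBasis:
    def test_shape_and_identity_column(self):
        x = np.linspace(0, 12, 50)
        B = rcs_basis(x, SPEC)
        assert B.shape == (50, 3)
        np.testing.assert_allclose(B[:, 0], x)

    def test_zero_below_first_knot(self):
        x = np.linspace(-5, 2.0, 30)
        B = rcs_basis(x, SPEC)
        np.testing.assert_array_equal(B[:, 1:], 0.0)

    def test_linear_beyond_last_knot(self):
        """Second differences of every basis column vanish above the last knot."""
        x = np.arange(8.0, 30.0, 0.25)
        B = rcs_basis(x, SPEC)
        second = np.diff(B, n=2, axis=0)
        assert np.abs(second).max() < 1e-6

    def test_continuity_of_value_and_derivatives_at_knots(self):
        h = 1e-6
        for t in SPEC.knots:
            pts = rcs_basis(np.array([t - h, t, t + h]), SPEC)
            assert np.all(np.isfinite(pts))
            # value continuity: both one-sided limits agree with the knot value
            # to O(h) (the basis has bounded slope)
            assert np.abs(pts[0] - pts[1]).max() < 1e-4
            assert np.abs(pts[2] - pts[1]).max() < 1e-4
            # C2: second derivative from both sides via 5-point stencils
            hh = 1e-3
            left = rcs_basis(np.array([t - 2 * hh, t - hh, t]), SPEC)
            right = rcs_basis(np.array([t, t + hh, t + 2 * hh]), SPEC)
            d2l = (left[0] - 2 * left[1] + left[2]) / hh**2
            d2r = (right[0] - 2 * right[1] + right[2]) / hh**2
            assert np.abs(d2l - d2r).max() < 1e-3

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            SplineSpec(knots=(3.0, 2.0, 4.0, 5.0), window=(0, 10))
        with pytest.raises(ValueError, match="window"):
            SplineSpec(knots=(2.0, 4.0, 6.0, 8.0), window=(3.0, 10.0))


def breslow_log_partial_likelihood(beta, times, events, X) -> float:
    """Hand-coded Breslow log partial likelihood (test oracle)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    eta = X @ beta
    ll = 0.0
    for t in np.unique(times[events == 1]):
        tied = (times == t) & (events == 1)
        risk = times >= t
        ll += eta[tied].sum() - tied.sum() * np.log(np.exp(eta[risk]).sum())
    return ll


def grid_search_mple(times, events, X, span=5.0, levels=8) -> np.ndarray:
    """Brute-force maximiser of the oracle likelihood by refined grid search."""
    p = X.shape[1]
    lo, hi = np.full(p, -span), np.full(p, span)
    best = np.zeros(p)
    for _ in range(levels):
        axes = [np.linspace(a, b, 21) for a, b in zip(lo, hi)]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=1)
        vals = [breslow_log_partial_likelihood(b, times, events, X) for b in pts]
        best = pts[int(np.argmax(vals))]
        step = (hi - lo) / 20
        lo, hi = best - 2 * step, best + 2 * step
    return best


def small_cox_fixtures():
    """Deterministic <=8-subject, <=2-covariate datasets (with and without ties)."""
    return [
        # all events, alternating binary covariate
        (np.array([1.0, 2, 3, 4]), np.array([1, 1, 1, 1]),
         np.array([[1.0], [0], [1], [0]])),
        # censoring mixed in
        (np.array([2.0, 3, 3.5, 5, 6, 8]), np.array([1, 0, 1, 1, 0, 1]),
         np.array([[0.5], [-1.0], [1.5], [0.0], [2.0], [-0.5]])),
        # tied event times
        (np.array([2.0, 2, 3, 3, 5, 6, 7, 8]), np.array([1, 1, 1, 0, 1, 1, 0, 1]),
         np.array([[1.0], [0], [0], [1], [1], [0], [1], [0]])),
        # two covariates (binary + continuous), mixed censoring
        (np.array([5.4, 15.8, 0.8, 1.5, 4.0, 5.5, 16.4, 3.0]),
         np.array([0, 0, 1, 1, 1, 1, 1, 1]),
         np.array([[0.0, -0.3], [1, -0.5], [1, -0.1], [0, -0.6],
                   [0, -0.6], [1, -0.3], [0, -0.7], [1, 0.8]])),
        (np.array([14.9, 8.1, 0.8, 14.0, 1.0, 6.8, 3.6, 5.4]),
         np.array([1, 1, 1, 0, 1, 0, 0, 1]),
         np.array([[0.0, 0.0], [1, 1.0], [1, 0.0], [0, -0.3],
                   [0, 0.5], [0, 2.1], [0, -0.3], [0, 0.5]])),
        (np.array([2.5, 3.2, 10.6, 0.9, 10.5, 5.4, 1.1, 5.8]),
         np.array([1, 1, 1, 1, 1, 0, 1, 1]),
         np.array([[0.0, -0.6], [1, -1.3], [1, 0.6], [1, 0.7],
                   [0, 0.3], [0, -0.4], [1, 0.3], [1, 0.4]])),
    ]


class TestFitCox:
    @pytest.mark.parametrize("idx, fixture", list(enumerate(small_cox_fixtures())))
    def test_matches_brute_force_oracle(self, idx, fixture):
        """Fitted coefficients maximise the hand-coded Breslow partial
        likelihood (grid-search oracle, +/-1e-4)."""
        times, events, X = fixture
        oracle = grid_search_mple(times, events, X)
        model = fit_cox(
            pd.Series(times), events,
            pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])]),
        )
        np.testing.assert_allclose(model.coef.to_numpy(), oracle, atol=1e-4)

    def test_efron_matches_lifelines(self):
        """Efron ties agree with an independent implementation (lifelines)."""
        lifelines = pytest.importorskip("lifelines")
        times = np.array([2.0, 2, 2, 3, 3, 5, 6, 8, 9, 11])
        events = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 0])
        x = np.array([1.0, 0, 1, 0, 1, 1, 0, 0, 1, 0])
        model = fit_cox(
            pd.Series(times), events, pd.DataFrame({"x": x}), ties="efron"
        )
        cph = lifelines.CoxPHFitter()
        cph.fit(
            pd.DataFrame({"t": times, "e": events, "x": x}),
            duration_col="t", event_col="e",
        )
        assert model.coef["x"] == pytest.approx(cph.params_["x"], abs=1e-5)

    def test_stacked_duplicate_cohort_same_coefficient(self):
        times = np.array([1.0, 2, 3, 4, 5, 6])
        events = np.array([1, 1, 0, 1, 1, 0])
        X = pd.DataFrame({"x": [0.0, 1, 0, 1, 1, 0]})
        single = fit_cox(pd.Series(times), events, X)
        stacked = fit_cox(
            pd.Series(np.tile(times, 2)), np.tile(events, 2),
            pd.concat([X, X], ignore_index=True),
        )
        assert stacked.coef["x"] == pytest.approx(single.coef["x"], abs=1e-6)

    def test_breslow_baseline_matches_hand_computation(self):
        times = np.array([1.0, 2, 3, 4])
        events = np.ones(4, dtype=int)
        X = pd.DataFrame({"x": [1.0, 0, 1, 0]})
        model = fit_cox(pd.Series(times), events, X)
        eta = X["x"].to_numpy() * model.coef["x"]
        expected, cum = [], 0.0
        for t in times:
            cum += 1.0 / np.exp(eta[times >= t]).sum()
            expected.append(cum)
        np.testing.assert_allclose(model.baseline_cumhaz, expected, rtol=1e-10)
        # step interpolation: 0 before first event, carry-forward beyond last
        np.testing.assert_allclose(
            model.cumulative_baseline_hazard([0.5, 1.0, 99.0]),
            [0.0, expected[0], expected[-1]],
        )

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            fit_cox(pd.Series([1.0, 2.0]), np.array([0, 0]),
                    pd.DataFrame({"x": [0.0, 1.0]}))

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_cox(pd.Series([1.0, 2.0, 3.0]), np.array([1, 1, 0]),
                    pd.DataFrame({"x": [2.0, 2.0, 2.0]}))

    def test_perfect_separation_raises_convergence_error(self):
        # covariate perfectly orders the event times: monotone likelihood
        times = np.arange(1.0, 9.0)
        events = np.ones(8, dtype=int)
        X = pd.DataFrame({"sep": np.arange(8.0)})
        with pytest.raises(ConvergenceError, match="sep"):
            fit_cox(pd.Series(times), events, X)


def _fit_spline_model(df, exposure="hgs", spec=None):
    sub = df.dropna(subset=[exposure])
    x = sub[exposure].to_numpy(dtype=float)
    spec = spec or SplineSpec.from_sample(x)
    cols = [f"s{i}" for i in range(spec.n_basis)]
    X = pd.DataFrame(rcs_basis(x, spec), columns=cols, index=sub.index)
    X[MODEL_COVARIATES] = sub[MODEL_COVARIATES]
    model = fit_cox(sub["time"], (sub["cause"] == "death").astype(int), X)
    return model, spec, cols


class TestHazardCurve:
    def test_reference_point_is_exactly_one(self, proportional_cohort):
        df = proportional_cohort.data[proportional_cohort.data.sex == "M"]
        model, spec, cols = _fit_spline_model(df)
        ref = float(np.median(df["hgs"]))
        curve = hazard_curve(model, spec, ref, cols)
        i = int(np.argmin(np.abs(curve.grid - ref)))
        assert curve.grid[i] == ref
        assert curve.hr[i] == 1.0
        assert curve.lower[i] == 1.0 and curve.upper[i] == 1.0
        assert (curve.lower <= curve.hr + 1e-12).all()
        assert (curve.hr <= curve.upper + 1e-12).all()

    def test_reference_outside_window_rejected(self, proportional_cohort):
        df = proportional_cohort.data[proportional_cohort.data.sex == "M"]
        model, spec, cols = _fit_spline_model(df)
        with pytest.raises(ValueError, match="window"):
            hazard_curve(model, spec, spec.window[1] + 10, cols)

    def test_affine_equivariance_under_exposure_shift(self, proportional_cohort):
        """Shifting the exposure and the reference by +c re-fits to the same curve."""
        df = proportional_cohort.data[proportional_cohort.data.sex == "F"].copy()
        model, spec, cols = _fit_spline_model(df)
        ref = float(np.median(df["hgs"]))
        base = hazard_curve(model, spec, ref, cols)
        c = 7.0
        df["hgs"] = df["hgs"] + c
        model2, spec2, cols2 = _fit_spline_model(df)
        shifted = hazard_curve(model2, spec2, ref + c, cols2)
        np.testing.assert_allclose(shifted.grid - c, base.grid, atol=1e-9)
        np.testing.assert_allclose(shifted.log_hr, base.log_hr, atol=1e-6)
        np.testing.assert_allclose(shifted.se, base.se, atol=1e-6)

    def test_location_invariance_in_adjusters(self, proportional_cohort):
        """Adding a constant to an adjuster column leaves the HR curve unchanged."""
        df = proportional_cohort.data[proportional_cohort.data.sex == "M"].copy()
        model, spec, cols = _fit_spline_model(df)
        ref = float(np.median(df["hgs"]))
        base = hazard_curve(model, spec, ref, cols)
        df["age"] = df["age"] + 100.0
        model2, _, _ = _fit_spline_model(df, spec=spec)
        shifted = hazard_curve(model2, spec, ref, cols)
        np.testing.assert_allclose(shifted.log_hr, base.log_hr, atol=1e-6)

    def test_ci_widens_with_covariance_scale(self, proportional_cohort):
        df = proportional_cohort.data[proportional_cohort.data.sex == "M"]
        model, spec, cols = _fit_spline_model(df)
        ref = float(np.median(df["hgs"]))
        base = hazard_curve(model, spec, ref, cols)
        inflated = CoxModel(
            coef=model.coef, cov=model.cov * 4.0, ties=model.ties,
            baseline_times=model.baseline_times,
            baseline_cumhaz=model.baseline_cumhaz,
            n=model.n, n_events=model.n_events,
        )
        wide = hazard_curve(inflated, spec, ref, cols)
        off_ref = base.se > 0
        np.testing.assert_allclose(wide.se[off_ref], 2 * base.se[off_ref], rtol=1e-9)


def _synthetic_curve(grid, log_hr, se, reference):
    return HazardCurve(
        grid=np.asarray(grid, dtype=float),
        log_hr=np.asarray(log_hr, dtype=float),
        se=np.asarray(se, dtype=float),
        reference=reference,
    )


class TestFindCutoff:
    def test_flat_null_curve_gives_none(self):
        grid = np.linspace(0, 10, 101)
        curve = _synthetic_curve(grid, np.zeros_like(grid), np.full_like(grid, 0.1), 5.0)
        assert find_cutoff(curve) is None
        assert find_cutoff(curve, method="significance") is None

    def test_half_height_locates_transition_midpoint(self):
        """On a smoothed-step curve, the read-out sits where log-HR halves."""
        grid = np.linspace(0, 10, 201)
        log_hr = np.log(2.0) / (1.0 + np.exp(3.0 * (grid - 4.0)))  # sigmoid step at 4
        curve = _synthetic_curve(grid, log_hr, np.full_like(grid, 0.05), 8.0)
        assert find_cutoff(curve) == pytest.approx(4.0, abs=0.1)

    def test_significance_method_returns_loss_of_significance_point(self):
        grid = np.linspace(0, 10, 11)
        log_hr = np.where(grid < 4, 0.7, 0.0)
        se = np.full_like(grid, 0.1)
        curve = _synthetic_curve(grid, log_hr, se, 8.0)
        # lower bound > 1 exactly for grid < 4; first failure at 4.0
        assert find_cutoff(curve, method="significance") == pytest.approx(4.0)

    def test_elevated_only_at_high_end_gives_none(self):
        grid = np.linspace(0, 10, 101)
        log_hr = np.where(grid > 8, 1.0, 0.0)
        curve = _synthetic_curve(grid, log_hr, np.full_like(grid, 0.1), 5.0)
        assert find_cutoff(curve) is None  # low-exposure plateau not elevated

    def test_unknown_method_rejected(self):
        grid = np.linspace(0, 10, 11)
        curve = _synthetic_curve(grid, np.ones_like(grid), np.full_like(grid, 0.1), 5.0)
        with pytest.raises(ValueError, match="method"):
            find_cutoff(curve, method="bogus")


class TestDeriveCutoffs:
    def test_step_truth_recovered_single_seed(self, step_cohort):
        pair = derive_cutoffs(step_cohort, "hgs")
        assert pair.male == pytest.approx(24.5, abs=3.0)
        assert pair.female == pytest.approx(14.0, abs=3.0)
        assert pair.units == "kg"

    def test_deterministic(self, step_cohort):
        a = derive_cutoffs(step_cohort, "hgs")
        b = derive_cutoffs(step_cohort, "hgs")
        assert (a.male, a.female) == (b.male, b.female)

    def test_exposure_independent_of_hazard_gives_null(self, proportional_cohort):
        """LMI does not drive the hazard in an HGS-driven cohort and carries
        only weak indirect signal; a null cut-off is expected for at least
        one sex on a cohort with no direct LMI effect."""
        import dataclasses

        from sarco_cutpoint.synthetic_cohort import SimulationParams, generate_cohort

        p = SimulationParams(n=2000, seed=31, beta_hgs=0.0)  # no exposure effect
        cohort = generate_cohort(p)
        pair = derive_cutoffs(cohort, "hgs")
        assert pair.male is None and pair.female is None

    def test_too_few_events_warns_and_returns_null(self, step_cohort):
        small = step_cohort.data.groupby("sex", group_keys=False).head(40)
        from sarco_cutpoint.cohort_ops import Cohort

        cohort = Cohort(small.reset_index(drop=True), "development")
        with pytest.warns(UserWarning, match="death"):
            pair = derive_cutoffs(cohort, "hgs")
        assert pair.male is None and pair.female is None

    def test_provenance_recorded(self, step_cohort):
        pair = derive_cutoffs(step_cohort, "hgs")
        for sex in ("M", "F"):
            assert len(pair.provenance[sex]["knots"]) == 4
            lo, hi = pair.provenance[sex]["window"]
            assert lo < pair.provenance[sex]["reference"] < hi
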