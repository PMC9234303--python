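"""PRS construction, logistic models, restricted cubic splines, stratification."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special

from gdf15mr.prs_spline import (
    MODEL_COVARIATES,
    Cohort,
    FitFailureError,
    build_prs,
    default_knots,
    fit_models,
    fit_spline,
    rcs_basis,
    read_cohort,
    stratified_by_turning_point,
    write_cohort,
)
from gdf15mr.synthetic_data import SimulationConfig, extended_config, simulate_cohort


class TestBuildPrs:
    def test_homozygous_carrier_raw_score(self):
        weights = [0.059, 0.370, 0.160, 0.270]
        score = build_prs(np.full((1, 4), 2.0), weights, standardize=False)
        assert score[0] == pytest.approx(1.718)

    def test_all_zero_dosages(self):
        assert build_prs(np.zeros((3, 4)), [0.1] * 4, standardize=False).tolist() == [0, 0, 0]

    def test_weight_scale_invariance_after_standardization(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(500, 4)).astype(float)
        w = [0.059, 0.370, 0.160, 0.270]
        a = build_prs(d, w)
        b = build_prs(d, [2 * x for x in w])
        assert np.allclose(a, b, atol=1e-12)
        assert abs(a.mean()) < 1e-10 and abs(a.std() - 1) < 1e-10

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="weight count"):
            build_prs(np.zeros((5, 3)), [0.1, 0.2])

    def test_zero_variance_score(self):
        with pytest.raises(ValueError, match="zero variance"):
            build_prs(np.ones((5, 2)), [0.1, 0.2])


class TestRcsBasis:
    KNOTS = [-1.0, 0.0, 1.5, 2.5]

    def test_below_first_knot_nonlinear_columns_vanish(self):
        x = np.array([-3.0, -2.0, -1.0])
        basis = rcs_basis(x, self.KNOTS)
        assert np.allclose(basis[:, 1:], 0.0)
        assert np.allclose(basis[:, 0], x)

    def test_linear_in_both_tails(self):
        # second differences vanish far beyond the boundary knots
        for x0 in (-8.0, 9.0):
            h = 1e-3
            x = np.array([x0 - h, x0, x0 + h])
            basis = rcs_basis(x, self.KNOTS)
            second = basis[0] - 2 * basis[1] + basis[2]
            assert np.allclose(second, 0.0, atol=1e-9)

    def test_matches_direct_formula_evaluation(self):
        """Brute-force evaluation of the truncated-power formula on a 5-point
        toy set, written out term by term."""
        t = np.array(self.KNOTS)
        x = np.array([-1.7, -0.2, 0.4, 1.9, 3.1])
        k = len(t)
        expected = np.empty((5, k - 1))
        expected[:, 0] = x
        for j in range(k - 2):
            col = np.zeros(5)
            for i, xi in enumerate(x):
                p3 = lambda v: max(v, 0.0) ** 3
                col[i] = (
                    p3(xi - t[j])
                    - p3(xi - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
                    + p3(xi - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2])
                ) / (t[k - 1] - t[0]) ** 2
            expected[:, j + 1] = col
        assert np.allclose(rcs_basis(x, t), expected, atol=1e-12)

    def test_continuity_of_value_and_derivatives_at_knots(self):
        h = 1e-4
        for knot in self.KNOTS:
            x = np.array([knot - 2 * h, knot - h, knot, knot + h, knot + 2 * h])
            basis = rcs_basis(x, self.KNOTS)
            for col in basis.T:
                d1 = np.diff(col) / h
                d2 = np.diff(d1) / h
                assert abs(d1[0] - d1[-1]) < 1e-2  # first derivative continuous
                assert abs(d2[0] - d2[-1]) < 1.0e-1 * max(1, abs(d2[0]))  # second too

    def test_invalid_knots(self):
        with pytest.raises(ValueError):
            rcs_basis(np.zeros(3), [0.0, 0.0, 1.0])
        with pytest.raises(ValueError):
            rcs_basis(np.zeros(3), [0.0, 1.0])

    def test_default_knot_quantiles(self):
        x = np.random.default_rng(0).standard_normal(100_000)
        assert np.allclose(default_knots(x, 3), np.quantile(x, [0.1, 0.5, 0.9]))
        with pytest.raises(ValueError):
            default_knots(x, 6)


def _small_cohort(n=2000, seed=5, **kw):
    return simulate_cohort(SimulationConfig(n=n, seed=seed, **kw))


class TestFitModels:
    def test_matches_independent_likelihood_oracle(self):
        """Model-2 coefficients agree to 1e-6 with an independent optimizer
        (BFGS on the raw Bernoulli log-likelihood)."""
        cohort = _small_cohort()
        eff = fit_models(cohort, model=2)
        covs = MODEL_COVARIATES[2]
        X = np.column_stack(
            [np.ones(cohort.n), cohort.data["prs"], cohort.data[covs].to_numpy()]
        )
        y = cohort.data["gallstones"].to_numpy(dtype=float)

        def nll(b):
            eta = X @ b
            return -np.sum(y * eta - np.logaddexp(0.0, eta))

        res = optimize.minimize(nll, np.zeros(X.shape[1]), method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 500})
        assert eff.beta == pytest.approx(res.x[1], abs=1e-6)

    def test_per_sd_or_invariant_to_affine_prs_rescaling(self):
        cohort = _small_cohort()
        eff = fit_models(cohort, model=1)
        raw = 3.0 * cohort.data.prs.to_numpy() + 1.0  # arbitrary affine rescale
        restd = (raw - raw.mean()) / raw.std()
        rescaled = Cohort(
            dosages=cohort.dosages, snp_ids=cohort.snp_ids,
            data=cohort.data.assign(prs=restd),
        )
        eff2 = fit_models(rescaled, model=1)
        assert eff2.beta == pytest.approx(eff.beta, abs=1e-9)

    def test_covariate_sets_are_nested(self):
        assert set(MODEL_COVARIATES[1]) < set(MODEL_COVARIATES[2]) < set(MODEL_COVARIATES[3])

    def test_missing_covariate_column_is_named(self):
        cohort = _small_cohort()
        broken = Cohort(
            dosages=cohort.dosages, snp_ids=cohort.snp_ids,
            data=cohort.data.drop(columns=["ldl"]),
        )
        with pytest.raises(KeyError, match="ldl"):
            fit_models(broken, model=3)

    def test_single_class_stratum_rejected(self):
        cohort = _small_cohort()
        allcase = Cohort(
            dosages=cohort.dosages, snp_ids=cohort.snp_ids,
            data=cohort.data.assign(gallstones=1),
        )
        with pytest.raises(FitFailureError, match="single class"):
            fit_models(allcase, model=1)

    def test_diabetic_stratum_subsets(self):
        cohort = _small_cohort(n=20_000)
        eff = fit_models(cohort, model=1, stratum="diabetic")
        assert eff.n == int((cohort.data["diabetes"] == 1).sum())


class TestFitSpline:
    def test_recovers_u_shape_and_flags_nothing_flat(self):
        cohort = simulate_cohort(extended_config(60_000, seed=3, causal_shape="ushape"))
        fit = fit_spline(cohort, model=1)
        assert fit.nonlinearity_pvalue < 0.05
        assert not fit.is_flat
        assert cohort.data.prs.min() <= fit.turning_point <= cohort.data.prs.max()
        assert len(fit.knots) == 3

    def test_flat_curve_flagged_when_outcome_independent(self):
        cohort = simulate_cohort(extended_config(150_000, seed=4, causal_shape="null"))
        fit = fit_spline(cohort, model=1)
        assert fit.nonlinearity_pvalue > 0.01
        assert fit.curve_range == pytest.approx(
            fit.curve.log_odds.max() - fit.curve.log_odds.min()
        )

    def test_turning_point_tie_breaks_toward_smaller_prs(self):
        cohort = simulate_cohort(extended_config(30_000, seed=5, causal_shape="ushape"))
        fit = fit_spline(cohort, model=1, grid_step=0.5)
        grid = fit.curve.prs.to_numpy()
        mins = grid[fit.curve.log_odds.to_numpy() == fit.curve.log_odds.min()]
        assert fit.turning_point == mins.min()


def _fit_with_turning_point(cohort, turning_point: float):
    """A SplineFit carrying a prescribed cutoff (only the turning point is
    consumed by the stratified split)."""
    import pandas as pd
    from gdf15mr.prs_spline import SplineFit

    return SplineFit(
        knots=np.array([-1.0, 0.0, 1.0]), coefficients=pd.Series(dtype=float),
        nonlinearity_pvalue=1.0, turning_point=turning_point,
        curve=pd.DataFrame({"prs": [0.0], "log_odds": [0.0]}), curve_range=0.0,
        n=cohort.n, n_cases=int(cohort.data.gallstones.sum()), model=1, stratum="all",
    )


class TestStratification:
    def test_u_shape_gives_opposite_sides_of_one(self):
        cohort = simulate_cohort(extended_config(100_000, seed=6, causal_shape="ushape"))
        fit = fit_spline(cohort, model=1)
        table = stratified_by_turning_point(cohort, fit, model=1)
        assert set(table["stratum"]) == {"all", "nondiabetic", "diabetic"}
        overall = table[table.stratum == "all"].set_index("group")
        assert overall.loc["low", "or"] < 1 < overall.loc["high", "or"]

    def test_symmetric_u_has_balanced_arms(self):
        cfg = extended_config(150_000, seed=8, causal_shape="ushape", ushape_vertex=0.0)
        cohort = simulate_cohort(cfg)
        fit = fit_spline(cohort, model=1)
        table = stratified_by_turning_point(cohort, fit, model=1).set_index(["stratum", "group"])
        lo = np.log(table.loc[("all", "low"), "or"])
        hi = np.log(table.loc[("all", "high"), "or"])
        assert abs(abs(lo) - abs(hi)) < 0.1  # equal magnitude within simulation error

    def test_linear_effect_keeps_both_arms_on_same_side(self):
        """Splitting a linear-effect cohort at an interior cutoff leaves
        both arms' per-SD ORs on the same side of 1."""
        cohort = simulate_cohort(extended_config(100_000, seed=9, causal_shape="linear",
                                                 causal_or_per_sd=1.3))
        fit = _fit_with_turning_point(cohort, turning_point=0.0)
        table = stratified_by_turning_point(cohort, fit, model=1).set_index(["stratum", "group"])
        assert table.loc[("all", "low"), "or"] > 1
        assert table.loc[("all", "high"), "or"] > 1

    def test_boundary_turning_point_raises_empty_side_error(self):
        """A monotone fitted curve puts the argmin on the boundary; the
        split must then refuse to produce an empty group, not hide it."""
        cohort = simulate_cohort(extended_config(30_000, seed=10, causal_shape="linear"))
        fit = _fit_with_turning_point(cohort, turning_point=float(cohort.data.prs.min()))
        with pytest.raises(FitFailureError, match="low side"):
            stratified_by_turning_point(cohort, fit, model=1)


def test_cohort_roundtrip_io(tmp_path):
    cohort = _small_cohort(n=300)
    path = tmp_path / "cohort.tsv"
    write_cohort(cohort, path)
    back = read_cohort(path)
    assert back.snp_ids == cohort.snp_ids
    assert np.allclose(back.dosages, cohort.dosages)
    pd.testing.assert_frame_equal(back.data, cohort.data, check_exact=False, atol=1e-9)
    assert np.allclose(back.exposure, cohort.exposure, atol=1e-9)


def test_cohort_validation():
    with pytest.raises(ValueError, match="matching"):
        Cohort(dosages=np.zeros((3, 2)), snp_ids=["a", "b"], data=pd.DataFrame({"prs": [0.0] * 4}))
    with pytest.raises(ValueError, match=r"\[0, 2\]"):
        Cohort(dosages=np.full((2, 1), 3.0), snp_ids=["a"], data=pd.DataFrame({"prs": [0.0, 1.0]}))
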