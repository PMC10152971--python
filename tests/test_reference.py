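"""Reference-interval model: transform, fractional polynomials, fit, centiles."""

import json
import math

import numpy as np
import pytest
from scipy import stats

from cvemp.reference import (BoxCoxTransform, ClassificationCriteria, FitConfig,
                             FracPoly, ReferenceIntervalModel,
                             ReferenceIntervalResults, StratumEstimate, boxcox,
                             classify_subject, fp_basis)
from cvemp.simulate import (DEFAULT_CURVES, CohortConfig, cohort_to_frame,
                            sample_cohort)

LAMBDA_GRID = np.arange(-2.0, 2.0001, 0.05)


class TestBoxCox:
    @pytest.mark.parametrize("lmbda,y,expected", [
        (1.0, 3.0, 2.0),
        (0.0, 1.0, 0.0),
        (0.5, 4.0, 2.0),
    ])
    def test_known_values(self, lmbda, y, expected):
        assert boxcox(y, BoxCoxTransform(lmbda)) == pytest.approx(expected)

    def test_round_trip_on_grid(self):
        y = np.concatenate([np.linspace(0.05, 6.0, 40), [0.01, 25.0]])
        for lam in LAMBDA_GRID:
            t = BoxCoxTransform(float(lam))
            assert np.max(np.abs(t.inverse(t.transform(y)) - y)) < 1e-10

    def test_continuous_at_zero(self):
        y = np.linspace(0.2, 5.0, 20)
        near = BoxCoxTransform(1e-9).transform(y)
        assert np.allclose(near, np.log(y), atol=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            BoxCoxTransform(0.5).transform(-1.0)
        with pytest.raises(ValueError):
            BoxCoxTransform(-1.0).inverse(5.0)  # lam*b + 1 < 0


class TestFracPoly:
    def test_power_zero_is_log(self):
        x = np.array([1.0, math.e, math.e**2])
        assert np.allclose(fp_basis(x, (0.0,))[:, 0], [0.0, 1.0, 2.0])

    def test_repeated_power_adds_log_factor(self):
        x = np.array([2.0, 3.0])
        b = fp_basis(x, (2.0, 2.0))
        assert np.allclose(b[:, 0], x**2)
        assert np.allclose(b[:, 1], x**2 * np.log(x))

    def test_nonpositive_age_rejected(self):
        with pytest.raises(ValueError, match="age > 0"):
            fp_basis(np.array([0.0, 1.0]), (1.0,))

    def test_evaluation_scalar_and_vector(self):
        fp = FracPoly((1.0,), (2.0,), 1.0)
        assert fp(3.0) == pytest.approx(7.0)
        assert np.allclose(fp(np.array([1.0, 2.0])), [3.0, 5.0])


def _lognormal_data(n=500, seed=0, a0=0.2, a1=0.35, sigma=0.3):
    rng = np.random.default_rng(seed)
    age = rng.uniform(0.5, 16.0, n)
    y = np.exp(a0 + a1 * np.log(age) + rng.normal(0.0, sigma, n))
    return age, y, (a0, a1, sigma)


class TestFit:
    def test_gaussian_data_with_identity_transform(self):
        rng = np.random.default_rng(4)
        age = rng.uniform(1.0, 15.0, 400)
        y = rng.normal(5.0, 0.8, 400)
        cfg = FitConfig(lambda_min=1.0, lambda_max=1.0, lambda_step=1.0)
        res = ReferenceIntervalModel(age, y, config=cfg).fit()
        grid = np.linspace(1.0, 15.0, 30)
        assert np.allclose(res.mu(grid) + 1.0, 5.0, atol=0.15)
        assert np.allclose(res.sigma(grid), 0.8, atol=0.12)
        z = res.strata["all"].zscores
        assert abs(np.mean(z)) < 3 / math.sqrt(len(z))
        assert np.std(z, ddof=1) == pytest.approx(1.0, abs=0.1)

    def test_lognormal_recovery(self):
        age, y, (a0, a1, sigma) = _lognormal_data(n=500, seed=8)
        res = ReferenceIntervalModel(age, y).fit()
        assert abs(res.boxcox.lmbda) <= 0.3
        grid = np.linspace(1.0, 15.0, 40)
        median_true = np.exp(a0 + a1 * np.log(grid))
        median_fit = np.array([res.mean_curve(a) for a in grid])
        assert np.sqrt(np.mean((median_fit / median_true - 1) ** 2)) < 0.05
        # spread recovery via the one-sigma-up centile
        p84_fit = np.array([res.centile(a, 84.134) for a in grid])
        p84_true = median_true * math.exp(sigma)
        assert np.sqrt(np.mean((p84_fit / p84_true - 1) ** 2)) < 0.05

    def test_profile_matches_joint_optimisation_on_toy_set(self):
        # independent oracle: direct maximisation of the same likelihood with
        # the structure fixed to mu ~ log age, constant sigma
        age, y, _ = _lognormal_data(n=50, seed=15)
        from scipy.optimize import minimize

        log_age, log_y_sum = np.log(age), np.sum(np.log(y))

        def negll(theta):
            lam, b0, b1, logs = theta
            b = (y**lam - 1) / lam if abs(lam) > 1e-9 else np.log(y)
            s = math.exp(logs)
            return (np.sum(np.log(s) + 0.5 * ((b - b0 - b1 * log_age) / s) ** 2)
                    - (lam - 1) * log_y_sum)

        brute = min(
            (minimize(negll, [l0, 0.2, 0.3, -1.0], method="Nelder-Mead",
                      options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 5000})
             for l0 in (-0.5, 0.0, 0.5)),
            key=lambda r: r.fun)
        cfg = FitConfig(mu_powers=(0.0,), sigma_powers=(), min_n=30)
        res = ReferenceIntervalModel(age, y, config=cfg).fit()
        assert abs(res.boxcox.lmbda - brute.x[0]) <= 0.05 + 1e-9

    def test_record_order_irrelevant(self):
        age, y, _ = _lognormal_data(n=300, seed=5)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(age))
        res1 = ReferenceIntervalModel(age, y).fit()
        res2 = ReferenceIntervalModel(age[perm], y[perm]).fit()
        assert res1.boxcox.lmbda == res2.boxcox.lmbda
        grid = np.linspace(1.0, 15.0, 20)
        assert np.allclose(res1.mu(grid), res2.mu(grid), atol=1e-8)

    def test_small_stratum_rejected(self):
        age, y, _ = _lognormal_data(n=20, seed=5)
        with pytest.raises(ValueError, match="at least"):
            ReferenceIntervalModel(age, y).fit()

    def test_degenerate_ages_rejected(self):
        y = np.exp(np.random.default_rng(0).normal(0.5, 0.3, 50))
        with pytest.raises(ValueError, match="degenerate age"):
            ReferenceIntervalModel(np.full(50, 8.0), y)

    def test_from_dataframe_filters_domain(self):
        df = cohort_to_frame(sample_cohort(CohortConfig(n_children=60,
                                                        n_adults=20), seed=2))
        sub = df[df["mode"] == "AC"].rename(columns={"true_ratio":
                                                     "amplitude_ratio"})
        model = ReferenceIntervalModel.from_dataframe(sub, group_col=None)
        ages = np.concatenate([a for a, _ in model._data.values()])
        assert ages.max() <= 16.0  # adults excluded by the age domain


class TestResults:
    @staticmethod
    def _constant_results(lmbda=1.0, mu=2.0, sigma=0.5):
        strata = {"all": StratumEstimate(
            group="all", n=100, mu=FracPoly((), (), mu),
            sigma=FracPoly((), (), sigma), sigma_fallback=False)}
        return ReferenceIntervalResults(
            mode="AC", boxcox=BoxCoxTransform(lmbda), strata=strata,
            config=FitConfig())

    def test_z_score_centering_and_unit_step(self):
        res = self._constant_results()
        y_at_mu = res.boxcox.inverse(2.0)
        assert res.z_score(8.0, y_at_mu) == pytest.approx(0.0)
        y_up = res.boxcox.inverse(2.5)
        assert res.z_score(8.0, y_up) == pytest.approx(1.0)

    def test_centile_gaussian_closed_form(self):
        # lambda=1: inverse transform is b + 1, so p95 = mu + 1.6449 sigma + 1
        res = self._constant_results()
        expected = 2.0 + stats.norm.ppf(0.95) * 0.5 + 1.0
        assert res.centile(8.0, 95.0) == pytest.approx(expected, abs=1e-6)
        assert res.centile(8.0, 50.0) == pytest.approx(3.0)

    def test_age_domain_enforced(self):
        res = self._constant_results()
        with pytest.raises(ValueError, match="domain"):
            res.z_score(20.0, 2.0)
        with pytest.raises(ValueError, match="domain"):
            res.centile(0.2, 50.0)

    def test_centiles_never_cross(self):
        df = cohort_to_frame(sample_cohort(CohortConfig(n_children=120,
                                                        n_adults=0), seed=6))
        sub = df[df["mode"] == "BC"]
        res = ReferenceIntervalModel(sub["age_years"].to_numpy(),
                                     sub["true_ratio"].to_numpy(),
                                     sub["sex"].to_numpy()).fit()
        for age in np.linspace(1.0, 15.0, 15):
            vals = [res.centile(age, p, "F") for p in (1, 5, 10, 50, 90, 95, 99)]
            assert np.all(np.diff(vals) > 0)

    def test_normative_table_layout_monotone_and_deterministic(self):
        df = cohort_to_frame(sample_cohort(CohortConfig(n_children=120,
                                                        n_adults=0), seed=6))
        sub = df[df["mode"] == "AC"]
        args = (sub["age_years"].to_numpy(), sub["true_ratio"].to_numpy(),
                sub["sex"].to_numpy())
        t1 = ReferenceIntervalModel(*args).fit().normative_table()
        t2 = ReferenceIntervalModel(*args).fit().normative_table()
        assert t1.equals(t2)
        assert len(t1) == 30 and set(t1["group"]) == {"M", "F"}
        cols = ["p5", "p10", "mean", "p90", "p95"]
        assert (t1[cols].to_numpy() > 0).all()
        assert np.all(np.diff(t1[cols].to_numpy(), axis=1) > 0)

    def test_normative_table_recovers_known_quantiles(self):
        # large cohort so estimation noise is small relative to the 10% band
        df = cohort_to_frame(sample_cohort(CohortConfig(n_children=3000,
                                                        n_adults=0), seed=13))
        sub = df[df["mode"] == "AC"]
        res = ReferenceIntervalModel(sub["age_years"].to_numpy(),
                                     sub["true_ratio"].to_numpy(),
                                     sub["sex"].to_numpy()).fit()
        table = res.normative_table()
        curve = DEFAULT_CURVES["AC"]
        for _, row in table.iterrows():
            m = curve.mean(row["age_years"], row["group"])
            assert row["p95"] == pytest.approx(
                m * math.exp(stats.norm.ppf(0.95) * 0.4), rel=0.10)
            assert row["mean"] == pytest.approx(m, rel=0.10)

    def test_serialisation_round_trip(self):
        df = cohort_to_frame(sample_cohort(CohortConfig(n_children=120,
                                                        n_adults=0), seed=6))
        sub = df[df["mode"] == "AC"]
        res = ReferenceIntervalModel(sub["age_years"].to_numpy(),
                                     sub["true_ratio"].to_numpy(),
                                     sub["sex"].to_numpy()).fit()
        clone = ReferenceIntervalResults.from_dict(
            json.loads(json.dumps(res.to_dict())))
        for age in (1.0, 8.0, 15.0):
            for g in ("M", "F"):
                assert clone.centile(age, 95, g) == pytest.approx(
                    res.centile(age, 95, g))
                assert clone.z_score(age, 1.5, g) == pytest.approx(
                    res.z_score(age, 1.5, g))

    def test_summary_mentions_fit_ingredients(self):
        res = self._constant_results()
        text = res.summary()
        assert "lambda" in text and "sigma" in text and "mode: AC" in text

    def test_centile_plot_renders(self):
        import matplotlib

        matplotlib.use("Agg")
        df = cohort_to_frame(sample_cohort(CohortConfig(n_children=60,
                                                        n_adults=0), seed=6))
        sub = df[df["mode"] == "AC"]
        res = ReferenceIntervalModel(sub["age_years"].to_numpy(),
                                     sub["true_ratio"].to_numpy()).fit()
        ax = res.plot_centiles(percentiles=(5, 50, 95))
        assert len(ax.lines) == 4  # three centile curves plus the data overlay


class TestClassification:
    @staticmethod
    def _results():
        return TestResults._constant_results(lmbda=0.0, mu=math.log(2.0),
                                             sigma=0.3)

    @staticmethod
    def _record(ear, **kw):
        base = dict(ear=ear, age_years=8.0, sex="all", amplitude_ratio=2.0,
                    threshold_dbnhl=78.0, p_latency_ms=13.0,
                    response_present=True)
        base.update(kw)
        return base

    def test_interior_point_all_flags_true(self):
        res = self._results()
        cls = classify_subject(res, [self._record("R"), self._record("L")])
        assert all(v is True for v in cls.flags.values())
        assert cls.overall is True
        assert cls.z["R"] == pytest.approx(0.0, abs=1e-9)
        assert cls.centile["R"] == pytest.approx(50.0, abs=1e-6)

    def test_ratio_below_fifth_centile_flagged(self):
        res = self._results()
        low = float(res.centile(8.0, 5.0)) * 0.9
        cls = classify_subject(res, [self._record("R", amplitude_ratio=low),
                                     self._record("L")])
        assert cls.flags["ratio_in_band"] is False and cls.overall is False

    def test_asymmetry_and_threshold_difference_flags(self):
        res = self._results()
        cls = classify_subject(res, [
            self._record("R", amplitude_ratio=3.0, threshold_dbnhl=83.0),
            self._record("L", amplitude_ratio=1.0, threshold_dbnhl=73.0)])
        assert cls.flags["asymmetry_ok"] is False  # |asym| = 50% > 35%
        assert cls.flags["threshold_asym_ok"] is False  # 10 dB > 5 dB

    def test_absent_response_fails_threshold_criterion(self):
        res = self._results()
        cls = classify_subject(res, [
            self._record("R", amplitude_ratio=None, threshold_dbnhl=None,
                         p_latency_ms=None, response_present=False),
            self._record("L")])
        assert cls.flags["threshold_ok"] is False

    def test_missing_inputs_stay_indeterminate(self):
        res = self._results()
        cls = classify_subject(res, [
            self._record("R", threshold_dbnhl=None, p_latency_ms=None)])
        assert cls.flags["threshold_ok"] is None
        assert cls.flags["p_latency_ok"] is None
        assert cls.flags["asymmetry_ok"] is None  # one ear only
        assert cls.overall is True  # remaining flags all pass

    def test_configurable_asymmetry_cut(self):
        res = self._results()
        crit = ClassificationCriteria(asym_limit_pct=32.0)
        cls = classify_subject(res, [
            self._record("R", amplitude_ratio=2.0),
            self._record("L", amplitude_ratio=1.0)], crit)
        assert cls.flags["asymmetry_ok"] is False  # 33.3% > 32%
        default = classify_subject(res, [
            self._record("R", amplitude_ratio=2.0),
            self._record("L", amplitude_ratio=1.0)])
        assert default.flags["asymmetry_ok"] is True  # 33.3% < 35%
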