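"""Scaling, Huber IRLS fit, bootstrap interval families and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from sipipe.errors import (
    CollinearityError,
    DegenerateRangeError,
    DegenerateScaleError,
    ValidationError,
)
from sipipe.pbcor import PBParams, SIEstimate
from sipipe.regression import (
    _bca_interval,
    bootstrap_cis,
    build_regression_table,
    fit_robust,
    min_max_scale,
    pearson_screen,
    percentile_from_sorted,
    residual_diagnostics,
)
from sipipe.timeseries import RecruitmentSeries


def _si_stub(area, year, rho):
    p = PBParams()
    return SIEstimate(area, year, 15, rho, 0.0, 0.5, np.nan, np.nan, False, False, p)


class TestMinMaxScale:
    def test_closed_form(self):
        scaled = min_max_scale([2, 4, 6], "x", "A")
        assert scaled.values == pytest.approx([0.0, 0.5, 1.0])

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateRangeError):
            min_max_scale([7, 7, 7], "x", "A")

    def test_affine_invariance_and_inversion(self, rng):
        x = rng.uniform(10, 50, 12)
        scaled = min_max_scale(x, "x", "A")
        shifted = min_max_scale(3.0 + 2.5 * x, "x", "A")
        assert shifted.values == pytest.approx(scaled.values, abs=1e-12)
        assert scaled.invert() == pytest.approx(x, abs=1e-12)


class TestBuildRegressionTable:
    def _inputs(self, n_years=(18, 18, 15)):
        rng = np.random.default_rng(2)
        recruits, si, sst = [], [], {}
        for area, n in zip(("SoS", "GoL", "AS"), n_years):
            years = list(range(2002, 2002 + n))
            recruits.append(
                RecruitmentSeries(area, {y: float(rng.uniform(1e4, 1e6)) for y in years})
            )
            for y in years:
                si.append(_si_stub(area, y, float(rng.uniform(-0.5, 1.0))))
                sst[(area, y)] = float(rng.uniform(15, 25))
        return recruits, si, sst

    def test_pooled_row_count(self):
        recruits, si, sst = self._inputs()
        table = build_regression_table(recruits, si, sst)
        assert len(table) == 51
        assert set(table["area_id"]) == {"SoS", "GoL", "AS"}

    def test_year_missing_si_is_dropped(self, caplog):
        recruits, si, sst = self._inputs()
        si = [e for e in si if not (e.area_id == "SoS" and e.recruit_year == 2010)]
        with caplog.at_level("WARNING"):
            table = build_regression_table(recruits, si, sst)
        assert len(table) == 50
        assert "2010" in caplog.text

    def test_max_recruitment_year_maps_to_ln2(self):
        recruits, si, sst = self._inputs()
        table = build_regression_table(recruits, si, sst)
        for _, sub in table.groupby("area_id"):
            assert sub["y"].max() == pytest.approx(np.log(2))
            assert sub["y"].min() == pytest.approx(0.0)
            assert sub[["si_scaled", "sst_scaled"]].to_numpy().min() >= 0.0
            assert sub[["si_scaled", "sst_scaled"]].to_numpy().max() <= 1.0

    def test_area_with_single_complete_year_rejected(self):
        recruits, si, sst = self._inputs(n_years=(1, 5, 5))
        with pytest.raises(ValidationError, match="SoS"):
            build_regression_table(recruits, si, sst)


class TestFitRobust:
    def test_noiseless_table_recovered_exactly(self, clean_table):
        fit = fit_robust(clean_table)
        assert fit.converged
        assert fit.coefficients == pytest.approx([0.21, 0.21, -0.07], abs=1e-8)
        assert fit.weights == pytest.approx(np.ones(len(clean_table)))

    def test_huber_resists_response_outlier_better_than_ols(self, clean_table):
        contaminated = clean_table.copy()
        contaminated.loc[5, "y"] += 5.0
        huber = fit_robust(contaminated).coefficients[1]
        X = np.column_stack(
            [np.ones(len(contaminated)), contaminated["si_scaled"], contaminated["sst_scaled"]]
        )
        ols = np.linalg.lstsq(X, contaminated["y"], rcond=None)[0][1]
        assert abs(huber - 0.21) < 0.02
        assert abs(huber - 0.21) < abs(ols - 0.21)

    def test_infinite_tuning_constant_equals_ols(self, clean_table, rng):
        noisy = clean_table.copy()
        noisy["y"] = noisy["y"] + rng.normal(0, 0.1, len(noisy))
        fit = fit_robust(noisy, tuning_k=1e12)
        X = np.column_stack([np.ones(len(noisy)), noisy["si_scaled"], noisy["sst_scaled"]])
        ols = np.linalg.lstsq(X, noisy["y"], rcond=None)[0]
        assert fit.coefficients == pytest.approx(ols, abs=1e-8)

    def test_intercept_equivariance_under_response_shift(self, clean_table, rng):
        noisy = clean_table.copy()
        noisy["y"] = noisy["y"] + rng.normal(0, 0.05, len(noisy))
        base = fit_robust(noisy).coefficients
        shifted = noisy.copy()
        shifted["y"] = shifted["y"] + 2.5
        moved = fit_robust(shifted).coefficients
        assert moved[0] == pytest.approx(base[0] + 2.5, abs=1e-6)
        assert moved[1:] == pytest.approx(base[1:], abs=1e-6)

    def test_collinear_predictors_rejected(self, clean_table):
        degenerate = clean_table.copy()
        degenerate["sst_scaled"] = degenerate["si_scaled"]
        with pytest.raises(CollinearityError):
            fit_robust(degenerate)

    def test_agrees_with_statsmodels_rlm_on_noisy_data(self, clean_table, rng):
        sm = pytest.importorskip("statsmodels.api")
        noisy = clean_table.copy()
        noisy["y"] = noisy["y"] + rng.normal(0, 0.1, len(noisy))
        noisy.loc[3, "y"] += 1.5
        fit = fit_robust(noisy)
        X = np.column_stack([np.ones(len(noisy)), noisy["si_scaled"], noisy["sst_scaled"]])
        rlm = sm.RLM(noisy["y"], X, M=sm.robust.norms.HuberT(t=1.345)).fit(
            scale_est="mad"
        )
        # scale conventions differ (MAD centering, update order): compare loosely
        assert fit.coefficients == pytest.approx(rlm.params, abs=2e-2)


class TestIntervalFamilies:
    def test_percentile_endpoints_are_order_statistics(self, rng):
        reps = np.sort(rng.normal(size=999))
        lo = percentile_from_sorted(reps, 0.025)
        hi = percentile_from_sorted(reps, 0.975)
        assert lo == reps[24] and hi == reps[974]  # floor(1000*.025)=25th smallest
        assert lo in reps and hi in reps

    def test_bca_reduces_to_percentile_without_bias_or_acceleration(self):
        # symmetric replicate set around the estimate -> z0 = 0; symmetric
        # jackknife -> acceleration = 0
        reps = np.sort(np.concatenate([-np.linspace(0.1, 2, 500), np.linspace(0.1, 2, 500)]))
        jack = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
        lo, hi = _bca_interval(reps, 0.0, jack, 0.025)
        assert lo == percentile_from_sorted(reps, 0.025)
        assert hi == percentile_from_sorted(reps, 0.975)

    def test_zero_residual_table_collapses_all_families(self, clean_table):
        cis = bootstrap_cis(clean_table, n_boot=199, seed=4)
        for family in ("normal", "percentile", "bca"):
            band = getattr(cis, family)
            assert band[:, 0] == pytest.approx(cis.estimates, abs=1e-10)
            assert band[:, 1] == pytest.approx(cis.estimates, abs=1e-10)

    def test_bootstrap_deterministic_and_ordered(self, clean_table, rng):
        noisy = clean_table.copy()
        noisy["y"] = noisy["y"] + rng.normal(0, 0.1, len(noisy))
        a = bootstrap_cis(noisy, n_boot=299, seed=9)
        b = bootstrap_cis(noisy, n_boot=299, seed=9)
        for family in ("normal", "percentile", "bca"):
            band_a, band_b = getattr(a, family), getattr(b, family)
            assert np.array_equal(band_a, band_b)
            assert (band_a[:, 0] <= band_a[:, 1]).all()

    def test_stratified_resampling_keeps_area_sizes(self, clean_table, rng):
        noisy = clean_table.copy()
        noisy["y"] = noisy["y"] + rng.normal(0, 0.1, len(noisy))
        cis = bootstrap_cis(noisy, n_boot=99, seed=2, stratify_by_area=True)
        assert cis.replicates.shape == (99, 3)

    def test_tidy_output_schema(self, clean_table):
        frame = bootstrap_cis(clean_table, n_boot=99, seed=0).to_frame()
        assert len(frame) == 9  # 3 coefficients x 3 families
        assert set(frame["family"]) == {"normal", "percentile", "bca"}


class TestPearsonScreen:
    def test_exact_linear_relation(self):
        rho, p = pearson_screen([1, 2, 3, 4], [2, 4, 6, 8])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_matches_covariance_formula(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 3.0, 2.0])
        rho, _ = pearson_screen(x, y)
        brute = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert rho == pytest.approx(brute, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateScaleError):
            pearson_screen([1, 2, 3], [5, 5, 5])


class TestResidualDiagnostics:
    def test_exact_fit_flagged_degenerate(self, clean_table):
        fit = fit_robust(clean_table)
        report = residual_diagnostics(fit, clean_table)
        assert report.degenerate
        assert "zero residual variance" in report.note

    def test_heteroscedastic_residuals_are_detected(self, clean_table, rng):
        heter = pd.concat([clean_table] * 6, ignore_index=True)
        heter["recruit_year"] = np.arange(len(heter))
        base = 0.21 + 0.21 * heter["si_scaled"] - 0.07 * heter["sst_scaled"]
        heter["y"] = base + rng.normal(0, 1, len(heter)) * (0.02 + 0.4 * base)
        fit = fit_robust(heter)
        report = residual_diagnostics(fit, heter)
        assert not report.degenerate
        assert report.hetero_corr > 0
        assert report.hetero_p < 0.05

    def test_normality_rejection_rate_is_calibrated(self):
        # i.i.d. Gaussian residuals: Shapiro-Wilk should reject ~5% of the time
        rng = np.random.default_rng(77)
        n_reps, rejections = 400, 0
        si = rng.uniform(0, 1, 200)
        sst = rng.uniform(0, 1, 200)
        for _ in range(n_reps):
            table = pd.DataFrame(
                {
                    "area_id": ["A"] * 200,
                    "recruit_year": np.arange(200),
                    "y": 0.2 + 0.2 * si - 0.07 * sst + rng.normal(0, 0.1, 200),
                    "si_scaled": si,
                    "sst_scaled": sst,
                }
            )
            report = residual_diagnostics(fit_robust(table), table)
            rejections += report.normality_p < 0.05
        assert 0.02 <= rejections / n_reps <= 0.09

    def test_lag1_autocorrelation_reported_per_area(self, clean_table, rng):
        noisy = clean_table.copy()
        noisy["y"] = noisy["y"] + rng.normal(0, 0.1, len(noisy))
        report = residual_diagnostics(fit_robust(noisy), noisy)
        assert set(report.lag1_by_area) == {"A", "B"}
        assert all(-1 <= v <= 1 for v in report.lag1_by_area.values())
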