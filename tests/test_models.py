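"""Model engine: spec validation, covariate logic, fitting, curves, export."""

import json
import warnings

import numpy as np
import pandas as pd
import pytest

from neurocohort.cohort import complete_cases
from neurocohort.gam import (
    FactorTerm,
    LinearByFactorTerm,
    LinearTerm,
    SmoothByFactorTerm,
    SmoothTerm,
)
from neurocohort.models import (
    ModelSpec,
    SystemColumns,
    build_terms,
    compare_models,
    export_bundle,
    fit_model,
    partial_residuals,
    predict_curves,
    run_bundle_script,
    validate_spec,
)

AREA = "MRI_cort_area.ctx.total"
AGE = "Age_At_IMGExam"


def full_spec(**kw):
    defaults = dict(dependent=AREA, independent=AGE, smooth=True,
                    covariates=["ICV"], interaction="Gender")
    defaults.update(kw)
    return ModelSpec(**defaults)


@pytest.fixture(scope="module")
def fitted(view):
    sc = SystemColumns()
    mt = build_terms(full_spec(), ancestry_names=sc.ancestry_names(view.measures))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_model(view, mt)


class TestValidateSpec:
    def test_valid_spec_has_no_errors(self, dictionary):
        spec = full_spec(covariates=["ICV", "Household_Income"])
        assert validate_spec(spec, dictionary) == []

    def test_typo_gets_nearest_match_suggestion(self, dictionary):
        spec = full_spec(independent="Age_At_IMGExm")
        errors = validate_spec(spec, dictionary)
        assert any("Age_At_IMGExam" in e for e in errors)

    def test_dependent_equal_independent_is_an_error(self, dictionary):
        errors = validate_spec(full_spec(independent=AREA), dictionary)
        assert any("must differ" in e for e in errors)

    def test_interaction_may_not_be_a_covariate(self, dictionary):
        errors = validate_spec(
            full_spec(covariates=["Gender"], interaction="Gender"), dictionary
        )
        assert any("covariate" in e for e in errors)


class TestBuildTerms:
    def test_interaction_brings_main_effect_and_smooth_by(self):
        mt = build_terms(full_spec(), ancestry_names=["GAF_1", "GAF_2"])
        kinds = [(type(t), getattr(t, "role", None)) for t in mt.terms]
        assert (FactorTerm, "interaction_main") in kinds
        assert (SmoothByFactorTerm, "interaction") in kinds

    def test_linear_interaction_when_smooth_off(self):
        mt = build_terms(full_spec(smooth=False), ancestry_names=["GAF_1", "GAF_2"])
        assert any(isinstance(t, LinearByFactorTerm) for t in mt.terms)
        assert not any(isinstance(t, (SmoothTerm, SmoothByFactorTerm)) for t in mt.terms)

    def test_five_ancestry_columns_give_four_terms(self):
        names = [f"GAF_{k}" for k in range(1, 6)]
        mt = build_terms(full_spec(interaction=None), ancestry_names=names)
        ancestry = [t.name for t in mt.terms if getattr(t, "role", "") == "ancestry"]
        assert len(ancestry) == 4
        assert "GAF_5" not in ancestry  # last in canonical order is dropped

    def test_all_system_toggles_off_leaves_user_terms_only(self):
        mt = build_terms(full_spec(interaction=None, use_device=False,
                                   use_ses=False, use_ancestry=False))
        roles = {getattr(t, "role", None) for t in mt.terms}
        assert roles == {"independent", "covariate"}

    def test_ancestry_enabled_without_columns_is_an_error(self):
        with pytest.raises(ValueError, match="ancestry"):
            build_terms(full_spec(), ancestry_names=[])


class TestFitModel:
    def test_recovers_generated_gender_effect_within_3_se(self, fitted, fixture_dir):
        names = fitted.estimator.design_.column_names
        se = np.sqrt(np.diag(fitted.estimator.fit_.cov))
        i = next(j for j, nm in enumerate(names) if nm.startswith("Gender["))
        target = fixture_dir.truth["gender_coefficient_target"]
        assert abs(fitted.estimator.coef_[i] - target) < 3 * se[i]

    def test_recovers_income_slope_within_3_se(self, fitted, fixture_dir):
        names = fitted.estimator.design_.column_names
        se = np.sqrt(np.diag(fitted.estimator.fit_.cov))
        i = names.index("Household_Income")
        assert abs(fitted.estimator.coef_[i] - fixture_dir.truth["income_slope"]) \
            < 3 * se[i]

    def test_n_used_equals_complete_cases(self, view, fitted):
        expected = complete_cases(view, fitted.model_terms.variables).n_sessions
        assert fitted.n_used == expected

    def test_interaction_effect_is_significant(self, fitted):
        assert fitted.term_pvalues[f"s({AGE}):Gender"] < 0.001

    def test_longitudinal_sessions_trigger_warning(self, view):
        df = view.data.iloc[:50].copy()
        second = df.iloc[:5].copy()
        second.index = pd.MultiIndex.from_tuples(
            [(s, "V2") for s, _ in second.index], names=df.index.names
        )
        doubled = pd.concat([df, second])
        mt = build_terms(full_spec(interaction=None, use_device=False,
                                   use_ses=False, use_ancestry=False))
        with pytest.warns(UserWarning, match="cross-sectional"):
            fit_model(doubled, mt)

    def test_noise_covariate_does_not_inflate_adjusted_r2(self):
        """Median adjusted-R2 change from a pure-noise covariate is <= 0."""
        rng = np.random.default_rng(33)
        deltas = []
        for _ in range(50):
            n = 150
            df = pd.DataFrame({
                "x": rng.uniform(0, 10, n),
                "noise": rng.normal(size=n),
            })
            df["y"] = 2.0 + 0.5 * df.x + rng.normal(0, 1.0, n)
            base = fit_model(df, terms_of("y", (LinearTerm("x", role="independent"),)))
            extra = fit_model(df, terms_of("y", (
                LinearTerm("x", role="independent"), LinearTerm("noise"))))
            deltas.append(extra.adjusted_r2 - base.adjusted_r2)
        assert np.median(deltas) <= 0


def terms_of(dependent, terms):
    from neurocohort.models import ModelTerms

    return ModelTerms(dependent, tuple(terms))


class TestPredictCurves:
    def test_one_curve_per_interaction_level(self, fitted):
        curves = predict_curves(fitted, n_grid=40)
        assert sorted(c.level for c in curves) == ["F", "M"]
        assert all(len(c.grid) == 40 for c in curves)

    def test_single_curve_without_interaction(self, view):
        mt = build_terms(full_spec(interaction=None, use_device=False,
                                   use_ses=False, use_ancestry=False))
        fit = fit_model(view, mt)
        curves = predict_curves(fit)
        assert [c.level for c in curves] == ["all"]

    def test_male_peak_earlier_than_female_peak(self, fitted):
        curves = {c.level: c for c in predict_curves(fitted, n_grid=200)}
        male_peak = curves["M"].grid[np.argmax(curves["M"].fitted)]
        female_peak = curves["F"].grid[np.argmax(curves["F"].fitted)]
        assert male_peak < female_peak

    def test_grid_spans_observed_range(self, fitted):
        c = predict_curves(fitted, n_grid=10)[0]
        x = fitted.data[AGE]
        assert c.grid[0] == pytest.approx(x.min())
        assert c.grid[-1] == pytest.approx(x.max())
        assert (np.diff(c.grid) > 0).all()


class TestPartialResiduals:
    def test_zero_covariates_returns_raw_observations(self, view):
        mt = build_terms(full_spec(interaction=None, use_device=False,
                                   use_ses=False, use_ancestry=False,
                                   covariates=[]))
        fit = fit_model(view, mt)
        points = partial_residuals(fit)
        assert np.allclose(points["partial_residual"],
                           fit.data[AREA].to_numpy(float))

    def test_point_count_equals_n_used(self, fitted):
        assert len(partial_residuals(fitted)) == fitted.n_used

    def test_device_offsets_are_removed(self):
        """Known +-200 device offsets: residualized between-device gap
        shrinks by more than 90% relative to the raw gap."""
        rng = np.random.default_rng(44)
        n = 400
        device = np.where(np.arange(n) % 2 == 0, "SN_A", "SN_B")
        age = rng.uniform(3, 21, n)
        offset = np.where(device == "SN_A", 200.0, -200.0)
        y = 1000.0 + 10.0 * age + offset + rng.normal(0, 50.0, n)
        df = pd.DataFrame({"age": age, "dev": device, "y": y})
        fit = fit_model(df, terms_of("y", (
            LinearTerm("age", role="independent"),
            FactorTerm("dev", role="device"))))
        points = partial_residuals(fit)["partial_residual"].to_numpy()
        raw_gap = abs(y[device == "SN_A"].mean() - y[device == "SN_B"].mean())
        res_gap = abs(points[device == "SN_A"].mean()
                      - points[device == "SN_B"].mean())
        assert res_gap < 0.1 * raw_gap

    def test_points_carry_demographics(self, fitted):
        points = partial_residuals(fitted)
        assert {"subject_id", "gender", "age"} <= set(points.columns)


class TestCompareModels:
    def test_identical_fits_have_zero_deltas(self, fitted):
        result = compare_models(fitted, fitted)
        assert result["delta_aic"] == 0.0
        assert result["delta_bic"] == 0.0

    def test_different_row_subsets_are_rejected(self, view):
        mt_full = build_terms(full_spec(), ancestry_names=[f"GAF_{k}" for k in range(1, 6)])
        mt_small = build_terms(full_spec(interaction=None, use_ses=False,
                                         use_device=False, use_ancestry=False))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_a = fit_model(view, mt_full)   # SES missingness drops rows
        fit_b = fit_model(view, mt_small)
        with pytest.raises(ValueError, match="subset"):
            compare_models(fit_a, fit_b)

    def test_true_model_preferred_over_covariate_omitted(self):
        rng = np.random.default_rng(55)
        n = 200
        df = pd.DataFrame({
            "age": rng.uniform(3, 21, n),
            "income": rng.integers(1, 6, n).astype(float),
        })
        df["y"] = 100.0 + 5.0 * df.age + 8.0 * df.income + rng.normal(0, 10.0, n)
        true_fit = fit_model(df, terms_of("y", (
            LinearTerm("age", role="independent"), LinearTerm("income", role="ses"))))
        omitted = fit_model(df, terms_of("y", (
            LinearTerm("age", role="independent"),)))
        assert compare_models(true_fit, omitted)["preferred"] == "A"


class TestExportBundle:
    def test_bundle_rerun_reproduces_coefficients(self, fitted, tmp_path):
        out = export_bundle(fitted, tmp_path / "bundle", n_grid=30)
        refit = run_bundle_script(out)
        for name, value in fitted.coefficients.items():
            assert refit[name] == pytest.approx(value, rel=1e-6)

    def test_curves_csv_row_count(self, fitted, tmp_path):
        out = export_bundle(fitted, tmp_path / "bundle2", n_grid=25)
        curves = pd.read_csv(out / "curves.csv")
        assert len(curves) == 25 * 2  # two gender levels
        assert list(curves.columns) == ["level", "grid", "fitted", "se"]

    def test_summary_json_carries_data_version(self, view, tmp_path):
        table = view.copy()
        table.version_label = "v2.1"
        mt = build_terms(full_spec(interaction=None, use_device=False,
                                   use_ses=False, use_ancestry=False))
        fit = fit_model(table, mt)
        out = export_bundle(fit, tmp_path / "bundle3", n_grid=5)
        meta = json.loads((out / "model.json").read_text())
        assert meta["summary"]["data_version"] == "v2.1"

    def test_scatter_pdf_is_written(self, fitted, tmp_path):
        out = export_bundle(fitted, tmp_path / "bundle4", n_grid=5)
        assert (out / "scatter.pdf").stat().st_size > 0
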