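"""Tests for the quasi-binomial viability model and standardization."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from thermotol.synthetic import ViabilityCurveSpec, generate_viability_data
from thermotol.viability import (
    f_test_nested,
    fit_intercept_only,
    fit_quasibinomial_cubic,
    per_temperature_tests,
    standardize_viability,
)


def newton_raphson_binomial(X, successes, totals, max_iter=60, tol=1e-12):
    """Independent oracle: direct Newton-Raphson maximization of the grouped
    binomial log-likelihood (no IRLS machinery shared with the package)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        p = expit(X @ beta)
        grad = X.T @ (successes - totals * p)
        hess = X.T @ (X * (totals * p * (1 - p))[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta
    raise RuntimeError("oracle did not converge")


def _oracle_design(df, with_interaction=True):
    temps = df["temperature"].to_numpy(float)
    z = (temps - temps.mean()) / temps.std()
    treatments = sorted(df["treatment"].unique())
    t = (df["treatment"].to_numpy() == treatments[1]).astype(float)
    cols = [np.ones(len(df)), z, z**2, z**3, t]
    if with_interaction:
        cols += [t * z, t * z**2, t * z**3]
    return np.column_stack(cols)


class TestQuasiBinomialFit:
    @pytest.mark.parametrize("with_interaction", [True, False])
    def test_coefficients_match_newton_raphson_oracle(
        self, small_viability_fixture, with_interaction
    ):
        fit = fit_quasibinomial_cubic(
            small_viability_fixture, with_interaction=with_interaction
        )
        X = _oracle_design(small_viability_fixture, with_interaction)
        beta = newton_raphson_binomial(
            X,
            small_viability_fixture["adults_emerged"].to_numpy(float),
            small_viability_fixture["eggs_set"].to_numpy(float),
        )
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-6)

    def test_flat_curve_recovers_logit_p(self):
        temps = [11.0, 15.0, 20.0, 25.0, 30.0, 33.0]
        rows = []
        for treatment in ("field", "lab25"):
            for temp in temps:
                for v in range(3):
                    rows.append((f"{treatment}_{temp}_{v}", treatment, temp, 20, 12))
        df = pd.DataFrame(rows, columns=[
            "vial_id", "treatment", "temperature", "eggs_set", "adults_emerged"])
        fit = fit_quasibinomial_cubic(df, with_interaction=False)
        assert fit.params["intercept"] == pytest.approx(logit(0.6), abs=1e-8)
        for term in ("z", "z2", "z3", "treat"):
            assert fit.params[term] == pytest.approx(0.0, abs=1e-7)

    def test_dispersion_near_one_for_binomial_data(self):
        specs = [
            ViabilityCurveSpec(t, (1.5, -0.5, -1.5, -0.4), overdispersion_rho=0.0)
            for t in ("field", "lab25")
        ]
        df = pd.concat(
            [generate_viability_data(s, seed=31 + i) for i, s in enumerate(specs)],
            ignore_index=True,
        )
        fit = fit_quasibinomial_cubic(df)
        assert 0.8 < fit.dispersion_phi < 1.2

    def test_parameter_recovery_with_huge_vials(self):
        """With 10^4 eggs per vial and no overdispersion, fitted
        probabilities reproduce the generating curve to 1e-3."""
        specs = [
            ViabilityCurveSpec("field", (1.0, -0.9, -1.8, -0.3),
                               overdispersion_rho=0.0, vials_per_temp=100,
                               eggs_per_vial=10_000),
            ViabilityCurveSpec("lab25", (1.8, -0.2, -2.0, -0.6),
                               overdispersion_rho=0.0, vials_per_temp=100,
                               eggs_per_vial=10_000),
        ]
        df = pd.concat(
            [generate_viability_data(s, seed=41 + i) for i, s in enumerate(specs)],
            ignore_index=True,
        )
        fit = fit_quasibinomial_cubic(df, with_interaction=True)
        for spec in specs:
            fitted = fit.predict(spec.temperatures, spec.treatment)
            assert np.allclose(fitted, spec.probabilities(), atol=1e-3)

    def test_quasi_scaling_touches_only_standard_errors(
        self, small_viability_fixture
    ):
        """phi rescales the SEs by sqrt(phi) but the point estimates are the
        plain binomial fit (checked against the independent oracle above);
        here: bse/params ratio structure and phi > 0."""
        fit = fit_quasibinomial_cubic(small_viability_fixture)
        assert fit.dispersion_phi > 0
        unscaled = fit.bse / np.sqrt(fit.dispersion_phi)
        assert np.all(unscaled > 0)
        assert np.allclose(fit.bse, unscaled * np.sqrt(fit.dispersion_phi))

    def test_raw_scale_coefficients_equivalent_curve(self, small_viability_fixture):
        fit = fit_quasibinomial_cubic(small_viability_fixture)
        raw = fit.raw_scale_coefficients()
        grid = np.linspace(11, 33, 23)
        base_logit = sum(raw[f"T{i}"] * grid**i for i in range(4))
        assert np.allclose(expit(base_logit), fit.predict(grid, fit.treatments[0]),
                           atol=1e-10)
        both = base_logit + sum(raw[f"treat_T{i}"] * grid**i for i in range(4))
        assert np.allclose(expit(both), fit.predict(grid, fit.treatments[1]),
                           atol=1e-10)

    def test_preconditions(self, small_viability_fixture):
        one_treatment = small_viability_fixture.query("treatment == 'field'")
        with pytest.raises(ValueError, match="2 treatments"):
            fit_quasibinomial_cubic(one_treatment)
        few_temps = small_viability_fixture[
            small_viability_fixture["temperature"] <= 20
        ]
        with pytest.raises(ValueError, match="5 distinct temperatures"):
            fit_quasibinomial_cubic(few_temps)


class TestNestedFTest:
    def test_identical_models_give_f_zero_p_one(self, small_viability_fixture):
        fit = fit_quasibinomial_cubic(small_viability_fixture)
        res = f_test_nested(fit, fit)
        assert res.f_stat == 0.0
        assert res.p_value == 1.0

    def test_df_accounting_on_default_design(self):
        from thermotol.defaults import default_viability_specs

        df = pd.concat(
            [generate_viability_data(s, seed=51 + i)
             for i, s in enumerate(default_viability_specs())],
            ignore_index=True,
        )
        full = fit_quasibinomial_cubic(df, with_interaction=True)
        reduced = fit_quasibinomial_cubic(df, with_interaction=False)
        res = f_test_nested(full, reduced)
        assert res.df_num == 3
        assert res.df_den == len(df) - 8

    def test_non_nested_rejected(self, small_viability_fixture):
        full = fit_quasibinomial_cubic(small_viability_fixture)
        null = fit_intercept_only(small_viability_fixture)
        with pytest.raises(ValueError, match="not nested"):
            f_test_nested(null, full)


class TestStandardization:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=[
            "vial_id", "treatment", "temperature", "eggs_set", "adults_emerged"])

    def test_arithmetic(self):
        df = self._frame([
            ("v1", "field", 20.0, 20, 16),
            ("v2", "field", 25.0, 20, 16),
            ("v3", "field", 29.0, 20, 8),
            ("v1b", "lab25", 20.0, 20, 20),
            ("v2b", "lab25", 25.0, 20, 20),
            ("v3b", "lab25", 29.0, 20, 10),
        ])
        out = standardize_viability(df)
        stress = out.loc[~out["is_benign"]]
        assert stress.loc[stress["treatment"] == "field",
                          "relative_viability"].iloc[0] == pytest.approx(0.5)
        assert stress.loc[stress["treatment"] == "lab25",
                          "relative_viability"].iloc[0] == pytest.approx(0.5)

    def test_benign_mean_normalizes_to_one(self, small_viability_fixture):
        out = standardize_viability(small_viability_fixture)
        for _, grp in out.loc[out["is_benign"]].groupby("treatment"):
            assert grp["relative_viability"].mean() == pytest.approx(1.0, abs=1e-12)

    def test_all_equal_vials_give_unit_relative_viability(self):
        df = self._frame([
            (f"{t}_{temp}", t, temp, 20, 15)
            for t in ("field", "lab25") for temp in (17.0, 20.0, 25.0, 29.0)
        ])
        out = standardize_viability(df)
        assert np.allclose(out["relative_viability"], 1.0)

    def test_missing_benign_temperature_rejected(self):
        df = self._frame([
            ("a", "field", 20.0, 20, 10), ("b", "field", 29.0, 20, 5),
            ("c", "lab25", 20.0, 20, 10), ("d", "lab25", 25.0, 20, 12),
        ])
        with pytest.raises(ValueError, match="benign temperature"):
            standardize_viability(df)

    def test_zero_benign_mean_rejected(self):
        df = self._frame([
            ("a", "field", 20.0, 20, 0), ("b", "field", 25.0, 20, 0),
            ("c", "field", 29.0, 20, 5),
        ])
        with pytest.raises(ValueError, match="0 for"):
            standardize_viability(df)


class TestPerTemperatureTests:
    def test_default_design_yields_eight_rows(self):
        from thermotol.defaults import default_viability_specs

        df = pd.concat(
            [generate_viability_data(s, seed=61 + i)
             for i, s in enumerate(default_viability_specs())],
            ignore_index=True,
        )
        out = per_temperature_tests(standardize_viability(df), n_perm=200, seed=0)
        assert list(out["temperature"]) == [11.0, 14.0, 17.0, 27.0, 29.0, 31.0,
                                            32.0, 33.0]

    def test_identical_treatments_give_null_result(self):
        rows = []
        for t in ("field", "lab25"):
            for temp in (20.0, 25.0, 29.0):
                for v in range(5):
                    rows.append((f"{t}_{temp}_{v}", t, temp, 20, 10 + v))
        df = pd.DataFrame(rows, columns=[
            "vial_id", "treatment", "temperature", "eggs_set", "adults_emerged"])
        out = per_temperature_tests(standardize_viability(df), n_perm=500, seed=1)
        assert len(out) == 1
        assert out["md_diff"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["p_value"].iloc[0] == 1.0

    def test_single_treatment_temperature_skipped(self, caplog):
        rows = [
            (f"f_{temp}_{v}", "field", temp, 20, 12)
            for temp in (20.0, 25.0, 29.0) for v in range(3)
        ] + [
            (f"l_{temp}_{v}", "lab25", temp, 20, 14)
            for temp in (20.0, 25.0) for v in range(3)
        ]
        df = pd.DataFrame(rows, columns=[
            "vial_id", "treatment", "temperature", "eggs_set", "adults_emerged"])
        import logging

        with caplog.at_level(logging.WARNING, logger="thermotol.viability"):
            out = per_temperature_tests(standardize_viability(df), n_perm=100,
                                        seed=2)
        assert out.empty
        assert "skipping" in caplog.text
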