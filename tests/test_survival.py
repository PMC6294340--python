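"""Mixed-effects Cox machinery: closed forms, oracles, shrinkage, maps."""

import numpy as np
import pandas as pd
import pytest

from spatgxe.simulation import SimulationConfig, simulate_population
from spatgxe.survival import (
    CoxData,
    ModelSpec,
    fit_fixed_only,
    fit_inner,
    fit_variance_components,
    lrt_random_effects,
    median_hazard_ratio,
    model_spec,
    urban_rural_contrast,
    weighted_partial_loglik,
)

from conftest import random_survival_frame

NULL_SPEC = ModelSpec((), False, False, strata_col=None)


class TestPartialLoglikClosedForms:
    def test_three_distinct_events_null_model(self):
        df = pd.DataFrame({"event_age": [1.0, 2.0, 3.0], "case": 1, "weight": 1.0})
        v = weighted_partial_loglik(CoxData(df, NULL_SPEC), np.empty(0), order=0)
        assert v == pytest.approx(-np.log(6), abs=1e-12)

    def test_weighted_breslow_closed_form(self):
        # weight-2 subject fails first: -(2 log 4 + log 2)
        df = pd.DataFrame(
            {"event_age": [1.0, 2.0, 3.0], "case": 1, "weight": [2.0, 1.0, 1.0]}
        )
        v = weighted_partial_loglik(CoxData(df, NULL_SPEC), np.empty(0), order=0)
        assert v == pytest.approx(-(2 * np.log(4) + np.log(2)), abs=1e-12)

    def test_all_censored_stratum_contributes_zero(self):
        df = pd.DataFrame(
            {
                "event_age": [1.0, 2.0, 3.0, 4.0],
                "case": [1, 1, 0, 0],
                "weight": 1.0,
                "res_stratum": [0, 0, 1, 1],
            }
        )
        spec = ModelSpec((), False, False, strata_col="res_stratum")
        v = weighted_partial_loglik(CoxData(df, spec), np.empty(0), order=0)
        assert v == pytest.approx(-(np.log(2) + np.log(1)), abs=1e-12)

    def test_nonfinite_eta_names_subject(self):
        df = random_survival_frame(0, n=20)
        df["subject_id"] = [f"S{i}" for i in range(20)]
        spec = ModelSpec(("x1",), False, False, strata_col=None)
        data = CoxData(df, spec)
        with pytest.raises(FloatingPointError, match="S"):
            weighted_partial_loglik(data, np.array([np.inf]), order=0)


class TestDerivatives:
    @pytest.mark.parametrize("with_random", [False, True])
    def test_gradient_matches_finite_differences(self, with_random):
        df = random_survival_frame(1, n=50, n_locales=5)
        spec = ModelSpec(("x1", "x2"), with_random, with_random,
                         strata_col="res_stratum")
        data = CoxData(df, spec)
        p, qE, qG = data.dim()
        dim = p + qE + qG
        r = np.random.default_rng(2)
        x0 = r.normal(scale=0.3, size=dim)

        def split(x):
            return x[:p], x[p:p + qE] if qE else None, x[p + qE:] if qG else None

        v, g, h = weighted_partial_loglik(data, *split(x0), order=2)
        eps = 1e-6
        for i in range(dim):
            e = np.zeros(dim)
            e[i] = eps
            fp = weighted_partial_loglik(data, *split(x0 + e), order=0)
            fm = weighted_partial_loglik(data, *split(x0 - e), order=0)
            fd = (fp - fm) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-6, abs=1e-7)

    def test_hessian_matches_gradient_differences(self):
        df = random_survival_frame(3, n=40, n_locales=4)
        spec = ModelSpec(("x1",), True, True, strata_col=None)
        data = CoxData(df, spec)
        p, qE, qG = data.dim()
        dim = p + qE + qG
        x0 = np.random.default_rng(4).normal(scale=0.2, size=dim)
        _, _, h = weighted_partial_loglik(
            data, x0[:p], x0[p:p + qE], x0[p + qE:], order=2
        )
        eps = 1e-6
        for i in range(dim):
            e = np.zeros(dim)
            e[i] = eps
            _, gp = weighted_partial_loglik(
                data, (x0 + e)[:p], (x0 + e)[p:p + qE], (x0 + e)[p + qE:], order=1
            )
            _, gm = weighted_partial_loglik(
                data, (x0 - e)[:p], (x0 - e)[p:p + qE], (x0 - e)[p + qE:], order=1
            )
            # h is the information (negative Hessian)
            np.testing.assert_allclose(-h[:, i], (gp - gm) / (2 * eps), atol=1e-5)


class TestReferenceCoxEquivalence:
    @pytest.mark.parametrize("n", [200, 1000])
    def test_fixed_effects_match_lifelines(self, n):
        from lifelines import CoxPHFitter

        df = random_survival_frame(5, n=n)
        spec = ModelSpec(("x1", "x2", "prs"), False, False, strata_col="res_stratum")
        fit = fit_fixed_only(CoxData(df, spec))
        cph = CoxPHFitter()
        cph.fit(
            df[["event_age", "case", "x1", "x2", "prs", "weight", "res_stratum"]],
            "event_age", "case", weights_col="weight", strata=["res_stratum"],
            robust=True,
        )
        np.testing.assert_allclose(fit.beta, cph.params_.values, rtol=1e-4)
        assert fit.loglik == pytest.approx(cph.log_likelihood_, rel=1e-6)

    def test_robust_sandwich_se_match_lifelines(self):
        from lifelines import CoxPHFitter

        from spatgxe.survival import _robust_se

        df = random_survival_frame(6, n=300)
        spec = ModelSpec(("x1", "x2"), False, False, strata_col="res_stratum")
        data = CoxData(df, spec)
        fit = fit_fixed_only(data)
        cph = CoxPHFitter()
        cph.fit(
            df[["event_age", "case", "x1", "x2", "weight", "res_stratum"]],
            "event_age", "case", weights_col="weight", strata=["res_stratum"],
            robust=True,
        )
        np.testing.assert_allclose(
            _robust_se(data, fit), cph.standard_errors_.values, rtol=1e-4
        )

    def test_vanishing_variance_recovers_fixed_cox(self):
        df = random_survival_frame(7, n=300, n_locales=6)
        spec = ModelSpec(("x1", "x2"), True, False, strata_col=None)
        data = CoxData(df, spec)
        inner = fit_inner(data, (1e-10, 0.0))
        spec0 = ModelSpec(("x1", "x2"), False, False, strata_col=None)
        ref = fit_fixed_only(CoxData(df, spec0))
        np.testing.assert_allclose(inner.beta, ref.beta, atol=1e-4)
        assert np.max(np.abs(inner.b_E)) < 1e-5


class TestInnerFit:
    def test_eventless_locale_blup_negative_finite(self):
        df = random_survival_frame(8, n=200, n_locales=5)
        df.loc[df["locale_id"] == 3, "case"] = 0  # locale 3 has no events
        spec = ModelSpec(("x1",), True, False, strata_col=None)
        inner = fit_inner(CoxData(df, spec), (0.5, 0.0))
        assert inner.converged
        b3 = inner.b_E[3]
        assert np.isfinite(b3) and b3 < 0

    def test_negative_theta_rejected(self):
        df = random_survival_frame(9, n=50, n_locales=4)
        spec = ModelSpec(("x1",), True, False, strata_col=None)
        with pytest.raises(ValueError, match="non-negative"):
            fit_inner(CoxData(df, spec), (-0.1, 0.0))

    def test_shrinkage_toward_zero_with_smaller_variance(self):
        df = random_survival_frame(10, n=300, n_locales=6)
        spec = ModelSpec(("x1",), True, False, strata_col=None)
        data = CoxData(df, spec)
        b_loose = fit_inner(data, (100.0, 0.0)).b_E  # near-unpenalized
        b_tight = fit_inner(data, (0.05, 0.0)).b_E
        assert np.all(np.abs(b_tight) <= np.abs(b_loose) + 1e-8)


class TestVarianceComponents:
    def test_single_locale_error(self):
        df = random_survival_frame(11, n=50, n_locales=1)
        spec = ModelSpec(("x1",), True, False, strata_col=None)
        with pytest.raises(ValueError, match="at least 2 locales"):
            fit_variance_components(df, spec)

    def test_recovers_nonzero_variance_and_likelihood_ascent(self):
        cfg = SimulationConfig(n_individuals=8000, n_locales=80, sigma2_E=0.5,
                               prevalence=0.05, seed=21)
        pop, _ = simulate_population(cfg)
        spec = ModelSpec(("prs",), True, False, strata_col=None)
        fit = fit_variance_components(pop, spec, robust=False)
        assert fit.converged
        assert 0.1 < fit.sigma2_E < 1.5
        # ascent relative to the no-random-effects likelihood
        assert fit.loglik_integrated >= fit.loglik_fixed - 1e-8

    def test_null_data_estimates_near_zero(self):
        cfg = SimulationConfig(n_individuals=8000, n_locales=50, sigma2_E=0.0,
                               prevalence=0.05, seed=22)
        pop, _ = simulate_population(cfg)
        spec = ModelSpec(("prs",), True, False, strata_col=None)
        fit = fit_variance_components(pop, spec, robust=False)
        assert fit.sigma2_E < 0.02

    def test_blups_shrink_toward_zero_mean(self, small_population):
        pop, truth, _ = small_population
        spec = ModelSpec(("prs",), True, False, strata_col=None)
        fit = fit_variance_components(pop, spec, robust=False)
        if fit.sigma2_E > 0:
            assert np.var(fit.blup_E) <= np.var(truth["b_E"]) * 2.5
            assert abs(fit.blup_E.mean()) < 0.2


class TestLRT:
    def make_fits(self):
        cfg = SimulationConfig(n_individuals=3000, n_locales=20, sigma2_E=0.3,
                               prevalence=0.05, seed=23)
        pop, _ = simulate_population(cfg)
        full = fit_variance_components(
            pop, ModelSpec(("prs",), True, False, strata_col=None), robust=False
        )
        reduced = fit_variance_components(
            pop, ModelSpec(("prs",), False, False, strata_col=None), robust=False
        )
        return full, reduced

    def test_statistic_df_and_p(self):
        full, reduced = self.make_fits()
        stat, df, p = lrt_random_effects(full, reduced)
        assert df == 1
        assert stat >= 0
        assert 0 <= p <= 1

    def test_identical_fits_give_zero_statistic(self):
        full, _ = self.make_fits()
        stat, df, p = lrt_random_effects(full, full)
        assert (stat, df, p) == (0.0, 0, 1.0)

    def test_non_nested_specs_rejected(self):
        full, reduced = self.make_fits()
        with pytest.raises(ValueError, match="nested"):
            lrt_random_effects(reduced, full)


class TestMedianHazardRatio:
    def test_equal_blups_give_unity(self):
        res = median_hazard_ratio(np.zeros(5))
        assert res["pairwise_empirical"].mhr == 1.0

    def test_three_blup_enumeration(self):
        res = median_hazard_ratio(np.array([0.0, np.log(2), np.log(4)]))
        # pairwise |diffs| = {ln2, ln4, ln2}; median = ln2
        assert res["pairwise_empirical"].mhr == pytest.approx(2.0, abs=1e-12)

    def test_gaussian_closed_form_consistency(self):
        r = np.random.default_rng(24)
        b = r.normal(size=2000)
        res = median_hazard_ratio(b, sigma2=1.0)
        assert res["closed_form"].mhr == pytest.approx(
            np.exp(np.sqrt(2) * 0.6744897501960817), rel=1e-6
        )
        assert res["pairwise_empirical"].mhr == pytest.approx(
            res["closed_form"].mhr, rel=0.02
        )

    def test_requires_two_locales(self):
        with pytest.raises(ValueError):
            median_hazard_ratio(np.array([0.1]))


class TestRiskMapExport:
    def make_map(self, n=10):
        from spatgxe.tessellation import GridPoint, build_tessellation, grow_locales

        r = np.random.default_rng(25)
        pts = [GridPoint(x, y, 5) for x, y in r.uniform(0, 10000, (n, 2))]
        return grow_locales(build_tessellation(pts), n_min=1)

    def fake_fit(self, blup_E, blup_GxE=None):
        from spatgxe.survival import SpatialCoxFit

        spec = ModelSpec(("prs",), True, blup_GxE is not None, strata_col=None)
        return SpatialCoxFit(
            spec=spec, beta=pd.Series(dtype=float), se=pd.Series(dtype=float),
            robust_se=None, sigma2_E=0.1, sigma2_GxE=0.1,
            blup_E=blup_E,
            blup_GxE=blup_GxE if blup_GxE is not None else pd.Series(dtype=float),
            loglik_integrated=0.0, loglik_penalized=0.0, loglik_fixed=0.0,
            converged=True, n_iter=1,
        )

    def test_zero_blups_give_unit_hazard_ratios(self):
        from spatgxe.survival import export_risk_map

        lmap = self.make_map()
        ids = [l.id for l in lmap.locales]
        fit = self.fake_fit(pd.Series(0.0, index=ids))
        gj = export_risk_map(fit, lmap)
        assert all(f["properties"]["hr_E"] == 1.0 for f in gj["features"])

    def test_log2_blup_maps_to_hr_2(self):
        from spatgxe.survival import export_risk_map

        lmap = self.make_map()
        ids = [l.id for l in lmap.locales]
        b = pd.Series(0.0, index=ids)
        b.iloc[0] = np.log(2)
        gj = export_risk_map(self.fake_fit(b), lmap)
        hrs = {f["properties"]["locale_id"]: f["properties"]["hr_E"] for f in gj["features"]}
        assert hrs[ids[0]] == pytest.approx(2.0)

    def test_ten_distinct_hrs_fill_each_decile_once(self):
        from spatgxe.survival import export_risk_map

        lmap = self.make_map(10)
        ids = [l.id for l in lmap.locales]
        gj = export_risk_map(
            self.fake_fit(pd.Series(np.linspace(-1, 1, len(ids)), index=ids)), lmap
        )
        deciles = sorted(f["properties"]["hr_E_decile"] for f in gj["features"])
        assert deciles == list(range(1, 11))

    def test_missing_locale_gets_null_property(self):
        from spatgxe.survival import export_risk_map

        lmap = self.make_map()
        ids = [l.id for l in lmap.locales]
        fit = self.fake_fit(pd.Series(0.0, index=ids[:-1]))
        gj = export_risk_map(fit, lmap)
        props = {f["properties"]["locale_id"]: f["properties"] for f in gj["features"]}
        assert props[ids[-1]]["hr_E"] is None


def test_model3_spec_contains_prs_interactions():
    spec = model_spec(3)
    assert spec.random_intercept and spec.random_slope
    assert "prs:famhx" in spec.fixed and "prs:pc1" in spec.fixed


def test_urban_rural_contrast_scales_density_coefficient():
    df = random_survival_frame(26, n=500)
    df["log_density"] = np.random.default_rng(26).normal(size=len(df))
    spec = ModelSpec(("x1", "log_density"), False, False, strata_col=None)
    fit = fit_variance_components(df, spec, robust=False)
    res = urban_rural_contrast(fit)
    delta = np.log(5220.0) - np.log(55.0)
    assert res["hr"] == pytest.approx(np.exp(fit.beta["log_density"] * delta))
    assert res["ci_low"] <= res["hr"] <= res["ci_high"]


from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=30)
@given(
    blups=st.lists(st.floats(-3, 3, allow_nan=False), min_size=2, max_size=20),
    shift=st.floats(-2, 2, allow_nan=False),
)
def test_median_hr_at_least_one_and_translation_invariant(blups, shift):
    b = np.asarray(blups)
    res = median_hazard_ratio(b)["pairwise_empirical"].mhr
    assert res >= 1.0
    shifted = median_hazard_ratio(b + shift)["pairwise_empirical"].mhr
    assert shifted == pytest.approx(res, rel=1e-12)
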