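"""Acclimated surfaces and the homeostasis ratio: closed forms, invariances,
homotopy toward perfect homeostasis, and the respiration/V_cmax ratio."""

import numpy as np
import pandas as pd
import pytest

from rdacclim import (
    AcclimationSurface,
    ParameterTrendSet,
    PolynomialFit,
    acclim_homeo,
    build_surface,
    build_surfaces,
    compute_ratio_records,
    evaluate_polynomial,
    fit_all_individuals,
    fit_mixed_ancova,
    homeostasis_table,
    make_design,
    rd_at_acclimation,
    simulate_measurements,
)
from rdacclim.surface import acclim_homeo_individual
from rdacclim.synthetic import default_trends

from helpers import zero_variance_truth

TA_GRID = (15.0, 20.0, 30.0, 35.0)


def flat_trendset(a=-6.5, b=0.0, c=0.0, tissues=("leaf", "root")):
    """No parameter drift with T_a; instantaneous shape (b, c) fixed."""
    return ParameterTrendSet({t: {"a": (a, 0.0), "b": (b, 0.0), "c": (c, 0.0)}
                              for t in tissues})


class TestBuildSurface:
    def test_zero_slopes_make_surface_ta_independent(self):
        surf = build_surface(flat_trendset(b=0.1, c=-0.001), "leaf")
        for t_tissue in (10.0, 25.0, 40.0):
            vals = [surf.evaluate(t_tissue, ta) for ta in (15, 25, 35)]
            assert np.ptp(vals) == 0.0

    def test_fixed_ta_reduces_to_polynomial_evaluation(self):
        trends = ParameterTrendSet({"root": {
            "a": (-7.0, 0.02), "b": (0.15, -0.003), "c": (-0.002, 5e-5)}})
        surf = build_surface(trends, "root")
        ta = 30.0
        a, b, c = surf.params_at(ta)
        fit = PolynomialFit(a=a, b=b, c=c, rmse=0.0, n_points=5)
        for T in (14.0, 25.0, 41.0):
            assert surf.evaluate(T, ta) == pytest.approx(
                evaluate_polynomial(fit, T), rel=1e-14)

    def test_spot_values_match_direct_exponential(self):
        trends = ParameterTrendSet({"leaf": {
            "a": (-6.2, 0.01), "b": (0.09, -0.002), "c": (-0.001, 3e-5)}})
        surf = build_surface(trends, "leaf")
        for tt, ta in ((14.0, 15.0), (32.0, 20.0), (45.0, 35.0)):
            direct = np.exp((-6.2 + 0.01 * ta) + (0.09 - 0.002 * ta) * tt
                            + (-0.001 + 3e-5 * ta) * tt ** 2)
            assert surf.evaluate(tt, ta) == pytest.approx(direct, rel=1e-14)

    def test_missing_trend_rejected(self):
        with pytest.raises(KeyError):
            ParameterTrendSet({"leaf": {"a": (0, 0), "b": (0, 0)}})


class TestRdAtAcclimation:
    def test_flat_unit_surface_is_one_everywhere(self):
        surf = build_surface(flat_trendset(a=0.0), "leaf")
        for ta in (15.0, 25.0, 35.0):
            assert rd_at_acclimation(surf, ta) == 1.0

    def test_equals_surface_diagonal(self):
        trends = ParameterTrendSet({"root": {
            "a": (-7.0, 0.02), "b": (0.15, -0.003), "c": (-0.002, 5e-5)}})
        surf = build_surface(trends, "root")
        for ta in TA_GRID:
            assert rd_at_acclimation(surf, ta) == surf.evaluate(ta, ta)


class TestAcclimHomeo:
    def test_flat_homeostatic_surface_gives_one(self):
        surf = build_surface(flat_trendset(), "leaf")
        for ta in TA_GRID:
            assert acclim_homeo(surf, ta) == pytest.approx(1.0, abs=1e-12)

    def test_reference_temperature_is_exactly_one(self):
        trends = ParameterTrendSet({"root": {
            "a": (-7.0, 0.02), "b": (0.15, -0.003), "c": (-0.002, 5e-5)}})
        assert acclim_homeo(build_surface(trends, "root"), 25.0) == 1.0

    def test_non_acclimating_exponential_closed_form(self):
        # b = 0.07, c = 0, no trends: both sides of the reference give
        # exp(-0.7) because the orientation swap makes the case symmetric
        surf = build_surface(flat_trendset(b=0.07), "leaf")
        assert acclim_homeo(surf, 15.0) == pytest.approx(np.exp(-0.7), rel=1e-12)
        assert acclim_homeo(surf, 35.0) == pytest.approx(np.exp(-0.7), rel=1e-12)

    def test_basal_rate_invariance(self):
        base = default_trends()
        shifted = {t: {**tr, "a": (tr["a"][0] + 1.234, tr["a"][1])}
                   for t, tr in base.items()}
        s1 = build_surfaces(ParameterTrendSet(base))
        s2 = build_surfaces(ParameterTrendSet(shifted))
        for tissue in s1:
            for ta in TA_GRID:
                assert abs(acclim_homeo(s1[tissue], ta)
                           - acclim_homeo(s2[tissue], ta)) < 1e-12

    def test_homotopy_toward_homeostatic_trends(self):
        """Linearly interpolating the trends from a non-acclimating surface
        to one whose diagonal R_d(T_a; T_a) is constant must drive every
        grid value monotonically to 1."""
        start = {"a": (-6.5, 0.0), "b": (0.1, 0.0), "c": (0.0, 0.0)}
        target = {"a": (-6.5 + 0.1 * 25.0, -0.1), "b": (0.1, 0.0),
                  "c": (0.0, 0.0)}  # a-slope cancels the diagonal exactly
        prev = None
        for lam in (0.0, 0.25, 0.5, 0.75, 1.0):
            trends = ParameterTrendSet({"leaf": {
                p: tuple((1 - lam) * np.array(start[p])
                         + lam * np.array(target[p])) for p in "abc"}})
            surf = build_surface(trends, "leaf")
            dev = max(abs(acclim_homeo(surf, ta) - 1.0) for ta in TA_GRID)
            if prev is not None:
                assert dev < prev
            prev = dev
        assert prev == pytest.approx(0.0, abs=1e-12)

    def test_monotone_approach_to_reference(self):
        # T_a-invariant surface, instantaneous response strictly increasing
        # on [15, 35]: homeostasis improves monotonically toward T_ref
        surf = build_surface(flat_trendset(b=0.12, c=-0.001), "leaf")
        below = [acclim_homeo(surf, ta) for ta in np.linspace(15, 24.9, 30)]
        above = [acclim_homeo(surf, ta) for ta in np.linspace(35, 25.1, 30)]
        assert np.all(np.diff(below) > 0)
        assert np.all(np.diff(above) > 0)
        assert max(below + above) < 1.0


class TestHomeostasisTable:
    def test_averages_are_means_of_grid(self):
        surfaces = build_surfaces(ParameterTrendSet(default_trends()))
        result = homeostasis_table(surfaces)
        np.testing.assert_allclose(result.tissue_averages,
                                   result.grid.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(result.ta_averages,
                                   result.grid.mean(axis=1), atol=1e-12)
        assert result.grand_average == pytest.approx(
            result.grid.to_numpy().mean(), abs=1e-12)

    def test_all_flat_surfaces_give_all_ones(self):
        surfaces = build_surfaces(flat_trendset(tissues=("leaf", "root")))
        result = homeostasis_table(surfaces)
        np.testing.assert_allclose(result.grid.to_numpy(), 1.0, atol=1e-12)
        assert result.grand_average == pytest.approx(1.0, abs=1e-12)

    def test_report_layout(self):
        surfaces = build_surfaces(ParameterTrendSet(default_trends()))
        frame = homeostasis_table(surfaces).to_frame()
        assert list(frame.index) == ["15 C", "20 C", "30 C", "35 C", "Average"]
        assert list(frame.columns) == ["leaf", "ps_stem", "nonps_stem",
                                       "root", "Average"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            homeostasis_table({})


class TestIndividualVariant:
    def test_matches_population_formula_for_shared_curve(self):
        fit = PolynomialFit(a=-6.0, b=0.07, c=0.0, rmse=0.0, n_points=5)
        assert acclim_homeo_individual(fit, fit, 15.0) == pytest.approx(
            np.exp(-0.7), rel=1e-12)
        assert acclim_homeo_individual(fit, fit, 25.0) == 1.0


@pytest.fixture(scope="module")
def constructed_study():
    """V_cmax constant in T_a; non-Ps-stem respiration built so that
    ln(R_d,acc/V_cmax,acc) = -2.20 - 0.063 * T_a exactly (no noise)."""
    av = -0.6
    trends = {
        "leaf": {"a": (av - 3.0, 0.0), "b": (0.0, 0.0), "c": (0.0, 0.0)},
        "ps_stem": {"a": (av - 3.2, 0.0), "b": (0.0, 0.0), "c": (0.0, 0.0)},
        "nonps_stem": {"a": (av - 2.20, -0.063), "b": (0.0, 0.0),
                       "c": (0.0, 0.0)},
        "root": {"a": (av - 2.94, -0.030), "b": (0.0, 0.0), "c": (0.0, 0.0)},
    }
    vtrends = {"a": (av, 0.0), "b": (0.0, 0.0), "c": (0.0, 0.0)}
    design = make_design("balanced", species=["s1", "s2"], n_per_cell=2,
                         seed=21, tissue_plan={
                             "s1": ("leaf", "stem", "root"),
                             "s2": ("leaf", "stem", "root")},
                         tissue_class_map={
                             ("s1", "leaf"): "photosynthetic",
                             ("s1", "stem"): "non_photosynthetic",
                             ("s1", "root"): "non_photosynthetic",
                             ("s2", "leaf"): "photosynthetic",
                             ("s2", "stem"): "photosynthetic",
                             ("s2", "root"): "non_photosynthetic"})
    truth = zero_variance_truth(trends=trends, vcmax_trends=vtrends)
    study = simulate_measurements(design, truth)
    rd_fits, _ = fit_all_individuals(study.records)
    vc_fits, _ = fit_all_individuals(study.vcmax_records)
    return rd_fits, vc_fits


class TestRatioRecords:
    def test_constructed_ln_ratio_slope_recovered(self, constructed_study):
        rd_fits, vc_fits = constructed_study
        ratio = compute_ratio_records(rd_fits, vc_fits)
        model = fit_mixed_ancova(ratio, "ln_ratio")
        trends = model.lsm_trends().set_index("tissue_class4")
        assert trends.loc["nonps_stem", "slope"] == pytest.approx(-0.063,
                                                                  abs=1e-6)
        assert trends.loc["root", "slope"] == pytest.approx(-0.030, abs=1e-6)
        assert trends.loc["leaf", "slope"] == pytest.approx(0.0, abs=1e-6)

    def test_constant_ratio_construction(self, table1_design):
        trends = default_trends()
        leaf = trends["leaf"]
        vtrends = {"a": (leaf["a"][0] + np.log(10.0), leaf["a"][1]),
                   "b": leaf["b"], "c": leaf["c"]}
        truth = zero_variance_truth(trends=trends, vcmax_trends=vtrends)
        study = simulate_measurements(table1_design, truth)
        rd_fits, _ = fit_all_individuals(study.records)
        vc_fits, _ = fit_all_individuals(study.vcmax_records)
        ratio = compute_ratio_records(
            rd_fits[rd_fits["tissue"] == "leaf"], vc_fits)
        np.testing.assert_allclose(ratio["rd_acc"] / ratio["vcmax_acc"], 0.1,
                                   rtol=1e-8)
        model = fit_mixed_ancova(ratio, "ln_ratio")
        assert np.max(np.abs(model.lsm_trends()["slope"])) < 1e-8

    def test_invalid_rate_excluded_with_warning(self, constructed_study,
                                                caplog):
        rd_fits, vc_fits = constructed_study
        broken = vc_fits.copy()
        broken.loc[broken.index[0], "a"] = -800.0  # V_cmax,acc underflows to 0
        with caplog.at_level("WARNING", logger="rdacclim.surface"):
            ratio = compute_ratio_records(rd_fits, broken)
        assert "excluded" in caplog.text
        full = compute_ratio_records(rd_fits, vc_fits)
        assert len(ratio) < len(full)

    def test_no_overlap_rejected(self, constructed_study):
        rd_fits, vc_fits = constructed_study
        vc_other = vc_fits.copy()
        vc_other["individual_id"] = "elsewhere_" + vc_other["individual_id"]
        with pytest.raises(ValueError, match="overlap"):
            compute_ratio_records(rd_fits, vc_other)
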