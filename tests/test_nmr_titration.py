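"""Fast-exchange observation model, global fitting, model selection."""

import math

import numpy as np
import pytest

from quadbind import (
    BindingModelSpec,
    DomainError,
    FitOptions,
    ModelId,
    NucleusTrace,
    ShiftParameters,
    TitrationDesign,
    TitrationSeries,
    average_constants,
    compare_models,
    fit_titration,
    gen_titration,
    merge_replicates,
    predict_shifts,
    statistical_from_micro,
)
from conftest import bisection_oracle


def make_series(equivalents, shifts_ppm, fixed=125e-6, **kw):
    return TitrationSeries(
        fixed_species_total=fixed,
        equivalents=np.asarray(equivalents),
        nuclei=(NucleusTrace("H1", np.asarray(shifts_ppm)),),
        **kw,
    )


class TestSeriesValidation:
    def test_equivalents_must_increase(self):
        with pytest.raises(DomainError):
            make_series([0.0, 0.5, 0.5], [7.3, 7.2, 7.1])

    def test_trace_length_must_match(self):
        with pytest.raises(DomainError):
            TitrationSeries(
                fixed_species_total=125e-6,
                equivalents=np.array([0.0, 1.0]),
                nuclei=(NucleusTrace("H1", np.array([7.3])),),
            )

    def test_titrant_defaults_to_equivalents_times_fixed(self):
        s = make_series([0.0, 1.0, 2.0], [7.3, 7.2, 7.1])
        np.testing.assert_allclose(s.titrant_total, [0.0, 125e-6, 250e-6])


class TestPredictShifts:
    def test_zero_titrant_returns_delta_free_exactly(self):
        s = make_series([0.0, 0.5, 1.0, 1.5, 2.0], [7.3] * 5)
        shifts = {"H1": ShiftParameters(7.300, 7.100, 7.100)}
        pred = predict_shifts(statistical_from_micro(5e3), shifts, s)
        assert pred["H1"][0] == 7.300  # bit-for-bit

    def test_null_response_is_constant(self):
        s = make_series([0.0, 0.5, 1.0, 1.5, 2.0], [0.0] * 5)
        shifts = {"H1": ShiftParameters(7.300, 7.300, 7.300)}
        pred = predict_shifts(statistical_from_micro(5e3), shifts, s)
        np.testing.assert_allclose(pred["H1"], 7.300, rtol=1e-12)

    def test_weighted_average_matches_speciation_oracle(self):
        """Prediction is delta_free minus the excursion times the ligand
        bound fraction, with the bound fraction from an independent bisection."""
        m = BindingModelSpec(ModelId.TWO_TO_ONE_FULL, K1=2000.0, K2=500.0)
        s = make_series([0.0, 0.5], [0.0, 0.0])
        shifts = {"H1": ShiftParameters(7.300, 7.100, 7.100)}
        pred = predict_shifts(m, shifts, s)
        p = bisection_oracle(62.5e-6, 125e-6, 2000.0, 500.0)
        denom = 1 + 2000.0 * p + 2000.0 * 500.0 * p * p
        bound = 62.5e-6 * (2000.0 * p + 2 * 2000.0 * 500.0 * p * p) / denom
        expected = 7.300 - 0.200 * bound / 125e-6
        assert pred["H1"][1] == pytest.approx(expected, rel=1e-9)

    def test_monotone_isotherm_for_fixed_sign_excursion(self):
        grid = np.linspace(0.0, 2.0, 25)
        s = make_series(grid, np.zeros(grid.size))
        shifts = {"H1": ShiftParameters(7.300, 7.100, 7.100)}
        for model in (statistical_from_micro(5e3), BindingModelSpec(ModelId.ONE_TO_ONE, K1=5e3)):
            pred = predict_shifts(model, shifts, s)["H1"]
            assert np.all(np.diff(pred) <= 1e-15)


class TestFitTitration:
    def test_noiseless_recovery(self, noiseless_titration):
        series, truth = noiseless_titration
        fit = fit_titration(series, ModelId.TWO_TO_ONE_STATISTICAL)
        k_true = truth["K1"] / 2.0
        assert fit.model.k_micro == pytest.approx(k_true, rel=1e-3)
        sp = fit.shifts["Phe_aromatic_H"]
        assert sp.delta_free == pytest.approx(7.300, abs=1e-4)
        assert sp.delta_bound_1 == pytest.approx(7.180, abs=1e-4)
        assert sp.delta_bound_1 == sp.delta_bound_2  # one bound environment

    def test_flat_trace_flagged_unidentifiable(self):
        grid = np.linspace(0.0, 2.0, 12)
        s = make_series(grid, np.full(grid.size, 7.300))
        fit = fit_titration(s, ModelId.TWO_TO_ONE_STATISTICAL)
        assert fit.unidentifiable
        assert math.isnan(fit.standard_errors["k_micro"])

    def test_too_few_points_rejected(self):
        s = make_series([0.0, 0.5, 1.0, 1.5], [7.3, 7.25, 7.22, 7.2])
        with pytest.raises(DomainError):
            fit_titration(s, ModelId.TWO_TO_ONE_STATISTICAL)

    def test_reparametrization_invariance(self, noiseless_titration):
        """A fine brute-force grid in plain K finds no better optimum than the
        log10-space fit (same minimum rss to 1e-6 relative)."""
        series, truth = noiseless_titration
        fit = fit_titration(series, ModelId.TWO_TO_ONE_STATISTICAL)

        def rss_at_k(k):
            model = statistical_from_micro(k)
            shifts = {}
            x = []
            for r_tot, in zip(series.titrant_total):
                from quadbind import MixtureComposition, solve_speciation

                res = solve_speciation(model, MixtureComposition(float(r_tot), series.fixed_species_total))
                l = series.fixed_species_total
                x.append([res.free_ligand / l, (res.complex_RL + 2 * res.complex_RL2) / l])
            X = np.asarray(x)
            y = series.nuclei[0].delta_obs
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ coef
            return float(r @ r)

        ks = np.linspace(0.95 * fit.model.k_micro, 1.05 * fit.model.k_micro, 101)
        best_grid = min(rss_at_k(k) for k in ks)
        assert fit.rss <= best_grid + 1e-6 * max(best_grid, 1e-30)

    def test_aicc_matches_hand_formula(self, noisy_titration):
        series, _ = noisy_titration
        fit = fit_titration(series, ModelId.TWO_TO_ONE_STATISTICAL)
        n, p, rss = fit.n_points, fit.n_params, fit.rss
        expected = n * math.log(rss / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)
        assert fit.aicc == pytest.approx(expected, rel=1e-12)
        assert n == 12 and p == 3


class TestMergeReplicates:
    def test_global_fit_recovers_truth(self):
        series_list, truth = gen_titration(TitrationDesign(noise_sd=0.002, seed=21))
        joint = merge_replicates(series_list)
        assert len(joint.nuclei) == 2  # one nucleus per replicate
        fit = fit_titration(joint, ModelId.TWO_TO_ONE_STATISTICAL)
        k_true = truth["K1"] / 2.0
        assert fit.model.k_micro == pytest.approx(k_true, rel=0.3)
        assert fit.n_points == 24 and fit.n_params == 5

    def test_mismatched_grids_rejected(self):
        a = make_series(np.linspace(0, 2, 12), np.full(12, 7.3))
        b = make_series(np.linspace(0, 4, 12), np.full(12, 7.3))
        with pytest.raises(DomainError):
            merge_replicates([a, b])


class TestCompareModels:
    def test_single_candidate_rank_one(self, noisy_titration):
        series, _ = noisy_titration
        comp = compare_models(series, [ModelId.TWO_TO_ONE_STATISTICAL])
        assert len(comp.results) == 1
        assert comp.best.model.model_id is ModelId.TWO_TO_ONE_STATISTICAL

    def test_one_to_one_truth_preferred_by_parsimony(self):
        design = TitrationDesign(
            true_model=BindingModelSpec(ModelId.ONE_TO_ONE, K1=5e3),
            noise_sd=0.002,
            seed=5,
            n_replicates=1,
        )
        series, _ = gen_titration(design)
        comp = compare_models(
            series[0],
            [ModelId.ONE_TO_ONE, ModelId.TWO_TO_ONE_STATISTICAL, ModelId.TWO_TO_ONE_FULL],
        )
        assert comp.best.model.model_id is ModelId.ONE_TO_ONE

    def test_failures_recorded_not_fatal(self):
        # 12 observations cannot constrain the 5-parameter full model when
        # only 4 points are available, but the statistical fit still runs
        s = make_series([0.0, 0.4, 0.8, 1.2, 1.6, 2.0], [7.3, 7.25, 7.22, 7.2, 7.19, 7.18])
        comp = compare_models(s, [ModelId.TWO_TO_ONE_STATISTICAL, ModelId.TWO_TO_ONE_FULL])
        assert comp.results  # at least the statistical fit succeeded

    def test_comparison_table_shape(self, noisy_titration):
        series, _ = noisy_titration
        comp = compare_models(series, [ModelId.TWO_TO_ONE_STATISTICAL, ModelId.TWO_TO_ONE_FULL])
        tab = comp.table()
        assert list(tab.columns) == ["model", "n_params", "rss", "aicc", "delta_aicc"]
        assert tab["delta_aicc"].min() == 0.0


class TestAverageConstants:
    def _fit_like(self, k, se, model_id=ModelId.TWO_TO_ONE_STATISTICAL):
        from quadbind import TitrationFitResult

        if model_id is ModelId.TWO_TO_ONE_STATISTICAL:
            model = statistical_from_micro(k)
            errs = {"k_micro": se}
        else:
            model = BindingModelSpec(ModelId.ONE_TO_ONE, K1=k)
            errs = {"K1": se}
        return TitrationFitResult(
            model=model,
            shifts={},
            standard_errors=errs,
            rss=0.0,
            n_points=12,
            n_params=3,
            aicc=0.0,
            covariance=np.zeros((1, 1)),
            param_names=("k",),
        )

    def test_single_fit_is_identity(self):
        k, se = average_constants([self._fit_like(1234.0, 56.0)])
        assert k == 1234.0 and se == 56.0

    def test_closed_form_weighted_mean(self):
        fits = [self._fit_like(1000.0, 100.0), self._fit_like(2000.0, 200.0)]
        k, se = average_constants(fits)
        w = np.array([1 / 100.0**2, 1 / 200.0**2])
        expected = np.sum(w * np.array([1000.0, 2000.0])) / np.sum(w)
        assert k == pytest.approx(expected, rel=1e-12)
        assert se == pytest.approx(math.sqrt(1 / np.sum(w)), rel=1e-12)

    def test_equal_errors_give_arithmetic_mean(self):
        fits = [self._fit_like(1000.0, 50.0), self._fit_like(3000.0, 50.0)]
        k, _ = average_constants(fits)
        assert k == pytest.approx(2000.0, rel=1e-12)

    def test_mixed_models_rejected(self):
        fits = [
            self._fit_like(1000.0, 100.0),
            self._fit_like(1000.0, 100.0, model_id=ModelId.ONE_TO_ONE),
        ]
        with pytest.raises(DomainError):
            average_constants(fits)
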