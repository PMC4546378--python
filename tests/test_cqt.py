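"""Concentration-effect mixed models: slopes, AIC selection, predictions."""

import types

import numpy as np
import pandas as pd
import pytest

from cqtkit.cqt import (
    ConcentrationQtModel,
    bootstrap_prediction_ci,
    geometric_mean_cmax,
    predict_linear_effect,
    select_by_aic,
)
from cqtkit.ecg import build_observations
from cqtkit.nca import nca_table

from conftest import QtModelParams, small_trial


@pytest.fixture(scope="module")
def drug_obs():
    design, pk, ecg = small_trial(n_subjects=12, seed=29, qt_params=QtModelParams(drug_slope=-0.0008))
    obs, _ = build_observations(ecg, pk, design.subjects_frame())
    return obs, nca_table(pk)


class TestModelValidation:
    def test_bad_series_or_variant(self, drug_obs):
        obs, _ = drug_obs
        with pytest.raises(ValueError):
            ConcentrationQtModel(obs, series=3)
        with pytest.raises(ValueError):
            ConcentrationQtModel(obs, series=2, variant=3)

    def test_all_zero_concentration_rejected(self, drug_obs):
        obs, _ = drug_obs
        zeroed = obs.copy()
        zeroed["conc_ng_ml"] = 0.0
        with pytest.raises(ValueError, match="concentrations"):
            ConcentrationQtModel(zeroed, series=1, variant=1)

    def test_series2_requires_placebo_rows(self, drug_obs):
        obs, _ = drug_obs
        actives = obs[obs["treatment"] != "placebo"]
        with pytest.raises(ValueError, match="placebo"):
            ConcentrationQtModel(actives, series=2, variant=1)


class TestSlope:
    def test_sign_flip_is_exact(self, drug_obs):
        obs, _ = drug_obs
        s1 = ConcentrationQtModel(obs, series=1, variant=1).fit().slope
        flipped = obs.copy()
        flipped["ddqtci_ms"] = -flipped["ddqtci_ms"]
        s2 = ConcentrationQtModel(flipped, series=1, variant=1).fit().slope
        assert s2 == pytest.approx(-s1, rel=1e-6)

    def test_concentration_rescaling_invariance(self, drug_obs):
        """Slope scales by 1/k and the prediction at a rescaled concentration
        is unchanged when all concentrations are multiplied by k."""
        obs, _ = drug_obs
        base = ConcentrationQtModel(obs, series=2, variant=1).fit()
        scaled = obs.copy()
        scaled["conc_ng_ml"] = scaled["conc_ng_ml"] * 3.0
        refit = ConcentrationQtModel(scaled, series=2, variant=1).fit()
        assert refit.slope == pytest.approx(base.slope / 3.0, rel=1e-9)
        p0 = base.predict_at(3000.0).point
        p1 = refit.predict_at(9000.0).point
        assert p1 == pytest.approx(p0, abs=1e-6)

    def test_slope_ci_brackets_slope(self, drug_obs):
        obs, _ = drug_obs
        fit = ConcentrationQtModel(obs, series=1, variant=1).fit()
        lo, hi = fit.slope_ci()
        assert lo <= fit.slope <= hi

    def test_series_agreement_same_trial(self, drug_obs):
        """Series 1 and series 2 estimate the same slope on the same data."""
        obs, _ = drug_obs
        s1 = ConcentrationQtModel(obs, series=1, variant=1).fit()
        s2 = ConcentrationQtModel(obs, series=2, variant=1).fit()
        se = np.hypot(s1.slope_se, s2.slope_se)
        assert abs(s1.slope - s2.slope) < 3 * se


class TestTimeEffects:
    def test_series1_has_no_time_effects(self, drug_obs):
        obs, _ = drug_obs
        fit = ConcentrationQtModel(obs, series=1, variant=1).fit()
        with pytest.raises(ValueError):
            fit.time_effects()

    def test_food_effect_visible_and_drug_corrected(self, drug_obs):
        """The postprandial dip appears in the series-2 time effects even
        though a drug slope is present (slope term absorbs the drug)."""
        obs, _ = drug_obs
        fit = ConcentrationQtModel(obs, series=2, variant=1, qtc_variable="qtcf").fit()
        te = fit.time_effects().set_index("time_h")
        assert te.loc[6.0, "estimate_ms"] < -4.0
        assert abs(te.loc[1.0, "estimate_ms"]) < 2.5  # pre-lunch time is clean

    def test_constant_delta_shift_cancels_in_time_contrasts(self, drug_obs):
        obs, _ = drug_obs
        base = ConcentrationQtModel(obs, series=2, variant=1).fit().time_effects()
        shifted = obs.copy()
        shifted["dqtci_ms"] = shifted["dqtci_ms"] + 5.0
        after = ConcentrationQtModel(shifted, series=2, variant=1).fit().time_effects()
        np.testing.assert_allclose(
            base["estimate_ms"], after["estimate_ms"], atol=1e-5
        )


def _stub_fit(aic, n_var):
    return types.SimpleNamespace(aic_ml=aic, aic_reml=aic, n_variance_params=n_var)


class TestAicSelection:
    def test_reported_aic_pattern_selects_random_slope_variant(self):
        """AICs like the trial report's series-1 table: the middle model wins."""
        fits = [_stub_fit(8985.8, 2), _stub_fit(8882.0, 4), _stub_fit(8908.3, 4)]
        assert select_by_aic(fits) is fits[1]

    def test_singleton(self):
        fits = [_stub_fit(100.0, 2)]
        assert select_by_aic(fits) is fits[0]

    def test_tie_prefers_fewer_variance_params(self):
        fits = [_stub_fit(100.0, 4), _stub_fit(100.0, 2)]
        assert select_by_aic(fits) is fits[1]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_by_aic([])


class TestGeometricMeanCmax:
    def _nca(self, values):
        return pd.DataFrame(
            {"subject_id": range(len(values)), "treatment": "500 mg",
             "analyte": "parent", "cmax": values}
        )

    def test_constant(self):
        assert geometric_mean_cmax(self._nca([4.0, 4.0, 4.0]), "500 mg") == pytest.approx(4.0)

    def test_log_mean(self):
        assert geometric_mean_cmax(self._nca([1.0, 100.0]), "500 mg") == pytest.approx(10.0)

    def test_below_arithmetic_mean(self):
        rng = np.random.default_rng(0)
        vals = np.exp(rng.normal(8, 0.4, 50))
        assert geometric_mean_cmax(self._nca(vals), "500 mg") < vals.mean()

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            geometric_mean_cmax(self._nca([5.0, 0.0]), "500 mg")


class TestPredictions:
    def test_slope_times_concentration(self):
        assert round(predict_linear_effect(-0.00079, 5464.0), 1) == -4.3
        assert round(predict_linear_effect(-0.00079, 4302.4), 1) == -3.4
        assert predict_linear_effect(-0.00079, 0.0) == 0.0

    def test_negative_concentration_rejected(self, drug_obs):
        obs, _ = drug_obs
        fit = ConcentrationQtModel(obs, series=2, variant=1).fit()
        with pytest.raises(ValueError):
            fit.predict_at(-1.0)
        with pytest.raises(ValueError):
            predict_linear_effect(-0.0008, -5.0)

    def test_series2_prediction_is_slope_only(self, drug_obs):
        obs, _ = drug_obs
        fit = ConcentrationQtModel(obs, series=2, variant=1).fit()
        pred = fit.predict_at(4000.0)
        assert pred.point == pytest.approx(fit.slope * 4000.0, rel=1e-9)
        assert pred.ci_low <= pred.point <= pred.ci_high
        assert fit.predict_at(0.0).point == 0.0

    def test_series1_prediction_includes_intercept(self, drug_obs):
        obs, _ = drug_obs
        fit = ConcentrationQtModel(obs, series=1, variant=1).fit()
        pred = fit.predict_at(4000.0)
        assert pred.point == pytest.approx(fit.intercept + fit.slope * 4000.0, rel=1e-9)


@pytest.fixture(scope="module")
def bootstrap_obs():
    """Smaller trial: the bootstrap refits the model per replicate."""
    design, pk, ecg = small_trial(n_subjects=8, seed=31, qt_params=QtModelParams(drug_slope=-0.0008))
    obs, _ = build_observations(ecg, pk, design.subjects_frame(), fit_qtci=True)
    return obs, nca_table(pk)


class TestBootstrap:
    def test_seeded_determinism_and_coverage_of_point(self, bootstrap_obs):
        obs, nca = bootstrap_obs
        kw = dict(series=2, variant=1, qtc_variable="qtci", B=200, ci_level=0.90)
        p1 = bootstrap_prediction_ci(obs, nca, "500 mg", seed=3, **kw)
        p2 = bootstrap_prediction_ci(obs, nca, "500 mg", seed=3, **kw)
        assert (p1.ci_low, p1.ci_high) == (p2.ci_low, p2.ci_high)
        assert p1.method == "bootstrap"
        assert p1.ci_low < p1.point < p1.ci_high
        p3 = bootstrap_prediction_ci(obs, nca, "500 mg", seed=4, **kw)
        assert (p3.ci_low, p3.ci_high) != (p1.ci_low, p1.ci_high)

    def test_minimum_replicates_enforced(self, drug_obs):
        obs, nca = drug_obs
        with pytest.raises(ValueError, match="B"):
            bootstrap_prediction_ci(obs, nca, "500 mg", B=50, seed=0)
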