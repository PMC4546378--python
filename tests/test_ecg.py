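"""ECG processing: triplicate reduction, corrections, selection rule, deltas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cqtkit.ecg import (
    CorrectionModel,
    build_observations,
    compute_baseline_av,
    compute_deltas,
    drug_free_records,
    fit_individual_corrections,
    fridericia,
    reduce_triplicates,
    select_correction,
)
from cqtkit.simulate import QtModelParams, simulate_pk, simulate_ecg

from conftest import small_design


def _records(qt_by_replicate, rr=1.0, **coords):
    base = {"subject_id": 1, "period": 1, "day": 1, "treatment": "placebo", "nominal_time_h": 0.0}
    base.update(coords)
    return pd.DataFrame(
        [{**base, "replicate": i + 1, "qt_ms": qt, "rr_s": rr} for i, qt in enumerate(qt_by_replicate)]
    )


class TestReduceTriplicates:
    @pytest.mark.parametrize(
        "qts,expected",
        [([398.0, 402.0, 410.0], 402.0), ([400.0, 400.0, 400.0], 400.0), ([398.0, 402.0], 400.0)],
    )
    def test_median_rules(self, qts, expected):
        out = reduce_triplicates(_records(qts))
        assert out["qt_ms"].iloc[0] == expected
        assert out["n_replicates"].iloc[0] == len(qts)

    @given(st.permutations([398.0, 402.0, 410.0]))
    def test_permutation_invariant(self, qts):
        out = reduce_triplicates(_records(list(qts)))
        assert out["qt_ms"].iloc[0] == 402.0

    def test_rr_ms_autoconverted(self):
        rec = _records([400.0, 402.0, 404.0], rr=900.0)  # RR mistakenly in ms
        out = reduce_triplicates(rec)
        assert out["rr_s"].iloc[0] == pytest.approx(0.9)


class TestFridericia:
    def test_rr_one_is_identity(self):
        assert fridericia(400.0, 1.0) == 400.0

    def test_cube_root_value(self):
        assert fridericia(400.0, 0.64) == pytest.approx(400.0 / 0.64 ** (1 / 3), abs=1e-6)
        assert fridericia(400.0, 0.64) == pytest.approx(464.16, abs=0.01)

    def test_fast_heart_rate_lengthens_qtc(self):
        assert fridericia(400.0, 0.8) > 400.0

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValueError):
            fridericia(400.0, 0.0)


def _subject_records(qt, rr):
    return pd.DataFrame(
        {
            "subject_id": 1, "period": 1, "day": -1, "treatment": "placebo",
            "nominal_time_h": np.arange(len(qt), dtype=float), "replicate": 1,
            "qt_ms": qt, "rr_s": rr,
        }
    )


class TestIndividualCorrection:
    def test_loglog_generator_recovered_exactly(self):
        rr = np.linspace(0.7, 1.2, 30)
        rec = _subject_records(420.0 * rr**0.25, rr)
        linear, loglog = fit_individual_corrections(rec)[1]
        assert loglog.slope_or_exponent == pytest.approx(0.25, abs=1e-9)
        assert abs(loglog.residual_corr) < 1e-9
        assert select_correction(linear, loglog).method == "loglog"

    def test_linear_generator_recovered_exactly(self):
        rr = np.linspace(0.7, 1.2, 30)
        rec = _subject_records(350.0 + 60.0 * rr, rr)
        linear, loglog = fit_individual_corrections(rec)[1]
        assert linear.slope_or_exponent == pytest.approx(60.0, abs=1e-9)
        assert abs(linear.residual_corr) < 1e-9
        assert select_correction(linear, loglog).method == "linear"

    def test_constant_rr_falls_back_to_fridericia(self):
        rec = _subject_records(np.full(25, 400.0), np.full(25, 0.9))
        linear, loglog = fit_individual_corrections(rec)[1]
        assert linear.method == "fridericia"

    def test_too_few_points_falls_back(self):
        rr = np.linspace(0.8, 1.0, 5)
        rec = _subject_records(400.0 * rr**0.3, rr)
        linear, _ = fit_individual_corrections(rec, n_min=20)[1]
        assert linear.method == "fridericia"


def _cm(method, r, slope):
    return CorrectionModel(
        subject_id=1, method=method, slope_or_exponent=0.3, intercept=0.0,
        residual_corr=r, qtc_on_rr_slope=slope, n_points=30,
    )


class TestSelectionRule:
    def test_step1_smaller_correlation_wins(self):
        assert select_correction(_cm("linear", 0.10, 5.0), _cm("loglog", 0.02, 9.0)).method == "loglog"
        assert select_correction(_cm("linear", -0.01, 5.0), _cm("loglog", 0.02, 1.0)).method == "linear"

    def test_step2_smaller_slope_wins_on_tied_correlation(self):
        assert select_correction(_cm("linear", 0.05, 2.0), _cm("loglog", -0.05, 4.0)).method == "linear"

    def test_step3_loglog_wins_full_tie(self):
        assert select_correction(_cm("linear", 0.05, -2.0), _cm("loglog", 0.05, 2.0)).method == "loglog"


class TestBaselineAndDeltas:
    def test_baseline_is_mean_of_day_minus1_medians(self):
        rows = []
        for t, qtc in ((0.0, 400.0), (1.0, 404.0)):
            rows.append({"subject_id": 1, "period": 1, "day": -1, "nominal_time_h": t, "qtc": qtc})
        base = compute_baseline_av(pd.DataFrame(rows), "qtc")
        assert base["baseline_av_ms"].iloc[0] == 402.0

    def test_delta_arithmetic(self):
        day1 = pd.DataFrame(
            [
                {"subject_id": 1, "period": 1, "treatment": "placebo", "nominal_time_h": 1.0, "qtc": 402.0},
                {"subject_id": 1, "period": 2, "treatment": "500 mg", "nominal_time_h": 1.0, "qtc": 405.0},
            ]
        )
        baselines = pd.DataFrame(
            [
                {"subject_id": 1, "period": 1, "baseline_av_ms": 400.0},
                {"subject_id": 1, "period": 2, "baseline_av_ms": 400.0},
            ]
        )
        obs = compute_deltas(day1, baselines, "qtc")
        active = obs[obs["treatment"] == "500 mg"].iloc[0]
        assert active["delta_qtc_ms"] == 5.0
        assert active["ddqtc_ms"] == 3.0  # 5 - 2
        assert np.isnan(obs[obs["treatment"] == "placebo"]["ddqtc_ms"]).all()

    def test_missing_placebo_time_not_imputed(self):
        day1 = pd.DataFrame(
            [
                {"subject_id": 1, "period": 1, "treatment": "placebo", "nominal_time_h": 1.0, "qtc": 402.0},
                {"subject_id": 1, "period": 2, "treatment": "500 mg", "nominal_time_h": 2.0, "qtc": 405.0},
            ]
        )
        baselines = pd.DataFrame(
            [
                {"subject_id": 1, "period": 1, "baseline_av_ms": 400.0},
                {"subject_id": 1, "period": 2, "baseline_av_ms": 400.0},
            ]
        )
        obs = compute_deltas(day1, baselines, "qtc")
        assert np.isnan(obs.loc[obs["treatment"] == "500 mg", "ddqtc_ms"]).all()


class TestPipelineProperties:
    def test_noiseless_baseline_equals_generator_truth(self):
        """With all noise off the average baseline is the subject's true QTc."""
        design = small_design(4)
        pk = simulate_pk(design, seed=0, between_subject_cv=0.0)
        params = QtModelParams(
            qtc_between_subject_sd=0.0, replicate_sd=0.0, food_effect_amplitude=0.0,
            sex_effect=0.0, rr_between_subject_sd=0.0, rr_within_subject_sd=0.0,
            rr_food_effect_s=0.0, qt_rr_exponent_sd=0.0,
        )
        ecg = simulate_ecg(design, pk, params, seed=0)
        obs, _ = build_observations(ecg, fit_qtci=False)
        np.testing.assert_allclose(obs["baseline_qtcf_ms"], obs["baseline_qtcf_ms"].iloc[0], rtol=1e-9)

    def test_ddqtc_invariant_to_subject_period_shift(self, null_observations):
        """Adding a per-subject-period constant shifts Δ but cancels in ΔΔ only
        if it is also present on Day -1; adding it to Δ directly must shift
        placebo and active alike, so ΔΔ is unchanged when applied per subject."""
        obs, _ = null_observations
        shifted = obs.copy()
        shift = shifted["subject_id"] * 3.0
        shifted["dqtcf_ms"] = shifted["dqtcf_ms"] + shift
        placebo = shifted[shifted["treatment"] == "placebo"][
            ["subject_id", "nominal_time_h", "dqtcf_ms"]
        ].rename(columns={"dqtcf_ms": "p"})
        merged = shifted.merge(placebo, on=["subject_id", "nominal_time_h"])
        active = merged[merged["treatment"] != "placebo"]
        np.testing.assert_allclose(
            (active["dqtcf_ms"] - active["p"]).to_numpy(),
            active["ddqtcf_ms"].to_numpy(),
            atol=1e-9,
        )

    def test_selected_correction_beats_fridericia_on_own_criterion(self, null_trial):
        design, pk, ecg = null_trial
        fits = fit_individual_corrections(drug_free_records(ecg))
        for sid, (linear, loglog) in fits.items():
            chosen = select_correction(linear, loglog)
            sub = drug_free_records(ecg)
            sub = sub[sub["subject_id"] == sid]
            qt, rr = sub["qt_ms"].to_numpy(), sub["rr_s"].to_numpy()
            qtci = chosen.apply(qt, rr)
            qtcf = fridericia(qt, rr)
            r_i = abs(np.corrcoef(qtci, rr)[0, 1])
            r_f = abs(np.corrcoef(qtcf, rr)[0, 1])
            assert r_i <= r_f + 1e-9
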