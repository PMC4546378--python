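"""Concentration-QTc exposure-response mixed models.

Two series of linear mixed models relate the QTc endpoint to the
time-matched plasma concentration of an analyte:

* **Series 1** regresses the placebo-subtracted double difference ΔΔQTc on
  concentration. Variants: (1) period, sequence and sex as fixed effects
  with a random subject intercept; (2) variant 1 plus a random concentration
  slope; (3) no fixed effects except the slope — fixed intercept constrained
  to 0 — with random intercepts and slopes.
* **Series 2** regresses the single difference ΔQTc on concentration with
  time as a categorical factor, using active *and* placebo periods (placebo
  concentration is 0), so the spontaneous time course is estimated from all
  data and the slope is corrected for it. Variants: (1) random intercept;
  (2) plus random slope.

Within a series, the variant with the better AIC is used for predictions of
the QTc effect at the geometric-mean Cmax of each dose group. AICs for
selection are computed from maximum-likelihood refits by default (restricted
likelihoods are not comparable across different fixed-effect sets); the
REML-likelihood AIC is also reported and can be selected on for
mirror-the-report runs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._mixed import (
    contrast_rows,
    fit_mixedlm,
    information_criterion,
    linear_combination,
    n_groups,
    robust_fixed_cov,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConcentrationQtModel",
    "ConcentrationQtResults",
    "EffectPrediction",
    "select_by_aic",
    "geometric_mean_cmax",
    "predict_linear_effect",
    "bootstrap_prediction_ci",
]

_QTC_DD = {"qtci": "ddqtci_ms", "qtcf": "ddqtcf_ms"}
_QTC_D = {"qtci": "dqtci_ms", "qtcf": "dqtcf_ms"}

# concentrations are standardised to unit SD inside the model: slope
# variances of order 1e-8 (ms per ng/mL squared) otherwise wreck the mixed
# model optimisation, and standardising by the data's own SD makes fits
# exactly invariant to rescaling the concentration units; slopes are
# reported back in ms per ng/mL


@dataclass(frozen=True)
class EffectPrediction:
    """Predicted QTc effect (ms) at a plasma concentration (ng/mL)."""

    dose_group: str
    concentration: float
    point: float
    ci_low: float
    ci_high: float
    ci_level: float
    method: str  # {"parametric", "bootstrap"}


class ConcentrationQtModel:
    """One concentration-QTc mixed model (one series, one variant).

    Parameters
    ----------
    observations
        Tidy observation table from :func:`cqtkit.ecg.build_observations`
        with the time-matched ``conc_ng_ml`` column.
    series, variant
        Series 1 variants 1-3, series 2 variants 1-2 (see module docstring).
    qtc_variable
        ``"qtci"`` or ``"qtcf"``.
    ci_level
        Two-sided level for the slope and prediction intervals.
    """

    def __init__(
        self,
        observations: pd.DataFrame,
        series: int = 1,
        variant: int = 1,
        qtc_variable: str = "qtci",
        analyte: str = "parent",
        ci_level: float = 0.90,
    ):
        if series not in (1, 2):
            raise ValueError("series must be 1 or 2")
        if (series, variant) not in {(1, 1), (1, 2), (1, 3), (2, 1), (2, 2)}:
            raise ValueError(f"variant {variant} is not defined for series {series}")
        if qtc_variable not in _QTC_DD:
            raise ValueError(f"qtc_variable must be one of {sorted(_QTC_DD)}")
        self.series, self.variant = series, variant
        self.qtc_variable, self.analyte = qtc_variable, analyte
        self.ci_level = ci_level

        if series == 1:
            col = _QTC_DD[qtc_variable]
            data = observations.dropna(subset=[col]).copy()
            data["endog"] = data[col]
        else:
            col = _QTC_D[qtc_variable]
            data = observations.dropna(subset=[col]).copy()
            data["endog"] = data[col]
            if not ((data["treatment"] == "placebo") & (data["conc_ng_ml"] == 0)).any():
                raise ValueError("series 2 requires placebo rows with concentration 0")
        if (data["conc_ng_ml"] == 0).all():
            raise ValueError("all concentrations are 0; the slope is unidentifiable")
        self.conc_scale_ = 1.0 / float(data["conc_ng_ml"].std())
        data["conc"] = data["conc_ng_ml"] * self.conc_scale_
        self.data = data

        if series == 1:
            if variant == 3:
                self.formula = "endog ~ 0 + conc"
                self.re_formula = "~conc"
            else:
                self.formula = "endog ~ conc + C(period) + C(sequence) + C(sex)"
                self.re_formula = "~conc" if variant == 2 else None
        else:
            self.formula = "endog ~ C(nominal_time_h) + C(period) + C(sequence) + C(sex) + conc"
            self.re_formula = "~conc" if variant == 2 else None

    def fit(self, reml: bool = True) -> "ConcentrationQtResults":
        res = fit_mixedlm(self.formula, self.data, re_formula=self.re_formula, reml=reml)
        return ConcentrationQtResults(self, res, reml=reml)


class ConcentrationQtResults:
    """A fitted concentration-QTc model.

    Exposes the concentration slope with its t-based CI, both AIC flavours
    (restricted and ML — the ML refit is performed lazily and cached), the
    series-2 time effects, and effect predictions at a concentration.
    """

    def __init__(self, model: ConcentrationQtModel, mixedlm_results, reml: bool = True):
        self.model = model
        self.mixedlm_results = mixedlm_results
        self._reml = reml
        self._aic_ml: float | None = None
        names = list(mixedlm_results.fe_params.index)
        self._conc_ix = names.index("conc")
        self._intercept_ix = names.index("Intercept") if "Intercept" in names else None

    # -- parameter accessors -------------------------------------------------
    @property
    def slope(self) -> float:
        """Concentration slope, ms per ng/mL."""
        return float(self.mixedlm_results.fe_params.iloc[self._conc_ix]) * self.model.conc_scale_

    @property
    def slope_se(self) -> float:
        """Cluster-robust SE of the slope.

        The slope's uncertainty is dominated by between-subject response
        heterogeneity, which a random-effects plug-in covariance
        understates; the subject-level sandwich covariance is used instead.
        """
        cov = robust_fixed_cov(self.mixedlm_results)
        return float(np.sqrt(cov[self._conc_ix, self._conc_ix])) * self.model.conc_scale_

    def slope_ci(self, ci_level: float | None = None) -> tuple[float, float]:
        """Two-sided t CI with n_subjects - 1 degrees of freedom."""
        lvl = self.model.ci_level if ci_level is None else ci_level
        t = stats.t.ppf(0.5 + lvl / 2.0, df=n_groups(self.mixedlm_results) - 1)
        return self.slope - t * self.slope_se, self.slope + t * self.slope_se

    @property
    def intercept(self) -> float:
        """Fixed intercept (0 by construction for series-1 variant 3)."""
        if self._intercept_ix is None:
            return 0.0
        return float(self.mixedlm_results.fe_params.iloc[self._intercept_ix])

    @property
    def n_variance_params(self) -> int:
        return len(self.mixedlm_results.params) - self.mixedlm_results.model.k_fe + 1

    @property
    def aic_reml(self) -> float:
        if not self._reml:
            return float("nan")
        return information_criterion(self.mixedlm_results)

    @property
    def aic_ml(self) -> float:
        if not self._reml:
            return information_criterion(self.mixedlm_results)
        if self._aic_ml is None:
            from statsmodels.regression.mixed_linear_model import MixedLMParams

            r = self.mixedlm_results
            start = MixedLMParams.from_components(
                fe_params=np.asarray(r.fe_params), cov_re=np.asarray(r.cov_re) / r.scale
            )
            ml = fit_mixedlm(
                self.model.formula, self.model.data, re_formula=self.model.re_formula,
                reml=False, start_params=start,
            )
            self._aic_ml = information_criterion(ml)
        return self._aic_ml

    # -- series-2 time effects ----------------------------------------------
    def time_effects(self, ci_level: float = 0.90) -> pd.DataFrame:
        """Estimated spontaneous time course: each post-dose time vs pre-dose.

        Series-2 only. The contrast is evaluated at equal concentration, so
        the drug term cancels and the estimates are concentration-corrected
        by construction.
        """
        if self.model.series != 2:
            raise ValueError("time effects are defined for series-2 models only")
        data = self.model.data
        times = sorted(data["nominal_time_h"].unique())
        ref_t = times[0]
        base = data.iloc[0]
        ref = {"period": base["period"], "sequence": base["sequence"], "sex": base["sex"], "conc": 0.0}
        rows = []
        for t in times[1:]:
            L = contrast_rows(
                self.mixedlm_results,
                {**ref, "nominal_time_h": t},
                {**ref, "nominal_time_h": ref_t},
            )
            est, se, lo, hi = linear_combination(self.mixedlm_results, L, ci_level)
            rows.append({"time_h": t, "estimate_ms": est, "se_ms": se, "ci_low": lo, "ci_high": hi})
        return pd.DataFrame(rows)

    # -- predictions ---------------------------------------------------------
    def predict_at(
        self, concentration: float, dose_group: str = "", ci_level: float | None = None
    ) -> EffectPrediction:
        """Predicted QTc effect at a concentration, with a t-based CI.

        For series 2 and series-1 variant 3 the prediction is
        ``slope * concentration`` (intercept/time/covariate terms cancel
        between a treated and an untreated subject alike in all else); for
        series-1 variants 1-2 the fixed intercept is included. The CI uses
        the cluster-robust covariance with n_subjects - 1 t degrees of
        freedom, matching the slope inference.
        """
        if concentration < 0:
            raise ValueError("concentration must be nonnegative")
        lvl = self.model.ci_level if ci_level is None else ci_level
        res = self.mixedlm_results
        k = res.model.k_fe
        L = np.zeros(k)
        L[self._conc_ix] = concentration * self.model.conc_scale_
        if self.model.series == 1 and self._intercept_ix is not None:
            L[self._intercept_ix] = 1.0
        est = float(L @ np.asarray(res.fe_params))
        se = float(np.sqrt(L @ robust_fixed_cov(res) @ L))
        tcrit = stats.t.ppf(0.5 + lvl / 2.0, df=n_groups(res) - 1)
        lo, hi = est - tcrit * se, est + tcrit * se
        return EffectPrediction(
            dose_group=dose_group, concentration=float(concentration),
            point=est, ci_low=lo, ci_high=hi, ci_level=lvl, method="parametric",
        )

    def summary(self) -> str:
        lo, hi = self.slope_ci()
        lvl = int(round(self.model.ci_level * 100))
        lines = [
            f"Concentration-{self.model.qtc_variable.upper()} mixed model "
            f"(series {self.model.series}, variant {self.model.variant}, analyte {self.model.analyte})",
            f"observations: {int(self.mixedlm_results.model.nobs)}",
            f"slope: {self.slope:.5f} ms/(ng/mL)  {lvl}% CI [{lo:.5f}, {hi:.5f}]",
            f"fixed intercept: {self.intercept:.3f} ms",
            f"AIC (restricted): {self.aic_reml:.1f}",
        ]
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Scatter of the endpoint against concentration with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self.model.data
        ax.plot(d["conc_ng_ml"], d["endog"], ".", alpha=0.3, ms=3)
        grid = np.linspace(0.0, float(d["conc_ng_ml"].max()), 50)
        ax.plot(grid, self.intercept + self.slope * grid, "r-")
        ax.set_xlabel("concentration (ng/mL)")
        ax.set_ylabel(f"{'ΔΔ' if self.model.series == 1 else 'Δ'}{self.model.qtc_variable.upper()} (ms)")
        return ax


def select_by_aic(fits: list[ConcentrationQtResults], criterion: str = "ml") -> ConcentrationQtResults:
    """Pick the best-AIC fit from one series; ties go to the simpler variant.

    ``criterion`` is ``"ml"`` (default; likelihoods comparable across fixed
    structures) or ``"reml"`` (mirror-the-report mode).
    """
    if not fits:
        raise ValueError("no fits to select from")
    if criterion not in ("ml", "reml"):
        raise ValueError("criterion must be 'ml' or 'reml'")
    key = [(f.aic_ml if criterion == "ml" else f.aic_reml, f.n_variance_params) for f in fits]
    return fits[int(np.lexsort(([k[1] for k in key], [k[0] for k in key]))[0])]


def aic_table(fits: list[ConcentrationQtResults], criterion: str = "ml") -> pd.DataFrame:
    """AIC comparison table for a list of fits; flags the selected one."""
    best = select_by_aic(fits, criterion)
    return pd.DataFrame(
        {
            "series": [f.model.series for f in fits],
            "variant": [f.model.variant for f in fits],
            "analyte": [f.model.analyte for f in fits],
            "slope": [f.slope for f in fits],
            "ci_low": [f.slope_ci()[0] for f in fits],
            "ci_high": [f.slope_ci()[1] for f in fits],
            "aic_ml": [f.aic_ml for f in fits],
            "aic_reml": [f.aic_reml for f in fits],
            "best_fit": [f is best for f in fits],
        }
    )


def geometric_mean_cmax(nca: pd.DataFrame, treatment: str, analyte: str = "parent") -> float:
    """Geometric mean of per-subject observed Cmax for one dose group.

    exp(mean(ln Cmax)); missing Cmax values are excluded and counted; any
    nonpositive Cmax raises.
    """
    sub = nca[(nca["treatment"] == treatment) & (nca["analyte"] == analyte)]
    cmax = sub["cmax"]
    n_missing = int(cmax.isna().sum())
    if n_missing:
        logger.info("geometric_mean_cmax(%s): %d subjects missing Cmax excluded", treatment, n_missing)
    cmax = cmax.dropna()
    if len(cmax) == 0:
        raise ValueError(f"no Cmax values for dose group {treatment!r}")
    if (cmax <= 0).any():
        raise ValueError("Cmax values must be positive for the geometric mean")
    return float(np.exp(np.mean(np.log(cmax))))


def predict_linear_effect(slope: float, concentration: float) -> float:
    """Point prediction of a slope-only concentration-effect model (ms).

    The drug effect of a change-from-baseline model at concentration C is
    ``slope * C``: time and covariate terms are shared between a treated and
    an untreated subject and cancel in the difference.
    """
    if concentration < 0:
        raise ValueError("concentration must be nonnegative")
    return slope * concentration


def bootstrap_prediction_ci(
    observations: pd.DataFrame,
    nca: pd.DataFrame,
    treatment: str,
    series: int = 2,
    variant: int = 2,
    qtc_variable: str = "qtci",
    analyte: str = "parent",
    B: int = 1000,
    seed: int = 0,
    ci_level: float = 0.90,
) -> EffectPrediction:
    """Bootstrap CI for the predicted effect at the geometric-mean Cmax.

    Resamples subjects with replacement, stratified by sequence, and per
    replicate recomputes the dose group's geometric-mean Cmax *and* refits
    the concentration-QTc model before predicting — so the interval carries
    the sampling variability of the mean Cmax that the parametric CI
    ignores. Percentile interval over ``B`` replicates; non-convergent
    replicates are dropped and counted (warning above 10%).
    """
    if B < 200:
        raise ValueError("B must be at least 200")
    subjects = observations[["subject_id", "sequence"]].drop_duplicates()
    if len(subjects) < 5:
        raise ValueError("need at least 5 subjects to bootstrap")
    rng = np.random.default_rng(seed)

    base_model = ConcentrationQtModel(
        observations, series=series, variant=variant, qtc_variable=qtc_variable,
        analyte=analyte, ci_level=ci_level,
    )
    base_fit = base_model.fit()
    conc0 = geometric_mean_cmax(nca, treatment, analyte)
    point = base_fit.predict_at(conc0, dose_group=treatment).point

    by_seq = {s: g["subject_id"].to_numpy() for s, g in subjects.groupby("sequence")}
    obs_by_subject = dict(tuple(observations.groupby("subject_id")))
    nca_by_subject = dict(tuple(nca.groupby("subject_id")))

    draws = []
    n_failed = 0
    for _ in range(B):
        chosen: list[int] = []
        for s in sorted(by_seq):
            pool = by_seq[s]
            chosen.extend(rng.choice(pool, size=len(pool), replace=True))
        obs_b = []
        nca_b = []
        for new_id, sid in enumerate(chosen, start=1):
            o = obs_by_subject[sid].copy()
            o["subject_id"] = new_id
            obs_b.append(o)
            if sid in nca_by_subject:
                n = nca_by_subject[sid].copy()
                n["subject_id"] = new_id
                nca_b.append(n)
        obs_b = pd.concat(obs_b, ignore_index=True)
        nca_b = pd.concat(nca_b, ignore_index=True)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit_b = ConcentrationQtModel(
                    obs_b, series=series, variant=variant, qtc_variable=qtc_variable,
                    analyte=analyte, ci_level=ci_level,
                ).fit()
                conc_b = geometric_mean_cmax(nca_b, treatment, analyte)
                draws.append(fit_b.predict_at(conc_b).point)
        except Exception:
            n_failed += 1
    if n_failed > 0.1 * B:
        logger.warning("bootstrap: %d/%d replicates failed to converge", n_failed, B)
    if not draws:
        raise RuntimeError("all bootstrap replicates failed")
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0])
    return EffectPrediction(
        dose_group=treatment, concentration=conc0, point=point,
        ci_low=float(lo), ci_high=float(hi), ci_level=ci_level, method="bootstrap",
    )
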