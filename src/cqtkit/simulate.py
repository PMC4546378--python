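"""Synthetic crossover-trial generator.

Generates complete trials — concentrations, triplicate ECG intervals, design
tables — with the statistical structure the downstream analyses assume:

* one-compartment first-order-absorption PK, dose proportional, with a
  per-subject lognormal exposure multiplier;
* per-subject QT-RR power relationships (log-log exponent drawn per subject)
  around a subject-level "true QTc" with between-subject SD ~8 ms;
* a postprandial QTc shortening that starts at each meal and decays
  exponentially, present on the baseline day and the dosing day alike;
* an optional linear drug effect on QTc (ms per ng/mL of plasma drug);
* triplicate 10 s ECGs at every nominal time point with additive
  replicate-level measurement noise.

Everything is driven by :class:`numpy.random.Generator` seeded explicitly, so
identical inputs and seed give bit-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import DOSE_MG, TrialDesign, build_design

__all__ = [
    "PkParams",
    "QtModelParams",
    "default_pk_params",
    "simulate_pk",
    "simulate_ecg",
    "simulate_trial",
    "food_effect",
    "power_time_matched_crossover",
]


@dataclass(frozen=True)
class PkParams:
    """One-compartment, first-order absorption PK parameters for one dose.

    ``v_over_f`` is the apparent volume of distribution (V/F, litres); the
    elimination rate is ``ln 2 / t_half``. The default volume is tuned so a
    500 mg dose peaks near 3.9 µg/mL, matching the trial's reported Cmax
    magnitudes.
    """

    dose_mg: float
    ka: float = 1.0          # 1/h
    t_half: float = 35.0     # h
    v_over_f: float = 118.0  # L

    def __post_init__(self) -> None:
        if min(self.ka, self.t_half, self.v_over_f) <= 0 or self.dose_mg < 0:
            raise ValueError("PK parameters must be strictly positive (dose >= 0)")
        if abs(self.ka - self.ke) < 1e-12:
            raise ValueError("ka equal to ke makes the one-compartment model degenerate")
        if self.ke >= self.ka:
            raise ValueError("flip-flop kinetics (ke >= ka) not supported by default")

    @property
    def ke(self) -> float:
        return math.log(2.0) / self.t_half

    def concentration(self, t_h: np.ndarray | float) -> np.ndarray:
        """Noise-free plasma concentration (ng/mL) at ``t_h`` hours post-dose."""
        t = np.asarray(t_h, dtype=float)
        amount_ng_per_ml = self.dose_mg * 1e6 / (self.v_over_f * 1e3)
        c = amount_ng_per_ml * self.ka / (self.ka - self.ke) * (
            np.exp(-self.ke * t) - np.exp(-self.ka * t)
        )
        return np.where(t <= 0, 0.0, c)


def default_pk_params(treatment: str) -> PkParams:
    """Default :class:`PkParams` for a treatment label (dose from its mg)."""
    return PkParams(dose_mg=DOSE_MG[treatment])


@dataclass(frozen=True)
class QtModelParams:
    """Parameters of the QT/RR generative model.

    ``qtc_pop_mean`` is the male population mean of the subject-level true QTc
    (ms); females add ``sex_effect``. The postprandial term is
    ``food_effect_amplitude * exp(-(t - t_meal)/food_effect_decay_h)`` for
    ``t >= t_meal``, summed over meals — negative amplitude means QTc
    shortening. ``drug_slope`` is the linear concentration effect in ms per
    ng/mL. RR intervals are in seconds; the observed QT of each replicate is
    ``true_qtc * RR**exponent + noise`` with a per-subject exponent.
    """

    qtc_pop_mean: float = 410.0
    qtc_between_subject_sd: float = 8.0
    replicate_sd: float = 5.0
    circadian_amplitude: float = 0.0
    food_effect_amplitude: float = -8.0
    food_effect_decay_h: float = 16.0
    drug_slope: float = 0.0
    sex_effect: float = 10.0
    rr_mean_s: float = 0.90
    rr_between_subject_sd: float = 0.07
    rr_within_subject_sd: float = 0.05
    rr_food_effect_s: float = -0.04
    qt_rr_exponent_mean: float = 0.32
    qt_rr_exponent_sd: float = 0.04

    def __post_init__(self) -> None:
        for name in (
            "qtc_between_subject_sd", "replicate_sd", "rr_between_subject_sd",
            "rr_within_subject_sd", "qt_rr_exponent_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.food_effect_decay_h <= 0:
            raise ValueError("food_effect_decay_h must be positive")


def food_effect(
    t_h: np.ndarray | float,
    amplitude: float,
    decay_h: float,
    meal_times_h: tuple[float, ...] = (5.0, 9.0),
) -> np.ndarray:
    """Postprandial effect at ``t_h`` hours post-dose, summed over meals.

    Zero before each meal; from the meal onwards the contribution is
    ``amplitude * exp(-(t - t_meal)/decay_h)``.
    """
    t = np.asarray(t_h, dtype=float)
    out = np.zeros_like(t)
    for tm in meal_times_h:
        mask = t >= tm
        out = out + np.where(mask, amplitude * np.exp(-(t - tm) / decay_h), 0.0)
    return out


def simulate_pk(
    design: TrialDesign,
    params: dict[str, PkParams] | None = None,
    seed: int = 0,
    between_subject_cv: float = 0.2,
    metabolite_scales: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate the Day 1 concentration table for every subject and period.

    Each subject carries a lognormal exposure multiplier with coefficient of
    variation ``between_subject_cv`` applied to all their active-period
    concentrations (shared across analytes, so metabolite profiles stay
    proportional to parent). Placebo periods get concentration 0.

    Parameters
    ----------
    params
        Mapping treatment label -> :class:`PkParams`; defaults built from
        :func:`default_pk_params` for the active doses.
    metabolite_scales
        Optional mapping analyte label -> scale factor (< 1) producing
        metabolite rows as scaled parent curves.

    Returns
    -------
    DataFrame with columns ``subject_id, period, treatment, dose_mg, analyte,
    nominal_time_h, conc_ng_ml``.
    """
    rng = np.random.default_rng(seed)
    if params is None:
        params = {t: default_pk_params(t) for t in DOSE_MG if t != "placebo"}
    sigma = math.sqrt(math.log(1.0 + between_subject_cv**2))
    mult = np.exp(rng.normal(-0.5 * sigma**2, sigma, design.n_subjects)) if sigma > 0 else np.ones(design.n_subjects)

    times = np.asarray(design.nominal_times_h)
    analytes = {"parent": 1.0}
    if metabolite_scales:
        analytes.update(metabolite_scales)

    frames = []
    for subj in range(1, design.n_subjects + 1):
        for period in range(1, design.n_periods + 1):
            treatment = design.treatment_for(subj, period)
            if treatment == "placebo":
                base = np.zeros_like(times)
                dose = 0.0
            else:
                base = params[treatment].concentration(times) * mult[subj - 1]
                dose = params[treatment].dose_mg
            for analyte, scale in analytes.items():
                frames.append(
                    pd.DataFrame(
                        {
                            "subject_id": subj,
                            "period": period,
                            "treatment": treatment,
                            "dose_mg": dose,
                            "analyte": analyte,
                            "nominal_time_h": times,
                            "conc_ng_ml": base * scale,
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)


def simulate_ecg(
    design: TrialDesign,
    pk_table: pd.DataFrame,
    qt_params: QtModelParams | None = None,
    seed: int = 0,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Simulate the triplicate ECG interval table for Day -1 and Day 1.

    Per replicate trace, RR is drawn around the subject's mean (meals
    transiently lower RR) and the observed QT is
    ``true_qtc(t) * RR**b_subject + replicate noise`` where ``true_qtc``
    collects the subject baseline, sex effect, circadian and postprandial
    terms, and the linear drug effect at the Day 1 concentration. Day -1 is
    drug-free but has the same meal schedule.

    Returns
    -------
    DataFrame with columns ``subject_id, sequence, period, day, treatment,
    nominal_time_h, replicate, qt_ms, rr_s``.

    Raises
    ------
    ValueError
        If ``pk_table`` does not cover every subject/period/time cell of the
        design (parent analyte).
    """
    if qt_params is None:
        qt_params = QtModelParams()
    p = qt_params
    rng = np.random.default_rng(seed)

    times = np.asarray(design.nominal_times_h)
    n_sub, n_per, n_t = design.n_subjects, design.n_periods, len(times)

    parent = pk_table[pk_table["analyte"] == "parent"]
    conc = np.zeros((n_sub, n_per, n_t))
    lookup = parent.set_index(["subject_id", "period", "nominal_time_h"])["conc_ng_ml"]
    try:
        for s in range(n_sub):
            for per in range(n_per):
                conc[s, per, :] = lookup.loc[(s + 1, per + 1)].reindex(times).to_numpy()
    except KeyError as err:
        raise ValueError(f"pk_table is missing cells for the design: {err}") from None
    if np.isnan(conc).any():
        raise ValueError("pk_table is missing concentration values for some design cells")

    # per-subject latent parameters
    qtc_i = p.qtc_pop_mean + rng.normal(0.0, p.qtc_between_subject_sd, n_sub)
    sex_is_f = np.array([s == "F" for s in design.sex_assignment])
    qtc_i = qtc_i + np.where(sex_is_f, p.sex_effect, 0.0)
    b_i = rng.normal(p.qt_rr_exponent_mean, p.qt_rr_exponent_sd, n_sub)
    rr_i = rng.normal(p.rr_mean_s, p.rr_between_subject_sd, n_sub)

    food_qt = food_effect(times, p.food_effect_amplitude, p.food_effect_decay_h, design.meal_times_h)
    food_rr = food_effect(times, p.rr_food_effect_s, p.food_effect_decay_h, design.meal_times_h)
    # circadian acrophase set so QTc peaks in the night assuming morning dosing
    circ = p.circadian_amplitude * np.cos(2.0 * np.pi * (times - 19.0) / 24.0)

    days = np.array([-1, 1])
    shape = (n_sub, n_per, 2, n_t, n_replicates)
    rr = (
        rr_i[:, None, None, None, None]
        + food_rr[None, None, None, :, None]
        + rng.normal(0.0, p.rr_within_subject_sd, shape)
    )
    np.clip(rr, 0.4, None, out=rr)

    conc_day = np.zeros((n_sub, n_per, 2, n_t))
    conc_day[:, :, 1, :] = conc  # Day -1 is drug-free
    true_qtc = (
        qtc_i[:, None, None, None]
        + (circ + food_qt)[None, None, None, :]
        + p.drug_slope * conc_day
    )
    qt = true_qtc[..., None] * rr ** b_i[:, None, None, None, None]
    qt = qt + rng.normal(0.0, p.replicate_sd, shape)

    idx = pd.MultiIndex.from_product(
        [range(1, n_sub + 1), range(1, n_per + 1), days, times, range(1, n_replicates + 1)],
        names=["subject_id", "period", "day", "nominal_time_h", "replicate"],
    )
    out = pd.DataFrame(index=idx).reset_index()
    out["qt_ms"] = qt.ravel()
    out["rr_s"] = rr.ravel()
    out["sequence"] = np.repeat([design.sequence_assignment[s] + 1 for s in range(n_sub)], n_per * 2 * n_t * n_replicates)
    day1_treat = np.array(
        [[design.treatment_for(s + 1, per + 1) for per in range(n_per)] for s in range(n_sub)]
    )
    treat = np.where(
        out["day"].to_numpy() == 1,
        day1_treat[out["subject_id"].to_numpy() - 1, out["period"].to_numpy() - 1],
        "placebo",
    )
    out["treatment"] = treat
    return out[
        ["subject_id", "sequence", "period", "day", "treatment", "nominal_time_h", "replicate", "qt_ms", "rr_s"]
    ]


def simulate_trial(
    n_subjects: int = 32,
    seed: int = 0,
    qt_params: QtModelParams | None = None,
    pk_params: dict[str, PkParams] | None = None,
    pk_between_subject_cv: float = 0.2,
    metabolite_scales: dict[str, float] | None = None,
    dropout: bool = False,
) -> tuple[TrialDesign, pd.DataFrame, pd.DataFrame]:
    """Generate a complete trial: ``(design, pk_table, ecg_table)``.

    Sub-seeds for the PK and ECG stages are derived from ``seed`` so that the
    whole trial is reproducible from one integer. With ``dropout=True`` one
    subject is withdrawn after period 1 (mirroring a 31/32 completer pattern).
    """
    design = build_design(n_subjects, seed)
    ss = np.random.SeedSequence(seed).spawn(2)
    pk = simulate_pk(
        design,
        params=pk_params,
        seed=ss[0].generate_state(1)[0] % (2**31),
        between_subject_cv=pk_between_subject_cv,
        metabolite_scales=metabolite_scales,
    )
    ecg = simulate_ecg(design, pk, qt_params, seed=ss[1].generate_state(1)[0] % (2**31))
    if dropout:
        drop_subject = n_subjects  # last enrolled subject withdraws
        pk = pk[~((pk["subject_id"] == drop_subject) & (pk["period"] > 1))]
        ecg = ecg[~((ecg["subject_id"] == drop_subject) & (ecg["period"] > 1))]
        pk, ecg = pk.reset_index(drop=True), ecg.reset_index(drop=True)
    return design, pk, ecg


def power_time_matched_crossover(
    n_subjects: int = 28,
    effect_ms: float = 8.0,
    sd_ms: float = 8.0,
    alpha: float = 0.05,
    n_sim: int = 1000,
    seed: int = 0,
) -> float:
    """Empirical power of a time-matched crossover QTc comparison.

    Each replicate draws ``n_subjects`` within-subject drug-minus-placebo QTc
    differences from Normal(effect, sd²) and tests mean = 0 with a two-sided
    one-sample t-test; the returned fraction of rejections at ``alpha``
    estimates the design's power to detect ``effect_ms``.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(effect_ms, sd_ms, size=(n_sim, n_subjects))
    t = x.mean(axis=1) / (x.std(axis=1, ddof=1) / math.sqrt(n_subjects))
    crit = stats.t.ppf(1.0 - alpha / 2.0, df=n_subjects - 1)
    return float(np.mean(np.abs(t) > crit))
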