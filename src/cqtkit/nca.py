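"""Non-compartmental pharmacokinetic analysis (NCA).

Model-free PK parameters from a concentration-time profile:

* Cmax / tmax by direct maximum (ties resolve to the earliest time);
* AUC0-t by the linear-up / log-down trapezoid to the last quantifiable
  concentration (log interpolation on declining segments, linear otherwise);
* AUC0-24 by the same rule, log/linear-interpolating at 24 h if it is not a
  sampling time;
* the terminal elimination rate λz by log-linear regression over the tail,
  choosing the best adjusted R² among all candidate tails of 3-8 points
  strictly after tmax; t½ = ln2/λz and AUC0-∞ = AUC0-t + Clast/λz.

Profiles whose terminal fit fails (λz <= 0 or fewer than 3 eligible points)
keep their AUC0-t but report t½ / AUC0-∞ as missing, flagged in the output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["NcaResult", "run_nca", "nca_table", "summarize_dose_groups", "auc_linear_up_log_down"]


@dataclass(frozen=True)
class NcaResult:
    """Per subject-period non-compartmental PK parameters."""

    subject_id: int
    period: int
    dose_mg: float
    analyte: str
    cmax: float
    tmax: float
    t_half: float | None
    auc_0_t: float
    auc_0_24: float | None
    auc_0_inf: float | None
    lambda_z: float | None
    n_lambda_points: int
    r2_adj: float | None


def _segment_auc(t0: float, t1: float, c0: float, c1: float) -> float:
    """Linear-up/log-down trapezoid area of one segment."""
    dt = t1 - t0
    if c1 < c0 and c1 > 0 and c0 > 0:
        return dt * (c0 - c1) / math.log(c0 / c1)
    return dt * (c0 + c1) / 2.0


def auc_linear_up_log_down(times: np.ndarray, concs: np.ndarray, t_end: float | None = None) -> float:
    """AUC from time 0 to ``t_end`` (default: last point) by lin-up/log-down.

    If ``t_end`` falls between sampling times the concentration there is
    interpolated with the same rule (log on a declining segment).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t_end is None:
        t_end = float(t[-1])
    auc = 0.0
    for i in range(len(t) - 1):
        if t[i] >= t_end:
            break
        if t[i + 1] <= t_end:
            auc += _segment_auc(t[i], t[i + 1], c[i], c[i + 1])
        else:  # partial segment: interpolate at t_end
            c0, c1 = c[i], c[i + 1]
            if c1 < c0 and c0 > 0 and c1 > 0:
                k = math.log(c0 / c1) / (t[i + 1] - t[i])
                c_end = c0 * math.exp(-k * (t_end - t[i]))
            else:
                c_end = c0 + (c1 - c0) * (t_end - t[i]) / (t[i + 1] - t[i])
            auc += _segment_auc(t[i], t_end, c0, c_end)
            break
    return auc


def _terminal_fit(t: np.ndarray, c: np.ndarray, tmax: float, max_points: int = 8):
    """Best adjusted-R² log-linear tail fit strictly after tmax.

    Returns (lambda_z, n_points, r2_adj) or (None, 0, None).
    """
    mask = (t > tmax) & (c > 0)
    tt, cc = t[mask], np.log(c[mask])
    n_avail = len(tt)
    best = (None, 0, None)
    best_r2 = -np.inf
    for n in range(3, min(max_points, n_avail) + 1):
        x, y = tt[-n:], cc[-n:]
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            continue
        resid = y - (intercept + slope * x)
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if r2_adj > best_r2 + 1e-12:
            best_r2 = r2_adj
            best = (-float(slope), n, float(r2_adj))
    return best


def run_nca(
    times: np.ndarray,
    concs: np.ndarray,
    dose_mg: float,
    subject_id: int = 0,
    period: int = 0,
    analyte: str = "parent",
) -> NcaResult:
    """NCA of one concentration-time profile.

    ``times`` must be strictly increasing; at least 3 post-dose
    concentrations must be positive. Pre-dose (t<=0) concentrations are
    fixed at 0 for these single-dose profiles.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float).copy()
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    c[t <= 0] = 0.0
    if int((c[t > 0] > 0).sum()) < 3:
        raise ValueError("need at least 3 positive post-dose concentrations")

    i_max = int(np.argmax(c))  # argmax returns the earliest tie
    cmax, tmax = float(c[i_max]), float(t[i_max])

    pos = np.where(c > 0)[0]
    t_last = float(t[pos[-1]])
    c_last = float(c[pos[-1]])
    auc_0_t = auc_linear_up_log_down(t[: pos[-1] + 1], c[: pos[-1] + 1])
    auc_0_24 = auc_linear_up_log_down(t, c, t_end=24.0) if t_last >= 24.0 else None

    lambda_z, n_pts, r2_adj = _terminal_fit(t, c, tmax)
    if lambda_z is None:
        logger.warning(
            "subject %s period %s: no valid terminal phase; t1/2 and AUC0-inf missing",
            subject_id, period,
        )
        t_half = auc_0_inf = None
    else:
        t_half = math.log(2.0) / lambda_z
        auc_0_inf = auc_0_t + c_last / lambda_z

    return NcaResult(
        subject_id=subject_id, period=period, dose_mg=dose_mg, analyte=analyte,
        cmax=cmax, tmax=tmax, t_half=t_half, auc_0_t=auc_0_t, auc_0_24=auc_0_24,
        auc_0_inf=auc_0_inf, lambda_z=lambda_z, n_lambda_points=n_pts, r2_adj=r2_adj,
    )


def nca_table(pk: pd.DataFrame, analyte: str = "parent") -> pd.DataFrame:
    """Run NCA for every active subject-period of a tidy PK table.

    Placebo periods (dose 0) are skipped. Returns one row per
    subject/period with the :class:`NcaResult` fields plus the treatment
    label when present.
    """
    rows = []
    sub = pk[pk["analyte"] == analyte]
    for (sid, period), grp in sub.groupby(["subject_id", "period"]):
        grp = grp.sort_values("nominal_time_h")
        dose = float(grp["dose_mg"].iloc[0])
        if dose <= 0:
            continue
        res = run_nca(
            grp["nominal_time_h"].to_numpy(), grp["conc_ng_ml"].to_numpy(),
            dose_mg=dose, subject_id=int(sid), period=int(period), analyte=analyte,
        )
        row = res.__dict__.copy()
        if "treatment" in grp.columns:
            row["treatment"] = grp["treatment"].iloc[0]
        rows.append(row)
    if not rows:
        raise ValueError("no active-dose profiles found in the PK table")
    return pd.DataFrame(rows)


def summarize_dose_groups(
    nca: pd.DataFrame, normalize_reference_mg: float | None = None
) -> pd.DataFrame:
    """Dose-group summary mirroring the trial report's PK table layout.

    Arithmetic mean (SD) for Cmax, t½ and the AUCs; median (SD) for tmax;
    the geometric-mean Cmax is carried separately for the effect-prediction
    stage. Dose-normalised columns divide by the row's own dose unless
    ``normalize_reference_mg`` pins a common reference dose
    (mirror-the-report mode). A singleton group reports SD 0 with an n=1
    flag.
    """
    rows = []
    for dose, grp in nca.groupby("dose_mg"):
        n = len(grp)
        sd = (lambda s: float(s.std(ddof=1)) if n > 1 else 0.0)
        ref = normalize_reference_mg if normalize_reference_mg else dose
        row = {
            "dose_mg": float(dose),
            "n": n,
            "cmax_mean": float(grp["cmax"].mean()),
            "cmax_sd": sd(grp["cmax"]),
            "cmax_geomean": float(np.exp(np.log(grp["cmax"]).mean())),
            "tmax_median": float(grp["tmax"].median()),
            "tmax_sd": sd(grp["tmax"]),
            "t_half_mean": float(grp["t_half"].mean()),
            "t_half_sd": sd(grp["t_half"].dropna()),
            "auc_0_t_mean": float(grp["auc_0_t"].mean()),
            "auc_0_t_sd": sd(grp["auc_0_t"]),
            "auc_0_inf_mean": float(grp["auc_0_inf"].mean()),
            "auc_0_inf_sd": sd(grp["auc_0_inf"].dropna()),
            "auc_0_24_mean": float(grp["auc_0_24"].mean()),
            "auc_0_24_sd": sd(grp["auc_0_24"].dropna()),
        }
        row["cmax_per_dose"] = row["cmax_mean"] / ref
        row["auc_0_24_per_dose"] = row["auc_0_24_mean"] / ref
        if "treatment" in grp.columns:
            row["treatment"] = grp["treatment"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows).sort_values("dose_mg").reset_index(drop=True)
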