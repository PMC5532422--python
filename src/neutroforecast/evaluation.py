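"""Evaluation layer: summary variables, RMSE, classification, accuracy.

Summary variables of a myelosuppression time-course:

* ``nadir_time`` — time (days) of the lowest post-dose ANC,
* ``nadir_anc`` — the ANC at nadir (x10^9 cells/L),
* ``recovery_time`` — first time after nadir at which the ANC regains the
  baseline value (NaN when not reached within the horizon).

Prediction error of a summary variable across patients is reported as a
root-mean-squared error in the variable's own unit,

    RMSE = sqrt( mean_i (pred_i - true_i)^2 )

and as a perc--error variant normalised by the true value,

    RMSE% = 100 * sqrt( mean_i ((pred_i - true_i) / true_i)^2 ).

Severe-neutropenia classification compares threshold crossings of the true
and the MAP-predicted residual-free trajectories: Grade 4 is ANC strictly
below 0.5 x10^9/L at any time during the cycle; the deeper category is
ANC <= 0.1 x10^9/L. Positives are defined on the true profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ode import Trajectory

__all__ = [
    "SummaryVariables",
    "ClassificationResult",
    "summarize_trajectory",
    "rmse",
    "rmse_pct",
    "classify",
    "first_event_day",
    "sensitivity_specificity",
    "accuracy_distribution",
    "GRADE4_THRESHOLD",
    "DEEP_THRESHOLD",
]

GRADE4_THRESHOLD = 0.5   # x10^9 cells/L, strict "<"
DEEP_THRESHOLD = 0.1     # x10^9 cells/L, non-strict "<="
CYCLE_DAYS = 21.0

ACCURACY_PERCENTILES = (2.5, 25.0, 50.0, 75.0, 97.5)


@dataclass(frozen=True)
class SummaryVariables:
    nadir_time: float        # days
    nadir_anc: float         # x10^9 cells/L
    recovery_time: float     # days; NaN = not reached within horizon

    @property
    def recovery_reached(self) -> bool:
        return np.isfinite(self.recovery_time)


@dataclass(frozen=True)
class ClassificationResult:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else np.nan

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else np.nan


def summarize_trajectory(traj: Trajectory, anc0_i: float | None = None) -> SummaryVariables:
    """Summary variables of a residual-free trajectory on its dense grid.

    The nadir is the global post-dose minimum; recovery is the first time
    after the nadir at which the ANC reaches the baseline ``anc0_i`` (by
    default the trajectory's own baseline). A trajectory that never dips
    below baseline has its nadir at dose time and no recovery time.
    """
    if traj.times[-1] < 42.0 * 24.0 - 1e-6:
        raise ValueError("summary variables need a dense grid covering >= 42 days")
    base = traj.anc0 if anc0_i is None else float(anc0_i)
    i_min = int(np.argmin(traj.circ))
    if traj.circ[i_min] >= base * (1.0 - 1e-9):
        return SummaryVariables(0.0, float(traj.circ[0]), np.nan)
    nadir_t = traj.times[i_min] / 24.0
    after = traj.circ[i_min:] >= base
    if np.any(after):
        rec_t = traj.times[i_min + int(np.argmax(after))] / 24.0
    else:
        rec_t = np.nan
    return SummaryVariables(float(nadir_t), float(traj.circ[i_min]), float(rec_t))


def rmse(pred, truth) -> float:
    """Root-mean-squared error in the unit of the variable."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def rmse_pct(pred, truth) -> float:
    """Root-mean-squared relative error, in percent of the true value."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    if np.any(truth == 0):
        raise ValueError("truth must be non-zero for RMSE%")
    return float(np.sqrt(np.mean(((pred - truth) / truth) ** 2)) * 100.0)


def classify(
    traj: Trajectory,
    threshold: float = GRADE4_THRESHOLD,
    strict_below: bool = True,
    *,
    window_days: tuple = (0.0, CYCLE_DAYS),
) -> bool:
    """Whether the trajectory crosses ``threshold`` during the cycle window."""
    sel = (traj.days >= window_days[0]) & (traj.days <= window_days[1])
    m = float(np.min(traj.circ[sel]))
    return m < threshold if strict_below else m <= threshold


def first_event_day(
    traj: Trajectory,
    threshold: float = GRADE4_THRESHOLD,
    strict_below: bool = True,
    days=None,
) -> float:
    """First monitored day on which the trajectory crosses the threshold.

    Evaluated on the daily sampling grid (days 3..21 by default), matching
    how a first event day is read off a daily-sampled data set; NaN when
    the threshold is never crossed.
    """
    days = np.arange(3, 22) if days is None else np.asarray(days)
    anc = traj.at_days(days)
    hit = anc < threshold if strict_below else anc <= threshold
    return float(days[np.argmax(hit)]) if np.any(hit) else np.nan


def sensitivity_specificity(true_labels, pred_labels, threshold: float = GRADE4_THRESHOLD) -> ClassificationResult:
    """Confusion-matrix summary; positives are events on the TRUE profile."""
    t = np.asarray(true_labels, dtype=bool)
    p = np.asarray(pred_labels, dtype=bool)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    return ClassificationResult(
        threshold=threshold,
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


def accuracy_distribution(fits, patients, scenario, forecast_days) -> pd.DataFrame:
    """Percentiles of the forecast-accuracy ratio (predicted/true ANC).

    For each forecast day D (beyond the scenario's last monitored day) the
    across-patient 2.5/25/50/75/97.5 percentiles of
    ``ANC_pred(D) / ANC_true(D)`` are tabulated.
    """
    if len(fits) != len(patients):
        raise ValueError("fits and patients must align")
    rows = []
    for day in forecast_days:
        ratios = np.array([
            f.accuracy_ratio(p, day) for f, p in zip(fits, patients) if f.converged
        ])
        pct = np.percentile(ratios, ACCURACY_PERCENTILES)
        rows.append((scenario.name, scenario.last_day, float(day), len(ratios), *pct))
    cols = ["scenario", "monitored_until", "forecast_day", "n"] + [
        f"p{q:g}" for q in ACCURACY_PERCENTILES
    ]
    return pd.DataFrame(rows, columns=cols)
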