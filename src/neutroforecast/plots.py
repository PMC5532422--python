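"""Plot helpers for study reports (matplotlib, non-interactive friendly)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # noqa: E402 - headless by default
import matplotlib.pyplot as plt
import numpy as np


__all__ = ["plot_trajectory_fit", "plot_rmse_vs_duration", "plot_sens_spec"]


def plot_trajectory_fit(patient, fit, ax=None):
    """True vs MAP-predicted ANC time-course with the fitted observations."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(patient.true_traj.days, patient.true_traj.circ, "-", label="true")
    ax.plot(fit.pred_traj.days, fit.pred_traj.circ, "--", label="predicted")
    obs = fit.model.obs
    ax.plot(obs.days, obs.anc, "o", label="observed")
    ax.axhline(0.5, color="0.6", lw=0.8, ls=":")
    ax.set_xlabel("day")
    ax.set_ylabel("ANC (x10^9 cells/L)")
    ax.set_yscale("log")
    ax.legend()
    return ax


def plot_rmse_vs_duration(report: dict, variable: str = "recovery_time", ax=None):
    """RMSE of a summary variable against monitoring duration (daily scenarios)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    rows = []
    for name, scen in report["scenarios"].items():
        if name.startswith("daily:"):
            rows.append((int(name.split(":")[1]), scen["summary_rmse"][variable]["rmse"]))
    rows.sort()
    if rows:
        d, r = zip(*rows)
        ax.plot(d, r, "o-")
    base = report["scenarios"].get("baseline_only")
    if base:
        ax.axhline(base["summary_rmse"][variable]["rmse"], color="0.5", ls="--",
                   label="baseline only")
        ax.legend()
    ax.set_xlabel("last monitored day")
    ax.set_ylabel(f"RMSE of {variable}")
    return ax


def plot_sens_spec(report: dict, label: str = "grade4", ax=None):
    """Sensitivity and specificity against monitoring duration."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    rows = []
    for name, scen in report["scenarios"].items():
        if name.startswith("daily:"):
            c = scen["classification"][label]
            rows.append((int(name.split(":")[1]), c["sensitivity"], c["specificity"]))
    rows.sort()
    if rows:
        d, se, sp = zip(*rows)
        ax.plot(d, np.asarray(se) * 100, "o-", label="sensitivity")
        ax.plot(d, np.asarray(sp) * 100, "s-", label="specificity")
    ax.set_xlabel("last monitored day")
    ax.set_ylabel("%")
    ax.set_ylim(0, 102)
    ax.legend()
    return ax
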