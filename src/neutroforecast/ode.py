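"""Transit-compartment myelosuppression ODE and its production solver.

The model tracks a proliferating progenitor pool, ``n_transit`` maturation
compartments and the circulating neutrophil pool::

    dProl/dt = k_prol * Prol * (1 - E(t)) * (Circ0 / Circ)^gamma - k_tr * Prol
    dT_i/dt  = k_tr * (T_{i-1} - T_i)          i = 1..n_transit
    dCirc/dt = k_tr * T_n - k_circ * Circ

with ``k_prol = k_tr = k_circ = (n_transit + 1) / MTT`` and a linear drug
effect ``E = Slope * Conc(t)``, optionally capped just below 1 so that
proliferation never turns negative. At baseline every compartment equals the
individual baseline ANC, which is the system's steady state in the absence
of drug.

The production integrator is a fixed-step classical Runge-Kutta (RK4) scheme
compiled with numba, on a time grid refined around concentration
discontinuities (infusion start/stop) where the exposure varies on the scale
of minutes. Concentrations are pre-evaluated at grid nodes and midpoints so
any vectorised concentration profile can drive the system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .population import IndividualParameters
from .pk import ConcentrationProfile

__all__ = ["Trajectory", "solve_model", "predict_anc", "default_dense_times"]

#: dense output step used for trajectories and summary variables (0.1 day)
DENSE_STEP_H = 2.4

#: default drug-effect cap: uncapped, E > 1 means net kill of proliferating
#: cells — the standard behaviour of the linear-effect model for potent
#: cytotoxics. Pass e_cap=0.999 to keep production non-negative instead.
E_CAP_NONE = np.inf


class IntegrationError(RuntimeError):
    """Raised when the trajectory leaves the physically meaningful domain."""


@dataclass
class Trajectory:
    """ANC time-course on a dense grid (times in hours)."""

    times: np.ndarray
    circ: np.ndarray
    anc0: float
    state: np.ndarray | None = None

    def at(self, times_h) -> np.ndarray:
        """ANC interpolated at arbitrary times (h)."""
        return np.interp(np.asarray(times_h, dtype=float), self.times, self.circ)

    def at_days(self, days) -> np.ndarray:
        return self.at(np.asarray(days, dtype=float) * 24.0)

    @property
    def days(self) -> np.ndarray:
        return self.times / 24.0


@njit(cache=True)
def _rhs(y, c, ktr, gamma, circ0, slope, e_cap, dy):
    m = y.shape[0]
    e = slope * c
    if e > e_cap:
        e = e_cap
    circ = y[m - 1]
    if circ < 1e-12:
        circ = 1e-12
    fb = (circ0 / circ) ** gamma
    dy[0] = ktr * y[0] * ((1.0 - e) * fb - 1.0)
    for i in range(1, m - 1):
        dy[i] = ktr * (y[i - 1] - y[i])
    dy[m - 1] = ktr * (y[m - 2] - y[m - 1])


@njit(cache=True)
def _rk4_kernel(ts, c_node, c_mid, y0, ktr, gamma, circ0, slope, e_cap):
    n = ts.shape[0]
    m = y0.shape[0]
    out = np.empty((n, m))
    y = y0.copy()
    out[0] = y
    k1 = np.empty(m)
    k2 = np.empty(m)
    k3 = np.empty(m)
    k4 = np.empty(m)
    ytmp = np.empty(m)
    for i in range(n - 1):
        h = ts[i + 1] - ts[i]
        _rhs(y, c_node[i], ktr, gamma, circ0, slope, e_cap, k1)
        for j in range(m):
            ytmp[j] = y[j] + 0.5 * h * k1[j]
        _rhs(ytmp, c_mid[i], ktr, gamma, circ0, slope, e_cap, k2)
        for j in range(m):
            ytmp[j] = y[j] + 0.5 * h * k2[j]
        _rhs(ytmp, c_mid[i], ktr, gamma, circ0, slope, e_cap, k3)
        for j in range(m):
            ytmp[j] = y[j] + h * k3[j]
        _rhs(ytmp, c_node[i + 1], ktr, gamma, circ0, slope, e_cap, k4)
        for j in range(m):
            y[j] = y[j] + h / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
            # states are physically non-negative; clamp to a tiny positive
            # floor so the proliferative pool can regrow after deep kill
            if y[j] < 1e-12:
                y[j] = 1e-12
        out[i + 1] = y
    return out


def _build_grid(t_max: float, knots, requested: np.ndarray) -> np.ndarray:
    """Integration grid: coarse base, refined near profile discontinuities."""
    parts = [np.arange(0.0, t_max, 0.5), np.asarray([t_max])]
    for k in knots:
        lo, hi = max(0.0, k - 0.5), min(t_max, k + 8.0)
        if hi > lo:
            parts.append(np.arange(lo, hi, 0.02))
    # medium refinement over the first three days (drug-effect decay phase)
    parts.append(np.arange(0.0, min(72.0, t_max), 0.1))
    if requested.size:
        parts.append(requested)
    grid = np.unique(np.concatenate(parts))
    return grid[(grid >= 0.0) & (grid <= t_max)]


def solve_model(
    ind: IndividualParameters,
    gamma: float,
    conc: ConcentrationProfile,
    times,
    *,
    n_transit: int = 3,
    e_cap: float = E_CAP_NONE,
    keep_state: bool = False,
) -> Trajectory:
    """Integrate the myelosuppression system and return the ANC trajectory.

    Parameters
    ----------
    ind : IndividualParameters
        Realized individual parameters (baseline ANC, MTT, slope).
    gamma : float
        Feedback exponent (population value; no IIV).
    conc : ConcentrationProfile
        Drug exposure driving ``E = slope * conc(t)``.
    times : array-like
        Requested output times (h), increasing, starting >= 0. The returned
        trajectory's grid is the full integration grid (a superset), so the
        requested times are exact nodes.
    e_cap : float
        Cap on the drug effect. The default (infinity) allows E > 1, i.e.
        net kill of proliferating cells; a cap just below 1 (e.g. 0.999)
        instead clamps production at zero.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if np.any(np.diff(times) < 0) or times[0] < 0:
        raise ValueError("times must be increasing and start at >= 0")
    t_max = float(times[-1])
    anc0 = ind.anc0_i
    if t_max == 0.0:
        # pre-dose: the system sits at its steady state
        return Trajectory(times=times.copy(), circ=np.full(times.shape, anc0), anc0=anc0)

    grid = _build_grid(t_max, getattr(conc, "knots", ()), times)
    c_node = np.asarray(conc(grid), dtype=float)
    c_mid = np.asarray(conc(0.5 * (grid[:-1] + grid[1:])), dtype=float)
    y0 = np.full(n_transit + 2, anc0, dtype=float)
    ktr = (n_transit + 1) / ind.mtt_i
    sol = _rk4_kernel(
        np.ascontiguousarray(grid), c_node, c_mid, y0,
        ktr, float(gamma), anc0, ind.slope_i, float(e_cap),
    )
    circ = sol[:, -1]
    if not np.all(np.isfinite(circ)):
        raise IntegrationError(
            f"non-finite ANC trajectory (anc0={anc0:.3g}, mtt={ind.mtt_i:.3g}, "
            f"slope={ind.slope_i:.3g})"
        )
    return Trajectory(
        times=grid,
        circ=circ,
        anc0=anc0,
        state=sol if keep_state else None,
    )


def predict_anc(
    ind: IndividualParameters,
    gamma: float,
    conc: ConcentrationProfile,
    times_h,
    **kwargs,
) -> np.ndarray:
    """Residual-free model-predicted ANC at the requested times (h)."""
    times_h = np.atleast_1d(np.asarray(times_h, dtype=float))
    if times_h.size and times_h[-1] == 0.0:
        return np.full(times_h.shape, ind.anc0_i)
    traj = solve_model(ind, gamma, conc, times_h, **kwargs)
    return traj.at(times_h)


def default_dense_times(horizon_days: float = 42.0) -> np.ndarray:
    """Requested output grid for stored trajectories: 0.1-day steps."""
    return np.arange(0.0, horizon_days * 24.0 + 1e-9, DENSE_STEP_H)
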