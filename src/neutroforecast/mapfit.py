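"""MAP ("Bayesian feedback") estimation of individual random effects.

Population parameters are fixed; only one patient's random effects
``eta = (eta_anc0, eta_mtt, eta_slope)`` are estimated from that patient's
observed ANC under a monitoring scenario. With log-normal residual error and
log-normal IIV the negative twice-log-posterior (up to a constant) is

    J(eta) = sum_j (log y_j - log f(t_j; eta))^2 / sigma^2
           + sum_k eta_k^2 / omega_k^2

whose minimiser is the posterior mode (MAP / empirical-Bayes estimate).
``IndividualMAP`` is the model object; ``fit`` runs a bounded quasi-Newton
multi-start minimisation and returns an ``IndividualMAPResults`` carrying
the estimates, a Laplace covariance, the predicted trajectory and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .ode import (
    E_CAP_NONE,
    Trajectory,
    _build_grid,
    _rk4_kernel,
    default_dense_times,
    predict_anc,
    solve_model,
)
from .population import Covariates, PopulationModel, realize_parameters
from .simulate import ObservationSet, Patient, Scenario, restrict_observations

__all__ = ["IndividualMAP", "IndividualMAPResults", "map_objective",
           "fit_individual", "fit_scenario"]

_ETA_LABELS = ("eta_anc0", "eta_mtt", "eta_slope")


class IndividualMAP:
    """MAP model for one patient's random effects given observed ANC.

    Parameters
    ----------
    obs : ObservationSet
        Observed (day, ANC) pairs available under the monitoring scenario.
    population : PopulationModel
        Fixed population parameters acting as the prior.
    covariates : Covariates
        The patient's covariates (assumed known).
    concentration : ConcentrationProfile
        The patient's drug exposure (assumed known).
    sigma : float, optional
        Residual log-SD used in the data term; defaults to the population
        value (the generating value in the simulation study).

    Examples
    --------
    >>> model = IndividualMAP(obs, pop, cov, conc)
    >>> res = model.fit()
    >>> res.params          # MAP random effects
    >>> res.summary()
    """

    def __init__(
        self,
        obs: ObservationSet,
        population: PopulationModel,
        covariates: Covariates,
        concentration,
        *,
        sigma: float | None = None,
        e_cap: float = E_CAP_NONE,
    ):
        if len(obs.days) == 0:
            raise ValueError("observation set is empty")
        self.obs = obs
        self.population = population
        self.covariates = covariates
        self.concentration = concentration
        self.sigma = population.sigma_log if sigma is None else float(sigma)
        if self.sigma <= 0:
            raise ValueError("sigma must be strictly positive")
        self.e_cap = e_cap
        self._log_obs = np.log(np.asarray(obs.anc, dtype=float))
        self._times_h = obs.times_h
        omegas = population.omegas
        # zero-IIV components are pinned at 0 rather than dividing by 0
        self._free = omegas > 0
        self._inv_om2 = np.where(self._free, 1.0 / np.where(self._free, omegas, 1.0) ** 2, 0.0)
        self._omegas = omegas
        # the integration grid and concentration samples do not depend on
        # eta; precompute them once so each objective evaluation only runs
        # the compiled integration kernel
        t_max = float(self._times_h[-1])
        if t_max > 0.0:
            grid = _build_grid(t_max, getattr(concentration, "knots", ()), self._times_h)
            self._grid = np.ascontiguousarray(grid)
            self._c_node = np.asarray(concentration(grid), dtype=float)
            self._c_mid = np.asarray(
                concentration(0.5 * (grid[:-1] + grid[1:])), dtype=float
            )
            self._obs_idx = np.searchsorted(grid, self._times_h)
        else:
            self._grid = None

    # ------------------------------------------------------------------ core
    def predict(self, eta: np.ndarray, times_h) -> np.ndarray:
        """Residual-free predicted ANC at ``times_h`` for random effects eta."""
        ind = realize_parameters(self.population, self.covariates, eta)
        return predict_anc(
            ind, self.population.gamma, self.concentration, times_h,
            n_transit=self.population.n_transit, e_cap=self.e_cap,
        )

    def _predict_obs(self, eta: np.ndarray) -> np.ndarray:
        """Model prediction at the observation times (cached-grid fast path)."""
        ind = realize_parameters(self.population, self.covariates, eta)
        if self._grid is None:
            return np.full(self._times_h.shape, ind.anc0_i)
        sol = _rk4_kernel(
            self._grid, self._c_node, self._c_mid,
            np.full(self.population.n_transit + 2, ind.anc0_i),
            (self.population.n_transit + 1) / ind.mtt_i,
            self.population.gamma, ind.anc0_i, ind.slope_i, float(self.e_cap),
        )
        return sol[self._obs_idx, -1]

    def objective(self, eta) -> float:
        """The MAP objective J(eta); +inf when the model cannot be evaluated."""
        eta = np.asarray(eta, dtype=float)
        try:
            f = self._predict_obs(eta)
        except Exception:  # noqa: BLE001 - flagged as infeasible point
            return np.inf
        if np.any(f <= 0) or not np.all(np.isfinite(f)):
            return np.inf
        resid = self._log_obs - np.log(f)
        return float(resid @ resid / self.sigma**2 + (eta**2 * self._inv_om2).sum())

    # ------------------------------------------------------------------- fit
    def fit(
        self,
        *,
        n_starts: int = 5,
        jitter_scale: float = 1.0,
        seed: int = 0,
        tol: float = 1e-8,
        bound_sd: float = 6.0,
        horizon_days: float = 42.0,
    ) -> "IndividualMAPResults":
        """Multi-start bounded quasi-Newton minimisation of the MAP objective.

        Starts at eta = 0 (the prior mode) plus ``n_starts - 1`` starts
        jittered by ``jitter_scale`` prior SDs; the best converged solution
        wins. Components with zero IIV stay fixed at 0.
        """
        rng = np.random.default_rng(seed)
        starts = [np.zeros(3)]
        for _ in range(max(0, n_starts - 1)):
            starts.append(rng.normal(0.0, jitter_scale * self._omegas))
        bounds = [
            (-bound_sd * w, bound_sd * w) if f else (0.0, 0.0)
            for w, f in zip(self._omegas, self._free)
        ]
        best = None
        n_failed = 0
        for x0 in starts:
            res = optimize.minimize(
                self.objective, np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds]),
                method="L-BFGS-B", bounds=bounds,
                options={"ftol": tol, "gtol": 1e-8, "maxiter": 500},
            )
            if not res.success:
                n_failed += 1
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
        converged = best is not None and n_failed < len(starts) and np.isfinite(best.fun)
        eta_hat = best.x if best is not None else np.zeros(3)
        dense = default_dense_times(horizon_days)
        ind_hat = realize_parameters(self.population, self.covariates, eta_hat)
        pred_traj = solve_model(
            ind_hat, self.population.gamma, self.concentration, dense,
            n_transit=self.population.n_transit, e_cap=self.e_cap,
        )
        return IndividualMAPResults(
            model=self,
            params=np.asarray(eta_hat, dtype=float),
            objective_value=float(best.fun) if best is not None else np.inf,
            converged=bool(converged),
            pred_traj=pred_traj,
            scenario=self.obs.scenario,
        )


@dataclass
class IndividualMAPResults:
    """MAP estimates and the individual prediction they imply."""

    model: IndividualMAP
    params: np.ndarray           # eta_hat (anc0, mtt, slope)
    objective_value: float
    converged: bool
    pred_traj: Trajectory
    scenario: str = "full"

    @property
    def individual_parameters(self):
        return realize_parameters(self.model.population, self.model.covariates, self.params)

    def cov_params(self) -> np.ndarray:
        """Laplace posterior covariance: 2 * H^-1 of the objective at the mode.

        The objective equals -2 log posterior up to a constant, so its
        Hessian is twice the posterior precision. Pinned (zero-IIV)
        components get zero variance.
        """
        free = self.model._free
        idx = np.flatnonzero(free)
        h = 1e-4
        k = idx.size
        H = np.zeros((k, k))
        for a in range(k):
            for b in range(a, k):
                e_a = np.zeros(3); e_a[idx[a]] = h
                e_b = np.zeros(3); e_b[idx[b]] = h
                fpp = self.model.objective(self.params + e_a + e_b)
                fpm = self.model.objective(self.params + e_a - e_b)
                fmp = self.model.objective(self.params - e_a + e_b)
                fmm = self.model.objective(self.params - e_a - e_b)
                H[a, b] = H[b, a] = (fpp - fpm - fmp + fmm) / (4 * h * h)
        cov = np.zeros((3, 3))
        try:
            cov_free = 2.0 * np.linalg.inv(H)
            cov[np.ix_(idx, idx)] = cov_free
        except np.linalg.LinAlgError:
            cov[:] = np.nan
        return cov

    @property
    def bse(self) -> np.ndarray:
        """Approximate posterior SDs of the random effects."""
        return np.sqrt(np.clip(np.diag(self.cov_params()), 0.0, None))

    def predict(self, times_h) -> np.ndarray:
        """Predicted ANC at arbitrary times (h) from the MAP estimate."""
        return self.pred_traj.at(times_h)

    def forecast_error(self, patient: Patient, day: float) -> float:
        """Log forecast error at ``day``: log(ANC_pred) - log(ANC_true)."""
        pred = float(self.pred_traj.at_days([day])[0])
        true = float(patient.true_traj.at_days([day])[0])
        return np.log(pred) - np.log(true)

    def accuracy_ratio(self, patient: Patient, day: float) -> float:
        """Predicted / true ANC at ``day`` (the forecast-accuracy ratio)."""
        return float(np.exp(self.forecast_error(patient, day)))

    def summary(self) -> str:
        ip = self.individual_parameters
        bse = self.bse
        lines = [
            "Individual MAP fit (myelosuppression model)",
            "=" * 52,
            f"scenario: {self.scenario}   n_obs: {len(self.model.obs.days)}   "
            f"converged: {self.converged}",
            f"objective: {self.objective_value:.6g}",
            "-" * 52,
            f"{'effect':<10}{'estimate':>12}{'post. SD':>12}{'prior SD':>12}",
        ]
        for name, est, se, om in zip(_ETA_LABELS, self.params, bse, self.model._omegas):
            lines.append(f"{name:<10}{est:>12.4f}{se:>12.4f}{om:>12.4f}")
        lines.append("-" * 52)
        lines.append(
            f"ANC0_i {ip.anc0_i:8.3f} x10^9/L   MTT_i {ip.mtt_i:7.1f} h   "
            f"Slope_i {ip.slope_i:7.2f} L/umol"
        )
        return "\n".join(lines)


def map_objective(
    eta,
    obs: ObservationSet,
    pop: PopulationModel,
    cov: Covariates,
    conc,
    *,
    sigma: float | None = None,
) -> float:
    """Functional form of the MAP objective (see :class:`IndividualMAP`)."""
    return IndividualMAP(obs, pop, cov, conc, sigma=sigma).objective(eta)


def fit_individual(
    obs: ObservationSet,
    pop: PopulationModel,
    cov: Covariates,
    conc,
    *,
    sigma: float | None = None,
    **fit_kwargs,
) -> IndividualMAPResults:
    """Convenience wrapper: build the model and fit in one call."""
    return IndividualMAP(obs, pop, cov, conc, sigma=sigma).fit(**fit_kwargs)


def fit_scenario(
    patients: list[Patient],
    scenario: Scenario,
    pop: PopulationModel,
    *,
    sigma: float | None = None,
    **fit_kwargs,
) -> list[IndividualMAPResults]:
    """Fit every patient under one monitoring scenario."""
    fits = []
    for p in patients:
        obs = restrict_observations(p, scenario)
        fits.append(fit_individual(obs, pop, p.covariates, p.conc,
                                   sigma=sigma, **fit_kwargs))
    return fits
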