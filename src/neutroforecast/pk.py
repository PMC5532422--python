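"""Surrogate docetaxel exposure model.

Individual concentration-time profiles drive the drug effect of the
myelosuppression model. Docetaxel disposition is linear and classically
described by a three-compartment mammillary model with a short 1-h
intravenous infusion; the concentration solution is a tri-exponential
evaluated in closed form from the eigendecomposition of the micro-rate
matrix, so no ODE integration is needed for exposure.

Defaults are literature-plausible for docetaxel: clearance ~36 L/h at a
body surface area (BSA) of 1.8 m^2 scaling linearly with BSA, central
volume ~8 L, steady-state volume ~115 L, and alpha/beta/gamma half-lives of
minutes / tens of minutes / ~12 h. A global ``exposure_scale`` multiplies
the whole profile; it is the calibration handle that stands in for the
original per-patient exposures (see the study runner).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PKConfig",
    "ConcentrationProfile",
    "TriExponentialProfile",
    "SquarePulseProfile",
    "ZeroProfile",
    "make_concentration_profile",
    "DOCETAXEL_MOLAR_MASS",
]

#: g/mol, used to convert the mg dose to umol.
DOCETAXEL_MOLAR_MASS = 807.9

#: Allowed dose levels (mg/m^2) for the simulated regimen (1-h infusion q3w).
DOSE_LEVELS = (75.0, 100.0)


@dataclass(frozen=True)
class PKConfig:
    """Three-compartment disposition parameters (volumes L, flows L/h).

    ``cl_typ`` is the typical clearance at the reference BSA; individual
    clearance scales linearly with BSA and optionally carries log-normal IIV
    with SD ``iiv_cv_cl`` on the log scale.
    """

    cl_typ: float = 36.0
    bsa_ref: float = 1.8
    v1: float = 8.0
    q2: float = 25.0
    v2: float = 20.0
    q3: float = 7.0
    v3: float = 110.0
    infusion_h: float = 1.0
    molar_mass: float = DOCETAXEL_MOLAR_MASS
    iiv_cv_cl: float = 0.30
    exposure_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cl_typ", "bsa_ref", "v1", "q2", "v2", "q3", "v3",
                     "infusion_h", "molar_mass", "exposure_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.iiv_cv_cl < 0:
            raise ValueError("iiv_cv_cl must be non-negative")


class ConcentrationProfile:
    """Callable mapping time (h) to drug concentration (umol/L).

    Subclasses must be vectorised over time, return 0 before the infusion
    start and expose ``knots`` — times where the profile or its derivative is
    discontinuous — so that the ODE integrator can refine its grid there.
    """

    knots: tuple = ()

    def __call__(self, t):  # pragma: no cover - interface
        raise NotImplementedError

    def scaled(self, factor: float) -> "ConcentrationProfile":
        """A copy of the profile with concentrations multiplied by ``factor``."""
        raise NotImplementedError


class ZeroProfile(ConcentrationProfile):
    """No drug: concentration identically zero (homeostasis runs)."""

    def __call__(self, t):
        return np.zeros_like(np.asarray(t, dtype=float))

    def scaled(self, factor: float) -> "ZeroProfile":
        return self


class SquarePulseProfile(ConcentrationProfile):
    """Constant concentration on [start, stop), zero elsewhere (test inputs)."""

    def __init__(self, level: float, start: float = 0.0, stop: float = 24.0):
        if stop <= start:
            raise ValueError("stop must exceed start")
        self.level = float(level)
        self.start = float(start)
        self.stop = float(stop)
        self.knots = (self.start, self.stop)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return np.where((t >= self.start) & (t < self.stop), self.level, 0.0)

    def scaled(self, factor: float) -> "SquarePulseProfile":
        return SquarePulseProfile(self.level * factor, self.start, self.stop)


class TriExponentialProfile(ConcentrationProfile):
    """Closed-form central-compartment concentration for a zero-order infusion.

    Built from the eigendecomposition of the 3x3 micro-rate matrix ``K``
    (amounts): during the infusion ``A(t) = P diag((e^{l t}-1)/l) P^-1 e1 R``
    and afterwards ``A(t) = e^{K (t - tau)} A(tau)``, with concentration
    ``A1/V1`` times the global exposure scale.
    """

    def __init__(
        self,
        dose_umol: float,
        cl: float,
        config: PKConfig,
        scale: float = 1.0,
    ):
        if dose_umol <= 0 or cl <= 0 or scale <= 0:
            raise ValueError("dose, clearance and scale must be positive")
        self.dose_umol = float(dose_umol)
        self.cl = float(cl)
        self.config = config
        self.scale = float(scale)
        self.tau = config.infusion_h
        self.knots = (0.0, self.tau)

        v1, q2, v2, q3, v3 = config.v1, config.q2, config.v2, config.q3, config.v3
        k10, k12, k21 = cl / v1, q2 / v1, q2 / v2
        k13, k31 = q3 / v1, q3 / v3
        K = np.array(
            [
                [-(k10 + k12 + k13), k21, k31],
                [k12, -k21, 0.0],
                [k13, 0.0, -k31],
            ]
        )
        lam, P = np.linalg.eig(K)
        order = np.argsort(lam)  # most negative (fastest) first
        lam, P = lam[order].real, P[:, order].real
        Pinv = np.linalg.inv(P)
        rate = self.dose_umol / self.tau  # umol/h zero-order input
        w = Pinv[:, 0] * rate
        # during infusion: c(t) = sum_i cd_i (exp(lam_i t) - 1), t in [0, tau]
        self._lam = lam
        self._cd = P[0, :] * w / lam / v1
        A_tau = P @ (w * (np.exp(lam * self.tau) - 1.0) / lam)
        z = Pinv @ A_tau
        # after infusion: c(t) = sum_i cp_i exp(lam_i (t - tau))
        self._cp = P[0, :] * z / v1

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        c = np.zeros_like(t)
        during = (t >= 0.0) & (t < self.tau)
        after = t >= self.tau
        if np.any(during):
            td = t[during][:, None]
            c[during] = (self._cd * (np.exp(self._lam * td) - 1.0)).sum(axis=1)
        if np.any(after):
            ta = (t[after] - self.tau)[:, None]
            c[after] = (self._cp * np.exp(self._lam * ta)).sum(axis=1)
        return np.maximum(c * self.scale, 0.0)

    @property
    def auc(self) -> float:
        """Analytic AUC (umol*h/L): scale * dose / CL (linear disposition)."""
        return self.scale * self.dose_umol / self.cl

    @property
    def half_lives(self) -> np.ndarray:
        """Disposition half-lives (h), fastest first."""
        return np.log(2.0) / -self._lam

    def scaled(self, factor: float) -> "TriExponentialProfile":
        new = replace(self.config)  # config immutable; reuse
        return TriExponentialProfile(self.dose_umol, self.cl, new, self.scale * factor)


def make_concentration_profile(
    cov,
    dose_mg_per_m2: float,
    pk_config: PKConfig | None = None,
    rng: np.random.Generator | None = None,
) -> TriExponentialProfile:
    """Individual docetaxel profile for a 1-h infusion of 75 or 100 mg/m^2.

    The absolute dose is ``dose_mg_per_m2 * BSA`` converted to umol.
    Clearance scales linearly with BSA from the typical value; when ``rng``
    is given, log-normal IIV with SD ``iiv_cv_cl`` is applied to clearance.
    """
    cfg = pk_config or PKConfig()
    if float(dose_mg_per_m2) not in DOSE_LEVELS:
        raise ValueError(f"dose must be one of {DOSE_LEVELS} mg/m^2")
    dose_mg = float(dose_mg_per_m2) * cov.bsa
    dose_umol = dose_mg / cfg.molar_mass * 1000.0  # mg -> umol
    cl = cfg.cl_typ * cov.bsa / cfg.bsa_ref
    if rng is not None and cfg.iiv_cv_cl > 0:
        cl *= np.exp(rng.normal(0.0, cfg.iiv_cv_cl))
    return TriExponentialProfile(dose_umol, cl, cfg, scale=cfg.exposure_scale)
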