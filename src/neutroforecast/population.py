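"""Population pharmacodynamic model for docetaxel-induced myelosuppression.

Fixed effects, inter-individual variability (IIV) and covariate relationships
of the semi-mechanistic transit-compartment model of granulopoiesis, with the
docetaxel parameterisation estimated on log-transformed neutrophil data.
Baseline ANC (``anc0``) carries covariate effects of alpha-1-acid glycoprotein
(AAG, hockey-stick power relationship anchored at the population median),
sex, performance status and previous chemotherapy; the drug-effect ``slope``
is linear in AAG centred at the same anchor. Mean transit time (MTT) carries
no covariates, and the feedback exponent gamma carries no IIV.

IIV is log-normal: realized = typical * exp(eta), eta ~ N(0, omega^2), with
omega read directly from the reported CV fractions. Residual error is
additive on log(ANC).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PopulationModel",
    "Covariates",
    "IndividualParameters",
    "apply_covariates",
    "realize_parameters",
    "sample_individual",
    "AAG_REFERENCE",
]

#: Population median AAG (g/L); anchor for both AAG covariate relationships.
AAG_REFERENCE = 1.34

_ETA_NAMES = ("anc0", "mtt", "slope")


def _default_iiv() -> dict:
    return {"anc0": 0.25, "mtt": 0.14, "slope": 0.36}


def _default_cov_coefs() -> dict:
    return {
        "anc0_aag_low": 0.175,   # power on AAG/1.34 when AAG <= breakpoint
        "anc0_aag_high": 0.495,  # power on AAG/1.34 when AAG > breakpoint
        "anc0_sex": -0.121,      # proportional shift, females
        "anc0_ps": 0.131,        # proportional shift, performance status >= 1
        "anc0_prevchemo": -0.147,  # proportional shift, previous chemotherapy
        "slope_aag": -0.351,     # linear in (AAG - breakpoint)
    }


@dataclass(frozen=True)
class PopulationModel:
    """Fixed effects and variability of the myelosuppression model.

    Parameters
    ----------
    anc0_typ : float
        Typical baseline absolute neutrophil count (x10^9 cells/L).
    mtt_typ : float
        Typical mean transit time through the maturation chain (hours).
    gamma : float
        Feedback exponent on (ANC0/ANC); upregulates proliferation when
        circulating counts fall (G-CSF-like rebound). No IIV.
    slope_typ : float
        Typical linear drug-effect coefficient (L/umol).
    iiv_cv : dict
        Log-scale IIV standard deviations (CV fractions) for
        ``anc0``, ``mtt`` and ``slope``.
    sigma_log : float
        Residual error SD, additive on log(ANC).
    cov_coefs : dict
        Covariate coefficients, see :func:`apply_covariates`.
    aag_breakpoint : float
        AAG (g/L) anchoring the hockey-stick and the centred linear term.
    n_transit : int
        Number of transit (maturation) compartments; the shared rate
        constant is ``(n_transit + 1) / MTT``.
    """

    anc0_typ: float = 5.22
    mtt_typ: float = 84.2
    gamma: float = 0.145
    slope_typ: float = 15.6
    iiv_cv: dict = field(default_factory=_default_iiv)
    sigma_log: float = 0.424
    cov_coefs: dict = field(default_factory=_default_cov_coefs)
    aag_breakpoint: float = AAG_REFERENCE
    n_transit: int = 3

    def __post_init__(self) -> None:
        for name in ("anc0_typ", "mtt_typ", "slope_typ", "aag_breakpoint"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be non-negative")
        if self.n_transit < 1:
            raise ValueError("n_transit must be >= 1")
        missing = set(_ETA_NAMES) - set(self.iiv_cv)
        if missing:
            raise ValueError(f"iiv_cv missing entries: {sorted(missing)}")
        if any(self.iiv_cv[k] < 0 for k in _ETA_NAMES):
            raise ValueError("iiv_cv entries must be non-negative")

    @property
    def k_tr(self) -> float:
        """Shared transit/proliferation/elimination rate constant (1/h)."""
        return (self.n_transit + 1) / self.mtt_typ

    @property
    def omegas(self) -> np.ndarray:
        """Log-scale IIV SDs in (anc0, mtt, slope) order."""
        return np.array([self.iiv_cv[k] for k in _ETA_NAMES])

    def with_updates(self, **kwargs) -> "PopulationModel":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Covariates:
    """Patient covariates entering the pharmacodynamic or surrogate PK model.

    ``performance_status`` follows the trial coding: 0 means WHO performance
    status 0 or unknown (reference), 1 means >= 1. ``bsa`` feeds only the
    surrogate exposure model; ``age`` is carried for bookkeeping but unused.
    """

    aag: float = AAG_REFERENCE          # g/L
    sex: str = "male"                   # "male" | "female"
    performance_status: int = 0         # 0 = 0-or-unknown, 1 = >= 1
    previous_chemo: bool = False
    bsa: float = 1.8                    # m^2
    age: float = 56.0                   # years

    def __post_init__(self) -> None:
        if self.aag <= 0:
            raise ValueError("aag must be strictly positive")
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if self.performance_status not in (0, 1):
            raise ValueError("performance_status must be 0 (0/unknown) or 1 (>=1)")
        if self.bsa <= 0:
            raise ValueError("bsa must be strictly positive")


@dataclass(frozen=True)
class IndividualParameters:
    """Random effects and the realized individual parameters they imply."""

    eta: np.ndarray       # (anc0, mtt, slope) log-scale random effects
    anc0_i: float
    mtt_i: float
    slope_i: float

    def __post_init__(self) -> None:
        if min(self.anc0_i, self.mtt_i, self.slope_i) <= 0:
            raise ValueError("realized individual parameters must be positive")


def apply_covariates(pop: PopulationModel, cov: Covariates) -> tuple[float, float, float]:
    """Covariate-adjusted typical values (anc0, mtt, slope) for one patient.

    Baseline ANC is multiplicative: a hockey-stick power of AAG relative to
    the breakpoint (continuous there, with a steeper exponent above it) times
    proportional shifts for female sex (lower), performance status >= 1
    (higher) and previous chemotherapy (lower). Slope is linear in AAG
    centred at the breakpoint, floored at a small positive value. MTT has no
    covariates.
    """
    c = pop.cov_coefs
    ratio = cov.aag / pop.aag_breakpoint
    exponent = c["anc0_aag_low"] if cov.aag <= pop.aag_breakpoint else c["anc0_aag_high"]
    anc0 = pop.anc0_typ * ratio ** exponent
    if cov.sex == "female":
        anc0 *= 1.0 + c["anc0_sex"]
    if cov.performance_status >= 1:
        anc0 *= 1.0 + c["anc0_ps"]
    if cov.previous_chemo:
        anc0 *= 1.0 + c["anc0_prevchemo"]

    slope = pop.slope_typ * (1.0 + c["slope_aag"] * (cov.aag - pop.aag_breakpoint))
    slope = max(slope, 1e-3 * pop.slope_typ)

    if anc0 <= 0:
        raise ValueError(f"covariates {cov} yield non-positive baseline ANC")
    return anc0, pop.mtt_typ, slope


def realize_parameters(
    pop: PopulationModel, cov: Covariates, eta: np.ndarray
) -> IndividualParameters:
    """Individual parameters for given random effects (log-normal convention)."""
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (3,):
        raise ValueError("eta must be a 3-vector (anc0, mtt, slope)")
    anc0_t, mtt_t, slope_t = apply_covariates(pop, cov)
    return IndividualParameters(
        eta=eta,
        anc0_i=anc0_t * np.exp(eta[0]),
        mtt_i=mtt_t * np.exp(eta[1]),
        slope_i=slope_t * np.exp(eta[2]),
    )


def sample_individual(
    pop: PopulationModel, cov: Covariates, rng: np.random.Generator
) -> IndividualParameters:
    """Draw random effects eta ~ N(0, omega^2) and realize the individual."""
    eta = rng.normal(0.0, pop.omegas)
    return realize_parameters(pop, cov, eta)
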