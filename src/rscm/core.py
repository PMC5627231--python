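"""Model types and the right-hand side of the regulation-structured cybernetic model.

The model couples batch-reactor mass balances of a two-step denitrification
chain (NO3- -> NO2- -> N2, driven by dissolved organic carbon) to a
transcription/translation regulation cascade.  Each reduction pathway *i* has
an internal resource pool ``rho_i`` (ATP, polymerases, ribosomes, genes —
lumped, dimensionless), a transcript pool ``tau_i`` (dimensionless) and a
functional enzyme pool ``e_i`` (pmol per g soil).  Carbon uptake through
pathway *i* proceeds at ``r_i = e_i * r_i_kin`` where ``r_i_kin`` is a
dual-substrate Monod product in DOC and the pathway's electron acceptor.
Resource allocation between the two pathways follows the cybernetic matching
law: the fraction ``u_i = p_i / (p_1 + p_2)`` of inductive resource synthesis
is allocated in proportion to each pathway's return-on-investment ``p_i``,
taken here to be its carbon uptake rate ``r_i``.

Stoichiometry (per mole DOC routed through pathway *i*, with energy fraction
``f_i`` respired and ``(1 - f_i)/5`` assimilated into C5H7O2N biomass):

* pathway 1:  DOC + 2 f1 NO3-  ->  2 f1 NO2- + f1 DIC + (1-f1)/5 BM
* pathway 2:  DOC + 4/3 f2 NO2-  ->  2/3 f2 N2 + f2 DIC + (1-f2)/5 BM

Biomass decays at rate ``kdeg`` back into DOC (5 carbons per biomass unit),
closing the carbon balance: d(DOC + DIC + 5 BM)/dt = 0 identically, and
d(NO3 + NO2 + 2 N2)/dt = 0 identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = [
    "DomainError",
    "IntegrationError",
    "ModelParameters",
    "ModelState",
    "DerivedRates",
    "STATE_NAMES",
    "monod_factor",
    "unregulated_rates",
    "cybernetic_u",
    "synthesis_rates",
    "rhs",
    "rhs_array",
    "derived_rates",
    "instantaneous_yield",
]


class DomainError(ValueError):
    """An argument lies outside the physical domain of an operation."""


class IntegrationError(RuntimeError):
    """The ODE solver failed; ``time`` holds the last reached time."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


#: Canonical ordering of the 12 integrated state components.
STATE_NAMES = (
    "xDOC", "xNO3", "xNO2", "xN2", "xDIC", "xBM",
    "rho1", "rho2", "tau1", "tau2", "e1", "e2",
)


@dataclass(frozen=True)
class ModelParameters:
    """Kinetic, stoichiometric and regulatory constants of the model.

    Defaults are the published parameter set for the hyporheic-zone sediment
    batch experiment (point estimates of the data fit plus the fixed
    literature values).

    Parameters
    ----------
    f1, f2
        Fractions of DOC respired for energy through NO3- and NO2- reduction;
        the pathway biomass yields are ``(1 - f_i) / 5``.  Dimensionless,
        in [0, 1].
    k1, k2
        Maximum DOC-uptake rate constants, mM (g soil / pmol enzyme) / d.
        Multiplied by the enzyme level they give the regulated rate in mM/d.
    Kd1, Kd2
        DOC half-saturation constants, mM.
    Ka1, Ka2
        Electron-acceptor (NO3-, NO2-) half-saturation constants, mM.
    kdeg
        Biomass degradation rate constant, 1/d.
    kR1, kR2, kT1, kT2, kE1, kE2
        Maximum synthesis rate constants of the resource pools, transcripts
        and enzymes, 1/d.
    KT1, KT2
        Transcript-synthesis half-saturation in the resource pool,
        dimensionless.
    KET1, KET2, KER1, KER2
        Translation half-saturations with respect to the transcript and the
        resource pool.  The published table lists a single value per pathway;
        it is applied to both factors.
    alphaR1, alphaR2
        Constitutive resource synthesis rates, 1/d.
    betaR1, betaR2, betaT1, betaT2, betaE1, betaE2
        First-order degradation rate constants of resources, transcripts and
        enzymes, 1/d.
    """

    f1: float = 0.56
    f2: float = 0.99
    k1: float = 6.23
    k2: float = 5.71
    Kd1: float = 0.25
    Kd2: float = 0.25
    Ka1: float = 0.001
    Ka2: float = 0.004
    kdeg: float = 0.11
    kR1: float = 2.84
    kR2: float = 1.03
    kT1: float = 0.13
    kT2: float = 0.25
    kE1: float = 1.84
    kE2: float = 1.56
    KT1: float = 0.25
    KT2: float = 0.25
    KET1: float = 0.25
    KET2: float = 0.25
    KER1: float = 0.25
    KER2: float = 0.25
    alphaR1: float = 0.2
    alphaR2: float = 0.2
    betaR1: float = 0.8
    betaR2: float = 0.8
    betaT1: float = 0.8
    betaT2: float = 0.8
    betaE1: float = 0.8
    betaE2: float = 0.8

    def __post_init__(self) -> None:
        for frac in ("f1", "f2"):
            v = getattr(self, frac)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{frac} must lie in [0, 1], got {v}")
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise DomainError(f"{f.name} must be finite, got {v}")
            # half-saturation constants (capital K) appear in denominators and
            # must be strictly positive; rate constants may be zero so limiting
            # cases (switched-off synthesis, no decay) stay expressible
            if f.name.startswith("K"):
                if v <= 0:
                    raise DomainError(f"{f.name} must be > 0, got {v}")
            elif v < 0:
                raise DomainError(f"{f.name} must be >= 0, got {v}")

    def with_updates(self, **updates: float) -> "ModelParameters":
        """Return a copy with the named fields replaced."""
        return replace(self, **updates)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in fields(self))


@dataclass(frozen=True)
class ModelState:
    """The 12 integrated concentrations.

    Nutrients and biomass (``xDOC``, ``xNO3``, ``xNO2``, ``xN2``, ``xDIC``,
    ``xBM``) are in mM; ``rho``/``tau`` are dimensionless pool abundances and
    ``e1``/``e2`` are enzyme levels in pmol per g soil.  Defaults are the
    published batch initial condition.
    """

    xDOC: float = 61.1
    xNO3: float = 18.3
    xNO2: float = 0.0
    xN2: float = 0.0
    xDIC: float = 1.0
    xBM: float = 1.5
    rho1: float = 0.001
    rho2: float = 0.001
    tau1: float = 0.001
    tau2: float = 0.001
    e1: float = 0.001
    e2: float = 0.001

    def __post_init__(self) -> None:
        for name in STATE_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise DomainError(
                    f"state component {name} must be finite and >= 0, got {v}"
                )

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        y = np.asarray(y, dtype=float)
        if y.shape != (12,):
            raise DomainError(f"state vector must have 12 components, got {y.shape}")
        return cls(**dict(zip(STATE_NAMES, y)))

    def with_updates(self, **updates: float) -> "ModelState":
        return replace(self, **updates)


@dataclass(frozen=True)
class DerivedRates:
    """Rates derived from a state: kinetics, control variables and yield."""

    r1_kin: float
    r2_kin: float
    r1: float
    r2: float
    u1: float
    u2: float
    p1: float
    p2: float
    rR1: float
    rR2: float
    rT1: float
    rT2: float
    rE1: float
    rE2: float
    yield_inst: float


def monod_factor(x: float, K: float) -> float:
    """Saturating Monod fraction ``x / (K + x)`` in [0, 1).

    ``x`` is a substrate concentration (>= 0) and ``K`` the half-saturation
    constant (> 0), in the same units.
    """
    if K <= 0:
        raise DomainError(f"half-saturation constant must be > 0, got {K}")
    if x < 0:
        raise DomainError(f"concentration must be >= 0, got {x}")
    return x / (K + x)


def unregulated_rates(state: ModelState, params: ModelParameters) -> tuple[float, float]:
    """Dual-substrate Monod kinetic rates before enzyme regulation.

    ``r1_kin`` saturates in DOC and NO3-, ``r2_kin`` in DOC and NO2-.  The
    regulated uptake rate of pathway *i* is ``e_i * r_i_kin``.
    """
    r1_kin = (params.k1 * monod_factor(state.xDOC, params.Kd1)
              * monod_factor(state.xNO3, params.Ka1))
    r2_kin = (params.k2 * monod_factor(state.xDOC, params.Kd2)
              * monod_factor(state.xNO2, params.Ka2))
    return r1_kin, r2_kin


def cybernetic_u(p1: float, p2: float) -> tuple[float, float]:
    """Matching-law allocation fractions ``u_i = p_i / (p_1 + p_2)``.

    When both returns-on-investment vanish, inductive synthesis is switched
    off entirely (``u1 = u2 = 0``) so that only constitutive resource
    synthesis persists; this is the continuous limit that avoids an arbitrary
    regularisation scale.
    """
    if p1 < 0 or p2 < 0:
        raise DomainError(f"return-on-investment must be >= 0, got ({p1}, {p2})")
    total = p1 + p2
    if total == 0:
        return 0.0, 0.0
    return p1 / total, p2 / total


def synthesis_rates(
    state: ModelState, params: ModelParameters
) -> tuple[float, float, float, float, float, float]:
    """Synthesis rates of resources, transcripts and enzymes.

    Resource synthesis mirrors the substrate-uptake Monod product (without an
    enzyme factor); transcription saturates in the resource pool; translation
    saturates in both the transcript and the resource pool.
    """
    rR1 = (params.kR1 * monod_factor(state.xDOC, params.Kd1)
           * monod_factor(state.xNO3, params.Ka1))
    rR2 = (params.kR2 * monod_factor(state.xDOC, params.Kd2)
           * monod_factor(state.xNO2, params.Ka2))
    rT1 = params.kT1 * monod_factor(state.rho1, params.KT1)
    rT2 = params.kT2 * monod_factor(state.rho2, params.KT2)
    rE1 = (params.kE1 * monod_factor(state.tau1, params.KET1)
           * monod_factor(state.rho1, params.KER1))
    rE2 = (params.kE2 * monod_factor(state.tau2, params.KET2)
           * monod_factor(state.rho2, params.KER2))
    return rR1, rR2, rT1, rT2, rE1, rE2


def instantaneous_yield(r1: float, r2: float, params: ModelParameters) -> float:
    """Rate-weighted biomass yield ``(Y1 r1 + Y2 r2) / (r1 + r2)``.

    ``Y_i = (1 - f_i) / 5`` is the stoichiometric biomass yield of pathway
    *i* (mM biomass per mM DOC).  Defined as 0 when both rates vanish.
    """
    if r1 < 0 or r2 < 0:
        raise DomainError(f"rates must be >= 0, got ({r1}, {r2})")
    total = r1 + r2
    if total == 0:
        return 0.0
    y1 = (1.0 - params.f1) / 5.0
    y2 = (1.0 - params.f2) / 5.0
    return (y1 * r1 + y2 * r2) / total


def derived_rates(state: ModelState, params: ModelParameters) -> DerivedRates:
    """Evaluate every derived rate at one state."""
    r1_kin, r2_kin = unregulated_rates(state, params)
    r1 = state.e1 * r1_kin
    r2 = state.e2 * r2_kin
    u1, u2 = cybernetic_u(r1, r2)
    rR1, rR2, rT1, rT2, rE1, rE2 = synthesis_rates(state, params)
    return DerivedRates(
        r1_kin=r1_kin, r2_kin=r2_kin, r1=r1, r2=r2, u1=u1, u2=u2,
        p1=r1, p2=r2, rR1=rR1, rR2=rR2, rT1=rT1, rT2=rT2, rE1=rE1, rE2=rE2,
        yield_inst=instantaneous_yield(r1, r2, params),
    )


def _params_tuple(params: ModelParameters) -> tuple[float, ...]:
    return (
        params.f1, params.f2, params.k1, params.k2,
        params.Kd1, params.Kd2, params.Ka1, params.Ka2, params.kdeg,
        params.kR1, params.kR2, params.kT1, params.kT2, params.kE1, params.kE2,
        params.KT1, params.KT2, params.KET1, params.KET2, params.KER1, params.KER2,
        params.alphaR1, params.alphaR2,
        params.betaR1, params.betaR2, params.betaT1, params.betaT2,
        params.betaE1, params.betaE2,
    )


def rhs_array(y, pv) -> list[float]:
    """Time derivative of the raw 12-vector ``y`` given the parameter tuple ``pv``.

    Hot path for the ODE solver: plain scalar arithmetic, no dataclass
    construction.  Monod factors are evaluated on states clipped at zero so
    tiny negative excursions from adaptive stepping cannot produce negative
    rates.
    """
    (f1, f2, k1, k2, Kd1, Kd2, Ka1, Ka2, kdeg,
     kR1, kR2, kT1, kT2, kE1, kE2,
     KT1, KT2, KET1, KET2, KER1, KER2,
     aR1, aR2, bR1, bR2, bT1, bT2, bE1, bE2) = pv

    DOC = y[0] if y[0] > 0.0 else 0.0
    NO3 = y[1] if y[1] > 0.0 else 0.0
    NO2 = y[2] if y[2] > 0.0 else 0.0
    BM = y[5] if y[5] > 0.0 else 0.0
    rho1 = y[6] if y[6] > 0.0 else 0.0
    rho2 = y[7] if y[7] > 0.0 else 0.0
    tau1 = y[8] if y[8] > 0.0 else 0.0
    tau2 = y[9] if y[9] > 0.0 else 0.0
    e1 = y[10] if y[10] > 0.0 else 0.0
    e2 = y[11] if y[11] > 0.0 else 0.0

    mDOC1 = DOC / (Kd1 + DOC)
    mDOC2 = DOC / (Kd2 + DOC)
    mNO3 = NO3 / (Ka1 + NO3)
    mNO2 = NO2 / (Ka2 + NO2)

    r1 = e1 * k1 * mDOC1 * mNO3
    r2 = e2 * k2 * mDOC2 * mNO2
    total = r1 + r2
    if total > 0.0:
        u1 = r1 / total
        u2 = r2 / total
    else:
        u1 = u2 = 0.0

    rR1 = kR1 * mDOC1 * mNO3
    rR2 = kR2 * mDOC2 * mNO2
    rT1 = kT1 * rho1 / (KT1 + rho1)
    rT2 = kT2 * rho2 / (KT2 + rho2)
    rE1 = kE1 * (tau1 / (KET1 + tau1)) * (rho1 / (KER1 + rho1))
    rE2 = kE2 * (tau2 / (KET2 + tau2)) * (rho2 / (KER2 + rho2))

    return [
        -r1 - r2 + 5.0 * kdeg * BM,                         # DOC
        -2.0 * f1 * r1,                                     # NO3-
        2.0 * f1 * r1 - (4.0 / 3.0) * f2 * r2,              # NO2-
        (2.0 / 3.0) * f2 * r2,                              # N2
        f1 * r1 + f2 * r2,                                  # DIC
        (1.0 - f1) / 5.0 * r1 + (1.0 - f2) / 5.0 * r2 - kdeg * BM,  # BM
        aR1 + u1 * rR1 - bR1 * rho1,
        aR2 + u2 * rR2 - bR2 * rho2,
        rT1 - bT1 * tau1,
        rT2 - bT2 * tau2,
        rE1 - bE1 * e1,
        rE2 - bE2 * e2,
    ]


def rhs(state: ModelState, params: ModelParameters) -> np.ndarray:
    """Time derivative of the full state, in per-day units.

    Nutrient rows follow the two-pathway stoichiometry; biomass decay feeds
    5 carbons back to DOC per biomass unit; the regulation rows implement the
    resource/transcript/enzyme balances with matching-law allocation of
    inductive resource synthesis.
    """
    y = state.to_array()
    if not np.all(np.isfinite(y)):
        raise IntegrationError("non-finite state passed to rhs")
    return np.array(rhs_array(y, _params_tuple(params)), dtype=float)
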