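"""Model symbols and the right-hand side of the biomarker cascade ODE system.

State variables (all normalized, dimensionless levels, nominal range [0, 1]):

====================  =====================================================
``a_beta``            amyloid-beta pathology
``tau_p``             amyloid-related phosphorylated tau (p-tau)
``tau_o``             aging/SNAP-related tauopathy
``n_deg``             neuronal dysfunction / loss
``cog``               cognitive impairment
====================  =====================================================

Total tau is derived, not integrated: ``tau = tau_p + tau_o``.  Each of the
amyloid, p-tau, neurodegeneration, and cognition cascades grows logistically
with a carrying capacity K; the SNAP-tau compartment grows linearly from the
constant aging/SNAP driver.  Constant host factors (amyloidopathy, aging/SNAP
burden, ApoE genetic risk, cognitive reserve) shift the onset of the
downstream cascades; anti-amyloid therapy enters as a Heaviside step that
switches on an amyloid clearance term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "BiomarkerState",
    "RateParameters",
    "CarryingCapacities",
    "HostFactors",
    "TherapySchedule",
    "heaviside",
    "therapy_input",
    "total_tau",
    "rhs",
    "rhs_array",
    "DEGRADATION_FORMS",
]

#: Supported shapes of the therapy clearance term: "literal" is the
#: state-independent sink -delta_ab * H(t - onset); "proportional" scales the
#: sink by the current amyloid level, -delta_ab * a_beta * H(t - onset).
DEGRADATION_FORMS = ("literal", "proportional")


def _check_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class BiomarkerState:
    """Levels of the five integrated biomarkers at one age."""

    a_beta: float = 0.0
    tau_p: float = 0.0
    tau_o: float = 0.0
    n_deg: float = 0.0
    cog: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.a_beta, self.tau_p, self.tau_o, self.n_deg, self.cog])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "BiomarkerState":
        return cls(*(float(v) for v in y))


@dataclass(frozen=True)
class RateParameters:
    """Rate constants of the cascade ODEs (units 1/yr unless noted).

    ``lam_ab``, ``lam_tp``, ``lam_n``, ``lam_c`` are the logistic growth
    rates of the four capacity-bearing cascades; the remaining constants are
    linear coupling rates that set when downstream cascades take off.
    ``delta_ab`` (level/yr) is the amyloid clearance rate under therapy.
    """

    lam_ab: float = 0.0
    lam_ab_ao: float = 0.0
    delta_ab: float = 0.0
    lam_tp_ab: float = 0.0
    lam_tp: float = 0.0
    lam_to_as: float = 0.0
    lam_n: float = 0.0
    lam_n_tp: float = 0.0
    lam_n_to: float = 0.0
    lam_n_as: float = 0.0
    lam_c: float = 0.0
    lam_cn: float = 0.0
    lam_c_as: float = 0.0
    lam_c_eps: float = 0.0


@dataclass(frozen=True)
class CarryingCapacities:
    """Logistic saturation levels. SNAP-tau grows linearly and has none."""

    k_ab: float = 1.0
    k_tp: float = 1.0
    k_n: float = 1.0
    k_c: float = 1.0

    def as_array(self) -> np.ndarray:
        return np.array([self.k_ab, self.k_tp, self.k_n, self.k_c])


@dataclass(frozen=True)
class HostFactors:
    """Constant host-level drivers, fixed over the whole age span.

    ``a_o``
        amyloidopathy, an external constant amyloid driver.
    ``as_level``
        aging and/or SNAP comorbidity burden.
    ``eps``
        ApoE allele genetic risk feeding cognitive decline.
    ``reserve_low`` / ``reserve_high``
        cognitive reserve constants R for the low-risk and high-risk groups;
        R multiplies the neurodegeneration-to-cognition coupling, so a larger
        R translates neuronal loss into earlier cognitive decline.
    """

    a_o: float = 0.0
    as_level: float = 0.0
    eps: float = 0.0
    reserve_low: float = 1.0
    reserve_high: float = 25.0


@dataclass(frozen=True)
class TherapySchedule:
    """Anti-amyloid therapy switch: off, or on from ``onset_age`` for life."""

    active: bool = False
    onset_age: float = 0.0


def heaviside(n: float) -> float:
    """Unit step with the half-maximum convention: 0 for n<0, 1/2 at n=0, 1 for n>0."""
    _check_finite("heaviside argument", n)
    if n < 0.0:
        return 0.0
    if n > 0.0:
        return 1.0
    return 0.5


def therapy_input(t: float, schedule: TherapySchedule) -> float:
    """Therapy level A_Rx(t): 0 when inactive, else a step up at onset age."""
    if not schedule.active:
        return 0.0
    return heaviside(t - schedule.onset_age)


def total_tau(state: BiomarkerState) -> float:
    """Total tau pathology, the sum of p-tau and SNAP-related tau."""
    return state.tau_p + state.tau_o


def _validate_inputs(
    state: BiomarkerState, rates: RateParameters, caps: CarryingCapacities, host: HostFactors
) -> None:
    for obj in (state, rates, caps, host):
        for f in fields(obj):
            _check_finite(f.name, getattr(obj, f.name))


def rhs(
    t: float,
    state: BiomarkerState,
    rates: RateParameters,
    caps: CarryingCapacities,
    host: HostFactors,
    schedule: TherapySchedule = TherapySchedule(),
    *,
    reserve: float | None = None,
    degradation_form: str = "literal",
) -> BiomarkerState:
    """Time derivative of the biomarker state, in level/yr.

    The equations, writing A for a_beta, Tp for tau_p, To for tau_o, and
    T = Tp + To for total tau::

        dA/dt  = lam_ab * A * (k_ab - A) + lam_ab_ao * A_o - clearance(t)
        dTp/dt = lam_tp_ab * A + lam_tp * Tp * (k_tp - Tp)
        dTo/dt = lam_to_as * AS
        dN/dt  = lam_n_to * (T - Tp) + lam_n_tp * Tp
                 + lam_n * N * (k_n - N) + lam_n_as * AS
        dC/dt  = lam_cn * N * R + lam_c * C * (k_c - C)
                 + lam_c_as * AS + lam_c_eps * eps

    so that d(Tp + To)/dt reproduces the total-tau equation exactly.  The
    clearance term is ``delta_ab * A_Rx(t)`` ("literal") or
    ``delta_ab * A * A_Rx(t)`` ("proportional").

    Parameters
    ----------
    reserve
        Cognitive reserve R to use; defaults to ``host.reserve_low``.
    """
    _check_finite("t", t)
    _validate_inputs(state, rates, caps, host)
    if degradation_form not in DEGRADATION_FORMS:
        raise ValueError(
            f"degradation_form must be one of {DEGRADATION_FORMS}, got {degradation_form!r}"
        )
    r = host.reserve_low if reserve is None else reserve
    a_rx = therapy_input(t, schedule)
    dy = rhs_array(state.as_array(), rates, caps, host, a_rx, r, degradation_form)
    return BiomarkerState.from_array(dy)


def rhs_array(
    y: np.ndarray,
    rates: RateParameters,
    caps: CarryingCapacities,
    host: HostFactors,
    a_rx: float,
    reserve: float,
    degradation_form: str = "literal",
) -> np.ndarray:
    """Same derivative as :func:`rhs` on a raw state vector, no validation.

    ``y`` is ordered (a_beta, tau_p, tau_o, n_deg, cog) and ``a_rx`` is the
    pre-evaluated therapy input, constant on any interval not containing the
    therapy onset.  Intended for the integrator's hot loop.
    """
    a_beta, tau_p, tau_o, n_deg, cog = y
    clearance = rates.delta_ab * a_rx
    if degradation_form == "proportional":
        clearance *= a_beta
    d_ab = rates.lam_ab * a_beta * (caps.k_ab - a_beta) + rates.lam_ab_ao * host.a_o - clearance
    d_tp = rates.lam_tp_ab * a_beta + rates.lam_tp * tau_p * (caps.k_tp - tau_p)
    d_to = rates.lam_to_as * host.as_level
    # tau_o == total tau - tau_p, the SNAP-driven share of neurodegeneration
    d_n = (
        rates.lam_n_to * tau_o
        + rates.lam_n_tp * tau_p
        + rates.lam_n * n_deg * (caps.k_n - n_deg)
        + rates.lam_n_as * host.as_level
    )
    d_c = (
        rates.lam_cn * n_deg * reserve
        + rates.lam_c * cog * (caps.k_c - cog)
        + rates.lam_c_as * host.as_level
        + rates.lam_c_eps * host.eps
    )
    return np.array([d_ab, d_tp, d_to, d_n, d_c])
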