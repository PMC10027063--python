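"""Systemic pharmacokinetics: closed-form compartment models and bolus dosing.

Two linear PK models describe the circulating drug concentration ``C`` (in
arbitrary concentration units, time in minutes):

* one-compartment:  dC/dt = -lam * C
* two-compartment:  dC/dt = (k21 / R) * P - (k12 + lam) * C
                    dP/dt = k12 * R * C - k21 * P

where ``P`` is the peripheral-compartment concentration, ``k12``/``k21`` are
the intercompartmental clearance rates, ``R`` the central-to-peripheral volume
ratio and ``lam`` the central elimination rate.  Both systems are advanced
with their exact solutions (a scalar exponential, respectively the matrix
exponential of the 2x2 generator computed by closed-form eigendecomposition),
so stepping introduces no integration error regardless of step size.

Doses are intravenous boluses: an instantaneous increase of ``C``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "OneCompartmentParams",
    "TwoCompartmentParams",
    "PKState",
    "BiotNumber",
    "step_one_compartment",
    "step_two_compartment",
    "two_compartment_propagator",
    "apply_dose",
    "CompartmentPK",
]

#: relative discriminant threshold below which the 2x2 eigenvalues are treated
#: as repeated and the limit formula exp(mu)*(I + (B - mu*I)) is used instead
#: of the two-eigenvalue form, avoiding catastrophic cancellation.
_DEGENERATE_REL_TOL = 1e-12


@dataclass(frozen=True)
class OneCompartmentParams:
    """Parameters of the one-compartment model.

    Parameters
    ----------
    elimination_rate
        Central elimination rate ``lam`` (1/min), must be >= 0.
    """

    elimination_rate: float

    def __post_init__(self) -> None:
        if not (self.elimination_rate >= 0.0):
            raise ValueError(
                f"elimination_rate must be >= 0, got {self.elimination_rate}"
            )


@dataclass(frozen=True)
class TwoCompartmentParams:
    """Parameters of the two-compartment model.

    Parameters
    ----------
    elimination_rate
        Central elimination rate ``lam`` (1/min), >= 0.
    k12
        Central-to-periphery clearance rate (1/min), >= 0.
    k21
        Periphery-to-central clearance rate (1/min), >= 0.
    volume_ratio
        Ratio ``R`` of central to peripheral compartment volumes
        (dimensionless, > 0); it makes the concentration exchange
        mass-conserving.
    """

    elimination_rate: float
    k12: float
    k21: float
    volume_ratio: float

    def __post_init__(self) -> None:
        for name in ("elimination_rate", "k12", "k21"):
            if not (getattr(self, name) >= 0.0):
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not (self.volume_ratio > 0.0):
            raise ValueError(f"volume_ratio must be > 0, got {self.volume_ratio}")

    def generator(self) -> np.ndarray:
        """The 2x2 generator M with d/dt [C, P] = M @ [C, P]."""
        lam, k12, k21, R = self.elimination_rate, self.k12, self.k21, self.volume_ratio
        return np.array([[-(k12 + lam), k21 / R], [k12 * R, -k21]], dtype=float)


@dataclass(frozen=True)
class PKState:
    """Instantaneous systemic state: circulation (and optional periphery)."""

    circulation: float
    periphery: Optional[float] = None
    time: float = 0.0


@dataclass(frozen=True)
class BiotNumber:
    """Ratio of perivascular to intravascular concentration (default 1).

    Scales circulation concentration into the Dirichlet boundary value seen by
    the tissue; 1 means equal concentrations on both sides of the vessel wall.
    """

    value: float = 1.0

    def __post_init__(self) -> None:
        if not (self.value >= 0.0):
            raise ValueError(f"Biot number must be >= 0, got {self.value}")


def _check_dt(dt: float) -> None:
    if not (dt > 0.0):
        raise ValueError(f"dt must be > 0, got {dt}")


def step_one_compartment(
    state: PKState, params: OneCompartmentParams, dt: float
) -> PKState:
    """Advance the one-compartment model by ``dt`` minutes (exact)."""
    _check_dt(dt)
    c = state.circulation * math.exp(-params.elimination_rate * dt)
    return replace(state, circulation=c, time=state.time + dt)


def two_compartment_propagator(params: TwoCompartmentParams, dt: float) -> np.ndarray:
    """expm(M * dt) for the two-compartment generator, in closed form.

    The generator has real eigenvalues (its off-diagonal product
    ``k12 * k21`` is nonnegative so the discriminant is a sum of squares).
    For well-separated eigenvalues the two-point Lagrange form is used; when
    the discriminant is below ``1e-12 * trace**2`` the repeated-root limit
    ``exp(mu) * (I + (B - mu*I))`` is used instead.
    """
    _check_dt(dt)
    B = params.generator() * dt
    tr = B[0, 0] + B[1, 1]
    det = B[0, 0] * B[1, 1] - B[0, 1] * B[1, 0]
    disc = tr * tr - 4.0 * det
    eye = np.eye(2)
    if disc <= _DEGENERATE_REL_TOL * tr * tr or disc <= 0.0:
        mu = 0.5 * tr
        return math.exp(mu) * (eye + (B - mu * eye))
    s = math.sqrt(disc)
    mu1 = 0.5 * (tr + s)
    mu2 = 0.5 * (tr - s)
    # Lagrange interpolation of exp on the spectrum {mu1, mu2}
    return (math.exp(mu1) * (B - mu2 * eye) - math.exp(mu2) * (B - mu1 * eye)) / (
        mu1 - mu2
    )


def step_two_compartment(
    state: PKState,
    params: TwoCompartmentParams,
    dt: float,
    propagator: Optional[np.ndarray] = None,
) -> PKState:
    """Advance the two-compartment model by ``dt`` minutes (exact).

    ``propagator`` may carry a precomputed ``two_compartment_propagator`` for
    this exact ``dt``; passing it reuses the matrix bit-for-bit so that
    repeated stepping equals repeated fresh computation.
    """
    _check_dt(dt)
    if state.periphery is None:
        raise ValueError("two-compartment step requires a periphery concentration")
    if propagator is None:
        propagator = two_compartment_propagator(params, dt)
    c = propagator[0, 0] * state.circulation + propagator[0, 1] * state.periphery
    p = propagator[1, 0] * state.circulation + propagator[1, 1] * state.periphery
    return PKState(circulation=c, periphery=p, time=state.time + dt)


def apply_dose(state: PKState, amount: float) -> PKState:
    """Instantaneous IV bolus: circulation increases by ``amount``."""
    if not (amount >= 0.0):
        raise ValueError(f"dose amount must be >= 0, got {amount}")
    return replace(state, circulation=state.circulation + amount)


class CompartmentPK:
    """Stateful wrapper advancing one substrate's systemic PK on a fixed step.

    Caches the two-compartment propagator per ``dt`` so the tight simulation
    loop pays one 2x2 matrix-vector product per step.
    """

    def __init__(self, params, state: Optional[PKState] = None):
        self.params = params
        if isinstance(params, TwoCompartmentParams):
            self.state = state or PKState(0.0, 0.0)
            if self.state.periphery is None:
                self.state = replace(self.state, periphery=0.0)
        elif isinstance(params, OneCompartmentParams):
            self.state = state or PKState(0.0)
        else:
            raise TypeError(f"unsupported PK parameter type: {type(params)!r}")
        self._prop_dt: Optional[float] = None
        self._prop: Optional[np.ndarray] = None

    @property
    def circulation(self) -> float:
        return self.state.circulation

    def dose(self, amount: float) -> None:
        self.state = apply_dose(self.state, amount)

    def step(self, dt: float) -> None:
        if isinstance(self.params, OneCompartmentParams):
            self.state = step_one_compartment(self.state, self.params, dt)
            return
        if dt != self._prop_dt:
            self._prop = two_compartment_propagator(self.params, dt)
            self._prop_dt = dt
        self.state = step_two_compartment(self.state, self.params, dt, self._prop)
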