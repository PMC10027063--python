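"""Per-cell pharmacodynamics: damage accumulation and Hill-type effects.

Each (substrate, cell type) pair carries two per-cell state variables:

* ``A`` — internalized substrate, either a concentration ("AUC" damage model)
  or a raw amount ("AUC_amount"); fed by cellular uptake, catabolized at the
  metabolism rate ``m``.
* ``D`` — abstract drug damage, driven by ``A`` (proportionality constant 1)
  and repaired at a first-order rate ``r1`` plus a zero-order rate ``r0``:

      dA/dt = -m * A
      dD/dt = A - r1 * D - r0

The linear system has an exact solution that is applied per PD step; the
four scalar coefficients of the affine update (decay of A, decay of D, the
A-into-D transfer, and the constant repair increment) depend only on the
parameters and the step size, so they are precomputed once and reused.
Degenerate parameter combinations (``r1 == m``, ``r1 = 0``, ``m = 0``) are
continuous limits handled through ``expm1`` so nearby parameters give nearby
updates.  ``D`` is clamped at zero after each step: with zero-order repair
the closed form can undershoot, but damage is a nonnegative abstraction.

Damage maps onto phenotype through a Hill-type factor

    f = 1 + (f_sat - 1) * (D/EC50)^n / (1 + (D/EC50)^n)

where ``f_sat`` is the ratio of the user-supplied saturation rate to the
cell's base rate.  When several substrates share a mechanism of action the
factors multiply; necrosis is the exception (its base rate is commonly 0, so
``f_sat`` is undefined) and combines additively on the rate itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "DAMAGE_MODELS",
    "MOA_NAMES",
    "PDParams",
    "PDState",
    "PDPrecomputed",
    "HillParams",
    "MOAConfig",
    "build_precomputed",
    "pd_step",
    "hill_factor",
    "hill_response",
    "apply_moas",
]

DAMAGE_MODELS = ("AUC", "AUC_amount")

#: mechanism-of-action names, matching the phenotype rates they target
MOA_NAMES = ("prolif", "apop", "necrosis", "motility")

# branch threshold for |r1 - m| relative to max(r1, m)
_REPEATED_RATE_REL_TOL = 1e-12


@dataclass(frozen=True)
class PDParams:
    """Damage-accumulation parameters for one (substrate, cell type) pair.

    Parameters
    ----------
    metabolism_rate
        ``m`` (1/min): first-order catabolism of the internalized substrate.
    repair_rate_constant
        ``r0`` (damage/min): zero-order damage repair.
    repair_rate_linear
        ``r1`` (1/min): first-order damage repair.
    dt
        PD step (min); defaults to the mechanics step in the orchestrator.
    damage_model
        "AUC" (A is a concentration) or "AUC_amount" (A is an amount).
    precompute
        Whether the affine update coefficients are cached (the default) or
        re-derived from the parameters at every step.
    """

    metabolism_rate: float
    repair_rate_constant: float = 0.0
    repair_rate_linear: float = 0.0
    dt: float = 0.1
    damage_model: str = "AUC"
    precompute: bool = True

    def __post_init__(self) -> None:
        for name in ("metabolism_rate", "repair_rate_constant", "repair_rate_linear"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0.0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not (self.dt > 0.0):
            raise ValueError(f"pd dt must be > 0, got {self.dt}")
        if self.damage_model not in DAMAGE_MODELS:
            raise ValueError(
                f"damage_model must be one of {DAMAGE_MODELS}, got {self.damage_model!r}"
            )


@dataclass
class PDState:
    """Internalized substrate ``A`` and damage ``D`` (scalars or arrays)."""

    internalized: Union[float, np.ndarray] = 0.0
    damage: Union[float, np.ndarray] = 0.0


@dataclass(frozen=True)
class PDPrecomputed:
    """Cached affine-update coefficients for a fixed (params, dt).

    The update is  A' = a_factor * A;  D' = max(0, d_factor*D + a_to_d*A + repair_term).
    """

    a_factor: float
    d_factor: float
    a_to_d: float
    repair_term: float
    dt: float
    params: PDParams


def _transfer_coefficient(m: float, r1: float, dt: float) -> float:
    """Integral of exp(-r1*(dt-s)) * exp(-m*s) over s in [0, dt].

    Written as exp(-m*dt) * (1 - exp(-(r1-m)*dt)) / (r1 - m) via expm1 so the
    repeated-rate limit r1 -> m is approached smoothly; at the limit the value
    is dt * exp(-m*dt).
    """
    d = r1 - m
    scale = max(abs(r1), abs(m))
    if abs(d) <= _REPEATED_RATE_REL_TOL * scale or d == 0.0:
        return dt * math.exp(-m * dt)
    return math.exp(-m * dt) * (-math.expm1(-d * dt)) / d


def build_precomputed(params: PDParams, dt: Optional[float] = None) -> PDPrecomputed:
    """Derive the affine-update coefficients for ``params`` over step ``dt``."""
    dt = params.dt if dt is None else dt
    if not (dt > 0.0):
        raise ValueError(f"pd dt must be > 0, got {dt}")
    m, r0, r1 = params.metabolism_rate, params.repair_rate_constant, params.repair_rate_linear
    a_factor = math.exp(-m * dt)
    d_factor = math.exp(-r1 * dt)
    a_to_d = _transfer_coefficient(m, r1, dt)
    if r1 > 0.0:
        repair_term = (r0 / r1) * math.expm1(-r1 * dt)
    else:
        repair_term = -r0 * dt
    return PDPrecomputed(a_factor, d_factor, a_to_d, repair_term, dt, params)


def pd_step(
    state: PDState, params: Union[PDParams, PDPrecomputed], dt: Optional[float] = None
) -> PDState:
    """Advance (A, D) by one PD step using the exact affine update.

    Accepts either raw :class:`PDParams` (coefficients derived on the fly —
    the non-precomputed path used when parameters vary per cell) or a
    :class:`PDPrecomputed`; both produce bit-identical results for the same
    step size.  ``state`` fields may be numpy arrays for whole-population
    updates.
    """
    if isinstance(params, PDPrecomputed):
        if dt is not None and dt != params.dt:
            raise ValueError(
                f"precomputed coefficients are for dt={params.dt}, got dt={dt}"
            )
        pre = params
    else:
        pre = build_precomputed(params, dt)
    a = np.asarray(state.internalized, dtype=float)
    d = np.asarray(state.damage, dtype=float)
    new_d = np.maximum(pre.d_factor * d + pre.a_to_d * a + pre.repair_term, 0.0)
    new_a = pre.a_factor * a
    if np.ndim(state.internalized) == 0:
        return PDState(float(new_a), float(new_d))
    return PDState(new_a, new_d)


def hill_factor(damage, ec50: float, hill_power: float, f_sat: float):
    """Hill-type effect factor between 1 (no damage) and ``f_sat``.

    Monotone in ``damage``; equals ``(1 + f_sat) / 2`` at ``damage == ec50``.
    Accepts scalar or array damage.
    """
    if not (ec50 > 0.0):
        raise ValueError(f"EC50 must be > 0, got {ec50}")
    if not (hill_power > 0.0):
        raise ValueError(f"hill power must be > 0, got {hill_power}")
    x = np.power(np.asarray(damage, dtype=float) / ec50, hill_power)
    f = 1.0 + (f_sat - 1.0) * x / (1.0 + x)
    return float(f) if np.ndim(damage) == 0 else f


def hill_response(damage, ec50: float, hill_power: float):
    """Saturating response (D/EC50)^n / (1 + (D/EC50)^n) in [0, 1)."""
    if not (ec50 > 0.0):
        raise ValueError(f"EC50 must be > 0, got {ec50}")
    x = np.power(np.asarray(damage, dtype=float) / ec50, hill_power)
    r = x / (1.0 + x)
    return float(r) if np.ndim(damage) == 0 else r


@dataclass(frozen=True)
class HillParams:
    """Saturation rate, EC50 and Hill power for one MOA of one substrate."""

    saturation_rate: float
    ec50: float
    hill_power: float = 1.0

    def __post_init__(self) -> None:
        if not (self.ec50 > 0.0):
            raise ValueError(f"EC50 must be > 0, got {self.ec50}")
        if not (self.hill_power > 0.0):
            raise ValueError(f"hill power must be > 0, got {self.hill_power}")
        if not (self.saturation_rate >= 0.0):
            raise ValueError(
                f"saturation rate must be >= 0, got {self.saturation_rate}"
            )


@dataclass(frozen=True)
class MOAConfig:
    """Active mechanisms of action of one substrate on one cell type.

    ``moas`` maps an MOA name from :data:`MOA_NAMES` to its Hill parameters;
    absent names are inactive.
    """

    moas: Dict[str, HillParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.moas:
            if name not in MOA_NAMES:
                raise ValueError(f"unknown MOA {name!r}; expected one of {MOA_NAMES}")

    @property
    def active(self) -> Tuple[str, ...]:
        return tuple(n for n in MOA_NAMES if n in self.moas)


def apply_moas(
    base_rates: Dict[str, float],
    effects: Sequence[Tuple[MOAConfig, float]],
) -> Dict[str, float]:
    """Combine damage-driven effects from several substrates onto one cell.

    ``base_rates`` holds the cell type's base values for "prolif", "apop",
    "necrosis" (1/min) and "motility" (speed, um/min).  ``effects`` pairs each
    substrate's MOA configuration with its current damage on this cell.

    Rates are first reset to base (effects never stack across steps), then
    multiplicative MOAs (prolif/apop/motility) scale the base by the product
    of per-substrate Hill factors with ``f_sat = saturation_rate / base``;
    necrosis adds per-substrate saturating increments to the base instead,
    which stays well-defined at the customary base necrosis rate of 0.
    Idempotent and order-independent by construction.
    """
    current = dict(base_rates)
    for moa in MOA_NAMES:
        base = base_rates.get(moa, 0.0)
        if moa == "necrosis":
            extra = 0.0
            for cfg, damage in effects:
                hp = cfg.moas.get(moa)
                if hp is not None:
                    extra += hp.saturation_rate * hill_response(
                        damage, hp.ec50, hp.hill_power
                    )
            current[moa] = base + extra
        else:
            factor = 1.0
            for cfg, damage in effects:
                hp = cfg.moas.get(moa)
                if hp is None:
                    continue
                if base <= 0.0:
                    raise ValueError(
                        f"multiplicative MOA {moa!r} requires a positive base rate "
                        "(f_sat = saturation_rate / base is undefined at 0); "
                        "use the additive necrosis pattern for zero-base rates"
                    )
                factor *= hill_factor(
                    damage, hp.ec50, hp.hill_power, hp.saturation_rate / base
                )
            current[moa] = base * factor
    return current
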