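"""Minimal off-lattice 2D cell population.

Cells are circles with a type-defined radius carrying base phenotype rates
(cycle entry, apoptosis, necrosis — all 1/min — and a migration speed in
um/min), per-substrate uptake rates, and per-substrate PD state (internalized
substrate ``A`` and damage ``D``).  Each phenotype step a cell divides or
dies stochastically: exponential waiting times are sampled for the three
competing processes and the earliest one inside the step wins, which is
unbiased for small rate*dt.  Mechanics is a persistent random walk plus a
pairwise linear repulsion that relaxes overlapping neighbours apart.

Population state is stored as flat numpy arrays (struct-of-arrays) for
vectorized stepping; :class:`CellAgent` is a light per-cell view used by the
functional API and snapshots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .pd import MOAConfig, PDParams, hill_factor, hill_response

__all__ = [
    "CellType",
    "CellAgent",
    "Population",
    "phenotype_step",
    "mechanics_step",
    "confluence",
    "damage_coloring",
]

RATE_NAMES = ("prolif", "apop", "necrosis", "motility")

# fraction of pair overlap removed per mechanics step (each cell moves half)
REPULSION_RELAXATION = 0.5


@dataclass(frozen=True)
class CellType:
    """A named cell type with base phenotype rates and per-substrate PKPD.

    ``motility`` is a migration speed (um/min); the other rates are
    probabilities per minute.  ``uptake_rates`` maps substrate name to the
    cellular uptake rate rho (1/min); ``pd_params`` and ``moa_configs`` map
    substrate name to the damage dynamics and mechanisms of action of that
    substrate on this type.
    """

    name: str
    radius: float = 8.4
    prolif: float = 0.0
    apop: float = 0.0
    necrosis: float = 0.0
    motility: float = 0.0
    persistence_time: float = 15.0  # min, direction redraw timescale
    uptake_rates: Dict[str, float] = dc_field(default_factory=dict)
    pd_params: Dict[str, PDParams] = dc_field(default_factory=dict)
    moa_configs: Dict[str, MOAConfig] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in RATE_NAMES:
            if getattr(self, name) < 0.0:
                raise ValueError(f"base {name} rate must be >= 0")
        if not (self.radius > 0.0):
            raise ValueError("cell radius must be > 0")

    @property
    def volume(self) -> float:
        """Spherical cell volume (um^3) used for uptake bookkeeping."""
        return 4.0 / 3.0 * math.pi * self.radius**3

    @property
    def base_rates(self) -> Dict[str, float]:
        return {n: getattr(self, n) for n in RATE_NAMES}


@dataclass
class CellAgent:
    """Read-mostly view of one cell (snapshot/API convenience)."""

    id: int
    type: CellType
    position: np.ndarray
    internalized: Dict[str, float]
    damage: Dict[str, float]
    current_rates: Dict[str, float]


class Population:
    """All live cells of a simulation, stored as flat arrays."""

    def __init__(
        self,
        cell_types: Sequence[CellType],
        substrates: Sequence[str] = (),
        domain: Tuple[float, float, float, float] = (-400.0, 400.0, -400.0, 400.0),
    ):
        self.cell_types = list(cell_types)
        self.type_by_name = {ct.name: i for i, ct in enumerate(self.cell_types)}
        self.substrates = list(substrates)
        self.domain = tuple(map(float, domain))
        n0 = 0
        self.ids = np.zeros(n0, dtype=np.int64)
        self.type_index = np.zeros(n0, dtype=np.int64)
        self.positions = np.zeros((n0, 2))
        self.direction = np.zeros(n0)  # heading angle, radians
        self.A = {s: np.zeros(n0) for s in self.substrates}
        self.D = {s: np.zeros(n0) for s in self.substrates}
        self.rates = {n: np.zeros(n0) for n in RATE_NAMES}
        self._next_id = 0
        self.births = 0
        self.deaths_apop = 0
        self.deaths_necrosis = 0

    # ------------------------------------------------------------ population

    def __len__(self) -> int:
        return len(self.ids)

    def add_cells(
        self, positions: np.ndarray, type_name: str, rng: Optional[np.random.Generator] = None
    ) -> None:
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        n = len(positions)
        if n == 0:
            return
        ti = self.type_by_name[type_name]
        ct = self.cell_types[ti]
        new_ids = np.arange(self._next_id, self._next_id + n, dtype=np.int64)
        self._next_id += n
        self.ids = np.concatenate([self.ids, new_ids])
        self.type_index = np.concatenate([self.type_index, np.full(n, ti, dtype=np.int64)])
        self.positions = np.concatenate([self.positions, positions])
        if rng is not None:
            angles = rng.uniform(0.0, 2.0 * math.pi, n)
        else:
            angles = np.zeros(n)
        self.direction = np.concatenate([self.direction, angles])
        for s in self.substrates:
            self.A[s] = np.concatenate([self.A[s], np.zeros(n)])
            self.D[s] = np.concatenate([self.D[s], np.zeros(n)])
        for name in RATE_NAMES:
            self.rates[name] = np.concatenate(
                [self.rates[name], np.full(n, getattr(ct, name))]
            )

    def _keep(self, mask: np.ndarray) -> None:
        self.ids = self.ids[mask]
        self.type_index = self.type_index[mask]
        self.positions = self.positions[mask]
        self.direction = self.direction[mask]
        for s in self.substrates:
            self.A[s] = self.A[s][mask]
            self.D[s] = self.D[s][mask]
        for name in RATE_NAMES:
            self.rates[name] = self.rates[name][mask]

    # type-derived per-cell arrays -----------------------------------------

    def _type_values(self, getter) -> np.ndarray:
        table = np.array([getter(ct) for ct in self.cell_types])
        return table[self.type_index]

    @property
    def radii(self) -> np.ndarray:
        return self._type_values(lambda ct: ct.radius)

    @property
    def volumes(self) -> np.ndarray:
        return self._type_values(lambda ct: ct.volume)

    def uptake_rates(self, substrate: str) -> np.ndarray:
        return self._type_values(lambda ct: ct.uptake_rates.get(substrate, 0.0))

    def base_rate(self, name: str) -> np.ndarray:
        return self._type_values(lambda ct: getattr(ct, name))

    # ------------------------------------------------------------------- PD

    def update_current_rates(self) -> None:
        """Recompute phenotype rates from base rates and current damage.

        Rates are reset to base first, so effects never stack between calls
        (the update is idempotent): multiplicative mechanisms scale the base
        by the product of per-substrate Hill factors, necrosis adds
        per-substrate saturating increments.
        """
        n = len(self)
        for name in RATE_NAMES:
            self.rates[name] = self.base_rate(name).copy()
        if n == 0:
            return
        for ti, ct in enumerate(self.cell_types):
            mask = self.type_index == ti
            if not mask.any():
                continue
            for s, moa in ct.moa_configs.items():
                if s not in self.D:
                    continue
                damage = self.D[s][mask]
                for name, hp in moa.moas.items():
                    if name == "necrosis":
                        self.rates[name][mask] += hp.saturation_rate * hill_response(
                            damage, hp.ec50, hp.hill_power
                        )
                    else:
                        base = getattr(ct, name)
                        if base <= 0.0:
                            raise ValueError(
                                f"cell type {ct.name!r}: multiplicative MOA {name!r} "
                                "needs a positive base rate"
                            )
                        self.rates[name][mask] *= hill_factor(
                            damage, hp.ec50, hp.hill_power, hp.saturation_rate / base
                        )

    # ------------------------------------------------------------ phenotype

    def phenotype_step(self, dt: float, rng: np.random.Generator) -> Tuple[int, int, int]:
        """Sample division/apoptosis/necrosis; returns (births, apop, necr).

        Competing risks are resolved by exponential waiting times: the
        earliest event within ``dt`` happens.  Daughters are placed one
        radius apart at a uniform random angle (each offset half a radius
        from the parent position); dead cells are removed immediately.
        """
        n = len(self)
        if n == 0:
            return (0, 0, 0)
        lam = np.column_stack(
            [self.rates["prolif"], self.rates["apop"], self.rates["necrosis"]]
        )
        u = rng.random((n, 3))
        with np.errstate(divide="ignore"):
            tau = np.where(lam > 0.0, -np.log(u) / np.where(lam > 0.0, lam, 1.0), np.inf)
        winner = np.argmin(tau, axis=1)
        happened = np.min(tau, axis=1) <= dt
        angles = rng.uniform(0.0, 2.0 * math.pi, n)  # drawn for all cells

        divide = happened & (winner == 0)
        die_apop = happened & (winner == 1)
        die_necr = happened & (winner == 2)

        if divide.any():
            idx = np.where(divide)[0]
            radii = self.radii[idx]
            offset = 0.5 * radii[:, None] * np.column_stack(
                [np.cos(angles[idx]), np.sin(angles[idx])]
            )
            parent_pos = self.positions[idx].copy()
            daughter_pos = self._clip(parent_pos + offset)
            self.positions[idx] = self._clip(parent_pos - offset)
            for ti_pos, i in enumerate(idx):
                ct = self.cell_types[self.type_index[i]]
                self.ids = np.append(self.ids, self._next_id)
                self._next_id += 1
                self.type_index = np.append(self.type_index, self.type_index[i])
                self.positions = np.concatenate(
                    [self.positions, daughter_pos[ti_pos][None, :]]
                )
                self.direction = np.append(self.direction, self.direction[i])
                for s in self.substrates:
                    params = ct.pd_params.get(s)
                    if params is not None and params.damage_model == "AUC_amount":
                        # amounts are extensive: split between the daughters
                        self.A[s][i] *= 0.5
                        self.D[s][i] *= 0.5
                        self.A[s] = np.append(self.A[s], self.A[s][i])
                        self.D[s] = np.append(self.D[s], self.D[s][i])
                    else:
                        # concentrations/damage are intensive: inherited
                        self.A[s] = np.append(self.A[s], self.A[s][i])
                        self.D[s] = np.append(self.D[s], self.D[s][i])
                for name in RATE_NAMES:
                    self.rates[name] = np.append(self.rates[name], self.rates[name][i])

        n_div = int(divide.sum())
        n_apop = int(die_apop.sum())
        n_necr = int(die_necr.sum())
        if n_apop or n_necr:
            keep = np.ones(len(self), dtype=bool)
            keep[: len(die_apop)] &= ~(die_apop | die_necr)
            self._keep(keep)
        self.births += n_div
        self.deaths_apop += n_apop
        self.deaths_necrosis += n_necr
        return (n_div, n_apop, n_necr)

    # ------------------------------------------------------------ mechanics

    def _clip(self, pos: np.ndarray) -> np.ndarray:
        x0, x1, y0, y1 = self.domain
        return np.column_stack(
            [np.clip(pos[:, 0], x0, x1), np.clip(pos[:, 1], y0, y1)]
        )

    def mechanics_step(self, dt: float, rng: np.random.Generator) -> None:
        """Persistent random walk plus pairwise overlap relaxation."""
        n = len(self)
        if n == 0:
            return
        persistence = self._type_values(lambda ct: ct.persistence_time)
        u = rng.random(n)
        fresh = rng.uniform(0.0, 2.0 * math.pi, n)
        redraw = u < dt / np.maximum(persistence, 1e-12)
        self.direction = np.where(redraw, fresh, self.direction)
        speed = self.rates["motility"]
        if (speed > 0.0).any():
            step = speed[:, None] * dt * np.column_stack(
                [np.cos(self.direction), np.sin(self.direction)]
            )
            self.positions = self._clip(self.positions + step)
        self._relax_overlaps()

    def _relax_overlaps(self) -> None:
        n = len(self)
        if n < 2:
            return
        radii = self.radii
        cutoff = 2.0 * radii.max()
        pairs = cKDTree(self.positions).query_pairs(cutoff, output_type="ndarray")
        if len(pairs) == 0:
            return
        i, j = pairs[:, 0], pairs[:, 1]
        delta = self.positions[j] - self.positions[i]
        dist = np.hypot(delta[:, 0], delta[:, 1])
        target = radii[i] + radii[j]
        overlap = target - dist
        touching = overlap > 0.0
        if not touching.any():
            return
        i, j = i[touching], j[touching]
        delta = delta[touching]
        dist = dist[touching]
        overlap = overlap[touching]
        # coincident centers: push along x deterministically
        zero = dist < 1e-12
        axis = np.where(
            zero[:, None], np.array([1.0, 0.0]), delta / np.maximum(dist, 1e-12)[:, None]
        )
        shift = (0.5 * REPULSION_RELAXATION * overlap)[:, None] * axis
        disp = np.zeros_like(self.positions)
        np.add.at(disp, j, shift)
        np.add.at(disp, i, -shift)
        self.positions = self._clip(self.positions + disp)

    # ----------------------------------------------------------- observables

    def confluence(self) -> float:
        """Fraction of the domain area covered by cell cross-sections (<= 1)."""
        x0, x1, y0, y1 = self.domain
        area = (x1 - x0) * (y1 - y0)
        covered = float(np.pi * (self.radii**2).sum())
        return min(covered / area, 1.0)

    def agent(self, index: int) -> CellAgent:
        ct = self.cell_types[self.type_index[index]]
        return CellAgent(
            id=int(self.ids[index]),
            type=ct,
            position=self.positions[index].copy(),
            internalized={s: float(self.A[s][index]) for s in self.substrates},
            damage={s: float(self.D[s][index]) for s in self.substrates},
            current_rates={n: float(self.rates[n][index]) for n in RATE_NAMES},
        )


# -------------------------------------------------------- functional wrappers


def phenotype_step(
    population: Population, dt: float, rng: np.random.Generator
) -> Population:
    population.phenotype_step(dt, rng)
    return population


def mechanics_step(
    population: Population, dt: float, rng: np.random.Generator
) -> Population:
    population.mechanics_step(dt, rng)
    return population


def confluence(population: Population) -> float:
    return population.confluence()


# colors for the two-drug damage display (RGB in [0, 1])
_BASE_COLOR = np.array([0.80, 0.80, 0.80])
_CH1_COLOR = np.array([0.85, 0.10, 0.10])
_CH2_COLOR = np.array([0.10, 0.10, 0.85])
_BOTH_COLOR = np.array([0.25, 0.00, 0.25])


def damage_coloring(
    damages: Sequence[float], ec50s: Sequence[float]
) -> Tuple[float, float, float]:
    """Deterministic RGB for up to two drugs' damage, EC50-normalized.

    Each channel saturates as ``D / (D + EC50)``; the color interpolates
    bilinearly between the base color (no damage), a per-drug color at full
    single-drug saturation, and a dedicated corner color when both saturate.
    Monotone along each channel by construction.
    """
    if len(damages) != len(ec50s):
        raise ValueError("damages and ec50s must have equal length")
    if len(damages) > 2:
        raise ValueError("damage coloring supports at most two substrates")
    sats = [0.0, 0.0]
    for k, (d, e) in enumerate(zip(damages, ec50s)):
        if not (e > 0.0):
            raise ValueError(f"EC50 must be > 0, got {e}")
        sats[k] = d / (d + e) if d > 0.0 else 0.0
    s1, s2 = sats
    rgb = (
        (1.0 - s1) * (1.0 - s2) * _BASE_COLOR
        + s1 * (1.0 - s2) * _CH1_COLOR
        + (1.0 - s1) * s2 * _CH2_COLOR
        + s1 * s2 * _BOTH_COLOR
    )
    return (float(rgb[0]), float(rgb[1]), float(rgb[2]))
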