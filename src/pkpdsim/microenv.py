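"""2D voxelized substrate fields: diffusion, decay, Dirichlet coupling, uptake.

Each substrate lives on a regular grid of square voxels and obeys

    du/dt = D * laplacian(u) - decay * u

advanced by first-order operator splitting: an implicit decay factor, then
implicit tridiagonal solves along x, then along y (unconditionally stable for
any step).  Voxels flagged Dirichlet are held at ``biot * circulation`` — the
perivascular concentration imposed by the systemic PK — by replacing their
rows with identity rows, so they are exact through the solves.  Non-Dirichlet
domain edges are zero-flux.

Cellular uptake treats each cell as a point sink in its voxel, relaxing the
voxel concentration implicitly; the mass removed from the voxel is credited
to the cell's internalized pool, so field + internalized mass is conserved
exactly for uptake-only steps.  Secretion is a net source toward a target
concentration (no internal pool is drained), mirroring common
microenvironment-solver semantics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import solve_banded

__all__ = ["Grid", "ExchangeRecord"]

EDGE_NAMES = ("bottom", "top", "left", "right")


@dataclass
class ExchangeRecord:
    """Mass moved between one cell and its voxel during one exchange step."""

    cell_index: int
    substrate: str
    amount: float  # a.u. * um^3 removed from (positive) or added to (negative) the field


@dataclass
class _Substrate:
    conc: np.ndarray  # (ny, nx)
    diffusion: float  # um^2/min
    decay: float  # 1/min
    dirichlet_mask: np.ndarray  # (ny, nx) bool
    dirichlet_value: float = 0.0
    warned_no_mask: bool = False


class Grid:
    """Rectangular 2D microenvironment with per-substrate fields.

    Parameters
    ----------
    x_range, y_range
        Domain extents in um, e.g. ``(-400, 400)``.
    voxel_size
        Square voxel edge length in um; must divide both extents.
    thickness
        Fictitious z-depth (um) used to convert concentrations to masses;
        defaults to the voxel size.
    """

    def __init__(
        self,
        x_range: Tuple[float, float] = (-400.0, 400.0),
        y_range: Tuple[float, float] = (-400.0, 400.0),
        voxel_size: float = 20.0,
        thickness: Optional[float] = None,
    ):
        if not (voxel_size > 0.0):
            raise ValueError(f"voxel size must be > 0, got {voxel_size}")
        self.x_min, self.x_max = map(float, x_range)
        self.y_min, self.y_max = map(float, y_range)
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("domain extents must be increasing")
        self.h = float(voxel_size)
        self.thickness = float(thickness) if thickness is not None else self.h
        self.nx = int(round((self.x_max - self.x_min) / self.h))
        self.ny = int(round((self.y_max - self.y_min) / self.h))
        if abs(self.nx * self.h - (self.x_max - self.x_min)) > 1e-9 * self.h:
            raise ValueError("voxel size must evenly divide the x extent")
        if abs(self.ny * self.h - (self.y_max - self.y_min)) > 1e-9 * self.h:
            raise ValueError("voxel size must evenly divide the y extent")
        self.x_centers = self.x_min + self.h * (np.arange(self.nx) + 0.5)
        self.y_centers = self.y_min + self.h * (np.arange(self.ny) + 0.5)
        self.voxel_volume = self.h * self.h * self.thickness
        self.substrates: Dict[str, _Substrate] = {}
        self._solver_cache: Dict[Tuple[str, float, int], tuple] = {}
        self._mask_version: Dict[str, int] = {}

    # ------------------------------------------------------------------ setup

    def add_substrate(
        self,
        name: str,
        diffusion: float,
        decay: float,
        initial: float = 0.0,
        dirichlet_edges: Sequence[str] = (),
    ) -> None:
        mask = np.zeros((self.ny, self.nx), dtype=bool)
        for edge in dirichlet_edges:
            if edge not in EDGE_NAMES:
                raise ValueError(f"unknown edge {edge!r}; expected one of {EDGE_NAMES}")
            if edge == "bottom":
                mask[0, :] = True
            elif edge == "top":
                mask[-1, :] = True
            elif edge == "left":
                mask[:, 0] = True
            else:
                mask[:, -1] = True
        self.substrates[name] = _Substrate(
            conc=np.full((self.ny, self.nx), float(initial)),
            diffusion=float(diffusion),
            decay=float(decay),
            dirichlet_mask=mask,
        )
        self._mask_version[name] = 0

    def set_dirichlet_mask(self, name: str, mask: np.ndarray) -> None:
        sub = self.substrates[name]
        sub.dirichlet_mask = np.asarray(mask, dtype=bool).reshape(self.ny, self.nx)
        self._mask_version[name] += 1
        self._solver_cache = {
            k: v for k, v in self._solver_cache.items() if k[0] != name
        }

    # ------------------------------------------------------------- operations

    def update_dirichlet(self, name: str, circulation: float, biot: float = 1.0) -> None:
        """Pin Dirichlet voxels of ``name`` to ``biot * circulation``."""
        sub = self.substrates[name]
        if not sub.dirichlet_mask.any():
            if not sub.warned_no_mask:
                warnings.warn(
                    f"substrate {name!r} has no Dirichlet voxels; update ignored",
                    stacklevel=2,
                )
                sub.warned_no_mask = True
            return
        sub.dirichlet_value = biot * circulation
        sub.conc[sub.dirichlet_mask] = sub.dirichlet_value

    def _sweep_groups(self, name: str, dt: float, axis: int):
        """Banded matrices for the implicit 1D solves, grouped by mask pattern.

        Rows (axis=1 sweeps along x) or columns (axis=0, along y) sharing the
        same Dirichlet pattern share one tridiagonal matrix; Dirichlet voxels
        get identity rows.
        """
        key = (name, dt, axis)
        cached = self._solver_cache.get(key)
        sub = self.substrates[name]
        if cached is not None and cached[0] == self._mask_version[name]:
            return cached[1]
        alpha = sub.diffusion * dt / (self.h * self.h)
        mask = sub.dirichlet_mask if axis == 1 else sub.dirichlet_mask.T
        n_lines, n = mask.shape
        groups = {}
        for j in range(n_lines):
            groups.setdefault(mask[j].tobytes(), []).append(j)
        built = []
        for pattern_bytes, lines in groups.items():
            pattern = np.frombuffer(pattern_bytes, dtype=bool)
            ab = np.zeros((3, n))
            ab[1, :] = 1.0 + 2.0 * alpha
            if n == 1:
                ab[1, 0] = 1.0  # single voxel: nothing to diffuse with
            else:
                ab[1, 0] = ab[1, -1] = 1.0 + alpha  # zero-flux edges
            ab[0, 1:] = -alpha  # upper diagonal: (i, i+1)
            ab[2, :-1] = -alpha  # lower diagonal: (i, i-1)
            idx = np.where(pattern)[0]
            ab[1, idx] = 1.0
            ab[0, idx[idx < n - 1] + 1] = 0.0
            ab[2, idx[idx > 0] - 1] = 0.0
            built.append((np.array(lines), ab))
        self._solver_cache[key] = (self._mask_version[name], built)
        return built

    def diffuse_decay_step(self, dt: float) -> None:
        """Advance all substrate fields by ``dt`` minutes."""
        if not (dt > 0.0):
            raise ValueError(f"dt must be > 0, got {dt}")
        for name, sub in self.substrates.items():
            u = sub.conc
            if sub.decay > 0.0:
                u /= 1.0 + sub.decay * dt
            if sub.dirichlet_mask.any():
                u[sub.dirichlet_mask] = sub.dirichlet_value
            if sub.diffusion > 0.0:
                # x sweep: independent tridiagonal solve per grid row
                for lines, ab in self._sweep_groups(name, dt, axis=1):
                    u[lines, :] = solve_banded(
                        (1, 1), ab, u[lines, :].T, check_finite=False
                    ).T
                # y sweep: per grid column
                for lines, ab in self._sweep_groups(name, dt, axis=0):
                    u[:, lines] = solve_banded(
                        (1, 1), ab, u[:, lines], check_finite=False
                    )
            if sub.dirichlet_mask.any():
                u[sub.dirichlet_mask] = sub.dirichlet_value
            np.maximum(u, 0.0, out=u)

    def voxel_indices(self, positions: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """(row, col) of the voxel containing each (x, y) position."""
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        if (
            (pos[:, 0] < self.x_min).any()
            or (pos[:, 0] > self.x_max).any()
            or (pos[:, 1] < self.y_min).any()
            or (pos[:, 1] > self.y_max).any()
        ):
            raise ValueError("cell position outside the domain")
        ix = np.floor((pos[:, 0] - self.x_min) / self.h).astype(int)
        iy = np.floor((pos[:, 1] - self.y_min) / self.h).astype(int)
        # positions exactly on the max edge belong to the last voxel
        np.clip(ix, 0, self.nx - 1, out=ix)
        np.clip(iy, 0, self.ny - 1, out=iy)
        return iy, ix

    def exchange_with_cells(
        self,
        name: str,
        positions: np.ndarray,
        uptake_rates: np.ndarray,
        cell_volumes: np.ndarray,
        dt: float,
        secretion_rates: Optional[np.ndarray] = None,
        secretion_targets: Optional[np.ndarray] = None,
        return_records: bool = False,
    ) -> Tuple[np.ndarray, List[ExchangeRecord]]:
        """Exchange substrate between the field and a set of cells.

        All sinks in a voxel act simultaneously: with per-cell relaxation
        weights ``a_i = dt * rho_i * V_cell_i / V_voxel`` (and secretion
        weights ``b_i`` analogously) the voxel concentration updates as

            u' = (u + sum_i b_i * target_i) / (1 + sum_i a_i + sum_i b_i)

        and each cell is credited ``a_i * u' * V_voxel`` of removed mass.
        Returns the per-cell net uptaken mass (a.u. * um^3) and, optionally,
        per-cell :class:`ExchangeRecord` entries.
        """
        if not (dt > 0.0):
            raise ValueError(f"dt must be > 0, got {dt}")
        sub = self.substrates[name]
        n = len(positions)
        if n == 0:
            return np.zeros(0), []
        iy, ix = self.voxel_indices(positions)
        flat = iy * self.nx + ix
        a = dt * np.asarray(uptake_rates, dtype=float) * (
            np.asarray(cell_volumes, dtype=float) / self.voxel_volume
        )
        if secretion_rates is not None:
            b = dt * np.asarray(secretion_rates, dtype=float) * (
                np.asarray(cell_volumes, dtype=float) / self.voxel_volume
            )
            bt = b * np.asarray(secretion_targets, dtype=float)
        else:
            b = np.zeros(n)
            bt = np.zeros(n)
        u = sub.conc.ravel()
        denom = np.ones(u.size)
        np.add.at(denom, flat, a + b)
        source = np.zeros(u.size)
        np.add.at(source, flat, bt)
        u_new = (u + source) / denom
        taken = a * u_new[flat] * self.voxel_volume  # mass into each cell
        secreted = (bt - b * u_new[flat]) * self.voxel_volume
        u[:] = u_new
        sub.conc[:] = u.reshape(self.ny, self.nx)
        if sub.dirichlet_mask.any():
            sub.conc[sub.dirichlet_mask] = sub.dirichlet_value
        records: List[ExchangeRecord] = []
        if return_records:
            net = taken - secreted
            records = [
                ExchangeRecord(cell_index=i, substrate=name, amount=float(net[i]))
                for i in range(n)
            ]
        return taken, records

    # -------------------------------------------------------------- summaries

    def total_mass(self, name: str) -> float:
        """Total substrate mass in the field (a.u. * um^3)."""
        return float(self.substrates[name].conc.sum() * self.voxel_volume)

    def field_dataframe(self, name: str):
        import pandas as pd

        sub = self.substrates[name]
        xx, yy = np.meshgrid(self.x_centers, self.y_centers)
        return pd.DataFrame(
            {
                "x_um": xx.ravel(),
                "y_um": yy.ravel(),
                "substrate": name,
                "concentration": sub.conc.ravel(),
            }
        )
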