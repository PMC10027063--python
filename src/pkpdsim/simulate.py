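"""The main simulation loop wiring PK -> boundary -> field -> PD -> phenotype.

Per diffusion step (the finest cadence) each PK substrate is processed in a
fixed order: due doses are applied as boluses, the systemic model is advanced
by the exact closed form (or the SBML integrator), the Dirichlet boundary is
re-pinned to Biot x circulation, the field diffuses and decays, and cells
exchange substrate with their voxels.  On the mechanics cadence the damage
ODEs are advanced per (substrate, cell type) pair — each pair may run on its
own PD step, a multiple of the mechanics step — phenotype rates are recomputed
from damage, and cell positions relax.  On the phenotype cadence cells divide
and die, confluence is monitored (it can trigger the first dose), and
snapshots are written.

All outputs are plain text CSV; identical seed and configuration give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .cells import Population, damage_coloring
from .config import SimulationConfig, load_config
from .dosing import DoseEvent, build_dose_times
from .microenv import Grid
from .pd import PDState, build_precomputed, pd_step
from .pk import CompartmentPK
from .sbml import load_sbml_pk

__all__ = ["RunLog", "Simulation", "run_simulation", "summarize"]

_FLOAT_FMT = "%.17g"


@dataclass
class RunLog:
    """What happened during a run: warnings, doses, per-snapshot summaries."""

    warnings: List[str] = field(default_factory=list)
    dose_events: List[Tuple[float, str, float, bool]] = field(default_factory=list)
    summaries: List[Dict] = field(default_factory=list)
    pk_records: List[Tuple[float, str, float, float]] = field(default_factory=list)
    trace: List[Tuple[int, str]] = field(default_factory=list)
    first_dose_times: Dict[str, float] = field(default_factory=dict)
    final_cell_count: int = 0
    births: int = 0
    deaths_apop: int = 0
    deaths_necrosis: int = 0
    output_dir: Optional[str] = None

    def doses_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dose_events, columns=["time_min", "substrate", "amount", "is_loading"]
        )

    def pk_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pk_records, columns=["time_min", "substrate", "circulation", "periphery"]
        )

    def summary_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.summaries)


class Simulation:
    """A fully configured simulation ready to run."""

    def __init__(self, config: SimulationConfig, trace: bool = False):
        self.config = config
        self.trace = trace
        self.rng = np.random.default_rng(config.seed)
        self.log = RunLog(warnings=list(config.warnings))

        x0, x1, y0, y1 = config.domain
        self.grid = Grid((x0, x1), (y0, y1), config.voxel_size)
        for name, sub in config.substrates.items():
            self.grid.add_substrate(
                name,
                diffusion=sub.diffusion,
                decay=sub.decay,
                initial=sub.initial,
                dirichlet_edges=sub.dirichlet_edges,
            )

        # systemic PK per substrate
        self.pk_models: Dict[str, object] = {}
        for name in config.pk_substrates:
            sub = config.substrates[name]
            if sub.pk_model == "SBML":
                self.pk_models[name] = load_sbml_pk(sub.sbml_file)
            else:
                self.pk_models[name] = CompartmentPK(sub.pk_params)

        # dose schedules: fixed-start schedules expand now, confluence-
        # triggered ones wait for the monitor
        self._pending_doses: Dict[str, List[DoseEvent]] = {}
        self._awaiting_confluence: Dict[str, float] = {}
        for name in config.pk_substrates:
            sub = config.substrates[name]
            if sub.schedule is None or sub.schedule.max_number_doses == 0:
                continue
            if sub.schedule.set_first_dose_time:
                events = build_dose_times(
                    sub.schedule, sub.schedule.first_dose_time, config.t_end
                )
                self._pending_doses[name] = events
                if events:
                    self.log.first_dose_times[name] = events[0].time
            else:
                self._awaiting_confluence[name] = sub.schedule.confluence_condition

        # cells
        self.population = Population(
            config.cell_types,
            substrates=list(config.pd_substrates),
            domain=config.domain,
        )
        for placement in config.placements:
            if placement.layout_file:
                layout = pd.read_csv(placement.layout_file)
                mask = layout["cell_type"] == placement.cell_type
                pos = layout.loc[mask, ["x_um", "y_um"]].to_numpy()
                if len(pos):
                    self.population.add_cells(pos, placement.cell_type, self.rng)
            elif placement.n_cells > 0:
                from .experiments import make_initial_tumor

                ct = config.cell_types[
                    self.population.type_by_name[placement.cell_type]
                ]
                pos = make_initial_tumor(
                    placement.n_cells,
                    placement.tumor_radius,
                    cell_radius=ct.radius,
                    rng=self.rng,
                )
                self.population.add_cells(pos, placement.cell_type, self.rng)

        # per-(substrate, cell type) PD stepping state
        self._pd_pairs: List[Dict] = []
        for s in config.pd_substrates:
            for ti, ct in enumerate(config.cell_types):
                params = ct.pd_params.get(s)
                if params is None:
                    continue
                use_pre = config.precompute_overrides.get(
                    (s, ct.name), config.precompute_all_pd
                )
                self._pd_pairs.append(
                    {
                        "substrate": s,
                        "type_index": ti,
                        "params": params,
                        "pre": build_precomputed(params) if use_pre else None,
                        "mech_period": int(round(params.dt / config.mechanics_dt)),
                        "mech_count": 0,
                    }
                )

    # ------------------------------------------------------------------ steps

    def _apply_due_doses(self, name: str, t_next: float, step: int) -> None:
        events = self._pending_doses.get(name)
        if not events:
            return
        model = self.pk_models[name]
        while events and events[0].time < t_next - 1e-9:
            ev = events.pop(0)
            model.dose(ev.amount)
            self.log.dose_events.append((ev.time, name, ev.amount, ev.is_loading))
            if self.trace:
                self.log.trace.append((step, f"dose:{name}"))

    def _check_confluence_trigger(self, t: float) -> None:
        if not self._awaiting_confluence:
            return
        conf = self.population.confluence()
        for name in list(self._awaiting_confluence):
            if conf >= self._awaiting_confluence[name]:
                sub = self.config.substrates[name]
                events = build_dose_times(sub.schedule, t, self.config.t_end)
                self._pending_doses[name] = events
                if events:
                    self.log.first_dose_times[name] = events[0].time
                del self._awaiting_confluence[name]

    def _mechanics_block(self, step: int) -> None:
        pop = self.population
        for pair in self._pd_pairs:
            pair["mech_count"] += 1
            if pair["mech_count"] < pair["mech_period"]:
                continue
            pair["mech_count"] = 0
            mask = pop.type_index == pair["type_index"]
            if not mask.any():
                continue
            s = pair["substrate"]
            updater = pair["pre"] if pair["pre"] is not None else pair["params"]
            new_state = pd_step(PDState(pop.A[s][mask], pop.D[s][mask]), updater)
            pop.A[s][mask] = new_state.internalized
            pop.D[s][mask] = new_state.damage
        pop.update_current_rates()
        pop.mechanics_step(self.config.mechanics_dt, self.rng)
        if self.trace:
            self.log.trace.append((step, "mechanics"))

    def _snapshot(self, t: float, out: Optional[Path], index: int) -> None:
        pop = self.population
        entry: Dict = {"time_min": t, "n_cells": len(pop)}
        for ti, ct in enumerate(self.config.cell_types):
            entry[f"n_{ct.name}"] = int((pop.type_index == ti).sum())
        for s in self.config.pd_substrates:
            d = pop.D[s]
            positive = d[d > 0.0]
            entry[f"mean_log10_damage_{s}"] = (
                float(np.log10(positive).mean()) if len(positive) else float("nan")
            )
            entry[f"sd_log10_damage_{s}"] = (
                float(np.log10(positive).std(ddof=0)) if len(positive) else float("nan")
            )
        for name, model in self.pk_models.items():
            if isinstance(model, CompartmentPK):
                c = model.circulation
                p = model.state.periphery if model.state.periphery is not None else float("nan")
            else:
                c, p = model.circulation, float("nan")
            entry[f"circulation_{name}"] = c
            self.log.pk_records.append((t, name, c, p))
        self.log.summaries.append(entry)
        if out is None:
            return
        snap_dir = out / "snapshots"
        snap_dir.mkdir(exist_ok=True)
        cells = {
            "id": pop.ids,
            "type": [self.config.cell_types[ti].name for ti in pop.type_index],
            "x_um": pop.positions[:, 0],
            "y_um": pop.positions[:, 1],
        }
        for s in self.config.pd_substrates:
            cells[f"A_{s}"] = pop.A[s]
            cells[f"D_{s}"] = pop.D[s]
        for rate in ("prolif", "apop", "necrosis", "motility"):
            cells[f"rate_{rate}"] = pop.rates[rate]
        display = self.config.pd_substrates[:2]
        if display:
            colors = np.zeros((len(pop), 3))
            for i in range(len(pop)):
                damages, ec50s = [], []
                for s in display:
                    ct = self.config.cell_types[pop.type_index[i]]
                    moa = ct.moa_configs.get(s)
                    hp = next(iter(moa.moas.values())) if moa and moa.moas else None
                    damages.append(pop.D[s][i])
                    ec50s.append(hp.ec50 if hp else 1.0)
                colors[i] = damage_coloring(damages, ec50s)
            cells["color_r"], cells["color_g"], cells["color_b"] = colors.T
        pd.DataFrame(cells).to_csv(
            snap_dir / f"cells_t{index:05d}.csv", index=False, float_format=_FLOAT_FMT
        )
        fields = [self.grid.field_dataframe(s) for s in self.config.substrates]
        if fields:
            pd.concat(fields, ignore_index=True).to_csv(
                snap_dir / f"field_t{index:05d}.csv", index=False, float_format=_FLOAT_FMT
            )

    # -------------------------------------------------------------------- run

    def run(self, output_dir: Optional[str] = None) -> RunLog:
        cfg = self.config
        out: Optional[Path] = None
        if output_dir is not None:
            out = Path(output_dir)
            out.mkdir(parents=True, exist_ok=True)
        dt = cfg.diffusion_dt
        n_steps = int(round(cfg.t_end / dt))
        mech_every = int(round(cfg.mechanics_dt / dt))
        phen_every = int(round(cfg.phenotype_dt / dt))
        snap_every = max(int(round(cfg.snapshot_interval / dt)), 1)

        snapshot_index = 0
        self._check_confluence_trigger(0.0)
        self._snapshot(0.0, out, snapshot_index)
        snapshot_index += 1

        for i in range(n_steps):
            t_next = (i + 1) * dt
            for name in cfg.pk_substrates:
                model = self.pk_models[name]
                if isinstance(model, CompartmentPK):
                    self._apply_due_doses(name, t_next, i)
                    model.step(dt)
                else:
                    model.advance_to(t_next)  # SBML: exact clock, no drift
                sub = cfg.substrates[name]
                self.grid.update_dirichlet(name, _circulation(model), sub.biot.value)
                if self.trace:
                    self.log.trace.append((i, f"dirichlet:{name}"))
            self.grid.diffuse_decay_step(dt)
            if self.trace:
                self.log.trace.append((i, "diffuse"))
            if len(self.population):
                for s in cfg.pd_substrates:
                    taken, _ = self.grid.exchange_with_cells(
                        s,
                        self.population.positions,
                        self.population.uptake_rates(s),
                        self.population.volumes,
                        dt,
                    )
                    conv = self._amount_conversion(s)
                    self.population.A[s] += taken * conv

            if (i + 1) % mech_every == 0:
                self._mechanics_block(i)
            if (i + 1) % phen_every == 0:
                self.population.phenotype_step(cfg.phenotype_dt, self.rng)
                self._check_confluence_trigger(t_next)
            if (i + 1) % snap_every == 0:
                self._snapshot(t_next, out, snapshot_index)
                snapshot_index += 1

        for name, threshold in self._awaiting_confluence.items():
            self.log.warnings.append(
                f"confluence threshold {threshold} for {name!r} never reached "
                "before t_end; no doses administered"
            )
        self.log.final_cell_count = len(self.population)
        self.log.births = self.population.births
        self.log.deaths_apop = self.population.deaths_apop
        self.log.deaths_necrosis = self.population.deaths_necrosis
        if out is not None:
            self.log.output_dir = str(out)
            self.log.doses_dataframe().to_csv(
                out / "doses.csv", index=False, float_format=_FLOAT_FMT
            )
            self.log.pk_dataframe().to_csv(
                out / "pk_trajectory.csv", index=False, float_format=_FLOAT_FMT
            )
            self.log.summary_dataframe().to_csv(
                out / "summary.csv", index=False, float_format=_FLOAT_FMT
            )
            with open(out / "run.log", "w") as fh:
                for w in self.log.warnings:
                    fh.write(f"WARNING: {w}\n")
                for t, s, amount, loading in self.log.dose_events:
                    kind = "loading dose" if loading else "dose"
                    fh.write(f"t={t:g} min: {kind} of {amount:g} a.u. {s}\n")
                fh.write(
                    f"final cells: {self.log.final_cell_count} "
                    f"(births {self.log.births}, apoptosis {self.log.deaths_apop}, "
                    f"necrosis {self.log.deaths_necrosis})\n"
                )
        return self.log

    def _amount_conversion(self, substrate: str) -> np.ndarray:
        """Per-cell factor converting uptaken mass to the internalized variable.

        Concentration-kind damage models divide by cell volume; amount-kind
        models keep the raw mass.
        """
        factors = np.empty(len(self.population.cell_types))
        for ti, ct in enumerate(self.population.cell_types):
            params = ct.pd_params.get(substrate)
            if params is not None and params.damage_model == "AUC_amount":
                factors[ti] = 1.0
            else:
                factors[ti] = 1.0 / ct.volume
        return factors[self.population.type_index]


def _circulation(model) -> float:
    return model.circulation


def run_simulation(
    config, output_dir: Optional[str] = None, trace: bool = False
) -> RunLog:
    """Load (if needed), build and run a simulation; returns its RunLog.

    With ``output_dir=None`` the run stays in memory (no files are written);
    pass a directory (e.g. ``config.output_dir``) to write the CSV outputs.
    """
    if not isinstance(config, SimulationConfig):
        config = load_config(config)
    sim = Simulation(config, trace=trace)
    return sim.run(output_dir=output_dir)


def summarize(output_dir: str) -> Dict[str, pd.DataFrame]:
    """Digest a run's output directory into tidy summary tables.

    Returns ``{"summary": per-snapshot cell counts and log10-damage stats,
    "profiles": x-averaged concentration over y per snapshot}``.  Damage
    statistics cover cells with positive damage only; snapshots where no cell
    has damage carry NaN.
    """
    out = Path(output_dir)
    summary = pd.read_csv(out / "summary.csv")
    profiles = []
    snap_dir = out / "snapshots"
    if snap_dir.is_dir():
        field_files = sorted(snap_dir.glob("field_t*.csv"))
        times = summary["time_min"].to_numpy()
        for idx, path in enumerate(field_files):
            df = pd.read_csv(path)
            prof = (
                df.groupby(["substrate", "y_um"], sort=True)["concentration"]
                .mean()
                .reset_index()
            )
            prof.insert(0, "time_min", times[idx] if idx < len(times) else float("nan"))
            profiles.append(prof)
    profiles_df = (
        pd.concat(profiles, ignore_index=True)
        if profiles
        else pd.DataFrame(columns=["time_min", "substrate", "y_um", "concentration"])
    )
    return {"summary": summary, "profiles": profiles_df}
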