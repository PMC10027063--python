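"""Packaged sample simulations and the IC50 dose-sweep experiment.

Each sample is a complete configuration built in code (no downloads): one per
mechanism of action, a two-drug combination, a confluence-triggered start,
an SBML-defined PK variant, and two bare templates.  The samples run at a
reduced scale — an 800 um square domain, ~300 initial cells, 48 simulated
hours — chosen so each completes in minutes on one CPU; the base phenotype
rates and PKPD parameters are plausible values for a slowly cycling tumor
line exposed to a systemically cleared small molecule, and no quantitative
claim is attached to them.

The dose sweep reruns an anti-proliferative sample with a single bolus at
t = 0 across log-spaced dose levels (plus a zero-dose control), several
seeds per dose, and reports final tumor size relative to the control mean —
the in-silico analogue of an IC50 viability curve.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import load_config
from .sbml import write_linear_pk_sbml
from .simulate import RunLog, run_simulation

__all__ = [
    "SAMPLE_NAMES",
    "sample_config",
    "run_sample",
    "make_initial_tumor",
    "make_toy_sbml",
    "DoseSweepResult",
    "run_ic50_sweep",
]

# --------------------------------------------------------------- tumor layout

# hard close packing of equal circles; layouts denser than a safety margin
# below this are rejected
_CLOSE_PACKING = math.pi / (2.0 * math.sqrt(3.0))
_DENSITY_MARGIN = 0.82
_MIN_SEPARATION = 1.9  # in units of the cell radius


def make_initial_tumor(
    n_cells: int,
    radius_um: float,
    cell_radius: float = 8.4,
    rng: Optional[np.random.Generator] = None,
    max_iter: int = 200,
) -> np.ndarray:
    """Non-overlapping positions roughly uniformly filling a disc.

    Cells are dart-thrown uniformly into the disc and then relaxed by
    iterative pairwise repulsion until no pair is closer than 1.9 cell radii
    (or the iteration budget runs out, which at the accepted densities it
    does not).  Raises if the requested density exceeds close packing.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if n_cells == 0:
        return np.zeros((0, 2))
    density = n_cells * cell_radius**2 / radius_um**2  # relative to disc area
    if density > _CLOSE_PACKING * _DENSITY_MARGIN:
        raise ValueError(
            f"requested density {density:.3f} exceeds the packable fraction "
            f"{_CLOSE_PACKING * _DENSITY_MARGIN:.3f} of a disc of radius {radius_um}"
        )
    rng = rng or np.random.default_rng()
    r = radius_um * np.sqrt(rng.random(n_cells))
    theta = rng.uniform(0.0, 2.0 * math.pi, n_cells)
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    target = _MIN_SEPARATION * cell_radius
    for _ in range(max_iter):
        pairs = cKDTree(pos).query_pairs(target, output_type="ndarray")
        if len(pairs) == 0:
            break
        i, j = pairs[:, 0], pairs[:, 1]
        delta = pos[j] - pos[i]
        dist = np.hypot(delta[:, 0], delta[:, 1])
        zero = dist < 1e-12
        axis = np.where(
            zero[:, None],
            np.array([1.0, 0.0]),
            delta / np.maximum(dist, 1e-12)[:, None],
        )
        overlap = target - dist
        shift = (0.55 * overlap)[:, None] * axis
        np.add.at(pos, j, shift)
        np.add.at(pos, i, -shift)
        # keep the layout inside the disc (with room for the cell body)
        rad = np.hypot(pos[:, 0], pos[:, 1])
        outside = rad > radius_um
        if outside.any():
            pos[outside] *= (radius_um / rad[outside])[:, None]
    return pos


def make_toy_sbml(
    path: str,
    kind: str = "1C",
    elimination_rate: float = 0.0025,
    k12: float = 0.005,
    k21: float = 0.002,
    volume_ratio: float = 1.5,
    initial_circulation: float = 0.0,
    doses: Sequence = (),
) -> str:
    """Write a minimal linear PK model as SBML; see :func:`write_linear_pk_sbml`.

    ``kind`` is "1C", "2C" or "with_events" (a 1C model plus bolus events).
    """
    if kind == "with_events":
        if not doses:
            doses = [(60.0, 10.0)]
        kind = "1C"
    return write_linear_pk_sbml(
        path,
        kind,
        elimination_rate=elimination_rate,
        k12=k12,
        k21=k21,
        volume_ratio=volume_ratio,
        initial_circulation=initial_circulation,
        doses=doses,
    )


# -------------------------------------------------------------------- samples


def _base_sample(t_end: float = 2880.0) -> Dict:
    """Shared scaffold: 800 um domain, reduced-scale steps, one tumor type."""
    return {
        "seed": 0,
        "output_dir": "output",
        "domain": {
            "x_min": -400.0,
            "x_max": 400.0,
            "y_min": -400.0,
            "y_max": 400.0,
            "voxel_size": 20.0,
        },
        "time": {
            "diffusion_dt": 0.1,
            "mechanics_dt": 0.5,
            "phenotype_dt": 6.0,
            "t_end": t_end,
            "snapshot_interval": 360.0,
        },
        "user_parameters": {
            "PKPD_pk_substrate_names": "drugA",
            "PKPD_pd_substrate_names": "drugA",
            "PKPD_precompute_all_pd_quantities": True,
        },
        "substrates": {},
        "cell_types": {},
    }


def _drug_block(
    name: str,
    pk_model: str = "2C",
    dose: float = 20.0,
    max_doses: int = 3,
    interval: float = 720.0,
) -> Dict:
    block = {
        "diffusion_coefficient": 60000.0,
        "decay_rate": 0.01,
        "dirichlet_edges": ["bottom"],
        f"{name}_pk_model": pk_model,
        f"{name}_biot_number": 1.0,
        f"{name}_central_elimination_rate": 0.0025,
        f"{name}_max_number_doses": max_doses,
        f"{name}_number_loading_doses": 0,
        f"{name}_dose_interval": interval,
        f"{name}_central_increase_on_dose": dose,
        f"{name}_set_first_dose_time": True,
        f"{name}_first_dose_time": 0.0,
    }
    if pk_model == "2C":
        block.update(
            {
                f"{name}_central_to_periphery_clearance_rate": 0.005,
                f"{name}_periphery_to_central_clearance_rate": 0.002,
                f"{name}_central_to_periphery_volume_ratio": 1.5,
            }
        )
    return block


def _tumor_block(drug: str = "drugA", moa: str = "prolif") -> Dict:
    custom = {
        f"{drug}_uptake_rate": 0.02,
        f"{drug}_on_tumor_pd_model": "AUC",
        f"{drug}_metabolism_rate": 0.02,
        f"{drug}_repair_rate_constant": 0.0001,
        f"{drug}_repair_rate_linear": 0.002,
        f"{drug}_dt_tumor": 0.5,
        f"{drug}_moa_is_{moa}": 1.0,
        f"{drug}_{moa}_hill_power": 2.0,
        f"{drug}_{moa}_EC50": 1000.0,
    }
    if moa == "prolif":
        custom[f"{drug}_prolif_saturation_rate"] = 0.0
    elif moa == "apop":
        custom[f"{drug}_apop_saturation_rate"] = 0.002
    elif moa == "necrosis":
        custom[f"{drug}_necrosis_saturation_rate"] = 0.002
    elif moa == "motility":
        custom[f"{drug}_motility_saturation_rate"] = 0.02
    return {
        "radius": 8.4,
        "prolif_rate": 0.00048,  # ~24 h doubling
        "apop_rate": 1.0e-05,
        "necrosis_rate": 0.0,
        "motility_speed": 0.1,
        "persistence_time": 15.0,
        "initial_count": 300,
        "initial_tumor_radius": 250.0,
        "custom_data": custom,
    }


def _moa_sample(moa: str) -> Dict:
    cfg = _base_sample()
    cfg["substrates"]["drugA"] = _drug_block("drugA")
    tumor = _tumor_block("drugA", moa)
    if moa == "motility":
        tumor["motility_speed"] = 0.5
    cfg["cell_types"]["tumor"] = tumor
    return cfg


def _combo_sample() -> Dict:
    cfg = _base_sample()
    cfg["user_parameters"]["PKPD_pk_substrate_names"] = "drugA,drugB"
    cfg["user_parameters"]["PKPD_pd_substrate_names"] = "drugA,drugB"
    cfg["substrates"]["drugA"] = _drug_block("drugA")
    cfg["substrates"]["drugB"] = _drug_block("drugB", pk_model="1C")
    tumor = _tumor_block("drugA", "prolif")
    tumor["custom_data"].update(
        {
            "drugB_uptake_rate": 0.02,
            "drugB_on_tumor_pd_model": "AUC",
            "drugB_metabolism_rate": 0.02,
            "drugB_repair_rate_constant": 0.0001,
            "drugB_repair_rate_linear": 0.002,
            "drugB_dt_tumor": 0.5,
            "drugB_moa_is_apop": 1.0,
            "drugB_apop_saturation_rate": 0.002,
            "drugB_apop_EC50": 1000.0,
            "drugB_apop_hill_power": 2.0,
        }
    )
    cfg["cell_types"]["tumor"] = tumor
    return cfg


def _confluence_sample() -> Dict:
    cfg = _moa_sample("prolif")
    drug = cfg["substrates"]["drugA"]
    drug["drugA_set_first_dose_time"] = False
    del drug["drugA_first_dose_time"]
    drug["drugA_confluence_condition"] = 0.15
    return cfg


def _sbml_sample() -> Dict:
    # placeholder path; run_sample / tests write the SBML file and point
    # drugA_sbml_file at it before loading
    cfg = _moa_sample("prolif")
    cfg["substrates"]["drugA"] = {
        "diffusion_coefficient": 60000.0,
        "decay_rate": 0.01,
        "dirichlet_edges": ["bottom"],
        "drugA_pk_model": "SBML",
        "drugA_biot_number": 1.0,
        "drugA_sbml_file": None,
    }
    return cfg


def _template(pk_model: str) -> Dict:
    cfg = _base_sample(t_end=360.0)
    cfg["substrates"]["drugA"] = _drug_block("drugA", pk_model=pk_model, max_doses=1)
    cfg["cell_types"]["tumor"] = _tumor_block("drugA", "prolif")
    cfg["cell_types"]["tumor"]["initial_count"] = 100
    return cfg


_BUILDERS = {
    "prolif_sample": lambda: _moa_sample("prolif"),
    "apop_sample": lambda: _moa_sample("apop"),
    "necrosis_sample": lambda: _moa_sample("necrosis"),
    "motility_sample": lambda: _moa_sample("motility"),
    "combo_sample": _combo_sample,
    "confluence_start_sample": _confluence_sample,
    "sbml_pk_sample": _sbml_sample,
    "template_1C": lambda: _template("1C"),
    "template_2C": lambda: _template("2C"),
}

SAMPLE_NAMES = tuple(_BUILDERS)


def sample_config(name: str) -> Dict:
    """The raw configuration dict of a packaged sample."""
    if name not in _BUILDERS:
        raise KeyError(f"unknown sample {name!r}; available: {SAMPLE_NAMES}")
    return _BUILDERS[name]()


def run_sample(
    name: str,
    seed: int = 0,
    t_end: Optional[float] = None,
    output_dir: Optional[str] = None,
    overrides: Optional[Dict] = None,
) -> RunLog:
    """Run a packaged sample end to end; returns its :class:`RunLog`."""
    cfg = sample_config(name)
    cfg["seed"] = seed
    if t_end is not None:
        cfg["time"]["t_end"] = t_end
    if overrides:
        cfg = _deep_update(cfg, overrides)
    if name == "sbml_pk_sample":
        base = Path(output_dir) if output_dir else Path(".")
        base.mkdir(parents=True, exist_ok=True)
        sbml_path = str(base / "drugA_pk.xml")
        native = _drug_block("drugA")
        write_linear_pk_sbml(
            sbml_path,
            "2C",
            elimination_rate=native["drugA_central_elimination_rate"],
            k12=native["drugA_central_to_periphery_clearance_rate"],
            k21=native["drugA_periphery_to_central_clearance_rate"],
            volume_ratio=native["drugA_central_to_periphery_volume_ratio"],
            doses=[
                (i * native["drugA_dose_interval"], native["drugA_central_increase_on_dose"])
                for i in range(native["drugA_max_number_doses"])
            ],
        )
        cfg["substrates"]["drugA"]["drugA_sbml_file"] = sbml_path
    return run_simulation(load_config(cfg), output_dir=output_dir)


def _deep_update(base: Dict, extra: Dict) -> Dict:
    out = copy.deepcopy(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


# ----------------------------------------------------------------- IC50 sweep


@dataclass
class DoseSweepResult:
    """Final tumor sizes across a single-bolus dose sweep."""

    doses: List[float]
    final_counts: Dict[float, List[int]]  # dose -> per-replicate final cell count
    control_mean: float

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for dose in self.doses:
            for rep, count in enumerate(self.final_counts[dose]):
                rows.append(
                    {
                        "dose": dose,
                        "replicate": rep,
                        "final_count": count,
                        "relative_size": count / self.control_mean,
                    }
                )
        return pd.DataFrame(rows)

    def relative_means(self) -> Dict[float, float]:
        return {
            dose: float(np.mean(c)) / self.control_mean
            for dose, c in self.final_counts.items()
        }


def run_ic50_sweep(
    base_config: Optional[Dict] = None,
    doses: Optional[Sequence[float]] = None,
    replicates: int = 5,
    seed: int = 0,
    t_end: float = 2880.0,
) -> DoseSweepResult:
    """Single-dose-at-t0 sweep over log-spaced dose levels plus a control.

    Each (dose, replicate) pair runs the anti-proliferative sample to
    ``t_end`` with exactly one bolus at t = 0 and its own seed; tumor size is
    the final cell count, reported relative to the zero-dose control mean.
    """
    if replicates <= 0:
        raise ValueError("replicates must be > 0")
    if base_config is None:
        base_config = sample_config("prolif_sample")
    if doses is None:
        doses = [0.0] + list(np.logspace(-1, 2, 7))
    doses = sorted(set(float(d) for d in doses))
    if 0.0 not in doses:
        doses = [0.0] + doses
    final_counts: Dict[float, List[int]] = {d: [] for d in doses}
    for di, dose in enumerate(doses):
        for rep in range(replicates):
            cfg = copy.deepcopy(base_config)
            cfg["time"]["t_end"] = t_end
            cfg["time"]["snapshot_interval"] = t_end  # endpoints only
            run_seed = (seed * 7919 + di * 101 + rep) % (2**31 - 1)
            cfg["seed"] = int(run_seed)
            drug = cfg["substrates"]["drugA"]
            drug["drugA_max_number_doses"] = 1 if dose > 0.0 else 0
            drug["drugA_central_increase_on_dose"] = float(dose)
            drug["drugA_dose_interval"] = 1.0
            drug["drugA_set_first_dose_time"] = True
            drug["drugA_first_dose_time"] = 0.0
            log = run_simulation(load_config(cfg), output_dir=None)
            final_counts[dose].append(log.final_cell_count)
    control_mean = float(np.mean(final_counts[0.0]))
    return DoseSweepResult(doses=list(doses), final_counts=final_counts, control_mean=control_mean)
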