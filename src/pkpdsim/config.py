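"""Configuration loading and validation.

The configuration is a hierarchical YAML file.  Structural sections
(``domain``, ``time``, ``substrates``, ``cell_types``) are the container;
the leaf parameter names inside substrate and cell-type blocks are the
compatibility surface and follow the ``S_...`` / ``S_X_...`` / ``S_..._C``
naming convention with the substrate name substituted for ``S``, the MOA
name for ``X`` and the cell type name for ``C`` — e.g.
``drugA_max_number_doses``, ``drugA_prolif_EC50``, ``drugA_dt_tumor``.

The loader is permissive where it can be and strict where it must be:
optional parameters fall back to documented defaults, each recorded exactly
once as a warning; required parameters that are missing or inconsistent are
collected and reported together in a single :class:`ConfigurationError`.

Defaults applied with a warning: PK model "2C", Biot number 1, damage model
"AUC", Hill power 1, zero loading doses with the loading amount equal to the
regular amount, and a fixed first dose at t = 0.  Hard errors: a missing
``S_central_increase_on_dose`` with doses scheduled, a missing
``S_dose_interval`` with more than one dose, a missing saturation rate or
EC50 for any active MOA, an EC50 <= 0, an unknown PK model or MOA name, and
dangling substrate references.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence, Tuple, Union

import yaml

from .cells import CellType
from .dosing import ConfigurationError, DoseSchedule
from .pd import DAMAGE_MODELS, MOA_NAMES, HillParams, MOAConfig, PDParams
from .pk import BiotNumber, OneCompartmentParams, TwoCompartmentParams

__all__ = ["SimulationConfig", "SubstrateConfig", "PlacementConfig", "load_config"]

PK_MODELS = ("1C", "2C", "SBML")

#: a double-typed flag counts as "true" iff its value exceeds this threshold
MOA_FLAG_THRESHOLD = 0.5


@dataclass
class SubstrateConfig:
    name: str
    diffusion: float
    decay: float
    initial: float = 0.0
    dirichlet_edges: Tuple[str, ...] = ()
    has_pk: bool = False
    pk_model: str = "2C"
    pk_params: Optional[Union[OneCompartmentParams, TwoCompartmentParams]] = None
    sbml_file: Optional[str] = None
    biot: BiotNumber = field(default_factory=BiotNumber)
    schedule: Optional[DoseSchedule] = None


@dataclass
class PlacementConfig:
    """Initial cells of one type: a disc layout or an explicit CSV file."""

    cell_type: str
    n_cells: int = 0
    tumor_radius: float = 250.0
    layout_file: Optional[str] = None


@dataclass
class SimulationConfig:
    domain: Tuple[float, float, float, float] = (-400.0, 400.0, -400.0, 400.0)
    voxel_size: float = 20.0
    diffusion_dt: float = 0.01
    mechanics_dt: float = 0.1
    phenotype_dt: float = 6.0
    t_end: float = 2880.0
    snapshot_interval: float = 6.0
    seed: int = 0
    pk_substrates: List[str] = field(default_factory=list)
    pd_substrates: List[str] = field(default_factory=list)
    substrates: Dict[str, SubstrateConfig] = field(default_factory=dict)
    cell_types: List[CellType] = field(default_factory=list)
    placements: List[PlacementConfig] = field(default_factory=list)
    precompute_all_pd: bool = True
    precompute_overrides: Dict[Tuple[str, str], bool] = field(default_factory=dict)
    output_dir: str = "output"
    warnings: List[str] = field(default_factory=list)


class _Collector:
    """Accumulates defaults-used warnings and hard errors during a load."""

    def __init__(self) -> None:
        self.warnings: List[str] = []
        self.errors: List[str] = []

    def default(self, key: str, value: Any) -> None:
        self.warnings.append(f"missing parameter {key!r}: using default {value!r}")

    def error(self, message: str) -> None:
        self.errors.append(message)

    def raise_if_errors(self) -> None:
        if self.errors:
            raise ConfigurationError(
                "invalid configuration:\n  - " + "\n  - ".join(self.errors)
            )


def _as_bool(value: Any) -> bool:
    """Double-typed flag semantics: values > 0.5 are true."""
    if isinstance(value, bool):
        return value
    return float(value) > MOA_FLAG_THRESHOLD


def _split_names(value: Any) -> List[str]:
    if value is None:
        return []
    if isinstance(value, (list, tuple)):
        return [str(v).strip() for v in value if str(v).strip()]
    return [part.strip() for part in str(value).split(",") if part.strip()]


def _parse_substrate(
    name: str,
    block: Dict[str, Any],
    has_pk: bool,
    col: _Collector,
) -> SubstrateConfig:
    def key(suffix: str) -> str:
        return f"{name}_{suffix}"

    def get(suffix: str, default=None):
        return block.get(key(suffix), default)

    cfg = SubstrateConfig(
        name=name,
        diffusion=float(block.get("diffusion_coefficient", 0.0)),
        decay=float(block.get("decay_rate", 0.0)),
        initial=float(block.get("initial_condition", 0.0)),
        dirichlet_edges=tuple(block.get("dirichlet_edges", ())),
        has_pk=has_pk,
    )
    if not has_pk:
        return cfg

    model = get("pk_model")
    if model is None:
        model = "2C"
        col.default(key("pk_model"), model)
    if model not in PK_MODELS:
        col.error(f"{key('pk_model')}: unknown PK model {model!r}; expected {PK_MODELS}")
        return cfg
    cfg.pk_model = model

    biot = get("biot_number")
    if biot is None:
        biot = 1.0
        col.default(key("biot_number"), biot)
    try:
        cfg.biot = BiotNumber(float(biot))
    except ValueError as exc:
        col.error(f"{key('biot_number')}: {exc}")

    if model == "SBML":
        sbml_file = get("sbml_file")
        if sbml_file is None:
            col.error(f"{key('sbml_file')}: required for an SBML-defined PK model")
        cfg.sbml_file = sbml_file
        return cfg  # dosing lives inside the SBML file

    lam = get("central_elimination_rate")
    if lam is None:
        lam = 0.0
        col.default(key("central_elimination_rate"), lam)
    try:
        if model == "1C":
            cfg.pk_params = OneCompartmentParams(float(lam))
        else:
            k12 = get("central_to_periphery_clearance_rate")
            k21 = get("periphery_to_central_clearance_rate")
            ratio = get("central_to_periphery_volume_ratio")
            if k12 is None:
                k12 = 0.0
                col.default(key("central_to_periphery_clearance_rate"), k12)
            if k21 is None:
                k21 = 0.0
                col.default(key("periphery_to_central_clearance_rate"), k21)
            if ratio is None:
                ratio = 1.0
                col.default(key("central_to_periphery_volume_ratio"), ratio)
            cfg.pk_params = TwoCompartmentParams(
                float(lam), float(k12), float(k21), float(ratio)
            )
    except ValueError as exc:
        col.error(f"{name} PK parameters: {exc}")

    max_doses = int(get("max_number_doses", 0) or 0)
    if max_doses > 0:
        amount = get("central_increase_on_dose")
        if amount is None:
            col.error(f"{key('central_increase_on_dose')}: required when doses are scheduled")
            amount = 0.0
        interval = get("dose_interval")
        if interval is None:
            if max_doses > 1:
                col.error(f"{key('dose_interval')}: required when more than one dose is scheduled")
            interval = math.inf
        n_loading = get("number_loading_doses")
        if n_loading is None:
            n_loading = 0
            col.default(key("number_loading_doses"), 0)
        loading_amount = get("central_increase_on_loading_dose")
        if loading_amount is None and int(n_loading) > 0:
            col.default(key("central_increase_on_loading_dose"), float(amount))
        set_first = get("set_first_dose_time")
        first_time = get("first_dose_time")
        confluence = get("confluence_condition")
        if set_first is None:
            if confluence is not None:
                set_first = False
            else:
                set_first = True
                if first_time is None:
                    col.default(key("first_dose_time"), 0.0)
        set_first = _as_bool(set_first)
        try:
            cfg.schedule = DoseSchedule(
                max_number_doses=max_doses,
                number_loading_doses=int(n_loading),
                dose_interval=float(interval),
                central_increase_on_dose=float(amount),
                central_increase_on_loading_dose=(
                    float(loading_amount) if loading_amount is not None else None
                ),
                set_first_dose_time=set_first,
                first_dose_time=float(first_time if first_time is not None else 0.0),
                confluence_condition=float(confluence if confluence is not None else 1.0),
            )
        except ConfigurationError as exc:
            col.error(f"{name} dose schedule: {exc}")
    return cfg


def _parse_cell_type(
    name: str,
    block: Dict[str, Any],
    pd_substrates: Sequence[str],
    mechanics_dt: float,
    col: _Collector,
) -> Tuple[CellType, Dict[Tuple[str, str], bool], PlacementConfig]:
    custom: Dict[str, Any] = dict(block.get("custom_data", {}))
    uptake: Dict[str, float] = {}
    pd_params: Dict[str, PDParams] = {}
    moa_configs: Dict[str, MOAConfig] = {}
    precompute_overrides: Dict[Tuple[str, str], bool] = {}

    for s in pd_substrates:
        def ckey(suffix: str) -> str:
            return f"{s}_{suffix}"

        uptake[s] = float(custom.get(ckey("uptake_rate"), 0.0))

        model = custom.get(f"{s}_on_{name}_pd_model")
        if model is None:
            model = "AUC"
            col.default(f"{s}_on_{name}_pd_model", model)
        if model not in DAMAGE_MODELS:
            col.error(
                f"{s}_on_{name}_pd_model: unknown damage model {model!r}; "
                f"expected one of {DAMAGE_MODELS}"
            )
            model = "AUC"

        pd_dt = custom.get(f"{s}_dt_{name}")
        if pd_dt is None:
            pd_dt = mechanics_dt
        else:
            pd_dt = float(pd_dt)
            ratio = pd_dt / mechanics_dt
            if abs(ratio - round(ratio)) > 1e-9 or ratio < 1.0 - 1e-9:
                col.error(
                    f"{s}_dt_{name}: PD step {pd_dt} must be a positive multiple "
                    f"of the mechanics step {mechanics_dt}"
                )
        missing = [
            k
            for k in ("metabolism_rate", "repair_rate_constant", "repair_rate_linear")
            if ckey(k) not in custom
        ]
        for k in missing:
            col.default(ckey(k), 0.0)
        try:
            pd_params[s] = PDParams(
                metabolism_rate=float(custom.get(ckey("metabolism_rate"), 0.0)),
                repair_rate_constant=float(custom.get(ckey("repair_rate_constant"), 0.0)),
                repair_rate_linear=float(custom.get(ckey("repair_rate_linear"), 0.0)),
                dt=float(pd_dt),
                damage_model=model,
            )
        except ValueError as exc:
            col.error(f"{s} damage parameters for {name!r}: {exc}")

        pre = custom.get(f"{s}_precompute_pd_for_{name}")
        if pre is not None:
            precompute_overrides[(s, name)] = _as_bool(pre)

        moas: Dict[str, HillParams] = {}
        for moa in MOA_NAMES:
            flag = custom.get(ckey(f"moa_is_{moa}"))
            if flag is None or not _as_bool(flag):
                continue
            sat = custom.get(ckey(f"{moa}_saturation_rate"))
            ec50 = custom.get(ckey(f"{moa}_EC50"))
            power = custom.get(ckey(f"{moa}_hill_power"))
            if sat is None:
                col.error(f"{ckey(f'{moa}_saturation_rate')}: required for the active MOA")
                continue
            if ec50 is None:
                col.error(f"{ckey(f'{moa}_EC50')}: required for the active MOA")
                continue
            if power is None:
                power = 1.0
                col.default(ckey(f"{moa}_hill_power"), power)
            try:
                moas[moa] = HillParams(
                    saturation_rate=float(sat),
                    ec50=float(ec50),
                    hill_power=float(power),
                )
            except ValueError as exc:
                col.error(f"{s} {moa} effect on {name!r}: {exc}")
        # reject MOA flags that match no known mechanism
        for key_name in custom:
            if key_name.startswith(f"{s}_moa_is_"):
                moa = key_name[len(f"{s}_moa_is_") :]
                if moa not in MOA_NAMES:
                    col.error(f"{key_name}: unknown MOA {moa!r}; expected one of {MOA_NAMES}")
        if moas:
            moa_configs[s] = MOAConfig(moas)

    try:
        ct = CellType(
            name=name,
            radius=float(block.get("radius", 8.4)),
            prolif=float(block.get("prolif_rate", 0.0)),
            apop=float(block.get("apop_rate", 0.0)),
            necrosis=float(block.get("necrosis_rate", 0.0)),
            motility=float(block.get("motility_speed", 0.0)),
            persistence_time=float(block.get("persistence_time", 15.0)),
            uptake_rates=uptake,
            pd_params=pd_params,
            moa_configs=moa_configs,
        )
    except ValueError as exc:
        col.error(f"cell type {name!r}: {exc}")
        ct = CellType(name=name)

    # multiplicative MOA on a zero base rate is a load-time error
    for s, moa in moa_configs.items():
        for moa_name in moa.moas:
            if moa_name != "necrosis" and getattr(ct, moa_name) <= 0.0:
                col.error(
                    f"{s} targets {moa_name!r} on {name!r} but the base rate is 0; "
                    "multiplicative factors are undefined — use the additive "
                    "necrosis pattern or a positive base rate"
                )

    placement = PlacementConfig(
        cell_type=name,
        n_cells=int(block.get("initial_count", 0)),
        tumor_radius=float(block.get("initial_tumor_radius", 250.0)),
        layout_file=block.get("layout_file"),
    )
    return ct, precompute_overrides, placement


def load_config(source: Union[str, Path, Dict[str, Any]]) -> SimulationConfig:
    """Load and validate a configuration from a YAML path or a dict."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = source
    if not isinstance(raw, dict):
        raise ConfigurationError("configuration must be a mapping")

    col = _Collector()
    dom = raw.get("domain", {})
    domain = (
        float(dom.get("x_min", -400.0)),
        float(dom.get("x_max", 400.0)),
        float(dom.get("y_min", -400.0)),
        float(dom.get("y_max", 400.0)),
    )
    voxel = float(dom.get("voxel_size", 20.0))
    if voxel <= 0.0:
        col.error(f"voxel_size must be > 0, got {voxel}")

    tm = raw.get("time", {})
    diffusion_dt = float(tm.get("diffusion_dt", 0.01))
    mechanics_dt = float(tm.get("mechanics_dt", 0.1))
    phenotype_dt = float(tm.get("phenotype_dt", 6.0))
    t_end = float(tm.get("t_end", 2880.0))
    snapshot = float(tm.get("snapshot_interval", 6.0))
    for label, small, big in (
        ("mechanics_dt/diffusion_dt", diffusion_dt, mechanics_dt),
        ("phenotype_dt/mechanics_dt", mechanics_dt, phenotype_dt),
    ):
        if small <= 0 or big <= 0:
            col.error(f"time steps must be > 0 ({label})")
            continue
        ratio = big / small
        if abs(ratio - round(ratio)) > 1e-9:
            col.error(f"{label}: {big} is not an integer multiple of {small}")

    user = raw.get("user_parameters", {})
    pk_names = _split_names(user.get("PKPD_pk_substrate_names"))
    pd_names = _split_names(user.get("PKPD_pd_substrate_names"))
    precompute_all = _as_bool(user.get("PKPD_precompute_all_pd_quantities", True))

    sub_blocks = raw.get("substrates", {}) or {}
    for s in pk_names:
        if s not in sub_blocks:
            col.error(f"PKPD_pk_substrate_names includes undeclared substrate {s!r}")
    for s in pd_names:
        if s not in sub_blocks:
            col.error(f"PKPD_pd_substrate_names includes undeclared substrate {s!r}")

    substrates: Dict[str, SubstrateConfig] = {}
    for name, block in sub_blocks.items():
        substrates[name] = _parse_substrate(name, block or {}, name in pk_names, col)

    cell_types: List[CellType] = []
    placements: List[PlacementConfig] = []
    precompute_overrides: Dict[Tuple[str, str], bool] = {}
    for name, block in (raw.get("cell_types", {}) or {}).items():
        ct, overrides, placement = _parse_cell_type(
            name, block or {}, pd_names, mechanics_dt, col
        )
        cell_types.append(ct)
        precompute_overrides.update(overrides)
        placements.append(placement)

    col.raise_if_errors()
    return SimulationConfig(
        domain=domain,
        voxel_size=voxel,
        diffusion_dt=diffusion_dt,
        mechanics_dt=mechanics_dt,
        phenotype_dt=phenotype_dt,
        t_end=t_end,
        snapshot_interval=snapshot,
        seed=int(raw.get("seed", 0)),
        pk_substrates=pk_names,
        pd_substrates=pd_names,
        substrates=substrates,
        cell_types=cell_types,
        placements=placements,
        precompute_all_pd=precompute_all,
        precompute_overrides=precompute_overrides,
        output_dir=str(raw.get("output_dir", "output")),
        warnings=col.warnings,
    )
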