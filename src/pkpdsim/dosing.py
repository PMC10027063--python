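"""Dose schedules: regular-interval IV boluses with loading doses.

A schedule gives up to ``max_number_doses`` boluses at a fixed
``dose_interval``, the first ``number_loading_doses`` of them at the loading
amount, the remainder at the regular amount.  Dosing starts either at a fixed
time or when the 2D confluence of the culture first reaches a threshold
(checked on the phenotype step, so the realized start time quantizes to that
grid).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

__all__ = ["DoseSchedule", "DoseEvent", "build_dose_times", "resolve_first_dose_time"]


class ConfigurationError(ValueError):
    """A schedule or simulation configuration is inconsistent."""


@dataclass(frozen=True)
class DoseSchedule:
    """Regular-interval bolus schedule for one substrate.

    ``first_dose_time`` applies iff ``set_first_dose_time`` is true, otherwise
    dosing starts at the first phenotype step where confluence reaches
    ``confluence_condition``.
    """

    max_number_doses: int = 0
    number_loading_doses: int = 0
    dose_interval: float = math.inf
    central_increase_on_dose: float = 0.0
    central_increase_on_loading_dose: Optional[float] = None
    set_first_dose_time: bool = True
    first_dose_time: float = 0.0
    confluence_condition: float = 1.0

    def __post_init__(self) -> None:
        if self.max_number_doses < 0 or self.number_loading_doses < 0:
            raise ConfigurationError("dose counts must be >= 0")
        if self.number_loading_doses > self.max_number_doses:
            raise ConfigurationError(
                f"number_loading_doses ({self.number_loading_doses}) exceeds "
                f"max_number_doses ({self.max_number_doses})"
            )
        if self.max_number_doses > 1 and not (self.dose_interval > 0.0):
            raise ConfigurationError(
                "dose_interval must be > 0 when more than one dose is scheduled"
            )
        if not (0.0 <= self.confluence_condition <= 1.0):
            raise ConfigurationError(
                f"confluence_condition must lie in [0, 1], got {self.confluence_condition}"
            )
        if self.central_increase_on_dose < 0.0:
            raise ConfigurationError("central_increase_on_dose must be >= 0")

    @property
    def loading_amount(self) -> float:
        """Loading bolus amount; defaults to the regular amount."""
        if self.central_increase_on_loading_dose is None:
            return self.central_increase_on_dose
        return self.central_increase_on_loading_dose


@dataclass(frozen=True)
class DoseEvent:
    """One administered (or scheduled) bolus."""

    time: float
    amount: float
    is_loading: bool = False


def build_dose_times(
    schedule: DoseSchedule, start_time: float, t_end: float
) -> List[DoseEvent]:
    """Expand a schedule into concrete dose events in ``[start_time, t_end]``.

    Events fall at ``start_time + i * dose_interval`` for
    ``i = 0 .. max_number_doses - 1``, truncated at the simulation end; the
    first ``number_loading_doses`` events carry the loading amount.
    """
    events: List[DoseEvent] = []
    for i in range(schedule.max_number_doses):
        t = start_time + i * schedule.dose_interval
        if t > t_end:
            break
        loading = i < schedule.number_loading_doses
        amount = schedule.loading_amount if loading else schedule.central_increase_on_dose
        events.append(DoseEvent(time=t, amount=amount, is_loading=loading))
    return events


def resolve_first_dose_time(
    schedule: DoseSchedule,
    confluence_series: Optional[Iterable[Tuple[float, float]]] = None,
) -> Optional[float]:
    """Determine when the first dose is given.

    With ``set_first_dose_time`` the configured time is returned directly.
    Otherwise ``confluence_series`` — (time, confluence) samples on the
    phenotype grid, ordered in time — is scanned for the first sample at or
    above ``confluence_condition``.  Returns ``None`` (with a warning) if the
    threshold is never reached: no doses are administered.
    """
    if schedule.set_first_dose_time:
        return schedule.first_dose_time
    if confluence_series is None:
        raise ConfigurationError(
            "confluence-triggered dosing requires a confluence series/monitor"
        )
    for t, conf in confluence_series:
        if conf >= schedule.confluence_condition:
            return t
    warnings.warn(
        "confluence threshold "
        f"{schedule.confluence_condition} never reached; no doses administered",
        stacklevel=2,
    )
    return None
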