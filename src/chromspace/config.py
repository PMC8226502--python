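"""Instrument and method condition containers.

Two small frozen dataclasses carry everything the forward model needs:

* :class:`InstrumentConfig` — the column/system constants (hold-up volume,
  gradient dwell volume, apparent plate number).  Dead time ``t0`` and dwell
  time ``tD`` are always *derived* from the flow rate, never stored.
* :class:`MethodConditions` — one complete linear gradient program
  (tG, T, pH, flow, start/end organic fraction).

Organic fraction is a 0–1 fraction everywhere inside the package; the I/O
layer converts to/from %B at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Any, List

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import InvalidParameterError

__all__ = [
    "InstrumentConfig",
    "MethodConditions",
    "ProjectConfig",
    "DEFAULT_INSTRUMENT",
]


def _require_finite(name: str, value: float) -> float:
    if not math.isfinite(value):
        raise InvalidParameterError(f"{name} must be finite, got {value!r}")
    return float(value)


@dataclass(frozen=True)
class InstrumentConfig:
    """UHPLC system constants.

    Parameters
    ----------
    dead_volume_mL:
        Column hold-up volume V_M (mL).  Default 0.110 mL, the geometric
        hold-up of a 50 x 2.1 mm column at ~0.64 total porosity.
    dwell_volume_mL:
        System volume between the gradient mixer and the column inlet (mL);
        the gradient reaches the column with delay tD = V_D / F.
    plate_number:
        Apparent (gradient-compressed) plate number N used by the Gaussian
        width model.  This is a fixture-level efficiency constant, not a
        measured isocratic plate count.
    max_pressure_bar:
        Informational only; never enters any computation.
    """

    dead_volume_mL: float = 0.110
    dwell_volume_mL: float = 0.12
    plate_number: float = 120_000.0
    max_pressure_bar: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("dead_volume_mL", "dwell_volume_mL", "plate_number"):
            value = _require_finite(name, getattr(self, name))
            if value <= 0:
                raise InvalidParameterError(f"{name} must be > 0, got {value}")

    def dead_time_min(self, flow_mL_min: float) -> float:
        """Column dead time t0 = V_M / F in minutes."""
        return self.dead_volume_mL / flow_mL_min

    def dwell_time_min(self, flow_mL_min: float) -> float:
        """Gradient dwell (delay) time tD = V_D / F in minutes."""
        return self.dwell_volume_mL / flow_mL_min


DEFAULT_INSTRUMENT = InstrumentConfig()


@dataclass(frozen=True)
class MethodConditions:
    """One linear-gradient method: tG, T, pH, flow and %B endpoints."""

    tG_min: float
    T_C: float
    pH: float
    flow_mL_min: float = 0.8
    phi_start: float = 0.10
    phi_end: float = 0.80

    def __post_init__(self) -> None:
        for name in ("tG_min", "T_C", "pH", "flow_mL_min", "phi_start", "phi_end"):
            _require_finite(name, getattr(self, name))
        if self.tG_min <= 0:
            raise InvalidParameterError(f"tG_min must be > 0, got {self.tG_min}")
        if self.flow_mL_min <= 0:
            raise InvalidParameterError(
                f"flow_mL_min must be > 0, got {self.flow_mL_min}"
            )
        if not (0.0 <= self.phi_start < self.phi_end <= 1.0):
            raise InvalidParameterError(
                "organic fractions must satisfy 0 <= phi_start < phi_end <= 1, "
                f"got phi_start={self.phi_start}, phi_end={self.phi_end}"
            )
        if not (0.0 < self.pH < 14.0):
            raise InvalidParameterError(f"pH must be in (0, 14), got {self.pH}")

    def with_(self, **kwargs: Any) -> "MethodConditions":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def inlet_fraction(self, t_min: float, instr: InstrumentConfig) -> float:
        """Organic fraction at the column inlet at time ``t_min`` after injection.

        The programmed ramp is delayed by the dwell time and clamped to
        [phi_start, phi_end].
        """
        tD = instr.dwell_time_min(self.flow_mL_min)
        if t_min <= tD:
            return self.phi_start
        if t_min >= tD + self.tG_min:
            return self.phi_end
        frac = (t_min - tD) / self.tG_min
        return self.phi_start + (self.phi_end - self.phi_start) * frac


# ---------------------------------------------------------------------------
# Project-level configuration (validated, strict about unknown keys)
# ---------------------------------------------------------------------------


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class InstrumentBlock(_StrictModel):
    dead_volume_mL: float = Field(0.110, gt=0)
    dwell_volume_mL: float = Field(0.12, gt=0)
    plate_number: float = Field(120_000.0, gt=0)
    max_pressure_bar: float = Field(1000.0, gt=0)

    def to_instrument(self) -> InstrumentConfig:
        return InstrumentConfig(
            dead_volume_mL=self.dead_volume_mL,
            dwell_volume_mL=self.dwell_volume_mL,
            plate_number=self.plate_number,
            max_pressure_bar=self.max_pressure_bar,
        )


class DesignBlock(_StrictModel):
    tG_levels_min: List[float] = [1.5, 4.5]
    T_levels_C: List[float] = [20.0, 50.0]
    pH_levels: List[float] = [2.8, 4.6, 6.4]
    flow_mL_min: float = Field(0.8, gt=0)
    pctB_start: float = 10.0
    pctB_end: float = 80.0

    @model_validator(mode="after")
    def _check_levels(self) -> "DesignBlock":
        for name, levels, n in (
            ("tG_levels_min", self.tG_levels_min, 2),
            ("T_levels_C", self.T_levels_C, 2),
            ("pH_levels", self.pH_levels, 3),
        ):
            if len(levels) != n:
                raise ValueError(f"{name} must have exactly {n} levels")
            if any(b <= a for a, b in zip(levels, levels[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        return self


class RobustnessBlock(_StrictModel):
    tG_min: List[float] = [2.7, 3.0, 3.3]
    T_C: List[float] = [38.0, 40.0, 42.0]
    pH: List[float] = [5.8, 6.0, 6.2]
    flow_mL_min: List[float] = [0.72, 0.80, 0.88]
    pctB_start: List[float] = [9.0, 10.0, 11.0]
    pctB_end: List[float] = [79.0, 80.0, 81.0]


class ProjectConfig(_StrictModel):
    """Top-level validated configuration (YAML/JSON); unknown keys rejected."""

    instrument: InstrumentBlock = InstrumentBlock()
    design: DesignBlock = DesignBlock()
    robustness: RobustnessBlock = RobustnessBlock()
    criterion: float = Field(2.0, gt=0)
    report_decimals: int = Field(2, ge=0)
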