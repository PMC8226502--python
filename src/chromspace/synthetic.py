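"""Ground-truth generator emulating an apixaban-like reaction mixture.

Nine solutes (two starting materials Stm1/Stm2, six intermediates Int1-Int6
and apixaban) are modelled with a *physically richer* retention law than the
one the calibration module fits:

* each ionizable solute is a pH-weighted mixture of a neutral and an ionized
  species, each with its own LSS law — so the true pH dependence is a
  sigmoid, while the fitted model approximates it with a local quadratic;
* temperature acts through a van't Hoff shift, linear in 1/T(K);
* one solute (Stm2) can degrade (complete peak loss) at harsh
  high-temperature/high-pH conditions.

Run tables are produced by forward-simulating this truth through the
general numerical migration integral (never through the fitted model), with
seeded Gaussian retention-time jitter and relative area noise.

The packaged mixture constants are fixture data: authored once (by the
tuning script shipped in ``scripts/tune_fixture.py``) so that at the nominal
working point (tG = 3.0 min, 40 C, pH 6.0, 0.8 mL/min, 10->80 %B) the
elution order is Int6 < Stm1 < Apixaban < Int2 < Int1 < Int5 < Stm2 <
Int4 < Int3 with the Int4/Int3 pair critical at Rs about 2.4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .calibration import CalibrationDesign, RunTable
from .config import InstrumentConfig, MethodConditions
from .errors import InvalidParameterError
from .lss import migration_time

__all__ = [
    "GroundTruthSolute",
    "NoiseSpec",
    "effective_k",
    "default_apixaban_mixture",
    "generate_run_table",
    "T_REF_C",
]

T_REF_C = 40.0
_T_REF_K = T_REF_C + 273.15


@dataclass(frozen=True)
class GroundTruthSolute:
    """True retention parameters of one mixture component.

    ``log_kw_*`` values are referenced to T_REF_C = 40 C.  ``vant_hoff_slope``
    is d(log10 k)/d(1/T_K) in kelvin (positive: retention drops as T rises).
    ``degradable`` is an optional (T_threshold_C, pH_threshold) pair; at or
    beyond *both* thresholds the compound's peak is lost entirely.
    """

    compound_id: str
    log_kw_neutral: float
    S_neutral: float
    vant_hoff_slope: float
    pKa: Optional[float] = None
    log_kw_ion: Optional[float] = None
    S_ion: Optional[float] = None
    degradable: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.pKa is not None:
            if not (2.0 < self.pKa < 9.0):
                raise InvalidParameterError(f"pKa must be in (2, 9), got {self.pKa}")
            if self.log_kw_ion is None or self.S_ion is None:
                raise InvalidParameterError(
                    "ionizable solute needs log_kw_ion and S_ion"
                )
            if self.log_kw_ion >= self.log_kw_neutral:
                raise InvalidParameterError(
                    "ionized species must be less retained than the neutral one"
                )

    def degrades_at(self, T_C: float, pH: float) -> bool:
        if self.degradable is None:
            return False
        T_thr, pH_thr = self.degradable
        return T_C >= T_thr - 1e-9 and pH >= pH_thr - 1e-9


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise description; the seed is mandatory (no hidden entropy)."""

    seed: int
    tR_jitter_sd_min: float = 0.0
    area_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.tR_jitter_sd_min < 0 or self.area_cv < 0:
            raise InvalidParameterError("noise standard deviations must be >= 0")


def effective_k(solute: GroundTruthSolute, phi, T_C: float, pH: float):
    """True retention factor at composition ``phi``, temperature and pH.

    Acid-base weighted mixture of the two species' LSS laws,

        k = (k_neutral + k_ion * 10**(pH - pKa)) / (1 + 10**(pH - pKa)),

    each species shifted in temperature by the shared van't Hoff slope.
    Neutral-only solutes use the neutral law alone.  Vectorized over phi.
    """
    phi = np.asarray(phi, dtype=float)
    shift = solute.vant_hoff_slope * (1.0 / (T_C + 273.15) - 1.0 / _T_REF_K)
    k_n = 10.0 ** (solute.log_kw_neutral - solute.S_neutral * phi + shift)
    if solute.pKa is None:
        return k_n
    r = 10.0 ** (pH - solute.pKa)
    k_i = 10.0 ** (solute.log_kw_ion - solute.S_ion * phi + shift)
    return (k_n + k_i * r) / (1.0 + r)


def simulate_retention_time(
    solute: GroundTruthSolute,
    cond: MethodConditions,
    instr: InstrumentConfig,
) -> float:
    """Noise-free true retention time via the numerical migration integral."""
    return migration_time(
        lambda phi: effective_k(solute, phi, cond.T_C, cond.pH), cond, instr
    )


# ---------------------------------------------------------------------------
# Packaged fixture mixture (frozen constants; see scripts/tune_fixture.py)
# ---------------------------------------------------------------------------

_MIXTURE_CONSTANTS = [
    # compound_id, log_kw_neutral, S_neutral, vant_hoff, pKa, log_kw_ion, S_ion, degradable
    ("Int6", 1.5588979686538684, 2.2, 850.0, 3.85, 1.2588979686538684, 2.2, None),
    ("Stm1", 1.3702028972504214, 2.2, 800.0, None, None, None, None),
    ("Apixaban", 1.601019005923253, 2.6, 900.0, None, None, None, None),
    ("Int2", 1.6512280666976968, 2.5, 880.0, None, None, None, None),
    ("Int1", 1.9022875502395133, 2.8, 920.0, None, None, None, None),
    ("Int5", 1.9655668491261031, 2.7, 910.0, None, None, None, None),
    ("Stm2", 2.153812081638581, 3.0, 1000.0, None, None, None, (80.0, 6.4)),
    ("Int4", 2.235987563653643, 2.9, 941.0, None, None, None, None),
    ("Int3", 2.2423295070150577, 2.88, 941.0, None, None, None, None),
]


def default_apixaban_mixture() -> List[GroundTruthSolute]:
    """The packaged 9-compound apixaban-like ground-truth mixture."""
    return [
        GroundTruthSolute(
            compound_id=cid,
            log_kw_neutral=lkw_n,
            S_neutral=s_n,
            vant_hoff_slope=vh,
            pKa=pka,
            log_kw_ion=lkw_i,
            S_ion=s_i,
            degradable=deg,
        )
        for cid, lkw_n, s_n, vh, pka, lkw_i, s_i, deg in _MIXTURE_CONSTANTS
    ]


def generate_run_table(
    mixture: List[GroundTruthSolute],
    design: CalibrationDesign,
    instr: InstrumentConfig,
    noise: NoiseSpec,
) -> RunTable:
    """Forward-simulate the calibration design into a run table.

    Every (run, compound) retention time comes from the numerical migration
    integral over the true retention law; seeded Gaussian jitter is then
    added.  Degradable compounds are omitted (no row) at conditions at or
    beyond their thresholds.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(noise.seed)
    rows = []
    for run_id, cond in design.runs():
        for solute in mixture:
            if solute.degrades_at(cond.T_C, cond.pH):
                continue
            tR = simulate_retention_time(solute, cond, instr)
            if noise.tR_jitter_sd_min > 0:
                tR += rng.normal(0.0, noise.tR_jitter_sd_min)
            area = 1.0
            if noise.area_cv > 0:
                area = max(0.0, 1.0 + rng.normal(0.0, noise.area_cv))
            rows.append(
                {
                    "run_id": run_id,
                    "tG_min": cond.tG_min,
                    "T_C": cond.T_C,
                    "pH": cond.pH,
                    "flow_mL_min": cond.flow_mL_min,
                    "pctB_start": 100.0 * cond.phi_start,
                    "pctB_end": 100.0 * cond.phi_end,
                    "compound_id": solute.compound_id,
                    "tR_min": tR,
                    "area": area,
                }
            )
    return RunTable(pd.DataFrame(rows))
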