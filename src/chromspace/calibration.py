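"""Calibration: fit per-compound LSS parameters from a 12-run design.

The design crosses 2 gradient times x 2 temperatures x 3 pH values.  At
each of the six (T, pH) corners a compound's two gradient runs (short and
long tG) are inverted into an LSS pair (log_kw, S) by nested 1-D root
finding; the six corner parameter sets are then interpolated to arbitrary
(T, pH) — linearly in 1/T(K) (van't Hoff convention) and quadratically
(3-point Lagrange) in pH.  Parameters, not predicted times, are
interpolated, so predictions stay self-consistent when tG, flow or the %B
endpoints change downstream.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd
from scipy.optimize import brentq

from .chromatogram import Chromatogram, Peak
from .config import InstrumentConfig, MethodConditions
from .errors import (
    ExtrapolationWarning,
    FitFailureError,
    InputError,
    InterpolationError,
    RangeError,
    UnretainedSoluteError,
)
from .lss import SoluteLSS, gradient_retention_time, peak_sigma

__all__ = [
    "CalibrationDesign",
    "RunTable",
    "FittedModel",
    "invert_two_gradients",
    "fit_model",
    "interpolate_params",
    "predict",
]

# fixed solver brackets and tolerances: reproducibility over adaptivity
S_BRACKET = (0.5, 100.0)
LOGKW_BRACKET = (-2.0, 10.0)
ROOT_TOL = 1e-10
_EQUAL_TR_EPS = 1e-7

RUN_TABLE_COLUMNS = [
    "run_id",
    "tG_min",
    "T_C",
    "pH",
    "flow_mL_min",
    "pctB_start",
    "pctB_end",
    "compound_id",
    "tR_min",
]


@dataclass(frozen=True)
class CalibrationDesign:
    """2 x 2 x 3 full factorial calibration design (12 runs).

    Defaults follow the wide screening design for an ionizable drug mixture:
    steep/shallow gradients 1.5 and 4.5 min, 20 and 50 C, pH 2.8/4.6/6.4 at
    0.8 mL/min with a 10 -> 80 %B ramp.
    """

    tG_levels: Tuple[float, float] = (1.5, 4.5)
    T_levels: Tuple[float, float] = (20.0, 50.0)
    pH_levels: Tuple[float, float, float] = (2.8, 4.6, 6.4)
    flow_mL_min: float = 0.8
    phi_start: float = 0.10
    phi_end: float = 0.80

    def __post_init__(self) -> None:
        for name, levels, n in (
            ("tG_levels", self.tG_levels, 2),
            ("T_levels", self.T_levels, 2),
            ("pH_levels", self.pH_levels, 3),
        ):
            if len(levels) != n:
                raise InputError(f"{name} must have exactly {n} levels")
            if any(b <= a for a, b in zip(levels, levels[1:])):
                raise InputError(f"{name} must be strictly increasing")

    @property
    def n_runs(self) -> int:
        return len(self.tG_levels) * len(self.T_levels) * len(self.pH_levels)

    def corners(self) -> List[Tuple[int, int]]:
        """(T index, pH index) pairs of the six fitting corners."""
        return list(
            itertools.product(range(len(self.T_levels)), range(len(self.pH_levels)))
        )

    def conditions(self, tG: float, T_C: float, pH: float) -> MethodConditions:
        return MethodConditions(
            tG_min=tG,
            T_C=T_C,
            pH=pH,
            flow_mL_min=self.flow_mL_min,
            phi_start=self.phi_start,
            phi_end=self.phi_end,
        )

    def runs(self) -> List[Tuple[str, MethodConditions]]:
        """Ordered (run_id, conditions), tG varying fastest within a corner."""
        out = []
        idx = 1
        for T_C in self.T_levels:
            for pH in self.pH_levels:
                for tG in self.tG_levels:
                    out.append((f"R{idx:02d}", self.conditions(tG, T_C, pH)))
                    idx += 1
        return out


class RunTable:
    """Measured (or simulated) retention times per run and compound.

    Thin validated wrapper around a DataFrame with the canonical run-table
    columns.  A blank/NaN ``tR_min`` means the peak was absent (e.g. a
    degraded compound); a missing row means the same.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in RUN_TABLE_COLUMNS if c not in frame.columns and c != "tR_min"]
        if missing or "tR_min" not in frame.columns:
            missing = [c for c in RUN_TABLE_COLUMNS if c not in frame.columns]
            raise InputError(f"run table missing columns: {missing}")
        dup = frame.duplicated(subset=["run_id", "compound_id"], keep=False)
        if dup.any():
            first = frame.loc[dup, ["run_id", "compound_id"]].iloc[0]
            raise InputError(
                "duplicate (run, compound) entry: "
                f"run_id={first['run_id']!r}, compound_id={first['compound_id']!r}"
            )
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def compounds(self) -> List[str]:
        return list(dict.fromkeys(self.frame["compound_id"]))

    def lookup(
        self, tG: float, T_C: float, pH: float, compound_id: str
    ) -> Optional[float]:
        """tR for one condition/compound, or None if absent or blank."""
        f = self.frame
        sel = (
            (f["compound_id"] == compound_id)
            & (abs(f["tG_min"] - tG) < 1e-9)
            & (abs(f["T_C"] - T_C) < 1e-9)
            & (abs(f["pH"] - pH) < 1e-9)
        )
        hits = f.loc[sel, "tR_min"]
        if hits.empty or pd.isna(hits.iloc[0]):
            return None
        return float(hits.iloc[0])


@dataclass
class FittedModel:
    """Per-compound LSS parameters at the six (T, pH) calibration corners."""

    design: CalibrationDesign
    params: Dict[str, Dict[Tuple[int, int], Optional[SoluteLSS]]]
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def compounds(self) -> List[str]:
        return list(self.params)

    def corner(self, compound_id: str, ti: int, pj: int) -> Optional[SoluteLSS]:
        return self.params[compound_id].get((ti, pj))


def invert_two_gradients(
    tR_1: float,
    tR_2: float,
    cond_1: MethodConditions,
    cond_2: MethodConditions,
    instr: InstrumentConfig,
    compound_id: str = "?",
) -> SoluteLSS:
    """Recover (log_kw, S) from two runs that differ only in gradient time.

    Nested bracketed root finding: for a trial S the inner solve finds the
    log_kw reproducing tR_1, the outer solve drives the residual at tR_2 to
    zero.  Equal retention times (within 1e-7 min) mean a
    gradient-insensitive solute and return S = 0 (flagged downstream).
    """
    same = (
        cond_1.T_C == cond_2.T_C
        and cond_1.pH == cond_2.pH
        and cond_1.flow_mL_min == cond_2.flow_mL_min
        and cond_1.phi_start == cond_2.phi_start
        and cond_1.phi_end == cond_2.phi_end
    )
    if not same or cond_1.tG_min == cond_2.tG_min:
        raise InputError("the two conditions must differ only in tG")
    t0 = instr.dead_time_min(cond_1.flow_mL_min)
    for tR in (tR_1, tR_2):
        if tR <= t0 * (1.0 + 1e-6):
            raise UnretainedSoluteError(
                f"{compound_id}: tR={tR:.4f} min is at/below the dead time"
            )

    if abs(tR_1 - tR_2) < _EQUAL_TR_EPS:
        # gradient steepness has no effect: isocratic solute, S ~ 0
        k = tR_1 / t0 - 1.0
        return SoluteLSS(log_kw=math.log10(k) , S=0.0)

    def logkw_for(S: float, cond: MethodConditions, tR_target: float) -> float:
        def resid(lkw: float) -> float:
            return (
                gradient_retention_time(SoluteLSS(lkw, S), cond, instr) - tR_target
            )

        lo, hi = LOGKW_BRACKET
        f_lo, f_hi = resid(lo), resid(hi)
        if f_lo > 0.0 or f_hi < 0.0:
            raise FitFailureError(
                f"{compound_id}: no log_kw in {LOGKW_BRACKET} reproduces "
                f"tR={tR_target:.4f} min at S={S:.3f}",
                compound_id,
            )
        return brentq(resid, lo, hi, xtol=ROOT_TOL)

    def outer(S: float) -> float:
        lkw = logkw_for(S, cond_1, tR_1)
        return gradient_retention_time(SoluteLSS(lkw, S), cond_2, instr) - tR_2

    # Very steep trial S may make tR_1 unreachable within the log_kw bracket
    # (k0 <= 10**(10 - 0.1*S) is bounded); shrink the upper end until feasible.
    lo, hi = S_BRACKET
    f_lo = outer(lo)
    f_hi = None
    while hi > lo * 1.01:
        try:
            f_hi = outer(hi)
            break
        except FitFailureError:
            hi *= 0.8
    if f_hi is None or f_lo * f_hi > 0.0:
        raise FitFailureError(
            f"{compound_id}: no S in {S_BRACKET} fits the two gradient runs "
            f"(tR {tR_1:.4f} / {tR_2:.4f} min)",
            compound_id,
        )
    S = brentq(outer, lo, hi, xtol=ROOT_TOL)
    return SoluteLSS(log_kw=logkw_for(S, cond_1, tR_1), S=S)


def fit_model(
    runs: RunTable, design: CalibrationDesign, instr: InstrumentConfig
) -> FittedModel:
    """Fit every compound at every (T, pH) corner of the design.

    A corner missing either gradient run for a compound is left unfitted and
    flagged in the diagnostics; a compound with no fitted corner at all is
    dropped with a warning.  Diagnostics record, per fitted corner, the
    worst absolute forward-prediction residual over the two calibration runs
    and any fit flags (``S_nonpositive`` for gradient-insensitive solutes).
    """
    records = []
    params: Dict[str, Dict[Tuple[int, int], Optional[SoluteLSS]]] = {}
    for compound in runs.compounds:
        corners: Dict[Tuple[int, int], Optional[SoluteLSS]] = {}
        for ti, pj in design.corners():
            T_C, pH = design.T_levels[ti], design.pH_levels[pj]
            tRs = [
                runs.lookup(tG, T_C, pH, compound) for tG in design.tG_levels
            ]
            rec = {
                "compound_id": compound,
                "T_C": T_C,
                "pH": pH,
                "residual_min": math.nan,
                "flags": "",
            }
            if any(tr is None for tr in tRs):
                corners[(ti, pj)] = None
                rec["flags"] = "unfitted_missing_run"
                records.append(rec)
                continue
            conds = [design.conditions(tG, T_C, pH) for tG in design.tG_levels]
            solute = invert_two_gradients(
                tRs[0], tRs[1], conds[0], conds[1], instr, compound_id=compound
            )
            resid = max(
                abs(gradient_retention_time(solute, c, instr) - tr)
                for c, tr in zip(conds, tRs)
            )
            flags = []
            if solute.S <= 0.0:
                flags.append("S_nonpositive")
            corners[(ti, pj)] = solute
            rec["residual_min"] = resid
            rec["flags"] = ";".join(flags)
            records.append(rec)
        if all(v is None for v in corners.values()):
            warnings.warn(
                f"compound {compound!r} has no fittable corner and was dropped",
                stacklevel=2,
            )
            continue
        params[compound] = corners
    return FittedModel(design=design, params=params, diagnostics=pd.DataFrame(records))


EXTRAPOLATION_MARGIN = 0.10  # fraction of the calibrated range per side


def _check_range(name: str, value: float, lo: float, hi: float) -> None:
    span = hi - lo
    if lo <= value <= hi:
        return
    excess = (lo - value) if value < lo else (value - hi)
    if excess <= EXTRAPOLATION_MARGIN * span + 1e-12:
        warnings.warn(
            f"{name}={value} extrapolates outside the calibrated range "
            f"[{lo}, {hi}]",
            ExtrapolationWarning,
            stacklevel=3,
        )
        return
    raise RangeError(
        f"{name}={value} outside the calibrated range [{lo}, {hi}] "
        f"plus the {EXTRAPOLATION_MARGIN:.0%} margin"
    )


def interpolate_params(
    model: FittedModel, compound_id: str, T_C: float, pH: float
) -> SoluteLSS:
    """Interpolate a compound's (log_kw, S) to an arbitrary (T, pH).

    Tensor-product interpolation: linear in 1/T(K) across the two
    temperature corners, 3-point Lagrange quadratic across the three pH
    corners, applied independently to log_kw and S.  Tensor-product weights
    make the T-then-pH and pH-then-T orders identical by construction.
    Up to 10% of each range may be extrapolated (with a warning); beyond
    that a RangeError is raised.
    """
    if compound_id not in model.params:
        raise InterpolationError(f"compound {compound_id!r} not in the model")
    design = model.design
    _check_range("T_C", T_C, design.T_levels[0], design.T_levels[-1])
    _check_range("pH", pH, design.pH_levels[0], design.pH_levels[-1])

    x = 1.0 / (T_C + 273.15)
    x1, x2 = (1.0 / (t + 273.15) for t in design.T_levels)
    wT = ((x2 - x) / (x2 - x1), (x - x1) / (x2 - x1))

    p = design.pH_levels
    wP = []
    for j in range(3):
        others = [p[m] for m in range(3) if m != j]
        wP.append(
            (pH - others[0]) * (pH - others[1])
            / ((p[j] - others[0]) * (p[j] - others[1]))
        )

    log_kw = 0.0
    S = 0.0
    corners = model.params[compound_id]
    for ti in range(2):
        for pj in range(3):
            w = wT[ti] * wP[pj]
            if abs(w) < 1e-14:
                continue
            solute = corners.get((ti, pj))
            if solute is None:
                raise InterpolationError(
                    f"{compound_id}: corner (T={design.T_levels[ti]} C, "
                    f"pH={design.pH_levels[pj]}) is unfitted"
                )
            log_kw += w * solute.log_kw
            S += w * solute.S
    return SoluteLSS(log_kw=log_kw, S=S)


def predict(
    model: FittedModel,
    cond: MethodConditions,
    instr: InstrumentConfig,
    amounts: Optional[Dict[str, float]] = None,
) -> Chromatogram:
    """Predict the chromatogram at arbitrary conditions.

    For every fitted compound: interpolate parameters to (T, pH), compute
    the gradient retention time and the Gaussian width.  Areas come from
    ``amounts`` (default: unit amount per compound).
    """
    peaks = []
    for compound in model.compounds:
        solute = interpolate_params(model, compound, cond.T_C, cond.pH)
        tR = gradient_retention_time(solute, cond, instr)
        sigma = peak_sigma(solute, cond, instr, tR)
        area = 1.0 if amounts is None else float(amounts.get(compound, 1.0))
        peaks.append(Peak(compound_id=compound, tR_min=tR, sigma_min=sigma, area=area))
    return Chromatogram(conditions=cond, peaks=tuple(peaks))
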