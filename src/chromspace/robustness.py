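"""Full-factorial virtual robustness study.

Six method parameters — gradient time, temperature, pH, flow rate and the
two %B endpoints — are perturbed around the working point at (usually)
three levels each, and every one of the 3^6 = 729 combinations is run
through the fitted retention model.  The study reports the critical
resolution and critical pair per combination, the success rate against the
resolution criterion, and the worst separations.

Enumeration order is fixed and documented: factors in the order
(tG, T, pH, flow, %B_start, %B_end) with the rightmost factor varying
fastest, 1-based combination indices.  Re-running produces byte-identical
tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from itertools import product
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .calibration import FittedModel, predict
from .chromatogram import critical_resolution
from .config import InstrumentConfig, MethodConditions
from .errors import ChromspaceError, InputError

__all__ = [
    "FactorLevels",
    "RobustnessResult",
    "MainEffects",
    "enumerate_factorial",
    "run_virtual_robustness",
    "main_effects",
    "FACTOR_ORDER",
]

FACTOR_ORDER = ("tG_min", "T_C", "pH", "flow_mL_min", "pctB_start", "pctB_end")


@dataclass(frozen=True)
class FactorLevels:
    """Ordered perturbation levels (-1, 0, +1) per method factor.

    Defaults are the +/-10% (tG, flow), +/-2 C, +/-0.2 pH and +/-1 %B
    deviations customary for a fast-gradient robustness study around the
    nominal point tG 3.0 min / 40 C / pH 6.0 / 0.8 mL/min / 10->80 %B.
    """

    tG_min: Tuple[float, ...] = (2.7, 3.0, 3.3)
    T_C: Tuple[float, ...] = (38.0, 40.0, 42.0)
    pH: Tuple[float, ...] = (5.8, 6.0, 6.2)
    flow_mL_min: Tuple[float, ...] = (0.72, 0.80, 0.88)
    pctB_start: Tuple[float, ...] = (9.0, 10.0, 11.0)
    pctB_end: Tuple[float, ...] = (79.0, 80.0, 81.0)

    def __post_init__(self) -> None:
        for f in fields(self):
            levels = getattr(self, f.name)
            if len(levels) not in (2, 3):
                raise InputError(f"{f.name}: each factor needs 2 or 3 levels")
            if any(b <= a for a, b in zip(levels, levels[1:])):
                raise InputError(f"{f.name}: levels must be strictly increasing")

    @property
    def n_combinations(self) -> int:
        return math.prod(len(getattr(self, name)) for name in FACTOR_ORDER)

    def level_indices(self, name: str) -> Tuple[int, ...]:
        levels = getattr(self, name)
        return (-1, 1) if len(levels) == 2 else (-1, 0, 1)


def enumerate_factorial(levels: FactorLevels) -> pd.DataFrame:
    """All factor combinations in the documented deterministic order.

    Columns: 1-based ``combination`` index, one value column per factor and
    one ``lv_<factor>`` level-index column (-1/0/+1).
    """
    per_factor = [
        [(val, lv) for val, lv in zip(getattr(levels, name), levels.level_indices(name))]
        for name in FACTOR_ORDER
    ]
    rows = []
    for idx, combo in enumerate(product(*per_factor), start=1):
        row: Dict[str, float] = {"combination": idx}
        for name, (val, lv) in zip(FACTOR_ORDER, combo):
            row[name] = val
            row[f"lv_{name}"] = lv
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RobustnessResult:
    """Outcome of the factorial study.

    ``table`` holds one row per combination (enumeration order); failed
    predictions carry Rs_crit = NaN and count against the success rate.
    """

    table: pd.DataFrame
    criterion: float
    levels: FactorLevels

    @property
    def success_rate(self) -> float:
        rs = self.table["Rs_crit"]
        return float((rs >= self.criterion).sum() / len(rs))

    def worst(self, n: int = 6) -> pd.DataFrame:
        """The n worst combinations, ascending Rs_crit (NaN failures first).

        The sort is stable: ties keep enumeration order.
        """
        t = self.table
        order = np.argsort(t["Rs_crit"].fillna(-np.inf).to_numpy(), kind="stable")
        return t.iloc[order[:n]].reset_index(drop=True)


def run_virtual_robustness(
    model: FittedModel,
    levels: FactorLevels,
    instr: InstrumentConfig,
    criterion: float = 2.0,
) -> RobustnessResult:
    """Run every factor combination through the fitted model.

    Flow rescales the dead and dwell times; the %B endpoints rescale the
    gradient's organic-fraction limits.  Any prediction failure (e.g. a
    range error) is recorded as Rs_crit = NaN for that row rather than
    aborting the study.
    """
    grid = enumerate_factorial(levels)
    rs_out: List[float] = []
    pair_out: List[str] = []
    for row in grid.itertuples(index=False):
        try:
            cond = MethodConditions(
                tG_min=row.tG_min,
                T_C=row.T_C,
                pH=row.pH,
                flow_mL_min=row.flow_mL_min,
                phi_start=row.pctB_start / 100.0,
                phi_end=row.pctB_end / 100.0,
            )
            chrom = predict(model, cond, instr)
            rs, pair = critical_resolution(chrom)
            rs_out.append(rs)
            pair_out.append("/".join(pair))
        except ChromspaceError:
            rs_out.append(math.nan)
            pair_out.append("")
    table = grid.copy()
    table["Rs_crit"] = rs_out
    table["crit_pair"] = pair_out
    return RobustnessResult(table=table, criterion=criterion, levels=levels)


@dataclass
class MainEffects:
    """Per-factor mean Rs_crit at each level, plus the grand mean."""

    table: pd.DataFrame  # columns: factor, level, mean_Rs_crit
    grand_mean: float


def main_effects(result: RobustnessResult) -> MainEffects:
    """Level means of Rs_crit per factor for a complete factorial.

    In a balanced design the mean of a factor's level means equals the
    grand mean; an incomplete factorial (missing combinations) is rejected.
    """
    t = result.table
    if len(t) != result.levels.n_combinations:
        raise InputError(
            f"incomplete factorial: {len(t)} rows, expected "
            f"{result.levels.n_combinations}"
        )
    rows = []
    for name in FACTOR_ORDER:
        means = t.groupby(f"lv_{name}")["Rs_crit"].mean()
        expected = result.levels.level_indices(name)
        if tuple(means.index) != expected:
            raise InputError(f"incomplete factorial: levels missing for {name}")
        for lv, m in means.items():
            rows.append({"factor": name, "level": int(lv), "mean_Rs_crit": float(m)})
    return MainEffects(
        table=pd.DataFrame(rows), grand_mean=float(t["Rs_crit"].mean())
    )
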