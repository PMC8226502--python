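"""Design-space mapping and robust working-point selection.

The design space is the region of (tG, T, pH) where the critical resolution
meets the acceptance criterion (Rs_crit >= 2.0 by default).  Maps are
evaluated on explicit grids — every node is a full forward prediction, so
re-evaluating a sub-range always reproduces the parent values at shared
nodes.  The working point is the passing node with the largest L-infinity
"robustness radius" on the normalized grid: the half-width of the biggest
axis-aligned box around it that stays inside both the passing set and the
grid, mirroring the +/-1-level boxes of a factorial robustness study.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calibration import FittedModel, predict
from .chromatogram import critical_resolution
from .config import InstrumentConfig, MethodConditions
from .errors import InputError, NoDesignSpaceError

__all__ = [
    "DesignSpaceMap",
    "WorkingPoint",
    "map_design_space",
    "find_robust_working_point",
    "extract_subspace",
    "DEFAULT_SUBSPACE_RANGES",
    "DEFAULT_GRID_STEPS",
]

# default grid density: finer than the factorial robustness levels
DEFAULT_GRID_STEPS = (0.1, 1.0, 0.1)  # tG (min), T (C), pH
# default cut-out around the working point for the robustness sub-map
DEFAULT_SUBSPACE_RANGES = ((2.0, 4.0), (35.0, 45.0), (5.8, 6.4))


@dataclass(frozen=True)
class WorkingPoint:
    conditions: MethodConditions
    rs_crit: float
    robustness_radius: float
    critical_pair: Tuple[str, str]


@dataclass
class DesignSpaceMap:
    """Rs_crit (and critical pair) on a (tG, T, pH) grid."""

    tG_axis: np.ndarray
    T_axis: np.ndarray
    pH_axis: np.ndarray
    rs: np.ndarray        # shape (n_tG, n_T, n_pH)
    pairs: np.ndarray     # object array of (id, id) tuples (or None)
    criterion: float
    model: FittedModel
    shared: MethodConditions
    instr: InstrumentConfig

    @property
    def axes(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.tG_axis, self.T_axis, self.pH_axis)

    def passing_fraction(self) -> float:
        return float(np.mean(self.rs >= self.criterion))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, tG in enumerate(self.tG_axis):
            for j, T in enumerate(self.T_axis):
                for m, pH in enumerate(self.pH_axis):
                    pair = self.pairs[i, j, m]
                    rows.append(
                        {
                            "tG_min": tG,
                            "T_C": T,
                            "pH": pH,
                            "Rs_crit": self.rs[i, j, m],
                            "crit_pair": "" if pair is None else "/".join(pair),
                        }
                    )
        return pd.DataFrame(rows)


def map_design_space(
    model: FittedModel,
    axes: Tuple[Sequence[float], Sequence[float], Sequence[float]],
    shared_cond: MethodConditions,
    instr: InstrumentConfig,
    criterion: float = 2.0,
) -> DesignSpaceMap:
    """Evaluate Rs_crit at every node of the (tG, T, pH) grid.

    ``shared_cond`` supplies flow and the %B endpoints (its tG/T/pH are
    overridden node by node).  Evaluation is pure: identical inputs give
    bit-identical maps.
    """
    tG_axis = np.asarray(sorted(axes[0]), dtype=float)
    T_axis = np.asarray(sorted(axes[1]), dtype=float)
    pH_axis = np.asarray(sorted(axes[2]), dtype=float)
    for name, ax in (("tG", tG_axis), ("T", T_axis), ("pH", pH_axis)):
        if ax.size == 0:
            raise InputError(f"{name} axis is empty")
    shape = (tG_axis.size, T_axis.size, pH_axis.size)
    rs = np.full(shape, np.nan)
    pairs = np.full(shape, None, dtype=object)
    for i, tG in enumerate(tG_axis):
        for j, T in enumerate(T_axis):
            for m, pH in enumerate(pH_axis):
                cond = shared_cond.with_(tG_min=float(tG), T_C=float(T), pH=float(pH))
                chrom = predict(model, cond, instr)
                if len(chrom) < 2:
                    continue
                rs[i, j, m], pairs[i, j, m] = critical_resolution(chrom)
    return DesignSpaceMap(
        tG_axis=tG_axis,
        T_axis=T_axis,
        pH_axis=pH_axis,
        rs=rs,
        pairs=pairs,
        criterion=criterion,
        model=model,
        shared=shared_cond,
        instr=instr,
    )


def _normalized_coords(axis: np.ndarray) -> Optional[np.ndarray]:
    """Axis scaled to [0, 1]; None for degenerate (single-node) axes."""
    if axis.size < 2 or axis[-1] == axis[0]:
        return None
    return (axis - axis[0]) / (axis[-1] - axis[0])


def find_robust_working_point(dsmap: DesignSpaceMap) -> WorkingPoint:
    """Pick the passing node farthest (L-infinity, normalized) from failure.

    The robustness radius of a passing node is the smaller of its distance
    to the grid boundary and its distance to the nearest failing node, both
    measured in normalized axis units.  Ties are broken toward smaller tG,
    then smaller T, then smaller pH (shorter analyses preferred).
    """
    ok = np.isfinite(dsmap.rs) & (dsmap.rs >= dsmap.criterion)
    if not ok.any():
        raise NoDesignSpaceError(
            f"no grid node meets Rs_crit >= {dsmap.criterion}"
        )
    norm_axes = [_normalized_coords(ax) for ax in dsmap.axes]
    active = [n for n, c in enumerate(norm_axes) if c is not None]

    fail_idx = np.argwhere(~ok)
    ok_idx = np.argwhere(ok)
    best_key = None
    best = None
    for idx in ok_idx:
        if active:
            coords = np.array([norm_axes[n][idx[n]] for n in active])
            d_boundary = float(np.min(np.minimum(coords, 1.0 - coords)))
            if fail_idx.size:
                fail_coords = np.stack(
                    [np.asarray(norm_axes[n])[fail_idx[:, n]] for n in active], axis=1
                )
                d_fail = float(
                    np.min(np.max(np.abs(fail_coords - coords), axis=1))
                )
            else:
                d_fail = np.inf
            radius = min(d_boundary, d_fail)
        else:
            radius = 0.0
        node = (
            float(dsmap.tG_axis[idx[0]]),
            float(dsmap.T_axis[idx[1]]),
            float(dsmap.pH_axis[idx[2]]),
        )
        key = (-radius, *node)
        if best_key is None or key < best_key:
            best_key = key
            best = (idx, radius, node)

    idx, radius, node = best
    cond = dsmap.shared.with_(tG_min=node[0], T_C=node[1], pH=node[2])
    return WorkingPoint(
        conditions=cond,
        rs_crit=float(dsmap.rs[tuple(idx)]),
        robustness_radius=radius,
        critical_pair=dsmap.pairs[tuple(idx)],
    )


def grid_axis(lo: float, hi: float, step: float) -> np.ndarray:
    """Inclusive uniform grid from lo to hi with the given nominal step."""
    n = max(1, int(round((hi - lo) / step)))
    return np.linspace(lo, hi, n + 1)


def extract_subspace(
    dsmap: DesignSpaceMap,
    sub_ranges: Optional[Sequence[Tuple[float, float]]] = None,
    steps: Tuple[float, float, float] = DEFAULT_GRID_STEPS,
    axes: Optional[Tuple[Sequence[float], Sequence[float], Sequence[float]]] = None,
) -> DesignSpaceMap:
    """Cut out and *re-evaluate* a sub-region of an existing map.

    The sub-map is computed on a fresh grid (explicit ``axes`` win over
    ``sub_ranges`` + ``steps``), never sliced from the parent, so its
    density is independent of the parent's.  Default ranges cover the
    region typically cut out around the working point of this separation
    (tG 2.0-4.0 min, T 35-45 C, pH 5.8-6.4).
    """
    if axes is None:
        if sub_ranges is None:
            sub_ranges = DEFAULT_SUBSPACE_RANGES
        parent_ranges = [
            (dsmap.tG_axis[0], dsmap.tG_axis[-1]),
            (dsmap.T_axis[0], dsmap.T_axis[-1]),
            (dsmap.pH_axis[0], dsmap.pH_axis[-1]),
        ]
        for name, (lo, hi), (plo, phi_) in zip(
            ("tG", "T", "pH"), sub_ranges, parent_ranges
        ):
            if lo > hi:
                raise InputError(f"{name} sub-range is empty: ({lo}, {hi})")
            if lo < plo - 1e-12 or hi > phi_ + 1e-12:
                raise InputError(
                    f"{name} sub-range ({lo}, {hi}) outside parent range "
                    f"({plo}, {phi_})"
                )
        axes = tuple(
            grid_axis(lo, hi, st) for (lo, hi), st in zip(sub_ranges, steps)
        )
    return map_design_space(
        dsmap.model, axes, dsmap.shared, dsmap.instr, criterion=dsmap.criterion
    )
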