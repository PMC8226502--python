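"""Linear-solvent-strength (LSS) retention physics.

The retention law is the base-10 LSS model

    log10 k(phi) = log_kw - S * phi

where ``phi`` is the organic-modifier fraction (0-1), ``log_kw`` the
extrapolated retention factor at pure aqueous eluent and ``S`` the solvent
sensitivity.  Under a linear gradient delivered with dwell delay tD the
solute migration obeys

    integral_0^tau  dt / (t0 * k(phi_inlet(t)))  =  1,      tR = tau + t0

with ``phi_inlet`` the dwell-delayed, clamped inlet composition.  For
elution during the ramp this integral has the classic closed form used by
:func:`gradient_retention_time`; elution after the ramp (the solute still on
column when the gradient ends) is handled by the general numerical migration
solver :func:`migration_time`, which works for *any* retention law
``k(phi)`` and is also what the synthetic-data generator uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .config import InstrumentConfig, MethodConditions
from .errors import InvalidParameterError

__all__ = [
    "SoluteLSS",
    "isocratic_k",
    "gradient_retention_time",
    "migration_time",
    "peak_sigma",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class SoluteLSS:
    """One compound's LSS law at a fixed (T, pH).

    ``log_kw`` may be ``-inf`` as an explicit unretained-marker sentinel
    (k = 0 at every composition); ``S`` must be finite.  ``S <= 0`` is
    physically unusual (retention increasing with organic content) and is
    flagged by the calibration fitter, but the forward model accepts it.
    """

    log_kw: float
    S: float

    def __post_init__(self) -> None:
        if math.isnan(self.log_kw) or self.log_kw == math.inf:
            raise InvalidParameterError(f"log_kw invalid: {self.log_kw!r}")
        if not math.isfinite(self.S):
            raise InvalidParameterError(f"S must be finite, got {self.S!r}")


def isocratic_k(solute: SoluteLSS, phi: float) -> float:
    """Isocratic retention factor k = 10**(log_kw - S*phi).

    ``phi`` must lie in [0, 1].
    """
    if not math.isfinite(phi) or not (0.0 <= phi <= 1.0):
        raise InvalidParameterError(f"phi must be in [0, 1], got {phi!r}")
    if solute.log_kw == -math.inf:
        return 0.0
    return 10.0 ** (solute.log_kw - solute.S * phi)


def migration_time(
    kfun: Callable[[np.ndarray], np.ndarray],
    cond: MethodConditions,
    instr: InstrumentConfig,
    n_grid: int = 4001,
) -> float:
    """Numerically solve the migration integral for an arbitrary k(phi).

    ``kfun`` maps organic fraction (scalar or ndarray) to retention factor.
    The dwell and post-gradient segments (constant composition) are handled
    analytically; the ramp segment is integrated on a dense trapezoid grid
    and the elution crossing refined by bracketed root finding on an
    adaptive-quadrature cumulative, so the result is accurate to well below
    1e-6 min for smooth retention laws.
    """
    t0 = instr.dead_time_min(cond.flow_mL_min)
    tD = instr.dwell_time_min(cond.flow_mL_min)
    k_start = float(kfun(cond.phi_start))
    if k_start <= 0.0:
        return t0
    # fraction of the column travelled during the isocratic dwell segment
    x_dwell = tD / (t0 * k_start)
    if x_dwell >= 1.0:
        return t0 * (1.0 + k_start)

    dphi = cond.phi_end - cond.phi_start
    ts = np.linspace(0.0, cond.tG_min, n_grid)
    phis = cond.phi_start + dphi * ts / cond.tG_min
    integrand = 1.0 / (t0 * np.asarray(kfun(phis), dtype=float))
    # cumulative trapezoid over the ramp
    steps = np.diff(ts) * 0.5 * (integrand[:-1] + integrand[1:])
    cum = np.concatenate(([0.0], np.cumsum(steps)))
    need = 1.0 - x_dwell

    if cum[-1] < need:
        # solute still on column when the gradient ends: finish isocratically
        k_end = float(kfun(cond.phi_end))
        if k_end <= 0.0:
            tau = tD + cond.tG_min
        else:
            tau = tD + cond.tG_min + (need - cum[-1]) * t0 * k_end
        return tau + t0

    idx = int(np.searchsorted(cum, need))
    idx = max(1, min(idx, n_grid - 1))
    lo, hi = ts[idx - 1], ts[idx]
    base = cum[idx - 1]

    def scalar_integrand(t: float) -> float:
        phi = cond.phi_start + dphi * t / cond.tG_min
        return 1.0 / (t0 * float(kfun(phi)))

    def deficit(t: float) -> float:
        return base + quad(scalar_integrand, lo, t, limit=200)[0] - need

    f_lo, f_hi = base - need, deficit(hi)
    if f_lo >= 0.0:
        t_cross = lo
    elif f_hi <= 0.0:
        t_cross = hi
    else:
        t_cross = brentq(deficit, lo, hi, xtol=1e-12)
    return tD + t_cross + t0


def gradient_retention_time(
    solute: SoluteLSS, cond: MethodConditions, instr: InstrumentConfig
) -> float:
    """Retention time (min) of an LSS solute under a linear gradient.

    Three regimes, all returned as one number:

    (i)  the solute elutes before the delayed gradient catches it
         -> isocratic at phi_start, tR = t0*(1+k0);
    (ii) elution during the ramp -> closed-form LSS solution;
    (iii) elution after the ramp ends -> numerical migration integral,
         continuing isocratically at phi_end.

    Degenerate steepness (S = 0 or phi_end = phi_start is impossible by
    construction of MethodConditions, but S = 0 is allowed) falls back to
    the isocratic limit, and an unretained solute returns t0.
    """
    t0 = instr.dead_time_min(cond.flow_mL_min)
    tD = instr.dwell_time_min(cond.flow_mL_min)
    k0 = isocratic_k(solute, cond.phi_start)
    if k0 <= 0.0:
        return t0

    dphi = cond.phi_end - cond.phi_start
    b = t0 * dphi * solute.S / cond.tG_min
    if b == 0.0:
        return t0 * (1.0 + k0)

    x_dwell = tD / (t0 * k0)
    if x_dwell >= 1.0:
        return t0 * (1.0 + k0)

    arg = LN10 * k0 * b * (1.0 - x_dwell) + 1.0
    if arg <= 0.0:
        # negative steepness so extreme the solute never elutes in the ramp
        return migration_time(
            lambda phi: 10.0 ** (solute.log_kw - solute.S * np.asarray(phi)),
            cond,
            instr,
        )
    tR = t0 + tD + (t0 / b) * math.log10(arg)
    if tR > tD + cond.tG_min + t0:
        # regime (iii): the band is still on column when the ramp ends
        return migration_time(
            lambda phi: 10.0 ** (solute.log_kw - solute.S * np.asarray(phi)),
            cond,
            instr,
        )
    return tR


def peak_sigma(
    solute: SoluteLSS,
    cond: MethodConditions,
    instr: InstrumentConfig,
    tR_min: float,
) -> float:
    """Gaussian peak standard deviation (min).

    sigma = (t0 / sqrt(N)) * (1 + k_e), with k_e the isocratic retention
    factor at the inlet composition at time (tR - t0), i.e. approximately
    the local retention factor of the band as it leaves the column.  Any
    gradient peak-compression factor is absorbed into the apparent N.
    """
    t0 = instr.dead_time_min(cond.flow_mL_min)
    phi_e = cond.inlet_fraction(max(tR_min - t0, 0.0), instr)
    k_e = isocratic_k(solute, phi_e)
    return (t0 / math.sqrt(instr.plate_number)) * (1.0 + k_e)
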