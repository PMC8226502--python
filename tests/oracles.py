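"""Independent numerical oracles used by the test suite.

The gradient-elution oracle here solves the migration integral

    integral_0^tau dt / (t0 * k(phi_inlet(t))) = 1,    tR = tau + t0

by piecewise adaptive quadrature plus bracketed root finding, sharing no
code with the package's closed-form solution or its trapezoid-grid solver.
"""

from __future__ import annotations

from scipy.integrate import quad
from scipy.optimize import brentq


def oracle_gradient_tr(log_kw, S, cond, instr, rtol=1e-11):
    """Gradient retention time of an LSS solute by direct quadrature."""
    t0 = instr.dead_volume_mL / cond.flow_mL_min
    tD = instr.dwell_volume_mL / cond.flow_mL_min
    tG = cond.tG_min

    def k_at(t):
        if t <= tD:
            phi = cond.phi_start
        elif t >= tD + tG:
            phi = cond.phi_end
        else:
            phi = cond.phi_start + (cond.phi_end - cond.phi_start) * (t - tD) / tG
        return 10.0 ** (log_kw - S * phi)

    k0 = k_at(0.0)
    if k0 <= 0.0:
        return t0

    def integral(tau):
        total = 0.0
        segments = [(0.0, tD), (tD, tD + tG), (tD + tG, float("inf"))]
        for lo, hi in segments:
            if tau <= lo:
                break
            hi = min(hi, tau)
            total += quad(
                lambda t: 1.0 / (t0 * k_at(t)), lo, hi,
                epsabs=rtol, epsrel=rtol, limit=500,
            )[0]
        return total

    # bracket the elution time: the integral is monotone increasing in tau
    tau_hi = t0 * k0
    while integral(tau_hi) < 1.0:
        tau_hi *= 2.0
        if tau_hi > 1e6:
            raise RuntimeError("oracle failed to bracket the elution time")
    tau = brentq(lambda t: integral(t) - 1.0, 0.0, tau_hi, xtol=1e-12)
    return tau + t0
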