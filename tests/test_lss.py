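"""Core LSS retention physics: isocratic law, gradient regimes, widths."""

import math

import pytest
from hypothesis import given, strategies as st

from chromspace import (
    DEFAULT_INSTRUMENT,
    MethodConditions,
    SoluteLSS,
    gradient_retention_time,
    isocratic_k,
    migration_time,
    peak_sigma,
)
from chromspace.config import InstrumentConfig
from chromspace.errors import InvalidParameterError

from .oracles import oracle_gradient_tr

COND = MethodConditions(tG_min=3.0, T_C=40.0, pH=6.0)


@pytest.mark.parametrize(
    "log_kw,S,phi,expected",
    [
        (0.0, 0.0, 0.5, 1.0),       # identity
        (2.0, 4.0, 0.5, 1.0),       # exponent cancels
        (3.0, 10.0, 0.1, 100.0),    # 10**(3-1)
    ],
)
def test_isocratic_k_examples(log_kw, S, phi, expected):
    assert isocratic_k(SoluteLSS(log_kw, S), phi) == pytest.approx(expected)


def test_isocratic_k_rejects_bad_phi():
    with pytest.raises(InvalidParameterError):
        isocratic_k(SoluteLSS(1.0, 5.0), 1.5)
    with pytest.raises(InvalidParameterError):
        isocratic_k(SoluteLSS(1.0, 5.0), math.nan)


def test_solute_rejects_nonfinite_parameters():
    with pytest.raises(InvalidParameterError):
        SoluteLSS(math.nan, 1.0)
    with pytest.raises(InvalidParameterError):
        SoluteLSS(1.0, math.inf)


def test_zero_steepness_gives_isocratic_limit(instr):
    solute = SoluteLSS(0.7, 0.0)
    k = isocratic_k(solute, COND.phi_start)
    expected = instr.dead_time_min(COND.flow_mL_min) * (1.0 + k)
    assert gradient_retention_time(solute, COND, instr) == pytest.approx(expected)


def test_unretained_sentinel_elutes_at_dead_time(instr):
    solute = SoluteLSS(-math.inf, 5.0)
    t0 = instr.dead_time_min(COND.flow_mL_min)
    assert gradient_retention_time(solute, COND, instr) == pytest.approx(t0)


def test_dwell_dominated_solute_elutes_isocratically(instr):
    # k0 so small the band leaves during the gradient delay
    solute = SoluteLSS(-0.3, 3.0)
    t0 = instr.dead_time_min(COND.flow_mL_min)
    k0 = isocratic_k(solute, COND.phi_start)
    assert t0 * k0 <= instr.dwell_time_min(COND.flow_mL_min)
    assert gradient_retention_time(solute, COND, instr) == pytest.approx(
        t0 * (1.0 + k0)
    )


def test_closed_form_matches_oracle_reference_case(instr):
    """The spec-level reference case agrees with the quadrature oracle."""
    solute = SoluteLSS(3.0, 10.0)
    cond = MethodConditions(tG_min=3.0, T_C=40.0, pH=6.0, flow_mL_min=0.8)
    got = gradient_retention_time(solute, cond, instr)
    want = oracle_gradient_tr(3.0, 10.0, cond, instr)
    assert got == pytest.approx(want, abs=1e-4)


def test_post_gradient_elution_matches_oracle(instr):
    """A solute still on column at gradient end is finished isocratically."""
    solute = SoluteLSS(6.0, 4.0)  # very retained, shallow ramp
    cond = MethodConditions(tG_min=0.5, T_C=40.0, pH=6.0)
    t0 = instr.dead_time_min(cond.flow_mL_min)
    tD = instr.dwell_time_min(cond.flow_mL_min)
    got = gradient_retention_time(solute, cond, instr)
    assert got > tD + cond.tG_min + t0  # genuinely post-gradient
    assert got == pytest.approx(oracle_gradient_tr(6.0, 4.0, cond, instr), abs=1e-4)


def test_migration_time_general_law_matches_oracle(instr):
    """The generic numerical solver agrees with quadrature for an LSS law."""
    import numpy as np

    got = migration_time(
        lambda phi: 10.0 ** (2.4 - 3.0 * np.asarray(phi)), COND, instr
    )
    want = oracle_gradient_tr(2.4, 3.0, COND, instr)
    assert got == pytest.approx(want, abs=1e-6)


def test_isocratic_limit_of_narrow_gradient(instr):
    """As the %B span shrinks, gradient elution approaches isocratic."""
    solute = SoluteLSS(0.9, 3.0)
    t0 = instr.dead_time_min(0.8)
    k0 = isocratic_k(solute, 0.10)
    cond = MethodConditions(
        tG_min=3.0, T_C=40.0, pH=6.0, phi_start=0.10, phi_end=0.10 + 1e-7
    )
    assert gradient_retention_time(solute, cond, instr) == pytest.approx(
        t0 * (1.0 + k0), abs=1e-3
    )


@given(
    log_kw=st.floats(1.0, 3.0),
    S=st.floats(2.0, 8.0),
    bump=st.floats(0.01, 0.10),
)
def test_stronger_initial_eluent_never_increases_retention(log_kw, S, bump):
    instr = DEFAULT_INSTRUMENT
    solute = SoluteLSS(log_kw, S)
    base = MethodConditions(tG_min=3.0, T_C=40.0, pH=6.0, phi_start=0.10)
    pushed = base.with_(phi_start=0.10 + bump)
    tr_base = gradient_retention_time(solute, base, instr)
    tr_pushed = gradient_retention_time(solute, pushed, instr)
    assert tr_pushed <= tr_base + 1e-9


@given(
    log_kw=st.floats(1.0, 3.0),
    S=st.floats(2.0, 8.0),
    factor=st.floats(1.1, 2.0),
)
def test_higher_flow_never_increases_retention(log_kw, S, factor):
    instr = DEFAULT_INSTRUMENT
    solute = SoluteLSS(log_kw, S)
    slow = MethodConditions(tG_min=3.0, T_C=40.0, pH=6.0, flow_mL_min=0.8)
    fast = slow.with_(flow_mL_min=0.8 * factor)
    assert gradient_retention_time(solute, fast, instr) <= (
        gradient_retention_time(solute, slow, instr) + 1e-9
    )


def test_peak_sigma_direct_formula():
    instr = InstrumentConfig(dead_volume_mL=0.110, plate_number=10_000.0)
    # k_e = 1 at the clamped start composition: log_kw = S*phi_start
    solute = SoluteLSS(0.3, 3.0)
    cond = MethodConditions(tG_min=3.0, T_C=40.0, pH=6.0)
    t0 = instr.dead_time_min(cond.flow_mL_min)
    sigma = peak_sigma(solute, cond, instr, t0 * 1.5)  # still in the dwell
    assert sigma == pytest.approx((t0 / 100.0) * 2.0)


def test_peak_sigma_unretained_floor(instr):
    solute = SoluteLSS(-math.inf, 3.0)
    t0 = instr.dead_time_min(COND.flow_mL_min)
    sigma = peak_sigma(solute, COND, instr, t0)
    assert sigma == pytest.approx(t0 / math.sqrt(instr.plate_number))
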