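"""Calibration: LSS inversion, model fitting and (T, pH) interpolation."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from chromspace import (
    CalibrationDesign,
    FittedModel,
    MethodConditions,
    NoiseSpec,
    RunTable,
    SoluteLSS,
    fit_model,
    generate_run_table,
    gradient_retention_time,
    interpolate_params,
    invert_two_gradients,
    predict,
)
from chromspace.errors import (
    ExtrapolationWarning,
    InputError,
    InterpolationError,
    RangeError,
    UnretainedSoluteError,
)
from chromspace.synthetic import simulate_retention_time

from .conftest import WORKING_POINT


def _two_conditions(design):
    return (
        design.conditions(design.tG_levels[0], 40.0, 6.0),
        design.conditions(design.tG_levels[1], 40.0, 6.0),
    )


def test_invert_recovers_known_parameters(design, instr):
    truth = SoluteLSS(2.8, 12.0)
    c1, c2 = _two_conditions(design)
    tr1 = gradient_retention_time(truth, c1, instr)
    tr2 = gradient_retention_time(truth, c2, instr)
    got = invert_two_gradients(tr1, tr2, c1, c2, instr)
    assert abs(got.log_kw - truth.log_kw) <= 1e-3
    assert abs(got.S - truth.S) <= 1e-2


def test_invert_equal_times_flags_gradient_insensitive_solute(design, instr):
    c1, c2 = _two_conditions(design)
    t0 = instr.dead_time_min(c1.flow_mL_min)
    tr = t0 * (1.0 + 5.0)
    got = invert_two_gradients(tr, tr, c1, c2, instr)
    assert got.S == 0.0
    assert got.log_kw == pytest.approx(math.log10(5.0))


def test_invert_rejects_unretained_peak(design, instr):
    c1, c2 = _two_conditions(design)
    t0 = instr.dead_time_min(c1.flow_mL_min)
    with pytest.raises(UnretainedSoluteError):
        invert_two_gradients(t0, t0 * 2, c1, c2, instr)


def test_invert_requires_conditions_differing_only_in_tG(design, instr):
    c1, _ = _two_conditions(design)
    with pytest.raises(InputError):
        invert_two_gradients(1.0, 1.2, c1, c1.with_(T_C=50.0, tG_min=4.5), instr)


def test_invert_roundtrip_sweep_heldout_gradient(design, instr):
    """Random (log_kw, S) pairs are recovered well enough that a third,
    held-out gradient time is predicted to within 1e-3 min."""
    rng = np.random.default_rng(7)
    c1, c2 = _two_conditions(design)
    held_out = c1.with_(tG_min=3.0)
    t0 = instr.dead_time_min(c1.flow_mL_min)
    n_done = 0
    while n_done < 25:
        truth = SoluteLSS(rng.uniform(1.0, 5.0), rng.uniform(3.0, 30.0))
        tr1 = gradient_retention_time(truth, c1, instr)
        if tr1 < t0 * 1.3:  # effectively unretained draw; resample
            continue
        tr2 = gradient_retention_time(truth, c2, instr)
        got = invert_two_gradients(tr1, tr2, c1, c2, instr)
        want = gradient_retention_time(truth, held_out, instr)
        have = gradient_retention_time(got, held_out, instr)
        assert abs(have - want) <= 1e-3
        n_done += 1


def test_fit_model_noise_free_residuals(fitted_model):
    """All 9 compounds fit at all 6 corners, reproducing the calibration
    times to solver precision."""
    diag = fitted_model.diagnostics
    assert len(fitted_model.compounds) == 9
    assert len(diag) == 54
    assert (diag["flags"] == "").all()
    assert diag["residual_min"].max() <= 1e-6


def test_fit_model_flags_degraded_corner(mixture, instr):
    """Stm2 is lost at the harsh (80 C, pH 6.4) corner but the model still
    fits everywhere else."""
    harsh = CalibrationDesign(T_levels=(20.0, 80.0))
    table = generate_run_table(mixture, harsh, instr, NoiseSpec(seed=3))
    model = fit_model(table, harsh, instr)
    assert model.corner("Stm2", 1, 2) is None
    assert model.corner("Stm2", 0, 2) is not None
    diag = model.diagnostics
    row = diag[(diag.compound_id == "Stm2") & (diag.T_C == 80.0) & (diag.pH == 6.4)]
    assert list(row["flags"]) == ["unfitted_missing_run"]
    with pytest.raises(InterpolationError):
        interpolate_params(model, "Stm2", 70.0, 6.0)


def test_run_table_rejects_duplicate_entries(clean_run_table):
    frame = clean_run_table.frame
    dup = pd.concat([frame, frame.iloc[[0]]], ignore_index=True)
    with pytest.raises(InputError, match="duplicate"):
        RunTable(dup)


def test_interpolation_identity_at_corners(fitted_model, design):
    for ti, T in enumerate(design.T_levels):
        for pj, pH in enumerate(design.pH_levels):
            got = interpolate_params(fitted_model, "Apixaban", T, pH)
            corner = fitted_model.corner("Apixaban", ti, pj)
            assert got.log_kw == pytest.approx(corner.log_kw, abs=1e-12)
            assert got.S == pytest.approx(corner.S, abs=1e-12)


def _synthetic_model(design, fn):
    """FittedModel whose corner parameters follow fn(T_C, pH) -> (lkw, S)."""
    params = {"X": {}}
    for ti, T in enumerate(design.T_levels):
        for pj, pH in enumerate(design.pH_levels):
            lkw, S = fn(T, pH)
            params["X"][(ti, pj)] = SoluteLSS(lkw, S)
    return FittedModel(design=design, params=params)


def test_collinear_pH_corners_interpolate_linearly(design):
    """A parabola through collinear points degenerates to the line."""
    model = _synthetic_model(design, lambda T, pH: (1.0 + 0.5 * pH, 5.0))
    mid = 0.5 * (design.pH_levels[0] + design.pH_levels[1])
    got = interpolate_params(model, "X", design.T_levels[0], mid)
    assert got.log_kw == pytest.approx(1.0 + 0.5 * mid, abs=1e-12)


def test_interpolation_recovers_matched_model_class(design):
    """Truth linear in 1/T(K) and quadratic in pH is recovered exactly at
    random interior (T, pH) points."""

    def fn(T, pH):
        x = 1.0 / (T + 273.15)
        return (0.4 + 900.0 * x + 0.08 * pH - 0.012 * pH**2, 4.0 + 300.0 * x)

    model = _synthetic_model(design, fn)
    rng = np.random.default_rng(11)
    for _ in range(20):
        T = rng.uniform(*design.T_levels)
        pH = rng.uniform(design.pH_levels[0], design.pH_levels[-1])
        got = interpolate_params(model, "X", T, pH)
        lkw, S = fn(T, pH)
        assert got.log_kw == pytest.approx(lkw, abs=1e-10)
        assert got.S == pytest.approx(S, abs=1e-10)


def test_interpolation_orders_commute(fitted_model, design):
    """Tensor-product interpolation gives the same answer as sequential
    1-D interpolation in either order."""
    T_q, pH_q = 37.5, 5.1
    x = 1.0 / (T_q + 273.15)
    x1, x2 = (1.0 / (t + 273.15) for t in design.T_levels)
    wT = ((x2 - x) / (x2 - x1), (x - x1) / (x2 - x1))
    p = design.pH_levels
    wP = []
    for j in range(3):
        others = [p[m] for m in range(3) if m != j]
        wP.append(
            (pH_q - others[0]) * (pH_q - others[1])
            / ((p[j] - others[0]) * (p[j] - others[1]))
        )
    corners = {
        (ti, pj): fitted_model.corner("Int1", ti, pj)
        for ti in range(2)
        for pj in range(3)
    }
    # T first, then pH
    t_first = sum(
        wP[pj] * sum(wT[ti] * corners[(ti, pj)].log_kw for ti in range(2))
        for pj in range(3)
    )
    # pH first, then T
    p_first = sum(
        wT[ti] * sum(wP[pj] * corners[(ti, pj)].log_kw for pj in range(3))
        for ti in range(2)
    )
    direct = interpolate_params(fitted_model, "Int1", T_q, pH_q).log_kw
    assert t_first == pytest.approx(p_first, abs=1e-14)
    assert direct == pytest.approx(t_first, abs=1e-12)


def test_extrapolation_margin_warns_then_errors(fitted_model):
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        with pytest.raises(ExtrapolationWarning):
            interpolate_params(fitted_model, "Apixaban", 52.0, 6.0)
    with pytest.raises(RangeError):
        interpolate_params(fitted_model, "Apixaban", 60.0, 6.0)
    with pytest.raises(RangeError):
        interpolate_params(fitted_model, "Apixaban", 40.0, 7.2)


def test_predict_reproduces_calibration_runs(fitted_model, clean_run_table, instr):
    """Self-consistency: predicting at a calibration run's conditions
    reproduces the simulated retention times to within the fit residual."""
    for run_id in ("R01", "R08"):
        rows = clean_run_table.frame[clean_run_table.frame.run_id == run_id]
        cond = MethodConditions(
            tG_min=float(rows.tG_min.iloc[0]),
            T_C=float(rows.T_C.iloc[0]),
            pH=float(rows.pH.iloc[0]),
            flow_mL_min=float(rows.flow_mL_min.iloc[0]),
            phi_start=float(rows.pctB_start.iloc[0]) / 100.0,
            phi_end=float(rows.pctB_end.iloc[0]) / 100.0,
        )
        pred = {p.compound_id: p.tR_min for p in predict(fitted_model, cond, instr).peaks}
        for _, row in rows.iterrows():
            assert pred[row.compound_id] == pytest.approx(row.tR_min, abs=1e-5)


def test_predict_working_point_elution_order(fitted_model, instr):
    """The fitted fixture reproduces the mixture's elution order at the
    nominal working point."""
    chrom = predict(fitted_model, WORKING_POINT, instr)
    assert chrom.compound_order == [
        "Int6", "Stm1", "Apixaban", "Int2", "Int1", "Int5", "Stm2", "Int4", "Int3",
    ]


def test_predict_matches_truth_at_perturbed_corner_conditions(
    fitted_model, mixture, instr, design
):
    """At calibration (T, pH) corners the fit is exact, so predictions at
    perturbed tG / flow / %B match the generator's forward simulation."""
    perturbed = [
        dict(tG_min=2.2, T_C=20.0, pH=2.8),
        dict(tG_min=3.7, T_C=50.0, pH=6.4, flow_mL_min=0.9),
        dict(tG_min=3.0, T_C=20.0, pH=4.6, phi_start=0.12),
        dict(tG_min=2.6, T_C=50.0, pH=2.8, phi_end=0.75),
        dict(tG_min=4.2, T_C=20.0, pH=6.4, flow_mL_min=0.7),
        dict(tG_min=1.8, T_C=50.0, pH=4.6),
    ]
    for kw in perturbed:
        cond = MethodConditions(**{"flow_mL_min": 0.8, **kw})
        pred = {p.compound_id: p.tR_min for p in predict(fitted_model, cond, instr).peaks}
        for solute in mixture:
            want = simulate_retention_time(solute, cond, instr)
            assert pred[solute.compound_id] == pytest.approx(want, abs=1e-3)
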