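"""UV response correction factors and corrected area-percent purity.

Raw peak areas over-/under-state the amount of a compound whose specific UV
absorbance differs from the reference compound's.  The pairwise correction
factor f[i][j] is the ratio of detector response slopes, slope_i / slope_j,
so a consistent matrix is multiplicative: f[i][j] * f[j][k] = f[i][k].
Corrected area-percent weights each raw area by the factor of the reference
row; the result is independent of which compound is chosen as reference.

``apixaban_correction_factors`` ships the published pairwise factors of the
apixaban mixture measured at 280 nm (upper triangle as printed; the lower
triangle is reconstructed by reciprocal symmetry on load).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, List, Mapping, Optional, Tuple

import math

import numpy as np
import pandas as pd

from .errors import InputError, QuantitationError

__all__ = [
    "FactorMatrix",
    "factor_matrix_from_responses",
    "consistency_check",
    "corrected_area_percent",
    "apixaban_correction_factors",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Report-style rounding: 2 decimals by default, ties away from zero."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class FactorMatrix:
    """Pairwise correction factors with a fixed compound order.

    ``values[i, j]`` is f[i][j] (NaN where unknown); the diagonal is
    exactly 1.
    """

    compounds: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.compounds)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n, n):
            raise InputError("factor matrix shape must match the compound list")
        if not np.allclose(np.diag(self.values), 1.0, atol=0.0):
            raise InputError("factor matrix diagonal must be exactly 1")
        present = self.values[~np.isnan(self.values)]
        if (present <= 0).any():
            raise InputError("all present correction factors must be > 0")

    def __getitem__(self, key: Tuple[str, str]) -> float:
        i = self.compounds.index(key[0])
        j = self.compounds.index(key[1])
        return float(self.values[i, j])

    def to_frame(self, decimals: Optional[int] = 2) -> pd.DataFrame:
        """Report view (2-decimal half-up by default); None = full precision."""
        v = self.values
        if decimals is not None:
            v = np.vectorize(
                lambda x: math.nan if np.isnan(x) else round_half_up(x, decimals)
            )(v)
        return pd.DataFrame(v, index=self.compounds, columns=self.compounds)


def factor_matrix_from_responses(slopes: Mapping[str, float]) -> FactorMatrix:
    """Build a full-precision factor matrix from per-compound response slopes.

    f[i][j] = slope_i / slope_j; the construction is exactly
    multiplicatively consistent.
    """
    compounds = list(slopes)
    arr = np.array([float(slopes[c]) for c in compounds])
    if (arr <= 0).any() or not np.isfinite(arr).all():
        raise InputError("response slopes must be finite and > 0")
    return FactorMatrix(compounds=compounds, values=arr[:, None] / arr[None, :])


def consistency_check(
    matrix: FactorMatrix, tol: float = 0.02
) -> List[Tuple[str, str, str]]:
    """All (i, j, k) triples violating |f[i][j]*f[j][k] - f[i][k]| <= tol.

    Triples with any missing entry are skipped.
    """
    v = matrix.values
    n = len(matrix.compounds)
    bad = []
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if len({i, j, k}) < 3:
                    continue
                a, b, c = v[i, j], v[j, k], v[i, k]
                if np.isnan(a) or np.isnan(b) or np.isnan(c):
                    continue
                if abs(a * b - c) > tol:
                    bad.append(
                        (
                            matrix.compounds[i],
                            matrix.compounds[j],
                            matrix.compounds[k],
                        )
                    )
    return bad


def corrected_area_percent(
    areas: Mapping[str, float],
    factors: FactorMatrix,
    reference: str,
) -> Dict[str, float]:
    """Corrected area-percent of each compound.

    percent_i = 100 * area_i * f[ref][i] / sum_j area_j * f[ref][j].
    Percents sum to 100 (to 1e-9) and, with full-precision factors, do not
    depend on the reference choice.  A present peak (area > 0) without a
    factor to the reference raises a QuantitationError.
    """
    if reference not in factors.compounds:
        raise QuantitationError(f"reference {reference!r} not in the factor matrix")
    if any(a < 0 for a in areas.values()):
        raise InputError("areas must be >= 0")
    if not any(a > 0 for a in areas.values()):
        raise InputError("at least one area must be > 0")
    weighted = {}
    for compound, area in areas.items():
        if area == 0:
            weighted[compound] = 0.0
            continue
        if compound not in factors.compounds:
            raise QuantitationError(f"no correction factor for {compound!r}")
        f = factors[reference, compound]
        if np.isnan(f):
            raise QuantitationError(
                f"correction factor {reference!r} -> {compound!r} is missing"
            )
        weighted[compound] = area * f
    total = sum(weighted.values())
    return {c: 100.0 * w / total for c, w in weighted.items()}


# Pairwise correction factors of the apixaban mixture at 280 nm (upper
# triangle as published; '—' entries are absent).
_COMPOUNDS_280 = [
    "Stm1", "Int1", "Int2", "Stm2", "Int3", "Int4", "Int5", "Int6", "Apixaban",
]
_UPPER_280: Dict[Tuple[str, str], float] = {
    ("Stm1", "Int1"): 0.87, ("Stm1", "Int2"): 0.64, ("Stm1", "Int3"): 0.92,
    ("Stm1", "Int4"): 1.13, ("Stm1", "Int5"): 0.90, ("Stm1", "Int6"): 0.98,
    ("Stm1", "Apixaban"): 1.16,
    ("Int1", "Int2"): 0.73, ("Int1", "Int3"): 1.06, ("Int1", "Int4"): 1.30,
    ("Int1", "Int5"): 1.03, ("Int1", "Int6"): 1.13, ("Int1", "Apixaban"): 1.34,
    ("Int2", "Int3"): 1.44, ("Int2", "Int4"): 1.77, ("Int2", "Int5"): 1.41,
    ("Int2", "Int6"): 1.54, ("Int2", "Apixaban"): 1.82,
    ("Stm2", "Int3"): 1.88, ("Stm2", "Int4"): 2.32, ("Stm2", "Int5"): 1.84,
    ("Stm2", "Int6"): 2.01, ("Stm2", "Apixaban"): 2.38,
    ("Int3", "Int4"): 1.23, ("Int3", "Int5"): 0.98, ("Int3", "Int6"): 1.07,
    ("Int3", "Apixaban"): 1.27,
    ("Int4", "Int5"): 0.79, ("Int4", "Int6"): 0.87, ("Int4", "Apixaban"): 1.03,
    ("Int5", "Int6"): 1.09, ("Int5", "Apixaban"): 1.29,
    ("Int6", "Apixaban"): 1.19,
}


def apixaban_correction_factors() -> FactorMatrix:
    """Published 280 nm correction-factor matrix of the apixaban mixture.

    Missing lower-triangle entries are reconstructed by reciprocal symmetry
    f[j][i] = 1 / f[i][j]; pairs absent from the publication (the Stm2
    column of the upper triangle) stay NaN.
    """
    n = len(_COMPOUNDS_280)
    v = np.full((n, n), np.nan)
    np.fill_diagonal(v, 1.0)
    idx = {c: i for i, c in enumerate(_COMPOUNDS_280)}
    for (a, b), f in _UPPER_280.items():
        v[idx[a], idx[b]] = f
        v[idx[b], idx[a]] = 1.0 / f
    return FactorMatrix(compounds=list(_COMPOUNDS_280), values=v)
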