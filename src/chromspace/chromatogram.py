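"""Peaks, chromatograms and resolution metrics."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Tuple

import pandas as pd

from .config import MethodConditions
from .errors import InvalidParameterError, UndefinedResultError

__all__ = ["Peak", "Chromatogram", "resolution", "critical_resolution"]


@dataclass(frozen=True)
class Peak:
    compound_id: str
    tR_min: float
    sigma_min: float
    area: float = 1.0

    def __post_init__(self) -> None:
        for name in ("tR_min", "sigma_min", "area"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")
        if self.sigma_min <= 0:
            raise InvalidParameterError(f"sigma_min must be > 0, got {self.sigma_min}")
        if self.area < 0:
            raise InvalidParameterError(f"area must be >= 0, got {self.area}")


@dataclass(frozen=True)
class Chromatogram:
    """Peaks at one condition, sorted by retention time.

    Ties in tR are broken lexicographically by compound_id so the order is
    stable and reproducible.
    """

    conditions: MethodConditions
    peaks: Tuple[Peak, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ordered = tuple(
            sorted(self.peaks, key=lambda p: (p.tR_min, p.compound_id))
        )
        object.__setattr__(self, "peaks", ordered)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def compound_order(self) -> List[str]:
        return [p.compound_id for p in self.peaks]

    def to_frame(self, report: bool = False) -> pd.DataFrame:
        """Peak table; ``report=True`` rounds times to 2 decimals."""
        decimals = 2 if report else 4
        return pd.DataFrame(
            {
                "compound_id": [p.compound_id for p in self.peaks],
                "tR_min": [round(p.tR_min, decimals) for p in self.peaks],
                "sigma_min": [round(p.sigma_min, 4 if report else 6) for p in self.peaks],
                "area": [p.area for p in self.peaks],
            }
        )


def resolution(peak_a: Peak, peak_b: Peak) -> float:
    """USP-style width-based resolution of two Gaussian peaks.

    Rs = 2|tR_b - tR_a| / (4 sigma_a + 4 sigma_b); symmetric and >= 0.
    """
    return 2.0 * abs(peak_b.tR_min - peak_a.tR_min) / (
        4.0 * peak_a.sigma_min + 4.0 * peak_b.sigma_min
    )


def critical_resolution(chrom: Chromatogram) -> Tuple[float, Tuple[str, str]]:
    """Minimum resolution over adjacent peak pairs, with the pair's ids.

    Ties go to the earlier-eluting pair.  Raises for fewer than two peaks.
    """
    if len(chrom) < 2:
        raise UndefinedResultError(
            "critical resolution undefined for fewer than 2 peaks"
        )
    best_rs = math.inf
    best_pair: Tuple[str, str] = ("", "")
    for a, b in zip(chrom.peaks, chrom.peaks[1:]):
        rs = resolution(a, b)
        if rs < best_rs:  # strict: first (earliest) minimum wins ties
            best_rs = rs
            best_pair = (a.compound_id, b.compound_id)
    return best_rs, best_pair
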