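"""Delta-notation arithmetic and baseline-referenced trophic descriptors.

Stable isotope values are expressed in delta notation: the per-mil
deviation of a sample's heavy:light isotope ratio from an international
standard,

    deltaX = (R_sample / R_standard - 1) * 1000   [permil]

with R = 13C/12C (standard V-PDB) or 15N/14N (standard: atmospheric air).
delta15N tracks trophic position; delta13C tracks the basal carbon source.

No conversion to discrete trophic levels is performed: that would require
a trophic enrichment factor, and delta15N is used directly as a continuous
trophic proxy referenced to a long-lived filter-feeder baseline (rock
scallop, default 10.32 permil).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .records import IsotopeRecord

C13 = "C13"
N15 = "N15"


@dataclass(frozen=True, slots=True)
class IsotopeRatioPair:
    """Measured and standard heavy:light isotope ratios (both > 0)."""

    r_sample: float
    r_standard: float

    def __post_init__(self):
        if not (self.r_sample > 0 and self.r_standard > 0):
            raise ValueError(
                f"isotope ratios must be strictly positive, got "
                f"r_sample={self.r_sample}, r_standard={self.r_standard}")


@dataclass(frozen=True, slots=True)
class DeltaValue:
    """A delta-notation value in permil; bounded below by -1000 (positive ratio)."""

    element: str
    value: float

    def __post_init__(self):
        if self.element not in (C13, N15):
            raise ValueError(f"element must be {C13} or {N15}, got {self.element!r}")
        if not self.value > -1000.0:
            raise ValueError(f"delta value must exceed -1000 permil, got {self.value}")


def delta_from_ratios(pair: IsotopeRatioPair, element: str = C13) -> DeltaValue:
    """Delta value (permil) from a sample/standard ratio pair."""
    return DeltaValue(element, (pair.r_sample / pair.r_standard - 1.0) * 1000.0)


def ratio_quotient_from_delta(d: DeltaValue) -> float:
    """Inverse map: R_sample / R_standard = 1 + delta/1000 (dimensionless)."""
    return 1.0 + d.value / 1000.0


def baseline_offset(records: Iterable[IsotopeRecord] | Sequence[float],
                    baseline_d15n: float = 10.32) -> pd.Series:
    """delta15N offset of each fish above the shared invertebrate baseline.

    Accepts isotope records (indexed by fish id in the result) or a plain
    sequence of delta15N values.  The baseline used is attached as metadata
    (``result.attrs['baseline_d15n']``).
    """
    if not math.isfinite(baseline_d15n):
        raise ValueError("baseline_d15n must be finite")
    records = list(records)
    if records and isinstance(records[0], IsotopeRecord):
        out = pd.Series({r.fish_id: r.d15n - baseline_d15n for r in records},
                        name="d15n_offset", dtype=float)
    else:
        out = pd.Series([float(v) - baseline_d15n for v in records],
                        name="d15n_offset", dtype=float)
    out.attrs["baseline_d15n"] = baseline_d15n
    return out
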