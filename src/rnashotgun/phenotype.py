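"""Growth-curve doubling times and dual-luciferase frameshift-reporter ratios.

Doubling time is estimated by a least-squares fit of log2(OD) against time
over a caller-chosen exponential window (the window is an explicit argument —
auto-detecting it would be silent guessing).  The dual-luciferase readout
normalizes firefly (Fluc) counts against Renilla (Rluc) counts per replicate
and then against a reference strain's mean F/R, the standard proxy for +1
frameshifting at a hungry codon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GrowthCurve",
    "ReporterMeasurement",
    "doubling_time",
    "relative_pausing",
]


class PhenotypeError(ValueError):
    pass


@dataclass(frozen=True)
class GrowthCurve:
    times: np.ndarray  # minutes
    od: np.ndarray
    strain: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "od", np.asarray(self.od, dtype=float))
        if self.times.shape != self.od.shape:
            raise PhenotypeError("times and OD differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise PhenotypeError("times must be strictly increasing")


@dataclass(frozen=True)
class ReporterMeasurement:
    strain: str
    fluc: float
    rluc: float
    construct: str = ""

    def __post_init__(self) -> None:
        if self.rluc <= 0:
            raise PhenotypeError(f"{self.strain}: Rluc counts must be positive")

    @property
    def fr(self) -> float:
        return self.fluc / self.rluc


def doubling_time(curve: GrowthCurve, fit_window: Optional[tuple[float, float]] = None) -> float:
    """Exponential-phase doubling time in minutes.

    Fits log2(OD) = a + m·t by least squares over points inside the window
    (all points when None) with OD > 0, and returns 1/m.  At least three such
    points are required; a non-positive slope (no growth) is an error.
    """
    mask = curve.od > 0
    if fit_window is not None:
        lo, hi = fit_window
        mask &= (curve.times >= lo) & (curve.times <= hi)
    t, od = curve.times[mask], curve.od[mask]
    if len(t) < 3:
        raise PhenotypeError(
            f"{curve.strain or 'curve'}: need >= 3 positive-OD points in the fit window, got {len(t)}"
        )
    slope, _ = np.polyfit(t, np.log2(od), 1)
    if slope <= 0:
        raise PhenotypeError(f"{curve.strain or 'curve'}: non-positive growth rate")
    return 1.0 / slope


def relative_pausing(
    test: Sequence[ReporterMeasurement], reference: Sequence[ReporterMeasurement]
) -> tuple[float, float]:
    """Mean F/R of the test strain normalized to the reference mean F/R.

    Returns (ratio, SD) where SD is the standard deviation of per-replicate
    normalized values (0 with a single replicate), matching a means ± SD
    presentation.
    """
    if not test or not reference:
        raise PhenotypeError("need >= 1 replicate in both test and reference sets")
    ref_mean = float(np.mean([m.fr for m in reference]))
    if ref_mean <= 0:
        raise PhenotypeError("reference F/R mean is non-positive")
    normalized = np.array([m.fr for m in test]) / ref_mean
    sd = float(np.std(normalized, ddof=1)) if len(normalized) > 1 else 0.0
    return float(np.mean(normalized)), sd
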