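"""Standard-curve calibration: Cq -> copy number.

Quantification uses the standard-curve method: an ordinary least-squares
regression of Cq on log10(copies) over the known-copy calibration wells,
fitted separately per gene and per baseline/threshold setting (the Cq scale
shifts with the setting).  Unknowns are then read off the line,
``copies = 10**((cq - intercept) / slope)``.  Replicate standards enter the
fit as individual points, not level means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _st

from .plate import WellRecord


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationPoint:
    log10_copies: float
    cq: float


@dataclass(frozen=True)
class StandardCurve:
    """Fitted linear calibration.

    slope is in cycles per decade (expected negative, -3.32 for perfect
    doubling); intercept is the Cq extrapolated for a single copy.
    """

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    @property
    def efficiency(self) -> float:
        return amplification_efficiency(self)

    def cq_to_copies(self, cq: float) -> float:
        return cq_to_copies(self, cq)

    def copies_to_cq(self, copies: float) -> float:
        if copies <= 0:
            raise CalibrationError("copies must be > 0")
        return self.slope * math.log10(copies) + self.intercept


def fit_standard_curve(points: Sequence[CalibrationPoint]) -> StandardCurve:
    """OLS fit of cq on log10(copies); needs >= 2 distinct levels.

    Undetermined wells must have been excluded beforehand.
    """
    if not points:
        raise CalibrationError("no calibration points (all Cq undetermined?)")
    x = np.array([p.log10_copies for p in points], dtype=float)
    y = np.array([p.cq for p in points], dtype=float)
    if len(np.unique(x)) < 2:
        raise CalibrationError(
            "standard curve needs at least 2 distinct concentration levels"
        )
    res = _st.linregress(x, y)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        n_points=len(points),
    )


def points_from_records(records: Iterable[WellRecord]) -> list[CalibrationPoint]:
    """Calibration points from standard wells, skipping undetermined Cq."""
    return [
        CalibrationPoint(log10_copies=math.log10(r.known_copies), cq=r.cq)
        for r in records
        if r.task == "standard" and r.cq is not None
    ]


def fit_curve_from_records(records: Iterable[WellRecord]) -> StandardCurve:
    return fit_standard_curve(points_from_records(records))


def cq_to_copies(curve: StandardCurve, cq: float) -> float:
    """Invert the calibration line; strictly decreasing in cq for the usual
    negative slope."""
    if curve.slope == 0:
        raise CalibrationError("degenerate standard curve: slope is 0")
    if not math.isfinite(cq):
        raise CalibrationError(f"non-finite Cq {cq!r}")
    return 10.0 ** ((cq - curve.intercept) / curve.slope)


def amplification_efficiency(curve: StandardCurve) -> float:
    """Per-cycle efficiency 10**(-1/slope) - 1; 1.0 means perfect doubling."""
    if curve.slope >= 0:
        raise CalibrationError(
            f"efficiency undefined for non-negative slope {curve.slope}"
        )
    return 10.0 ** (-1.0 / curve.slope) - 1.0


def validate_ntc(records: Iterable[WellRecord], max_cq: float | None = None) -> None:
    """No-template controls must be undetermined, or (if ``max_cq`` is given)
    may amplify only beyond that cut.  NTC wells never enter fits."""
    for r in records:
        if r.task != "ntc" or r.cq is None:
            continue
        if max_cq is None or r.cq <= max_cq:
            raise CalibrationError(
                f"NTC well {r.position} amplified (Cq {r.cq}); "
                "possible contamination"
            )
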