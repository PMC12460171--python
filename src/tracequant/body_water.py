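"""Body-water 2H enrichment via the acetone-exchange standard curve.

After a 2H2O dose, body-water deuterium equilibrates with acetone under
base catalysis; the 2H1-acetone fraction read by LC-MS is linear in the
water 2H fraction.  A serial dilution of 2H2O in naturally labelled
water gives the standard curve, and serum samples are inverted through
it.  The curve keeps its intercept (natural 2H background gives a
nonzero blank) and inverted values that scatter below the blank are
clamped to zero with a warning rather than erroring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BodyWaterStandard:
    """One calibration point: known water 2H fraction vs measured 2H1-acetone."""

    known_fraction: float
    acetone_h1_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.known_fraction < 1.0:
            raise ValueError(f"known_fraction must be in [0, 1), got {self.known_fraction}")
        if not 0.0 <= self.acetone_h1_fraction < 1.0:
            raise ValueError(
                f"acetone_h1_fraction must be in [0, 1), got {self.acetone_h1_fraction}"
            )


@dataclass(frozen=True)
class LinearCalibration:
    """OLS line ``response = slope * x + intercept`` with fit diagnostics."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    slope_stderr: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a calibration needs at least 2 points")

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept

    def invert(self, response: float) -> float:
        if self.slope == 0:
            raise ValueError("cannot invert a calibration with zero slope")
        return (response - self.intercept) / self.slope


def fit_line(x: Sequence[float], y: Sequence[float]) -> LinearCalibration:
    """Ordinary least-squares line fit shared by all calibration curves."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError(f"need >= 2 calibration points, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate calibration design: all x values identical")
    res = stats.linregress(x, y)
    return LinearCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0,
        n_points=int(x.size),
        slope_stderr=float(res.stderr),
    )


def fit_body_water_curve(standards: Iterable[BodyWaterStandard]) -> LinearCalibration:
    """Fit the acetone-exchange standard curve.

    Requires at least two distinct known fractions.  A non-positive
    slope is physically invalid (more 2H water must give more
    2H1-acetone) and is logged as a warning; inversion of such a curve
    raises.
    """
    standards = list(standards)
    curve = fit_line(
        [s.known_fraction for s in standards],
        [s.acetone_h1_fraction for s in standards],
    )
    if curve.slope <= 0:
        logger.warning(
            "body-water standard curve has non-positive slope %.4g; check standards",
            curve.slope,
        )
    return curve


def body_water_enrichment(acetone_h1: float, curve: LinearCalibration) -> float:
    """Invert a serum 2H1-acetone fraction through the standard curve.

    Returns the body-water 2H fraction clamped to [0, 1]; clamping is
    logged (blanks can scatter below the fitted intercept).
    """
    if curve.slope <= 0:
        raise ValueError(f"invalid standard curve: slope {curve.slope} <= 0")
    fraction = curve.invert(acetone_h1)
    if fraction < 0.0:
        logger.warning(
            "acetone 2H1 fraction %.5g below the curve blank; body water clamped to 0",
            acetone_h1,
        )
        return 0.0
    if fraction > 1.0:
        logger.warning("inverted body-water fraction %.5g above 1; clamped", fraction)
        return 1.0
    return float(fraction)
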