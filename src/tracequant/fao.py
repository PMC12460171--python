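"""Whole-body fatty-acid oxidation from 13CO2 breath traces.

Indirect-calorimetry cages report the 13CO2 / total-CO2 ratio at fixed
intervals after an oral 13C-palmitate (or 13C-acetate) dose.  The
instrument is calibrated to the 1.1% natural abundance of 13C, so the
oxidation signal is the excess above that baseline.  Two readouts:

* the initial appearance rate — the OLS slope of excess 13CO2 against
  time from dosing up to the (earliest) maximum of the trace;
* per-timepoint oxidation normalized to the circulating un-esterified
  13C-substrate enrichment, which removes differences in precursor
  availability between animals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from tracequant.body_water import fit_line

logger = logging.getLogger(__name__)

#: natural 13C abundance, the calibrated instrument baseline
NATURAL_13C_FRACTION = 0.011


@dataclass(frozen=True)
class CO2Trace:
    """13CO2/total-CO2 time series for one animal (minutes since dose)."""

    animal_id: str
    times: np.ndarray
    ratios: np.ndarray
    baseline_fraction: float = NATURAL_13C_FRACTION

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        ratios = np.asarray(self.ratios, dtype=float)
        if times.shape != ratios.shape:
            raise ValueError("times and ratios must have equal length")
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((ratios < 0) | (ratios > 1)):
            raise ValueError("CO2 ratios must lie in [0, 1]")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "ratios", ratios)


@dataclass(frozen=True)
class SubstrateEnrichmentTrace:
    """Circulating un-esterified 13C-substrate enrichment time series."""

    animal_id: str
    times: np.ndarray
    enrichments: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        enr = np.asarray(self.enrichments, dtype=float)
        if times.shape != enr.shape:
            raise ValueError("times and enrichments must have equal length")
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((enr < 0) | (enr > 1)):
            raise ValueError("enrichments must lie in [0, 1]")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "enrichments", enr)


@dataclass(frozen=True)
class SlopeToMax:
    """Initial 13CO2 appearance rate up to the trace maximum."""

    animal_id: str
    slope: float  # fraction per minute
    time_of_max: float  # minutes
    n_points: int


def excess_co2(trace: CO2Trace) -> np.ndarray:
    """Excess 13CO2 fraction above the natural-abundance baseline.

    Negative excess (ratio below the calibrated baseline) is floored at
    zero; the number of floored points is logged.
    """
    excess = trace.ratios - trace.baseline_fraction
    floored = int(np.sum(excess < 0))
    if floored:
        logger.warning(
            "animal %s: %d point(s) below the 13CO2 baseline floored to 0",
            trace.animal_id,
            floored,
        )
    return np.maximum(excess, 0.0)


def slope_to_max(trace: CO2Trace) -> SlopeToMax:
    """OLS slope of excess 13CO2 vs time from dosing through the maximum.

    Ties at the maximum resolve to the earliest time.  A trace whose
    maximum sits at the first point has no rising phase and raises.
    """
    if trace.times.size < 3:
        raise ValueError("slope_to_max needs >= 3 time points")
    excess = excess_co2(trace)
    i_max = int(np.argmax(excess))  # argmax returns the earliest tie
    if i_max == 0:
        raise ValueError(f"animal {trace.animal_id}: no rise (maximum at the first point)")
    fit = fit_line(trace.times[: i_max + 1], excess[: i_max + 1])
    return SlopeToMax(
        animal_id=trace.animal_id,
        slope=fit.slope,
        time_of_max=float(trace.times[i_max]),
        n_points=i_max + 1,
    )


def normalize_oxidation(
    trace: CO2Trace,
    substrate: SubstrateEnrichmentTrace,
    enrichment_floor: float = 0.001,
) -> tuple[np.ndarray, np.ndarray]:
    """Excess 13CO2 normalized to circulating substrate enrichment.

    The substrate enrichment is linearly interpolated to the CO2 time
    points; extrapolation outside the measured substrate span is
    refused.  Points where the interpolated enrichment falls at or below
    ``enrichment_floor`` are dropped with a warning (the ratio would be
    dominated by enrichment noise).

    Returns ``(times, normalized)`` for the retained points.
    """
    if trace.times[0] < substrate.times[0] or trace.times[-1] > substrate.times[-1]:
        raise ValueError(
            f"animal {trace.animal_id}: CO2 trace spans "
            f"[{trace.times[0]:g}, {trace.times[-1]:g}] min but substrate enrichment "
            f"covers only [{substrate.times[0]:g}, {substrate.times[-1]:g}] min"
        )
    excess = excess_co2(trace)
    divisor = np.interp(trace.times, substrate.times, substrate.enrichments)
    keep = divisor > enrichment_floor
    dropped = int(np.sum(~keep))
    if dropped:
        logger.warning(
            "animal %s: %d point(s) dropped (substrate enrichment <= %g)",
            trace.animal_id,
            dropped,
            enrichment_floor,
        )
    return trace.times[keep], excess[keep] / divisor[keep]
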