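"""Synthetic tracer-study generators.

Every generator emulates the statistical structure the estimators
assume, so the whole pipeline can be run and validated without any
instrument data.

* ``simulate_dnl_cohort`` — a 2H2O lipogenesis cohort.  Each animal's
  palmitate pool is a two-population mixture: a fraction ``1 - f`` of
  pre-existing unlabelled molecules and a fraction ``f`` synthesized
  during exposure, whose exchangeable hydrogens are labelled binomially
  at the body-water 2H probability.  That mixture is the minimal
  generative model under which the lipogenesis equations are exact.
  The labelling MID is forward-convolved with the deuterium natural
  abundance of all palmitate hydrogens, scaled to a total ion count and
  perturbed with multiplicative log-normal noise (the standard model
  for LC-MS ion counts).
* ``simulate_co2_traces`` — 13CO2 breath traces with a rise-then-decay
  excess ``A (1 - e^(-ka t)) e^(-ke t)`` on top of the 1.1% natural
  baseline, sampled at 40-min calorimetry intervals, plus a decaying
  circulating-substrate enrichment series.
* ``simulate_body_water_standards`` — the acetone-exchange serial
  dilution with Gaussian measurement noise.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from tracequant.fao import NATURAL_13C_FRACTION, CO2Trace, SubstrateEnrichmentTrace
from tracequant.body_water import BodyWaterStandard
from tracequant.na_correction import NaturalAbundanceModel, build_correction_matrix
from tracequant.peak_io import PeakRecord, SampleMeta, parse_formula

#: saponified palmitate anion as measured in negative mode
PALMITATE_FORMULA = "C16H31O2"
#: exchangeable hydrogens incorporated during palmitate synthesis
PALMITATE_EXCHANGEABLE_H = 22

# canonical acetone standard-curve parameters used when emitting
# per-sample acetone fractions (slope < 1: incomplete exchange plus the
# natural-2H blank at zero enrichment)
DEFAULT_ACETONE_SLOPE = 0.75
DEFAULT_ACETONE_INTERCEPT = 0.005
DEFAULT_STANDARD_FRACTIONS = (0.0, 0.01, 0.02, 0.04)

# study-shaped defaults: continuous-fructose (CF), inulin+fructose (IF)
# and delayed-inulin (CIF) groups with suppressed synthesis under inulin
DEFAULT_GROUP_DNL = MappingProxyType({"CF": 0.5, "IF": 0.25, "CIF": 0.3})

DOSE_TIME = pd.Timestamp("2024-01-01 18:00:00")
COLLECTION_TIME = pd.Timestamp("2024-01-02 09:00:00")  # 15 h later


@dataclass(frozen=True)
class SyntheticDesign:
    """Cohort design for the 2H2O lipogenesis generator."""

    groups: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_GROUP_DNL))
    n_per_group: int = 10
    n_sites: int = PALMITATE_EXCHANGEABLE_H
    body_water: float = 0.025
    intensity_cv: float = 0.05
    total_intensity: float = 1e6
    na_model: NaturalAbundanceModel = field(
        default_factory=lambda: NaturalAbundanceModel(tracer_element="H")
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0.0 <= f <= 1.0 for f in self.groups.values()):
            raise ValueError("group DNL fractions must lie in [0, 1]")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.intensity_cv < 0:
            raise ValueError("intensity_cv must be >= 0")
        if not 0.0 < self.body_water < 1.0:
            raise ValueError("body_water must be in (0, 1)")


@dataclass
class SimulatedCohort:
    records: list[PeakRecord]
    samples: list[SampleMeta]
    truth: pd.DataFrame  # sample_id, group, f, n_sites, body_water


def labelling_mid(f: float, n_sites: int, body_water: float, length: int) -> np.ndarray:
    """True tracer-labelling MID of the palmitate pool.

    Mixture ``(1 - f) * delta_0 + f * Binomial(n_sites, body_water)``
    embedded in a vector of the given length (the measured isotopologue
    axis spans all hydrogens, not just the exchangeable ones).
    """
    if length < n_sites + 1:
        raise ValueError("length must cover M0..M(n_sites)")
    mid = np.zeros(length)
    mid[: n_sites + 1] = f * stats.binom.pmf(np.arange(n_sites + 1), n_sites, body_water)
    mid[0] += 1.0 - f
    return mid


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_dnl_cohort(design: SyntheticDesign) -> SimulatedCohort:
    """Generate peak table + metadata + truth for a 2H2O DNL cohort."""
    rng = np.random.default_rng(design.seed)
    n_h = parse_formula(PALMITATE_FORMULA)["H"]
    A = build_correction_matrix(n_h, design.na_model)
    records: list[PeakRecord] = []
    samples: list[SampleMeta] = []
    truth_rows = []
    for group, f in design.groups.items():
        for k in range(design.n_per_group):
            sample_id = f"{group}_{k + 1:02d}"
            true_mid = labelling_mid(f, design.n_sites, design.body_water, n_h + 1)
            measured = A @ true_mid * design.total_intensity
            measured = measured * _lognormal_factors(rng, design.intensity_cv, measured.size)
            for i, intensity in enumerate(measured):
                records.append(
                    PeakRecord(
                        sample_id=sample_id,
                        metabolite="palmitate",
                        formula=PALMITATE_FORMULA,
                        tracer_element="H",
                        isotopologue_index=i,
                        intensity=float(intensity),
                    )
                )
            samples.append(
                SampleMeta(
                    sample_id=sample_id,
                    group=group,
                    dose_time=DOSE_TIME,
                    collection_time=COLLECTION_TIME,
                    body_water_acetone_fraction=DEFAULT_ACETONE_SLOPE * design.body_water
                    + DEFAULT_ACETONE_INTERCEPT,
                )
            )
            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "group": group,
                    "f": f,
                    "n_sites": design.n_sites,
                    "body_water": design.body_water,
                }
            )
    return SimulatedCohort(
        records=records,
        samples=samples,
        truth=pd.DataFrame(truth_rows),
    )


def co2_excess_curve(
    times: np.ndarray, amplitude: float, rise_rate: float, decay_rate: float
) -> np.ndarray:
    """Noise-free rise-then-decay excess 13CO2 curve."""
    return amplitude * (1.0 - np.exp(-rise_rate * times)) * np.exp(-decay_rate * times)


def simulate_co2_traces(
    n_per_group: int = 8,
    amplitudes: Mapping[str, float] | None = None,
    rise_rate: float = 0.02,
    decay_rate: float = 0.004,
    noise_cv: float = 0.10,
    seed: int = 0,
    duration_min: float = 480.0,
    interval_min: float = 40.0,
    substrate_e0: float = 0.15,
    substrate_decay: float = 0.003,
    baseline: float = NATURAL_13C_FRACTION,
) -> tuple[list[CO2Trace], list[SubstrateEnrichmentTrace], pd.DataFrame]:
    """Generate 13CO2 breath traces and substrate-enrichment series.

    Per-group amplitudes default to a 1.5x contrast between a control
    and a treated group.  Noise is multiplicative on the excess (the
    baseline itself is the calibrated instrument constant).
    """
    if rise_rate <= 0 or decay_rate <= 0:
        raise ValueError("rates must be > 0")
    amplitudes = dict(amplitudes) if amplitudes is not None else {"CF": 0.006, "IF": 0.004}
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_min + 0.5 * interval_min, interval_min)
    traces: list[CO2Trace] = []
    substrates: list[SubstrateEnrichmentTrace] = []
    truth_rows = []
    for group, amplitude in amplitudes.items():
        for k in range(n_per_group):
            animal_id = f"{group}_{k + 1:02d}"
            excess = co2_excess_curve(times, amplitude, rise_rate, decay_rate)
            excess = excess * _lognormal_factors(rng, noise_cv, excess.size)
            enr = substrate_e0 * np.exp(-substrate_decay * times)
            enr = np.clip(enr * _lognormal_factors(rng, noise_cv, enr.size), 0.0, 1.0)
            traces.append(
                CO2Trace(
                    animal_id=animal_id,
                    times=times,
                    ratios=np.clip(baseline + excess, 0.0, 1.0),
                    baseline_fraction=baseline,
                )
            )
            substrates.append(
                SubstrateEnrichmentTrace(animal_id=animal_id, times=times, enrichments=enr)
            )
            truth_rows.append(
                {
                    "animal_id": animal_id,
                    "group": group,
                    "amplitude": amplitude,
                    "rise_rate": rise_rate,
                    "decay_rate": decay_rate,
                }
            )
    return traces, substrates, pd.DataFrame(truth_rows)


def simulate_body_water_standards(
    fractions: Sequence[float] = DEFAULT_STANDARD_FRACTIONS,
    slope: float = DEFAULT_ACETONE_SLOPE,
    intercept: float = DEFAULT_ACETONE_INTERCEPT,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[BodyWaterStandard]:
    """Acetone-exchange standards along a line, with Gaussian noise."""
    fractions = list(fractions)
    if len(fractions) < 2:
        raise ValueError("need >= 2 standard fractions")
    rng = np.random.default_rng(seed)
    out = []
    for frac in fractions:
        response = slope * frac + intercept + rng.normal(0.0, noise_sd)
        out.append(
            BodyWaterStandard(
                known_fraction=frac,
                acetone_h1_fraction=float(np.clip(response, 0.0, 0.999)),
            )
        )
    return out
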