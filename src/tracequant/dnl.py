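"""De novo lipogenesis from 2H-palmitate MIDs and body-water enrichment.

The fraction of palmitate newly synthesized during 2H2O exposure is

    DNL = (2H enrichment) / (body water fraction * n)

where the 2H enrichment is the weighted isotopologue sum H1 + 2*H2 + 3*H3
and *n* is the number of exchangeable hydrogens — the palmitate hydrogen
positions that equilibrate with body water during synthesis.  Under
binomial labelling of the n exchangeable sites at the body-water
probability p, the doubly/singly labelled isotopomer ratio satisfies

    H2 / H1 = ((n - 1) / 2) * p / (1 - p)

so *n* is estimated per sample by algebraic inversion of that identity.
Dividing the DNL fraction by the hours elapsed since the 2H2O dose gives
the hourly synthesis rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from tracequant.enrichment import deuterium_enrichment

logger = logging.getLogger(__name__)


class UndefinedIsotopomerRatio(ValueError):
    """Raised when H1 = 0 so the H2/H1 ratio (and hence n) is undefined."""


@dataclass(frozen=True)
class DNLResult:
    """Per-sample lipogenesis output."""

    sample_id: str
    h_enrichment: float
    body_water: float
    n_exchangeable: float
    dnl_fraction: float
    dnl_rate_per_hour: float | None = None
    elapsed_hours: float | None = None
    qc_flags: tuple[str, ...] = field(default_factory=tuple)


def exchangeable_hydrogens(h2_to_h1_ratio: float, body_water: float) -> float:
    """Estimate the number of exchangeable hydrogens n.

    Inverts the binomial isotopomer-ratio identity:
    ``n = 1 + 2 * ratio * (1 - body_water) / body_water``.  Estimates
    below 1 (possible under noise) are clamped to 1 with a warning.
    """
    if not 0.0 < body_water < 1.0:
        raise ValueError(f"body_water must be strictly in (0, 1), got {body_water}")
    if h2_to_h1_ratio < 0:
        raise ValueError(f"isotopomer ratio must be >= 0, got {h2_to_h1_ratio}")
    n = 1.0 + 2.0 * h2_to_h1_ratio * (1.0 - body_water) / body_water
    if n < 1.0:  # unreachable with valid inputs, kept for safety
        logger.warning("estimated n %.3f < 1; clamped to 1", n)
        return 1.0
    return n


def dnl_fraction(h_enrichment: float, body_water: float, n: float) -> float:
    """Fraction of the palmitate pool newly synthesized (the DNL equation).

    Values above 1 are physically impossible and point at a calibration
    problem; they are returned as-is so QC can flag them (see
    :func:`dnl_from_mid`), never clamped.
    """
    if h_enrichment < 0:
        raise ValueError("h_enrichment must be >= 0")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    denom = body_water * n
    if denom <= 0:
        raise ValueError("body_water * n must be > 0")
    return h_enrichment / denom


def dnl_rate(dnl: float, elapsed_hours: float) -> float:
    """Hourly DNL rate: fraction synthesized divided by hours since dosing."""
    if elapsed_hours <= 0:
        raise ValueError(f"elapsed time must be > 0 h, got {elapsed_hours}")
    return dnl / elapsed_hours


def dnl_from_mid(
    mid: np.ndarray,
    body_water: float,
    elapsed_hours: float | None = None,
    sample_id: str = "",
) -> DNLResult:
    """Full per-sample DNL computation from a corrected palmitate MID.

    Chains the enrichment sum, the per-sample n estimate from the H2/H1
    ratio, the DNL fraction and (when the elapsed time is known) the
    hourly rate.  Raises :class:`UndefinedIsotopomerRatio` for an
    unlabelled sample (H1 = 0), which callers exclude with a reason.
    """
    de = deuterium_enrichment(mid)
    if de.h1 <= 1e-12:  # numerically zero after NNLS correction
        raise UndefinedIsotopomerRatio(
            f"sample {sample_id or '<unnamed>'}: 2H1 fraction is 0; H2/H1 undefined"
        )
    n = exchangeable_hydrogens(de.h2 / de.h1, body_water)
    fraction = dnl_fraction(de.enrichment, body_water, n)
    flags: list[str] = []
    if fraction > 1.0:
        flags.append("dnl_fraction>1")
    rate = None
    if elapsed_hours is not None:
        rate = dnl_rate(fraction, elapsed_hours)
    return DNLResult(
        sample_id=sample_id,
        h_enrichment=de.enrichment,
        body_water=body_water,
        n_exchangeable=n,
        dnl_fraction=fraction,
        dnl_rate_per_hour=rate,
        elapsed_hours=elapsed_hours,
        qc_flags=tuple(flags),
    )
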