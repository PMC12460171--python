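"""Labelling metrics computed from natural-abundance-corrected MIDs.

Two estimators: the carbon-weighted labelled ion count (each labelled
form weighted by the fraction of tracer atoms it carries, normalized to
the total pool for fractional labelling), and the deuterium enrichment
of palmitate, the weighted sum H1 + 2*H2 + 3*H3 over the first three
labelled isotopologues.  The deuterium sum is hard-truncated at M3 by
construction; the untruncated weighted sum is kept as a diagnostic so
the truncation bias is visible (for binomial labelling over 22 sites
the bias is ~1.5% relative at 2.5% body water and ~2.4% at 3%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class LabellingResult:
    metabolite: str
    sample_id: str
    labelled_ion_count: float
    fractional_labelling: float
    total_ion_count: float


@dataclass(frozen=True)
class DeuteriumEnrichment:
    """Palmitate 2H enrichment: h1 + 2*h2 + 3*h3 over isotopologue fractions."""

    h1: float
    h2: float
    h3: float
    enrichment: float
    #: full weighted sum over all isotopologues, kept as a truncation diagnostic
    untruncated: float


def labelled_ion_count(
    mid: np.ndarray,
    total_intensity: float,
    n_atoms: int,
    metabolite: str = "",
    sample_id: str = "",
) -> LabellingResult:
    """Atom-weighted labelled ion count and fractional labelling.

    ``fractional_labelling = sum_i (i / n_atoms) * mid[i]`` — the
    per-atom tracer enrichment of the pool; the labelled ion count is
    that fraction scaled by the total ion count.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    if total_intensity <= 0:
        raise ValueError("total_intensity must be > 0")
    mid = np.asarray(mid, dtype=float)
    weights = np.arange(mid.size) / n_atoms
    fraction = float(np.dot(weights, mid))
    return LabellingResult(
        metabolite=metabolite,
        sample_id=sample_id,
        labelled_ion_count=fraction * total_intensity,
        fractional_labelling=fraction,
        total_ion_count=float(total_intensity),
    )


def deuterium_enrichment(mid: np.ndarray) -> DeuteriumEnrichment:
    """Weighted 2H enrichment from a corrected palmitate MID.

    Uses only M1..M3 (fractions beyond M3 are ignored in the headline
    value); requires at least M0..M3 to be present.
    """
    mid = np.asarray(mid, dtype=float)
    if mid.size < 4:
        raise ValueError(f"MID must cover M0..M3 (>= 4 entries), got {mid.size}")
    h1, h2, h3 = (float(v) for v in mid[1:4])
    untruncated = float(np.dot(np.arange(mid.size), mid))
    return DeuteriumEnrichment(
        h1=h1,
        h2=h2,
        h3=h3,
        enrichment=h1 + 2.0 * h2 + 3.0 * h3,
        untruncated=untruncated,
    )
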