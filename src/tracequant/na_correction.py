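"""Natural-abundance correction of mass-isotopomer distributions.

Measured isotopologue intensities contain contributions from naturally
occurring heavy isotopes of the tracer element (1.1% 13C, 0.0156% 2H) on
top of tracer incorporation.  This module builds the forward convolution
matrix mapping a tracer-labelling MID to the measured MID and inverts it
by non-negative least squares, the standard high-resolution correction:
at orbitrap resolution the isotopologue peaks of non-tracer elements are
mass-resolved from the tracer series, so only the tracer element's
natural abundance is corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

#: Natural heavy-isotope fractions of the supported tracer elements.
HEAVY_FRACTION_DEFAULTS = {"C": 0.011, "H": 0.000156}


@dataclass(frozen=True)
class NaturalAbundanceModel:
    """Isotope model for one tracer element.

    Parameters
    ----------
    tracer_element:
        ``"C"`` for 13C tracing or ``"H"`` for 2H tracing.
    heavy_fraction:
        Natural abundance of the heavy isotope.  Defaults to 0.011 for
        13C and 0.000156 for 2H when not given.
    tracer_purity:
        Isotopic purity of the tracer: probability that a nominally
        labelled position actually carries the heavy isotope.  Default
        1.0 (no purity correction).
    """

    tracer_element: str = "C"
    heavy_fraction: float | None = None
    tracer_purity: float = 1.0

    def __post_init__(self) -> None:
        if self.tracer_element not in HEAVY_FRACTION_DEFAULTS:
            raise ValueError(
                f"unsupported tracer element {self.tracer_element!r}; "
                f"expected one of {sorted(HEAVY_FRACTION_DEFAULTS)}"
            )
        if self.heavy_fraction is None:
            object.__setattr__(
                self, "heavy_fraction", HEAVY_FRACTION_DEFAULTS[self.tracer_element]
            )
        if not 0.0 <= self.heavy_fraction < 0.5:
            raise ValueError(f"heavy_fraction must be in [0, 0.5), got {self.heavy_fraction}")
        if not 0.0 < self.tracer_purity <= 1.0:
            raise ValueError(f"tracer_purity must be in (0, 1], got {self.tracer_purity}")


@dataclass(frozen=True)
class CorrectedMID:
    """Natural-abundance-corrected MID with the NNLS fit diagnostic.

    ``fractions`` sum to 1; ``residual`` is the Euclidean norm of
    ``A @ x - measured`` on the normalized scale — large values indicate
    a measured pattern inconsistent with the isotope model.
    """

    fractions: np.ndarray
    residual: float
    n_atoms: int = field(default=0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "fractions", np.asarray(self.fractions, dtype=float))


def natural_mid(n_atoms: int, model: NaturalAbundanceModel | None = None) -> np.ndarray:
    """Binomial natural-abundance MID over ``n_atoms`` tracer-element atoms.

    Entry *i* is ``C(n, i) a^i (1-a)^(n-i)`` with *a* the heavy fraction;
    the vector sums to one.
    """
    if n_atoms < 0:
        raise ValueError("n_atoms must be >= 0")
    model = model or NaturalAbundanceModel()
    pmf = stats.binom.pmf(np.arange(n_atoms + 1), n_atoms, model.heavy_fraction)
    return pmf / pmf.sum()


def build_correction_matrix(n_atoms: int, model: NaturalAbundanceModel | None = None) -> np.ndarray:
    """Forward convolution matrix A with A[i, j] = P(measured mass i | j labelled).

    Column *j* combines the natural-abundance distribution of the
    ``n_atoms - j`` unlabelled positions with the tracer-purity binomial
    of the *j* labelled positions.  At purity 1 the matrix is lower
    triangular with columns equal to ``natural_mid(n_atoms - j)`` shifted
    down by *j* rows; columns sum to <= 1 (truncation only).
    """
    if n_atoms < 0:
        raise ValueError("n_atoms must be >= 0")
    model = model or NaturalAbundanceModel()
    size = n_atoms + 1
    A = np.zeros((size, size))
    for j in range(size):
        nat = natural_mid(n_atoms - j, model)
        purity = stats.binom.pmf(np.arange(j + 1), j, model.tracer_purity)
        A[:, j] = np.convolve(purity, nat)[:size]
    return A


def correct_mid(
    measured: np.ndarray,
    n_atoms: int,
    model: NaturalAbundanceModel | None = None,
) -> CorrectedMID:
    """Invert the natural-abundance convolution of a measured MID.

    Solves ``min ||A x - measured||_2`` subject to ``x >= 0`` and
    renormalizes to the simplex.  The non-negativity constraint is what
    keeps noisy low-abundance isotopologues from going negative, where a
    plain matrix inverse would.

    Parameters
    ----------
    measured:
        Raw intensity (or fraction) vector of length ``n_atoms + 1``.
    """
    measured = np.asarray(measured, dtype=float)
    if measured.shape != (n_atoms + 1,):
        raise ValueError(
            f"measured MID length {measured.shape} does not match n_atoms+1 = {n_atoms + 1}"
        )
    if np.any(measured < 0):
        raise ValueError("measured intensities must be non-negative")
    total = measured.sum()
    if total == 0:
        raise ValueError("empty MID: all measured intensities are zero")
    scaled = measured / total
    A = build_correction_matrix(n_atoms, model)
    x, residual = optimize.nnls(A, scaled)
    if x.sum() == 0:
        raise ValueError("correction produced an all-zero MID")
    return CorrectedMID(fractions=x / x.sum(), residual=float(residual), n_atoms=n_atoms)
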