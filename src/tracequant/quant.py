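"""Concentration quantitation and precursor-normalized lipogenesis readouts.

Metabolite concentrations come from external calibration curves against
authentic standards (OLS with intercept; inverse prediction of unknowns).
Tissue amounts follow the extraction bookkeeping

    tissue concentration = extract concentration (uM) * extraction volume (ul)
                           / tissue mass (mg)

which is dimensionally nmol per g of tissue; the unit label is emitted
next to the number and can be overridden.  Labelled fatty-acid readouts
can additionally be normalized to the 13C fractional labelling of
hepatic acetyl-CoA, removing precursor-pool enrichment differences
between animals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from tracequant.body_water import LinearCalibration, fit_line

#: dimensionally consistent reading of uM * ul / mg
DEFAULT_TISSUE_UNIT = "nmol/g"


@dataclass(frozen=True)
class ConcentrationStandard:
    known_concentration: float  # uM
    response: float  # ion count

    def __post_init__(self) -> None:
        if self.known_concentration < 0:
            raise ValueError("known_concentration must be >= 0")
        if self.response < 0:
            raise ValueError("response must be >= 0")


@dataclass(frozen=True)
class TissueConcentration:
    value: float
    unit: str = DEFAULT_TISSUE_UNIT


def fit_concentration_curve(standards: Iterable[ConcentrationStandard]) -> LinearCalibration:
    """OLS calibration line ``response = slope * concentration + intercept``."""
    standards = list(standards)
    return fit_line(
        [s.known_concentration for s in standards],
        [s.response for s in standards],
    )


def invert_concentration(response: float, curve: LinearCalibration) -> float:
    """Inverse prediction: ion-count response -> concentration (uM)."""
    return curve.invert(response)


def tissue_concentration(
    sample_conc: float,
    extraction_volume: float,
    tissue_mass: float,
    unit: str = DEFAULT_TISSUE_UNIT,
) -> TissueConcentration:
    """Per-mass tissue amount from the extract concentration.

    ``sample_conc`` in uM, ``extraction_volume`` in ul, ``tissue_mass``
    in mg.  The arithmetic is the printed extraction formula; the unit
    label rides along with the value.
    """
    if tissue_mass <= 0:
        raise ValueError("tissue_mass must be > 0 mg")
    if extraction_volume <= 0:
        raise ValueError("extraction_volume must be > 0 ul")
    if sample_conc < 0:
        raise ValueError("sample concentration must be >= 0")
    return TissueConcentration(
        value=sample_conc * extraction_volume / tissue_mass,
        unit=unit,
    )


def normalize_to_acetylcoa(labelled_fa: float, acetylcoa_fraction: float) -> float:
    """Normalize a labelled fatty-acid readout to acetyl-CoA labelling.

    Dividing by the hepatic 13C-acetyl-CoA fractional labelling makes
    readouts comparable across animals with different precursor
    enrichment: equal true synthesis at 2x different acetyl-CoA
    labelling yields equal normalized values.
    """
    if acetylcoa_fraction <= 0:
        raise ValueError(f"acetyl-CoA fraction must be > 0, got {acetylcoa_fraction}")
    return labelled_fa / acetylcoa_fraction
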