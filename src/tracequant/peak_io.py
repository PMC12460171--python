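"""Reading, validation and assembly of long-format LC-MS peak tables.

The v1 input dialect is a long CSV with one row per (sample, metabolite,
isotopologue): columns ``sample_id, metabolite, formula, tracer_element,
isotopologue_index, intensity``.  Sample metadata travels in a second
CSV keyed on ``sample_id``.  Records are assembled into raw per-sample
intensity vectors over M0..Mk (k = tracer atom count), zero-filling
isotopologues that the peak picker did not export.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from pyteomics.mass import Composition

PEAK_COLUMNS = [
    "sample_id",
    "metabolite",
    "formula",
    "tracer_element",
    "isotopologue_index",
    "intensity",
]
META_COLUMNS = [
    "sample_id",
    "group",
    "tissue_mass_mg",
    "extraction_volume_ul",
    "dose_time",
    "collection_time",
    "body_water_acetone_fraction",
]


class SchemaError(ValueError):
    """Input file header does not match the documented schema."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula (e.g. ``C16H31O2``) into atom counts.

    Charge is ignored: isotope bookkeeping depends only on atom counts,
    so ions are entered as their measured composition.
    """
    try:
        counts = dict(Composition(formula=formula))
    except Exception as exc:
        raise ValueError(f"unparseable formula {formula!r}: {exc}") from exc
    if not counts or any(v <= 0 for v in counts.values()):
        raise ValueError(f"formula {formula!r} must have strictly positive atom counts")
    return counts


@dataclass(frozen=True)
class PeakRecord:
    """One (sample, metabolite, isotopologue) intensity measurement."""

    sample_id: str
    metabolite: str
    formula: str
    tracer_element: str
    isotopologue_index: int
    intensity: float

    def __post_init__(self) -> None:
        if self.tracer_element not in ("C", "H"):
            raise ValueError(f"tracer_element must be C or H, got {self.tracer_element!r}")
        if self.isotopologue_index < 0:
            raise ValueError("isotopologue_index must be >= 0")
        if self.intensity < 0:
            raise ValueError(f"negative intensity {self.intensity}")
        n = self.n_tracer_atoms
        if self.isotopologue_index > n:
            raise ValueError(
                f"isotopologue_index {self.isotopologue_index} exceeds the "
                f"{n} {self.tracer_element} atoms of {self.formula}"
            )

    @property
    def atom_counts(self) -> dict[str, int]:
        return parse_formula(self.formula)

    @property
    def n_tracer_atoms(self) -> int:
        return self.atom_counts.get(self.tracer_element, 0)


@dataclass(frozen=True)
class SampleMeta:
    """Per-animal metadata joined to peak records on sample_id."""

    sample_id: str
    group: str
    tissue_mass: float | None = None  # mg
    extraction_volume: float | None = None  # ul
    dose_time: pd.Timestamp | None = None
    collection_time: pd.Timestamp | None = None
    body_water_acetone_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.tissue_mass is not None and self.tissue_mass <= 0:
            raise ValueError(f"tissue_mass must be > 0 mg, got {self.tissue_mass}")
        if (
            self.dose_time is not None
            and self.collection_time is not None
            and self.collection_time <= self.dose_time
        ):
            raise ValueError(
                f"sample {self.sample_id}: collection_time must be after dose_time"
            )

    @property
    def elapsed_hours(self) -> float | None:
        if self.dose_time is None or self.collection_time is None:
            return None
        return (self.collection_time - self.dose_time).total_seconds() / 3600.0


@dataclass(frozen=True)
class AssembledMID:
    """Raw (uncorrected, unnormalized) intensity vector over M0..Mk."""

    sample_id: str
    metabolite: str
    formula: str
    tracer_element: str
    n_atoms: int
    intensities: np.ndarray


@dataclass
class Dataset:
    records: list[PeakRecord] = field(default_factory=list)
    samples: list[SampleMeta] = field(default_factory=list)

    def validate(self) -> None:
        known = {}
        for s in self.samples:
            if s.sample_id in known:
                raise ValueError(f"duplicate sample metadata for {s.sample_id}")
            known[s.sample_id] = s
        missing = sorted({r.sample_id for r in self.records} - known.keys())
        if missing:
            raise ValueError(f"records reference unknown sample_ids: {missing}")
        seen: set[tuple[str, str, int]] = set()
        for r in self.records:
            key = (r.sample_id, r.metabolite, r.isotopologue_index)
            if key in seen:
                raise ValueError(f"duplicate isotopologue row {key}")
            seen.add(key)

    def sample(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


def read_peak_table(path: str | Path) -> list[PeakRecord]:
    """Read a long-CSV peak table into validated records (row order kept)."""
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in PEAK_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            records.append(
                PeakRecord(
                    sample_id=str(row.sample_id),
                    metabolite=str(row.metabolite),
                    formula=str(row.formula),
                    tracer_element=str(row.tracer_element),
                    isotopologue_index=int(row.isotopologue_index),
                    intensity=float(row.intensity),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path.name} line {i + 2}: {exc}") from exc
    return records


def write_peak_table(records: Iterable[PeakRecord], path: str | Path) -> None:
    # %.17g preserves float64 exactly, so written tables re-read identically
    records_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def records_to_frame(records: Iterable[PeakRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "metabolite": r.metabolite,
                "formula": r.formula,
                "tracer_element": r.tracer_element,
                "isotopologue_index": r.isotopologue_index,
                "intensity": r.intensity,
            }
            for r in records
        ],
        columns=PEAK_COLUMNS,
    )


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in ("sample_id", "group") if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")

    def opt(row, col):
        if col not in frame.columns or pd.isna(getattr(row, col)):
            return None
        return getattr(row, col)

    samples = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            dose = opt(row, "dose_time")
            coll = opt(row, "collection_time")
            samples.append(
                SampleMeta(
                    sample_id=str(row.sample_id),
                    group=str(row.group),
                    tissue_mass=opt(row, "tissue_mass_mg"),
                    extraction_volume=opt(row, "extraction_volume_ul"),
                    dose_time=pd.Timestamp(dose) if dose is not None else None,
                    collection_time=pd.Timestamp(coll) if coll is not None else None,
                    body_water_acetone_fraction=opt(row, "body_water_acetone_fraction"),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path.name} line {i + 2}: {exc}") from exc
    return samples


def assemble_mids(records: Iterable[PeakRecord]) -> dict[tuple[str, str], AssembledMID]:
    """Group records into raw intensity vectors keyed by (sample, metabolite).

    Each vector has length (tracer atom count + 1); isotopologues absent
    from the table are zero-filled with a warning apiece (peak pickers
    frequently export only the informative low-mass isotopologues).
    Intensities are left unnormalized for downstream correction.
    """
    by_key: dict[tuple[str, str], list[PeakRecord]] = {}
    for r in records:
        by_key.setdefault((r.sample_id, r.metabolite), []).append(r)
    if not by_key:
        raise ValueError("no records to assemble")
    out: dict[tuple[str, str], AssembledMID] = {}
    for key, recs in by_key.items():
        n = recs[0].n_tracer_atoms
        seen: set[int] = set()
        dupes = []
        for r in recs:
            if r.isotopologue_index in seen:
                dupes.append((*key, r.isotopologue_index))
            seen.add(r.isotopologue_index)
        if dupes:
            raise ValueError(f"duplicate isotopologue rows: {dupes}")
        vec = np.zeros(n + 1)
        for r in recs:
            vec[r.isotopologue_index] = r.intensity
        for i in range(n + 1):
            if i not in seen:
                _warnings.warn(
                    f"{key[0]}/{key[1]}: isotopologue M{i} missing; zero-filled",
                    stacklevel=2,
                )
        out[key] = AssembledMID(
            sample_id=key[0],
            metabolite=key[1],
            formula=recs[0].formula,
            tracer_element=recs[0].tracer_element,
            n_atoms=n,
            intensities=vec,
        )
    return out
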