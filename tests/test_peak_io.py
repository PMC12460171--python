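"""Peak-table parsing, validation and MID assembly."""

import warnings

import numpy as np
import pytest

from tracequant.peak_io import (
    Dataset,
    PeakRecord,
    SchemaError,
    assemble_mids,
    parse_formula,
    read_peak_table,
    records_to_frame,
    write_peak_table,
)
from tracequant.synthetic import SyntheticDesign, simulate_dnl_cohort


def rec(sample="s1", met="glycine", formula="C2H5NO2", tracer="C", idx=0, intensity=100.0):
    return PeakRecord(sample, met, formula, tracer, idx, intensity)


class TestPeakRecord:
    def test_formula_parsing(self):
        assert parse_formula("C16H31O2") == {"C": 16, "H": 31, "O": 2}

    def test_index_beyond_tracer_atoms_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            rec(formula="C16H31O2", tracer="C", idx=17)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="negative intensity"):
            rec(intensity=-1.0)

    def test_bad_formula_rejected(self):
        with pytest.raises(ValueError, match="formula"):
            rec(formula="NotAFormula!!")


class TestReadPeakTable:
    def test_three_row_parse(self, tmp_path):
        path = tmp_path / "peaks.csv"
        path.write_text(
            "sample_id,metabolite,formula,tracer_element,isotopologue_index,intensity\n"
            "s1,glycine,C2H5NO2,C,0,900\n"
            "s1,glycine,C2H5NO2,C,1,90\n"
            "s1,glycine,C2H5NO2,C,2,10\n"
        )
        records = read_peak_table(path)
        assert [r.isotopologue_index for r in records] == [0, 1, 2]
        assert records[0].intensity == 900

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "peaks.csv"
        path.write_text("sample_id,metabolite,formula,intensity\ns1,g,C2H5NO2,1\n")
        with pytest.raises(SchemaError, match="tracer_element"):
            read_peak_table(path)

    def test_row_error_carries_line_number(self, tmp_path):
        path = tmp_path / "peaks.csv"
        path.write_text(
            "sample_id,metabolite,formula,tracer_element,isotopologue_index,intensity\n"
            "s1,palmitate,C16H31O2,C,0,900\n"
            "s1,palmitate,C16H31O2,C,17,10\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            read_peak_table(path)

    def test_generator_round_trip(self, tmp_path):
        cohort = simulate_dnl_cohort(SyntheticDesign(n_per_group=2, seed=5))
        path = tmp_path / "peaks.csv"
        write_peak_table(cohort.records, path)
        assert read_peak_table(path) == cohort.records

    def test_reserialization_reproduces_table(self, tmp_path):
        cohort = simulate_dnl_cohort(SyntheticDesign(n_per_group=1, seed=5))
        path1 = tmp_path / "a.csv"
        path2 = tmp_path / "b.csv"
        write_peak_table(cohort.records, path1)
        write_peak_table(read_peak_table(path1), path2)
        assert path1.read_text() == path2.read_text()


class TestAssembleMIDs:
    def test_direct_assembly(self):
        records = [rec(idx=i, intensity=v) for i, v in enumerate([900, 90, 10])]
        mids = assemble_mids(records)
        np.testing.assert_allclose(mids[("s1", "glycine")].intensities, [900, 90, 10])

    def test_zero_fill_with_warnings(self):
        records = [rec(met="serine", formula="C3H7NO3", tracer="C", idx=0, intensity=100.0)]
        with pytest.warns(UserWarning) as caught:
            mids = assemble_mids(records)
        assert mids[("s1", "serine")].intensities.tolist() == [100, 0, 0, 0]
        assert len(caught) == 3

    def test_duplicate_key_rejected(self):
        records = [rec(idx=1, intensity=5.0), rec(idx=1, intensity=7.0)]
        with pytest.raises(ValueError, match="duplicate"):
            assemble_mids(records)

    def test_total_intensity_conserved(self):
        cohort = simulate_dnl_cohort(SyntheticDesign(n_per_group=2, seed=2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mids = assemble_mids(cohort.records)
        for m in mids.values():
            assert m.intensities.size == m.n_atoms + 1
            expected = sum(
                r.intensity
                for r in cohort.records
                if r.sample_id == m.sample_id and r.metabolite == m.metabolite
            )
            assert m.intensities.sum() == pytest.approx(expected)


class TestDataset:
    def test_unknown_sample_rejected(self):
        ds = Dataset(records=[rec()], samples=[])
        with pytest.raises(ValueError, match="unknown sample_ids"):
            ds.validate()

    def test_valid_join(self):
        from tracequant.peak_io import SampleMeta

        ds = Dataset(records=[rec()], samples=[SampleMeta("s1", "CF")])
        ds.validate()

    def test_collection_before_dose_rejected(self):
        import pandas as pd

        from tracequant.peak_io import SampleMeta

        with pytest.raises(ValueError, match="after dose_time"):
            SampleMeta(
                "s1",
                "CF",
                dose_time=pd.Timestamp("2024-01-02 09:00"),
                collection_time=pd.Timestamp("2024-01-01 18:00"),
            )
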