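"""Natural-abundance model and correction-matrix inversion."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tracequant.na_correction import (
    NaturalAbundanceModel,
    build_correction_matrix,
    correct_mid,
    natural_mid,
)


class TestNaturalMID:
    def test_zero_atoms_is_point_mass(self):
        assert natural_mid(0).tolist() == [1.0]

    @pytest.mark.parametrize(
        "n_atoms, expected",
        [
            (1, [0.989, 0.011]),
            (2, [0.978121, 0.021758, 0.000121]),
        ],
    )
    def test_binomial_expansion(self, n_atoms, expected):
        np.testing.assert_allclose(natural_mid(n_atoms), expected, atol=1e-12)

    def test_one_carbon_m1_is_natural_13c_abundance(self):
        # the calorimetry baseline: a single carbon is 1.1% likely to be 13C
        assert natural_mid(1, NaturalAbundanceModel("C"))[1] * 100 == pytest.approx(1.1)

    def test_sums_to_one(self):
        for n in (0, 1, 5, 16, 31):
            assert natural_mid(n).sum() == pytest.approx(1.0, abs=1e-12)


class TestCorrectionMatrix:
    def test_one_atom_matrix(self):
        A = build_correction_matrix(1, NaturalAbundanceModel("C", 0.011))
        np.testing.assert_allclose(A, [[0.989, 0.0], [0.011, 1.0]], atol=1e-12)

    def test_zero_abundance_is_identity(self):
        A = build_correction_matrix(5, NaturalAbundanceModel("C", heavy_fraction=0.0))
        np.testing.assert_allclose(A, np.eye(6), atol=1e-15)

    def test_column_zero_equals_natural_mid(self):
        model = NaturalAbundanceModel("C", 0.011)
        A = build_correction_matrix(2, model)
        np.testing.assert_allclose(A[:, 0], natural_mid(2, model), atol=1e-15)

    def test_lower_triangular_at_full_purity(self):
        A = build_correction_matrix(8, NaturalAbundanceModel("C"))
        assert np.allclose(A, np.tril(A))

    def test_columns_sum_to_at_most_one(self):
        A = build_correction_matrix(10, NaturalAbundanceModel("C", 0.05))
        assert np.all(A.sum(axis=0) <= 1.0 + 1e-12)


class TestCorrectMID:
    def test_unlabelled_standard_corrects_to_point_mass(self):
        model = NaturalAbundanceModel("C", 0.011)
        measured = natural_mid(2, model)
        result = correct_mid(measured, 2, model)
        np.testing.assert_allclose(result.fractions, [1.0, 0.0, 0.0], atol=1e-9)
        assert result.residual < 1e-9

    def test_zero_abundance_returns_normalized_input(self):
        model = NaturalAbundanceModel("C", heavy_fraction=0.0)
        result = correct_mid(np.array([300.0, 100.0, 100.0]), 2, model)
        np.testing.assert_allclose(result.fractions, [0.6, 0.2, 0.2], atol=1e-12)

    def test_round_trip_c2(self):
        model = NaturalAbundanceModel("C")
        A = build_correction_matrix(2, model)
        x = np.array([0.6, 0.3, 0.1])
        np.testing.assert_allclose(correct_mid(A @ x, 2, model).fractions, x, atol=1e-8)

    @given(
        st.integers(min_value=1, max_value=20),
        st.lists(st.floats(0.01, 1.0), min_size=1, max_size=21),
    )
    def test_round_trip_property(self, n_atoms, raw):
        """Forward convolution then NNLS inversion recovers any simplex MID."""
        x = np.zeros(n_atoms + 1)
        vals = np.asarray(raw[: n_atoms + 1])
        x[: vals.size] = vals
        x /= x.sum()
        model = NaturalAbundanceModel("C")
        A = build_correction_matrix(n_atoms, model)
        result = correct_mid(A @ x, n_atoms, model)
        np.testing.assert_allclose(result.fractions, x, atol=1e-8)

    def test_noisy_input_stays_non_negative_and_normalized(self, rng):
        # adversarial case: noise drives naive inversion negative
        model = NaturalAbundanceModel("C")
        n = 16
        A = build_correction_matrix(n, model)
        x = np.zeros(n + 1)
        x[0] = 1.0
        measured = A @ x
        noisy = measured * rng.lognormal(0, 0.2, size=n + 1) + 1e-4
        naive = np.linalg.solve(A, noisy / noisy.sum())
        assert np.any(naive < 0), "fixture should defeat plain inversion"
        result = correct_mid(noisy, n, model)
        assert np.all(result.fractions >= 0)
        assert result.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_skipping_correction_overestimates_m1_by_n_times_a(self):
        # unlabelled C16 standard: measured M1 fraction ~= 16 * 0.011
        model = NaturalAbundanceModel("C", 0.011)
        measured = natural_mid(16, model)
        assert measured[1] == pytest.approx(16 * 0.011, rel=0.2)
        corrected = correct_mid(measured, 16, model)
        assert corrected.fractions[1] < 1e-9

    def test_all_zero_input_rejected(self):
        with pytest.raises(ValueError, match="empty MID"):
            correct_mid(np.zeros(3), 2, NaturalAbundanceModel("C"))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            correct_mid(np.ones(3), 5, NaturalAbundanceModel("C"))


def test_model_validation():
    with pytest.raises(ValueError):
        NaturalAbundanceModel("N")
    with pytest.raises(ValueError):
        NaturalAbundanceModel("C", heavy_fraction=0.6)
    with pytest.raises(ValueError):
        NaturalAbundanceModel("C", tracer_purity=0.0)
    assert NaturalAbundanceModel("H").heavy_fraction == 0.000156
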