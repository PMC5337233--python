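import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from isolabel import (
    ElementSpec,
    FractionVector,
    MoietySpec,
    convert,
    ic_matrix,
    im_matrix,
    punctured_matrix,
    pseudoinverse_demo,
)
from isolabel.fraction_convert import (
    ConversionPathError,
    UnfaithfulConversionWarning,
    export_matrix_mtx,
    read_vector_tsv,
    write_vector_tsv,
)

from .printed_tables import IC_TABLE, IM_TABLE


class TestPublishedMatrices:
    @pytest.mark.parametrize("n,m", sorted(IC_TABLE))
    def test_ic_matrices_match_published_exemplars(self, n, m):
        assert np.array_equal(ic_matrix(n, m).entries, IC_TABLE[(n, m)])

    @pytest.mark.parametrize("n,m", sorted(IM_TABLE))
    def test_im_matrices_match_published_exemplars(self, n, m):
        assert np.array_equal(im_matrix(n, m).entries, IM_TABLE[(n, m)])

    @pytest.mark.parametrize("n", [2, 3])
    @pytest.mark.parametrize("m", [1, 2])
    def test_ic_is_kronecker_power_of_single_atom_block(self, n, m):
        single = ic_matrix(1, m).entries
        expected = np.ones((1, 1), dtype=np.int64)
        for _ in range(n):
            expected = np.kron(expected, single)
        assert np.array_equal(ic_matrix(n, m).entries, expected)

    @pytest.mark.parametrize("n,m", list(itertools.product(range(4), range(4))))
    def test_im_columns_have_exactly_one_entry(self, n, m):
        assert np.array_equal(
            im_matrix(n, m).entries.sum(axis=0), np.ones((m + 1) ** n, dtype=np.int64)
        )


class TestPuncturedMatrices:
    def test_classical_binary_puncture_is_reed_muller_pattern(self):
        assert np.array_equal(punctured_matrix(1, 1, 0).entries, [[0, 1], [1, 1]])

    def test_puncture_at_one_deletes_middle_row(self):
        assert np.array_equal(
            punctured_matrix(1, 2, 1).entries, [[1, 0, 0], [0, 0, 1], [1, 1, 1]]
        )

    def test_square_kron_power_inverts(self):
        mat = punctured_matrix(2, 1, 0).entries.astype(float)
        assert mat.shape == (4, 4)
        assert np.allclose(mat @ np.linalg.inv(mat), np.eye(4))

    @pytest.mark.parametrize("n", range(4))
    @pytest.mark.parametrize("m", range(4))
    def test_invertible_for_every_puncture(self, n, m):
        for s in range(m + 1):
            mat = punctured_matrix(n, m, s).entries.astype(float)
            assert mat.shape == ((m + 1) ** n,) * 2
            assert abs(np.linalg.det(mat)) > 0.5

    def test_product_of_two_punctured_matrices_invertible(self):
        a = punctured_matrix(2, 2, 0).entries
        b = punctured_matrix(2, 2, 1).entries
        assert abs(np.linalg.det((a @ b).astype(float))) > 0.5

    def test_puncture_out_of_range(self):
        with pytest.raises(ValueError, match="puncture"):
            punctured_matrix(1, 1, 2)


class TestConvert:
    def test_worked_example_mass_projection(self, worked_isotopomer):
        mass = convert(worked_isotopomer, "mass")
        assert np.allclose(mass.values, [0.4, 0.5, 0.1])

    def test_punctured_round_trip_is_exact(self, worked_isotopomer):
        for s in (0, 1):
            back = convert(convert(worked_isotopomer, "punctured", puncture=s), "isotopomer")
            assert np.allclose(back.values, worked_isotopomer.values, atol=1e-12)

    def test_isotopomer_delta_maps_to_cumomer_upset(self, two_atom_spec):
        delta = FractionVector("isotopomer", [0, 0, 0, 1.0], two_atom_spec)
        cum = convert(delta, "cumomer").values
        # nonzero exactly at (1,1), (1,T), (T,1), (T,T) in base-3 indexing
        expected = np.zeros(9)
        for idx in (1 * 3 + 1, 1 * 3 + 2, 2 * 3 + 1, 2 * 3 + 2):
            expected[idx] = 1.0
        assert np.array_equal(cum, expected)

    def test_mass_to_isotopomer_refused(self, worked_isotopomer):
        mass = convert(worked_isotopomer, "mass")
        with pytest.raises(ConversionPathError, match="non-invertible"):
            convert(mass, "isotopomer")

    def test_pseudoinverse_counterexample(self, worked_isotopomer):
        mass = convert(worked_isotopomer, "mass")
        with pytest.warns(UnfaithfulConversionWarning):
            approx = pseudoinverse_demo(mass)
        assert np.allclose(approx.values, [0.4, 0.25, 0.25, 0.1])
        assert not np.allclose(approx.values, worked_isotopomer.values)

    def test_pseudoinverse_recovers_symmetric_vectors(self, two_atom_spec):
        sym = FractionVector("isotopomer", [0.4, 0.25, 0.25, 0.1], two_atom_spec)
        with pytest.warns(UnfaithfulConversionWarning):
            approx = pseudoinverse_demo(convert(sym, "mass"))
        assert np.allclose(approx.values, sym.values, atol=1e-12)

    def test_pseudoinverse_exact_for_single_atom(self):
        spec = MoietySpec.homonuclear("B", 1, 2)
        iso = FractionVector("isotopomer", [0.5, 0.3, 0.2], spec)
        with pytest.warns(UnfaithfulConversionWarning):
            approx = pseudoinverse_demo(convert(iso, "mass"))
        assert np.allclose(approx.values, iso.values, atol=1e-12)


class TestSumRulesAndValidation:
    @given(
        n=st.integers(1, 4),
        m=st.integers(1, 3),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_cumomer_sum_rules_on_random_vectors(self, n, m, seed):
        """Isotopomer sums 1, cumomer sums 2^n, every EMU block sums 1."""
        rng = np.random.default_rng(seed)
        spec = MoietySpec.homonuclear("X", n, m)
        iso = FractionVector("isotopomer", rng.dirichlet(np.ones((m + 1) ** n)), spec)
        cum = convert(iso, "cumomer")
        cum.validate()  # enforces both the total and the per-block sum rules
        assert cum.values.sum() == pytest.approx(2**n, rel=1e-9)

    @given(n=st.integers(1, 4), m=st.integers(1, 2), seed=st.integers(0, 2**31 - 1))
    def test_highest_mass_fraction_equals_all_max_cumomer(self, n, m, seed):
        rng = np.random.default_rng(seed)
        spec = MoietySpec.homonuclear("X", n, m)
        iso = FractionVector("isotopomer", rng.dirichlet(np.ones((m + 1) ** n)), spec)
        mass = convert(iso, "mass")
        cum = convert(iso, "cumomer")
        all_max_index = sum(m * (m + 2) ** k for k in range(n))  # digits all = m
        assert mass.values[-1] == pytest.approx(cum.values[all_max_index], abs=1e-12)

    def test_surplus_states_must_carry_zero_probability(self):
        spec = MoietySpec("CH", (ElementSpec("C", 1), ElementSpec("H", 2)))
        bad = np.zeros(9)
        bad[2 * 3 + 0] = 1.0  # C at shift 2 exceeds its own cap of 1
        with pytest.raises(ValueError, match="surplus"):
            FractionVector("isotopomer", bad, spec).validate()
        good = np.zeros(9)
        good[1 * 3 + 2] = 1.0  # C at 1, H at 2: both within their caps
        FractionVector("isotopomer", good, spec).validate()

    def test_wrong_length_rejected(self, two_atom_spec):
        with pytest.raises(ValueError, match="length"):
            FractionVector("isotopomer", [1.0, 0.0], two_atom_spec).validate()


class TestSerialisation:
    def test_tsv_round_trip(self, tmp_path, worked_isotopomer):
        path = tmp_path / "vec.tsv"
        write_vector_tsv(worked_isotopomer, path)
        back = read_vector_tsv(path, worked_isotopomer.spec, "isotopomer")
        assert np.array_equal(back.values, worked_isotopomer.values)

    def test_cumomer_labels_use_top_symbol(self, worked_isotopomer):
        cum = convert(worked_isotopomer, "cumomer")
        labels = cum.labels()
        assert labels[-1] == "⊤,⊤"
        assert labels[0] == "0,0"

    def test_mtx_export_round_trips(self, tmp_path):
        import scipy.io

        path = tmp_path / "ic.mtx"
        export_matrix_mtx(ic_matrix(2, 1), path)
        assert np.array_equal(
            np.asarray(scipy.io.mmread(path).todense()), ic_matrix(2, 1).entries
        )
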