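import numpy as np
import pytest
from scipy.stats import norm

import connrep as cr
from connrep.connectivity import weighted_network


class TestPearson:
    def test_duplicated_and_negated_parcels(self, rng):
        x = rng.normal(size=100)
        series = np.column_stack([x, x, -x, rng.normal(size=100)])
        r = cr.pearson_correlation(series)
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)
        assert np.all(np.diag(r) == 0.0)

    def test_hand_computed_correlation(self):
        series = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 5.0]])
        r = cr.pearson_correlation(series)
        assert r[0, 1] == pytest.approx(0.9827, abs=1e-4)

    def test_censored_volumes_excluded(self, rng):
        series = rng.normal(size=(50, 3))
        mask = np.ones(50, dtype=bool)
        mask[40:] = False
        np.testing.assert_allclose(
            cr.pearson_correlation(series, mask),
            cr.pearson_correlation(series[:40]))

    def test_zero_variance_parcel_named(self, rng):
        series = rng.normal(size=(50, 3))
        series[:, 1] = 4.2
        with pytest.raises(ValueError, match=r"\[1\]"):
            cr.pearson_correlation(series)


class TestPartial:
    def test_two_parcels_reduce_to_pearson(self, rng):
        series = rng.normal(size=(200, 2))
        np.testing.assert_allclose(cr.partial_correlation(series),
                                   cr.pearson_correlation(series), atol=1e-12)

    def test_recovers_known_precision_structure(self):
        omega = np.array([[2.0, -1.0, 0.0], [-1.0, 2.0, -1.0], [0.0, -1.0, 2.0]])
        sigma = np.linalg.inv(omega)
        rng = np.random.default_rng(99)
        x = rng.multivariate_normal(np.zeros(3), sigma, size=10_000)
        pc = cr.partial_correlation(x)
        assert abs(pc[0, 2] - 0.0) < 0.05  # conditionally independent pair
        assert abs(pc[0, 1] - 0.5) < 0.05  # -omega_12/sqrt(omega_11*omega_22)

    def test_independent_variables_give_near_zero_partials(self):
        rng = np.random.default_rng(5)
        t = 2000
        x = rng.normal(size=(t, 4))
        pc = cr.partial_correlation(x)
        off = pc[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 3.0 / np.sqrt(t)

    def test_too_few_volumes_rejected(self, rng):
        with pytest.raises(ValueError, match="parcels \\+ 1"):
            cr.partial_correlation(rng.normal(size=(10, 9)))


class TestSignModes:
    def test_definitions_on_a_negative_value(self):
        m = np.array([[0.0, -0.4], [-0.4, 0.0]])
        assert cr.apply_sign_mode(m, "abs")[0, 1] == pytest.approx(0.4)
        assert cr.apply_sign_mode(m, "pos")[0, 1] == 0.0
        assert cr.apply_sign_mode(m, "neg")[0, 1] == pytest.approx(0.4)

    def test_pos_plus_neg_equals_abs(self, rng):
        m = rng.normal(size=(8, 8))
        m = (m + m.T) / 2
        np.testing.assert_allclose(
            cr.apply_sign_mode(m, "pos") + cr.apply_sign_mode(m, "neg"),
            cr.apply_sign_mode(m, "abs"))

    def test_all_positive_matrix_has_empty_neg_part(self, rng):
        m = np.abs(rng.normal(size=(5, 5)))
        m = (m + m.T) / 2
        assert cr.apply_sign_mode(m, "neg").max() == 0.0


class TestFisherZ:
    def test_zero_maps_to_zero_and_oddness(self, rng):
        r = rng.uniform(-0.8, 0.8, size=(6, 6))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 0.0)
        z = cr.fisher_z(r, n=120)
        assert z[r == 0].max() == 0.0
        np.testing.assert_allclose(cr.fisher_z(-r, n=120), -z)

    def test_reference_value(self):
        r = np.array([[0.0, 0.5], [0.5, 0.0]])
        z = cr.fisher_z(r, n=120, p=2)
        assert z[0, 1] == pytest.approx(np.sqrt(117) * np.arctanh(0.5), rel=1e-9)
        assert z[0, 1] == pytest.approx(5.941, abs=1e-3)

    def test_invalid_inputs_rejected(self):
        bad = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="< 1"):
            cr.fisher_z(bad, n=120)
        ok = np.array([[0.0, 0.5], [0.5, 0.0]])
        with pytest.raises(ValueError, match="dof"):
            cr.fisher_z(ok, n=10, p=20)


class TestZToWeight:
    def test_limits_and_reference_value(self):
        z = np.array([[0.0, 1.0, 50.0], [1.0, 0.0, 0.0], [50.0, 0.0, 0.0]])
        w = cr.z_to_weight(z)
        assert w[1, 2] == 0.0
        assert w[0, 2] == pytest.approx(1.0, abs=1e-6)
        expected = (2 * norm.cdf(1.0) - 1.0) ** 4
        assert w[0, 1] == pytest.approx(expected)
        assert w[0, 1] == pytest.approx(0.2172, abs=1e-4)

    def test_even_in_z_and_monotone_in_magnitude(self):
        z = np.linspace(0.1, 4.0, 25)
        m = np.zeros((26, 26))
        m[0, 1:] = z
        m += m.T
        w = cr.z_to_weight(m)[0, 1:]
        assert np.all(np.diff(w) > 0)
        np.testing.assert_allclose(cr.z_to_weight(-m), cr.z_to_weight(m))

    def test_bounded_in_unit_interval(self, rng):
        z = rng.normal(0, 5, size=(10, 10))
        w = cr.z_to_weight((z + z.T) / 2)
        assert w.min() >= 0.0 and w.max() <= 1.0


class TestBinarize:
    def _corr(self, rng, p=30):
        x = rng.normal(size=(200, p))
        return cr.pearson_correlation(x)

    def test_edge_count_at_five_percent_of_100_nodes(self, rng):
        m = np.abs(self._corr(rng, p=100))
        adj = cr.binarize_by_density(m, 0.05)
        assert adj.sum() / 2 == 248  # round(0.05 * 4950) half-up

    def test_full_density_gives_complete_graph(self, rng):
        m = np.abs(self._corr(rng, p=10))
        adj = cr.binarize_by_density(m, 0.999)  # k = round(44.955) = 45
        assert adj.sum() / 2 == 45

    def test_edge_sets_nested_across_densities(self, rng):
        m = np.abs(self._corr(rng))
        sparse = cr.binarize_by_density(m, 0.1)
        dense = cr.binarize_by_density(m, 0.3)
        assert np.all(dense[sparse == 1] == 1)

    def test_zero_edge_request_rejected(self):
        m = np.abs(np.eye(4) - 1.0) * 0.5
        with pytest.raises(ValueError, match="zero edges"):
            cr.binarize_by_density(m, 1e-4)


class TestOrderingPreservation:
    def test_top_k_edges_agree_across_weight_transforms(self, rng):
        """|r|, |Z| and the Phi-based w are monotone transforms of each
        other, so binary networks are construction-invariant."""
        r = cr.pearson_correlation(rng.normal(size=(150, 25)))
        n = 150
        absr = cr.apply_sign_mode(r, "abs")
        absz = cr.apply_sign_mode(cr.fisher_z(r, n), "abs")
        w = cr.z_to_weight(absz)
        for d in (0.1, 0.25):
            a = cr.binarize_by_density(absr, d)
            b = cr.binarize_by_density(absz, d)
            c = cr.binarize_by_density(w, d)
            np.testing.assert_array_equal(a, b)
            np.testing.assert_array_equal(a, c)


class TestWeightedNetwork:
    def test_raw_and_zphi_schemes_bounded_and_symmetric(self, rng):
        r = cr.pearson_correlation(rng.normal(size=(120, 15)))
        for scheme in ("raw", "zphi"):
            for sign in ("abs", "pos", "neg"):
                w = weighted_network(r, sign, scheme, n_usable=120)
                assert w.min() >= 0.0 and w.max() <= 1.0
                np.testing.assert_allclose(w, w.T)
                assert np.all(np.diag(w) == 0.0)
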