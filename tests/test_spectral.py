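import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mgca import RoiTimeSeries, VarModel, simulate_var
from mgca.spectral import (
    band_average,
    ddtf,
    default_freqs,
    doi,
    dtf,
    edge_statistics,
    ffdtf,
    fit_var,
    partial_coherence,
    select_order,
    spectral_density,
    transfer_function,
)
from mgca.synthetic import chain_model, coupled_pair_model


class TestFitVar:
    def test_recovers_bivariate_coefficients(self):
        model = coupled_pair_model(coupling=0.4, decay=0.5)
        ts = simulate_var(model, 2000, seed=1)
        est = fit_var(ts, 1, standardize=False)
        np.testing.assert_allclose(est.coeffs[0], model.coeffs[0], atol=0.05)

    def test_white_noise_coefficients_near_zero(self):
        model = VarModel(coeffs=np.zeros((1, 2, 2)), noise_cov=np.eye(2))
        ts = simulate_var(model, 2000, seed=2)
        est = fit_var(ts, 1, standardize=False)
        assert np.max(np.abs(est.coeffs)) < 0.06

    def test_insufficient_data_rejected(self):
        ts = RoiTimeSeries(data=np.random.default_rng(0).normal(size=(10, 10)), dt=2.0)
        with pytest.raises(ValueError, match="insufficient"):
            fit_var(ts, 2)

    def test_matches_statsmodels_var(self, chain3_series):
        """Independent cross-check: equation-wise OLS equals the reference
        multivariate VAR estimator."""
        from statsmodels.tsa.api import VAR as SmVAR

        est = fit_var(chain3_series, 2, standardize=False)
        sm_res = SmVAR(chain3_series.data).fit(2, trend="c")
        np.testing.assert_allclose(
            est.coeffs, sm_res.coefs, atol=1e-8
        )


class TestSelectOrder:
    def test_recovers_var2_order(self):
        hits = 0
        reps = 40
        for r in range(reps):
            coeffs = np.zeros((2, 2, 2))
            coeffs[0] = [[0.4, 0.2], [0.0, 0.3]]
            coeffs[1] = [[0.3, 0.0], [0.25, 0.3]]
            model = VarModel(coeffs=coeffs, noise_cov=np.eye(2))
            ts = simulate_var(model, 1000, seed=100 + r)
            hits += select_order(ts, max_order=6, criterion="bic") == 2
        assert hits >= 0.9 * reps

    def test_white_noise_selects_minimum(self):
        hits = 0
        for r in range(20):
            model = VarModel(coeffs=np.zeros((1, 2, 2)), noise_cov=np.eye(2))
            ts = simulate_var(model, 500, seed=200 + r)
            hits += select_order(ts, max_order=5, criterion="bic") == 1
        assert hits > 10

    def test_max_order_one(self, chain3_series):
        assert select_order(chain3_series, max_order=1) == 1


class TestTransferFunction:
    def test_zero_coupling_gives_identity(self):
        model = VarModel(coeffs=np.zeros((1, 3, 3)), noise_cov=np.eye(3))
        h = transfer_function(model, default_freqs(2.0), 2.0)
        np.testing.assert_allclose(h, np.broadcast_to(np.eye(3), h.shape), atol=1e-12)

    def test_univariate_nyquist_closed_form(self):
        model = VarModel(coeffs=np.array([[[0.5]]]), noise_cov=np.eye(1))
        h = transfer_function(model, np.array([0.5]), dt=1.0)  # Nyquist at dt=1
        assert h[0, 0, 0] == pytest.approx(1.0 / 1.5, abs=1e-12)

    def test_triangular_coefficients_give_triangular_h(self):
        model = chain_model(0.4, n_nodes=3)
        h = transfer_function(model, default_freqs(2.0), 2.0)
        upper = np.triu_indices(3, k=1)
        assert np.max(np.abs(h[:, upper[0], upper[1]])) < 1e-14

    def test_frequencies_outside_range_rejected(self):
        model = chain_model(0.4)
        with pytest.raises(ValueError, match="Nyquist"):
            transfer_function(model, np.array([0.3]), dt=2.0)


class TestDtfFamilies:
    def test_zero_coupling_dtf_identity_pattern(self):
        model = VarModel(coeffs=np.zeros((1, 3, 3)), noise_cov=np.eye(3))
        d = dtf(transfer_function(model, default_freqs(2.0), 2.0))
        np.testing.assert_allclose(d, np.broadcast_to(np.eye(3), d.shape), atol=1e-12)

    def test_noncausal_direction_exactly_zero(self):
        model = coupled_pair_model(0.4)
        spec = ddtf(model, default_freqs(2.0), 2.0)
        # node 2 never influences node 1
        assert np.all(spec.dtf[:, 0, 1] == 0)
        assert np.all(spec.ffdtf[:, 0, 1] == 0)
        assert np.all(spec.ddtf[:, 0, 1] == 0)
        assert np.all(spec.dtf[:, 1, 0] > 0)

    @settings(derandomize=True, max_examples=30)
    @given(
        st.integers(min_value=0, max_value=2**31 - 1),
        st.integers(min_value=2, max_value=6),
        st.integers(min_value=1, max_value=3),
    )
    def test_dtf_rows_normalized_random_models(self, seed, n, p):
        rng = np.random.default_rng(seed)
        coeffs = rng.normal(scale=0.25, size=(p, n, n))
        model = VarModel(coeffs=coeffs, noise_cov=np.eye(n))
        if not model.is_stable:
            coeffs = coeffs * 0.5
            model = VarModel(coeffs=coeffs, noise_cov=np.eye(n))
        d = dtf(transfer_function(model, default_freqs(2.0, 33), 2.0))
        np.testing.assert_allclose((d**2).sum(axis=2), 1.0, atol=1e-10)

    def test_spectral_density_closed_form_univariate(self):
        model = VarModel(coeffs=np.array([[[0.5]]]), noise_cov=np.eye(1))
        h = transfer_function(model, np.array([0.5]), dt=1.0)
        s = spectral_density(h, model.noise_cov)
        assert s[0, 0, 0].real == pytest.approx(1.0 / 1.5**2, abs=1e-12)

    def test_spectral_density_hermitian(self, stable_model_factory):
        rng = np.random.default_rng(5)
        model = stable_model_factory(rng, 4, 2)
        h = transfer_function(model, default_freqs(2.0, 17), 2.0)
        s = spectral_density(h, model.noise_cov)
        np.testing.assert_allclose(s, np.conj(np.swapaxes(s, 1, 2)), atol=1e-12)
        assert np.all(np.real(np.einsum("fii->fi", s)) > 0)


class TestPartialCoherence:
    def test_independent_channels_zero_off_diagonal(self):
        s = np.broadcast_to(np.diag([1.0, 2.0, 3.0]).astype(complex), (5, 3, 3))
        pc = partial_coherence(s)
        off = ~np.eye(3, dtype=bool)
        assert np.max(pc[:, off]) < 1e-12
        np.testing.assert_allclose(pc[:, np.eye(3, dtype=bool)], 1.0)

    def test_chain_suppresses_mediated_pair(self, chain3):
        """In a chain x1->x2->x3 the (1,3) association is entirely mediated
        by x2, so its partial coherence vanishes while (1,2) stays high."""
        spec = ddtf(chain3, default_freqs(2.0), 2.0)
        band = (spec.freqs >= 0.01) & (spec.freqs <= 0.08)
        assert spec.pcoh[band][:, 2, 0].max() < 1e-10
        assert spec.pcoh[band][:, 1, 0].min() > 0.1


class TestClosedFormBivariateOracle:
    def test_pipeline_matches_hand_inversion(self):
        """Hand-derived 2x2 spectral algebra for the triangular VAR(1)
        (scalar complex arithmetic only) matches the pipeline to 1e-10."""
        a_coup, a_dec, dt = 0.4, 0.5, 2.0
        model = coupled_pair_model(coupling=a_coup, decay=a_dec)
        freqs = default_freqs(dt)
        spec = ddtf(model, freqs, dt)

        z = np.exp(-2j * np.pi * freqs * dt)
        a11 = 1 - a_dec * z  # A-bar entries
        a21 = -a_coup * z
        a22 = 1 - a_dec * z
        det = a11 * a22
        # H = inv(A-bar) for [[a11, 0], [a21, a22]]
        h11 = a22 / det
        h21 = -a21 / det
        h22 = a11 / det
        np.testing.assert_allclose(spec.H[:, 0, 0], h11, atol=1e-10)
        np.testing.assert_allclose(spec.H[:, 1, 0], h21, atol=1e-10)
        np.testing.assert_allclose(spec.H[:, 1, 1], h22, atol=1e-10)
        np.testing.assert_allclose(spec.H[:, 0, 1], 0, atol=1e-14)

        # DTF rows
        dtf_21 = np.abs(h21) / np.sqrt(np.abs(h21) ** 2 + np.abs(h22) ** 2)
        np.testing.assert_allclose(spec.dtf[:, 1, 0], dtf_21, atol=1e-10)
        np.testing.assert_allclose(spec.dtf[:, 0, 0], 1.0, atol=1e-10)

        # ffDTF: pooled denominator over the whole grid
        denom1 = np.sum(np.abs(h21) ** 2 + np.abs(h22) ** 2)
        ff_21 = np.abs(h21) / np.sqrt(denom1)
        np.testing.assert_allclose(spec.ffdtf[:, 1, 0], ff_21, atol=1e-10)

        # partial coherence from S = H H* (unit noise): P = S^-1
        s11 = h11 * np.conj(h11)
        s12 = h11 * np.conj(h21)
        s21 = h21 * np.conj(h11)
        s22 = h21 * np.conj(h21) + h22 * np.conj(h22)
        det_s = s11 * s22 - s12 * s21
        p11 = s22 / det_s
        p12 = -s12 / det_s
        p22 = s11 / det_s
        pc_12 = np.abs(p12) / np.sqrt(np.real(p11) * np.real(p22))
        np.testing.assert_allclose(spec.pcoh[:, 1, 0], pc_12, atol=1e-10)
        np.testing.assert_allclose(spec.pcoh[:, 0, 1], pc_12, atol=1e-10)

        # dDTF = ffDTF * pcoh; reverse direction exactly zero
        np.testing.assert_allclose(spec.ddtf[:, 1, 0], ff_21 * pc_12, atol=1e-10)
        assert np.all(spec.ddtf[:, 0, 1] == 0)


class TestDdtfProperties:
    def test_values_in_unit_interval(self, stable_model_factory):
        rng = np.random.default_rng(17)
        for _ in range(5):
            model = stable_model_factory(rng, 4, 2)
            spec = ddtf(model, default_freqs(2.0, 33), 2.0)
            assert np.all(spec.ddtf >= 0) and np.all(spec.ddtf <= 1)
            assert np.all(spec.pcoh >= 0) and np.all(spec.pcoh <= 1)

    def test_zero_coupling_no_offdiagonal_ddtf(self):
        model = VarModel(coeffs=np.zeros((1, 4, 4)), noise_cov=np.eye(4))
        spec = ddtf(model, default_freqs(2.0), 2.0)
        off = ~np.eye(4, dtype=bool)
        assert np.max(spec.ddtf[:, off]) < 1e-12

    def test_weighting_suppresses_indirect_edge(self, chain3):
        """The partial-coherence weight pushes the mediated x1->x3 edge far
        below the direct edges, although its ffDTF alone is comparable."""
        spec = ddtf(chain3, default_freqs(2.0), 2.0)
        band = (spec.freqs >= 0.01) & (spec.freqs <= 0.08)
        ff_indirect = spec.ffdtf[band][:, 2, 0].mean()
        dd_indirect = spec.ddtf[band][:, 2, 0].mean()
        dd_direct = spec.ddtf[band][:, 1, 0].mean()
        assert ff_indirect > 0.5 * dd_direct  # unweighted: comparable
        assert dd_indirect < 0.05 * dd_direct  # weighted: suppressed

    def test_permutation_equivariance(self, chain3):
        perm = [2, 0, 1]
        permuted = VarModel(
            coeffs=chain3.coeffs[:, perm][:, :, perm],
            noise_cov=chain3.noise_cov[perm][:, perm],
            node_labels=tuple(chain3.node_labels[i] for i in perm),
        )
        spec = ddtf(chain3, default_freqs(2.0, 33), 2.0)
        spec_p = ddtf(permuted, default_freqs(2.0, 33), 2.0)
        np.testing.assert_allclose(
            spec_p.ddtf, spec.ddtf[:, perm][:, :, perm], atol=1e-12
        )


class TestBandAverageAndDoi:
    def test_constant_spectrum_returns_constant(self):
        freqs = default_freqs(2.0, 10)
        values = np.full((10, 2, 2), 0.3)
        out = band_average(values, band=(0.01, 0.08), freqs=freqs)
        off = ~np.eye(2, dtype=bool)
        np.testing.assert_allclose(out[off], 0.3)
        np.testing.assert_allclose(np.diag(out), 0.0)

    def test_single_grid_frequency(self):
        freqs = np.array([0.02, 0.05, 0.2])
        values = np.stack([np.full((2, 2), v) for v in (0.1, 0.4, 0.9)])
        out = band_average(values, band=(0.04, 0.06), freqs=freqs)
        assert out[0, 1] == pytest.approx(0.4)

    def test_linear_ramp_mean(self):
        freqs = np.linspace(0.02, 0.06, 5)
        ramp = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        values = ramp[:, None, None] * np.ones((5, 2, 2))
        out = band_average(values, band=(0.01, 0.08), freqs=freqs)
        assert out[1, 0] == pytest.approx(0.3)

    def test_empty_band_rejected(self):
        freqs = np.array([0.1, 0.2])
        with pytest.raises(ValueError, match="no grid frequency"):
            band_average(np.zeros((2, 2, 2)), band=(0.01, 0.05), freqs=freqs)

    def test_doi_symmetric_input_zero(self):
        m = np.array([[0.0, 0.2], [0.2, 0.0]])
        np.testing.assert_allclose(doi(m), 0.0)

    def test_doi_hand_example(self):
        # edge[target, source]: influence 2->1 is 0.3, 1->2 is 0.1
        m = np.array([[0.0, 0.3], [0.1, 0.0]])
        d = doi(m)
        assert d[0, 1] == pytest.approx(0.2)
        assert d[1, 0] == pytest.approx(-0.2)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_doi_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        m = np.abs(rng.normal(size=(4, 4)))
        np.fill_diagonal(m, 0.0)
        np.testing.assert_allclose(doi(m) + doi(m).T, 0.0, atol=1e-14)


class TestEdgeStatistics:
    def test_true_edges_dominate_chain(self, chain3_series):
        est = edge_statistics(chain3_series, order=1)
        flat = est.ddtf_band.copy()
        order = np.argsort(flat, axis=None)[::-1]
        top2 = {tuple(np.unravel_index(i, flat.shape)) for i in order[:2]}
        assert top2 == {(1, 0), (2, 1)}  # x1->x2 and x2->x3
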