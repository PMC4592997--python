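"""Selection-index mathematics: responses, gains, accuracies, selection."""

import numpy as np
import pytest

from gsindex.index import (
    GenomicSelectionIndex,
    IndexSpec,
    PhenotypicSelectionIndex,
    accuracy,
    efficiency_ratio,
    expected_gains,
    gsi_values,
    index_response,
    psi_coefficients,
    selection_intensity,
    technow_inequality,
    truncate_select,
)
from gsindex.markers import GEBVTable, GRM, compute_grm, fit_rrblup, markers_from_population, predict_gebv
from gsindex.phenotypes import PhenotypeTable, simulate_phenotypes
from gsindex.genome import compute_tbv, make_f2


def _random_psd(rng, t=4, jitter=0.5):
    A = rng.standard_normal((t, t))
    return A @ A.T + jitter * np.eye(t)


class TestSelectionIntensity:
    def test_top_decile_value(self):
        k = selection_intensity(0.10)
        assert round(k, 2) == 1.75
        assert k == pytest.approx(1.7550, abs=5e-4)

    def test_half_selected(self):
        # phi(0)/0.5 = 0.7979 (frozen from the closed form; a Monte-Carlo
        # mean of the upper half of N(0,1) draws gives the same value)
        assert selection_intensity(0.5) == pytest.approx(0.7979, abs=1e-4)

    def test_no_selection_limit(self):
        assert selection_intensity(1 - 1e-12) < 1e-5

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.5])
    def test_domain_errors(self, p):
        with pytest.raises(ValueError):
            selection_intensity(p)


class TestPsiCoefficients:
    def test_perfect_heritability_returns_weights(self):
        rng = np.random.default_rng(0)
        C = _random_psd(rng)
        w = np.array([1.0, -1.0, 1.0, 1.0])
        assert np.allclose(psi_coefficients(C, C, w), w)

    def test_diagonal_case(self):
        P = np.eye(4)
        C = np.diag([0.32, 0.5, 0.1, 0.9])
        b = psi_coefficients(P, C, np.array([1.0, 0, 0, 0]))
        assert np.allclose(b, [0.32, 0, 0, 0])

    def test_beats_random_indices(self):
        """Brute-force optimality oracle: corr(H, b'p) from the Smith-Hazel
        b exceeds that of 1e5 random unit-norm coefficient vectors."""
        rng = np.random.default_rng(1)
        C = _random_psd(rng)
        P = C + _random_psd(rng, jitter=1.0)
        w = np.array([1.0, -1.0, 0.5, 2.0])

        def corr_with_H(b):
            return (b @ C @ w) / np.sqrt((b @ P @ b) * (w @ C @ w))

        b_opt = psi_coefficients(P, C, w)
        B = rng.standard_normal((100_000, 4))
        corrs = (B @ C @ w) / np.sqrt(np.einsum("ij,jk,ik->i", B, P, B) * (w @ C @ w))
        assert corr_with_H(b_opt) >= corrs.max() - 1e-12


class TestResponseAndGains:
    def test_zero_coefficients_zero_response(self):
        spec = IndexSpec(w=np.ones(3), k=1.0, L=1.0)
        assert index_response(spec, np.eye(3), np.zeros(3)) == 0.0

    def test_unit_case(self):
        spec = IndexSpec(w=np.ones(3), k=1.0, L=1.0)
        assert index_response(spec, np.eye(3), np.array([1.0, 0, 0])) == pytest.approx(1.0)

    def test_interval_ratio(self):
        # same quadratic form at L = 1.5 vs L = 4 -> responses in ratio 8/3
        rng = np.random.default_rng(2)
        M = _random_psd(rng)
        v = rng.standard_normal(4)
        w = np.ones(4)
        r_fast = index_response(IndexSpec(w=w, k=1.755, L=1.5), M, v)
        r_slow = index_response(IndexSpec(w=w, k=1.755, L=4.0), M, v)
        assert r_fast / r_slow == pytest.approx(8.0 / 3.0, rel=1e-12)

    def test_monotonicity_in_k_and_L(self):
        rng = np.random.default_rng(3)
        M = _random_psd(rng)
        v = rng.standard_normal(4)
        w = np.ones(4)
        rs = [index_response(IndexSpec(w=w, k=k, L=1.0), M, v) for k in (0.5, 1.0, 2.0)]
        assert rs[0] < rs[1] < rs[2]
        rL = [index_response(IndexSpec(w=w, k=1.0, L=L), M, v) for L in (1.0, 2.0, 4.0)]
        assert rL[0] > rL[1] > rL[2]

    def test_negative_quadratic_form_raises(self):
        spec = IndexSpec(w=np.ones(2), k=1.0, L=1.0)
        with pytest.raises(ValueError):
            index_response(spec, np.array([[-5.0, 0], [0, -5.0]]), np.ones(2))

    def test_single_trait_breeders_equation(self):
        # E = k h sigma_g with h^2 = C/P
        C, P, k = np.array([[2.0]]), np.array([[5.0]]), 1.4
        spec = IndexSpec(w=np.ones(1), k=k, L=1.0)
        b = psi_coefficients(P, C, np.ones(1))
        gain = expected_gains(spec, C, P, b)[0]
        assert gain == pytest.approx(k * np.sqrt(2.0 / 5.0) * np.sqrt(2.0))

    def test_gsi_gains_contract_to_response(self):
        rng = np.random.default_rng(4)
        Gam = _random_psd(rng)
        w = np.array([1.0, -1.0, 1.0, 1.0])
        spec = IndexSpec(w=w, k=1.755, L=1.5)
        E = expected_gains(spec, Gam, Gam, w)
        R = index_response(spec, Gam, w)
        assert w @ E == pytest.approx(R, abs=1e-12)

    def test_matches_dense_matrix_oracle(self):
        rng = np.random.default_rng(5)
        C = _random_psd(rng)
        P = C + _random_psd(rng)
        w = rng.standard_normal(4)
        b = np.linalg.solve(P, C @ w)
        spec = IndexSpec(w=w, k=2.0, L=0.5)
        E = expected_gains(spec, C, P, b)
        oracle = 2.0 / 0.5 * C @ b / np.sqrt(b @ P @ b)
        assert np.allclose(E, oracle, atol=1e-12)

    def test_psi_contraction_identity(self):
        # b'E_PSI * sqrt(b'Pb) * L/k = b'Cb, an algebraic consequence of the
        # gain and coefficient definitions
        rng = np.random.default_rng(6)
        C = _random_psd(rng)
        P = C + _random_psd(rng)
        w = rng.standard_normal(4)
        b = psi_coefficients(P, C, w)
        spec = IndexSpec(w=w, k=1.755, L=4.0)
        E = expected_gains(spec, C, P, b)
        lhs = (b @ E) * np.sqrt(b @ P @ b) * spec.L / spec.k
        assert lhs == pytest.approx(b @ C @ b, rel=1e-10)


class TestAccuracy:
    def test_perfect_estimate_gives_unit_accuracy(self):
        rng = np.random.default_rng(7)
        C = _random_psd(rng)
        w = np.ones(4)
        assert accuracy(C, C, w) == pytest.approx(1.0)

    def test_zero_estimate_gives_zero(self):
        assert accuracy(np.zeros((2, 2)), np.eye(2), np.ones(2)) == 0.0

    def test_overshoot_is_clipped(self, caplog):
        rho = accuracy(4.0 * np.eye(2), np.eye(2), np.ones(2))
        assert rho == 1.0

    def test_unclipped_value_available(self):
        rho = accuracy(4.0 * np.eye(2), np.eye(2), np.ones(2), clip=False)
        assert rho == pytest.approx(2.0)

    def test_zero_merit_variance_raises(self):
        with pytest.raises(ValueError):
            accuracy(np.eye(2), np.zeros((2, 2)), np.ones(2))


class TestEfficiencyAndTechnow:
    def test_equal_responses_unit_ratio(self):
        assert efficiency_ratio(2.5, 2.5) == 1.0

    def test_interval_driven_ratio(self):
        # equal accuracies, L_PSI = 4, L_GSI = 1.5 -> lambda = 2.667
        k, q = 1.755, 3.7
        r_gsi = k / 1.5 * q
        r_psi = k / 4.0 * q
        assert efficiency_ratio(r_gsi, r_psi) == pytest.approx(2.667, abs=1e-3)

    def test_zero_psi_response_raises(self):
        with pytest.raises(ZeroDivisionError):
            efficiency_ratio(1.0, 0.0)

    def test_lambda_two_forms_agree(self):
        # response-ratio form equals (L_PSI/L_GSI) * accuracy-ratio form
        rng = np.random.default_rng(8)
        C = _random_psd(rng)
        P = C + _random_psd(rng)
        Gam = _random_psd(rng)
        w = np.array([1.0, -1.0, 1.0, 1.0])
        b = psi_coefficients(P, C, w)
        k, Lp, Lg = 1.755, 4.0, 1.5
        lam_resp = efficiency_ratio(
            index_response(IndexSpec(w=w, k=k, L=Lg), Gam, w),
            index_response(IndexSpec(w=w, k=k, L=Lp), P, b),
        )
        rho_g = accuracy(Gam, C, w, kind="GSI", clip=False)
        rho_p = accuracy(P, C, w, kind="PSI", b=b, clip=False)
        assert lam_resp == pytest.approx(Lp / Lg * rho_g / rho_p, rel=1e-10)

    def test_technow_boundary_and_decisions(self):
        boundary = technow_inequality(4.0, 4.0, 0.8, 0.8)
        assert boundary["holds"] is False
        assert boundary["threshold"] == pytest.approx(4.0)
        rec = technow_inequality(1.5, 4.0, 0.95, 0.9)
        assert rec["holds"] is True
        assert rec["threshold"] == pytest.approx(4.0 * 0.95 / 0.9, rel=1e-12)
        assert technow_inequality(4.0, 4.0, 0.5, 1.0)["holds"] is False
        with pytest.raises(ValueError):
            technow_inequality(1.5, 4.0, 1.2, 0.9)


class TestSelection:
    def test_gsi_values_weighted_sums(self):
        gamma = np.array([[1.0, 2.0, 0.5, 1.0],
                          [0.0, -1.0, 1.0, 2.0],
                          [3.0, 1.0, -1.0, 0.0]])
        w = np.array([1.0, -1.0, 1.0, 1.0])
        assert np.allclose(gsi_values(gamma, w), [0.5, 4.0, 1.0])
        assert np.allclose(gsi_values(gamma, np.array([1.0, 0, 0, 0])), gamma[:, 0])

    def test_top_decile_of_500(self):
        rng = np.random.default_rng(9)
        values = rng.standard_normal(500)
        sel = truncate_select(values, 0.10)
        assert sel.size == 50
        assert values[sel].min() >= np.sort(values)[-50]

    def test_ties_resolved_by_original_order(self):
        sel = truncate_select(np.zeros(10), 0.3)
        assert np.array_equal(sel, [0, 1, 2])

    def test_select_everything_and_errors(self):
        values = np.arange(5.0)
        assert np.array_equal(truncate_select(values, 0.999), np.arange(5))
        with pytest.raises(ValueError):
            truncate_select(np.array([]), 0.5)
        with pytest.raises(ValueError):
            truncate_select(values, 1.5)


class TestModelObjects:
    def test_psi_model_fit_and_summary(self, small_genome, small_config):
        from gsindex.architecture import assign_architecture

        rng = np.random.default_rng(12)
        arch = assign_architecture(small_genome, small_config.target_matrix(),
                                   small_config.qtl_counts, small_config.heritabilities,
                                   rng)
        pop = make_f2(small_genome, 150, rng)
        compute_tbv(pop, arch.effects, small_genome)
        phen = simulate_phenotypes(pop, 4, rng, heritabilities=arch.heritabilities)
        res = PhenotypicSelectionIndex(phen, (1, -1, 1, 1)).fit(
            true_genetic_cov=np.cov(pop.tbv, rowvar=False)
        )
        assert res.selected_ids.size == 15
        assert res.response > 0
        assert res.response_per_year == pytest.approx(res.response / 4.0)
        assert 0 <= res.rho_H <= 1
        text = res.summary()
        assert "PSI" in text and "response/cycle" in text

    def test_gsi_model_consistency(self, small_genome, small_config):
        from gsindex.architecture import assign_architecture
        from gsindex.varcomp import estimate_cr

        rng = np.random.default_rng(13)
        arch = assign_architecture(small_genome, small_config.target_matrix(),
                                   small_config.qtl_counts, small_config.heritabilities,
                                   rng)
        pop = make_f2(small_genome, 150, rng)
        compute_tbv(pop, arch.effects, small_genome)
        phen = simulate_phenotypes(pop, 4, rng, heritabilities=arch.heritabilities)
        mm = markers_from_population(pop, small_genome)
        eff = fit_rrblup(mm, phen, estimate_cr(phen))
        geb = predict_gebv(mm, eff)
        res = GenomicSelectionIndex(geb, compute_grm(mm), (1, -1, 1, 1)).fit()
        # the GSI gains contracted with w reproduce the response exactly
        assert np.asarray(res.spec.w) @ res.gains == pytest.approx(res.response, abs=1e-10)
        assert res.selected_ids.size == 15
        assert "GSI" in res.summary()
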