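"""NMF multiplicative updates, VAF, order selection and recovery."""

from itertools import permutations

import numpy as np
import pytest

from emgsyn import (SynergyExtractor, compute_vaf, make_ground_truth,
                    nmf_factorize, normalize_synergy, select_order)
from emgsyn.synth import synthesize_envelope


def best_perm_mean_cosine(A, B):
    """Exhaustive-permutation assignment oracle (columns of A vs B)."""
    An = A / np.linalg.norm(A, axis=0)
    Bn = B / np.linalg.norm(B, axis=0)
    S = An.T @ Bn
    r = A.shape[1]
    return max(np.mean([S[i, p[i]] for i in range(r)]) for p in permutations(range(r)))


class TestVaf:
    def test_perfect_reconstruction_is_100(self, rng):
        V = rng.uniform(size=(5, 20))
        assert compute_vaf(V, V) == pytest.approx(100.0)

    def test_global_mean_reconstruction_is_0(self, rng):
        V = rng.uniform(size=(5, 20))
        assert compute_vaf(V, np.full_like(V, V.mean())) == pytest.approx(0.0)

    def test_hand_computed_case(self):
        V = np.array([[1.0, 2.0], [3.0, 4.0]])
        Vr = np.array([[1.0, 2.0], [3.0, 5.0]])
        # global mean 2.5, Σ(V−V̄)² = 5, SSE = 1 → VAF = 80 %
        assert compute_vaf(V, Vr) == pytest.approx(80.0)
        sse = np.sum((V - Vr) ** 2)
        sst = np.sum((V - V.mean()) ** 2)
        assert compute_vaf(V, Vr) == pytest.approx((1 - sse / sst) * 100)

    def test_uncentered_variant(self):
        V = np.array([[1.0, 2.0], [3.0, 4.0]])
        Vr = np.array([[1.0, 2.0], [3.0, 5.0]])
        assert compute_vaf(V, Vr, centered=False) == pytest.approx(
            (1 - 1.0 / 30.0) * 100)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            compute_vaf(np.ones((3, 3)), np.ones((3, 3)))


class TestNmf:
    def test_exact_rank2_reaches_vaf_999(self, rng):
        M0 = rng.uniform(size=(10, 2))
        P0 = rng.uniform(size=(2, 60))
        V = M0 @ P0
        s = nmf_factorize(V, 2, seed=0, n_restarts=10)
        assert s.vaf >= 99.9

    def test_reconstruction_error_non_increasing(self, noisy_envelope):
        s = nmf_factorize(noisy_envelope, 4, seed=1, n_restarts=3)
        diffs = np.diff(s.error_history)
        assert np.all(diffs <= 1e-10 * s.error_history[0])

    def test_nested_model_dominance(self, noisy_envelope):
        vafs = [nmf_factorize(noisy_envelope, r, seed=2, n_restarts=5).vaf
                for r in (1, 3, 14)]
        assert vafs[2] >= vafs[1] >= vafs[0]

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            nmf_factorize(np.array([[1.0, -0.1], [0.2, 0.3]]), 1)

    def test_restart_stability_on_separated_fixture(self, model_r3, rng):
        """Final R² dispersion over 20 restarts stays under 0.5 points."""
        V = synthesize_envelope(model_r3, 0.02, rng)
        s = nmf_factorize(V, 3, seed=3, n_restarts=20)
        sst = np.sum((V - V.mean()) ** 2)
        r2s = 100.0 * (1.0 - np.array(s.restart_errors) / sst)
        assert r2s.max() - r2s.min() < 0.5

    def test_comparable_to_sklearn_nmf(self, noisy_envelope):
        """Independent solver cross-check: our reconstruction error is no
        more than 2 % above scikit-learn's coordinate-descent NMF."""
        from sklearn.decomposition import NMF
        ours = nmf_factorize(noisy_envelope, 4, seed=4, n_restarts=10)
        sk = NMF(n_components=4, init="random", random_state=0, max_iter=3000)
        W = sk.fit_transform(noisy_envelope)
        err_sk = np.linalg.norm(noisy_envelope - W @ sk.components_)
        err_us = np.linalg.norm(noisy_envelope - ours.reconstruction)
        assert err_us <= 1.02 * err_sk


class TestNormalization:
    def test_unit_columns_product_invariant_idempotent(self, rng):
        M = rng.uniform(0.1, 1.0, size=(8, 3))
        P = rng.uniform(size=(3, 40))
        M1, P1 = normalize_synergy(M, P)
        np.testing.assert_allclose(np.linalg.norm(M1, axis=0), 1.0)
        assert np.linalg.norm(M @ P - M1 @ P1) < 1e-10
        M2, P2 = normalize_synergy(M1, P1)
        np.testing.assert_allclose(M2, M1, atol=1e-12)

    def test_zero_column_rejected(self):
        with pytest.raises(ValueError):
            normalize_synergy(np.zeros((3, 1)), np.ones((1, 5)))


class TestOrderSelection:
    def test_exact_piecewise_linear_knee(self):
        r = np.arange(1, 13)
        vaf = np.where(r <= 4, 20.0 * r, 80.0 + 0.5 * (r - 4))
        selected, _ = select_order(vaf, r)
        assert selected == 4

    def test_straight_line_breaks_tie_to_smallest(self):
        vaf = 50.0 + 3.0 * np.arange(1, 13)
        selected, residuals = select_order(vaf)
        assert selected == 2
        assert all(v < 1e-9 for v in residuals.values())

    def test_noisy_knee_curve_matches_exhaustive_scan(self):
        vaf = np.array([60, 75, 88, 95, 96, 96.5, 97, 97.4, 97.8, 98.1, 98.4, 98.6])
        selected, _ = select_order(vaf)
        # independent exhaustive scan with explicit lstsq fits
        best, best_res = None, np.inf
        r = np.arange(1, 13, dtype=float)
        for i in range(1, 11):
            total = 0.0
            for sl in (slice(0, i + 1), slice(i, 12)):
                Ax = np.column_stack([r[sl], np.ones(len(r[sl]))])
                res = np.linalg.lstsq(Ax, vaf[sl], rcond=None)
                pred = Ax @ np.linalg.lstsq(Ax, vaf[sl], rcond=None)[0]
                total += float(np.sum((vaf[sl] - pred) ** 2))
            if total < best_res - 1e-12:
                best, best_res = int(r[i]), total
        assert selected == best == 4

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            select_order(np.array([50.0, 90.0]))


class TestRecovery:
    def test_noiseless_order_and_modules_recovered(self, rng):
        """Parameter recovery on noiseless data: the elbow lands on the true
        r and modules match ground truth at cosine ≥ 0.99 (assignment by
        exhaustive permutation)."""
        model = make_ground_truth(3, 14, seed=21)
        V = synthesize_envelope(model, 0.0, rng)
        ext = SynergyExtractor(r_max=8, n_restarts=10, random_state=0).fit(V)
        assert ext.n_synergies_ == 3
        cos = best_perm_mean_cosine(ext.modules_, model.effective_modules())
        assert cos >= 0.99
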