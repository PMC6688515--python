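"""Inverse mapping: minimum-norm closed form, GCV, ICA, rescaling."""

import warnings

import numpy as np
import pytest

from posthoclab import (
    ContinuousRecording,
    MNEConfig,
    ica_decompose,
    mne_inverse,
    rescale_sources,
    select_component,
    select_lambda_gcv,
)
from posthoclab.inverse import SourceEstimate


def dense_inverse_oracle(X, A, lam):
    """Brute-force A^T inv(I + lam A A^T) X with an explicit inverse."""
    n_c = A.shape[0]
    return A.T @ np.linalg.inv(np.eye(n_c) + lam * A @ A.T) @ X


class TestMNEInverse:
    def test_identity_leadfield_small_lambda_is_near_passthrough(self, rng):
        X = rng.standard_normal((4, 50))
        est = mne_inverse(X, np.eye(4), MNEConfig(lam=1e-12))
        assert np.max(np.abs(est.S_hat - X)) < 1e-6

    def test_identity_leadfield_unit_lambda_halves(self, rng):
        X = rng.standard_normal((3, 20))
        est = mne_inverse(X, np.eye(3), MNEConfig(lam=1.0))
        np.testing.assert_allclose(est.S_hat, X / 2)

    def test_matches_dense_inverse_oracle(self, rng):
        A = rng.standard_normal((4, 8))
        X = rng.standard_normal((4, 50))
        est = mne_inverse(X, A, MNEConfig(lam=0.1))
        oracle = dense_inverse_oracle(X, A, 0.1)
        rel = np.max(np.abs(est.S_hat - oracle)) / np.max(np.abs(oracle))
        assert rel < 1e-10

    def test_random_instances_match_oracle_and_quadratic_minimizer(self, rng):
        """Closed form == dense inverse; lam * closed form == the minimizer
        of lam*||X - A S||^2 + ||S||^2 (computed by least squares)."""
        for _ in range(20):
            n_c = int(rng.integers(2, 9))
            n_s = int(rng.integers(n_c, 17))
            lam = float(10 ** rng.uniform(-2, 1))
            A = rng.standard_normal((n_c, n_s))
            X = rng.standard_normal((n_c, 30))
            S = mne_inverse(X, A, MNEConfig(lam=lam)).S_hat
            oracle = dense_inverse_oracle(X, A, lam)
            assert np.max(np.abs(S - oracle)) <= 1e-10 * max(np.max(np.abs(oracle)), 1)
            # augmented least squares: minimize ||sqrt(lam)(X - A S)||^2 + ||S||^2
            M = np.vstack([np.sqrt(lam) * A, np.eye(n_s)])
            B = np.vstack([np.sqrt(lam) * X, np.zeros((n_s, X.shape[1]))])
            S_min = np.linalg.lstsq(M, B, rcond=None)[0]
            rel = np.max(np.abs(lam * S - S_min)) / np.max(np.abs(S_min))
            assert rel < 1e-6

    def test_ridge_form_matches_standard_minimizer(self, rng):
        A = rng.standard_normal((5, 9))
        X = rng.standard_normal((5, 20))
        est = mne_inverse(X, A, MNEConfig(lam=0.3, form="ridge"))
        expected = A.T @ np.linalg.inv(A @ A.T + 0.3 * np.eye(5)) @ X
        np.testing.assert_allclose(est.S_hat, expected, atol=1e-12)

    def test_linearity(self, rng):
        A = rng.standard_normal((4, 6))
        X1, X2 = rng.standard_normal((2, 4, 30))
        cfg = MNEConfig(lam=0.5)
        lhs = mne_inverse(2.0 * X1 - 3.0 * X2, A, cfg).S_hat
        rhs = 2.0 * mne_inverse(X1, A, cfg).S_hat - 3.0 * mne_inverse(X2, A, cfg).S_hat
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_nonfinite_input_rejected(self):
        X = np.full((2, 10), np.nan)
        with pytest.raises(ValueError):
            mne_inverse(X, np.eye(2), MNEConfig(lam=1.0))


class TestGCV:
    grid = np.logspace(-6, 2, 30)

    def _scaled_A(self, rng, n=8, lo=0.3, hi=0.9):
        # square lead field with sub-unit singular values (well-conditioned)
        q1, _ = np.linalg.qr(rng.standard_normal((n, n)))
        q2, _ = np.linalg.qr(rng.standard_normal((n, n)))
        return q1 @ np.diag(rng.uniform(lo, hi, n)) @ q2

    def test_pure_noise_selects_grid_maximum(self, rng):
        A = self._scaled_A(rng)
        X = rng.standard_normal((8, 500))
        assert select_lambda_gcv(X, A, self.grid) == self.grid[-1]

    def test_noiseless_selects_grid_minimum(self, rng):
        A = self._scaled_A(rng)
        X = A @ rng.standard_normal((8, 500))
        assert select_lambda_gcv(X, A, self.grid) == self.grid[0]

    def test_single_element_grid_passthrough(self, rng):
        X = rng.standard_normal((3, 40))
        assert select_lambda_gcv(X, np.eye(3) * 0.5, [0.7]) == 0.7

    def test_negative_trace_candidates_skipped_with_warning(self, rng):
        A = 3.0 * np.eye(3)  # singular values 3 -> trace(I-H) < 0 at small lam
        X = rng.standard_normal((3, 40))
        with pytest.warns(UserWarning, match="skipped"):
            lam = select_lambda_gcv(X, A, [1e-4, 1e-3, 10.0])
        assert lam == 10.0

    def test_all_candidates_skipped_raises(self, rng):
        A = 3.0 * np.eye(3)
        X = rng.standard_normal((3, 40))
        with pytest.warns(UserWarning):
            with pytest.raises(RuntimeError):
                select_lambda_gcv(X, A, [1e-5, 1e-4])

    def test_auto_lambda_resolves_through_config(self, rng):
        A = self._scaled_A(rng, n=4)
        X = rng.standard_normal((4, 60))
        est = mne_inverse(X, A, MNEConfig(lam="auto", lambda_grid=self.grid))
        assert est.meta["lam"] in self.grid


class TestICA:
    def test_recovers_independent_uniform_sources(self, rng):
        S = rng.uniform(-1, 1, size=(2, 10**5))
        A = np.array([[1.0, 0.6], [0.4, 1.0]])
        est = ica_decompose(A @ S, n_components=2, seed=0)
        corr = np.abs(np.corrcoef(np.vstack([est.S_hat, S]))[:2, 2:])
        # each recovered row matches one true source up to permutation/sign
        best = max(corr[0, 0] * corr[1, 1], corr[0, 1] * corr[1, 0])
        assert best > 0.99**2

    def test_super_gaussian_three_source_recovery(self, rng):
        S = rng.laplace(size=(3, 10**5))
        A = rng.standard_normal((5, 3))
        est = ica_decompose(A @ S, n_components=3, seed=1)
        corr = np.abs(np.corrcoef(np.vstack([est.S_hat, S]))[:3, 3:])
        from scipy.optimize import linear_sum_assignment

        r, c = linear_sum_assignment(-corr)
        assert corr[r, c].mean() >= 0.95

    def test_shat_is_phi_times_x(self, rng):
        X = rng.standard_normal((4, 5000))
        est = ica_decompose(X, n_components=4, seed=0)
        np.testing.assert_array_equal(est.S_hat, est.unmixing @ X)

    def test_determinism_bitwise(self, rng):
        X = rng.standard_normal((4, 5000))
        a = ica_decompose(X, n_components=4, seed=3)
        b = ica_decompose(X, n_components=4, seed=3)
        np.testing.assert_array_equal(a.unmixing, b.unmixing)

    def test_component_count_clipped_with_warning(self, rng):
        X = rng.standard_normal((3, 5000))
        with pytest.warns(UserWarning, match="clipping"):
            est = ica_decompose(X, n_components=20, seed=0)
        assert est.n_sources == 3

    def test_rank_deficient_data_rejected(self, rng):
        base = rng.standard_normal((2, 5000))
        X = np.vstack([base, base.sum(axis=0, keepdims=True)])
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            ica_decompose(X, n_components=3, seed=0)

    def test_nonnegative_skew_sign_convention(self, rng):
        from scipy import stats

        X = rng.standard_normal((4, 20000)) ** 3  # skewed channels
        est = ica_decompose(X, n_components=4, seed=0)
        assert np.all(stats.skew(est.S_hat, axis=1) >= 0)


class TestRescaleSources:
    def _est(self, S):
        return SourceEstimate(S_hat=S, method="ica", unmixing=np.eye(S.shape[0]))

    def test_single_matching_channel_scales_by_inverse_channel_count(self):
        s = np.array([3.0, 4.0, 0.0, 0.0])
        s_unit = s / np.linalg.norm(s)
        X = np.vstack([s_unit, np.zeros((4, 4))])  # N_c = 5
        out = rescale_sources(self._est(s[None, :]), X)
        np.testing.assert_allclose(out.S_hat[0], s_unit / 5)

    def test_orthogonal_source_collapses_to_zero_and_is_flagged(self):
        s = np.array([[1.0, 0.0, 0.0, 0.0]])
        X = np.array([[0.0, 1.0, 0.0, 0.0], [0.0, 0.0, 1.0, 0.0]])
        out = rescale_sources(self._est(s), X)
        np.testing.assert_allclose(out.S_hat, 0.0)

    def test_zero_norm_row_skipped_with_warning(self, rng):
        S = np.vstack([np.zeros(10), rng.standard_normal(10)])
        X = rng.standard_normal((3, 10))
        with pytest.warns(UserWarning, match="zero-norm"):
            out = rescale_sources(self._est(S), X)
        assert out.meta["zero_norm_rows"] == [0]

    def test_matches_loop_oracle(self, rng):
        S = rng.standard_normal((3, 40))
        X = rng.standard_normal((5, 40))
        out = rescale_sources(self._est(S), X)
        for i in range(3):
            s_unit = S[i] / np.linalg.norm(S[i])
            scale = sum(float(s_unit @ X[c]) for c in range(5)) / 5
            np.testing.assert_allclose(out.S_hat[i], scale * s_unit, atol=1e-12)

    def test_invariant_to_input_row_scale(self, rng):
        S = rng.standard_normal((2, 60))
        X = rng.standard_normal((4, 60))
        a = rescale_sources(self._est(S), X).S_hat
        b = rescale_sources(self._est(S * 37.5), X).S_hat
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestSelectComponent:
    def _est(self, S):
        return SourceEstimate(S_hat=S, method="ica", unmixing=np.eye(S.shape[0]))

    def test_by_index_passthrough(self, rng):
        est = self._est(rng.standard_normal((20, 100)))
        assert select_component(est, "by_index:3") == 3
        assert select_component(est, ("by_index", 7)) == 7

    def test_by_index_out_of_range(self, rng):
        est = self._est(rng.standard_normal((4, 100)))
        with pytest.raises(ValueError):
            select_component(est, ("by_index", 9))

    def test_max_band_power_finds_planted_sinusoid(self, rng):
        fs = 120.0
        t = np.arange(int(20 * fs)) / fs
        from posthoclab.synthgen import _pink_noise

        S = np.vstack(
            [_pink_noise(t.size, rng) for _ in range(4)]
            + [3.0 * np.sin(2 * np.pi * 10 * t)]
        )
        est = self._est(S)
        assert select_component(est, ("max_band_power", (8, 12)), fs=fs) == 4

    def test_random_policy_is_seed_deterministic(self, rng):
        est = self._est(rng.standard_normal((20, 50)))
        picks = {select_component(est, "random", seed=11) for _ in range(5)}
        assert len(picks) == 1
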