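"""NNMF factorization, k-selection, fixed weightings, FWHM and CoA."""

import numpy as np
import pytest

from synergait import synergy as sy
from synergait.synthetic import DEFAULT_PROFILES, DEFAULT_W, _max_normalize_columns


def _bump_matrix(profiles=DEFAULT_PROFILES, samples=100, n_strides=6):
    pct = np.tile(np.arange(samples) * 100.0 / samples, n_strides)
    return np.stack([
        p.amplitude * np.exp(-0.5 * (((pct - p.center + 50) % 100 - 50) / p.width) ** 2)
        for p in profiles
    ])


class TestNNMF:
    def test_exact_factorization_recovered(self):
        W0 = _max_normalize_columns(DEFAULT_W)
        A0 = _bump_matrix()
        E = W0 @ A0
        m = sy.nnmf(E, 5, restarts=6, seed=0)
        assert m.vaf >= 0.999

    def test_rank_one(self, rng):
        E = np.outer(rng.random(11), rng.random(300))
        m = sy.nnmf(E, 1, restarts=3, seed=1)
        assert m.vaf >= 0.999

    def test_output_invariants(self, rng):
        E = rng.random((11, 400))
        m = sy.nnmf(E, 3, restarts=4, seed=2)
        assert np.all(m.W >= 0) and np.all(m.A >= 0)
        np.testing.assert_allclose(m.W.max(axis=0), 1.0)
        assert 0.0 <= m.vaf <= 1.0
        assert m.rep_errors.size == 4

    def test_input_validation(self, rng):
        with pytest.raises(ValueError, match="nonnegative"):
            sy.nnmf(-np.ones((4, 10)), 2)
        with pytest.raises(ValueError, match="exceeds"):
            sy.nnmf(np.ones((4, 10)), 5)
        bad = np.ones((4, 10)); bad[2] = 0.0
        with pytest.raises(ValueError, match="all-zero"):
            sy.nnmf(bad, 2)

    def test_matches_reference_mu_solver(self, rng):
        """Reconstruction error agrees with scikit-learn's multiplicative-
        update NMF on the same problem (independent implementation)."""
        from sklearn.decomposition import NMF

        E = rng.random((11, 300)) + 0.1
        mine = sy.nnmf(E, 4, restarts=10, max_iter=2000, tol=1e-9, seed=3)
        ref_best = np.inf
        for rs in range(5):
            ref = NMF(n_components=4, solver="mu", init="random",
                      max_iter=2000, tol=1e-9, random_state=rs)
            Wr = ref.fit_transform(E)
            ref_best = min(ref_best, np.linalg.norm(E - Wr @ ref.components_))
        my_err = np.linalg.norm(E - mine.W @ mine.A)
        assert my_err == pytest.approx(ref_best, rel=0.01)


class TestSelectK:
    def test_vaf_threshold_rule(self):
        W0 = _max_normalize_columns(DEFAULT_W[:, :3])
        A0 = _bump_matrix(DEFAULT_PROFILES[:3])
        E = W0 @ A0 + 0.01
        k, models = sy.select_k(E, vaf_min=0.85, restarts=4, seed=0)
        assert k <= 3
        assert models[k].vaf >= 0.85
        vafs = [models[i].vaf for i in sorted(models)]
        assert all(b >= a - 1e-9 for a, b in zip(vafs, vafs[1:]))

    def test_unreachable_threshold_errors(self, rng):
        E = rng.random((3, 80))  # noise: full rank needed
        with pytest.raises(ValueError, match="no k"):
            sy.select_k(E, vaf_min=0.99999, k_max=2, restarts=2, seed=1)


class TestFixedW:
    def test_block_slicing_and_column_count(self):
        rng = np.random.default_rng(0)
        W0 = _max_normalize_columns(DEFAULT_W)
        blocks = {}
        for tp in ("Pre", "Post1", "Post2"):
            for cond in ("normal", "narrow"):
                blocks[(tp, cond)] = W0 @ _bump_matrix(n_strides=4) \
                    + 0.01 * rng.random((11, 400))
        model, A = sy.fit_fixed_W(blocks, 5, restarts=4, seed=0)
        assert model.A.shape[1] == 6 * 400
        assert set(A) == set(blocks)
        assert all(a.shape == (5, 400) for a in A.values())

    def test_block_specific_timing_recovered(self):
        """Blocks sharing W but with shifted bump centers: the per-block
        activations peak at the block's own centers."""
        W0 = _max_normalize_columns(DEFAULT_W)
        from synergait.synthetic import SynergyProfile
        base = DEFAULT_PROFILES
        shifted = tuple(
            SynergyProfile(center=(p.center + 10) % 100, width=p.width,
                           amplitude=p.amplitude) for p in base)
        blocks = {
            ("Pre", "normal"): W0 @ _bump_matrix(base),
            ("Pre", "narrow"): W0 @ _bump_matrix(shifted),
        }
        model, A = sy.fit_fixed_W(blocks, 5, restarts=8, seed=1)
        perm = sy.match_synergies(W0, model.W)
        for j, p in enumerate(base):
            prof_a = A[("Pre", "normal")][perm[j]].reshape(6, 100).mean(axis=0)
            prof_b = A[("Pre", "narrow")][perm[j]].reshape(6, 100).mean(axis=0)
            pk_a = np.argmax(prof_a)
            pk_b = np.argmax(prof_b)
            assert abs(pk_a - round(p.center)) <= 3 or abs(pk_a - round(p.center)) >= 97
            shift = (pk_b - pk_a) % 100
            assert abs(shift - 10) <= 3

    def test_mismatched_muscle_count_rejected(self):
        with pytest.raises(ValueError, match="muscle"):
            sy.fit_fixed_W({("Pre", "normal"): np.ones((11, 10)),
                            ("Pre", "narrow"): np.ones((10, 10))}, 2)


class TestFWHM:
    def test_rectangular_pulse(self):
        p = np.zeros(100); p[10:30] = 1.0
        assert sy.fwhm(p) == 20

    def test_baseline_subtraction(self):
        p = np.full(100, 0.5); p[10:30] = 1.5
        assert sy.fwhm(p) == 20

    def test_flat_profile_is_zero(self):
        assert sy.fwhm(np.full(100, 0.3)) == 0

    def test_gaussian_bump_counts_match_enumeration(self):
        x = np.arange(100)
        p = np.exp(-0.5 * ((x - 50) / 5.0) ** 2)
        expected = int(np.sum(p - p.min() > 0.5 * (p.max() - p.min())))
        assert sy.fwhm(p) == expected

    def test_scale_and_baseline_invariance(self, rng):
        p = rng.random(100)
        assert sy.fwhm(p) == sy.fwhm(3.7 * p) == sy.fwhm(p + 2.0)


class TestCoA:
    def test_single_sample_at_zero(self):
        p = np.zeros(100); p[0] = 1.0
        assert sy.coa(p) == pytest.approx(0.0)

    def test_symmetric_bump_at_quarter_cycle(self):
        x = np.arange(100)
        p = np.exp(-0.5 * (((x - 25 + 50) % 100 - 50) / 6.0) ** 2)
        assert sy.coa(p) == pytest.approx(np.pi / 2)

    def test_shift_equivariance(self, rng):
        for _ in range(100):
            p = rng.random(100) + 0.01
            s = int(rng.integers(1, 100))
            base = sy.coa(p)
            shifted = sy.coa(np.roll(p, s))
            expected = (base + 2 * np.pi * s / 100) % (2 * np.pi)
            diff = (shifted - expected + np.pi) % (2 * np.pi) - np.pi
            assert abs(diff) < 1e-9

    def test_amplitude_invariance(self, rng):
        p = rng.random(100) + 0.1
        assert sy.coa(5.0 * p) == pytest.approx(sy.coa(p))

    def test_zero_resultant_undefined(self):
        with pytest.raises(ValueError, match="resultant"):
            sy.coa(np.ones(100))


class TestMatching:
    def test_identity(self):
        W = _max_normalize_columns(DEFAULT_W)
        np.testing.assert_array_equal(sy.match_synergies(W, W), np.arange(5))

    def test_permuted_copy(self):
        W = _max_normalize_columns(DEFAULT_W)
        perm = np.array([3, 0, 4, 1, 2])
        got = sy.match_synergies(W, W[:, perm])
        # W[:, perm][:, got[j]] must equal W[:, j]
        np.testing.assert_array_equal(perm[got], np.arange(5))

    def test_noisy_copy(self, rng):
        W = _max_normalize_columns(DEFAULT_W)
        perm = np.array([1, 2, 0, 4, 3])
        noisy = np.clip(W[:, perm] + 0.1 * rng.standard_normal(W.shape), 0, None)
        got = sy.match_synergies(W, noisy)
        np.testing.assert_array_equal(perm[got], np.arange(5))
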