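"""Supervised admixture likelihood, EM estimation, and LD pruning."""

import numpy as np
import pytest

import biogps as bg
from biogps.admixture import ld_prune


class TestLogLikelihood:
    def test_single_component_requires_q_one(self):
        F = np.array([[0.3, 0.7, 0.5]])
        g = [0, 1, 2]
        # likelihood depends only on F when K=1
        assert bg.log_likelihood([1.0], g, F) == pytest.approx(
            np.log(0.7**2) + np.log(2 * 0.7 * 0.3) + np.log(0.5**2)
        )

    def test_all_missing_gives_zero(self):
        F = np.array([[0.3, 0.7], [0.5, 0.5]])
        assert bg.log_likelihood([0.5, 0.5], [bg.MISSING, bg.MISSING], F) == 0.0

    def test_single_heterozygous_locus_closed_form(self):
        # p = 0.5*0.2 + 0.5*0.6 = 0.4; P(g=1) = 2 * 0.4 * 0.6 = 0.48
        ll = bg.log_likelihood([0.5, 0.5], [1], [[0.2], [0.6]])
        assert ll == pytest.approx(np.log(0.48))

    def test_dimension_mismatch_raises(self):
        with pytest.raises(bg.ShapeError):
            bg.log_likelihood([0.5, 0.5], [1, 1], [[0.2], [0.6]])
        with pytest.raises(bg.ShapeError):
            bg.log_likelihood([1.0], [1], [[0.2], [0.6]])


class TestEstimateAdmixture:
    def test_boundary_recovery_fixed_differences(self):
        L = 200
        F = np.vstack([np.full(L, 0.99), np.full(L, 0.01)])
        g = np.full(L, 2)
        q, converged, _ = bg.estimate_admixture(g, F)
        assert converged
        assert q[0] > 0.99

    def test_identical_rows_flagged_unidentifiable(self):
        F = np.tile(np.array([0.3, 0.6, 0.4]), (3, 1))
        est = bg.SupervisedAdmixture().fit(F)
        res = est.fit_result([[1, 2, 0]])
        assert res.unidentifiable
        assert np.allclose(res.Q[0], 1 / 3)

    def test_all_loci_missing_rejected(self):
        F = np.array([[0.3, 0.7], [0.5, 0.5]])
        with pytest.raises(bg.InputError):
            bg.estimate_admixture([bg.MISSING, bg.MISSING], F)

    def test_parameter_recovery_two_components(self):
        # simulate L loci at q = (0.3, 0.7) and recover within +/- 0.02
        rng = np.random.default_rng(11)
        L = 10_000
        F = np.clip(rng.beta(0.5, 0.5, size=(2, L)), 1e-6, 1 - 1e-6)
        q_true = np.array([0.3, 0.7])
        g = rng.binomial(2, q_true @ F)
        q, converged, _ = bg.estimate_admixture(g, F)
        assert converged
        assert np.all(np.abs(q - q_true) <= 0.02)

    def test_loglik_nondecreasing_along_em_path(self):
        rng = np.random.default_rng(2)
        L = 200
        F = np.clip(rng.beta(0.5, 0.5, size=(3, L)), 1e-6, 1 - 1e-6)
        g = rng.binomial(2, np.array([0.2, 0.5, 0.3]) @ F)
        # replay the multiplicative update manually and track the likelihood
        q = np.full(3, 1 / 3)
        prev = bg.log_likelihood(q, g, F)
        for _ in range(100):
            p = q @ F
            update = (g * F / p + (2 - g) * (1 - F) / (1 - p)).sum(axis=1)
            q = q * update / (2 * L)
            q /= q.sum()
            cur = bg.log_likelihood(q, g, F)
            assert cur >= prev - 1e-9
            prev = cur

    def test_matches_grid_search_oracle_small_problems(self):
        # K=2, L<=3: exhaustive grid over q1 in {0, 0.001, ..., 1}
        rng = np.random.default_rng(7)
        grid = np.linspace(0, 1, 1001)
        for _ in range(5):
            L = int(rng.integers(1, 4))
            # distinguishable components: at least one locus separates them
            while True:
                F = rng.uniform(0.05, 0.95, size=(2, L))
                if np.max(np.abs(F[0] - F[1])) >= 0.1:
                    break
            g = rng.integers(0, 3, size=L)
            lls = [bg.log_likelihood([q1, 1 - q1], g, F) for q1 in grid]
            q_grid = grid[int(np.argmax(lls))]
            q, _, _ = bg.estimate_admixture(g, F, tol=1e-12, max_iter=20_000)
            assert abs(q[0] - q_grid) <= 0.002

    def test_component_permutation_equivariance(self):
        rng = np.random.default_rng(13)
        L = 500
        F = np.clip(rng.beta(0.5, 0.5, size=(3, L)), 1e-6, 1 - 1e-6)
        g = rng.binomial(2, np.array([0.6, 0.3, 0.1]) @ F)
        q, _, _ = bg.estimate_admixture(g, F)
        perm = [2, 0, 1]
        q_perm, _, _ = bg.estimate_admixture(g, F[perm])
        assert np.allclose(q_perm, q[perm], atol=1e-8)


class TestSupervisedAdmixtureEstimator:
    def test_transform_shape_and_simplex(self, small_world):
        est = bg.SupervisedAdmixture().fit(small_world.ancestral_freqs)
        Q = est.transform(small_world.genotypes[:10])
        assert Q.shape == (10, small_world.config.n_components)
        assert np.allclose(Q.sum(axis=1), 1.0, atol=1e-9)

    def test_get_params_roundtrip(self):
        est = bg.SupervisedAdmixture(tol=1e-5, max_iter=10)
        assert bg.SupervisedAdmixture(**est.get_params()).tol == 1e-5

    def test_wrong_locus_count_rejected(self, small_world):
        est = bg.SupervisedAdmixture().fit(small_world.ancestral_freqs)
        with pytest.raises(bg.ShapeError):
            est.transform(small_world.genotypes[:2, :50])


class TestLDPrune:
    def test_duplicated_locus_removed_once(self, rng):
        col = rng.integers(0, 3, size=60)
        G = np.column_stack([col, col, rng.integers(0, 3, size=60)])
        kept = ld_prune(G, window=3, step=1)
        assert kept == [0, 2]  # the later duplicate is dropped

    def test_window_one_examines_no_pairs(self, rng):
        G = rng.integers(0, 3, size=(30, 20))
        assert ld_prune(G, window=1) == list(range(20))

    def test_independent_loci_mostly_retained(self):
        rng = np.random.default_rng(17)
        n, L = 200, 300
        p = rng.uniform(0.1, 0.9, size=L)
        G = rng.binomial(2, np.tile(p, (n, 1)))
        kept = ld_prune(G, window=50, step=5, r2_max=0.2)
        assert len(kept) >= 0.95 * L

    def test_monomorphic_loci_never_removed(self, rng):
        G = rng.integers(0, 3, size=(40, 5))
        G[:, 2] = 1  # zero variance
        kept = ld_prune(G, window=5, step=1)
        assert 2 in kept

    def test_no_retained_pair_exceeds_r2_in_any_window(self):
        rng = np.random.default_rng(23)
        base = rng.binomial(2, 0.5, size=(80, 40)).astype(float)
        # induce blocks of correlated loci
        for j in range(1, 40, 3):
            flip = rng.random(80) < 0.1
            base[:, j] = np.where(flip, rng.integers(0, 3, size=80), base[:, j - 1])
        window, step, r2_max = 10, 2, 0.2
        kept = ld_prune(base, window=window, step=step, r2_max=r2_max)
        for start in range(0, 39, step):
            idx = [j for j in range(start, min(start + window, 40)) if j in kept]
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    x, y = base[:, idx[a]], base[:, idx[b]]
                    if x.std() == 0 or y.std() == 0:
                        continue
                    assert np.corrcoef(x, y)[0, 1] ** 2 <= r2_max + 1e-12

    def test_pruner_estimator_transform(self, rng):
        col = rng.integers(0, 3, size=50)
        G = np.column_stack([col, col, rng.integers(0, 3, size=50)])
        pruner = bg.LDPruner(window=3, step=1).fit(G)
        assert pruner.transform(G).shape == (50, 2)
        assert pruner.get_support(indices=True) == [0, 2]
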