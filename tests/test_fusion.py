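"""Three-way parallel ICA: coupling objective, triplet selection, recovery."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from parafuse.datatypes import MODALITIES
from parafuse.fusion import (
    FusionConfig,
    _coupling_gradient_A,
    aggregate_link,
    align_signs,
    component_zscores,
    fit_parafusion,
    select_linked_triplet,
)
from parafuse.ica import InfomaxConfig, infomax, match_sources, pca_whiten


def _columns_with_exact_corrs(R, n=200, seed=0):
    """Columns whose *sample* correlation matrix equals R exactly."""
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, R.shape[0]))
    Z -= Z.mean(axis=0)
    Q, _ = np.linalg.qr(Z)        # orthonormal, still mean-zero
    L = np.linalg.cholesky(R)
    return Q @ L.T


class TestAggregateLink:
    def test_identical_columns_give_three(self, rng):
        a = rng.standard_normal(50)
        assert np.isclose(aggregate_link(a, a.copy(), a.copy()), 3.0)

    def test_orthogonal_columns_give_zero(self):
        A = _columns_with_exact_corrs(np.eye(3))
        assert aggregate_link(A[:, 0], A[:, 1], A[:, 2]) < 1e-20

    def test_arithmetic_example(self):
        # pairwise r = (0.5, 0.3, 0.1) -> 0.25 + 0.09 + 0.01 = 0.35
        R = np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.1], [0.3, 0.1, 1.0]])
        A = _columns_with_exact_corrs(R)
        assert np.isclose(aggregate_link(A[:, 0], A[:, 1], A[:, 2]), 0.35, atol=1e-12)

    def test_constant_column_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            aggregate_link(np.ones(10), rng.standard_normal(10), rng.standard_normal(10))


class TestCouplingGradient:
    def test_matches_finite_differences(self, rng):
        n, C = 30, 4
        A = rng.standard_normal((n, C))
        B = rng.standard_normal((n, C))
        pairs = [(0, 1), (2, 0)]

        def f(Amat):
            return sum(
                np.corrcoef(Amat[:, i], B[:, j])[0, 1] ** 2 for i, j in pairs
            )

        G = _coupling_gradient_A(A, B, pairs)
        eps = 1e-6
        for _ in range(20):
            i, j = rng.integers(0, n), rng.integers(0, C)
            Ap = A.copy(); Ap[i, j] += eps
            Am = A.copy(); Am[i, j] -= eps
            num = (f(Ap) - f(Am)) / (2 * eps)
            assert np.isclose(G[i, j], num, atol=1e-6)

    def test_gradient_through_unmixing_matches_finite_differences(self, rng):
        # the chain rule through A = dewhiten @ W^{-1}
        n, C = 25, 3
        Dw = rng.standard_normal((n, C))
        W = np.eye(C) + 0.1 * rng.standard_normal((C, C))
        B = rng.standard_normal((n, C))
        pairs = [(0, 1), (1, 2)]

        def f(Wmat):
            A = Dw @ np.linalg.inv(Wmat)
            return sum(np.corrcoef(A[:, i], B[:, j])[0, 1] ** 2 for i, j in pairs)

        A = Dw @ np.linalg.inv(W)
        G = _coupling_gradient_A(A, B, pairs)
        M = np.linalg.inv(W)
        gradW = -M.T @ (Dw.T @ G) @ M.T
        eps = 1e-6
        for _ in range(15):
            i, j = rng.integers(0, C), rng.integers(0, C)
            Wp = W.copy(); Wp[i, j] += eps
            Wm = W.copy(); Wm[i, j] -= eps
            num = (f(Wp) - f(Wm)) / (2 * eps)
            assert np.isclose(gradW[i, j], num, atol=1e-5)


class TestFitParafusion:
    def test_planted_triplet_recovered(self, fitted, cohort, cohort_config):
        _, _, truth = cohort
        targets = dict(zip(
            [(MODALITIES[0], MODALITIES[1]), (MODALITIES[0], MODALITIES[2]),
             (MODALITIES[1], MODALITIES[2])],
            cohort_config.target_corrs,
        ))
        for pair, r in fitted.triplet_corrs.items():
            assert abs(r) - abs(targets[pair]) < 0.1
            assert abs(abs(r) - abs(targets[pair])) <= 0.1
        for m, t_idx in zip(MODALITIES, truth.triplet):
            assignment, corrs = match_sources(fitted.sources(m), truth.sources[m])
            assert corrs.mean() >= 0.9
            # the planted triplet component itself is recovered cleanly
            assert corrs[t_idx] >= 0.9

    def test_lambda_zero_equals_independent_infomax(self, prepared, cohort_config):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_parafusion(
                prepared[MODALITIES[0]], prepared[MODALITIES[1]], prepared[MODALITIES[2]],
                cohort_config.n_components, FusionConfig(seed=21, lam=0.0),
            )
        rng = np.random.default_rng(21)
        seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=3)]
        for m, order, s in zip(MODALITIES, cohort_config.n_components, seeds):
            Xw, K, Dw, _ = pca_whiten(prepared[m], order)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                d = infomax(Xw, K, Dw, InfomaxConfig(seed=s))
            assert np.abs(res.sources(m) - d.sources).max() < 1e-8
            assert np.abs(res.loadings(m) - d.loadings).max() < 1e-8

    def test_seeded_determinism(self, prepared, cohort_config, fitted):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res2 = fit_parafusion(
                prepared[MODALITIES[0]], prepared[MODALITIES[1]], prepared[MODALITIES[2]],
                cohort_config.n_components, FusionConfig(seed=11),
            )
        for m in MODALITIES:
            assert np.array_equal(res2.sources(m), fitted.sources(m))
        assert res2.triplet == fitted.triplet

    def test_coupling_strictly_helps_at_default_lambda(self, prepared, cohort_config):
        aggs = {}
        for lam in (0.0, 0.25, 0.5):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = fit_parafusion(
                    prepared[MODALITIES[0]], prepared[MODALITIES[1]],
                    prepared[MODALITIES[2]], cohort_config.n_components,
                    FusionConfig(seed=11, lam=lam),
                )
            i, j, k = res.triplet
            aggs[lam] = aggregate_link(
                res.loadings(MODALITIES[0])[:, i],
                res.loadings(MODALITIES[1])[:, j],
                res.loadings(MODALITIES[2])[:, k],
            )
        assert aggs[0.0] <= aggs[0.25] <= aggs[0.5]
        assert aggs[0.5] > aggs[0.0]

    def test_misaligned_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="subject"):
            fit_parafusion(
                rng.standard_normal((10, 20)), rng.standard_normal((11, 20)),
                rng.standard_normal((10, 20)), (2, 2, 2),
            )


class TestSelectTriplet:
    def test_single_component_models(self):
        R = {
            (MODALITIES[0], MODALITIES[1]): np.array([[0.4]]),
            (MODALITIES[0], MODALITIES[2]): np.array([[-0.2]]),
            (MODALITIES[1], MODALITIES[2]): np.array([[0.1]]),
        }
        triplet, corrs = select_linked_triplet(R)
        assert triplet == (0, 0, 0)
        assert corrs[(MODALITIES[0], MODALITIES[2])] == -0.2

    def test_tie_breaks_to_lowest_lexicographic(self):
        R0 = np.zeros((2, 2))
        R = {
            (MODALITIES[0], MODALITIES[1]): R0,
            (MODALITIES[0], MODALITIES[2]): R0.copy(),
            (MODALITIES[1], MODALITIES[2]): R0.copy(),
        }
        triplet, _ = select_linked_triplet(R)
        assert triplet == (0, 0, 0)

    def test_planted_indices_scored_highest(self, fitted, cohort, cohort_config):
        # the selected triplet matches the planted one through source matching
        _, _, truth = cohort
        for m, t_est, t_true in zip(MODALITIES, fitted.triplet, truth.triplet):
            assignment, _ = match_sources(fitted.sources(m), truth.sources[m])
            assert assignment[t_true] == t_est


class TestAlignSigns:
    def test_product_invariant_and_direction(self, fitted, cohort):
        _, pheno, _ = cohort
        dx = pheno["diagnosis"].to_numpy()
        before = {m: fitted.loadings(m) @ fitted.sources(m) for m in MODALITIES}
        res = align_signs(fitted, dx)
        hc = dx == "HC"
        for m in MODALITIES:
            after = res.loadings(m) @ res.sources(m)
            assert np.abs(after - before[m]).max() < 1e-12
            means_hc = res.loadings(m)[hc].mean(axis=0)
            means_sz = res.loadings(m)[~hc].mean(axis=0)
            assert (means_hc >= means_sz - 1e-12).all()

    def test_already_aligned_unchanged(self, rng):
        # equal group means: the >= convention flips nothing
        from parafuse.datatypes import Decomposition, FusionResult

        A = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        S = rng.standard_normal((2, 30))
        d = Decomposition(
            sources=S.copy(), loadings=A.copy(), unmixing=np.eye(2),
            bias=np.zeros(2), whitening=np.eye(2)[:, :2], dewhitening=A.copy(),
            order=2,
        )
        res = FusionResult(
            decompositions={m: d for m in MODALITIES},
            corr={k: np.zeros((2, 2)) for k in
                  [(MODALITIES[0], MODALITIES[1]), (MODALITIES[0], MODALITIES[2]),
                   (MODALITIES[1], MODALITIES[2])]},
            corr_p={k: np.ones((2, 2)) for k in
                    [(MODALITIES[0], MODALITIES[1]), (MODALITIES[0], MODALITIES[2]),
                     (MODALITIES[1], MODALITIES[2])]},
            triplet=(0, 0, 0),
            triplet_corrs={},
        )
        out = align_signs(res, np.array(["HC", "SZ", "HC", "SZ"]))
        assert np.array_equal(out.sources(MODALITIES[0]), S)


class TestComponentZscores:
    def test_normal_tail_fraction(self, rng):
        z, top = component_zscores(rng.standard_normal(100_000))
        assert np.isclose(len(top) / 100_000, 0.0455, atol=0.005)

    def test_spike_selected(self, rng):
        row = rng.standard_normal(1000)
        row[137] = 10 * row.std() + row.mean()
        _, top = component_zscores(row)
        assert 137 in top

    def test_constant_row_rejected(self):
        with pytest.raises(ValueError):
            component_zscores(np.full(50, 3.0))
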