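"""Linkage statistics, group tests, cognition associations, stability, PCs."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from parafuse.datatypes import MODALITIES
from parafuse.stats import (
    ancestry_pcs,
    chi2_independence,
    cognition_association,
    group_difference,
    group_difference_from_stats,
    pairwise_loading_correlations,
    partial_correlation,
    regress_out_medication,
    stability_10fold,
)
from parafuse.synthetic import CohortConfig, generate_genotypes, generate_linked_cohort


class TestPairwiseCorrelations:
    def test_family_size_arithmetic(self, rng):
        # orders (13, 10, 25): 13*10 + 13*25 + 10*25 = 705 pairs
        A1 = rng.standard_normal((30, 13))
        A2 = rng.standard_normal((30, 10))
        A3 = rng.standard_normal((30, 25))
        rep = pairwise_loading_correlations(A1, A2, A3)
        assert rep.family_size == 705
        assert np.isclose(rep.bonferroni_threshold, 0.05 / 705)

    def test_identical_columns(self, rng):
        a = rng.standard_normal(40)
        A = a[:, None]
        rep = pairwise_loading_correlations(A, A.copy(), A.copy())
        assert np.allclose(rep.pairs["r"], 1.0)
        assert (rep.pairs["p"] < 1e-30).all()

    def test_null_familywise_error_controlled(self):
        hits = 0
        n_seeds = 20
        for s in range(n_seeds):
            rng = np.random.default_rng(s)
            rep = pairwise_loading_correlations(
                rng.standard_normal((400, 8)),
                rng.standard_normal((400, 6)),
                rng.standard_normal((400, 10)),
            )
            hits += rep.pairs["significant"].any()
        # FWER is controlled at 0.05; allow binomial noise at 20 seeds
        assert hits <= 3

    def test_self_consistency(self, fitted):
        rep = pairwise_loading_correlations(
            fitted.loadings(MODALITIES[0]),
            fitted.loadings(MODALITIES[1]),
            fitted.loadings(MODALITIES[2]),
        )
        row = rep.pairs.iloc[17]
        A = fitted.loadings(row["modality_a"])[:, row["comp_a"]]
        B = fitted.loadings(row["modality_b"])[:, row["comp_b"]]
        assert np.isclose(row["r"], np.corrcoef(A, B)[0, 1], atol=1e-12)


class TestPartialCorrelation:
    def test_orthogonal_covariate_equals_plain(self, rng):
        x, y = rng.standard_normal((2, 80))
        c = _orthogonalize(rng.standard_normal(80), np.column_stack([x, y]))
        r_partial, _ = partial_correlation(x, y, c)
        r_plain = np.corrcoef(x, y)[0, 1]
        assert np.isclose(r_partial, r_plain, atol=1e-10)

    def test_outcome_linear_in_covariates(self, rng):
        c = rng.standard_normal((60, 2))
        x = rng.standard_normal(60)
        y = c @ [2.0, -1.0] + 3.0
        r, p = partial_correlation(x, y, c)
        assert abs(r) < 1e-6

    def test_worked_example_against_double_regression_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0, 8.0, 7.0])
        c = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        r, p = partial_correlation(x, y, c)
        D = np.column_stack([np.ones(8), c])
        rx = x - D @ np.linalg.lstsq(D, x, rcond=None)[0]
        ry = y - D @ np.linalg.lstsq(D, y, rcond=None)[0]
        r_oracle = np.corrcoef(rx, ry)[0, 1]
        t = r_oracle * np.sqrt((8 - 1 - 2) / (1 - r_oracle**2))
        p_oracle = 2 * sps.t.sf(abs(t), 8 - 1 - 2)
        assert np.isclose(r, r_oracle, atol=1e-12)
        assert np.isclose(p, p_oracle, atol=1e-12)

    def test_collinear_covariates_warn(self, rng):
        x, y = rng.standard_normal((2, 30))
        c = rng.standard_normal(30)
        with pytest.warns(UserWarning, match="collinear"):
            partial_correlation(x, y, np.column_stack([c, 2 * c]))


def _orthogonalize(v, others):
    D = np.column_stack([np.ones(len(v)), others])
    return v - D @ np.linalg.lstsq(D, v, rcond=None)[0]


class TestGroupDifference:
    def test_identical_groups(self):
        x = np.tile([1.0, 2.0, 3.0], 2)
        dx = np.array(["HC"] * 3 + ["SZ"] * 3)
        t, p = group_difference(x, dx)
        assert t == 0.0 and p == 1.0

    def test_summary_stats_equals_raw(self, rng):
        x = rng.standard_normal(50)
        dx = np.array(["HC"] * 30 + ["SZ"] * 20)
        t1, p1 = group_difference(x, dx)
        a, b = x[:30], x[30:]
        t2, p2 = group_difference_from_stats(
            a.mean(), a.std(ddof=1), 30, b.mean(), b.std(ddof=1), 20
        )
        assert np.isclose(t1, t2) and np.isclose(p1, p2)

    def test_power_matches_welch_formula(self):
        # planted d = 0.3, n = 450/450: closed-form Welch power as the oracle
        n1 = n2 = 450
        d = 0.3
        df = n1 + n2 - 2
        crit = sps.t.isf(0.025, df)
        nc = d / np.sqrt(1 / n1 + 1 / n2)
        power_theory = sps.nct.sf(crit, df, nc) + sps.nct.cdf(-crit, df, nc)
        hits = 0
        n_sim = 200
        for s in range(n_sim):
            rng = np.random.default_rng(s)
            x = np.concatenate([rng.standard_normal(n1) + d, rng.standard_normal(n2)])
            _, p = group_difference(x, np.array(["HC"] * n1 + ["SZ"] * n2))
            hits += p < 0.05
        assert abs(hits / n_sim - power_theory) < 0.05


class TestChi2:
    def test_exhaustive_small_tables_vs_margin_oracle(self):
        # every 2x2 table with n <= 20 and non-degenerate margins
        for a in range(21):
            for b in range(21 - a):
                for c in range(21 - a - b):
                    d = 20 - a - b - c
                    T = np.array([[a, b], [c, d]])
                    if (T.sum(0) == 0).any() or (T.sum(1) == 0).any():
                        continue
                    chi2, p = chi2_independence(T)
                    n = T.sum()
                    E = np.outer(T.sum(1), T.sum(0)) / n
                    chi2_oracle = ((T - E) ** 2 / E).sum()
                    assert np.isclose(chi2, chi2_oracle, atol=1e-10)


class TestCognitionAssociation:
    def test_null_pvalues_uniform(self):
        pvals = []
        for s in range(50):
            rng = np.random.default_rng(s)
            load = {"fALFF": rng.standard_normal(150)}
            scores = pd.DataFrame({"DB": rng.standard_normal(150)})
            out = cognition_association(load, scores)
            pvals.append(out["p"].iloc[0])
        _, ks_p = sps.kstest(pvals, "uniform")
        assert ks_p > 0.01

    def test_chain_generated_db_positive_association(self, fitted, cohort):
        _, pheno, truth = cohort
        res = fitted
        i = res.triplet[0]
        # sign-align the estimated fALFF triplet loading with the truth
        t_idx = truth.triplet[0]
        est = res.loadings("fALFF")[:, i]
        sign = np.sign(np.corrcoef(est, truth.loadings["fALFF"][:, t_idx])[0, 1])
        out = cognition_association(
            {"fALFF": est * sign},
            pheno[["DB"]],
            pheno,
            medication=pheno["medication"].to_numpy(),
        )
        row = out.iloc[0]
        assert row["r"] > 0 and row["p"] < 0.01

    def test_empty_covariates_equals_plain_pearson(self, rng):
        load = {"GM": rng.standard_normal(60)}
        scores = pd.DataFrame({"DF": rng.standard_normal(60) + 0.5 * load["GM"]})
        out = cognition_association(load, scores, covariates=None)
        r_plain, p_plain = sps.pearsonr(load["GM"], scores["DF"])
        assert np.isclose(out["r"].iloc[0], r_plain, atol=1e-10)
        assert np.isclose(out["p"].iloc[0], p_plain, atol=1e-10)

    def test_medication_regression_touches_only_dosed(self, rng):
        load = rng.standard_normal(20)
        med = np.full(20, np.nan)
        med[:8] = rng.uniform(100, 600, 8)
        adj = regress_out_medication(load, med)
        assert np.array_equal(adj[8:], load[8:])
        assert not np.array_equal(adj[:8], load[:8])
        # dosed subset is now uncorrelated with dose
        assert abs(np.corrcoef(adj[:8], med[:8])[0, 1]) < 1e-10


class TestStability:
    def test_fold_means_near_targets(self, prepared, cohort_config):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = stability_10fold(
                prepared[MODALITIES[0]], prepared[MODALITIES[1]],
                prepared[MODALITIES[2]], cohort_config.n_components, seed=11,
            )
        assert out["n_folds_used"] == 10
        targets = np.array(cohort_config.target_corrs)
        assert np.all(np.abs(out["mean"] - targets) <= 0.1)
        assert np.all(out["sd"] < 0.1)

    def test_same_seed_same_folds(self):
        cfg = CohortConfig(
            n_subjects=120, n_sites=2, n_features=(80, 80, 80),
            n_components=(2, 2, 2), triplet=(0, 0, 0),
        )
        feats, pheno, _ = generate_linked_cohort(cfg, seed=2)
        args = [feats[m].values for m in MODALITIES]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = stability_10fold(*args, cfg.n_components, seed=4, n_folds=5)
            b = stability_10fold(*args, cfg.n_components, seed=4, n_folds=5)
        assert np.array_equal(a["mean"], b["mean"])
        assert np.array_equal(a["sd"], b["sd"])


class TestAncestryPCs:
    def test_two_subpopulations_separated(self):
        rng = np.random.default_rng(0)
        # two populations with diverged allele frequencies
        n, p = 120, 300
        maf_a = rng.uniform(0.1, 0.5, p)
        shift = rng.uniform(-0.2, 0.2, p)
        maf_b = np.clip(maf_a + shift, 0.05, 0.5)
        dos = np.empty((n, p))
        for i in range(n):
            maf = maf_a if i < 60 else maf_b
            dos[i] = rng.binomial(2, maf)
        from parafuse.datatypes import GenotypeMatrix

        G = GenotypeMatrix(dos, [f"rs{j}" for j in range(p)], [f"S{i}" for i in range(n)])
        pcs = ancestry_pcs(G, 3)
        group = np.array([0.0] * 60 + [1.0] * 60)
        assert abs(np.corrcoef(pcs[:, 0], group)[0, 1]) > 0.9
        assert np.allclose(pcs.T @ pcs, np.eye(3), atol=1e-10)

    def test_homogeneous_population_no_separation(self):
        G = generate_genotypes(100, 300, maf_range=(0.1, 0.5), seed=1)
        pcs = ancestry_pcs(G, 1)
        group = np.array([0.0] * 50 + [1.0] * 50)
        assert abs(np.corrcoef(pcs[:, 0], group)[0, 1]) < 0.4

    def test_k_zero_and_k_too_large(self):
        G = generate_genotypes(20, 30, seed=2)
        assert ancestry_pcs(G, 0).shape == (20, 0)
        with pytest.raises(ValueError):
            ancestry_pcs(G, 25)
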