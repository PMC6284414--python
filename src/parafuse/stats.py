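"""Post-fusion statistics: linkage, group differences, cognition, stability.

All correlation families are Bonferroni-controlled with the family size
recorded.  The two-sample test defaults to Welch (unequal variances): on
published demographic tables of this design, Welch reproduces the printed age
p-value from the printed moments where the pooled-variance test does not.
The 2x2 chi-square defaults to Pearson without continuity correction for the
same reason.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix, MODALITIES
from .prep import build_design

__all__ = [
    "LinkageReport",
    "pairwise_loading_correlations",
    "partial_correlation",
    "group_difference",
    "group_difference_from_stats",
    "chi2_independence",
    "cognition_association",
    "stability_10fold",
    "ancestry_pcs",
]


@dataclass
class LinkageReport:
    """Correlation / group-difference evidence with its multiplicity family."""

    pairs: pd.DataFrame = field(default_factory=pd.DataFrame)
    family_size: int = 0
    alpha: float = 0.05
    extras: dict = field(default_factory=dict)

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / self.family_size if self.family_size else self.alpha


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant column: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def pairwise_loading_correlations(
    A1: np.ndarray, A2: np.ndarray, A3: np.ndarray, alpha: float = 0.05
) -> LinkageReport:
    """Pearson r and two-sided p for every cross-modality component pair.

    The Bonferroni family is the total pair count C1*C2 + C1*C3 + C2*C3.
    """
    mats = {m: np.asarray(a, float) for m, a in zip(MODALITIES, (A1, A2, A3))}
    n = mats[MODALITIES[0]].shape[0]
    if any(a.shape[0] != n for a in mats.values()):
        raise ValueError("loading matrices must share subject rows")
    rows = []
    for mi, mj in [(0, 1), (0, 2), (1, 2)]:
        Ai, Aj = mats[MODALITIES[mi]], mats[MODALITIES[mj]]
        for i in range(Ai.shape[1]):
            for j in range(Aj.shape[1]):
                r, p = _pearson(Ai[:, i], Aj[:, j])
                rows.append((MODALITIES[mi], MODALITIES[mj], i, j, r, p))
    df = pd.DataFrame(
        rows, columns=["modality_a", "modality_b", "comp_a", "comp_b", "r", "p"]
    )
    family = len(df)
    df["significant"] = df["p"] < alpha / family
    return LinkageReport(pairs=df, family_size=family, alpha=alpha)


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None,
) -> tuple[float, float]:
    """Pearson correlation of the covariate-regression residuals of x and y.

    p comes from the t-transform with df = n - n_covariates - 2.  Collinear
    covariate columns are dropped with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if covariates is None or (hasattr(covariates, "shape") and covariates.shape[-1] == 0):
        C = np.empty((n, 0))
    else:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
    D = np.column_stack([np.ones(n), C])
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        keep = []
        for j in range(D.shape[1]):
            if np.linalg.matrix_rank(D[:, keep + [j]]) > len(keep):
                keep.append(j)
        warnings.warn("collinear covariates dropped in partial correlation")
        D = D[:, keep]
    k = D.shape[1] - 1  # number of covariates actually used
    if n <= k + 2:
        raise ValueError("need n > n_covariates + 2")
    H = D @ np.linalg.lstsq(D, np.column_stack([x, y]), rcond=None)[0]
    rx = x - H[:, 0]
    ry = y - H[:, 1]
    scale = max(np.abs(x).max(), np.abs(y).max(), 1.0)
    if rx.std() < 1e-12 * scale or ry.std() < 1e-12 * scale:
        # a variable fully explained by the covariates has nothing left to
        # correlate
        return 0.0, 1.0
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - k - 2
    r_ = np.clip(r, -0.9999999999, 0.9999999999)
    t = r_ * np.sqrt(df / (1.0 - r_**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def group_difference(
    x: np.ndarray, diagnosis: np.ndarray, equal_var: bool = False
) -> tuple[float, float]:
    """Two-sample t-test HC vs SZ (Welch by default), two-sided."""
    diagnosis = np.asarray(diagnosis)
    a = np.asarray(x, float)[diagnosis == "HC"]
    b = np.asarray(x, float)[diagnosis == "SZ"]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 subjects")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def group_difference_from_stats(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    equal_var: bool = False,
) -> tuple[float, float]:
    """Summary-statistics entry point for the two-sample t-test; equals the
    raw-data version when fed that data's own moments."""
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var
    )
    return float(res.statistic), float(res.pvalue)


def chi2_independence(
    table: np.ndarray, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square of independence on a contingency table (no Yates
    correction by default)."""
    chi2, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=correction)
    return float(chi2), float(p)


def regress_out_medication(
    loadings: np.ndarray, medication: np.ndarray
) -> np.ndarray:
    """Residualize a loading vector on medication dose, on the dosed subset
    only; subjects without a recorded dose keep their unadjusted loading."""
    x = np.asarray(loadings, float).copy()
    med = np.asarray(medication, float)
    dosed = ~np.isnan(med)
    if not dosed.any():
        raise ValueError("no subject has a recorded medication dose")
    D = np.column_stack([np.ones(dosed.sum()), med[dosed] - med[dosed].mean()])
    beta, *_ = np.linalg.lstsq(D, x[dosed], rcond=None)
    # remove only the dose slope, preserving the subset's mean level so dosed
    # and un-dosed patients stay on a common scale
    x[dosed] = x[dosed] - D @ beta + beta[0]
    return x


def cognition_association(
    loadings: dict[str, np.ndarray] | pd.DataFrame,
    scores: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    covariate_columns: tuple[str, ...] = ("age", "sex", "site", "diagnosis"),
    medication: np.ndarray | None = None,
) -> pd.DataFrame:
    """Partial Pearson correlation of each loading with each cognition score.

    Covariates (age, sex, site dummies, diagnosis by default) are controlled.
    With ``medication`` given, medication is regressed from each loading on
    the dosed-subject subset only (others untouched) before the association
    is computed on all subjects.  PANSS columns go through the same path.
    """
    if isinstance(loadings, pd.DataFrame):
        loadings = {c: loadings[c].to_numpy() for c in loadings.columns}
    if covariates is not None and covariate_columns:
        cols = tuple(c for c in covariate_columns if c != "diagnosis")
        D, _ = build_design(covariates, cols)
        D = D[:, 1:]  # partial_correlation adds its own intercept
        if "diagnosis" in covariate_columns:
            dx = (covariates["diagnosis"] == "SZ").to_numpy(float)
            D = np.column_stack([D, dx])
    else:
        D = None
    rows = []
    for name, vec in loadings.items():
        vec = np.asarray(vec, float)
        if medication is not None:
            vec = regress_out_medication(vec, medication)
        for score in scores.columns:
            s = scores[score].to_numpy(float)
            ok = ~np.isnan(s)
            r, p = partial_correlation(
                vec[ok], s[ok], D[ok] if D is not None else None
            )
            rows.append((name, score, r, p, int(ok.sum())))
    return pd.DataFrame(rows, columns=["loading", "score", "r", "p", "n"])


def stability_10fold(
    X1, X2, X3,
    orders: tuple[int, int, int],
    config=None,
    seed: int = 0,
    n_folds: int = 10,
) -> dict:
    """Refit the fusion on each 90% fold complement and summarize the triplet.

    The full-data triplet is matched in each fold by source correlation; the
    three pairwise loading correlations (sign-aligned through the source
    match) are recorded, and their mean +/- SD returned.
    """
    from .fusion import FusionConfig, fit_parafusion

    config = config or FusionConfig()
    vals = [X.values if hasattr(X, "values") else np.asarray(X, float) for X in (X1, X2, X3)]
    n = vals[0].shape[0]
    if n // n_folds < 1 or n - n // n_folds < 10:
        raise ValueError("too few subjects per fold complement")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    full = fit_parafusion(X1, X2, X3, orders, config, seed=seed)
    i, j, k = full.triplet
    full_sources = {
        m: full.sources(m)[c] for m, c in zip(MODALITIES, (i, j, k))
    }
    records = []
    for f, hold in enumerate(folds):
        keep = np.setdiff1d(perm, hold)
        try:
            sub = fit_parafusion(
                vals[0][keep], vals[1][keep], vals[2][keep], orders, config,
                seed=seed + 1000 + f,
            )
        except RuntimeError as exc:
            warnings.warn(f"fold {f} failed to converge ({exc}); excluded")
            continue
        matched = {}
        signs = {}
        for m in MODALITIES:
            C = np.corrcoef(np.vstack([full_sources[m], sub.sources(m)]))[0, 1:]
            c = int(np.argmax(np.abs(C)))
            matched[m] = sub.loadings(m)[:, c] * np.sign(C[c])
            signs[m] = float(C[c])
        r12 = np.corrcoef(matched[MODALITIES[0]], matched[MODALITIES[1]])[0, 1]
        r13 = np.corrcoef(matched[MODALITIES[0]], matched[MODALITIES[2]])[0, 1]
        r23 = np.corrcoef(matched[MODALITIES[1]], matched[MODALITIES[2]])[0, 1]
        records.append((f, r12, r13, r23))
    arr = np.array([(a, b, c) for _, a, b, c in records])
    return {
        "folds": records,
        "mean": arr.mean(axis=0),
        "sd": arr.std(axis=0, ddof=1),
        "pairs": [
            (MODALITIES[0], MODALITIES[1]),
            (MODALITIES[0], MODALITIES[2]),
            (MODALITIES[1], MODALITIES[2]),
        ],
        "n_folds_used": len(records),
    }


def ancestry_pcs(G: GenotypeMatrix, k: int) -> np.ndarray:
    """Top-k principal component scores of the column-standardized dosages.

    Missing dosages are mean-imputed per SNP.  Columns are orthonormal
    (left singular vectors), intended as additional covariates in
    :func:`partial_correlation`.
    """
    X = G.dosages.copy()
    mean = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = np.take(mean, idx[1])
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X /= sd
    rank = np.linalg.matrix_rank(X)
    if k > rank:
        raise ValueError(f"k={k} exceeds rank {rank}")
    if k == 0:
        return np.empty((G.n_subjects, 0))
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    return U[:, :k]
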