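"""Covariate-adjusted simple mediation with percentile-bootstrap CIs.

For predictor X, mediator M, outcome Y and a shared covariate set C, three
OLS fits give the path estimates:

* ``M ~ X + C``      -> a   (X -> M)
* ``Y ~ X + M + C``  -> c' (direct), b (M -> Y | X)
* ``Y ~ X + C``      -> c   (total)

With identical covariates the decomposition ``c = c' + a*b`` is exact OLS
algebra.  The indirect effect ``a*b`` is tested by resampling subjects with
replacement, refitting, and taking a plain percentile interval of the
resampled indirect effects; the effect is declared significant when the CI
excludes zero.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import MediationResult
from .prep import build_design

__all__ = ["fit_mediation", "bootstrap_indirect", "run_model_suite"]


def _design(x: np.ndarray, covariates: np.ndarray | None, *extra: np.ndarray) -> np.ndarray:
    n = x.size
    cols = [np.ones(n), x, *extra]
    if covariates is not None and covariates.size:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        cols.append(C)
    return np.column_stack(cols)


def fit_mediation(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> dict[str, float]:
    """Point estimates of the mediation paths (a, b, c, c', indirect)."""
    x = np.asarray(x, float)
    m = np.asarray(m, float)
    y = np.asarray(y, float)
    n = x.size
    if m.size != n or y.size != n:
        raise ValueError("vectors must be aligned")
    k = 0 if covariates is None else np.atleast_2d(np.asarray(covariates)).shape[-1]
    if n <= k + 3:
        raise ValueError("need n > n_covariates + 3")
    if abs(np.corrcoef(x, m)[0, 1]) > 0.999:
        raise ValueError("X and M are collinear (|r| > 0.999)")
    Z1 = _design(x, covariates)           # m ~ 1 + x + C
    Z2 = _design(x, covariates, m)        # y ~ 1 + x + m + C (m at column 2)
    b1, *_ = np.linalg.lstsq(Z1, m, rcond=None)
    b2, *_ = np.linalg.lstsq(Z2, y, rcond=None)
    b3, *_ = np.linalg.lstsq(Z1, y, rcond=None)
    a = float(b1[1])
    c_prime = float(b2[1])
    b = float(b2[2])
    c = float(b3[1])
    out = {"a": a, "b": b, "c": c, "c_prime": c_prime, "indirect": a * b}
    # parametric two-sided p-values for the individual paths (OLS t-tests)
    from scipy import stats as _st

    for label, (Z, resp, beta, col) in {
        "a_p": (Z1, m, b1, 1),
        "c_prime_p": (Z2, y, b2, 1),
        "b_p": (Z2, y, b2, 2),
        "c_p": (Z1, y, b3, 1),
    }.items():
        resid = resp - Z @ beta
        dof = n - Z.shape[1]
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(Z.T @ Z)
        t = beta[col] / np.sqrt(cov[col, col])
        out[label] = float(2.0 * _st.t.sf(abs(t), dof))
    return out


def _batched_paths(
    Z1: np.ndarray, Z2: np.ndarray, m: np.ndarray, y: np.ndarray, idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-resample (a, b) via batched normal equations."""
    Z1b = Z1[idx]                      # (B, n, p1)
    Z2b = Z2[idx]
    mb = m[idx]
    yb = y[idx]
    G1 = np.einsum("bni,bnj->bij", Z1b, Z1b, optimize=True)
    G2 = np.einsum("bni,bnj->bij", Z2b, Z2b, optimize=True)
    r1 = np.einsum("bni,bn->bi", Z1b, mb, optimize=True)
    r2 = np.einsum("bni,bn->bi", Z2b, yb, optimize=True)
    beta1 = np.linalg.solve(G1, r1[..., None])[..., 0]
    beta2 = np.linalg.solve(G2, r2[..., None])[..., 0]
    return beta1[:, 1], beta2[:, 2]


def bootstrap_indirect(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int | None = None,
    covariate_names: list[str] | None = None,
) -> MediationResult:
    """Percentile-bootstrap CI for the indirect effect a*b.

    Subjects are resampled with replacement ``n_boot`` times and both path
    regressions refit per resample.  A resample with a degenerate (singular)
    design is redrawn, up to a capped number of retries.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    x = np.asarray(x, float)
    m = np.asarray(m, float)
    y = np.asarray(y, float)
    point = fit_mediation(x, m, y, covariates)
    n = x.size
    Z1 = _design(x, covariates)           # [1, x, C]
    Z2 = _design(x, covariates, m)        # [1, x, m, C] — m at column 2
    rng = np.random.default_rng(seed)
    indirect = np.empty(n_boot)
    chunk = max(1, min(n_boot, int(2e7 // (n * Z2.shape[1]))))
    done = 0
    retries = 0
    while done < n_boot:
        B = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(B, n))
        try:
            a_b, b_b = _batched_paths(Z1, Z2, m, y, idx)
        except np.linalg.LinAlgError:
            a_b = np.empty(B)
            b_b = np.empty(B)
            for r in range(B):
                ok = False
                for _ in range(100):
                    try:
                        a_b[r], b_b[r] = _batched_paths(
                            Z1, Z2, m, y, idx[r : r + 1]
                        )
                        ok = True
                        break
                    except np.linalg.LinAlgError:
                        retries += 1
                        idx[r] = rng.integers(0, n, size=n)
                if not ok:
                    raise RuntimeError("bootstrap resample degenerate after 100 retries")
        indirect[done : done + B] = a_b * b_b
        done += B
    if retries:
        warnings.warn(f"{retries} degenerate bootstrap resamples redrawn")
    alpha = 1.0 - level
    lo, hi = np.quantile(indirect, [alpha / 2.0, 1.0 - alpha / 2.0])
    return MediationResult(
        a=point["a"],
        b=point["b"],
        c=point["c"],
        c_prime=point["c_prime"],
        indirect=point["indirect"],
        ci_level=level,
        ci_lower=float(lo),
        ci_upper=float(hi),
        n_boot=n_boot,
        n=n,
        covariates=covariate_names or [],
        seed=seed,
        path_pvalues={k: v for k, v in point.items() if k.endswith("_p")},
    )


#: the four pathway models: (predictor, mediator, outcome, extra covariate)
MODEL_SUITE = {
    "A": ("SNP", "GM", "fALFF", None),
    "B": ("SNP", "fALFF", "DB", "GM"),
    "C": ("SNP", "GM", "DB", "fALFF"),
    "D": ("GM", "fALFF", "DB", None),
}


def run_model_suite(
    loadings: dict[str, np.ndarray],
    phenotypes: pd.DataFrame,
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int | None = None,
    adjust_medication: bool = True,
) -> dict[str, MediationResult]:
    """The four pathway models on the linked-triplet loadings.

    (A) SNP -> GM -> fALFF, (B) SNP -> fALFF -> DB with GM as an extra
    covariate, (C) SNP -> GM -> DB with fALFF as an extra covariate, and
    (D) GM -> fALFF -> DB; all with age, sex, site and diagnosis controlled.
    Medication (where recorded) is first regressed from the imaging loadings
    on the dosed subset.  Models needing DB are skipped (with a warning) when
    the phenotype table lacks it.
    """
    from .stats import regress_out_medication

    loadings = {k: np.asarray(v, float).copy() for k, v in loadings.items()}
    if adjust_medication and "medication" in phenotypes:
        med = phenotypes["medication"].to_numpy(float)
        if np.isnan(med).all():
            raise ValueError("medication adjustment requested but no dose recorded")
        for m in ("fALFF", "GM"):
            loadings[m] = regress_out_medication(loadings[m], med)
    D, _ = build_design(phenotypes, ("age", "sex", "site"))
    dx = (phenotypes["diagnosis"] == "SZ").to_numpy(float)
    base_cov = np.column_stack([D[:, 1:], dx])
    base_names = ["age", "sex", "site", "diagnosis"]

    have_db = "DB" in phenotypes and phenotypes["DB"].notna().all()
    rng = np.random.default_rng(seed)
    results: dict[str, MediationResult] = {}
    for key, (xm, mm, ym, extra) in MODEL_SUITE.items():
        if ym == "DB" and not have_db:
            warnings.warn(f"model {key} skipped: DB scores unavailable")
            continue
        yvec = loadings[ym] if ym in loadings else phenotypes[ym].to_numpy(float)
        cov = base_cov
        names = list(base_names)
        if extra is not None:
            cov = np.column_stack([cov, loadings[extra]])
            names.append(extra)
        results[key] = bootstrap_indirect(
            loadings[xm],
            loadings[mm],
            yvec,
            covariates=cov,
            n_boot=n_boot,
            level=level,
            seed=int(rng.integers(0, 2**31 - 1)),
            covariate_names=names,
        )
    return results
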