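"""Feature-matrix preparation: masking, site normalization, covariate regression.

The fusion stage consumes subjects x features matrices that have been (1)
vectorized through a shared binary brain mask, (2) scaled so all modalities
have the same average within-site row sum-of-squares, and (3) residualized on
age, sex and site.  The pipeline order is normalize -> regress; regression
residuals are not re-scaled.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import FeatureMatrix

__all__ = [
    "apply_mask",
    "unmask",
    "regress_covariates",
    "normalize_sum_squares",
    "build_design",
    "prepare_features",
]


def apply_mask(
    volumes: np.ndarray | list[np.ndarray],
    mask: np.ndarray,
    modality: str = "fALFF",
    subject_ids: list[str] | None = None,
) -> FeatureMatrix:
    """Vectorize a stack of 3-D volumes through a binary mask.

    ``volumes`` is a 4-D array (x, y, z, subjects) or a list of 3-D arrays.
    Output columns follow linear (C-order) voxel index order within the mask,
    so the same mask applied to a second cohort yields feature matrices of the
    same length and column meaning.
    """
    mask = np.asarray(mask).astype(bool)
    if isinstance(volumes, (list, tuple)):
        volumes = np.stack(volumes, axis=-1)
    volumes = np.asarray(volumes, dtype=float)
    if volumes.ndim != 4:
        raise ValueError("volumes must be 4-D (x, y, z, subjects) or a list of 3-D")
    if volumes.shape[:3] != mask.shape:
        raise ValueError(
            f"mask shape {mask.shape} != volume spatial shape {volumes.shape[:3]}"
        )
    if not mask.any():
        raise ValueError("mask has no true voxel")
    flat_idx = np.flatnonzero(mask.ravel())
    n = volumes.shape[3]
    values = volumes.reshape(-1, n).T[:, flat_idx]
    if subject_ids is None:
        subject_ids = [f"S{i + 1:04d}" for i in range(n)]
    return FeatureMatrix(
        values=values,
        modality=modality,
        feature_ids=[f"vox{j}" for j in flat_idx],
        subject_ids=subject_ids,
    )


def unmask(fm: FeatureMatrix, mask: np.ndarray, fill: float = 0.0) -> np.ndarray:
    """Inverse of :func:`apply_mask`: restore voxel positions exactly."""
    mask = np.asarray(mask).astype(bool)
    flat_idx = np.flatnonzero(mask.ravel())
    if flat_idx.size != fm.n_features:
        raise ValueError("mask voxel count does not match feature count")
    out = np.full((fm.n_subjects, mask.size), fill)
    out[:, flat_idx] = fm.values
    return out.reshape((fm.n_subjects,) + mask.shape)


def build_design(
    covariates: pd.DataFrame,
    columns: tuple[str, ...] = ("age", "sex", "site"),
) -> tuple[np.ndarray, list[str]]:
    """Intercept + mean-centred age + 0/1 sex + k-1 site dummies (+ extras).

    Any column named in ``columns`` beyond the three standard ones is included
    as-is (numeric).  Collinear columns are detected downstream.
    """
    n = len(covariates)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    for c in columns:
        if c == "age":
            a = covariates["age"].to_numpy(dtype=float)
            cols.append(a - a.mean())
            names.append("age")
        elif c == "sex":
            s = covariates["sex"]
            if s.dtype == object:
                s = (s == "M").astype(float)
            cols.append(np.asarray(s, dtype=float))
            names.append("sex")
        elif c == "site":
            levels = sorted(pd.unique(covariates["site"]))
            if len(levels) < 1:
                raise ValueError("site must have >= 1 level")
            for lev in levels[1:]:
                cols.append((covariates["site"] == lev).to_numpy(dtype=float))
                names.append(f"site[{lev}]")
        else:
            cols.append(covariates[c].to_numpy(dtype=float))
            names.append(c)
    return np.column_stack(cols), names


def regress_covariates(
    X: FeatureMatrix,
    covariates: pd.DataFrame,
    columns: tuple[str, ...] = ("age", "sex", "site"),
) -> FeatureMatrix:
    """Columnwise least-squares residuals of X on the covariate design.

    Every output column is orthogonal to age, sex and each site dummy.  A
    rank-deficient design (after dummy coding) is handled by dropping
    collinear columns with a warning; residuals are unchanged by the drop.
    """
    if len(covariates) != X.n_subjects:
        raise ValueError("covariate rows do not align with X rows")
    D, names = build_design(covariates, columns)
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # drop collinear columns greedily, keeping an independent subset
        keep: list[int] = []
        for j in range(D.shape[1]):
            cand = D[:, keep + [j]]
            if np.linalg.matrix_rank(cand) > len(keep):
                keep.append(j)
        dropped = [names[j] for j in range(D.shape[1]) if j not in keep]
        warnings.warn(f"design rank-deficient; dropping {dropped}")
        D = D[:, keep]
    beta, *_ = np.linalg.lstsq(D, X.values, rcond=None)
    resid = X.values - D @ beta
    return FeatureMatrix(
        values=resid,
        modality=X.modality,
        feature_ids=list(X.feature_ids),
        subject_ids=list(X.subject_ids),
    )


def normalize_sum_squares(
    X: FeatureMatrix,
    site: pd.Series | np.ndarray,
    target: float = 1.0,
) -> FeatureMatrix:
    """Scale each site block so its mean row sum-of-squares equals ``target``.

    A single scalar per site block, so relative values within a row are
    preserved.
    """
    if target <= 0:
        raise ValueError("target must be positive")
    site = np.asarray(site)
    if site.shape[0] != X.n_subjects:
        raise ValueError("site labels do not align with X rows")
    values = X.values.copy()
    for lev in pd.unique(site):
        block = site == lev
        ss = np.mean(np.sum(values[block] ** 2, axis=1))
        if ss == 0.0:
            raise ValueError(f"all-zero site block {lev!r}: scale undefined")
        values[block] *= np.sqrt(target / ss)
    return FeatureMatrix(
        values=values,
        modality=X.modality,
        feature_ids=list(X.feature_ids),
        subject_ids=list(X.subject_ids),
    )


def prepare_features(
    X: FeatureMatrix,
    phenotypes: pd.DataFrame,
    target_ss: float = 1.0,
    covariates: tuple[str, ...] = ("age", "sex", "site"),
) -> FeatureMatrix:
    """Full preparation: within-site sum-of-squares normalization, then
    covariate regression.  Deterministic, and idempotent up to the site
    rescaling of residuals."""
    normed = normalize_sum_squares(X, phenotypes["site"], target=target_ss)
    if covariates:
        return regress_covariates(normed, phenotypes, covariates)
    return normed
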