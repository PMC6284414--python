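"""Replication by pseudoinverse projection onto an independent cohort.

The discovery-cohort spatial sources S are assumed to generalize; a second
cohort's feature matrices (prepared with the discovery mask / SNP list, their
own site normalization and covariate regression) are multiplied by the
Moore-Penrose pseudoinverse of S to obtain subject-specific projected
loadings, on which the linkage statistics are re-run unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import FeatureMatrix, MODALITIES
from .stats import (
    LinkageReport,
    group_difference,
    pairwise_loading_correlations,
    partial_correlation,
)

__all__ = ["ProjectedLoadings", "project_loadings", "replicate_linkage"]


@dataclass
class ProjectedLoadings:
    """Cohort-2 subjects x cohort-1 components weights AA = Y @ pinv(S)."""

    values: np.ndarray
    modality: str
    subject_ids: list[str]
    residual_fraction: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_components(self) -> int:
        return self.values.shape[1]


def project_loadings(
    Y: FeatureMatrix | np.ndarray, S: np.ndarray, modality: str | None = None
) -> ProjectedLoadings:
    """AA = Y @ S^+ with per-subject residual diagnostics.

    When ``Y = A @ S`` exactly and S has full row rank, AA equals A.
    """
    if isinstance(Y, FeatureMatrix):
        values = Y.values
        subject_ids = list(Y.subject_ids)
        modality = modality or Y.modality
    else:
        values = np.asarray(Y, dtype=float)
        subject_ids = [f"S{i + 1:04d}" for i in range(values.shape[0])]
        modality = modality or "unknown"
    S = np.asarray(S, dtype=float)
    if values.shape[1] != S.shape[1]:
        raise ValueError(
            f"feature mismatch: cohort has {values.shape[1]}, sources have {S.shape[1]}"
        )
    if np.linalg.matrix_rank(S) < S.shape[0]:
        warnings.warn("source matrix is rank-deficient; pseudoinverse still defined")
    AA = values @ np.linalg.pinv(S)
    fitted = AA @ S
    num = np.sum((values - fitted) ** 2, axis=1)
    den = np.sum(values**2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        resid = np.where(den > 0, num / den, 0.0)
    return ProjectedLoadings(
        values=AA,
        modality=modality,
        subject_ids=subject_ids,
        residual_fraction=resid,
    )


def replicate_linkage(
    projected: dict[str, ProjectedLoadings],
    phenotypes: pd.DataFrame,
    triplet: tuple[int, int, int] | None = None,
    subset: np.ndarray | None = None,
    alpha: float = 0.05,
) -> LinkageReport:
    """Re-test the linkage on projected cohort-2 loadings.

    Reruns the pairwise correlation family, the partial correlations given
    diagnosis on the triplet columns, and per-modality group t-tests, using
    the same statistics operations as the discovery analysis.  ``subset``
    restricts to a phenotype-defined boolean mask of subjects.
    """
    if subset is not None:
        subset = np.asarray(subset, dtype=bool)
        projected = {
            m: ProjectedLoadings(
                values=pl.values[subset],
                modality=pl.modality,
                subject_ids=[s for s, m_ in zip(pl.subject_ids, subset) if m_],
                residual_fraction=pl.residual_fraction[subset]
                if pl.residual_fraction.size
                else pl.residual_fraction,
            )
            for m, pl in projected.items()
        }
        phenotypes = phenotypes.loc[subset].reset_index(drop=True)
    AA = [projected[m].values for m in MODALITIES]
    report = pairwise_loading_correlations(*AA, alpha=alpha)
    report.extras["n"] = len(phenotypes)
    diagnosis = phenotypes["diagnosis"].to_numpy()
    if triplet is not None:
        i, j, k = triplet
        cols = {m: AA[mi][:, c] for mi, (m, c) in enumerate(zip(MODALITIES, (i, j, k)))}
        both_groups = (diagnosis == "HC").sum() >= 2 and (diagnosis == "SZ").sum() >= 2
        if both_groups:
            dx = (diagnosis == "SZ").astype(float)
            partial = {}
            for (ma, mb) in [(0, 1), (0, 2), (1, 2)]:
                r, p = partial_correlation(
                    cols[MODALITIES[ma]], cols[MODALITIES[mb]], dx
                )
                partial[(MODALITIES[ma], MODALITIES[mb])] = (r, p)
            report.extras["partial_given_diagnosis"] = partial
            report.extras["group_t"] = {
                m: group_difference(cols[m], diagnosis) for m in MODALITIES
            }
        report.extras["triplet"] = (i, j, k)
    return report
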