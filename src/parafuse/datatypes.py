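"""Core containers shared across the fusion pipeline.

The pipeline is organized around three parallel modalities — fALFF (resting-state
fMRI), GM (voxel-based gray-matter volume), and SNP (minor-allele dosages) — each
carried as a subjects x features matrix.  A decomposition of one modality is
``X ~= A @ S`` with ``A`` the subjects x components loading (mixing) matrix and
``S`` the components x features source matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

MODALITIES = ("fALFF", "GM", "SNP")


@dataclass
class FeatureMatrix:
    """Subjects x features values for one modality."""

    values: np.ndarray
    modality: str
    feature_ids: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x features)")
        n, p = self.values.shape
        if p == 0:
            raise ValueError("feature count must be > 0")
        if len(self.feature_ids) != p:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {p} columns")
        if len(self.subject_ids) != n:
            raise ValueError(f"{len(self.subject_ids)} subject ids for {n} rows")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs minor-allele dosage matrix.

    Dosages are 0/1/2 counts of the minor allele; missing calls are ``nan``.
    """

    dosages: np.ndarray
    snp_ids: list[str]
    subject_ids: list[str]
    counted_allele: list[str] | None = None
    truth: dict[str, Any] | None = None  # generator-side ground truth, if synthetic

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = self.dosages[~ok][:5]
            raise ValueError(f"dosages must be 0/1/2/missing; found {bad}")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        """Per-SNP minor-allele frequency on non-missing calls, folded to [0, 0.5]."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)


@dataclass
class Decomposition:
    """Single-modality ICA result in the original (dewhitened) space."""

    sources: np.ndarray        # components x features
    loadings: np.ndarray       # subjects x components
    unmixing: np.ndarray       # components x components, whitened space
    bias: np.ndarray           # components
    whitening: np.ndarray      # components x subjects
    dewhitening: np.ndarray    # subjects x components
    order: int
    log: dict[str, Any] = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.order


@dataclass
class FusionResult:
    """Joint three-way decomposition plus the cross-modality linkage evidence."""

    decompositions: dict[str, Decomposition]
    corr: dict[tuple[str, str], np.ndarray]
    corr_p: dict[tuple[str, str], np.ndarray]
    triplet: tuple[int, int, int]
    triplet_corrs: dict[tuple[str, str], float]
    objective_trace: list[dict[str, float]] = field(default_factory=list)
    config: Any = None

    def loadings(self, modality: str) -> np.ndarray:
        return self.decompositions[modality].loadings

    def sources(self, modality: str) -> np.ndarray:
        return self.decompositions[modality].sources


@dataclass
class MediationResult:
    """Simple-mediation fit X -> M -> Y with a percentile-bootstrap CI.

    ``a`` is the X->M path, ``b`` the M->Y|X path, ``c`` the total X->Y effect,
    ``c_prime`` the direct effect, and the indirect effect is ``a * b``.
    """

    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    ci_level: float
    ci_lower: float
    ci_upper: float
    n_boot: int
    n: int
    covariates: list[str]
    seed: int | None = None
    path_pvalues: dict[str, float] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        """True when the bootstrap CI for the indirect effect excludes zero."""
        return (self.ci_lower > 0.0) or (self.ci_upper < 0.0)


@dataclass
class GroundTruth:
    """What the synthetic cohort generator planted, for recovery scoring."""

    sources: dict[str, np.ndarray]
    loadings: dict[str, np.ndarray]
    triplet: tuple[int, int, int]
    target_corrs: tuple[float, float, float]   # (fALFF-GM, fALFF-SNP, GM-SNP)
    group_effects: dict[str, float]            # standardized HC-SZ shift per modality
    mediation_paths: dict[str, float]
    noise_sd: dict[str, float]
    seed: int
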