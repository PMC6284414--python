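"""Synthetic tri-modal cohort generator with known ground truth.

Real imaging-genetics cohorts of this kind (two voxelwise imaging modalities
plus a few thousand candidate-SNP dosages, collected across several sites) are
not publicly shareable, so every downstream stage of the package is exercised
on cohorts generated here.  The generator plants exactly the structure the
fusion pipeline is meant to find:

* per modality, a sparse super-Gaussian source matrix ``S`` and Gaussian
  loadings ``A`` with ``X = A @ S + noise``;
* one linked component triplet whose loading columns are drawn jointly
  Gaussian with a target 3x3 correlation (default 0.75 imaging-imaging and
  0.17 SNP-imaging, the link strengths such fusion studies report);
* an HC > SZ mean shift on the linked loadings;
* digit-span working-memory scores generated through the mediation chain
  SNP-loading -> GM-loading -> fALFF-loading -> DB, so mediation models have a
  known causal structure to recover.

The joint-Gaussian triplet is drawn via the Cholesky factor of the target
correlation in the structural order (SNP, GM, fALFF); that factorization *is*
a linear chain SNP -> GM -> fALFF (with a direct SNP -> fALFF edge whenever the
targets require one), so the generating path coefficients reported in
``GroundTruth.mediation_paths`` are exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import FeatureMatrix, GenotypeMatrix, GroundTruth

__all__ = [
    "CohortConfig",
    "generate_sources",
    "generate_linked_cohort",
    "generate_genotypes",
    "mediation_chain_config",
]


def generate_sources(
    n_components: int,
    n_features: int,
    sparsity: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sparse super-Gaussian source rows, unit L2 norm, near-orthogonal.

    Each row is a small Gaussian background plus Laplacian spikes on a random
    support of ``sparsity * n_features`` features.  Random supports overlap
    little, so pairwise row correlations stay well below 0.2 at the default
    sizes.
    """
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must lie in (0, 1]")
    if n_components >= n_features:
        raise ValueError(
            f"n_components ({n_components}) must be < n_features ({n_features})"
        )
    rng = np.random.default_rng(seed)
    k = max(1, int(round(sparsity * n_features)))
    S = 0.1 * rng.standard_normal((n_components, n_features))
    for i in range(n_components):
        support = rng.choice(n_features, size=k, replace=False)
        S[i, support] += rng.laplace(scale=1.0, size=k)
    S /= np.linalg.norm(S, axis=1, keepdims=True)
    return S


@dataclass
class CohortConfig:
    """Study conditions for the linked synthetic cohort.

    Defaults emulate the discovery-cohort conditions at desk scale: ~900
    subjects over 7 sites, two imaging modalities and one SNP dosage matrix,
    one linked triplet at correlations 0.75 / 0.17 / 0.17, and HC > SZ shifts
    sized to give group p-values of order 1e-3 to 0.05 at n ~= 900.
    """

    n_subjects: int = 905
    n_sites: int = 7
    n_features: tuple[int, int, int] = (2000, 2000, 500)    # fALFF, GM, SNP
    n_components: tuple[int, int, int] = (8, 6, 10)
    triplet: tuple[int, int, int] = (2, 1, 3)
    # (fALFF-GM, fALFF-SNP, GM-SNP)
    target_corrs: tuple[float, float, float] = (0.75, 0.17, 0.17)
    group_effects: tuple[float, float, float] = (0.24, 0.21, 0.13)
    triplet_scale: float = 1.5
    sparsity: float = 0.05
    noise_rel: float = 0.5          # noise SD as a fraction of signal RMS
    site_sd: float = 0.1            # per-site feature intercept SD
    # mediation chain onto the digit-backward span
    falff_db: float = 0.3
    snp_db_direct: float = 0.0
    gm_db_direct: float = 0.0
    falff_df: float = 0.19
    discretize_spans: bool = True
    medication_fraction: float = 243.0 / 450.0
    n_hc: int | None = None     # None -> an even split

    def corr_matrix(self) -> np.ndarray:
        """Target triplet correlation in structural order (SNP, GM, fALFF)."""
        r_fg, r_fs, r_gs = self.target_corrs
        return np.array(
            [[1.0, r_gs, r_fs], [r_gs, 1.0, r_fg], [r_fs, r_fg, 1.0]]
        )


def mediation_chain_config(
    snp_gm: float = 0.3,
    gm_falff: float = 0.7,
    snp_falff_direct: float = 0.15,
    falff_db: float = 0.5,
    **kwargs,
) -> CohortConfig:
    """CohortConfig whose triplet correlations come from explicit chain paths.

    Used when the object of study is the mediation chain itself: the pairwise
    correlation targets are derived from standardized structural coefficients
    SNP -> GM (``snp_gm``), GM -> fALFF (``gm_falff``), a direct SNP -> fALFF
    edge, and fALFF -> DB, with no direct SNP -> DB or GM -> DB path.
    """
    r_gs = snp_gm
    r_fg = gm_falff + snp_falff_direct * snp_gm
    r_fs = snp_gm * gm_falff + snp_falff_direct
    return CohortConfig(
        target_corrs=(r_fg, r_fs, r_gs), falff_db=falff_db, **kwargs
    )


_MODALITIES = ("fALFF", "GM", "SNP")


def generate_linked_cohort(
    config: CohortConfig,
    seed: int = 0,
    sources: dict[str, np.ndarray] | None = None,
) -> tuple[dict[str, FeatureMatrix], pd.DataFrame, GroundTruth]:
    """Generate three feature matrices, a phenotype table, and ground truth.

    Returns ``(features, phenotypes, truth)`` where ``features`` maps modality
    name -> FeatureMatrix and ``phenotypes`` has one row per subject with
    diagnosis, age, sex, site, medication and DF/DB spans.  Passing
    ``sources`` (modality -> components x features) reuses fixed spatial /
    genetic patterns with fresh loadings — the construction of an independent
    replication cohort that shares the discovery cohort's sources.
    """
    R = config.corr_matrix()
    eigvals = np.linalg.eigvalsh(R)
    if eigvals.min() < -1e-10:
        raise ValueError(f"triplet correlation target is not PSD: eigs {eigvals}")
    n = config.n_subjects
    n_hc = config.n_hc if config.n_hc is not None else (n + 1) // 2
    n_sz = n - n_hc
    per_site = min(n_hc, n_sz) // config.n_sites
    if per_site < 10:
        raise ValueError(
            f"need >= 10 subjects per group per site, got ~{per_site}"
        )
    for t_idx, order in zip(config.triplet, config.n_components):
        if not 0 <= t_idx < order:
            raise ValueError("triplet index outside model order")

    rng = np.random.default_rng(seed)

    diagnosis = np.array(["HC"] * n_hc + ["SZ"] * n_sz)
    # round-robin site assignment within each group keeps sites balanced
    site = np.empty(n, dtype=object)
    site[:n_hc] = [f"site{i % config.n_sites + 1}" for i in range(n_hc)]
    site[n_hc:] = [f"site{i % config.n_sites + 1}" for i in range(n_sz)]
    age = np.where(
        diagnosis == "HC",
        rng.normal(28.7, 6.92, size=n),
        rng.normal(27.8, 6.93, size=n),
    ).round(1)
    sex = rng.choice(["F", "M"], size=n)

    # linked triplet loadings: joint Gaussian in structural order (SNP, GM, fALFF)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(3))
    Z = rng.standard_normal((n, 3)) @ L.T  # columns: SNP, GM, fALFF latents
    z_snp, z_gm, z_falff = Z[:, 0].copy(), Z[:, 1].copy(), Z[:, 2].copy()
    latents = {"fALFF": z_falff, "GM": z_gm, "SNP": z_snp}

    hc = diagnosis == "HC"
    shifted = {}
    for m, d in zip(_MODALITIES, config.group_effects):
        col = latents[m] + np.where(hc, d / 2.0, -d / 2.0)
        shifted[m] = col

    # digit spans through the mediation chain (latents before the group shift
    # already carry the chain; the shift propagates a group difference into DB)
    resid_db = 1.0 - (
        config.falff_db**2 + config.snp_db_direct**2 + config.gm_db_direct**2
    )
    if resid_db < 0:
        raise ValueError("DB path coefficients imply variance > 1")
    db_latent = (
        config.falff_db * shifted["fALFF"]
        + config.snp_db_direct * shifted["SNP"]
        + config.gm_db_direct * shifted["GM"]
        + np.sqrt(resid_db) * rng.standard_normal(n)
    )
    df_latent = config.falff_df * shifted["fALFF"] + np.sqrt(
        max(0.0, 1.0 - config.falff_df**2)
    ) * rng.standard_normal(n)
    if config.discretize_spans:
        db = np.clip(np.round(6.0 + 1.5 * db_latent), 0, 10).astype(int)
        df_ = np.clip(np.round(8.0 + 2.0 * df_latent), 0, 12).astype(int)
    else:
        db = 6.0 + 1.5 * db_latent
        df_ = 8.0 + 2.0 * df_latent

    medication = np.full(n, np.nan)
    sz_idx = np.flatnonzero(~hc)
    n_dosed = int(round(config.medication_fraction * sz_idx.size))
    dosed = rng.choice(sz_idx, size=n_dosed, replace=False)
    medication[dosed] = np.clip(rng.normal(411.1, 205.4, size=n_dosed), 25, None)

    subject_ids = [f"S{i + 1:04d}" for i in range(n)]
    pheno = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "diagnosis": diagnosis,
            "age": age,
            "sex": sex,
            "site": site,
            "medication": medication,
            "DF": df_,
            "DB": db,
        }
    )

    features: dict[str, FeatureMatrix] = {}
    true_sources: dict[str, np.ndarray] = {}
    loadings: dict[str, np.ndarray] = {}
    noise_sds: dict[str, float] = {}
    site_levels = sorted(set(site))
    prefix = {"fALFF": "vox", "GM": "vox", "SNP": "rs"}
    for m, p, order, t_idx in zip(
        _MODALITIES, config.n_features, config.n_components, config.triplet
    ):
        if sources is not None:
            S = np.asarray(sources[m], dtype=float)
            if S.shape != (order, p):
                raise ValueError(
                    f"{m} sources shape {S.shape} != ({order}, {p})"
                )
        else:
            S = generate_sources(order, p, config.sparsity, rng)
        A = rng.standard_normal((n, order))
        A[:, t_idx] = config.triplet_scale * shifted[m]
        signal = A @ S
        noise_sd = config.noise_rel * np.sqrt(np.mean(signal**2))
        X = signal + noise_sd * rng.standard_normal((n, p))
        # small per-site intercepts so covariate regression has work to do
        for s in site_levels:
            X[site == s] += config.site_sd * rng.standard_normal(p) / np.sqrt(p)
        features[m] = FeatureMatrix(
            values=X,
            modality=m,
            feature_ids=[f"{prefix[m]}{j}" for j in range(p)],
            subject_ids=subject_ids,
        )
        true_sources[m] = S
        loadings[m] = A
        noise_sds[m] = float(noise_sd)

    chain = {
        "snp_gm": float(L[1, 0]),
        "gm_falff": float(L[2, 1] / L[1, 1]),
        "snp_falff_direct": float(L[2, 0] - L[1, 0] * L[2, 1] / L[1, 1]),
        "falff_db": config.falff_db,
        "snp_db_direct": config.snp_db_direct,
        "gm_db_direct": config.gm_db_direct,
        "falff_df": config.falff_df,
    }
    truth = GroundTruth(
        sources=true_sources,
        loadings=loadings,
        triplet=config.triplet,
        target_corrs=config.target_corrs,
        group_effects=dict(zip(_MODALITIES, config.group_effects)),
        mediation_paths=chain,
        noise_sd=noise_sds,
        seed=seed,
    )
    return features, pheno, truth


def generate_genotypes(
    n_subjects: int,
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    missing_rate: float = 0.0,
    hwe_violation_fraction: float = 0.0,
    ld_block_spec: list[tuple[int, float]] | None = None,
    seed: int = 0,
    inbreeding: float = 0.5,
) -> GenotypeMatrix:
    """Dosage matrix fixture for the genotype-QC chain.

    Non-violating SNPs are drawn under Hardy-Weinberg proportions at a MAF
    uniform on ``maf_range``.  A ``hwe_violation_fraction`` of SNPs is drawn
    with excess homozygosity (inbreeding coefficient ``inbreeding``), which a
    1-df HWE chi-square flags with high power at the default sizes.  LD blocks
    are consecutive runs of SNPs generated from an equicorrelated latent
    Gaussian thresholded at the Hardy-Weinberg genotype quantiles; the dosage
    correlation is slightly attenuated relative to the latent correlation.
    ``truth`` on the returned matrix records violator flags and block indices.
    """
    from scipy.stats import norm

    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be a non-empty interval within (0, 0.5]")
    if not (0.0 <= missing_rate <= 1.0 and 0.0 <= hwe_violation_fraction <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=n_snps)
    dosages = np.empty((n_subjects, n_snps))

    ld_block_spec = ld_block_spec or []
    blocks: list[np.ndarray] = []
    pos = 0
    for size, r in ld_block_spec:
        if pos + size > n_snps:
            raise ValueError("LD blocks exceed n_snps")
        idx = np.arange(pos, pos + size)
        blocks.append(idx)
        common = rng.standard_normal(n_subjects)
        z = np.sqrt(r) * common[:, None] + np.sqrt(1.0 - r) * rng.standard_normal(
            (n_subjects, size)
        )
        p = mafs[idx]
        q = 1.0 - p
        c0 = norm.ppf(q**2)
        c1 = norm.ppf(q**2 + 2.0 * p * q)
        dosages[:, idx] = (z > c0).astype(float) + (z > c1).astype(float)
        pos += size

    free = np.arange(pos, n_snps)
    n_viol = int(round(hwe_violation_fraction * free.size))
    viol = rng.choice(free, size=n_viol, replace=False) if n_viol else np.array([], int)
    viol_mask = np.zeros(n_snps, dtype=bool)
    viol_mask[viol] = True
    for j in free:
        p = mafs[j]
        q = 1.0 - p
        if viol_mask[j]:
            f = inbreeding
            probs = [q**2 + p * q * f, 2 * p * q * (1 - f), p**2 + p * q * f]
        else:
            probs = [q**2, 2 * p * q, p**2]
        dosages[:, j] = rng.choice([0.0, 1.0, 2.0], size=n_subjects, p=probs)

    if missing_rate > 0:
        miss = rng.random((n_subjects, n_snps)) < missing_rate
        dosages[miss] = np.nan

    if viol_mask.any() and blocks:
        warnings.warn("HWE violators are drawn outside LD blocks only")
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=[f"rs{j}" for j in range(n_snps)],
        subject_ids=[f"S{i + 1:04d}" for i in range(n_subjects)],
        counted_allele=["A"] * n_snps,
        truth={"hwe_violators": viol_mask, "mafs": mafs, "blocks": blocks},
    )
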