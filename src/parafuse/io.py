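"""File formats: PLINK .raw dosages, NIfTI stacks, TSV matrices, YAML configs."""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import Decomposition, FeatureMatrix, FusionResult, GenotypeMatrix, MODALITIES

__all__ = [
    "read_plink_raw",
    "read_nifti_stack",
    "read_feature_matrix",
    "write_feature_matrix",
    "write_fusion_result",
    "read_fusion_result",
]

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def read_plink_raw(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a PLINK ``--recode A`` additive dosage file.

    The header is the six metadata columns then ``SNP_ALLELE`` columns; cells
    are 0/1/2 minor-allele counts with NA for missing.  Subject ids are
    ``FID_IID``; the counted allele is parsed from each header suffix.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    for col in _PLINK_META:
        if col not in df.columns[: len(_PLINK_META)]:
            raise ValueError(f"malformed PLINK .raw header: missing column {col!r}")
    snp_cols = [c for c in df.columns if c not in _PLINK_META]
    snp_ids, alleles = [], []
    for c in snp_cols:
        if "_" not in c:
            raise ValueError(f"SNP column {c!r} lacks the _ALLELE suffix")
        sid, allele = c.rsplit("_", 1)
        snp_ids.append(sid)
        alleles.append(allele)
    raw = df[snp_cols].to_numpy()
    dosages = np.full(raw.shape, np.nan)
    valid = {"0": 0.0, "1": 1.0, "2": 2.0}
    for val, num in valid.items():
        dosages[raw == val] = num
    bad = ~(np.isin(raw, list(valid)) | (raw == "NA") | pd.isna(raw))
    if bad.any():
        cell = raw[bad][0]
        raise ValueError(f"non-0/1/2/NA dosage cell: {cell!r}")
    subject_ids = (df["FID"] + "_" + df["IID"]).tolist()
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=snp_ids,
        subject_ids=subject_ids,
        counted_allele=alleles,
    )


def read_nifti_stack(
    paths: list[str] | str,
    mask_path: str,
    modality: str = "fALFF",
    subject_ids: list[str] | None = None,
    affine_tol: float = 1e-4,
) -> FeatureMatrix:
    """Load a 4-D NIfTI (or list of 3-D NIfTIs) and vectorize through a mask.

    Affines of mask and images must agree to ``affine_tol``.
    """
    import nibabel as nib

    from .prep import apply_mask

    mask_img = nib.load(mask_path)
    mask = np.asarray(mask_img.dataobj) > 0
    if isinstance(paths, (str, os.PathLike)):
        img = nib.load(paths)
        if not np.allclose(img.affine, mask_img.affine, atol=affine_tol):
            raise ValueError("affine mismatch between volumes and mask")
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise ValueError("expected a 4-D NIfTI")
    else:
        vols = []
        for p in paths:
            img = nib.load(p)
            if not np.allclose(img.affine, mask_img.affine, atol=affine_tol):
                raise ValueError(f"affine mismatch for {p}")
            vols.append(np.asarray(img.dataobj, dtype=float))
        data = np.stack(vols, axis=-1)
    return apply_mask(data, mask, modality=modality, subject_ids=subject_ids)


def write_feature_matrix(fm: FeatureMatrix, path: str | os.PathLike) -> None:
    """TSV with subject ids as the index and feature ids as the header."""
    pd.DataFrame(fm.values, index=fm.subject_ids, columns=fm.feature_ids).to_csv(
        path, sep="\t", index_label="subject_id"
    )


def read_feature_matrix(path: str | os.PathLike, modality: str) -> FeatureMatrix:
    df = pd.read_csv(path, sep=None, engine="python", index_col="subject_id")
    return FeatureMatrix(
        values=df.to_numpy(dtype=float),
        modality=modality,
        feature_ids=[str(c) for c in df.columns],
        subject_ids=[str(i) for i in df.index],
    )


def write_fusion_result(result: FusionResult, outdir: str | os.PathLike) -> None:
    """Serialize a FusionResult as a directory of TSV matrices + a YAML summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for m, d in result.decompositions.items():
        np.savetxt(out / f"S_{m}.tsv", d.sources, delimiter="\t")
        np.savetxt(out / f"A_{m}.tsv", d.loadings, delimiter="\t")
        np.savetxt(out / f"W_{m}.tsv", d.unmixing, delimiter="\t")
        np.savetxt(out / f"dewhiten_{m}.tsv", d.dewhitening, delimiter="\t")
        np.savetxt(out / f"whiten_{m}.tsv", d.whitening, delimiter="\t")
        np.savetxt(out / f"bias_{m}.tsv", d.bias, delimiter="\t")
    for (a, b), R in result.corr.items():
        np.savetxt(out / f"corr_{a}_{b}.tsv", R, delimiter="\t")
        np.savetxt(out / f"corr_p_{a}_{b}.tsv", result.corr_p[(a, b)], delimiter="\t")
    summary = {
        "triplet": [int(i) for i in result.triplet],
        "triplet_corrs": {f"{a}-{b}": float(v) for (a, b), v in result.triplet_corrs.items()},
        "orders": {m: int(d.order) for m, d in result.decompositions.items()},
        "logs": {m: {k: _plain(v) for k, v in d.log.items()}
                 for m, d in result.decompositions.items()},
    }
    (out / "fusion.yaml").write_text(yaml.safe_dump(summary))


def _plain(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v


def read_fusion_result(outdir: str | os.PathLike) -> FusionResult:
    out = Path(outdir)
    summary = yaml.safe_load((out / "fusion.yaml").read_text())
    decomps = {}
    for m in MODALITIES:
        decomps[m] = Decomposition(
            sources=np.atleast_2d(np.loadtxt(out / f"S_{m}.tsv", delimiter="\t")),
            loadings=np.atleast_2d(np.loadtxt(out / f"A_{m}.tsv", delimiter="\t")),
            unmixing=np.atleast_2d(np.loadtxt(out / f"W_{m}.tsv", delimiter="\t")),
            bias=np.atleast_1d(np.loadtxt(out / f"bias_{m}.tsv", delimiter="\t")),
            whitening=np.atleast_2d(np.loadtxt(out / f"whiten_{m}.tsv", delimiter="\t")),
            dewhitening=np.atleast_2d(np.loadtxt(out / f"dewhiten_{m}.tsv", delimiter="\t")),
            order=summary["orders"][m],
            log=summary["logs"].get(m, {}),
        )
    corr, corr_p = {}, {}
    for i, j in [(0, 1), (0, 2), (1, 2)]:
        a, b = MODALITIES[i], MODALITIES[j]
        corr[(a, b)] = np.atleast_2d(np.loadtxt(out / f"corr_{a}_{b}.tsv", delimiter="\t"))
        corr_p[(a, b)] = np.atleast_2d(np.loadtxt(out / f"corr_p_{a}_{b}.tsv", delimiter="\t"))
    triplet = tuple(summary["triplet"])
    i, j, k = triplet
    tcorrs = {
        (MODALITIES[0], MODALITIES[1]): float(corr[(MODALITIES[0], MODALITIES[1])][i, j]),
        (MODALITIES[0], MODALITIES[2]): float(corr[(MODALITIES[0], MODALITIES[2])][i, k]),
        (MODALITIES[1], MODALITIES[2]): float(corr[(MODALITIES[1], MODALITIES[2])][j, k]),
    }
    return FusionResult(
        decompositions=decomps,
        corr=corr,
        corr_p=corr_p,
        triplet=triplet,  # type: ignore[arg-type]
        triplet_corrs=tcorrs,
    )
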