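"""End-to-end pipeline driver: prep -> fusion -> stats -> mediation.

One global seed fans out to per-stage seeds by stable hashing of stage names,
so stages are reproducible independently and re-running a config + seed
reproduces every numeric output bit-identically.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .datatypes import MODALITIES
from .fusion import FusionConfig, align_signs, fit_parafusion
from .ica import estimate_order_mdl, pca_whiten
from .mediation import run_model_suite
from .prep import prepare_features
from .stats import cognition_association, group_difference, pairwise_loading_correlations
from .synthetic import CohortConfig, generate_linked_cohort

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, derived by hashing."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class PipelineConfig:
    outdir: str = "parafuse_run"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    orders: tuple[int, int, int] | str = "auto"
    fusion: FusionConfig = field(default_factory=FusionConfig)
    n_boot: int = 5000
    target_ss: float = 1.0
    covariates: tuple[str, ...] = ("age", "sex", "site")
    run_mediation: bool = True


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Simulate (or load), prepare, fuse, align, test, mediate; write a manifest.

    Returns the run directory.  Any stage failure raises with the stage name;
    partial outputs written so far are preserved.
    """
    from . import __version__
    from .io import write_feature_matrix, write_fusion_result

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        feats, pheno, truth = generate_linked_cohort(
            config.cohort, seed=stage_seed(config.seed, "simulate")
        )
        pheno.to_csv(out / "phenotypes.csv", index=False)

        stage = "prep"
        prepared = {
            m: prepare_features(feats[m], pheno, config.target_ss, config.covariates)
            for m in MODALITIES
        }
        for m in MODALITIES:
            write_feature_matrix(prepared[m], out / f"X_{m}.tsv")

        stage = "orders"
        if config.orders == "auto":
            orders = []
            for m in MODALITIES:
                _, _, _, eig = pca_whiten(prepared[m], 1)
                n_samples = prepared[m].n_features
                orders.append(max(2, estimate_order_mdl(eig, n_samples)))
            orders = tuple(orders)
        else:
            orders = tuple(config.orders)

        stage = "fusion"
        result = fit_parafusion(
            prepared[MODALITIES[0]],
            prepared[MODALITIES[1]],
            prepared[MODALITIES[2]],
            orders,
            config.fusion,
            seed=stage_seed(config.seed, "fusion"),
        )
        result = align_signs(result, pheno["diagnosis"].to_numpy())
        write_fusion_result(result, out / "fusion")

        stage = "stats"
        report = pairwise_loading_correlations(
            result.loadings(MODALITIES[0]),
            result.loadings(MODALITIES[1]),
            result.loadings(MODALITIES[2]),
        )
        report.pairs.to_csv(out / "linkage.tsv", sep="\t", index=False)
        i, j, k = result.triplet
        trip_cols = {
            m: result.loadings(m)[:, c]
            for m, c in zip(MODALITIES, (i, j, k))
        }
        group = {
            m: group_difference(trip_cols[m], pheno["diagnosis"].to_numpy())
            for m in MODALITIES
        }
        cog = cognition_association(
            trip_cols, pheno[["DF", "DB"]], pheno,
            medication=pheno["medication"].to_numpy(),
        )
        cog.to_csv(out / "cognition.tsv", sep="\t", index=False)

        mediation_rows = []
        if config.run_mediation:
            stage = "mediation"
            suite = run_model_suite(
                trip_cols, pheno, n_boot=config.n_boot,
                seed=stage_seed(config.seed, "mediation"),
            )
            for key, r in suite.items():
                mediation_rows.append(
                    {
                        "model": key, "a": r.a, "b": r.b, "c": r.c,
                        "c_prime": r.c_prime, "indirect": r.indirect,
                        "ci_lower": r.ci_lower, "ci_upper": r.ci_upper,
                        "n_boot": r.n_boot, "significant": r.significant,
                    }
                )
            pd.DataFrame(mediation_rows).to_csv(
                out / "mediation.tsv", sep="\t", index=False
            )

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "stage_seeds": {
                s: stage_seed(config.seed, s)
                for s in ("simulate", "fusion", "mediation")
            },
            "orders": [int(o) for o in orders],
            "triplet": [int(c) for c in result.triplet],
            "triplet_corrs": {
                f"{a}-{b}": float(v) for (a, b), v in result.triplet_corrs.items()
            },
            "group_tests": {m: [float(t), float(p)] for m, (t, p) in group.items()},
            "files": {
                p.name: _sha256(p)
                for p in sorted(out.rglob("*"))
                if p.is_file() and p.name != "manifest.yaml"
            },
        }
        (out / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
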