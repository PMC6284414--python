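"""Three-way parallel ICA: joint Infomax with a cross-modality coupling term.

Each modality m has its own Infomax entropy objective H(Y_m); the joint
objective adds an aggregation term f_{i,j,k} measuring the combined connection
strength of loading columns i, j, k across the three loading matrices.  Here
f is the sum of squared pairwise Pearson correlations — differentiable,
sign-free, bounded in [0, 3], and reducing to the familiar two-way parallel
ICA coupling per modality pair.  The optimizer alternates one stochastic
Infomax pass per modality with a gradient-ascent step on
``lambda * sum of r^2`` over the currently "constrained" component pairs
(those whose |r| already exceeds an activation threshold, capped per modality
pair), back-propagated through ``A = dewhiten @ W^{-1}``.

At ``lambda = 0`` the result is bit-identical to three independent Infomax
runs with the same seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .datatypes import Decomposition, FeatureMatrix, FusionResult, MODALITIES
from .ica import InfomaxConfig, InfomaxState, _canonicalize, _entropy_objective, pca_whiten

__all__ = [
    "FusionConfig",
    "aggregate_link",
    "fit_parafusion",
    "select_linked_triplet",
    "align_signs",
    "component_zscores",
    "loading_correlations",
]


@dataclass
class FusionConfig:
    """Knobs of the three-way coupling.

    ``lam`` weights the coupling term against the three entropies; the
    activation threshold and per-pair cap implement an adaptive constraint
    schedule (only already-correlated component pairs are pulled together,
    which keeps the coupling from overfitting every component to every other).
    ``lam`` is annealed when an entropy term degrades by more than
    ``entropy_tolerance`` relative to its running best.
    """

    infomax: InfomaxConfig = field(default_factory=InfomaxConfig)
    lam: float = 0.5
    coupling_rate: float = 0.5
    activation_threshold: float = 0.2
    max_pairs: int = 2
    max_outer: int = 512
    entropy_tolerance: float = 0.01
    lam_anneal: float = 0.9
    burn_in_tol: float = 1e-4   # couple only once every modality's weight
                                # change has dropped below this (demixed enough
                                # that loading correlations are meaningful)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if not 0 <= self.activation_threshold <= 1:
            raise ValueError("activation threshold must lie in [0, 1]")


def _corr_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix between columns of A and columns of B."""
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    sa = np.linalg.norm(Ac, axis=0)
    sb = np.linalg.norm(Bc, axis=0)
    sa[sa == 0] = np.nan
    sb[sb == 0] = np.nan
    return (Ac.T @ Bc) / np.outer(sa, sb)


def _corr_pvalues(R: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values for Pearson correlations at sample size n."""
    R = np.clip(R, -0.9999999999, 0.9999999999)
    df = n - 2
    t = R * np.sqrt(df / (1.0 - R**2))
    return 2.0 * stats.t.sf(np.abs(t), df)


def aggregate_link(a1: np.ndarray, a2: np.ndarray, a3: np.ndarray) -> float:
    """Combined connection strength of three loading columns:
    ``r^2(a1,a2) + r^2(a1,a3) + r^2(a2,a3)``.  Symmetric, in [0, 3]."""
    cols = [np.asarray(a, dtype=float) for a in (a1, a2, a3)]
    n = cols[0].size
    if n < 3 or any(c.size != n for c in cols):
        raise ValueError("columns must share length >= 3")
    if any(np.std(c) == 0 for c in cols):
        raise ValueError("constant column: correlation undefined")
    r12 = np.corrcoef(cols[0], cols[1])[0, 1]
    r13 = np.corrcoef(cols[0], cols[2])[0, 1]
    r23 = np.corrcoef(cols[1], cols[2])[0, 1]
    return float(r12**2 + r13**2 + r23**2)


def _coupling_gradient_A(
    A_m: np.ndarray, A_o: np.ndarray, pairs: list[tuple[int, int]]
) -> np.ndarray:
    """d/dA_m of sum over (i, j) in pairs of r(A_m[:, i], A_o[:, j])^2."""
    G = np.zeros_like(A_m)
    for i, j in pairs:
        a = A_m[:, i] - A_m[:, i].mean()
        b = A_o[:, j] - A_o[:, j].mean()
        sa = np.linalg.norm(a)
        sb = np.linalg.norm(b)
        if sa == 0 or sb == 0:
            continue
        r = float(a @ b) / (sa * sb)
        dr = (b - r * (sb / sa) * a) / (sa * sb)
        G[:, i] += 2.0 * r * dr
    return G


def _select_pairs(
    R: np.ndarray, threshold: float, max_pairs: int
) -> list[tuple[int, int]]:
    """Component pairs to couple: |r| above threshold, strongest first,
    at most ``max_pairs``, each component used once per modality pair."""
    flat = [
        (abs(R[i, j]), i, j)
        for i in range(R.shape[0])
        for j in range(R.shape[1])
        if np.isfinite(R[i, j]) and abs(R[i, j]) > threshold
    ]
    flat.sort(reverse=True)
    chosen: list[tuple[int, int]] = []
    used_i: set[int] = set()
    used_j: set[int] = set()
    for _, i, j in flat:
        if i in used_i or j in used_j:
            continue
        chosen.append((i, j))
        used_i.add(i)
        used_j.add(j)
        if len(chosen) >= max_pairs:
            break
    return chosen


def fit_parafusion(
    X1: FeatureMatrix | np.ndarray,
    X2: FeatureMatrix | np.ndarray,
    X3: FeatureMatrix | np.ndarray,
    orders: tuple[int, int, int],
    config: FusionConfig | None = None,
    seed: int | None = None,
) -> FusionResult:
    """Fit the three-way parallel ICA and select the strongest linked triplet.

    Modalities are taken in the order (fALFF, GM, SNP).  ``seed`` (or
    ``config.seed``) fans out to one Infomax seed per modality; with
    ``lam = 0`` the decompositions equal independent Infomax runs seeded the
    same way.
    """
    config = config or FusionConfig()
    if seed is None:
        seed = config.seed
    mats = []
    subj = None
    for X in (X1, X2, X3):
        v = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)
        if subj is None:
            subj = v.shape[0]
        elif v.shape[0] != subj:
            raise ValueError("modalities must share subject rows")
        mats.append(v)

    rng = np.random.default_rng(seed)
    mod_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=3)]
    states: list[InfomaxState] = []
    dewhites: list[np.ndarray] = []
    whites: list[np.ndarray] = []
    for v, order, s in zip(mats, orders, mod_seeds):
        Xw, K, Dw, _ = pca_whiten(v, order)
        cfg = replace(config.infomax, seed=s)
        states.append(InfomaxState(Xw, cfg))
        whites.append(K)
        dewhites.append(Dw)

    lam = config.lam
    pair_keys = [(0, 1), (0, 2), (1, 2)]
    best_entropy = [-np.inf] * 3
    trace: list[dict[str, float]] = []
    coupling_on = False
    for outer in range(config.max_outer):
        for st in states:
            if not st.converged:
                st.run_pass()
        entry: dict[str, float] = {"outer": float(outer), "lam": lam}
        if not coupling_on:
            coupling_on = all(
                st.trace and st.trace[-1] < config.burn_in_tol for st in states
            )
        if lam > 0.0 and coupling_on:
            A = [dw @ np.linalg.inv(st.W) for dw, st in zip(dewhites, states)]
            R = {k: _corr_columns(A[k[0]], A[k[1]]) for k in pair_keys}
            pairs = {
                k: _select_pairs(R[k], config.activation_threshold, config.max_pairs)
                for k in pair_keys
            }
            coupling = sum(
                float(R[k][i, j] ** 2) for k in pair_keys for i, j in pairs[k]
            )
            entry["coupling"] = coupling
            for m, st in enumerate(states):
                G = np.zeros_like(A[m])
                for k in pair_keys:
                    if m == k[0]:
                        G += _coupling_gradient_A(A[m], A[k[1]], pairs[k])
                    elif m == k[1]:
                        G += _coupling_gradient_A(
                            A[m], A[k[0]], [(j, i) for i, j in pairs[k]]
                        )
                if not G.any():
                    continue
                M = np.linalg.inv(st.W)
                dfdM = dewhites[m].T @ G
                gradW = -M.T @ dfdM @ M.T
                # coupling anneals together with the modality's learning rate,
                # so the joint optimization can settle
                step = (
                    config.coupling_rate
                    * lam
                    * (st.lrate / st.config.lrate)
                    * gradW
                )
                st.W += step
                if float(np.sum(step**2)) / st.W.shape[0] >= st.config.tol:
                    st.converged = False
        for m, st in enumerate(states):
            h = _entropy_objective(st.W, st.w0, st.Xw)
            entry[f"H{m + 1}"] = h
            if h < best_entropy[m] - config.entropy_tolerance * abs(best_entropy[m]):
                lam *= config.lam_anneal
                warnings.warn(
                    f"entropy of modality {m + 1} degraded; annealing lambda to {lam:.3g}"
                )
            best_entropy[m] = max(best_entropy[m], h)
        trace.append(entry)
        if all(st.converged for st in states):
            break

    return _finalize(states, whites, dewhites, trace, config, mats)


def _finalize(states, whites, dewhites, trace, config, mats) -> FusionResult:
    decomps: dict[str, Decomposition] = {}
    for name, st, K, Dw in zip(MODALITIES, states, whites, dewhites):
        S = st.W @ st.Xw
        A = Dw @ np.linalg.inv(st.W)
        S, A, W, w0 = _canonicalize(S, A, st.W, st.w0)
        decomps[name] = Decomposition(
            sources=S,
            loadings=A,
            unmixing=W,
            bias=w0,
            whitening=K,
            dewhitening=Dw,
            order=st.Xw.shape[0],
            log={
                "n_passes": st.n_passes,
                "converged": st.converged,
                "restarts": st.restarts,
            },
        )
    n = mats[0].shape[0]
    corr: dict[tuple[str, str], np.ndarray] = {}
    corr_p: dict[tuple[str, str], np.ndarray] = {}
    for (i, j) in [(0, 1), (0, 2), (1, 2)]:
        key = (MODALITIES[i], MODALITIES[j])
        R = _corr_columns(decomps[MODALITIES[i]].loadings, decomps[MODALITIES[j]].loadings)
        corr[key] = R
        corr_p[key] = _corr_pvalues(R, n)
    triplet, tcorrs = select_linked_triplet(corr)
    return FusionResult(
        decompositions=decomps,
        corr=corr,
        corr_p=corr_p,
        triplet=triplet,
        triplet_corrs=tcorrs,
        objective_trace=trace,
        config=config,
    )


def select_linked_triplet(
    corr: dict[tuple[str, str], np.ndarray] | FusionResult,
) -> tuple[tuple[int, int, int], dict[tuple[str, str], float]]:
    """Exhaustively score all component triplets with the sum of squared
    pairwise loading correlations and return the argmax (ties resolved to the
    lowest lexicographic index)."""
    if isinstance(corr, FusionResult):
        corr = corr.corr
    R12 = corr[(MODALITIES[0], MODALITIES[1])]
    R13 = corr[(MODALITIES[0], MODALITIES[2])]
    R23 = corr[(MODALITIES[1], MODALITIES[2])]
    agg = (
        (R12**2)[:, :, None]
        + (R13**2)[:, None, :]
        + (R23**2)[None, :, :]
    )
    flat = int(np.argmax(agg))  # C-order argmax = lowest lexicographic on ties
    i, j, k = np.unravel_index(flat, agg.shape)
    tcorrs = {
        (MODALITIES[0], MODALITIES[1]): float(R12[i, j]),
        (MODALITIES[0], MODALITIES[2]): float(R13[i, k]),
        (MODALITIES[1], MODALITIES[2]): float(R23[j, k]),
    }
    return (int(i), int(j), int(k)), tcorrs


def align_signs(result: FusionResult, diagnosis: np.ndarray) -> FusionResult:
    """Flip (source row, loading column) sign pairs so mean HC loading >= mean
    SZ loading on every component.  A @ S is unchanged."""
    diagnosis = np.asarray(diagnosis)
    hc = diagnosis == "HC"
    sz = diagnosis == "SZ"
    if not hc.any() or not sz.any():
        raise ValueError("both groups must be present")
    for name, d in result.decompositions.items():
        for c in range(d.order):
            if d.loadings[hc, c].mean() < d.loadings[sz, c].mean():
                d.loadings[:, c] *= -1.0
                d.sources[c, :] *= -1.0
                d.unmixing[c, :] *= -1.0
                d.bias[c] *= -1.0
    # correlations change sign with flips; recompute
    n = next(iter(result.decompositions.values())).loadings.shape[0]
    for (mi, mj) in list(result.corr):
        R = _corr_columns(
            result.decompositions[mi].loadings, result.decompositions[mj].loadings
        )
        result.corr[(mi, mj)] = R
        result.corr_p[(mi, mj)] = _corr_pvalues(R, n)
    i, j, k = result.triplet
    result.triplet_corrs = {
        (MODALITIES[0], MODALITIES[1]): float(result.corr[(MODALITIES[0], MODALITIES[1])][i, j]),
        (MODALITIES[0], MODALITIES[2]): float(result.corr[(MODALITIES[0], MODALITIES[2])][i, k]),
        (MODALITIES[1], MODALITIES[2]): float(result.corr[(MODALITIES[1], MODALITIES[2])][j, k]),
    }
    return result


def component_zscores(
    source_row: np.ndarray, threshold: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Z-score a source row over features and return (z, indices with |z| >
    threshold) — the 'top contributing' feature set."""
    s = np.asarray(source_row, dtype=float)
    sd = s.std()
    if sd == 0:
        raise ValueError("constant source row: z-scores undefined")
    z = (s - s.mean()) / sd
    return z, np.flatnonzero(np.abs(z) > threshold)


def loading_correlations(result: FusionResult) -> dict[tuple[str, str], np.ndarray]:
    return result.corr
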