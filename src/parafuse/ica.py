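"""Whitening, model-order estimation and Infomax ICA for one modality.

A subjects x features matrix ``X`` is reduced to ``order`` dimensions by an
(uncentered) SVD whitening in subject space, and an unmixing matrix ``W`` in
the whitened space is learned by maximizing the output entropy of a logistic
nonlinearity, ``H(Y)`` with ``Y = 1 / (1 + exp(-(W Xw + w0)))``, via the
natural-gradient update ``dW = lr * (I + (1 - 2Y) U^T) W``.  Sources are
``S = W Xw`` and loadings ``A = dewhiten @ W^{-1}``, so ``A @ S`` equals the
order-C PCA approximation of ``X``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .datatypes import Decomposition, FeatureMatrix

__all__ = [
    "InfomaxConfig",
    "pca_whiten",
    "estimate_order_mdl",
    "estimate_order_stability",
    "infomax",
    "InfomaxState",
    "amari_index",
    "match_sources",
]


@dataclass
class InfomaxConfig:
    lrate: float = 0.008
    anneal: float = 0.96        # rate multiplier when the update turns sharply
    anneal_deg: float = 60.0    # angle (degrees) between successive updates
    max_iter: int = 512
    tol: float = 1e-7           # stop when ||dW||^2 / C < tol
    block: int = 32
    max_restarts: int = 5
    blowup: float = 1e9
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.lrate <= 0 or self.tol <= 0:
            raise ValueError("learning rate and tolerance must be positive")


def pca_whiten(
    X: FeatureMatrix | np.ndarray, order: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Reduce to ``order`` dimensions with unit sample covariance.

    Returns ``(Xw, whitening, dewhitening, eigenvalues)`` where ``Xw`` is
    order x features with ``Xw @ Xw.T / n_features = I``, ``whitening`` maps
    subjects -> whitened rows, and ``dewhitening @ Xw`` is the rank-``order``
    SVD approximation of ``X``.  ``eigenvalues`` is the full spectrum of
    ``X X^T / n_features`` (for MDL order estimation).
    """
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    n, p = values.shape
    if order > min(n, p):
        raise ValueError(f"order {order} exceeds min(subjects, features) {min(n, p)}")
    U, s, Vt = np.linalg.svd(values, full_matrices=False)
    tol = s.max() * max(n, p) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if order > rank:
        raise ValueError(f"order {order} exceeds numerical rank {rank}")
    eigenvalues = s**2 / p
    Xw = np.sqrt(p) * Vt[:order]
    whitening = np.sqrt(p) * (U[:, :order] / s[:order]).T   # order x subjects
    dewhitening = U[:, :order] * s[:order] / np.sqrt(p)     # subjects x order
    return Xw, whitening, dewhitening, eigenvalues


def estimate_order_mdl(
    eigenvalues: np.ndarray, n_samples: int, iid_correction: float = 1.0
) -> int:
    """Minimum-description-length choice of the number of sources.

    Classic information-theoretic order selection from the eigen-spectrum: for
    each candidate order k, the code length combines the log ratio of the
    geometric to arithmetic mean of the trailing eigenvalues with a parameter
    penalty ``0.5 k (2p - k + 1) ln N``.  ``iid_correction`` rescales the
    effective sample count downward for smoothed (non-i.i.d.) data, the usual
    modification for imaging feature matrices; 1.0 means no correction.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size < 3:
        raise ValueError("need at least 3 eigenvalues")
    if np.any(np.diff(lam) > 1e-12) or np.any(lam < 0):
        raise ValueError("eigenvalues must be non-negative and descending")
    if not 0 < iid_correction <= 1:
        raise ValueError("iid_correction must lie in (0, 1]")
    n_eff = max(3.0, n_samples * iid_correction)
    p = lam.size
    lam = np.maximum(lam, lam.max() * 1e-12 + 1e-300)
    mdl = np.empty(p)
    log_lam = np.log(lam)
    for k in range(p):
        tail = lam[k:]
        log_g = log_lam[k:].mean()
        log_a = np.log(tail.mean())
        mdl[k] = -n_eff * (p - k) * (log_g - log_a) + 0.5 * k * (
            2 * p - k + 1
        ) * np.log(n_eff)
    return int(np.argmin(mdl))


def _sigmoid(u: np.ndarray) -> np.ndarray:
    out = np.empty_like(u)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-u[pos]))
    eu = np.exp(u[~pos])
    out[~pos] = eu / (1.0 + eu)
    return out


def _entropy_objective(W: np.ndarray, w0: np.ndarray, Xw: np.ndarray) -> float:
    """Infomax entropy up to an additive constant: log|det W| + E sum log y(1-y)."""
    U = W @ Xw + w0[:, None]
    # log y(1-y) = -u - 2 log(1 + exp(-u)), numerically stable form
    term = -np.abs(U) - 2.0 * np.log1p(np.exp(-np.abs(U)))
    sign, logdet = np.linalg.slogdet(W)
    if sign <= 0:
        return -np.inf
    return float(logdet + term.sum(axis=0).mean())


class InfomaxState:
    """Stepwise Infomax so parallel fusion can interleave coupling updates.

    ``run_pass`` performs one full sweep over the (permuted) samples in
    stochastic blocks and returns the squared weight change.  ``converged``
    flips when the change drops below tolerance.
    """

    def __init__(self, Xw: np.ndarray, config: InfomaxConfig):
        self.Xw = Xw
        self.config = config
        C = Xw.shape[0]
        self.rng = np.random.default_rng(config.seed)
        self.W = np.eye(C) + 0.01 * self.rng.standard_normal((C, C))
        self.W0 = self.W.copy()
        self.w0 = np.zeros(C)
        self.lrate = config.lrate
        self.prev_dW: np.ndarray | None = None
        self.converged = False
        self.n_passes = 0
        self.restarts = 0
        self.trace: list[float] = []

    def run_pass(self) -> float:
        cfg = self.config
        C, N = self.Xw.shape
        perm = self.rng.permutation(N)
        W_before = self.W.copy()
        I = np.eye(C)
        block = min(cfg.block, N)
        for start in range(0, N - block + 1, block):
            x = self.Xw[:, perm[start : start + block]]
            u = self.W @ x + self.w0[:, None]
            y = _sigmoid(u)
            g = 1.0 - 2.0 * y
            # natural-gradient update, normalized per sample within the block
            self.W += self.lrate * (I + (g @ u.T) / block) @ self.W
            self.w0 += self.lrate * g.mean(axis=1)
            if not np.isfinite(self.W).all() or np.abs(self.W).max() > cfg.blowup:
                self._restart()
                return np.inf
        dW = self.W - W_before
        change = float(np.sum(dW**2)) / C
        if self.prev_dW is not None:
            denom = np.linalg.norm(dW) * np.linalg.norm(self.prev_dW)
            if denom > 0:
                cosang = float(np.sum(dW * self.prev_dW)) / denom
                if cosang < np.cos(np.deg2rad(cfg.anneal_deg)):
                    self.lrate *= cfg.anneal
        self.prev_dW = dW
        self.n_passes += 1
        self.trace.append(change)
        if change < cfg.tol:
            self.converged = True
        return change

    def _restart(self) -> None:
        self.restarts += 1
        if self.restarts > self.config.max_restarts:
            raise RuntimeError(
                f"Infomax diverged after {self.restarts} restarts; "
                f"last lrate {self.lrate:.2e}"
            )
        C = self.Xw.shape[0]
        self.lrate *= 0.5
        self.W = np.eye(C) + 0.01 * self.rng.standard_normal((C, C))
        self.w0 = np.zeros(C)
        self.prev_dW = None

    def run(self) -> None:
        while not self.converged and self.n_passes < self.config.max_iter:
            self.run_pass()


def _canonicalize(
    S: np.ndarray, A: np.ndarray, W: np.ndarray, w0: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Resolve scale/sign indeterminacy: unit-variance source rows, sign such
    that each row's skewness is >= 0.  A is rescaled so A @ S is unchanged."""
    from scipy.stats import skew

    sd = S.std(axis=1)
    sd[sd == 0] = 1.0
    sign = np.where(skew(S, axis=1) >= 0, 1.0, -1.0)
    scale = sign / sd
    S = S * scale[:, None]
    A = A / scale[None, :]
    W = W * scale[:, None]
    w0 = w0 * scale
    return S, A, W, w0


def infomax(
    Xw: np.ndarray,
    whitening: np.ndarray,
    dewhitening: np.ndarray,
    config: InfomaxConfig | None = None,
) -> Decomposition:
    """Run Infomax on whitened data and return the dewhitened decomposition.

    Raises after a capped number of restarts if the updates diverge.  The
    decomposition log records pass count, final weight change, and the entropy
    objective at the initial and final weights (the final value is the larger
    of the two at convergence).
    """
    config = config or InfomaxConfig()
    state = InfomaxState(Xw, config)
    h0 = _entropy_objective(state.W, state.w0, Xw)
    state.run()
    if not state.converged:
        warnings.warn(
            f"Infomax reached max_iter={config.max_iter} without meeting tol"
        )
    h1 = _entropy_objective(state.W, state.w0, Xw)
    S = state.W @ Xw
    A = dewhitening @ np.linalg.inv(state.W)
    S, A, W, w0 = _canonicalize(S, A, state.W, state.w0)
    kurt = _excess_kurtosis(S)
    return Decomposition(
        sources=S,
        loadings=A,
        unmixing=W,
        bias=w0,
        whitening=whitening,
        dewhitening=dewhitening,
        order=Xw.shape[0],
        log={
            "n_passes": state.n_passes,
            "final_change": state.trace[-1] if state.trace else np.nan,
            "entropy_initial": h0,
            "entropy_final": h1,
            "restarts": state.restarts,
            "lrate_final": state.lrate,
            "kurtosis": kurt,
            "gaussian_flag": bool(np.all(np.abs(kurt) < 0.5)),
        },
    )


def _excess_kurtosis(S: np.ndarray) -> np.ndarray:
    from scipy.stats import kurtosis

    return kurtosis(S, axis=1, fisher=True)


def decompose(
    X: FeatureMatrix | np.ndarray, order: int, config: InfomaxConfig | None = None
) -> Decomposition:
    """Convenience: whiten then run Infomax."""
    Xw, K, Dw, _ = pca_whiten(X, order)
    return infomax(Xw, K, Dw, config)


def match_sources(
    S_est: np.ndarray, S_true: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Best-match assignment between two source sets by absolute correlation.

    Returns ``(assignment, correlations)``: for each true source row, the
    matched estimated row index and the absolute Pearson correlation.
    Hungarian matching, so the assignment is one-to-one.
    """
    est = S_est - S_est.mean(axis=1, keepdims=True)
    tru = S_true - S_true.mean(axis=1, keepdims=True)
    est /= np.linalg.norm(est, axis=1, keepdims=True)
    tru /= np.linalg.norm(tru, axis=1, keepdims=True)
    C = np.abs(tru @ est.T)  # true x est
    row, col = linear_sum_assignment(-C)
    return col, C[row, col]


def estimate_order_stability(
    X: FeatureMatrix | np.ndarray,
    candidate_orders: list[int],
    n_runs: int = 5,
    seed: int = 0,
    config: InfomaxConfig | None = None,
    subsample: float = 0.8,
) -> tuple[int, dict[int, float]]:
    """Pick the model order whose ICA components are most reproducible.

    For each candidate order, Infomax is run ``n_runs`` times with different
    seeds, each run on a random ``subsample`` fraction of the feature columns
    (the resampling that makes run-to-run agreement informative: with the
    order over-specified, the surplus components shuffle between resamples).
    Components are matched across run pairs by absolute loading correlation
    (loadings live in the shared subject space, so runs on different feature
    subsets remain comparable) and the mean best-match correlation is the
    stability score; the returned order is the peak of that curve, ties going
    to the smaller order.  ``subsample=1.0`` degenerates to re-seeded runs on
    identical data, which scores near 1 everywhere (warned).
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if not 0 < subsample <= 1:
        raise ValueError("subsample must lie in (0, 1]")
    if subsample == 1.0:
        warnings.warn(
            "subsample=1.0: runs differ only by seed; the stability curve "
            "will be nearly flat"
        )
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)
    base = config or InfomaxConfig()
    rng = np.random.default_rng(seed)
    p = values.shape[1]
    curve: dict[int, float] = {}
    for order in candidate_orders:
        loadings = []
        for _ in range(n_runs):
            cols = rng.choice(p, size=max(order + 1, int(subsample * p)),
                              replace=False)
            run_seed = int(rng.integers(0, 2**31 - 1))
            Xw, K, Dw, _ = pca_whiten(values[:, cols], order)
            cfg = InfomaxConfig(
                lrate=base.lrate, anneal=base.anneal, anneal_deg=base.anneal_deg,
                max_iter=base.max_iter, tol=base.tol, block=base.block,
                max_restarts=base.max_restarts, blowup=base.blowup, seed=run_seed,
            )
            try:
                loadings.append(infomax(Xw, K, Dw, cfg).loadings)
            except RuntimeError as exc:  # diverged run: exclude, warn
                warnings.warn(f"order {order}: run excluded ({exc})")
        if len(loadings) < 2:
            warnings.warn(f"order {order}: fewer than 2 converged runs; skipped")
            continue
        scores = []
        for i in range(len(loadings)):
            for j in range(i + 1, len(loadings)):
                A, B = loadings[i], loadings[j]
                Ac = A - A.mean(axis=0)
                Bc = B - B.mean(axis=0)
                C = np.abs(
                    (Ac / np.linalg.norm(Ac, axis=0)).T
                    @ (Bc / np.linalg.norm(Bc, axis=0))
                )
                ri, ci = linear_sum_assignment(-C)
                scores.append(C[ri, ci].mean())
        curve[order] = float(np.mean(scores))
    if not curve:
        raise RuntimeError("no candidate order had two converged runs")
    best = max(curve, key=lambda k: (curve[k], -k))
    return best, curve


def amari_index(P: np.ndarray) -> float:
    """Permutation/scale-invariant separation error of ``P = W_est @ A_true``.

    0 for perfect separation (P a scaled permutation), normalized to [0, 1].
    """
    P = np.abs(np.asarray(P, dtype=float))
    C = P.shape[0]
    rows = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    cols = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((rows.sum() + cols.sum()) / (2.0 * C * (C - 1)))
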