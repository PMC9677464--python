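"""Per-iteration 2-D embedding of the contig feature matrix.

PCA first reduces the CLR feature matrix to the smallest number of
components explaining 75% of the variance (at most 75). The 2-D
embedding is t-SNE with a multi-scale Gaussian kernel: input-space
affinities are averaged over a small and a large perplexity (Kobak &
Berens style) so that local and global structure are balanced, with
Manhattan distance in the input space to soften the unreliability of
Euclidean distances in high dimensions.

The optimizer schedule adapts to the number of un-binned contigs NUC:

* early exaggeration   EX    = clamp(NUC * 2.5e-4, 4, 100)
* early learning rate  LR_EX = max(2, NUC / EX)
* main learning rate   LR    = clamp(NUC * 0.1, 200, 64000)

The Kullback-Leibler divergence is measured every 250 optimization
iterations, and each phase stops once the improvement falls below 1%
of the current KLD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

PCA_VARIANCE_TARGET = 0.75
PCA_MAX_COMPONENTS = 75
KLD_CHECK_INTERVAL = 250
KLD_STOP_RATIO = 0.01

MACHINE_EPS = np.finfo(np.float64).eps


def early_exaggeration(nuc: int) -> float:
    """Early-exaggeration factor for NUC un-binned contigs.

    NUC * 2.5e-4 clamped to [4, 100], so exaggeration scales with the
    dataset up to very large assemblies.
    """
    if nuc < 1:
        raise ValueError("NUC must be >= 1")
    return float(min(100.0, max(4.0, nuc * 2.5e-4)))


def learning_rates(nuc: int, ex: float) -> tuple[float, float]:
    """(early-phase, main-phase) learning rates for NUC contigs."""
    if ex <= 0:
        raise ValueError("EX must be positive")
    lr_ex = max(2.0, nuc / ex)
    lr = max(200.0, min(64e3, nuc * 0.1))
    return lr_ex, lr


def perplexity_pair(binning_iteration: int) -> tuple[float, float]:
    """(small, large) perplexity for a given 0-based binning iteration.

    Starts at (10, 100); the small one grows by 2 per iteration up to
    20, the large one by 5 up to 130.
    """
    if binning_iteration < 0:
        raise ValueError("iteration must be >= 0")
    return (
        float(min(20, 10 + 2 * binning_iteration)),
        float(min(130, 100 + 5 * binning_iteration)),
    )


@dataclass
class OptimizationState:
    """KLD bookkeeping at a 250-iteration checkpoint."""

    kld: float
    kld_diff: float = float("inf")

    def __post_init__(self):
        if self.kld < 0:
            raise ValueError("KLD must be non-negative")


def should_stop(state: OptimizationState) -> bool:
    """Stop once the KLD improvement drops below 1% of the current KLD."""
    return state.kld_diff < state.kld * KLD_STOP_RATIO


@dataclass
class EmbeddingParams:
    """Fully resolved optimizer parameters for one embedding run."""

    nuc: int
    ex: float
    lr_ex: float
    lr: float
    perplexities: tuple[float, float]
    metric: str = "manhattan"
    seed: int = 0

    @classmethod
    def for_iteration(
        cls, nuc: int, binning_iteration: int, seed: int = 0
    ) -> "EmbeddingParams":
        ex = early_exaggeration(nuc)
        lr_ex, lr = learning_rates(nuc, ex)
        return cls(
            nuc=nuc, ex=ex, lr_ex=lr_ex, lr=lr,
            perplexities=perplexity_pair(binning_iteration), seed=seed,
        )

    def __post_init__(self):
        if not (4 <= self.ex <= 100):
            raise ValueError("EX out of range [4, 100]")
        if self.lr_ex < 2 or not (200 <= self.lr <= 64000):
            raise ValueError("learning rate out of range")


def pca_reduce(matrix: np.ndarray) -> np.ndarray:
    """PCA pre-reduction to >=75% explained variance, capped at 75 dims.

    If the input already has no more columns than the chosen target the
    matrix is passed through unchanged.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to embed")
    max_comp = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=max_comp, svd_solver="full", random_state=0)
    Xp = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cum, PCA_VARIANCE_TARGET) + 1)
    n_keep = min(n_keep, PCA_MAX_COMPONENTS, max_comp)
    if n_keep >= X.shape[1]:
        return X
    return Xp[:, :n_keep]


def _conditional_affinities(d2: np.ndarray, perplexity: float) -> np.ndarray:
    """Row-stochastic Gaussian affinities at a fixed perplexity.

    Standard per-point binary search of the bandwidth so that the
    entropy of each conditional distribution equals log2(perplexity).
    ``d2`` are squared input-space distances with an inf diagonal.
    """
    n = d2.shape[0]
    target = np.log(perplexity)
    P = np.zeros_like(d2)
    for i in range(n):
        beta, beta_lo, beta_hi = 1.0, 0.0, np.inf
        di = d2[i]
        for _ in range(64):
            w = np.exp(-di * beta)
            w[i] = 0.0
            s = w.sum()
            if s <= 0:
                entropy = 0.0
            else:
                p = w / s
                nz = p > 0
                entropy = -np.sum(p[nz] * np.log(p[nz]))
            if abs(entropy - target) < 1e-5:
                break
            if entropy > target:
                beta_lo = beta
                beta = beta * 2 if beta_hi == np.inf else (beta + beta_hi) / 2
            else:
                beta_hi = beta
                beta = beta / 2 if beta_lo == 0 else (beta + beta_lo) / 2
        w = np.exp(-di * beta)
        w[i] = 0.0
        s = w.sum()
        P[i] = w / s if s > 0 else 0.0
    return P


def multiscale_affinities(
    X: np.ndarray, perplexities: tuple[float, float], metric: str = "manhattan"
) -> np.ndarray:
    """Symmetric joint affinities averaged over the two perplexities."""
    scipy_metric = "cityblock" if metric == "manhattan" else metric
    d = squareform(pdist(np.asarray(X, dtype=float), metric=scipy_metric))
    d2 = d**2
    np.fill_diagonal(d2, np.inf)
    n = X.shape[0]
    P = np.zeros_like(d2)
    for perp in perplexities:
        perp = min(perp, (n - 1) / 3.0)
        P += _conditional_affinities(d2, max(perp, 1.0))
    P /= len(perplexities)
    P = (P + P.T) / (2.0 * n)
    P = np.maximum(P, 0.0)
    P /= P.sum()
    return P


def _kld(P: np.ndarray, Y: np.ndarray) -> float:
    num = 1.0 / (1.0 + _sq_dists(Y))
    np.fill_diagonal(num, 0.0)
    Q = num / num.sum()
    mask = P > 0
    return float(np.sum(P[mask] * np.log(P[mask] / np.maximum(Q[mask], MACHINE_EPS))))


def _sq_dists(Y: np.ndarray) -> np.ndarray:
    sq = np.sum(Y**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (Y @ Y.T)
    np.maximum(d2, 0.0, out=d2)
    return d2


def _gradient_descent(
    P: np.ndarray,
    Y: np.ndarray,
    lr: float,
    momentum: float,
    max_iter: int,
    P_report: np.ndarray,
) -> tuple[np.ndarray, float, int]:
    """Momentum + adaptive-gains t-SNE descent with KLD checkpoints.

    ``P`` drives the gradient (possibly exaggerated), ``P_report`` is
    the un-exaggerated matrix used for the stopping KLD. Returns the
    final layout, KLD and iteration count.
    """
    n = Y.shape[0]
    update = np.zeros_like(Y)
    gains = np.ones_like(Y)
    prev_kld = None
    it = 0
    while it < max_iter:
        for _ in range(min(KLD_CHECK_INTERVAL, max_iter - it)):
            num = 1.0 / (1.0 + _sq_dists(Y))
            np.fill_diagonal(num, 0.0)
            Q = num / max(num.sum(), MACHINE_EPS)
            PQd = (P - Q) * num
            grad = 4.0 * ((np.diag(PQd.sum(axis=1)) - PQd) @ Y)
            same_sign = np.sign(grad) == np.sign(update)
            gains = np.where(same_sign, gains * 0.8, gains + 0.2)
            np.maximum(gains, 0.01, out=gains)
            update = momentum * update - lr * gains * grad
            Y = Y + update
            Y = Y - Y.mean(axis=0)
            it += 1
        kld = _kld(P_report, Y)
        state = OptimizationState(
            kld=kld,
            kld_diff=float("inf") if prev_kld is None else prev_kld - kld,
        )
        prev_kld = kld
        if should_stop(state):
            break
    return Y, prev_kld if prev_kld is not None else _kld(P_report, Y), it


class MultiScaleTSNE(BaseEstimator):
    """t-SNE transformer with the adaptive binning schedule.

    Parameters default to the values resolved from the dataset size at
    fit time; pass an :class:`EmbeddingParams` via ``params`` to pin
    them (the orchestrator does). The estimator is deterministic for a
    fixed ``random_state``.

    Attributes set by :meth:`fit`: ``embedding_`` (n x 2 coordinates),
    ``kl_divergence_``, ``n_iter_``, ``params_``.
    """

    def __init__(
        self,
        params: EmbeddingParams | None = None,
        binning_iteration: int = 0,
        max_iter_early: int = 1000,
        max_iter_main: int = 2000,
        random_state: int = 0,
    ):
        self.params = params
        self.binning_iteration = binning_iteration
        self.max_iter_early = max_iter_early
        self.max_iter_main = max_iter_main
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("X must be 2-D with at least 2 rows")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        n = X.shape[0]
        params = self.params or EmbeddingParams.for_iteration(
            n, self.binning_iteration, seed=self.random_state
        )
        small, large = params.perplexities
        if n < 3 * large:
            # too few points for the large perplexity: shrink both
            # proportionally so (n - 1) / 3 becomes the large scale
            scale = max((n - 1) / 3.0, 1.0) / large
            warnings.warn(
                f"n={n} too small for perplexity {large}; scaling "
                f"perplexities by {scale:.3f}"
            )
            small, large = max(1.0, small * scale), max(1.0, large * scale)
        P = multiscale_affinities(X, (small, large), metric=params.metric)

        rng = np.random.default_rng(params.seed)
        n_init = min(2, X.shape[1], n - 1)
        pca = PCA(n_components=n_init, svd_solver="full", random_state=0)
        Y = pca.fit_transform(X)
        if Y.shape[1] < 2:  # rank-deficient input: jitter the second axis
            pad = rng.normal(scale=Y.std() + 1e-12, size=(n, 2 - Y.shape[1]))
            Y = np.hstack([Y, pad])
        std0 = Y[:, 0].std()
        if std0 > 0:
            Y = Y / std0 * 1e-4
        else:
            Y = rng.normal(scale=1e-4, size=(n, 2))

        Y, _, it_early = _gradient_descent(
            P * params.ex, Y, params.lr_ex, momentum=0.5,
            max_iter=self.max_iter_early, P_report=P,
        )
        Y, kld, it_main = _gradient_descent(
            P, Y, params.lr, momentum=0.8,
            max_iter=self.max_iter_main, P_report=P,
        )
        self.params_ = params
        self.embedding_ = Y
        self.kl_divergence_ = kld
        self.n_iter_ = it_early + it_main
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).embedding_


def embed(features: np.ndarray, params: EmbeddingParams) -> np.ndarray:
    """Embed a (PCA-reduced) feature matrix to 2-D under ``params``."""
    return MultiScaleTSNE(params=params, random_state=params.seed).fit_transform(
        features
    )
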