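"""Full-field reconstruction models from a measured subset of locations.

Four model families map the thresholds measured at an ordered subset of
locations to an estimate of the whole 54-location field:

``mean``
    the training-mean hill of vision, ignoring the measurements
    (no-seeding baseline);
``lr``
    ordinary linear regression, ``xhat = D s + beta`` with ``D`` of shape
    (54, |subset|) — one free row per output location;
``ttpcr``
    transformed-target principal component regression: linear regression
    from the measured subset to the *n*-dimensional PCA embedding of the
    full field, expanded back through the basis,
    ``xhat = W (D s + beta) + mu``.  The PCA basis is fitted once on the
    training targets and frozen across subsets;
``pls``
    partial least squares, a rank-*n* constrained affine map
    ``xhat = W D s + beta`` trained iteratively (NIPALS).

With the embedding dimension equal to the subset size (and 54), TTPCR and
PLS both collapse to ordinary linear regression; the dimensionality
reduction only matters — and helps — when the training sample is small
relative to the 54-dimensional field.

Fitting always uses the raw (unclipped) training thresholds; predictions
are clipped to the instrument range [0, 40] dB only at reconstruction
time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .fields import DB_MIN, DB_MAX, FieldDataset

logger = logging.getLogger(__name__)

PLS_TOL = 1e-6
PLS_MAX_ITER = 500


# ---------------------------------------------------------------------------
# PCA basis (fitted once, frozen across subsets)

@dataclass
class PCABasis:
    """Principal-component basis of a visual-field training matrix.

    ``mu`` is the per-location mean field; ``components`` the 54 x n
    orthonormal matrix of leading eigenvectors of the sample covariance
    ``S = B B^T / (N-1)`` of the centered matrix ``B``; ``eigenvalues``
    the corresponding non-increasing eigenvalues.
    """

    mu: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray

    @property
    def n(self) -> int:
        return self.components.shape[1]

    def embed(self, x: np.ndarray) -> np.ndarray:
        """Project field(s) onto the basis: ``t = W^T (x - mu)``."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            return self.components.T @ (x - self.mu)
        return self.components.T @ (x - self.mu[:, None])

    def expand(self, t: np.ndarray) -> np.ndarray:
        """Back-project embedding(s): ``xhat = W t + mu``."""
        t = np.asarray(t, dtype=float)
        if t.ndim == 1:
            return self.components @ t + self.mu
        return self.components @ t + self.mu[:, None]


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (deterministic basis)."""
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def fit_pca(X: FieldDataset | np.ndarray, n: int) -> PCABasis:
    """Fit the top-``n`` principal components of a 54 x N training matrix.

    Computed by SVD of the centered matrix (eigenvalues are squared
    singular values over N-1); the sign convention makes repeated fits
    bit-identical.
    """
    M = X.X if isinstance(X, FieldDataset) else np.asarray(X, dtype=float)
    p, N = M.shape
    if not 1 <= n <= p:
        raise ValueError(f"embedding dimension must be in [1, {p}], got {n}")
    if N < 2:
        raise ValueError("need at least two training fields")
    mu = M.mean(axis=1)
    B = M - mu[:, None]
    U, s, _ = np.linalg.svd(B, full_matrices=False)
    eigvals = s**2 / (N - 1)
    k = min(n, U.shape[1])
    W = _fix_signs(U[:, :k])
    if k < n:
        # rank-deficient training matrix: pad with an orthonormal complement
        comp = _orthonormal_complement(W, p, n - k)
        W = np.hstack([W, comp])
        eigvals = np.concatenate([eigvals[:k], np.zeros(n - k)])
    else:
        eigvals = eigvals[:n]
    return PCABasis(mu=mu, components=W, eigenvalues=eigvals)


def _orthonormal_complement(W: np.ndarray, p: int, m: int) -> np.ndarray:
    Q, _ = np.linalg.qr(np.hstack([W, np.eye(p)]))
    return _fix_signs(Q[:, W.shape[1]: W.shape[1] + m])


def pca_embed(basis: PCABasis, x: np.ndarray) -> np.ndarray:
    return basis.embed(x)


def pca_expand(basis: PCABasis, t: np.ndarray) -> np.ndarray:
    return basis.expand(t)


# ---------------------------------------------------------------------------
# Subset reconstructors

@dataclass
class SubsetReconstructor:
    """Affine map from measured subset values to a full-field estimate.

    All four kinds reduce to ``xhat = D_eff s + beta_eff`` at prediction
    time; ``factors`` keeps the rank-revealing pieces (PCA basis for
    ttpcr, the (W, D) pair for pls) for inspection and serialization.
    """

    kind: str
    subset: tuple[int, ...]
    D: np.ndarray  # (54, |subset|) effective weights
    beta: np.ndarray  # (54,) effective bias
    n: int | None = None
    basis: PCABasis | None = None  # ttpcr only
    factors: tuple[np.ndarray, np.ndarray] | None = None  # pls (W, D_n)

    def predict(self, s, clip: bool = True) -> np.ndarray:
        """Reconstruct the full field from the measured subset values."""
        s = np.asarray(s, dtype=float)
        if s.shape != (len(self.subset),):
            raise ValueError(
                f"expected {len(self.subset)} measured values, got {s.shape}"
            )
        xhat = self.D @ s + self.beta
        return np.clip(xhat, DB_MIN, DB_MAX) if clip else xhat

    def training_mse(self, X: FieldDataset | np.ndarray) -> float:
        """Mean squared reconstruction error in field space (dB^2), unclipped."""
        M = X.X if isinstance(X, FieldDataset) else np.asarray(X, dtype=float)
        S = M[list(self.subset), :] if self.subset else np.zeros((0, M.shape[1]))
        pred = self.D @ S + self.beta[:, None]
        return float(np.mean((pred - M) ** 2))


def reconstruct(model: SubsetReconstructor, s) -> np.ndarray:
    """Apply a fitted reconstructor to measured values; clipped to [0, 40] dB."""
    return model.predict(s, clip=True)


def _design(M: np.ndarray, subset) -> np.ndarray:
    S = M[list(subset), :]
    return np.vstack([S, np.ones(M.shape[1])]).T  # (N, k+1)


def _lstsq_affine(M: np.ndarray, subset, targets: np.ndarray):
    """Minimum-norm least squares of targets (m x N) on subset rows + bias."""
    A = _design(M, subset)
    coef, *_ = np.linalg.lstsq(A, targets.T, rcond=None)
    return coef[:-1].T, coef[-1]  # D (m x k), beta (m,)


def fit_mean(X: FieldDataset | np.ndarray, subset=()) -> SubsetReconstructor:
    """Hill-of-vision baseline: predict the training mean, ignore measurements."""
    M = X.X if isinstance(X, FieldDataset) else np.asarray(X, dtype=float)
    subset = tuple(subset)
    return SubsetReconstructor(
        kind="mean",
        subset=subset,
        D=np.zeros((M.shape[0], len(subset))),
        beta=M.mean(axis=1),
    )


def fit_lr(X: FieldDataset | np.ndarray, subset) -> SubsetReconstructor:
    """Ordinary linear regression from subset to all 54 locations.

    Solved by minimum-norm least squares; no regularization.  Rank
    deficiency (fewer training fields than subset size) yields the
    minimum-norm solution rather than an error.
    """
    subset = tuple(int(i) for i in subset)
    if not subset:
        raise ValueError("subset must contain at least one location")
    M = X.X if isinstance(X, FieldDataset) else np.asarray(X, dtype=float)
    D, beta = _lstsq_affine(M, subset, M)
    return SubsetReconstructor(kind="lr", subset=subset, D=D, beta=beta)


def fit_ttpcr(
    X: FieldDataset | np.ndarray, subset, basis: PCABasis
) -> SubsetReconstructor:
    """Transformed-target PC regression: regress embeddings, expand through W.

    Equivalent closed form: the TTPCR prediction is the orthogonal
    projection of the LR prediction onto the basis subspace, which is what
    makes the model robust when training data is scarce.
    """
    subset = tuple(int(i) for i in subset)
    if not subset:
        raise ValueError("subset must contain at least one location")
    M = X.X if isinstance(X, FieldDataset) else np.asarray(X, dtype=float)
    if basis.mu.shape[0] != M.shape[0]:
        raise ValueError("basis was fitted on a different grid size")
    T = basis.embed(M)  # (n, N)
    Dn, bn = _lstsq_affine(M, subset, T)
    W = basis.components
    return SubsetReconstructor(
        kind="ttpcr",
        subset=subset,
        D=W @ Dn,
        beta=W @ bn + basis.mu,
        n=basis.n,
        basis=basis,
    )


def fit_pls(X: FieldDataset | np.ndarray, subset, n: int) -> SubsetReconstructor:
    """Rank-``n`` partial least squares (PLS2/NIPALS) from subset to full field.

    The effective number of components is capped at min(n, |subset|, N-1);
    at full rank the fit coincides with ordinary linear regression.
    Non-convergence of a NIPALS component is logged and the best iterate
    kept.
    """
    subset = tuple(int(i) for i in subset)
    if not subset:
        raise ValueError("subset must contain at least one location")
    M = X.X if isinstance(X, FieldDataset) else np.asarray(X, dtype=float)
    N = M.shape[1]
    n_eff = int(min(n, len(subset), max(N - 1, 1)))
    if n_eff < 1:
        raise ValueError("embedding dimension must be at least 1")
    S = M[list(subset), :].T  # (N, k)
    Y = M.T  # (N, 54)
    pls = PLSRegression(n_components=n_eff, scale=False, max_iter=PLS_MAX_ITER, tol=PLS_TOL)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        pls.fit(S, Y)
    for w in caught:
        logger.warning("PLS fit (|subset|=%d, n=%d): %s", len(subset), n_eff, w.message)
    # xhat = W_n D_n (s - s_mean) + y_mean, with coef_ = (W_n D_n)^T of rank <= n
    Wn = pls.y_loadings_  # (54, n)
    Dn = pls.x_rotations_.T  # (n, k)
    D = pls.coef_  # (54, k)
    beta = pls.intercept_ - D @ S.mean(axis=0)
    return SubsetReconstructor(
        kind="pls", subset=subset, D=D, beta=np.asarray(beta, dtype=float),
        n=n_eff, factors=(Wn, Dn),
    )


def fit_reconstructor(
    kind: str,
    X: FieldDataset | np.ndarray,
    subset,
    n: int | None = None,
    basis: PCABasis | None = None,
) -> SubsetReconstructor:
    """Factory dispatching on reconstructor kind."""
    if kind == "mean":
        return fit_mean(X, subset)
    if kind == "lr":
        return fit_lr(X, subset)
    if kind == "ttpcr":
        if basis is None:
            raise ValueError("ttpcr requires a fitted PCABasis")
        return fit_ttpcr(X, subset, basis)
    if kind == "pls":
        if n is None:
            raise ValueError("pls requires an embedding dimension n")
        return fit_pls(X, subset, n)
    raise ValueError(f"unknown reconstructor kind {kind!r}")
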