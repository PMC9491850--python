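"""Linear PCA and Gaussian-kernel KPCA with contribution-rate component selection.

PCA follows the classical covariance-eigendecomposition route; KPCA solves the
eigenproblem of the double-centered kernel matrix, scales each eigenvector so
the corresponding feature-space component has unit norm, and retains the
smallest number of components whose cumulative contribution rate (eigenvalue
share of the total) reaches a configurable threshold xi.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PcaModel",
    "KpcaModel",
    "pca_fit",
    "pca_project",
    "gaussian_kernel",
    "median_heuristic_gamma",
    "kpca_fit",
    "kpca_project",
    "contribution_rates",
    "cumulative_contribution",
    "save_kpca",
    "load_kpca",
]

_EIG_TOL = 1e-12  # relative cutoff below which eigenvalues count as zero


# ---------------------------------------------------------------------------
# linear PCA (baseline)

@dataclass
class PcaModel:
    mean: np.ndarray          # (d,)
    axes: np.ndarray          # (k, d) orthonormal rows, by decreasing variance
    eigenvalues: np.ndarray   # (k,)
    k: int


def pca_fit(X: np.ndarray, k: int) -> PcaModel:
    """Top-k principal axes of the sample covariance (1/m) Xc^T Xc.

    Rows of X are samples.  Ties in eigenvalues are broken by original index
    (stable sort); each axis's sign is fixed so its largest-magnitude entry is
    positive, for reproducibility.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if k <= 0:
        raise ValueError("k must be positive")
    if k > min(n, d):
        raise ValueError(f"k={k} exceeds min(n_samples, n_features)={min(n, d)}")
    mean = X.mean(axis=0)
    Xc = X - mean
    C = (Xc.T @ Xc) / n
    evals, evecs = np.linalg.eigh(C)            # ascending
    order = np.argsort(-evals, kind="stable")
    evals = np.clip(evals[order], 0.0, None)[:k]
    axes = evecs[:, order].T[:k]
    for i in range(k):
        j = np.argmax(np.abs(axes[i]))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    return PcaModel(mean=mean, axes=axes, eigenvalues=evals, k=k)


def pca_project(model: PcaModel, x: np.ndarray) -> np.ndarray:
    """Project sample(s) onto the principal axes; returns k scores per sample."""
    x = np.asarray(x, dtype=float)
    return (x - model.mean) @ model.axes.T


# ---------------------------------------------------------------------------
# Gaussian-kernel KPCA

def gaussian_kernel(x: np.ndarray, y: np.ndarray, gamma: float) -> np.ndarray:
    """exp(-gamma * ||x - y||^2); symmetric, in (0, 1]."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape[-1] != y.shape[-1]:
        raise ValueError("x and y must have equal dimensionality")
    if x.ndim == 1 and y.ndim == 1:
        return float(np.exp(-gamma * np.sum((x - y) ** 2)))
    x2 = np.atleast_2d(x)
    y2 = np.atleast_2d(y)
    d2 = (
        (x2 ** 2).sum(axis=1)[:, None]
        + (y2 ** 2).sum(axis=1)[None, :]
        - 2.0 * x2 @ y2.T
    )
    return np.exp(-gamma * np.clip(d2, 0.0, None))


def median_heuristic_gamma(X: np.ndarray) -> float:
    """1 / median of pairwise squared distances (nonzero pairs)."""
    X = np.asarray(X, dtype=float)
    sq = (X ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    iu = np.triu_indices(len(X), k=1)
    vals = np.clip(d2[iu], 0.0, None)
    med = np.median(vals)
    if med <= 0:
        raise ValueError("median pairwise distance is zero (degenerate inputs)")
    return 1.0 / med


@dataclass
class KpcaModel:
    """Fitted Gaussian-kernel KPCA with explicit feature-space centering stats."""

    X_train: np.ndarray         # (n, d)
    gamma: float
    eigenvalues: np.ndarray     # centered-kernel eigenvalues, non-increasing
    alphas: np.ndarray          # (n, n_nonzero); column k scaled by 1/sqrt(lambda_k)
    contributions: np.ndarray   # eigenvalue shares over nonzero spectrum
    P: int                      # retained component count
    xi_threshold: float
    kernel_row_means: np.ndarray  # (n,) row means of the uncentered K
    grand_mean: float
    linear: bool = False        # plain inner-product kernel (testing/diagnostics)


def _kernel_matrix(model_or_gamma, X, Y, linear: bool) -> np.ndarray:
    if linear:
        return np.asarray(X, dtype=float) @ np.asarray(Y, dtype=float).T
    return gaussian_kernel(X, Y, model_or_gamma)


def kpca_fit(X: np.ndarray, gamma: float | None = None,
             xi_threshold: float = 0.85, *, linear: bool = False) -> KpcaModel:
    """Fit KPCA on sample rows of X.

    The kernel matrix is double-centered in feature space,
    ``K~ = K - 1K - K1 + 1K1``, its eigendecomposition taken, negative
    numerical eigenvalues clipped to zero, and eigenvectors alpha^k scaled by
    1/sqrt(lambda_k) so feature-space components have unit norm.  P is the
    smallest count whose cumulative contribution rate reaches
    ``xi_threshold``.  ``gamma=None`` uses the median heuristic.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not (0.0 < xi_threshold <= 1.0):
        raise ValueError("xi_threshold must be in (0, 1]")
    if gamma is None and not linear:
        gamma = median_heuristic_gamma(X)
    if not linear and gamma <= 0:
        raise ValueError("gamma must be positive")

    K = _kernel_matrix(gamma, X, X, linear)
    row_means = K.mean(axis=1)
    grand = float(K.mean())
    Kc = K - row_means[:, None] - row_means[None, :] + grand

    evals, evecs = np.linalg.eigh(Kc)
    order = np.argsort(-evals, kind="stable")
    evals = evals[order]
    evecs = evecs[:, order]
    evals = np.clip(evals, 0.0, None)

    nz = evals > _EIG_TOL * max(evals.max(), 1.0)
    if not nz.any():
        raise ValueError("degenerate input: all samples identical "
                         "(centered kernel matrix has rank 0)")
    lam = evals[nz]
    A = evecs[:, nz] / np.sqrt(lam)[None, :]
    # reproducible sign: largest-|alpha| entry positive per component
    for k in range(A.shape[1]):
        j = np.argmax(np.abs(A[:, k]))
        if A[j, k] < 0:
            A[:, k] = -A[:, k]

    cont = lam / lam.sum()
    P = int(np.searchsorted(np.cumsum(cont), xi_threshold - 1e-12) + 1)
    P = min(P, len(lam))
    return KpcaModel(X_train=X, gamma=float(gamma) if gamma is not None else 0.0,
                     eigenvalues=lam, alphas=A, contributions=cont, P=P,
                     xi_threshold=float(xi_threshold),
                     kernel_row_means=row_means, grand_mean=grand, linear=linear)


def kpca_project(model: KpcaModel, x: np.ndarray, n_components: int | None = None
                 ) -> np.ndarray:
    """Nonlinear principal-component scores h_k = sum_i alpha_i^k K~(x_i, x).

    Applies the training centering statistics to the test kernel rows.  With
    ``n_components=None`` the model's retained count P is used.
    """
    P = model.P if n_components is None else n_components
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.X_train.shape[1]:
        raise ValueError("x must have training dimensionality")
    Kt = _kernel_matrix(model.gamma, X, model.X_train, model.linear)  # (m, n)
    Ktc = (Kt - Kt.mean(axis=1, keepdims=True)
           - model.kernel_row_means[None, :] + model.grand_mean)
    H = Ktc @ model.alphas[:, :P]
    return H[0] if single else H


def contribution_rates(eigenvalues: np.ndarray) -> np.ndarray:
    """Per-component eigenvalue share Cont_i = lambda_i / sum(lambda)."""
    lam = np.asarray(eigenvalues, dtype=float)
    if (lam < 0).any():
        raise ValueError("eigenvalues must be non-negative")
    s = lam.sum()
    if s <= 0:
        raise ValueError("eigenvalues must not all be zero")
    return lam / s


def cumulative_contribution(eigenvalues: np.ndarray, P: int) -> float:
    """Cumulative contribution xi of the first P components."""
    cont = contribution_rates(eigenvalues)
    if not (1 <= P <= len(cont)):
        raise ValueError("P out of range")
    return float(cont[:P].sum())


# ---------------------------------------------------------------------------
# persistence: save -> load -> project is bit-identical

def save_kpca(model: KpcaModel, path) -> None:
    meta = {"gamma": model.gamma, "P": model.P,
            "xi_threshold": model.xi_threshold,
            "grand_mean": model.grand_mean, "linear": model.linear,
            "format_version": 1}
    np.savez(path, X_train=model.X_train, eigenvalues=model.eigenvalues,
             alphas=model.alphas, contributions=model.contributions,
             kernel_row_means=model.kernel_row_means,
             meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))


def load_kpca(path) -> KpcaModel:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        return KpcaModel(X_train=z["X_train"], gamma=meta["gamma"],
                         eigenvalues=z["eigenvalues"], alphas=z["alphas"],
                         contributions=z["contributions"], P=meta["P"],
                         xi_threshold=meta["xi_threshold"],
                         kernel_row_means=z["kernel_row_means"],
                         grand_mean=meta["grand_mean"], linear=meta["linear"])
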