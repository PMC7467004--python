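"""Per-site multivariate-normal composite likelihood with distance binning.

A usable site contributes the log-density of its mean-centered standardized
deviation vector ``w = C z`` under ``Sigma(r) = C (F'(r) + diag(1/n)) C^T``,
where ``F'(r)`` is the mode kernel at the site's recombination distance from
the proposed selected site.  Sites are binned by distance so the kernel (and
the factorization of ``Sigma``) is evaluated once per occupied bin; the
composite log-likelihood is the sum over sites.

Two linear-algebra paths are provided: Cholesky factorization (fast; the
default) and a pseudo-inverse/eigenvalue path that tolerates covariance
matrices that are not positive definite.  When Cholesky fails, a single
diagonal jitter of ``1e-10 * trace/p`` is tried before falling back to the
pseudo-inverse for that matrix (logged, never fatal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import EstimationError, ValidationError

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))

_warned: set[str] = set()


def _warn_once(key: str, msg: str, *args) -> None:
    """Warn the first time an event occurs; debug-log repeats."""
    if key in _warned:
        logger.debug(msg, *args)
    else:
        _warned.add(key)
        logger.warning(msg + " (further occurrences logged at DEBUG)", *args)


@dataclass
class BinnedDistances:
    """Assignment of selected-region sites to recombination-distance bins.

    ``bin_index[l]`` maps site ``l`` to a bin; ``bin_midpoint_r[b]`` is the
    representative distance at which the kernel is evaluated for bin ``b``.
    When ``num_bins`` is at least the number of distinct distances, each
    distinct distance is its own bin with itself as representative, making
    binning exact.
    """

    bin_index: np.ndarray
    bin_midpoint_r: np.ndarray
    num_bins: int
    r_sites: np.ndarray


def bin_distances(
    positions: np.ndarray, proposed_site: float, rec: float, num_bins: int
) -> BinnedDistances:
    """Bin sites by recombination distance from a proposed selected site.

    ``r = rec * |position - proposed_site|``; bins are ``num_bins`` uniform
    right-closed intervals over ``[0, max r]`` with midpoint representatives,
    except that distinct distances get their own (exact) bins whenever
    ``num_bins`` allows it.
    """
    if num_bins < 1:
        raise ValidationError("num_bins must be >= 1")
    if rec <= 0:
        raise ValidationError("rec must be > 0")
    positions = np.asarray(positions, dtype=float)
    r = rec * np.abs(positions - proposed_site)
    distinct = np.unique(r)
    if distinct.size <= num_bins:
        idx = np.searchsorted(distinct, r)
        return BinnedDistances(idx, distinct, num_bins, r)
    r_max = float(r.max())
    if r_max == 0.0:
        return BinnedDistances(np.zeros(r.size, dtype=int), np.zeros(1), num_bins, r)
    edges = np.linspace(0.0, r_max, num_bins + 1)
    # right-closed bins: a distance on an interior edge belongs to the lower bin
    idx = np.clip(np.searchsorted(edges, r, side="left") - 1, 0, num_bins - 1)
    mids = (edges[:-1] + edges[1:]) / 2.0
    return BinnedDistances(idx, mids, num_bins, r)


def _chol_logpdf_terms(Sigma: np.ndarray) -> tuple[np.ndarray, float]:
    """Cholesky factor and log-determinant of one covariance matrix."""
    L = np.linalg.cholesky(Sigma)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return L, logdet


def _pinv_logpdf(Sigma: np.ndarray, W: np.ndarray) -> float:
    """Gaussian log-density sum via eigendecomposition (pseudo-inverse path).

    Uses only eigenvalues above a relative threshold; the log-determinant is
    the log of the product of retained eigenvalues.
    """
    vals, vecs = np.linalg.eigh((Sigma + Sigma.T) / 2.0)
    tol = max(abs(vals.max()), 1.0e-300) * Sigma.shape[0] * np.finfo(float).eps
    keep = vals > tol
    if not keep.any():
        raise EstimationError("model covariance has no positive eigenvalues")
    vals_k = vals[keep]
    logdet = float(np.sum(np.log(vals_k)))
    proj = vecs[:, keep].T @ W  # (rank, n)
    quad = float(np.sum(proj * proj / vals_k[:, None]))
    n = W.shape[1]
    rank = int(keep.sum())
    return -0.5 * (n * (rank * _LOG2PI + logdet) + quad)


def _gaussian_block_loglik(Sigma: np.ndarray, W: np.ndarray, use_cholesky: bool) -> float:
    """Sum of zero-mean MVN log-densities of the columns of ``W`` under ``Sigma``."""
    p, n = W.shape
    if use_cholesky:
        try:
            L, logdet = _chol_logpdf_terms(Sigma)
        except np.linalg.LinAlgError:
            jitter = 1.0e-10 * float(np.trace(Sigma)) / p
            try:
                L, logdet = _chol_logpdf_terms(Sigma + jitter * np.eye(p))
                logger.warning("covariance required diagonal jitter %.3g", jitter)
            except np.linalg.LinAlgError:
                logger.warning("Cholesky failed; using pseudo-inverse path for this matrix")
                return _pinv_logpdf(Sigma, W)
        half = scipy.linalg.solve_triangular(L, W, lower=True)
        quad = float(np.sum(half * half))
        return -0.5 * (n * (p * _LOG2PI + logdet) + quad)
    return _pinv_logpdf(Sigma, W)


def site_loglik(
    z: np.ndarray,
    F_model: np.ndarray,
    sample_sizes: np.ndarray,
    C: np.ndarray,
    path: str = "cholesky",
) -> float:
    """Log-likelihood of one site's standardized deviation vector.

    ``Sigma = C (F_model + diag(1/n)) C^T``; returns the zero-mean
    multivariate-normal log-density of ``w = C z``.
    """
    if path not in ("cholesky", "pseudoinverse"):
        raise ValidationError(f"unknown linear-algebra path {path!r}")
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise ValidationError("site is not usable (non-finite standardized values)")
    D = np.diag(1.0 / np.asarray(sample_sizes, dtype=float))
    Sigma = C @ (F_model + D) @ C.T
    W = (C @ z)[:, None]
    return _gaussian_block_loglik(Sigma, W, use_cholesky=(path == "cholesky"))


def stacked_block_loglik(
    F_stack: np.ndarray,
    G_stack: np.ndarray,
    counts: np.ndarray,
    sample_sizes: np.ndarray,
    C: np.ndarray,
    use_cholesky: bool = True,
) -> float:
    """Composite log-likelihood over bins, vectorized across the bin stack.

    ``F_stack`` is (B, k, k) model coancestry per occupied bin; ``G_stack``
    is (B, p, p) with ``G_b = W_b W_b^T`` the Gram matrix of the centered
    site vectors in bin ``b``; ``counts[b]`` is the number of sites in the
    bin.  Returns ``sum_b -0.5 (n_b (p log 2pi + logdet Sigma_b)
    + tr(Sigma_b^{-1} G_b))``.
    """
    D = np.diag(1.0 / np.asarray(sample_sizes, dtype=float))
    Sigma = np.einsum("ai,bij,cj->bac", C, F_stack + D, C, optimize=True)
    p = C.shape[0]
    if use_cholesky:
        try:
            L = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:
            jitter = 1.0e-10 * np.trace(Sigma, axis1=1, axis2=2) / p
            try:
                L = np.linalg.cholesky(Sigma + jitter[:, None, None] * np.eye(p))
                _warn_once("jitter", "covariance required diagonal jitter")
            except np.linalg.LinAlgError:
                _warn_once(
                    "pinv-fallback",
                    "Cholesky failed for a model covariance stack; "
                    "using the pseudo-inverse path",
                )
                return _stacked_pinv_loglik(Sigma, G_stack, counts, p)
        logdets = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)), axis=1)
        X = np.linalg.solve(Sigma, G_stack)
        traces = np.trace(X, axis1=1, axis2=2)
        return float(-0.5 * np.sum(counts * (p * _LOG2PI + logdets) + traces))
    return _stacked_pinv_loglik(Sigma, G_stack, counts, p)


def _stacked_pinv_loglik(Sigma, G_stack, counts, p) -> float:
    """Pseudo-inverse path for a whole bin stack via batched eigendecomposition.

    Eigenvalues below a relative threshold are treated as zero: the
    log-determinant uses only the retained eigenvalues and the quadratic form
    uses the pseudo-inverse, so rank-deficient model covariances never abort
    a fit.
    """
    Sym = (Sigma + np.swapaxes(Sigma, 1, 2)) / 2.0
    vals, vecs = np.linalg.eigh(Sym)  # (B, p), (B, p, p)
    tol = np.maximum(np.abs(vals).max(axis=1), 1.0e-300) * p * np.finfo(float).eps
    keep = vals > tol[:, None]
    if not keep.any(axis=1).all():
        raise EstimationError("a model covariance has no positive eigenvalues")
    safe_vals = np.where(keep, vals, 1.0)
    logdets = np.sum(np.where(keep, np.log(safe_vals), 0.0), axis=1)
    ranks = keep.sum(axis=1)
    # v_m^T G v_m per eigenvector, then weight by kept 1/lambda
    GV = np.einsum("bij,bjm->bim", G_stack, vecs, optimize=True)
    quad_per_vec = np.einsum("bim,bim->bm", vecs, GV, optimize=True)
    traces = np.sum(np.where(keep, quad_per_vec / safe_vals, 0.0), axis=1)
    return float(-0.5 * np.sum(counts * (ranks * _LOG2PI + logdets) + traces))


def composite_loglik(
    Z: np.ndarray,
    sample_sizes: np.ndarray,
    cov_at: "callable",
    bins: BinnedDistances,
    C: np.ndarray,
    path: str = "cholesky",
) -> float:
    """Composite log-likelihood of the selected-region sites.

    ``Z`` is the (k, L) matrix of usable standardized deviations,
    ``cov_at(r_vector)`` returns the (B, k, k) model coancestry stack for the
    occupied bin representatives, and ``bins`` assigns sites to bins.
    """
    if path not in ("cholesky", "pseudoinverse"):
        raise ValidationError(f"unknown linear-algebra path {path!r}")
    if Z.shape[1] == 0:
        raise EstimationError("no usable selected-region sites")
    W = C @ Z
    occupied, inverse = np.unique(bins.bin_index, return_inverse=True)
    counts = np.bincount(inverse)
    p = W.shape[0]
    G = np.zeros((occupied.size, p, p))
    for b in range(occupied.size):
        Wb = W[:, inverse == b]
        G[b] = Wb @ Wb.T
    F_stack = cov_at(bins.bin_midpoint_r[occupied])
    return stacked_block_loglik(F_stack, G, counts, sample_sizes, C, path == "cholesky")
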