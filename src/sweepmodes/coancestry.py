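"""Neutral coancestry estimation from standardized allele-frequency deviations.

Across-population drift is summarised by a k x k coancestry matrix ``F``: the
covariance of per-site deviations from the across-population mean frequency,
standardized by the binomial scale ``sqrt(eps (1 - eps))`` where ``eps`` is the
mean frequency at the site (an ancestral-frequency proxy).  Every convergence
mode modifies this one neutral matrix near the selected site.

Because deviations are measured from the across-population mean, ``F`` only
enters the likelihood through its mean-centered projection; the projection
matrix that removes the redundant dimension is produced by
:func:`centering_projection`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import EstimationError, ValidationError
from .io import FrequencyMatrix

logger = logging.getLogger(__name__)


@dataclass
class StandardizedSite:
    """Standardized deviation vector for one site.

    ``usable`` is false when the site is monomorphic across populations
    (``eps`` in {0, 1}), in which case standardization is undefined and the
    site contributes nothing to estimation or likelihood.
    """

    z: np.ndarray
    eps: float
    usable: bool


@dataclass
class CoancestryMatrix:
    """Symmetric k x k coancestry of standardized frequency deviations."""

    F: np.ndarray
    k: int
    n_sites_used: int = 0

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.shape != (self.k, self.k):
            raise ValidationError(f"F has shape {self.F.shape}, expected ({self.k}, {self.k})")
        if not np.isfinite(self.F).all():
            raise ValidationError("F contains non-finite entries")
        if not np.allclose(self.F, self.F.T, atol=1e-12):
            raise ValidationError("F must be symmetric")


def standardize_site(x: np.ndarray) -> StandardizedSite:
    """Standardize one site's frequency vector across populations.

    ``eps = mean(x)``; if ``eps`` is 0 or 1 the site is flagged unusable,
    otherwise ``z = (x - eps) / sqrt(eps (1 - eps))``.
    """
    x = np.asarray(x, dtype=float)
    eps = float(np.mean(x))
    if eps <= 0.0 or eps >= 1.0:
        return StandardizedSite(z=np.full_like(x, np.nan), eps=eps, usable=False)
    z = (x - eps) / np.sqrt(eps * (1.0 - eps))
    return StandardizedSite(z=z, eps=eps, usable=True)


def standardize_matrix(freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized standardization of a (k, L) frequency matrix.

    Returns ``(Z, eps, usable)`` where ``Z`` is (k, L) with NaN columns at
    unusable (monomorphic) sites.
    """
    freqs = np.asarray(freqs, dtype=float)
    eps = freqs.mean(axis=0)
    usable = (eps > 0.0) & (eps < 1.0)
    scale = np.sqrt(np.where(usable, eps * (1.0 - eps), np.nan))
    Z = (freqs - eps) / scale
    return Z, eps, usable


def estimate_neutral_F(
    neutral: FrequencyMatrix, correct_sampling: bool | None = None
) -> CoancestryMatrix:
    """Estimate the neutral coancestry matrix from unlinked neutral sites.

    ``F[i, j]`` is the mean over usable sites of ``z_i z_j``.  Monomorphic
    sites are dropped (their count is logged).

    Because the likelihood adds the binomial term ``diag(1/n)`` on the model
    side, the estimate must describe drift alone: the expected sampling-noise
    contribution — ``x (1 - x) / n`` per population on the standardized
    scale, spread through the mean-centering — is subtracted using the
    unbiased per-site estimate ``x_hat (1 - x_hat) / (n - 1)``.  The
    correction defaults to on whenever every sample size is at least 2
    (``correct_sampling=None``); sample sizes of 1 denote frequencies known
    without sampling error and disable it.
    """
    Z, eps, usable = standardize_matrix(neutral.freqs)
    n_used = int(usable.sum())
    n_dropped = neutral.n_sites - n_used
    if n_dropped:
        logger.info("dropped %d monomorphic neutral site(s) of %d", n_dropped, neutral.n_sites)
    if n_used == 0:
        raise EstimationError("no usable (polymorphic) neutral sites")
    Zu = Z[:, usable]
    F = (Zu @ Zu.T) / n_used
    k = neutral.n_pops
    n = np.asarray(neutral.sample_sizes, dtype=float)
    if correct_sampling is None:
        correct_sampling = bool((n >= 2).all())
    if correct_sampling:
        if (n < 2).any():
            raise EstimationError("sampling correction requires all sample sizes >= 2")
        x = neutral.freqs[:, usable]
        denom = eps[usable] * (1.0 - eps[usable])
        noise = np.mean(x * (1.0 - x) / denom, axis=1) / (n - 1.0)
        P = np.eye(k) - np.full((k, k), 1.0 / k)
        F = F - P @ np.diag(noise) @ P
    F = (F + F.T) / 2.0
    return CoancestryMatrix(F=F, k=k, n_sites_used=n_used)


def centering_projection(k: int) -> np.ndarray:
    """First ``k - 1`` rows of the mean-centering projector ``I - J/k``.

    The returned ``(k-1, k)`` matrix ``C`` annihilates the constant vector and
    restores full rank lost by measuring deviations from the across-population
    mean: likelihoods are evaluated for ``w = C z`` under ``C Sigma C^T``.
    """
    if k < 2:
        raise ValidationError("need at least 2 populations")
    C = np.eye(k) - np.full((k, k), 1.0 / k)
    return C[: k - 1]
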