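"""Sequencing-depth estimation by an iterative Poisson goodness-of-fit scheme.

The depth of sample ``j`` is defined as

    d_hat_j = sum_{i in S} N_ij / sum_{i in S} sum_j N_ij

where ``S`` is the half set of genes least differentially expressed across
samples.  "Least differentially expressed" is measured by a chi-square type
Poisson goodness-of-fit score against the proportionality model
``E[N_ij] = d_hat_j * N_i.``; the scheme alternates between scoring genes at
the current depths and re-estimating depths on the best-fitting half until
the depths stop moving.  By construction ``sum_j d_hat_j = 1``, so the
normalized count ``n_ij = N_ij / d_hat_j`` is on the scale of total counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .counts_io import CountMatrix

logger = logging.getLogger(__name__)

__all__ = ["DepthFactors", "poisson_gof", "estimate_depths", "normalize"]


@dataclass
class DepthFactors:
    """Per-sample sequencing depths and the gene subset used to fit them."""

    d_hat: np.ndarray          # positive, sums to 1
    selected_genes: np.ndarray  # indices of the least-DE half used in the final pass
    n_iter: int = 0
    converged: bool = True


def poisson_gof(counts: np.ndarray, d_hat: np.ndarray) -> np.ndarray:
    """Chi-square goodness-of-fit of each gene to count proportionality.

    GOF_i = sum_j (N_ij - d_hat_j * N_i.)^2 / (d_hat_j * N_i.)  with
    N_i. the gene's total count.  Zero for genes exactly proportional to
    the depths; genes with zero total count must be dropped beforehand.
    """
    counts = np.asarray(counts, dtype=float)
    d_hat = np.asarray(d_hat, dtype=float)
    if np.any(d_hat <= 0):
        raise ValueError("depth factors must be strictly positive")
    row_tot = counts.sum(axis=1)
    if np.any(row_tot == 0):
        raise ValueError("gene with zero total count; drop all-zero genes first")
    expected = row_tot[:, None] * d_hat[None, :]
    return (((counts - expected) ** 2) / expected).sum(axis=1)


def estimate_depths(
    m: CountMatrix | np.ndarray,
    max_iter: int = 10,
    tol: float = 1e-10,
) -> DepthFactors:
    """Estimate per-sample depths on the least-DE half of genes.

    Starts from column-total fractions, then alternates: score every gene
    with :func:`poisson_gof`, keep the ``floor(G/2)`` genes with the
    smallest score (ties broken by input order), and recompute depths from
    that subset.  Stops when ``max_j |delta d_hat_j| < tol``; warns and
    returns the last iterate if ``max_iter`` is exhausted.
    """
    counts = m.counts if isinstance(m, CountMatrix) else np.asarray(m)
    counts = counts.astype(float)
    n_genes, n_samples = counts.shape
    if n_genes < 2 or n_samples < 2:
        raise ValueError("need at least 2 genes and 2 samples to estimate depths")
    if np.any(counts.sum(axis=1) == 0):
        raise ValueError("drop all-zero genes before depth estimation")

    d_hat = counts.sum(axis=0) / counts.sum()
    half = n_genes // 2
    selected = np.arange(n_genes)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        gof = poisson_gof(counts, d_hat)
        # stable argsort keeps input order among tied scores
        selected = np.argsort(gof, kind="stable")[:half]
        sub = counts[selected]
        d_new = sub.sum(axis=0) / sub.sum()
        if np.any(d_new == 0):
            # only possible with very few genes: the least-DE half has no
            # reads in some sample; keep the last strictly positive iterate
            warnings.warn(
                "least-DE gene half has zero counts in a sample; "
                "keeping previous depth estimates",
                RuntimeWarning,
                stacklevel=2,
            )
            converged = True
            break
        delta = np.max(np.abs(d_new - d_hat))
        d_hat = d_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"depth estimation did not converge in {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return DepthFactors(d_hat=d_hat, selected_genes=selected, n_iter=it,
                        converged=converged)


def normalize(m: CountMatrix | np.ndarray, d: DepthFactors | np.ndarray) -> np.ndarray:
    """Normalized counts ``n_ij = N_ij / d_hat_j``."""
    counts = m.counts if isinstance(m, CountMatrix) else np.asarray(m)
    d_hat = d.d_hat if isinstance(d, DepthFactors) else np.asarray(d, dtype=float)
    if np.any(d_hat <= 0):
        raise ValueError("depth factors must be strictly positive")
    return counts / d_hat[None, :]
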