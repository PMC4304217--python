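"""Comparison methods sharing LFCseq's preprocessing.

Two baselines are provided:

* a NOISeq-like test: the joint statistic is the log2 fold change ``L_i``
  plus the absolute difference ``|D_i| = |nbar_iA - nbar_iB|`` of mean
  normalized counts, judged against a single *common* null — the (l, d)
  values of every within-condition sample pair of every gene.  The
  probability of being DE is the fraction of null pairs strictly
  dominated in both coordinates.  This follows the published description
  of the statistic, not the internals of the released NOISeq package.

* SHGT, a simple permutation test: each gene's null is its own ``L``
  statistic recomputed under relabelings of the samples into
  pseudo-conditions of the original sizes, with no borrowing across
  genes.  It isolates the value of the expression-neighborhood pooling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .counts_io import ConditionDesign, CountMatrix, drop_allzero_genes, replace_zeros
from .core import LFCseqConfig, group_means, lfc_statistic
from .normalization import DepthFactors, estimate_depths, normalize

__all__ = [
    "JointNull",
    "abs_difference",
    "build_joint_null",
    "noiseq_prob_DE",
    "shgt_prob",
    "run_noiseq_like",
    "run_shgt",
    "NOISEQ_CUTOFF",
]

NOISEQ_CUTOFF = 0.8  # call DE when P(x=1) > 0.8


@dataclass
class JointNull:
    """Pooled (l, d) pairs from all within-condition sample pairs, all genes."""

    l: np.ndarray
    d: np.ndarray

    @property
    def size(self) -> int:
        return self.l.size


def abs_difference(mean_A, mean_B):
    """Absolute difference of mean normalized counts, |D_i|."""
    return np.abs(np.asarray(mean_A, dtype=float) - np.asarray(mean_B, dtype=float))


def build_joint_null(norm: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> JointNull:
    """(l, d) for every within-condition sample pair and every gene.

    Size is ``G * (C(|A|,2) + C(|B|,2))``.  ``norm`` must be
    zero-replaced so ratios are defined.
    """
    ls, ds = [], []
    for idx in (idx_a, idx_b):
        for j1, j2 in combinations(list(idx), 2):
            a, b = norm[:, j1], norm[:, j2]
            ls.append(np.log2(a / b))
            ds.append(np.abs(a - b))
    return JointNull(l=np.concatenate(ls), d=np.concatenate(ds))


def noiseq_prob_DE(L_i: float, D_i: float, null: JointNull) -> float:
    """Fraction of null pairs with |l| < |L_i| and |d| < |D_i| (both strict)."""
    if null.size == 0:
        raise ValueError("joint null is empty")
    hit = (np.abs(null.l) < abs(L_i)) & (np.abs(null.d) < abs(D_i))
    return float(np.count_nonzero(hit) / null.size)


def _noiseq_prob_all(L: np.ndarray, D: np.ndarray, null: JointNull,
                     chunk: int = 64) -> np.ndarray:
    """Vectorized, chunked version of :func:`noiseq_prob_DE` for all genes."""
    abs_l = np.abs(null.l)
    abs_d = np.abs(null.d)
    abs_L = np.abs(L)
    abs_D = np.abs(D)
    out = np.empty(L.size)
    for s in range(0, L.size, chunk):
        e = min(s + chunk, L.size)
        hit = (abs_l[None, :] < abs_L[s:e, None]) & (abs_d[None, :] < abs_D[s:e, None])
        out[s:e] = np.count_nonzero(hit, axis=1) / null.size
    return out


def _relabelings(n_a: int, n_b: int, max_exhaustive: int = 1000,
                 n_perm: int = 1000, seed: int | None = None) -> list[tuple]:
    """Index sets forming pseudo-condition A; identity labeling first."""
    n = n_a + n_b
    identity = tuple(range(n_a))
    total = math.comb(n, n_a)
    if total <= max_exhaustive:
        labelings = [identity] + [c for c in combinations(range(n), n_a) if c != identity]
        return labelings
    rng = np.random.default_rng(seed)
    seen = {identity}
    labelings = [identity]
    while len(labelings) < n_perm:
        c = tuple(sorted(rng.choice(n, size=n_a, replace=False)))
        if c not in seen:
            seen.add(c)
            labelings.append(c)
    return labelings


def shgt_prob(L_i: float, values: np.ndarray, n_a: int, n_b: int,
              max_exhaustive: int = 1000, n_perm: int = 1000,
              seed: int | None = None) -> float:
    """Permutation non-DE probability for one gene.

    ``values`` are the gene's zero-replaced normalized counts with the
    first ``n_a`` entries from condition A.  The null is the L statistic
    under every (or ``n_perm`` random) relabelings into pseudo-conditions
    of sizes (n_a, n_b); the probability is the fraction of null values
    with ``|l| >= |L_i|``.  The identity relabeling is always included,
    so the probability is at least ``1/#relabelings``.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n != n_a + n_b or n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 samples per pseudo-condition")
    null = []
    for lab in _relabelings(n_a, n_b, max_exhaustive, n_perm, seed):
        in_a = np.zeros(n, dtype=bool)
        in_a[list(lab)] = True
        null.append(np.log2(values[in_a].mean() / values[~in_a].mean()))
    null = np.abs(np.asarray(null))
    return float(np.count_nonzero(null >= abs(L_i)) / null.size)


def _prepare(counts: CountMatrix, design: ConditionDesign, config: LFCseqConfig):
    idx_a, idx_b = design.column_indices(counts.sample_ids)
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("each condition needs at least 2 samples")
    m = drop_allzero_genes(counts)
    if config.normalize:
        depths = estimate_depths(m)
    else:
        depths = DepthFactors(d_hat=np.ones(m.n_samples),
                              selected_genes=np.arange(m.n_genes))
    norm = replace_zeros(normalize(m, depths), m.counts)
    return m, norm, idx_a, idx_b


def run_noiseq_like(
    counts: CountMatrix,
    design: ConditionDesign,
    config: LFCseqConfig | None = None,
    cutoff: float = NOISEQ_CUTOFF,
) -> pd.DataFrame:
    """NOISeq-style common-null test over the shared preprocessing.

    Output schema matches :func:`lfcseq.core.run_lfcseq`; ``prob_nonDE``
    is ``1 - P(x=1)`` and a gene is called DE when ``P(x=1) > cutoff``.
    """
    if config is None:
        config = LFCseqConfig()
    m, norm, idx_a, idx_b = _prepare(counts, design, config)
    mean_a, mean_b, _ = group_means(norm, idx_a, idx_b)
    L = lfc_statistic(mean_a, mean_b)
    D = abs_difference(mean_a, mean_b)
    null = build_joint_null(norm, idx_a, idx_b)
    prob_de = _noiseq_prob_all(L, D, null)
    return pd.DataFrame(
        {
            "gene_id": m.gene_ids,
            "mean_A": mean_a,
            "mean_B": mean_b,
            "log2FC": L,
            "prob_nonDE": 1.0 - prob_de,
            "de_call": (prob_de > cutoff).astype(int),
            "method": "noiseq-like",
        }
    )


def run_shgt(
    counts: CountMatrix,
    design: ConditionDesign,
    config: LFCseqConfig | None = None,
    max_exhaustive: int = 1000,
    n_perm: int = 1000,
) -> pd.DataFrame:
    """Per-gene permutation test; shares preprocessing and output schema."""
    if config is None:
        config = LFCseqConfig()
    m, norm, idx_a, idx_b = _prepare(counts, design, config)
    n_a, n_b = len(idx_a), len(idx_b)
    if n_a + n_b < 4:
        raise ValueError("permutation test needs at least 4 samples in total")
    mean_a, mean_b, _ = group_means(norm, idx_a, idx_b)
    L = lfc_statistic(mean_a, mean_b)

    # relabelings are shared across genes; vectorize the null over genes
    vals = norm[:, np.concatenate([idx_a, idx_b])]
    labelings = _relabelings(n_a, n_b, max_exhaustive, n_perm, config.seed)
    n = n_a + n_b
    null_cols = []
    for lab in labelings:
        in_a = np.zeros(n, dtype=bool)
        in_a[list(lab)] = True
        null_cols.append(np.log2(vals[:, in_a].mean(axis=1) / vals[:, ~in_a].mean(axis=1)))
    null = np.abs(np.column_stack(null_cols))
    prob = np.count_nonzero(null >= np.abs(L)[:, None], axis=1) / null.shape[1]
    return pd.DataFrame(
        {
            "gene_id": m.gene_ids,
            "mean_A": mean_a,
            "mean_B": mean_b,
            "log2FC": L,
            "prob_nonDE": prob,
            "de_call": (prob < config.cutoff).astype(int),
            "method": "shgt",
        }
    )
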