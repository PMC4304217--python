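"""The LFCseq test.

LFCseq scores each gene with the log2 fold change of mean normalized
counts between conditions,

    L_i = log2(nbar_iA / nbar_iB),

and judges how extreme that change is against an empirical, gene-specific
null distribution built without using any between-condition contrast:

1. each condition's samples are split into two near-halves in every
   possible way (all partitions when the condition has at most 7 samples,
   20 random partitions otherwise), and the within-condition log fold
   change ``log2(nbar_iA1 / nbar_iA2)`` is recorded for every split —
   these carry only biological + technical noise, no DE signal;
2. because the spread of such null fold changes shrinks strongly as
   expression grows, the null for gene ``i`` pools the within-condition
   values of only its expression neighborhood ``N(i)`` — the ``k``
   (default 50) genes whose overall mean expression is closest to gene
   ``i``'s;
3. the probability of gene ``i`` being non-DE is the fraction of null
   values strictly exceeding ``|L_i|`` in magnitude.

Genes are called DE when that probability falls below a cutoff
(default 0.1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .counts_io import (
    ConditionDesign,
    CountMatrix,
    drop_allzero_genes,
    replace_zeros,
)
from .normalization import DepthFactors, estimate_depths, normalize

logger = logging.getLogger(__name__)

__all__ = [
    "LFCseqConfig",
    "PartitionSet",
    "Neighborhood",
    "NullPool",
    "lfc_statistic",
    "n_partitions",
    "enumerate_partitions",
    "within_condition_pool",
    "group_means",
    "build_neighborhood",
    "null_distribution",
    "prob_nonDE",
    "null_pool_sd",
    "run_lfcseq",
]


@dataclass
class LFCseqConfig:
    """Tunable parameters of the test.

    k: neighborhood size (genes sharing a null distribution).
    max_exhaustive: largest condition size for which all sample
        partitions are enumerated; above it ``n_random`` seeded random
        partitions are drawn.
    cutoff: DE call threshold on the non-DE probability (strict ``<``).
    normalize: estimate sequencing depths; when False all depths are 1
        and raw counts are used as-is.
    """

    k: int = 50
    max_exhaustive: int = 7
    n_random: int = 20
    cutoff: float = 0.1
    seed: int = 1
    normalize: bool = True


@dataclass
class PartitionSet:
    """Unordered splits of one condition's samples into two near-halves.

    Each partition is a pair of disjoint column-index tuples
    ``(A1, A2)`` with ``|A1| = floor(n/2)``.  ``(A1, A2)`` and
    ``(A2, A1)`` count once; for even ``n`` the half containing the
    first sample (input order) is A1.
    """

    partitions: list
    mode: str            # "exhaustive" | "random"
    seed: int | None = None


@dataclass
class Neighborhood:
    """Per-gene expression neighborhoods.

    ``members[i]`` holds the indices of the ``k`` genes (including ``i``)
    with overall mean expression closest to gene ``i``'s;
    ``epsilon[i]`` is the realized half-width, i.e. the largest absolute
    mean difference within ``members[i]``.
    """

    members: np.ndarray  # (G, k) int
    k: int
    epsilon: np.ndarray  # (G,) float


@dataclass
class NullPool:
    """Within-condition log fold change pools for every gene.

    ``pool_A[i, :]`` are the values ``log2(nbar_iA1 / nbar_iA2)`` over the
    partitions of condition A; likewise ``pool_B``.
    """

    pool_A: np.ndarray  # (G, #partitions of A)
    pool_B: np.ndarray  # (G, #partitions of B)

    @property
    def pooled(self) -> np.ndarray:
        return np.concatenate([self.pool_A, self.pool_B], axis=1)


def lfc_statistic(mean_A, mean_B):
    """Log2 fold change of mean normalized counts; both means must be > 0."""
    mean_A = np.asarray(mean_A, dtype=float)
    mean_B = np.asarray(mean_B, dtype=float)
    if np.any(mean_A <= 0) or np.any(mean_B <= 0):
        raise ValueError("group means must be positive (apply zero replacement first)")
    return np.log2(mean_A / mean_B)


def n_partitions(n: int) -> int:
    """Number of unordered near-half partitions of ``n`` samples."""
    if n < 2:
        raise ValueError("need at least 2 samples")
    h = n // 2
    c = math.comb(n, h)
    return c // 2 if n % 2 == 0 else c


def enumerate_partitions(
    samples,
    max_exhaustive: int = 7,
    n_random: int = 20,
    seed: int | None = None,
) -> PartitionSet:
    """All (or 20 random) unordered near-half splits of a condition's samples.

    ``samples`` is an ordered collection of column indices.  Exhaustive
    enumeration is used up to ``max_exhaustive`` samples; beyond that,
    ``n_random`` distinct partitions are drawn uniformly (without
    replacement among partitions), reproducibly from ``seed``.
    """
    samples = list(samples)
    n = len(samples)
    if n < 2:
        raise ValueError("a condition needs at least 2 samples to be partitioned")
    half = n // 2

    def canonical(comb: tuple) -> tuple:
        a1 = set(comb)
        a2 = tuple(s for s in samples if s not in a1)
        return tuple(comb), a2

    if n <= max_exhaustive:
        parts = []
        if n % 2 == 0:
            # unordered: fix the first sample in A1
            first, rest = samples[0], samples[1:]
            for comb in combinations(rest, half - 1):
                parts.append(canonical((first, *comb)))
        else:
            # |A1| = floor(n/2) != |A2|, so every combination is distinct
            for comb in combinations(samples, half):
                parts.append(canonical(comb))
        return PartitionSet(parts, mode="exhaustive", seed=seed)

    total = n_partitions(n)
    n_random = min(n_random, total)
    rng = np.random.default_rng(seed)
    seen: set = set()
    parts = []
    while len(parts) < n_random:
        comb = tuple(sorted(rng.choice(n, size=half, replace=False)))
        a1 = tuple(samples[t] for t in comb)
        if n % 2 == 0 and samples[0] not in a1:
            a1 = tuple(s for s in samples if s not in set(a1))
        if a1 in seen:
            continue
        seen.add(a1)
        parts.append((a1, tuple(s for s in samples if s not in set(a1))))
    return PartitionSet(parts, mode="random", seed=seed)


def within_condition_pool(norm: np.ndarray, pset: PartitionSet) -> np.ndarray:
    """Per-gene pool of within-condition log fold changes.

    For each partition ``(A1, A2)`` returns ``log2(mean over A1 / mean
    over A2)`` per gene; shape (G, #partitions).  ``norm`` must already
    have zeros replaced, so all means are positive.
    """
    norm = np.asarray(norm, dtype=float)
    cols = []
    for a1, a2 in pset.partitions:
        m1 = norm[:, list(a1)].mean(axis=1)
        m2 = norm[:, list(a2)].mean(axis=1)
        cols.append(np.log2(m1 / m2))
    return np.column_stack(cols)


def group_means(norm: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray):
    """Per-gene mean normalized counts for A, B and the pooled samples."""
    mean_a = norm[:, idx_a].mean(axis=1)
    mean_b = norm[:, idx_b].mean(axis=1)
    n_a, n_b = len(idx_a), len(idx_b)
    mean_ab = (n_a * mean_a + n_b * mean_b) / (n_a + n_b)
    return mean_a, mean_b, mean_ab


def build_neighborhood(mean_ab, k: int = 50) -> Neighborhood:
    """For each gene, the ``k`` genes with closest overall mean expression.

    Selection is by smallest ``|mean_i' - mean_i|`` with ties broken by
    gene input order; gene ``i`` is always a member.  ``k`` larger than
    the gene count degrades to all genes (with a warning).
    """
    means = np.asarray(mean_ab, dtype=float)
    g = means.size
    if k < 1:
        raise ValueError("neighborhood size k must be >= 1")
    if k > g:
        logger.warning("k=%d exceeds gene count %d; using all genes", k, g)
        k = g
    if k == g:
        members = np.tile(np.arange(g), (g, 1))
        eps = np.abs(means[None, :] - means[:, None]).max(axis=1) if g <= 2000 else \
            np.maximum(means.max() - means, means - means.min())
        return Neighborhood(members=members, k=k, epsilon=eps)

    order = np.argsort(means, kind="stable")
    v = means[order]
    members = np.empty((g, k), dtype=np.intp)
    eps = np.empty(g)
    pos_of = np.empty(g, dtype=np.intp)
    pos_of[order] = np.arange(g)

    for gene in range(g):
        p = pos_of[gene]
        # best contiguous k-window containing p: its max distance equals the
        # k-th smallest distance to gene `gene`
        s_lo = max(0, p - k + 1)
        s_hi = min(p, g - k)
        ss = np.arange(s_lo, s_hi + 1)
        costs = np.maximum(v[p] - v[ss], v[ss + k - 1] - v[p])
        thr = costs.min()
        # expand to the full contiguous run with distance <= thr (ties)
        lo = s_lo
        while lo > 0 and v[p] - v[lo - 1] <= thr:
            lo -= 1
        hi = s_hi + k - 1
        while hi < g - 1 and v[hi + 1] - v[p] <= thr:
            hi += 1
        cand = order[lo:hi + 1]
        d = np.abs(means[cand] - means[gene])
        # gene itself always in; remaining k-1 by (distance, input order)
        keep = cand != gene
        cand_o, d_o = cand[keep], d[keep]
        sel = np.lexsort((cand_o, d_o))[:k - 1]
        mem = np.concatenate(([gene], cand_o[sel]))
        members[gene] = np.sort(mem)
        eps[gene] = np.abs(means[mem] - means[gene]).max()
    return Neighborhood(members=members, k=k, epsilon=eps)


def null_distribution(i: int, pools: NullPool, nb: Neighborhood) -> np.ndarray:
    """Gene ``i``'s null: the multiset union of its neighbors' pools."""
    return pools.pooled[nb.members[i]].ravel()


def prob_nonDE(L_i: float, null: np.ndarray) -> float:
    """Fraction of null values strictly larger than ``|L_i|`` in magnitude."""
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    return float(np.count_nonzero(np.abs(null) > abs(L_i)) / null.size)


def _prob_nonDE_all(L: np.ndarray, pools: NullPool, nb: Neighborhood) -> np.ndarray:
    abs_pool = np.abs(pools.pooled)
    abs_L = np.abs(L)
    g = L.size
    out = np.empty(g)
    for i in range(g):
        vals = abs_pool[nb.members[i]]
        out[i] = np.count_nonzero(vals > abs_L[i]) / vals.size
    return out


def null_pool_sd(pools: NullPool, nb: Neighborhood) -> np.ndarray:
    """Sample standard deviation (ddof=1) of each gene's null distribution.

    Diagnostic for how null spread varies with expression: plotted against
    overall mean expression it should fall as expression grows, the
    motivation for gene-specific nulls.
    """
    pooled = pools.pooled
    g = pooled.shape[0]
    out = np.empty(g)
    for i in range(g):
        out[i] = pooled[nb.members[i]].ravel().std(ddof=1)
    return out


def run_lfcseq(
    counts: CountMatrix,
    design: ConditionDesign,
    config: LFCseqConfig | None = None,
) -> pd.DataFrame:
    """Full LFCseq pipeline on a raw count matrix.

    Drops all-zero genes, estimates sequencing depths, normalizes,
    replaces zeros by 0.5, computes the per-gene statistic ``L_i``, builds
    within-condition partition pools and expression neighborhoods, and
    returns a per-gene table with columns gene_id, mean_A, mean_B, log2FC,
    prob_nonDE, de_call.  Deterministic for a fixed ``config.seed``.
    """
    if config is None:
        config = LFCseqConfig()
    idx_a, idx_b = design.column_indices(counts.sample_ids)
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("each condition needs at least 2 samples")

    m = drop_allzero_genes(counts)
    if config.normalize:
        depths = estimate_depths(m)
        logger.info("depth factors: %s", np.array2string(depths.d_hat, precision=4))
    else:
        depths = DepthFactors(
            d_hat=np.ones(m.n_samples), selected_genes=np.arange(m.n_genes)
        )
    norm = replace_zeros(normalize(m, depths), m.counts)

    mean_a, mean_b, mean_ab = group_means(norm, idx_a, idx_b)
    L = lfc_statistic(mean_a, mean_b)

    ss = np.random.SeedSequence(config.seed)
    seed_a, seed_b = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    parts_a = enumerate_partitions(idx_a, config.max_exhaustive, config.n_random, seed_a)
    parts_b = enumerate_partitions(idx_b, config.max_exhaustive, config.n_random, seed_b)
    logger.info(
        "partitions: A %s (%d), B %s (%d)",
        parts_a.mode, len(parts_a.partitions), parts_b.mode, len(parts_b.partitions),
    )
    pools = NullPool(
        pool_A=within_condition_pool(norm, parts_a),
        pool_B=within_condition_pool(norm, parts_b),
    )
    nb = build_neighborhood(mean_ab, config.k)
    prob = _prob_nonDE_all(L, pools, nb)

    return pd.DataFrame(
        {
            "gene_id": m.gene_ids,
            "mean_A": mean_a,
            "mean_B": mean_b,
            "log2FC": L,
            "prob_nonDE": prob,
            "de_call": (prob < config.cutoff).astype(int),
        }
    )
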