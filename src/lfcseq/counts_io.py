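"""Reading and writing count matrices, design tables and result tables.

The on-disk formats are plain TSV:

* counts: header ``gene_id<TAB>sample1<TAB>...``, one gene per row,
  non-negative integer read counts;
* design: header ``sample_id<TAB>condition`` with exactly two distinct
  condition labels;
* results: one row per gene with group means, log2 fold change, the
  estimated probability of being non-differentially expressed and the
  binary DE call.

Zero handling follows the convention of offsetting expression values:
genes with zero counts in every sample are removed before any analysis,
and remaining zero counts are replaced by 0.5 *after* normalization so
that log ratios are always defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "ConditionDesign",
    "read_counts",
    "read_design",
    "drop_allzero_genes",
    "replace_zeros",
    "write_results",
    "read_results",
]

RESULT_COLUMNS = ["gene_id", "mean_A", "mean_B", "log2FC", "prob_nonDE", "de_call"]


@dataclass
class CountMatrix:
    """A genes x samples matrix of non-negative read counts.

    ``counts[i, j]`` is the number of reads mapped to gene ``gene_ids[i]``
    in sample ``sample_ids[j]``.
    """

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if self.counts.shape != (self.gene_ids.size, self.sample_ids.size):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{self.gene_ids.size} genes x {self.sample_ids.size} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            seen: set = set()
            for x in ids:
                if x in seen:
                    raise ValueError(f"duplicate {name} ID: {x!r}")
                seen.add(x)
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.gene_ids.size

    @property
    def n_samples(self) -> int:
        return self.sample_ids.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=list(self.sample_ids),
        )


@dataclass
class ConditionDesign:
    """Assignment of samples to the two conditions A and B."""

    assignment: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = set(self.assignment.values())
        if len(labels) != 2:
            raise ValueError(
                f"design must have exactly 2 condition labels, got {sorted(map(str, labels))}"
            )
        # canonical label order: sorted, so (A, B) for the conventional naming
        self.labels = tuple(sorted(labels))
        for lab in self.labels:
            if not any(v == lab for v in self.assignment.values()):
                raise ValueError(f"condition {lab!r} has no samples")

    def samples(self, label) -> list:
        return [s for s, lab in self.assignment.items() if lab == label]

    def column_indices(self, sample_ids) -> tuple[np.ndarray, np.ndarray]:
        """Column index arrays (condition A, condition B) into ``sample_ids``.

        Raises if the design and the matrix do not cover the same samples.
        """
        sample_ids = list(sample_ids)
        missing = [s for s in sample_ids if s not in self.assignment]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        extra = [s for s in self.assignment if s not in sample_ids]
        if extra:
            raise ValueError(f"design samples not in count matrix: {extra}")
        a_lab, b_lab = self.labels
        idx_a = np.array(
            [j for j, s in enumerate(sample_ids) if self.assignment[s] == a_lab],
            dtype=np.intp,
        )
        idx_b = np.array(
            [j for j, s in enumerate(sample_ids) if self.assignment[s] == b_lab],
            dtype=np.intp,
        )
        return idx_a, idx_b


def read_counts(path) -> CountMatrix:
    """Read a gene x sample count matrix from TSV.

    First row holds sample IDs, first column gene IDs, body is numeric and
    non-negative.  Malformed rows, non-numeric or negative cells and
    duplicate identifiers raise ``ValueError`` naming the offending
    row/column.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError("count matrix needs at least one sample column")
        sample_ids = header[1:]
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"row {lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            gene_ids.append(fields[0])
            vals = []
            for col, tok in enumerate(fields[1:], start=2):
                try:
                    v = float(tok)
                except ValueError:
                    raise ValueError(
                        f"row {lineno}, column {col}: non-numeric count {tok!r}"
                    ) from None
                if v < 0:
                    raise ValueError(f"row {lineno}, column {col}: negative count {tok}")
                vals.append(v)
            rows.append(vals)
    if not rows:
        raise ValueError("count matrix has no gene rows")
    counts = np.asarray(rows)
    if np.allclose(counts, np.round(counts)):
        counts = counts.astype(np.int64)
    return CountMatrix(np.array(gene_ids, dtype=object),
                       np.array(sample_ids, dtype=object), counts)


def read_design(path) -> ConditionDesign:
    """Read a two-column ``sample_id<TAB>condition`` table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("design table needs columns sample_id and condition")
    sample_col, cond_col = df.columns[0], df.columns[1]
    if df[sample_col].duplicated().any():
        dup = df[sample_col][df[sample_col].duplicated()].iloc[0]
        raise ValueError(f"duplicate sample in design: {dup!r}")
    assignment = dict(zip(df[sample_col], df[cond_col]))
    return ConditionDesign(assignment)


def drop_allzero_genes(m: CountMatrix) -> CountMatrix:
    """Remove genes with zero read counts in all samples.

    Keeps input order; logs the removed gene IDs.  Raises if no gene has a
    positive count.
    """
    keep = m.counts.sum(axis=1) > 0
    if not keep.any():
        raise ValueError("all genes have zero counts in every sample")
    n_removed = int((~keep).sum())
    if n_removed:
        removed = list(m.gene_ids[~keep])
        logger.info("removed %d all-zero gene(s): %s", n_removed, removed)
    return CountMatrix(m.gene_ids[keep], m.sample_ids, m.counts[keep])


def replace_zeros(normalized: np.ndarray, raw_counts: np.ndarray) -> np.ndarray:
    """Replace cells whose *raw* count was zero by 0.5 in the normalized matrix.

    All other cells are returned unchanged.  Operating on the normalized
    matrix keeps depth estimation on untouched raw counts.
    """
    normalized = np.asarray(normalized, dtype=float)
    raw_counts = np.asarray(raw_counts)
    if normalized.shape != raw_counts.shape:
        raise ValueError("normalized and raw matrices must have the same shape")
    out = normalized.copy()
    out[raw_counts == 0] = 0.5
    return out


def write_results(results: pd.DataFrame, path) -> None:
    """Write a per-gene DE result table as TSV, floats at 6 significant digits."""
    cols = [c for c in RESULT_COLUMNS if c in results.columns]
    cols += [c for c in results.columns if c not in cols]
    out = results[cols].copy()
    out["de_call"] = out["de_call"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
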