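import numpy as np
import pytest

from lfcseq.counts_io import ConditionDesign, CountMatrix


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """4 genes x 4 samples with one all-zero gene and scattered zeros."""
    counts = np.array(
        [
            [10, 12, 9, 11],
            [0, 0, 0, 0],
            [100, 80, 0, 120],
            [3, 0, 5, 2],
        ]
    )
    return CountMatrix(
        gene_ids=np.array(["g1", "g2", "g3", "g4"], dtype=object),
        sample_ids=np.array(["s1", "s2", "s3", "s4"], dtype=object),
        counts=counts,
    )


@pytest.fixture
def tiny_design() -> ConditionDesign:
    return ConditionDesign({"s1": "A", "s2": "A", "s3": "B", "s4": "B"})


def write_counts_tsv(path, gene_ids, sample_ids, counts):
    lines = ["gene_id\t" + "\t".join(sample_ids)]
    for g, row in zip(gene_ids, counts):
        lines.append(g + "\t" + "\t".join(str(x) for x in row))
    path.write_text("\n".join(lines) + "\n")
    return path
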