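import numpy as np
import pandas as pd
import pytest

from toxconcord.matrix import ExpressionMatrix


def build_matrix(values_by_group: dict[str, np.ndarray], probe_ids=None,
                 cell_line: str = "Man12") -> ExpressionMatrix:
    """Assemble an ExpressionMatrix from per-treatment value blocks.

    ``values_by_group`` maps treatment label -> (n_probes, n_replicates)
    array of log2 intensities.
    """
    values_by_group = {
        t: np.atleast_2d(np.asarray(b, dtype=float))
        for t, b in values_by_group.items()
    }
    blocks, columns, rows = [], [], []
    n_probes = next(iter(values_by_group.values())).shape[0]
    for treatment, block in values_by_group.items():
        blocks.append(block)
        for rep in range(1, block.shape[1] + 1):
            columns.append(f"{treatment}_r{rep}")
            rows.append((cell_line, treatment, rep))
    if probe_ids is None:
        probe_ids = [f"P{i:04d}" for i in range(n_probes)]
    values = pd.DataFrame(np.hstack(blocks), index=pd.Index(probe_ids, name="probe_id"),
                          columns=columns)
    samples = pd.DataFrame(rows, index=pd.Index(columns, name="sample_id"),
                           columns=["cell_line", "treatment", "replicate"])
    return ExpressionMatrix(values, samples)


@pytest.fixture
def two_group_matrix():
    """One probe, 3 replicates per group: control {1,2,3}, treated {4,5,6}."""
    return build_matrix({
        "control": np.array([[1.0, 2.0, 3.0]]),
        "BPA": np.array([[4.0, 5.0, 6.0]]),
    })


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
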