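"""Top-variance probe selection and sample-space PCA.

PCA is run on the log2 matrix restricted to the k probes with highest
across-sample variance (default 1000), per-probe mean-centered but not
scaled to unit variance -- the convention for expression data, where
down-weighting high-variance probes would defeat the purpose of selecting
them.  Percent variance explained is sigma_i^2 / sum(sigma_j^2) * 100 over
all singular values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # samples x components
    percent_variance: np.ndarray  # non-increasing, sums to <= 100
    probes: pd.Index  # the analyzed (top-variance) probe subset


def select_top_variance(matrix: ExpressionMatrix, k: int) -> pd.Index:
    """The k probes with largest sample variance across all samples.

    Ties are broken deterministically by probe order in the matrix.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > matrix.n_probes:
        raise ValueError(f"k={k} exceeds the {matrix.n_probes} probes available")
    variances = matrix.values.var(axis=1, ddof=1)
    # stable sort keeps matrix order among equal variances
    order = variances.sort_values(ascending=False, kind="stable").index
    return order[:k]


def pca(matrix: ExpressionMatrix) -> PcaResult:
    """Mean-centered PCA of samples over the matrix's probes."""
    if matrix.values.shape[1] < 2:
        raise ValueError("PCA requires at least 2 samples")
    x = matrix.values.to_numpy().T  # samples x probes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    total = (s**2).sum()
    pct = (s**2) / total * 100.0 if total > 0 else np.zeros_like(s)
    coords = pd.DataFrame(
        u * s,
        index=matrix.sample_ids,
        columns=[f"PC{i + 1}" for i in range(len(s))],
    )
    return PcaResult(
        coordinates=coords, percent_variance=pct, probes=matrix.probe_ids
    )
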