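"""Per-probe differential expression for compound-vs-control contrasts.

For each contrast the module computes log2 fold changes (difference of group
means on the log2 scale), a pooled-variance two-sample t test, the
Benjamini-Hochberg step-up FDR adjustment, and the three-way call:

* ``up``   -- linear fold change strictly > ``fc_threshold`` (default 1.5)
  and adjusted p strictly < ``alpha`` (default 0.05),
* ``down`` -- linear fold change strictly < ``1/fc_threshold`` and adjusted
  p strictly < ``alpha``,
* ``ns``   -- otherwise.

The test is a plain pooled-variance t rather than a moderated variant: the
downstream overlap and concordance statistics are agnostic to the upstream
test, and the function signature keeps the test pluggable.  The analysis
unit is the probe; no probe-to-gene collapsing is performed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

DE_COLUMNS = ("log2fc", "t_stat", "p_raw", "p_adj", "call")


def _group_arrays(
    matrix: ExpressionMatrix, treatment: str, control: str
) -> tuple[np.ndarray, np.ndarray]:
    treated = matrix.values[matrix.samples_for(treatment)].to_numpy()
    ctrl = matrix.values[matrix.samples_for(control)].to_numpy()
    return treated, ctrl


def log2_fold_changes(
    matrix: ExpressionMatrix, treatment: str, control: str
) -> pd.Series:
    """log2FC = mean(log2 treated) - mean(log2 control), per probe."""
    treated, ctrl = _group_arrays(matrix, treatment, control)
    fc = treated.mean(axis=1) - ctrl.mean(axis=1)
    return pd.Series(fc, index=matrix.probe_ids, name="log2fc")


def two_sample_test(
    matrix: ExpressionMatrix, treatment: str, control: str
) -> pd.DataFrame:
    """Pooled-variance two-sample t statistic and two-sided p per probe.

    Degrees of freedom are ``n_t + n_c - 2``.  Degenerate probes with zero
    pooled variance are assigned p = 1 when the group means are equal and
    p = 0 (t = +/-inf) when they differ.
    """
    treated, ctrl = _group_arrays(matrix, treatment, control)
    if treated.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError(
            "two_sample_test requires at least 2 replicates per group "
            f"(got {treated.shape[1]} treated, {ctrl.shape[1]} control)"
        )
    # zero-variance probes make scipy warn; their t/p are overwritten below
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, p_raw = stats.ttest_ind(treated, ctrl, axis=1, equal_var=True)
    diff = treated.mean(axis=1) - ctrl.mean(axis=1)
    degenerate = ~np.isfinite(t_stat)
    if degenerate.any():
        zero_diff = degenerate & (diff == 0.0)
        t_stat = np.where(zero_diff, 0.0, t_stat)
        p_raw = np.where(zero_diff, 1.0, p_raw)
        nonzero = degenerate & (diff != 0.0)
        with np.errstate(invalid="ignore"):
            t_stat = np.where(nonzero, np.sign(diff) * np.inf, t_stat)
        p_raw = np.where(nonzero, 0.0, p_raw)
    return pd.DataFrame(
        {"t_stat": t_stat, "p_raw": p_raw}, index=matrix.probe_ids
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sorted p-values are multiplied by m/rank, made monotone by a cumulative
    minimum from the largest rank, and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-d vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        bad = p[~((p >= 0) & (p <= 1))][:1]
        raise ValueError(f"p-values must lie in [0, 1]; got {bad}")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    de: pd.DataFrame, fc_threshold: float = 1.5, alpha: float = 0.05
) -> pd.DataFrame:
    """Attach up/down/ns calls to a table with ``log2fc`` and ``p_adj``.

    Both gates are strict: up iff 2^log2fc > fc_threshold and p_adj < alpha;
    down iff 2^log2fc < 1/fc_threshold and p_adj < alpha.
    """
    if fc_threshold <= 1.0:
        raise ValueError("fc_threshold must be a linear fold change > 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    log2_thr = np.log2(fc_threshold)
    sig = de["p_adj"] < alpha
    call = np.where(
        sig & (de["log2fc"] > log2_thr),
        "up",
        np.where(sig & (de["log2fc"] < -log2_thr), "down", "ns"),
    )
    out = de.copy()
    out["call"] = call
    return out


def de_table(
    matrix: ExpressionMatrix,
    treatment: str,
    control: str,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full contrast: log2fc, t, raw and BH-adjusted p, and the call."""
    de = pd.DataFrame({"log2fc": log2_fold_changes(matrix, treatment, control)})
    de[["t_stat", "p_raw"]] = two_sample_test(matrix, treatment, control)
    de["p_adj"] = bh_adjust(de["p_raw"].to_numpy())
    return call_de(de, fc_threshold=fc_threshold, alpha=alpha)


def write_de_table(de: pd.DataFrame, path) -> None:
    out = de.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def read_de_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def called_sets(de: pd.DataFrame) -> dict[str, set[str]]:
    """Probe-ID sets for the up and down calls of one contrast."""
    return {
        "up": set(de.index[de["call"] == "up"]),
        "down": set(de.index[de["call"] == "down"]),
    }
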