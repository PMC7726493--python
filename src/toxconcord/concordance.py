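"""Concordance of compound-induced fold-change profiles.

Similarity between compounds is quantified by the Spearman rank correlation
of per-probe log2 fold-change vectors computed against a common control.
Profiles are compared over the full shared probe universe (not only the
called DE probes), matching the genome-wide fold-change scatter that the
statistic is meant to summarize; callers may pass any probe subset.

P-values come from the large-sample t approximation with n-2 degrees of
freedom; formatted output floors tiny values at "< 2.2e-16".
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

P_FLOOR = 2.2e-16


class ProfileMismatchError(ValueError):
    """Raised when fold-change profiles do not share a probe universe."""


class UndefinedCorrelationError(ValueError):
    """Raised when a ranked vector has zero variance."""


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Returns (R, two-sided p).  Raises when either input, after ranking,
    is constant (the correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ProfileMismatchError(
            f"profiles must be 1-d and equal length, got {x.shape} vs {y.shape}"
        )
    if x.size < 3:
        raise ProfileMismatchError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined: an input vector is constant"
        )
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def format_p(p: float) -> str:
    """Human-readable p with the conventional 2.2e-16 floor."""
    return "< 2.2e-16" if p < P_FLOOR else f"{p:.3g}"


def _check_universe(profiles: Mapping[str, pd.Series]) -> pd.Index:
    names = list(profiles)
    if len(names) < 2:
        raise ProfileMismatchError("need at least two profiles")
    base = profiles[names[0]].index
    for name in names[1:]:
        other = profiles[name].index
        if len(other) != len(base) or not (other == base).all():
            diff = set(base).symmetric_difference(set(other))
            raise ProfileMismatchError(
                f"profiles {names[0]!r} and {name!r} disagree on "
                f"{len(diff)} probes, e.g. {sorted(diff)[:5]}"
            )
    return base


def pairwise_concordance(
    profiles: Mapping[str, pd.Series],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All pairwise Spearman correlations among named log2FC profiles.

    Returns (R matrix, p matrix); both are symmetric with unit diagonal /
    zero diagonal respectively.
    """
    _check_universe(profiles)
    names = list(profiles)
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    p = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    for a, b in combinations(names, 2):
        rho, pval = spearman(profiles[a].to_numpy(), profiles[b].to_numpy())
        r.loc[a, b] = r.loc[b, a] = rho
        p.loc[a, b] = p.loc[b, a] = pval
    return r, p
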