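"""Gene-set overlap ratios over a finite universe.

The overlap ratio compares the observed intersection of k deregulated gene
sets with the intersection size expected if each set had been drawn
randomly, without replacement, and independently of the others from the N
identifiers of the array:

* two sets:    E = n1*n2/N,        ratio = O*N/(n1*n2)
* three sets:  E = n1*n2*n3/N^2,   ratio = O*N^2/(n1*n2*n3)

In both cases ratio = O/E; a value of 1.0 means the overlap is exactly as
large as expected by chance under independence, and larger values indicate
overrepresentation.  A Monte-Carlo sampler of the independence null is
provided as a validation oracle, together with a three-set Venn partition.

The universe N is taken to be the number of probe identifiers on the
supplied matrix (all probes by default; an expressed-subset universe can be
supplied instead by the caller).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class OverlapInputError(ValueError):
    """Raised for inconsistent set sizes (O > min n_i, n_i > N, ...)."""


class UndefinedRatioError(ValueError):
    """Raised when a set size is 0 and the ratio is undefined."""


@dataclass(frozen=True)
class OverlapSummary:
    """Observed vs expected intersection of k gene sets."""

    k: int
    set_sizes: tuple[int, ...]
    observed: int
    universe_size: int
    expected: float
    ratio: float

    def as_row(self) -> dict:
        row = {f"n{i + 1}": n for i, n in enumerate(self.set_sizes)}
        row.update(
            k=self.k,
            N=self.universe_size,
            observed=self.observed,
            expected=self.expected,
            overlap_ratio=self.ratio,
        )
        return row


def _validate(sizes: Sequence[int], observed: int, universe: int) -> None:
    if universe <= 0:
        raise OverlapInputError("universe size N must be positive")
    for i, n in enumerate(sizes, start=1):
        if n < 0 or n > universe:
            raise OverlapInputError(f"set size n{i}={n} outside [0, N={universe}]")
    if any(n == 0 for n in sizes):
        raise UndefinedRatioError(
            "overlap ratio is undefined when a set is empty (n_i = 0)"
        )
    if observed < 0 or observed > min(sizes):
        raise OverlapInputError(
            f"observed overlap O={observed} exceeds the smallest set "
            f"(min n_i = {min(sizes)})"
        )


def overlap_ratio_pairwise(
    n1: int, n2: int, observed: int, universe_size: int
) -> OverlapSummary:
    """Overlap ratio O*N/(n1*n2) for two sets over a universe of size N."""
    _validate((n1, n2), observed, universe_size)
    expected = n1 * n2 / universe_size
    return OverlapSummary(
        k=2,
        set_sizes=(n1, n2),
        observed=observed,
        universe_size=universe_size,
        expected=expected,
        ratio=observed / expected,
    )


def overlap_ratio_threeway(
    n1: int, n2: int, n3: int, observed: int, universe_size: int
) -> OverlapSummary:
    """Overlap ratio O*N^2/(n1*n2*n3) for three sets."""
    _validate((n1, n2, n3), observed, universe_size)
    expected = n1 * n2 * n3 / universe_size**2
    return OverlapSummary(
        k=3,
        set_sizes=(n1, n2, n3),
        observed=observed,
        universe_size=universe_size,
        expected=expected,
        ratio=observed / expected,
    )


def ratio_from_observed_expected(observed: float, expected: float) -> float:
    """Observed intersection size divided by the expected size."""
    if expected <= 0:
        raise UndefinedRatioError(f"expected count must be > 0, got {expected}")
    if observed < 0:
        raise OverlapInputError("observed count must be >= 0")
    return observed / expected


@dataclass
class GeneSetCollection:
    """Named probe-ID sets over an explicit universe."""

    universe: frozenset
    sets: dict[str, frozenset]

    def __init__(self, universe, sets: Mapping) -> None:
        self.universe = frozenset(universe)
        self.sets = {name: frozenset(members) for name, members in sets.items()}
        for name, members in self.sets.items():
            stray = members - self.universe
            if stray:
                raise OverlapInputError(
                    f"set {name!r} contains members outside the universe, "
                    f"e.g. {sorted(stray)[:3]}"
                )

    @property
    def universe_size(self) -> int:
        return len(self.universe)

    def summary(self) -> OverlapSummary:
        """Overlap ratio of all sets in the collection (k = 2 or 3)."""
        names = list(self.sets)
        sizes = [len(self.sets[n]) for n in names]
        observed = len(frozenset.intersection(*self.sets.values()))
        if len(names) == 2:
            return overlap_ratio_pairwise(*sizes, observed, self.universe_size)
        if len(names) == 3:
            return overlap_ratio_threeway(*sizes, observed, self.universe_size)
        raise OverlapInputError("summary supports exactly 2 or 3 sets")


VENN_REGIONS = (
    "A_only",
    "B_only",
    "C_only",
    "AB_only",
    "AC_only",
    "BC_only",
    "ABC",
    "outside",
)


def venn_partition(collection: GeneSetCollection) -> dict[str, int]:
    """Counts of the 7 Venn regions of three sets, plus the outside region.

    Region counts sum to the universe size; pairwise and triple overlaps are
    recoverable by summation (e.g. |A∩B| = AB_only + ABC).
    """
    if len(collection.sets) != 3:
        raise OverlapInputError("venn_partition requires exactly three sets")
    a, b, c = collection.sets.values()
    abc = a & b & c
    counts = {
        "A_only": len(a - b - c),
        "B_only": len(b - a - c),
        "C_only": len(c - a - b),
        "AB_only": len((a & b) - abc),
        "AC_only": len((a & c) - abc),
        "BC_only": len((b & c) - abc),
        "ABC": len(abc),
        "outside": len(collection.universe - a - b - c),
    }
    return counts


@dataclass(frozen=True)
class MonteCarloNull:
    """Empirical null distribution of the overlap under independence.

    ``exceedance`` is a Monte-Carlo estimate of P(O >= O_obs) under the
    independence null, with the +1 correction; it is an extension beyond
    the analytic overlap ratio and is labelled as such in pipeline output.
    """

    overlaps: np.ndarray
    mean: float
    exceedance: float | None

    @property
    def reps(self) -> int:
        return len(self.overlaps)


def monte_carlo_null(
    n1: int,
    n2: int,
    universe_size: int,
    n3: int | None = None,
    reps: int = 10_000,
    seed: int = 0,
    observed: int | None = None,
    chunk: int = 20_000,
) -> MonteCarloNull:
    """Sample the independence null of the k-set overlap.

    Each replicate draws the k sets uniformly without replacement and
    independently of each other, and counts the intersection.  The
    empirical mean converges to the analytic expectation
    n1*...*nk / N^(k-1).
    """
    sizes = (n1, n2) if n3 is None else (n1, n2, n3)
    _validate(sizes, 0, universe_size)
    if reps < 1:
        raise OverlapInputError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    overlaps = np.empty(reps, dtype=np.int64)
    done = 0
    while done < reps:
        batch = min(chunk, reps - done)
        member = np.ones((batch, universe_size), dtype=bool)
        for size in sizes:
            # rank the uniform draws; the `size` smallest form the set
            u = rng.random((batch, universe_size))
            kth = np.argpartition(u, size - 1, axis=1)[:, :size]
            m = np.zeros((batch, universe_size), dtype=bool)
            np.put_along_axis(m, kth, True, axis=1)
            member &= m
        overlaps[done : done + batch] = member.sum(axis=1)
        done += batch
    exceedance = None
    if observed is not None:
        exceedance = (np.count_nonzero(overlaps >= observed) + 1) / (reps + 1)
    return MonteCarloNull(
        overlaps=overlaps, mean=float(overlaps.mean()), exceedance=exceedance
    )


def summaries_to_frame(summaries: Mapping[str, OverlapSummary]) -> pd.DataFrame:
    """Tabulate overlap summaries (one row per named comparison)."""
    rows = {name: s.as_row() for name, s in summaries.items()}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "comparison"
    return frame
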