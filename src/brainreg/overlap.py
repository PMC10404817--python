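"""Gene-set overlap enrichment: exact hypergeometric tests with BH control.

The enrichment p-value for an observed overlap k between sets of sizes a
and b drawn from a universe of size N is the upper hypergeometric tail
P(X >= k), identical to the one-sided Fisher exact test on the 2x2 table.
Matrices of pairwise overlaps are BH-adjusted across all cells.

Region-vs-region overlap (e.g. conserved elements vs. epigenetic peaks) is
reported as counts and the intersection ratio only, without a test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConsistencyError, InputError
from .expression import bh_adjust
from .io import IntervalSet

__all__ = ["GeneSetCollection", "OverlapTestResult",
           "hypergeometric_overlap_test", "overlap_matrix",
           "interval_overlap_counts", "bh_adjust"]


@dataclass
class GeneSetCollection:
    """Named gene sets over an explicit universe.

    The universe must be declared (by default the one-to-one ortholog
    universe of the study), never inferred from set unions; every set must
    be a subset of it.
    """

    universe: set
    sets: dict

    def __post_init__(self):
        self.universe = set(self.universe)
        clean = {}
        for name, s in self.sets.items():
            s = set(s)
            outside = s - self.universe
            if outside:
                raise ConsistencyError(
                    f"set {name!r} contains ids outside the universe: "
                    f"{sorted(outside)[:5]}")
            clean[name] = s
        self.sets = clean


@dataclass(frozen=True)
class OverlapTestResult:
    set_a: str
    set_b: str
    n_universe: int
    n_a: int
    n_b: int
    n_overlap: int
    odds_ratio: float
    p: float
    fdr: float = float("nan")


def hypergeometric_overlap_test(universe_n: int, a_n: int, b_n: int,
                                overlap_n: int,
                                alternative: str = "greater",
                                set_a: str = "A",
                                set_b: str = "B") -> OverlapTestResult:
    """Exact overlap test for two sets within a universe.

    One-sided enrichment p = P(X >= overlap_n) with
    X ~ Hypergeometric(universe_n, a_n, b_n) (two-sided selectable, via the
    Fisher exact test on the same 2x2 table). The odds ratio is the sample
    estimate from the 2x2 table with a 0.5 continuity correction applied
    when any cell is zero.
    """
    if not (0 <= a_n <= universe_n and 0 <= b_n <= universe_n):
        raise InputError("set sizes must lie within the universe size")
    if not (0 <= overlap_n <= min(a_n, b_n)):
        raise InputError("overlap must be <= min(set sizes)")
    if overlap_n < a_n + b_n - universe_n:
        raise InputError("overlap below the minimum forced by set sizes")
    if alternative == "greater":
        # survival function at k-1 gives P(X >= k); exact at k = 0 -> 1.
        p = float(stats.hypergeom.sf(overlap_n - 1, universe_n, a_n, b_n))
    elif alternative == "two-sided":
        table = [[overlap_n, a_n - overlap_n],
                 [b_n - overlap_n, universe_n - a_n - b_n + overlap_n]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    else:
        raise InputError(f"unknown alternative {alternative!r}")
    cells = np.array([overlap_n, a_n - overlap_n, b_n - overlap_n,
                      universe_n - a_n - b_n + overlap_n], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    odds = float(cells[0] * cells[3] / (cells[1] * cells[2]))
    return OverlapTestResult(set_a, set_b, universe_n, a_n, b_n, overlap_n,
                             odds, min(p, 1.0))


def overlap_matrix(collection: GeneSetCollection, rows, cols,
                   q: float = 0.05,
                   alternative: str = "greater") -> pd.DataFrame:
    """Test every row x col set pair; BH-adjust across all cells.

    Returns a long-format table with one line per cell: counts, odds
    ratio, raw p, fdr (adjusted over all cells) and a significance flag at
    fdr < q.
    """
    for name in list(rows) + list(cols):
        if name not in collection.sets:
            raise InputError(f"set {name!r} not in the collection")
    N = len(collection.universe)
    results = []
    for r in rows:
        for c in cols:
            A, B = collection.sets[r], collection.sets[c]
            res = hypergeometric_overlap_test(
                N, len(A), len(B), len(A & B), alternative, r, c)
            results.append(res)
    df = pd.DataFrame([vars(x) for x in results])
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["fdr"] < q
    return df


def interval_overlap_counts(elements: IntervalSet,
                            regions: IntervalSet) -> dict:
    """Count elements overlapping any region; report the intersection ratio
    (overlapping elements / total elements). No test is attached — region
    overlap extent is descriptive."""
    from .epigenome import _OverlapIndex
    idx = _OverlapIndex(regions)
    n = len(elements)
    hits = sum(1 for _, el in elements.df.iterrows()
               if idx.overlaps(el["chrom"], el["start"], el["end"]))
    return {"n_elements": n, "n_overlapping": hits,
            "ratio": hits / n if n else float("nan")}
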