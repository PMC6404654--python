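"""Evaluation statistics: mock-community Ideal Score and exact WMW test.

The Ideal Score benchmarks how well an amplicon workflow recovers a mock
community of known composition: it is the sum over taxa of the absolute
difference between expected and observed relative abundances (percent
scale).  A perfect recovery scores 0; the worst possible disagreement
between two compositions that each sum to 100% scores 200.

The Wilcoxon-Mann-Whitney (rank-sum) test compares two samples of values
(here, typically per-variant melting temperatures of two primer pools).
Mid-ranks are assigned to ties, and for small samples the exact two-sided p
is computed from the full permutation null distribution of the rank sum;
larger samples use the tie-corrected normal approximation with continuity
correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "AbundanceTable",
    "IdealScoreResult",
    "WmwResult",
    "ideal_score",
    "wmw_exact",
]


@dataclass(frozen=True)
class AbundanceTable:
    """Taxon -> relative abundance (percent), renormalized to sum to 100.

    Input sums may deviate from 100 by up to ``tolerance`` (default 0.5);
    larger deviations are rejected as likely unit errors.
    """

    entries: "pd.Series"

    def __post_init__(self):
        s = pd.Series(self.entries, dtype=float)
        if s.empty:
            raise ValueError("abundance table must contain at least one taxon")
        if s.index.has_duplicates:
            dups = s.index[s.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxa in abundance table: {dups}")
        if (s < 0).any():
            raise ValueError("abundances must be non-negative")
        object.__setattr__(self, "entries", s * (100.0 / s.sum()))

    @classmethod
    def from_mapping(
        cls, data: Mapping[str, float], tolerance: float = 0.5
    ) -> "AbundanceTable":
        s = pd.Series(dict(data), dtype=float)
        if abs(s.sum() - 100.0) > tolerance:
            raise ValueError(
                f"abundances sum to {s.sum():g}, expected 100 +/- {tolerance}"
            )
        return cls(s)

    @classmethod
    def from_tsv(cls, path, tolerance: float = 0.5) -> "AbundanceTable":
        """Read a two-column (taxon, percent) TSV with optional '#' comments."""
        df = pd.read_csv(path, sep="\t", comment="#", header=0)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns (taxon, percent)")
        return cls.from_mapping(
            dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float))),
            tolerance=tolerance,
        )

    def taxa(self) -> list[str]:
        return list(self.entries.index)


@dataclass(frozen=True)
class IdealScoreResult:
    """Ideal Score (percent scale, 0 = perfect, <= 200) and per-taxon terms."""

    score: float
    per_taxon: "pd.Series"


def ideal_score(expected: AbundanceTable, observed: AbundanceTable) -> IdealScoreResult:
    """Sum over taxa of |expected - observed| relative abundance.

    Taxa present in only one table contribute their full abundance from the
    other (they are imputed as 0 where missing).  Symmetric in its arguments.
    """
    e = expected.entries
    o = observed.entries
    taxa = e.index.union(o.index, sort=False)
    if taxa.empty:
        raise ValueError("no taxa to score")
    diff = (e.reindex(taxa, fill_value=0.0) - o.reindex(taxa, fill_value=0.0)).abs()
    return IdealScoreResult(score=float(diff.sum()), per_taxon=diff)


@dataclass(frozen=True)
class WmwResult:
    """Two-sided WMW outcome: rank-sum statistic of the first sample,
    p-value, and the method used ('exact' or 'normal')."""

    rank_sum: float
    p_value: float
    method: str


def _exact_rank_sum_p(ranks: np.ndarray, n: int, observed: float) -> float:
    """Exact two-sided p for the rank sum of a size-n subset of ``ranks``.

    The null distribution (every size-n labeling equally likely) is built by
    dynamic programming over doubled mid-ranks (mid-ranks are multiples of
    1/2, so doubling gives integers).  Counts stay below 2**53 for the sample
    sizes handled exactly, so float64 arithmetic is lossless.
    """
    doubled = np.rint(ranks * 2).astype(int)
    total = int(doubled.sum())
    # counts[k, s] = number of size-k subsets with doubled-rank sum s
    counts = np.zeros((n + 1, total + 1))
    counts[0, 0] = 1.0
    for r in doubled:
        for k in range(n, 0, -1):  # descending k: each item used at most once
            counts[k, r:] += counts[k - 1, : total + 1 - r]
    dist = counts[n]
    n_comb = dist.sum()
    obs = int(round(observed * 2))
    lower = dist[: obs + 1].sum() / n_comb
    upper = dist[obs:].sum() / n_comb
    return min(1.0, 2.0 * min(lower, upper))


def wmw_exact(
    sample_a: Sequence[float], sample_b: Sequence[float], exact_limit: int = 24
) -> WmwResult:
    """Two-sided Wilcoxon-Mann-Whitney test with mid-ranks for ties.

    For n + m <= ``exact_limit`` the p-value is exact over all C(n+m, n)
    labelings (ties handled through the mid-rank null distribution);
    otherwise the tie-corrected normal approximation with continuity
    correction is used.  The two-sided p doubles the smaller tail, capped
    at 1.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = a.size, b.size
    ranks = rankdata(np.concatenate([a, b]))
    w = float(ranks[:n].sum())
    if n + m <= exact_limit:
        return WmwResult(rank_sum=w, p_value=_exact_rank_sum_p(ranks, n, w), method="exact")
    mean = n * (n + m + 1) / 2.0
    # tie correction to the rank-sum variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n * m / 12.0 * ((n + m + 1) - tie_term / ((n + m) * (n + m - 1)))
    if var == 0:
        return WmwResult(rank_sum=w, p_value=1.0, method="normal")
    z = (abs(w - mean) - 0.5) / math.sqrt(var)
    p = min(1.0, math.erfc(max(z, 0.0) / math.sqrt(2.0)))
    return WmwResult(rank_sum=w, p_value=p, method="normal")
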