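"""Positional nucleotide composition of a primer pool as sequenced.

Illumina sequencers calibrate cluster identification during the first
sequencing cycles, and amplicon libraries primed from a synchronized pool
present a single nucleotide at almost every cycle ("low diversity").
Trimming different numbers of bases from the variants' 5' ends frame-shifts
them against the cycle clock, so a cycle position reads a mixture of
nucleotides.  This module quantifies that effect: per-position nucleotide
frequencies (weighted by pool molarity), the count of distinct nucleotides
per position (richness), and the Shannon index H = -sum(p ln p), whose
maximum for four nucleotides is ln 4 ~ 1.386.

Variants are aligned at their sequenced 5' start - the first retained base
of the locus-specific region, i.e. after 5' trimming - not at parent
coordinates: the diversity exists precisely because trimmed variants start
at shifted template positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import entropy

from .primers import PrimerPool

__all__ = [
    "NUCLEOTIDES",
    "PositionalProfile",
    "positional_composition",
    "positional_richness",
    "positional_shannon",
    "profile_frame",
]

NUCLEOTIDES = "ACGT"


@dataclass(frozen=True)
class PositionalProfile:
    """Weighted nucleotide frequencies over the first N sequenced positions.

    ``composition`` is an (N, 4) array of A/C/G/T frequencies summing to 1
    at every covered position; ``coverage`` is the fraction of pool weight
    contributing at each position (1.0 everywhere when all variants span N).
    """

    n_positions: int
    composition: np.ndarray
    coverage: np.ndarray

    def __post_init__(self):
        comp = np.asarray(self.composition, dtype=float)
        if comp.shape != (self.n_positions, 4):
            raise ValueError("composition must have shape (n_positions, 4)")
        if (comp < -1e-12).any():
            raise ValueError("frequencies must be non-negative")
        sums = comp.sum(axis=1)
        covered = np.asarray(self.coverage) > 0
        if not np.allclose(sums[covered], 1.0, atol=1e-9):
            raise ValueError("frequencies must sum to 1 at covered positions")


def positional_composition(pool: PrimerPool, n_positions: int = 16) -> PositionalProfile:
    """Per-position weighted nucleotide frequencies over the first N positions.

    Variants are aligned at their 5' sequenced start; every variant must span
    all N positions (the 16-base minimum-length design constraint guarantees
    this for N = 16).
    """
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    short = [v for v in pool if len(v.sequence) < n_positions]
    if short:
        raise ValueError(
            f"{len(short)} variant(s) shorter than {n_positions} positions "
            f"(e.g. {short[0].label}); lower n_positions to at most "
            f"{min(len(v.sequence) for v in pool)}"
        )
    comp = np.zeros((n_positions, 4))
    idx = {b: k for k, b in enumerate(NUCLEOTIDES)}
    for variant, weight in zip(pool.variants, pool.weights):
        for p in range(n_positions):
            comp[p, idx[variant.sequence[p]]] += weight
    coverage = np.ones(n_positions)
    comp /= comp.sum(axis=1, keepdims=True)
    return PositionalProfile(n_positions=n_positions, composition=comp, coverage=coverage)


def positional_richness(profile: PositionalProfile) -> tuple[np.ndarray, float]:
    """Count of nucleotides present (frequency > 0) per position, and the average."""
    counts = (profile.composition > 0).sum(axis=1)
    return counts, float(counts.mean())


def positional_shannon(profile: PositionalProfile) -> tuple[np.ndarray, float]:
    """Shannon index H = -sum(p ln p) per position (natural log), and the average."""
    h = entropy(profile.composition, axis=1)
    return h, float(h.mean())


def profile_frame(profile: PositionalProfile) -> pd.DataFrame:
    """Tabular view: position, A/C/G/T frequencies, richness, Shannon,
    plus a trailing 'average' row (full precision; round for display)."""
    rich, mean_rich = positional_richness(profile)
    sh, mean_sh = positional_shannon(profile)
    df = pd.DataFrame(
        profile.composition,
        columns=list(NUCLEOTIDES),
        index=pd.RangeIndex(1, profile.n_positions + 1, name="position"),
    )
    df["richness"] = rich
    df["shannon"] = sh
    avg = df.mean(axis=0)
    avg.name = "average"
    return pd.concat([df, avg.to_frame().T])
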