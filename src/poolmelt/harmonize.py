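"""Per-variant end-trimming to harmonize melting temperatures in a pool.

The design procedure: every resolved variant of a degenerate primer may have
bases removed from its 5' and/or 3' ends, subject to (a) a minimum retained
length and (b) retention of every originally degenerate position.  Among all
per-variant trim choices, a selection is sought that minimizes the spread
(max - min) of the variants' predicted melting temperatures.  5' removals
additionally stagger the variants' sequenced start positions, creating the
nucleotide diversity Illumina sequencers need in the first cycles, so equal-
range optima preferring distinct 5' trims are favored.

The optimizer is exact for the range objective: it is the classical
"smallest range covering one element from each of k lists" sweep over the
sorted union of candidate Tm values, which considers every minimal window.

The model-style entry point is :class:`TmHarmonizer` (``fit()`` returns a
:class:`HarmonizationResult` with a ``summary()`` table); the functional
interface is :func:`harmonize_pool`.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Sequence

from . import diversity as _diversity
from .primers import (
    DegeneratePrimer,
    PrimerPool,
    PrimerVariant,
    expand,
    trim_variant,
)
from .thermo import DEFAULT_CONDITIONS, PoolTmStats, ThermoConditions, pool_tm_stats, tm

__all__ = [
    "TrimConstraints",
    "TrimCandidate",
    "ConstraintError",
    "SelectionResult",
    "HarmonizationResult",
    "TmHarmonizer",
    "candidate_trims",
    "smallest_range_selection",
    "harmonize_pool",
    "wmw_range_report",
]

_EPS = 1e-9


class ConstraintError(ValueError):
    """Raised when the trim constraints admit no candidate for some variant."""


@dataclass(frozen=True)
class TrimConstraints:
    """Constraints on per-variant trimming.

    ``min_length`` is the minimum retained locus-specific length (default 16
    bases); ``retain_degenerate`` forbids trimming away any originally
    degenerate position; the optional caps bound the per-end removals.
    """

    min_length: int = 16
    retain_degenerate: bool = True
    max_trim5: int | None = None
    max_trim3: int | None = None

    def __post_init__(self):
        if self.min_length < 2:
            raise ValueError("min_length must be >= 2")
        for name in ("max_trim5", "max_trim3"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class TrimCandidate:
    """One admissible (trim5, trim3) choice for a variant, with its Tm."""

    variant_index: int
    trim5: int
    trim3: int
    tm_celsius: float


def candidate_trims(
    parent: DegeneratePrimer,
    variant: PrimerVariant,
    constraints: TrimConstraints = TrimConstraints(),
    conditions: ThermoConditions = DEFAULT_CONDITIONS,
) -> list[TrimCandidate]:
    """All admissible (trim5, trim3) pairs for one untrimmed variant.

    A pair (a, b) is admissible when the retained window has at least
    ``min_length`` bases, contains every originally degenerate position of
    the parent (when ``retain_degenerate``), and respects the per-end caps.
    Candidates are returned with their Tm, ordered by (a, b) ascending.
    """
    if variant.trim5 or variant.trim3:
        raise ValueError("candidate_trims expects an untrimmed variant")
    length = len(variant.sequence)
    deg = sorted(parent.degenerate_positions)
    a_max = length - constraints.min_length
    b_max = length - constraints.min_length
    if constraints.retain_degenerate and deg:
        a_max = min(a_max, deg[0] - 1)          # keep first degenerate position
        b_max = min(b_max, length - deg[-1])    # keep last degenerate position
    if constraints.max_trim5 is not None:
        a_max = min(a_max, constraints.max_trim5)
    if constraints.max_trim3 is not None:
        b_max = min(b_max, constraints.max_trim3)
    out: list[TrimCandidate] = []
    for a in range(0, max(a_max, -1) + 1):
        for b in range(0, max(b_max, -1) + 1):
            if length - a - b < constraints.min_length:
                break
            window = variant.sequence[a: length - b]
            out.append(
                TrimCandidate(
                    variant_index=variant.index,
                    trim5=a,
                    trim3=b,
                    tm_celsius=tm(window, conditions),
                )
            )
    if not out:
        raise ConstraintError(
            f"constraints admit no trim for variant {variant.label} "
            f"(length {length}, min_length {constraints.min_length})"
        )
    return out


@dataclass(frozen=True)
class SelectionResult:
    """One chosen element per list, with the realized value window."""

    indices: tuple[int, ...]
    low: float
    high: float

    @property
    def range(self) -> float:
        return self.high - self.low


def _minimal_range(lists: Sequence[Sequence[float]]) -> float:
    """Exact minimum of max-min over one-per-list selections (heap sweep)."""
    sorted_lists = [sorted(lst) for lst in lists]
    ptrs = [0] * len(lists)
    heap = [(sorted_lists[i][0], i) for i in range(len(lists))]
    heapq.heapify(heap)
    cur_max = max(v for v, _ in heap)
    best = cur_max - heap[0][0]
    while True:
        lo, i = heapq.heappop(heap)
        best = min(best, cur_max - lo)
        ptrs[i] += 1
        if ptrs[i] == len(sorted_lists[i]):
            return best
        nxt = sorted_lists[i][ptrs[i]]
        cur_max = max(cur_max, nxt)
        heapq.heappush(heap, (nxt, i))


def _minimal_windows(lists: Sequence[Sequence[float]], rng: float) -> list[tuple[float, float]]:
    """All windows [lo, hi] of width rng (up to eps) covering every list,
    with lo anchored at a candidate value."""
    sorted_lists = [sorted(lst) for lst in lists]
    union = sorted({v for lst in lists for v in lst})
    windows = []
    for lo in union:
        hi = lo
        ok = True
        for lst in sorted_lists:
            pick = next((v for v in lst if v >= lo - _EPS), None)
            if pick is None:
                ok = False
                break
            hi = max(hi, pick)
        if ok and hi - lo <= rng + _EPS:
            windows.append((lo, hi))
    return windows


def smallest_range_selection(lists: Sequence[Sequence[float]]) -> SelectionResult:
    """Choose one value per list minimizing the spread max - min (exact).

    Implemented by the sorted-merge sweep over the union of candidate values;
    every sweep window covering at least one candidate from each list is
    considered, so the returned range is the global minimum.  Ties are broken
    toward the lowest-valued window, and within a list toward the earliest
    candidate inside the window.
    """
    if not lists:
        raise ValueError("at least one candidate list is required")
    for i, lst in enumerate(lists):
        if not lst:
            raise ValueError(f"candidate list {i} is empty")
    rng = _minimal_range(lists)
    lo, hi = _minimal_windows(lists, rng)[0]
    indices = []
    for lst in lists:
        idx = min(
            (j for j, v in enumerate(lst) if lo - _EPS <= v <= hi + _EPS),
            key=lambda j: lst[j],
        )
        indices.append(idx)
    return SelectionResult(indices=tuple(indices), low=lo, high=hi)


def _max_stagger_assignment(
    feasible: list[list[TrimCandidate]],
) -> tuple[list[TrimCandidate], int]:
    """Pick one candidate per variant from its feasible set, maximizing the
    number of distinct trim5 values (exact, via bipartite matching), then
    per-variant preferring longer windows and lexicographically small trims."""
    values = sorted({c.trim5 for cands in feasible for c in cands})
    adj = {
        v: [i for i, cands in enumerate(feasible) if any(c.trim5 == v for c in cands)]
        for v in values
    }
    match_of_variant: dict[int, int] = {}  # variant index in feasible -> trim5 value

    def try_assign(v: int, visited: set[int]) -> bool:
        for i in adj[v]:
            if i in visited:
                continue
            visited.add(i)
            if i not in match_of_variant or try_assign(match_of_variant[i], visited):
                match_of_variant[i] = v
                return True
        return False

    for v in values:
        try_assign(v, set())

    chosen: list[TrimCandidate] = []
    for i, cands in enumerate(feasible):
        if i in match_of_variant:
            pool = [c for c in cands if c.trim5 == match_of_variant[i]]
        else:
            pool = cands
        chosen.append(min(pool, key=lambda c: (c.trim5 + c.trim3, c.trim5, c.trim3)))
    return chosen, len({c.trim5 for c in chosen})


@dataclass(frozen=True)
class HarmonizationResult:
    """Outcome of Tm harmonization for one degenerate primer.

    Carries the chosen trim per variant, the trimmed pool, the realized and
    untrimmed Tm summaries, a positional-diversity summary of the trimmed
    pool, and the constraints/conditions used (provenance).
    """

    primer: DegeneratePrimer
    constraints: TrimConstraints
    conditions: ThermoConditions
    selection: tuple[TrimCandidate, ...]
    pool: PrimerPool
    untrimmed_stats: PoolTmStats
    realized_stats: PoolTmStats
    diversity_positions: int
    mean_richness: float
    mean_shannon: float

    @property
    def realized_range(self) -> float:
        return self.realized_stats.tm_range

    @property
    def realized_min(self) -> float:
        return self.realized_stats.tm_min

    @property
    def realized_max(self) -> float:
        return self.realized_stats.tm_max

    def wmw_p_value(self) -> float:
        """Exact two-sided WMW p comparing untrimmed vs harmonized Tm values."""
        return wmw_range_report(self.untrimmed_stats.tms, self.realized_stats.tms)

    def summary(self) -> str:
        """Human-readable design summary."""
        u, r = self.untrimmed_stats, self.realized_stats
        lines = [
            f"Tm harmonization of primer {self.primer.name} "
            f"({self.primer.iupac_sequence}, {len(self.pool)} variants)",
            f"  constraints: min_length={self.constraints.min_length}, "
            f"retain_degenerate={self.constraints.retain_degenerate}",
            f"  conditions: oligo={self.conditions.oligo_conc * 1e9:g} nM, "
            f"monovalent={self.conditions.monovalent * 1e3:g} mM, "
            f"Mg={self.conditions.mg * 1e3:g} mM, dNTP={self.conditions.dntp * 1e3:g} mM, "
            f"x={self.conditions.duplex_factor}, nn={self.conditions.nn_table}, "
            f"salt={self.conditions.salt_correction}",
            f"  untrimmed Tm: {u.tm_min:.1f}-{u.tm_max:.1f} C (range {u.tm_range:.1f})",
            f"  harmonized Tm: {r.tm_min:.1f}-{r.tm_max:.1f} C (range {r.tm_range:.1f})",
            f"  diversity over first {self.diversity_positions} positions: "
            f"mean richness {self.mean_richness:.2f}, mean Shannon {self.mean_shannon:.2f}",
            "  variant  trim5  trim3  length  Tm(C)  sequence",
        ]
        for cand, var in zip(self.selection, self.pool.variants):
            lines.append(
                f"  {var.index:>7d}  {cand.trim5:>5d}  {cand.trim3:>5d}  "
                f"{len(var.sequence):>6d}  {cand.tm_celsius:>5.1f}  {var.sequence}"
            )
        return "\n".join(lines)


class TmHarmonizer:
    """Model object: harmonize the Tm of one degenerate primer's pool.

    Parameters
    ----------
    primer : DegeneratePrimer
        The degenerate primer to redesign.
    constraints : TrimConstraints, optional
        Trimming constraints (default: 16-base minimum, degenerate positions
        retained).
    conditions : ThermoConditions, optional
        Thermodynamic context for Tm prediction.

    ``fit()`` enumerates admissible trims per variant, solves the smallest-
    range selection exactly, and returns a :class:`HarmonizationResult`.
    """

    def __init__(
        self,
        primer: DegeneratePrimer,
        constraints: TrimConstraints | None = None,
        conditions: ThermoConditions | None = None,
    ):
        self.primer = primer
        self.constraints = constraints or TrimConstraints()
        self.conditions = conditions or DEFAULT_CONDITIONS

    @classmethod
    def from_sequence(cls, name: str, iupac_sequence: str, **kwargs) -> "TmHarmonizer":
        return cls(DegeneratePrimer(name=name, iupac_sequence=iupac_sequence), **kwargs)

    def fit(self) -> HarmonizationResult:
        primer, constraints, conditions = self.primer, self.constraints, self.conditions
        base_pool = expand(primer)
        untrimmed = pool_tm_stats(base_pool, conditions)
        cands = [
            candidate_trims(primer, v, constraints, conditions) for v in base_pool
        ]
        value_lists = [[c.tm_celsius for c in lst] for lst in cands]
        rng = _minimal_range(value_lists)

        best_choice: list[TrimCandidate] | None = None
        best_key: tuple | None = None
        for lo, hi in _minimal_windows(value_lists, rng):
            feasible = [
                [c for c in lst if lo - _EPS <= c.tm_celsius <= hi + _EPS]
                for lst in cands
            ]
            if any(not f for f in feasible):
                continue
            chosen, stagger = _max_stagger_assignment(feasible)
            total_trim = sum(c.trim5 + c.trim3 for c in chosen)
            key = (-stagger, total_trim, tuple((c.trim5, c.trim3) for c in chosen))
            if best_key is None or key < best_key:
                best_key, best_choice = key, chosen
        assert best_choice is not None

        trimmed = PrimerPool(
            name=primer.name,
            variants=tuple(
                trim_variant(v, c.trim5, c.trim3)
                for v, c in zip(base_pool.variants, best_choice)
            ),
            weights=base_pool.weights,
        )
        realized = pool_tm_stats(trimmed, conditions)
        n_div = min(16, min(len(v.sequence) for v in trimmed))
        profile = _diversity.positional_composition(trimmed, n_div)
        _, mean_rich = _diversity.positional_richness(profile)
        _, mean_sh = _diversity.positional_shannon(profile)
        return HarmonizationResult(
            primer=primer,
            constraints=constraints,
            conditions=conditions,
            selection=tuple(best_choice),
            pool=trimmed,
            untrimmed_stats=untrimmed,
            realized_stats=realized,
            diversity_positions=n_div,
            mean_richness=mean_rich,
            mean_shannon=mean_sh,
        )


def harmonize_pool(
    primer: DegeneratePrimer,
    constraints: TrimConstraints | None = None,
    conditions: ThermoConditions | None = None,
) -> HarmonizationResult:
    """Expand, enumerate trims, and minimize the pool's Tm range (exact)."""
    return TmHarmonizer(primer, constraints, conditions).fit()


def wmw_range_report(
    original_pool_tms: Sequence[float], harmonized_pool_tms: Sequence[float]
) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p comparing the two Tm samples."""
    from .evaluate import wmw_exact

    return wmw_exact(list(original_pool_tms), list(harmonized_pool_tms)).p_value
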