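"""Nearest-neighbor duplex thermodynamics for primer variants.

Duplex stability is modeled as a sum of dinucleotide-stack enthalpies and
entropies plus initiation terms (the nearest-neighbor model), from which the
melting temperature at 1 M Na+ follows as

    Tm = dH * 1000 / (dS + R * ln(CT / x))        [kelvin]

with CT the total oligonucleotide concentration and x the duplex symmetry /
strand-excess factor.  The Tm is then corrected for the actual ionic
conditions.  Two published correction schemes are provided:

``na_eq`` (default)
    Free Mg2+ (total Mg minus dNTP, which chelates stoichiometrically) is
    converted to a sodium equivalent, Na_eq = mono + 120 * sqrt([Mg2+]free)
    (all mM), and the monovalent correction Tm += 12.5 * log10([Na_eq]) is
    applied.
``owczarzy``
    The Owczarzy 2004 GC-fraction 1/Tm monovalent correction and the
    Owczarzy 2008 1/Tm Mg2+ polynomial, with the regime chosen by the ratio
    sqrt([Mg2+]free) / [monovalent] at the published thresholds.

Both are computed through Biopython's ``MeltingTemp`` machinery on the
SantaLucia unified parameter tables.  The default model and duplex factor
(x = 2) were calibrated once against published melting temperatures of the
515F/806R Earth Microbiome Project primer pools; see docs/methods.md.

Self-dimer screening scores every ungapped antiparallel self-alignment by
summing stack free energies over contiguous complementary runs of >= 2 bp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio.SeqUtils import MeltingTemp as _mt

from .primers import PrimerPool, validate_iupac

__all__ = [
    "GAS_CONSTANT",
    "NN_TABLES",
    "ThermoConditions",
    "ThermoResult",
    "DimerHit",
    "PoolTmStats",
    "parse_concentration",
    "nn_sum",
    "tm",
    "dg37",
    "thermo_profile",
    "self_dimer",
    "pool_tm_stats",
]

#: Gas constant in cal/(mol*K), as used throughout the nearest-neighbor model.
GAS_CONSTANT = 1.987

#: Named SantaLucia unified parameter sets (dH kcal/mol, dS cal/(mol*K)).
NN_TABLES = {
    "santalucia1998": _mt.DNA_NN3,  # Allawi & SantaLucia unified parameters
    "santalucia2004": _mt.DNA_NN4,  # SantaLucia & Hicks refinement
}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

_UNIT_SCALE = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12}


def parse_concentration(text: str | float) -> float:
    """Parse a concentration with an optional unit suffix into molar.

    Accepts plain numbers (interpreted as molar) or strings such as
    ``"250nM"``, ``"2 mM"``, ``"0.05M"``.
    """
    if isinstance(text, (int, float)):
        return float(text)
    s = text.strip()
    for unit in sorted(_UNIT_SCALE, key=len, reverse=True):
        if s.endswith(unit):
            return float(s[: -len(unit)].strip()) * _UNIT_SCALE[unit]
    return float(s)


@dataclass(frozen=True)
class ThermoConditions:
    """Ionic and concentration context for Tm prediction.

    All concentrations are molar.  Defaults are the standard assay
    conditions for degenerate 16S primer pools: 250 nM oligo, 50 mM
    monovalent, 2 mM Mg2+, 0.2 mM dNTP.

    ``duplex_factor`` is the x in the Tm denominator ``R ln(CT/x)``;
    ``nn_table`` and ``salt_correction`` select the parameter set and the
    ionic-correction scheme (see module docstring).
    """

    oligo_conc: float = 250e-9
    monovalent: float = 50e-3
    mg: float = 2e-3
    dntp: float = 0.2e-3
    duplex_factor: int = 2
    nn_table: str = "santalucia2004"
    salt_correction: str = "na_eq"

    def __post_init__(self):
        for name in ("oligo_conc", "monovalent", "mg", "dntp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.duplex_factor not in (1, 2, 4):
            raise ValueError("duplex_factor must be 1, 2 or 4")
        if self.nn_table not in NN_TABLES:
            raise ValueError(f"unknown nn_table {self.nn_table!r}; options {sorted(NN_TABLES)}")
        if self.salt_correction not in ("na_eq", "owczarzy"):
            raise ValueError("salt_correction must be 'na_eq' or 'owczarzy'")

    @property
    def free_mg(self) -> float:
        """Free Mg2+ after stoichiometric dNTP chelation: max(mg - dntp, 0)."""
        return max(self.mg - self.dntp, 0.0)

    @property
    def sodium_equivalent(self) -> float:
        """Monovalent-equivalent cation concentration (molar), von-Ahsen style."""
        return self.monovalent + 120e-3 * math.sqrt(self.free_mg * 1e3)


#: The study's default prediction conditions.
DEFAULT_CONDITIONS = ThermoConditions()


@dataclass(frozen=True)
class ThermoResult:
    """Duplex thermodynamics of one sequence: dH (kcal/mol), dS (cal/mol/K),
    Tm (Celsius) under the given conditions, and dG at 37 C (kcal/mol)."""

    sequence: str
    dh: float
    ds: float
    tm_celsius: float
    dg37: float


@dataclass(frozen=True)
class DimerHit:
    """Strongest self-dimer alignment.

    ``offset`` is the shift of the antiparallel copy relative to perfect
    head-to-tail register (0 = the 5' end of one strand aligned with the 3'
    end of the other); ``paired_runs`` lists (start, length) of complementary
    stretches (1-based start on the input strand); ``dg`` is the summed stack
    free energy (kcal/mol) of the best alignment, 0 if no run of >= 2 bp
    pairs anywhere.
    """

    offset: int
    paired_runs: tuple[tuple[int, int], ...]
    dg: float


@dataclass(frozen=True)
class PoolTmStats:
    """Per-variant Tm values and the pool summary (Celsius)."""

    tms: tuple[float, ...]
    tm_min: float
    tm_max: float
    tm_mean: float
    tm_range: float


def _check_duplex_sequence(sequence: str) -> str:
    seq = validate_iupac(sequence)
    if any(ch not in "ACGT" for ch in seq):
        raise ValueError(
            f"thermodynamics require a fully resolved A/C/G/T sequence, got {sequence!r}"
        )
    if len(seq) < 2:
        raise ValueError("duplex thermodynamics require length >= 2")
    return seq


def nn_sum(sequence: str, nn_table: str = "santalucia2004") -> tuple[float, float]:
    """Sum of nearest-neighbor stack parameters plus initiation terms.

    Returns (dH, dS) in kcal/mol and cal/(mol*K) for the perfect-match duplex
    of ``sequence``, using the same accounting as the Tm computation:
    a general initiation term, an all-A/T (or one-G/C) duplex term, terminal
    5'-T/3'-A penalties, per-terminal A/T and G/C terms, and the 10 unified
    dinucleotide stacks.
    """
    seq = _check_duplex_sequence(sequence)
    table = NN_TABLES[nn_table]
    cseq = "".join(_COMPLEMENT[c] for c in seq)
    dh, ds = 0.0, 0.0

    def add(key):
        nonlocal dh, ds
        dh += table[key][0]
        ds += table[key][1]

    add("init")
    add("init_allA/T" if all(c in "AT" for c in seq) else "init_oneG/C")
    if seq.startswith("T"):
        add("init_5T/A")
    if seq.endswith("A"):
        add("init_5T/A")
    ends = seq[0] + seq[-1]
    for _ in range(ends.count("A") + ends.count("T")):
        add("init_A/T")
    for _ in range(ends.count("G") + ends.count("C")):
        add("init_G/C")
    for i in range(len(seq) - 1):
        key = seq[i: i + 2] + "/" + cseq[i: i + 2]
        add(key if key in table else key[::-1])
    return dh, ds


def tm(sequence: str, conditions: ThermoConditions = DEFAULT_CONDITIONS) -> float:
    """Corrected duplex melting temperature in Celsius.

    The 1 M Na+ Tm from the nearest-neighbor sums is adjusted for the
    conditions' ionic context by the scheme named in
    ``conditions.salt_correction``.  Invariant under reverse complement.
    """
    seq = _check_duplex_sequence(sequence)
    if conditions.oligo_conc <= 0:
        raise ValueError("oligo concentration must be positive for a finite Tm")
    if conditions.monovalent <= 0 and conditions.free_mg <= 0:
        raise ValueError("at least one of monovalent or free Mg2+ must be positive")
    dnac1 = conditions.oligo_conc * 1e9 / conditions.duplex_factor  # nM
    table = NN_TABLES[conditions.nn_table]
    if conditions.salt_correction == "na_eq":
        return _mt.Tm_NN(
            seq, nn_table=table, dnac1=dnac1, dnac2=0,
            Na=conditions.sodium_equivalent * 1e3, saltcorr=3,
        )
    return _mt.Tm_NN(
        seq, nn_table=table, dnac1=dnac1, dnac2=0,
        Na=conditions.monovalent * 1e3, Mg=conditions.mg * 1e3,
        dNTPs=conditions.dntp * 1e3, saltcorr=7,
    )


def dg37(sequence: str, nn_table: str = "santalucia2004") -> float:
    """Duplex free energy at 37 C: dG = dH - 310.15 * dS / 1000 (kcal/mol)."""
    dh, ds = nn_sum(sequence, nn_table)
    return dh - 310.15 * ds / 1000.0


def thermo_profile(
    sequence: str, conditions: ThermoConditions = DEFAULT_CONDITIONS
) -> ThermoResult:
    """Full thermodynamic report (dH, dS, Tm, dG37) for one sequence."""
    seq = _check_duplex_sequence(sequence)
    dh, ds = nn_sum(seq, conditions.nn_table)
    return ThermoResult(
        sequence=seq,
        dh=dh,
        ds=ds,
        tm_celsius=tm(seq, conditions),
        dg37=dh - 310.15 * ds / 1000.0,
    )


def _stack_dg37(dinuc: str, table) -> float:
    cdinuc = _COMPLEMENT[dinuc[0]] + _COMPLEMENT[dinuc[1]]
    key = dinuc + "/" + cdinuc
    dh, ds = table[key] if key in table else table[key[::-1]]
    return dh - 310.15 * ds / 1000.0


def self_dimer(sequence: str, nn_table: str = "santalucia2004") -> DimerHit:
    """Strongest ungapped antiparallel self-alignment of a sequence.

    Two copies of the strand are slid against each other in antiparallel
    orientation; at each register, maximal runs of Watson-Crick pairs are
    found and every run of >= 2 bp contributes its internal stack dG37 values
    (no initiation or loop terms; unpaired positions contribute zero).  The
    register with the most negative total is returned.
    """
    seq = _check_duplex_sequence(sequence)
    table = NN_TABLES[nn_table]
    n = len(seq)
    best: DimerHit | None = None
    # Position i of one strand pairs position j = c - i of the antiparallel copy.
    for c in range(2 * n - 1):
        lo = max(0, c - n + 1)
        hi = min(n - 1, c)
        paired = [
            lo + k
            for k in range(hi - lo + 1)
            if _COMPLEMENT[seq[lo + k]] == seq[c - (lo + k)]
        ]
        runs: list[tuple[int, int]] = []
        total = 0.0
        idx = 0
        while idx < len(paired):
            start = paired[idx]
            length = 1
            while idx + 1 < len(paired) and paired[idx + 1] == paired[idx] + 1:
                idx += 1
                length += 1
            idx += 1
            if length >= 2:
                runs.append((start + 1, length))  # 1-based for reporting
                for p in range(start, start + length - 1):
                    total += _stack_dg37(seq[p: p + 2], table)
        hit = DimerHit(offset=c - (n - 1), paired_runs=tuple(runs), dg=total)
        if best is None or hit.dg < best.dg - 1e-12 or (
            abs(hit.dg - best.dg) <= 1e-12
            and (abs(hit.offset), hit.offset) < (abs(best.offset), best.offset)
        ):
            best = hit
    assert best is not None
    if best.dg >= 0.0:
        return DimerHit(offset=0, paired_runs=(), dg=0.0)
    return best


def pool_tm_stats(
    pool: PrimerPool, conditions: ThermoConditions = DEFAULT_CONDITIONS
) -> PoolTmStats:
    """Per-variant Tm and the pool min/max/mean/range summary."""
    tms = tuple(tm(v.sequence, conditions) for v in pool)
    return PoolTmStats(
        tms=tms,
        tm_min=min(tms),
        tm_max=max(tms),
        tm_mean=sum(tms) / len(tms),
        tm_range=max(tms) - min(tms),
    )
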