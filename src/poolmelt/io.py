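"""File I/O, run configuration, and seeded fixture generation.

Tabular files are tab-delimited UTF-8 with '#' comment lines.  Primer tables
carry columns ``name``, ``sequence`` (IUPAC), optional ``orientation`` and
``linker``.  Primers may also be read from FASTA, with orientation inferred
from a configurable name suffix.  Pool FASTA records are named
``<parent>_<index>_t5-<a>_t3-<b>`` so trim offsets round-trip exactly.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .diversity import positional_composition, profile_frame
from .harmonize import HarmonizationResult, TrimConstraints
from .primers import (
    IUPAC_CODES,
    DegeneratePrimer,
    PrimerPool,
    PrimerVariant,
    degeneracy,
)
from .thermo import ThermoConditions, self_dimer, thermo_profile

__all__ = [
    "RunConfig",
    "read_primer_table",
    "read_pool_fasta",
    "write_pool_fasta",
    "thermo_report",
    "write_reports",
    "generate_fixture_primers",
]

logger = logging.getLogger("poolmelt")

_VARIANT_NAME = re.compile(r"^(?P<parent>.+)_(?P<index>\d+)_t5-(?P<t5>\d+)_t3-(?P<t3>\d+)$")


@dataclass(frozen=True)
class RunConfig:
    """Bundled run configuration (thermo conditions, trim constraints,
    diversity window, output directory, seed, verbosity).

    With a fixed seed all outputs are byte-identical across runs; the
    pipeline itself is deterministic, the seed only drives fixture
    generation.
    """

    conditions: ThermoConditions = field(default_factory=ThermoConditions)
    constraints: TrimConstraints = field(default_factory=TrimConstraints)
    diversity_positions: int = 16
    out_dir: Path = Path(".")
    seed: int = 0
    verbose: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cond = ThermoConditions(**raw.get("conditions", {}))
        cons = TrimConstraints(**raw.get("constraints", {}))
        return cls(
            conditions=cond,
            constraints=cons,
            diversity_positions=int(raw.get("diversity_positions", 16)),
            out_dir=Path(raw.get("out_dir", ".")),
            seed=int(raw.get("seed", 0)),
            verbose=bool(raw.get("verbose", False)),
        )


def _infer_orientation(name: str, reverse_suffix: str = "R") -> str:
    return "reverse" if name.upper().endswith(reverse_suffix.upper()) else "forward"


def read_primer_table(path, reverse_suffix: str = "R") -> list[DegeneratePrimer]:
    """Read degenerate primers from a TSV table or a FASTA file.

    TSV requires a header with ``name`` and ``sequence`` columns; optional
    ``orientation`` and ``linker`` columns are honored.  FASTA records use
    the record id as name, with orientation inferred from ``reverse_suffix``.
    Duplicate names are rejected; errors name the offending line.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty primer file")
    primers = (
        _read_primer_fasta(path, reverse_suffix)
        if text.lstrip().startswith(">")
        else _read_primer_tsv(path)
    )
    seen: set[str] = set()
    for p in primers:
        if p.name in seen:
            raise ValueError(f"{path}: duplicate primer name {p.name!r}")
        seen.add(p.name)
    return primers


def _read_primer_fasta(path: Path, reverse_suffix: str) -> list[DegeneratePrimer]:
    primers = []
    for rec in SeqIO.parse(str(path), "fasta"):
        primers.append(
            DegeneratePrimer(
                name=rec.id,
                iupac_sequence=str(rec.seq),
                orientation=_infer_orientation(rec.id, reverse_suffix),
            )
        )
    if not primers:
        raise ValueError(f"{path}: no FASTA records found")
    return primers


def _read_primer_tsv(path: Path) -> list[DegeneratePrimer]:
    header: list[str] | None = None
    primers = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [h.strip().lower() for h in fields]
            for required in ("name", "sequence"):
                if required not in header:
                    raise ValueError(
                        f"{path}:{lineno}: header must contain {required!r} "
                        f"(got {header})"
                    )
            continue
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected at least 2 tab-separated fields")
        row = dict(zip(header, (f.strip() for f in fields)))
        if not row.get("name") or not row.get("sequence"):
            raise ValueError(f"{path}:{lineno}: missing name or sequence")
        try:
            primers.append(
                DegeneratePrimer(
                    name=row["name"],
                    iupac_sequence=row["sequence"],
                    orientation=row.get("orientation") or _infer_orientation(row["name"]),
                    linker=row.get("linker") or None,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if header is None:
        raise ValueError(f"{path}: no header row found")
    if not primers:
        raise ValueError(f"{path}: no primer rows found")
    return primers


def write_pool_fasta(pool: PrimerPool, path, width: int = 80) -> None:
    """Write one FASTA record per variant, named with its trim offsets."""
    with open(path, "w") as fh:
        for v in pool:
            fh.write(f">{v.label}\n")
            for i in range(0, len(v.sequence), width):
                fh.write(v.sequence[i: i + width] + "\n")


def read_pool_fasta(path) -> PrimerPool:
    """Round-trip reader for pool FASTA written by :func:`write_pool_fasta`."""
    variants = []
    parent = None
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _VARIANT_NAME.match(rec.id)
        if not m:
            raise ValueError(
                f"{path}: record {rec.id!r} does not match "
                "<parent>_<index>_t5-<a>_t3-<b>"
            )
        parent = m.group("parent")
        variants.append(
            PrimerVariant(
                parent=parent,
                index=int(m.group("index")),
                sequence=str(rec.seq),
                trim5=int(m.group("t5")),
                trim3=int(m.group("t3")),
            )
        )
    if not variants:
        raise ValueError(f"{path}: no FASTA records found")
    return PrimerPool(name=parent, variants=tuple(variants))


def thermo_report(pool: PrimerPool, conditions: ThermoConditions) -> pd.DataFrame:
    """Per-variant thermodynamic table: name, length, trims, dH, dS, Tm,
    dG37, and self-dimer dG (kcal/mol)."""
    rows = []
    for v in pool:
        prof = thermo_profile(v.sequence, conditions)
        dimer = self_dimer(v.sequence, conditions.nn_table)
        rows.append(
            {
                "variant": v.label,
                "sequence": v.sequence,
                "length": len(v.sequence),
                "trim5": v.trim5,
                "trim3": v.trim3,
                "dH_kcal_mol": prof.dh,
                "dS_cal_mol_K": prof.ds,
                "tm_celsius": round(prof.tm_celsius, 1),
                "dG37_kcal_mol": round(prof.dg37, 2),
                "self_dimer_dG_kcal_mol": round(dimer.dg, 2),
            }
        )
    return pd.DataFrame(rows)


def _log_model(conditions: ThermoConditions, constraints: TrimConstraints | None) -> None:
    logger.info(
        "thermo model: nn=%s salt=%s x=%d oligo=%gM mono=%gM Mg=%gM dNTP=%gM",
        conditions.nn_table,
        conditions.salt_correction,
        conditions.duplex_factor,
        conditions.oligo_conc,
        conditions.monovalent,
        conditions.mg,
        conditions.dntp,
    )
    if constraints is not None:
        logger.info("trim constraints: %s", constraints)


def write_reports(result: HarmonizationResult, out_dir, prefix: str | None = None) -> dict:
    """Write the harmonized pool FASTA, thermo TSV, diversity TSV, design
    summary text, and a machine-readable JSON summary.

    Returns the summary dictionary (also written as ``<prefix>_summary.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prefix = prefix or result.primer.name
    _log_model(result.conditions, result.constraints)

    write_pool_fasta(result.pool, out / f"{prefix}_pool.fasta")
    thermo_report(result.pool, result.conditions).to_csv(
        out / f"{prefix}_thermo.tsv", sep="\t", index=False
    )
    profile = positional_composition(result.pool, result.diversity_positions)
    profile_frame(profile).round(4).to_csv(out / f"{prefix}_diversity.tsv", sep="\t")
    (out / f"{prefix}_summary.txt").write_text(result.summary() + "\n")

    summary = {
        "primer": result.primer.name,
        "iupac_sequence": result.primer.iupac_sequence,
        "n_variants": len(result.pool),
        "untrimmed_tm_min": round(result.untrimmed_stats.tm_min, 1),
        "untrimmed_tm_max": round(result.untrimmed_stats.tm_max, 1),
        "untrimmed_tm_range": round(result.untrimmed_stats.tm_range, 1),
        "realized_tm_min": round(result.realized_min, 1),
        "realized_tm_max": round(result.realized_max, 1),
        "realized_tm_range": round(result.realized_range, 1),
        "mean_richness": round(result.mean_richness, 2),
        "mean_shannon": round(result.mean_shannon, 2),
        "wmw_p_vs_original": result.wmw_p_value(),
        "constraints": asdict(result.constraints),
        "conditions": asdict(result.conditions),
    }
    with open(out / f"{prefix}_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def generate_fixture_primers(
    count: int,
    length_range: tuple[int, int] = (18, 22),
    degeneracy_range: tuple[int, int] = (2, 32),
    seed: int = 0,
) -> list[DegeneratePrimer]:
    """Reproducible random degenerate primers for tests and demos.

    Each primer's degeneracy falls within ``degeneracy_range``; unless the
    range is (1, 1), every primer carries at least one degenerate position.
    Deterministic for a fixed seed.
    """
    lo_len, hi_len = length_range
    lo_deg, hi_deg = degeneracy_range
    if count < 1 or lo_len < 2 or hi_len < lo_len or lo_deg < 1 or hi_deg < lo_deg:
        raise ValueError("infeasible fixture ranges")
    if lo_deg > 4 ** lo_len:
        raise ValueError("degeneracy range unreachable at the requested lengths")
    rng = np.random.default_rng(seed)
    plain = "ACGT"
    degen = [c for c, opts in IUPAC_CODES.items() if len(opts) > 1]
    primers = []
    for i in range(count):
        length = int(rng.integers(lo_len, hi_len + 1))
        seq = list(rng.choice(list(plain), size=length))
        target_min = max(lo_deg, 2) if hi_deg >= 2 else lo_deg
        current = 1
        attempts = 0
        while current < target_min:
            attempts += 1
            if attempts > 100 * length:  # pragma: no cover - defensive
                raise ValueError("could not satisfy degeneracy range")
            pos = int(rng.integers(0, length))
            if seq[pos] not in plain:
                continue
            options = [c for c in degen if current * len(IUPAC_CODES[c]) <= hi_deg]
            if not options:  # pragma: no cover - unreachable for valid ranges
                break
            code = str(rng.choice(options))
            seq[pos] = code
            current *= len(IUPAC_CODES[code])
        primers.append(
            DegeneratePrimer(name=f"fixture_{seed}_{i}", iupac_sequence="".join(seq))
        )
        assert lo_deg <= degeneracy(primers[-1].iupac_sequence) <= hi_deg
    return primers
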