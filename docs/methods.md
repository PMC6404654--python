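# Methods

## Scope

poolmelt models one degenerate primer at a time: its expansion into an
equimolar pool of resolved variants, per-variant duplex thermodynamics,
constrained end-trimming to minimize the pool's Tm spread, the positional
nucleotide diversity of the pool as sequenced, and two evaluation
statistics (Ideal Score, exact WMW).  It does not model primer–template
mismatches, hairpins, heterodimers between different primers, cross-pool
(forward vs reverse) Tm matching, or anything downstream of the primers
(read processing, OTU clustering, community statistics).

## Nearest-neighbor thermodynamics

ΔH and ΔS of the perfect-match duplex are summed over dinucleotide stacks
plus initiation terms, using the SantaLucia unified parameter tables as
shipped with Biopython (`DNA_NN4`, the 2004 refinement, by default;
`DNA_NN3`, the 1998 unified set, selectable).  The 1 M Na⁺ melting
temperature is

    Tm(1M) = ΔH·1000 / (ΔS + R·ln(C_T/x)) − 273.15

with R = 1.987 cal/(mol·K), C_T the total oligo concentration, and x the
duplex/strand-excess factor (1, 2, or 4; default 2).

Two ionic-correction schemes are implemented, both via Biopython's
`MeltingTemp`:

* **`na_eq` (default).**  Free Mg²⁺ — total Mg²⁺ minus total dNTP, which
  chelates Mg²⁺ roughly stoichiometrically — is converted to a sodium
  equivalent, Na_eq = [monovalent] + 120·√([Mg²⁺]_free) (mM), and the
  monovalent correction Tm += 12.5·log₁₀[Na_eq] is applied.
* **`owczarzy`.**  The GC-fraction-dependent 1/Tm monovalent correction
  (Owczarzy 2004) and the 1/Tm Mg²⁺ polynomial with dNTP-corrected free
  Mg²⁺ (Owczarzy 2008), the regime selected by the ratio
  √[Mg²⁺]_free/[monovalent] at the published thresholds.

**Default conditions** are 250 nM oligo, 50 mM monovalent, 2 mM Mg²⁺,
0.2 mM dNTP — the standard assay context for the EMP V4 primer pools;
all are configurable (unit suffixes accepted on the CLI).  Temperatures
are reported to 0.1 °C; full precision is kept internally.

**Calibration.**  The proprietary calculator that published reference Tm
values for the 515F/806R pools does not disclose its exact formula chain,
so the default model was fixed once by calibrating the open choices —
parameter table, correction scheme, and x ∈ {1, 2, 4} — against the four
published pool endpoints (515F 66.9/71.8 °C, 806R 54.7/61.7 °C).  The
selected default (`santalucia2004` + `na_eq` + x = 2) reproduces them with
residuals +0.5/+1.0/−0.9/−0.2 °C; the best Owczarzy-scheme configuration
(x = 2) leaves residuals up to +1.8 °C.  ±1.0 °C at reporting precision is
the declared model fidelity, not bit-exactness; predicted values should be
compared between runs of this tool, not mixed with other calculators'.

**Self-dimers.**  All ungapped antiparallel self-alignments are scored by
summing stack ΔG°₃₇ over contiguous complementary runs of ≥ 2 bp — no
initiation, loop, dangling-end, or mismatch terms.  The most negative
alignment is reported ("strongest"); a sequence with no ≥ 2 bp
self-complementarity scores 0.  This is a screening statistic comparable
only within this tool.

## Harmonization

For each variant of length L with originally degenerate positions D
(1-based, from the parent IUPAC string), the admissible trims (a, b)
satisfy L − a − b ≥ `min_length` (default 16), a < min(D), b ≤ L − max(D)
(when `retain_degenerate`, the default), plus optional per-end caps.  The
retained window must contain every originally degenerate position, so the
redesigned pool targets no narrower a taxon range than the original.

Choosing one candidate per variant to minimize max − min of Tm is the
classical smallest-range-over-k-lists problem, solved exactly by the
sorted-merge sweep (every minimal window over the union of candidate Tm
values is visited).  Among equal-range optima the tie-breaks are, in
order: (1) maximize the number of distinct trim5 values — the 5′ stagger
that creates frameshift diversity — computed exactly per window by
bipartite matching between trim5 values and variants; (2) prefer longer
retained windows (smaller total trim); (3) lexicographically smallest
(trim5, trim3) per variant.  Ranks (2)–(3) are applied greedily within the
fixed matching, which keeps the procedure deterministic; the optimal
*range* itself is always exact (property-tested against brute force).
Tm ties are compared with an absolute tolerance of 1e-9 °C.

Zero trim is always admissible when the parent satisfies the constraints,
so the realized range can never exceed the untrimmed pool's range.  The
optimizer minimizes range only; the accompanying drop in mean Tm (trimmed
primers are shorter) is reported, not constrained.

## Positional diversity

Variants are aligned at their sequenced 5′ start — the first retained base
after 5′ trimming, i.e. the base the sequencer reads first after the
common-sequence linker — never at parent coordinates.  Per position
1..N (default N = 16, the early cycles in which Illumina cluster
calibration happens), nucleotide frequencies are weighted by pool molarity
(equimolar by default).  Richness counts nucleotides with frequency > 0;
the Shannon index is H = −Σ p·ln p (natural log, 0·ln 0 ≡ 0, maximum
ln 4 ≈ 1.386).  Every variant must span all N positions; the default
16-base minimum-length design constraint guarantees this for N = 16.

For the synchronized (untrimmed, equimolar) pools these definitions give
the known reference values: 515F averages 18/16 = 1.125 nucleotides per
position and H̄ = 2·ln 2/16 ≈ 0.09; 806R averages 22/16 ≈ 1.38 and
H̄ = (ln 4 + ln 3 + ln 2)/16 ≈ 0.2.

## Evaluation statistics

**Ideal Score.**  Both abundance tables are renormalized to 100% (input
sums may deviate by ≤ 0.5, guarding against unit errors); taxa missing
from one table are imputed as 0; the score is Σ|expected − observed|,
which is symmetric, relabeling-invariant, 0 iff the tables agree, and
≤ 200.  Scoring sequenced observations requires an upstream
reads-to-abundances pipeline, which is out of scope here.

**Wilcoxon–Mann–Whitney.**  Mid-ranks are assigned to ties.  For
n + m ≤ 24 the two-sided p is exact: the null distribution of the rank sum
over all C(n+m, n) equally likely labelings is computed by dynamic
programming over doubled mid-ranks (doubling makes them integers; subset
counts stay below 2⁵³, so float64 accumulation is lossless), and the
smaller tail is doubled, capped at 1.  Larger samples use the
tie-corrected normal approximation with continuity correction.  The exact
path is validated against full enumeration for all n, m ≤ 5 and against
scipy's exact method on tie-free samples.

## Synthetic fixtures

`generate_fixture_primers` draws random degenerate primers (seeded NumPy
generator): a uniform A/C/G/T backbone of random length within the
requested range, then random positions upgraded to random ambiguity codes
until the degeneracy enters the requested range.  It emulates the
combinatorial structure of real degenerate primers — length, fold
degeneracy, code placement — but not their biology: no conservation
profile, GC constraints, or 3′-end design rules.  Property tests on these
fixtures therefore exercise the algorithms (expansion counts, constraint
satisfaction, optimizer bounds, determinism), not primer quality on real
loci; the EMP 515F/806R sequences serve as the realistic anchors.

## Numerical and design choices

* Variant ordering is lexicographic over expansion choices (A < C < G < T):
  reproducible pool indices; no canonical ordering exists for synthesized
  variant sets.
* Positions are 1-based in every user-facing report; internal offsets are
  0-based half-open.
* The linker is stored separately and excluded from thermodynamics,
  trimming, and the 16-position diversity window (the window starts at the
  locus-specific 5′ base; reference Tm ranges are linker-free).
* The minimum-length constraint applies to the locus-specific region, not
  the full synthesized oligo including linker.
* Degenerate-position retention is enforced by the harmonizer; the
  low-level `trim_variant` permits arbitrary trims for generality.
* WMW sidedness: two-sided by doubling the smaller tail (capped at 1);
  one-sided users can halve it externally.
* Problem sizes throughout are small — ≤ a few dozen variants × ≤ ~20
  candidate trims — so the full pipeline (both EMP primers) completes in
  about a second; tests and the acceptance script run the real
  computations, never cached values.

## Known limitations

* Tm values are model predictions calibrated to one published calculator's
  outputs within ±1 °C; absolute accuracy against measured melting curves
  is not claimed.
* Self-dimer scores ignore loops and dangling ends and are not comparable
  with full secondary-structure predictors.
* The harmonizer may find trims equal to or better (in range) than a
  published manual redesign, but it will generally not reproduce any
  specific published variant set: many optima exist, and a manual design
  need not be range-optimal under this thermodynamic model.
* Equal amplification of Tm-harmonized variants is an assumption about
  PCR, not a guarantee; primer utilization in real reactions also depends
  on template mismatches and annealing kinetics.
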