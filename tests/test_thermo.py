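"""Nearest-neighbor thermodynamics: sums, Tm corrections, self-dimers."""

import math

import pytest
from Bio.SeqUtils import MeltingTemp as mt
from hypothesis import given
from hypothesis import strategies as st

from poolmelt import (
    DegeneratePrimer,
    PrimerPool,
    PrimerVariant,
    ThermoConditions,
    dg37,
    expand,
    nn_sum,
    pool_tm_stats,
    reverse_complement,
    self_dimer,
    thermo_profile,
    tm,
)
from poolmelt.thermo import GAS_CONSTANT, parse_concentration

duplex_sequences = st.text(alphabet="ACGT", min_size=2, max_size=25)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class TestNNSums:
    # Hand sums from the published unified parameter tables:
    # AA duplex = one AA/TT stack + two terminal A/T initiations (+ general init).
    @pytest.mark.parametrize(
        "seq, table, expected_dh, expected_ds",
        [
            ("AA", "santalucia2004", 0.2 + 2 * 2.2 - 7.6, -5.7 + 2 * 6.9 - 21.3),
            ("AA", "santalucia1998", 0.0 + 2 * 2.3 - 7.9, 0.0 + 2 * 4.1 - 22.2),
            # ACGT = AC + CG + GT stacks + two A/T terminal initiations
            ("ACGT", "santalucia2004", 0.2 + 4.4 - 8.4 - 10.6 - 8.4, -5.7 + 13.8 - 22.4 - 27.2 - 22.4),
            ("ACGT", "santalucia1998", 0.0 + 4.6 - 8.4 - 10.6 - 8.4, 0.0 + 8.2 - 22.4 - 27.2 - 22.4),
        ],
    )
    def test_hand_sums(self, seq, table, expected_dh, expected_ds):
        dh, ds = nn_sum(seq, table)
        assert dh == pytest.approx(expected_dh, abs=1e-9)
        assert ds == pytest.approx(expected_ds, abs=1e-9)

    def test_length_one_rejected(self):
        with pytest.raises(ValueError):
            nn_sum("A")
        with pytest.raises(ValueError):
            tm("G")

    def test_degenerate_sequence_rejected(self):
        with pytest.raises(ValueError):
            nn_sum("ACRT")

    @given(duplex_sequences)
    def test_matches_library_accounting(self, seq):
        """nn_sum must reproduce the dH/dS used by the library Tm machinery:
        at 1 M Na+ the salt correction vanishes and Tm is the bare
        two-state formula."""
        dh, ds = nn_sum(seq, "santalucia2004")
        ct = 125e-9  # 250 nM / x=2
        expected = dh * 1000.0 / (ds + GAS_CONSTANT * math.log(ct)) - 273.15
        library = mt.Tm_NN(seq, nn_table=mt.DNA_NN4, dnac1=125, dnac2=0, Na=1000, saltcorr=3)
        assert expected == pytest.approx(library, abs=1e-6)

    @given(duplex_sequences)
    def test_dg37_definition_and_gcgc(self, seq):
        dh, ds = nn_sum(seq)
        assert dg37(seq) == pytest.approx(dh - 310.15 * ds / 1000.0)
        # frozen hand sum: GCGC = init + GC + CG + GC stacks
        assert dg37("GCGC") == pytest.approx(-30.0 + 310.15 * 81.7 / 1000.0, abs=1e-9)


class TestTm:
    @given(duplex_sequences)
    def test_duplex_symmetry(self, seq):
        rc = reverse_complement(seq)
        for cond in (ThermoConditions(), ThermoConditions(salt_correction="owczarzy")):
            assert tm(seq, cond) == pytest.approx(tm(rc, cond), abs=1e-9)
        assert nn_sum(seq) == pytest.approx(nn_sum(rc), abs=1e-9)

    @given(duplex_sequences, st.sampled_from([1e-9, 5e-8, 2.5e-7, 1e-6]))
    def test_tm_increases_with_oligo_concentration(self, seq, conc):
        low = tm(seq, ThermoConditions(oligo_conc=conc))
        high = tm(seq, ThermoConditions(oligo_conc=conc * 10))
        assert high >= low

    @given(duplex_sequences)
    def test_mg_free_limit_matches_monovalent_only(self, seq):
        """As free Mg2+ -> 0 the corrected Tm converges to the
        monovalent-only correction, in both schemes."""
        for scheme in ("na_eq", "owczarzy"):
            no_mg = tm(seq, ThermoConditions(mg=0.0, dntp=0.0, salt_correction=scheme))
            tiny = tm(seq, ThermoConditions(mg=1e-12, dntp=0.0, salt_correction=scheme))
            assert tiny == pytest.approx(no_mg, abs=1e-3)

    def test_chelation_zeroes_free_mg(self):
        cond = ThermoConditions(mg=0.2e-3, dntp=0.5e-3)
        assert cond.free_mg == 0.0

    def test_zero_oligo_concentration_rejected(self):
        with pytest.raises(ValueError):
            tm("ACGTACGT", ThermoConditions(oligo_conc=0.0))

    def test_no_cations_rejected(self):
        with pytest.raises(ValueError):
            tm("ACGTACGT", ThermoConditions(monovalent=0.0, mg=0.0))

    def test_pool_anchor_ranges(self, primer_515f, primer_806r):
        """Published pool extremes under the default assay conditions,
        to the declared +/-1.0 C model fidelity."""
        s515 = pool_tm_stats(expand(primer_515f))
        s806 = pool_tm_stats(expand(primer_806r))
        assert round(s515.tm_min, 1) == pytest.approx(66.9, abs=1.0)
        assert round(s515.tm_max, 1) == pytest.approx(71.8, abs=1.0)
        assert round(s806.tm_min, 1) == pytest.approx(54.7, abs=1.0)
        assert round(s806.tm_max, 1) == pytest.approx(61.7, abs=1.0)

    def test_original_806r_range_about_7_degrees(self, primer_806r):
        stats = pool_tm_stats(expand(primer_806r))
        assert stats.tm_range == pytest.approx(7.0, abs=1.0)

    def test_profile_consistency(self):
        prof = thermo_profile("GGACTACAAGGGTATCTAAT")
        assert prof.dh < 0 and prof.ds < 0
        assert prof.dg37 == pytest.approx(prof.dh - 310.15 * prof.ds / 1000.0)
        assert prof.tm_celsius == pytest.approx(tm(prof.sequence))


class TestPoolStats:
    def test_single_variant_range_zero(self):
        pool = PrimerPool(
            name="p", variants=(PrimerVariant(parent="p", index=0, sequence="ACGTACGT"),)
        )
        assert pool_tm_stats(pool).tm_range == 0.0

    def test_duplicate_variant_range_zero(self):
        v0 = PrimerVariant(parent="p", index=0, sequence="ACGTACGT")
        v1 = PrimerVariant(parent="p", index=1, sequence="ACGTACGT")
        assert pool_tm_stats(PrimerPool(name="p", variants=(v0, v1))).tm_range == 0.0


def _brute_force_self_dimer(seq, table_name="santalucia2004"):
    """Independent oracle: scan every antiparallel register position by
    position and sum stack dG37 over complementary runs of >= 2."""
    table = {"santalucia2004": mt.DNA_NN4, "santalucia1998": mt.DNA_NN3}[table_name]

    def stack_dg(dinuc):
        cd = _COMP[dinuc[0]] + _COMP[dinuc[1]]
        key = f"{dinuc}/{cd}"
        dh, ds = table[key] if key in table else table[key[::-1]]
        return dh - 310.15 * ds / 1000.0

    n = len(seq)
    best = 0.0
    for c in range(2 * n - 1):
        total = 0.0
        run = 0
        for i in range(n):
            j = c - i
            if 0 <= j < n and _COMP[seq[i]] == seq[j]:
                run += 1
                if run >= 2:
                    total += stack_dg(seq[i - 1: i + 1])
            else:
                run = 0
        best = min(best, total)
    return best


class TestSelfDimer:
    def test_poly_a_has_no_self_pairing(self):
        hit = self_dimer("AAAA")
        assert hit.dg == 0.0 and hit.paired_runs == ()

    def test_gcgc_full_self_complement(self):
        hit = self_dimer("GCGC")
        assert hit.paired_runs == ((1, 4),)
        # GC + CG + GC stacks, hand-summed
        assert hit.dg == pytest.approx(-9.8 - 10.6 - 9.8 + 310.15 * (24.4 + 27.2 + 24.4) / 1000.0)

    @given(st.text(alphabet="ACGT", min_size=2, max_size=12))
    def test_matches_brute_force_oracle(self, seq):
        assert self_dimer(seq).dg == pytest.approx(_brute_force_self_dimer(seq), abs=1e-9)

    @given(st.text(alphabet="ACGT", min_size=15, max_size=20))
    def test_matches_brute_force_on_20mers(self, seq):
        assert self_dimer(seq).dg == pytest.approx(_brute_force_self_dimer(seq), abs=1e-9)


class TestConcentrationParsing:
    @pytest.mark.parametrize(
        "text, molar",
        [("250nM", 250e-9), ("2 mM", 2e-3), ("0.05M", 0.05), ("1uM", 1e-6), ("0.001", 0.001)],
    )
    def test_unit_suffixes(self, text, molar):
        assert parse_concentration(text) == pytest.approx(molar)

    def test_duplex_factor_validated(self):
        with pytest.raises(ValueError):
            ThermoConditions(duplex_factor=3)
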