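"""Window scanning, composition binning and structure-profile tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lcdstruct.complexity import ComplexityParams
from lcdstruct.composition import (
    bin_profiles,
    category_fractions,
    composition_frequency_table,
    lcd_class_ss_profile,
    opposite_charge_mask,
    scan_windows,
    subsidiary_composition,
)
from lcdstruct.core import AMINO_ACIDS, CategoryMap

from .oracles import naive_bin_profile

CMAP = CategoryMap.default()
HET12 = "ACDEFGHIKLMN"


class TestScanWindows:
    def test_window_count_is_length_minus_width_plus_one(self, make_chain):
        chain = make_chain("ACDEFGHIKLMNPQRSTVWY")  # length 20
        assert len(list(scan_windows(chain, 12))) == 9

    def test_non_canonical_windows_omitted(self, make_chain):
        chain = make_chain("AAAAABAAAAAA")  # B -> X kills every window
        assert list(scan_windows(chain, 12)) == []

    def test_counts_sum_to_width(self, make_chain):
        (win,) = scan_windows(make_chain("AAAAAASSSSTT"), 12)
        assert win.counts.sum() == 12 and win.category_counts.sum() == 12

    def test_short_chain_empty(self, make_chain):
        assert list(scan_windows(make_chain("AAAA"), 12)) == []


class TestCategoryFractions:
    def test_half_helix_half_sheet(self, make_chain):
        (win,) = scan_windows(make_chain("AAAAAASSSSTT", "HHHHHHEEEEEE"), 12)
        frac = dict(zip(CMAP.names, category_fractions(win)))
        assert frac["alpha_helix"] == 0.5 and frac["beta_sheet"] == 0.5

    def test_disorder_overrides_codes(self, make_chain):
        (win,) = scan_windows(
            make_chain("AAAAAASSSSTT", "HHHHHHEEEEEE", "X" * 12), 12
        )
        frac = dict(zip(CMAP.names, category_fractions(win)))
        assert frac["disorder"] == 1.0 and frac["alpha_helix"] == 0.0

    def test_turn_bend_and_coil(self, make_chain):
        (win,) = scan_windows(make_chain("AAAAAASSSSTT", "TTSS        "), 12)
        frac = dict(zip(CMAP.names, category_fractions(win)))
        assert frac["turn_bend"] == pytest.approx(4 / 12)
        assert frac["loop_irregular"] == pytest.approx(8 / 12)


class TestCompositionFrequencyTable:
    def test_pure_run_hits_the_100pct_bin(self, make_chain):
        chain = make_chain("L" * 10 + HET12)
        table = composition_frequency_table([chain], widths=(10,))
        row = table[(table.amino_acid == "L") & (table.k == 10)]
        assert row.n_windows.item() == 1 and row.n_chains.item() == 1
        assert row.pct_composition.item() == 100.0

    def test_window_conservation_per_amino_acid(self, small_proteome):
        widths = (10, 12)
        table = composition_frequency_table(small_proteome.chains, widths)
        for w in widths:
            expected = sum(
                sum(
                    1
                    for s in range(len(c) - w + 1)
                    if "X" not in c.sequence[s : s + w]
                )
                for c in small_proteome.chains
            )
            for aa in AMINO_ACIDS:
                got = table[(table.amino_acid == aa) & (table.width == w)]
                assert got.n_windows.sum() == expected

    def test_chain_attainment_counts_each_chain_once(self, make_chain):
        tail = "CDEFGHIKLMNP"  # no alanine
        chains = [
            make_chain("A" * 10 + tail, chain_id="C0"),
            make_chain("A" * 11 + tail, chain_id="C1"),
        ]
        table = composition_frequency_table(chains, widths=(10,))
        row = table[(table.amino_acid == "A") & (table.k == 10)]
        assert row.n_chains.item() == 2
        assert row.n_windows.item() == 3  # one + two qualifying windows


class TestBinProfiles:
    def test_bin_mean_is_arithmetic_mean(self, make_chain):
        chains = [
            make_chain("AAAAAASSSSTT", "HHHHHH------"),  # helix fraction 0.5
            make_chain("AAAAAATTSSQQ", "HHHHHHHHHHHH"),  # helix fraction 1.0
        ]
        prof = bin_profiles(chains, "A", 12)
        row = prof.table.loc[6]
        assert row["n_windows"] == 2
        assert row["alpha_helix"] == pytest.approx(0.75)

    def test_empty_bin_is_nan_not_zero(self, make_chain):
        prof = bin_profiles([make_chain("AAAAAASSSSTT")], "A", 12)
        assert np.isnan(prof.table.loc[3, "alpha_helix"])
        assert prof.table.loc[3, "n_windows"] == 0

    def test_opposite_charge_filter_definition(self, make_chain):
        mixed = make_chain("KKKKKDAAAAAA")
        same = make_chain("KKKKKKAAAAAA")
        assert bin_profiles([mixed], "K", 12, True).table["n_windows"].sum() == 0
        assert bin_profiles([same], "K", 12, True).table["n_windows"].sum() == 1

    def test_filter_never_increases_bin_counts(self, small_proteome):
        for aa in "KDEAQ":
            plain = bin_profiles(small_proteome.chains, aa, 12, False)
            filt = bin_profiles(small_proteome.chains, aa, 12, True)
            assert (
                filt.table["n_windows"] <= plain.table["n_windows"]
            ).all()

    def test_category_means_sum_to_one(self, small_proteome):
        prof = bin_profiles(small_proteome.chains, "A", 12)
        occupied = prof.table[prof.table["n_windows"] > 0]
        sums = occupied[list(CMAP.names)].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_matches_naive_loop_oracle_exactly(self, small_proteome):
        for aa in "AVP":
            prof = bin_profiles(small_proteome.chains, aa, 12)
            n_ref, sums_ref = naive_bin_profile(small_proteome.chains, aa, 12, CMAP)
            for k in range(13):
                assert prof.table.loc[k, "n_windows"] == n_ref[k]
                if n_ref[k] == 0:
                    continue
                got = prof.table.loc[k, list(CMAP.names)].to_numpy(dtype=float)
                assert np.allclose(got, sums_ref[k] / n_ref[k], atol=1e-12)


class TestLcdClassProfile:
    def test_pure_helical_lcd_row(self, make_chain):
        chain = make_chain("A" * 12, "H" * 12)
        prof = lcd_class_ss_profile([chain])
        assert prof.loc["A", "alpha_helix"] == pytest.approx(1.0)

    def test_pdb_row_sums_to_one(self, small_proteome):
        prof = lcd_class_ss_profile(small_proteome.chains)
        assert prof.loc["PDB", list(CMAP.names)].sum() == pytest.approx(1.0)

    def test_pooled_lcd_row_matches_recount(self, small_proteome):
        params = ComplexityParams()
        prof = lcd_class_ss_profile(small_proteome.chains, params)
        total = np.zeros(CMAP.n_categories)
        n = 0
        from lcdstruct.complexity import window_counts, window_entropies
        from lcdstruct.composition import chain_window_arrays

        for chain in small_proteome.chains:
            counts, cats, valid = chain_window_arrays(chain, 12, CMAP)
            if counts.shape[0] == 0:
                continue
            ent = window_entropies(counts, 12)
            qual = valid & (ent <= params.entropy_threshold)
            total += (cats[qual] / 12.0).sum(axis=0)
            n += int(qual.sum())
        assert prof.loc["LCDs", "n_windows"] == n
        got = prof.loc["LCDs", list(CMAP.names)].to_numpy(dtype=float)
        assert np.allclose(got, total / n, atol=1e-12)

    def test_type_without_windows_is_nan(self, make_chain):
        prof = lcd_class_ss_profile([make_chain("A" * 12, "H" * 12)])
        assert np.isnan(prof.loc["W", "alpha_helix"])


class TestSubsidiaryComposition:
    def test_poly_a_rows(self, make_chain):
        table = subsidiary_composition([make_chain("A" * 12)])
        assert table.loc["A", "A"] == pytest.approx(1.0)

    def test_rows_sum_to_one_and_diagonal_dominates(self, small_proteome):
        table = subsidiary_composition(small_proteome.chains)
        occupied = table[table["n_windows"] > 0]
        sums = occupied[list(AMINO_ACIDS)].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        for aa in occupied.index:
            assert occupied.loc[aa, aa] >= 0.5 - 1e-12
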