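"""Window scans, frequency statistics, heat maps, supercharged detection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chargescape.charge_model import ResidueChargeTable, peptide_net_charge
from chargescape.charge_landscape import (
    charge_histogram,
    correlate_with_trait,
    find_supercharged,
    group_mean_window_profile,
    heatmap_matrix,
    nc_terminal_correlation,
    neg_pos_ratio_curve,
    per_position_mean_charge,
    scan_proteome,
    sign_fractions,
    window_scan,
)
from chargescape.proteome_io import ProteinRecord


def brute_force_windows(seq, table, window):
    """Independent oracle: net charge of each window by direct summation."""
    return [
        peptide_net_charge(seq[i : i + window], table)
        for i in range(len(seq) - window + 1)
    ]


class TestWindowScan:
    def test_single_all_positive_window(self):
        prof = window_scan("K" * 30)
        assert list(prof.window_charges) == [30]

    def test_slide_drops_and_adds(self):
        prof = window_scan("K" * 30 + "D")
        assert list(prof.window_charges) == [30, 28]

    def test_window_count_formula(self):
        assert window_scan("A" * 129).n_windows == 100

    def test_rolling_sum_equals_brute_force(self, random_records, default_table):
        for rec in random_records:
            prof = window_scan(rec, default_table)
            assert list(prof.window_charges) == brute_force_windows(
                rec.sequence, default_table, 30
            )

    def test_fractional_mode_matches_brute_force(self, random_records):
        table = ResidueChargeTable(rounding="three_decimals")
        for rec in random_records[:10]:
            prof = window_scan(rec, table)
            oracle = brute_force_windows(rec.sequence, table, 30)
            np.testing.assert_allclose(prof.window_charges, oracle, atol=2e-3)

    def test_short_protein_raises_but_proteome_scan_skips(self, caplog):
        with pytest.raises(ValueError):
            window_scan("MKA")
        records = [ProteinRecord(id="ok", sequence="A" * 40),
                   ProteinRecord(id="short", sequence="A" * 10)]
        with caplog.at_level("WARNING"):
            profiles = scan_proteome(records)
        assert len(profiles) == 1
        assert "skipped 1" in caplog.text

    def test_one_based_window_accessor(self):
        prof = window_scan("K" * 30 + "D" * 30)
        assert prof.window(1) == prof.first_window_charge == 30
        assert prof.window(prof.n_windows) == prof.last_window_charge == -30


class TestPerPositionMeans:
    def test_initiator_met_position_is_zero(self, random_records):
        means = per_position_mean_charge(random_records, region="first30")
        assert means[0] == 0.0

    def test_single_sequence_position_two(self):
        recs = [ProteinRecord(id="x", sequence="MK" + "A" * 28)]
        means = per_position_mean_charge(recs)
        assert means[1] == 1.0

    def test_last30_aligned_to_c_terminus(self):
        recs = [ProteinRecord(id="x", sequence="M" + "A" * 40 + "K")]
        means = per_position_mean_charge(recs, region="last30")
        assert means[-1] == 1.0
        assert means[:-1].sum() == 0.0

    def test_short_proteins_excluded_empty_raises(self):
        with pytest.raises(ValueError):
            per_position_mean_charge([ProteinRecord(id="s", sequence="MKA")])


class TestSignFractions:
    def test_example_thirds(self):
        frac = sign_fractions([1, 0, -1])
        assert frac.as_tuple() == (pytest.approx(1 / 3),) * 3

    def test_all_zero(self):
        assert sign_fractions([0, 0]).as_tuple() == (0.0, 1.0, 0.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            sign_fractions([])

    @settings(deadline=None)
    @given(st.lists(st.integers(min_value=-20, max_value=20), min_size=1, max_size=200))
    def test_fractions_sum_to_one(self, charges):
        frac = sign_fractions(charges)
        # counts are integers, so the fraction sum is exact up to division
        assert frac.positive + frac.neutral + frac.negative == pytest.approx(1.0, abs=1e-12)


class TestRatioCurve:
    def test_symmetric_histogram_all_ones(self):
        hist = {q: 5 for q in range(-4, 5)}
        curve = neg_pos_ratio_curve(hist)
        assert all(r == 1.0 for r in curve.values())

    def test_simple_ratio(self):
        assert neg_pos_ratio_curve({2: 10, -2: 20})[2] == 2.0

    def test_missing_when_no_positive_side(self):
        curve = neg_pos_ratio_curve({-5: 7})
        assert curve[5] is None  # distinct from 0.0

    def test_negated_proteome_gives_reciprocals(self, random_records, default_table):
        profiles = scan_proteome(random_records, default_table)
        charges = np.concatenate([p.window_charges for p in profiles])
        curve = neg_pos_ratio_curve(charge_histogram(charges))
        flipped = neg_pos_ratio_curve(charge_histogram(-charges))
        for q, ratio in curve.items():
            if ratio is None or ratio == 0.0:
                continue
            assert flipped[q] == pytest.approx(1.0 / ratio)


class TestHeatmap:
    def test_poly_k_nterm_all_tiles(self):
        prof = window_scan(ProteinRecord(id="k", sequence="K" * 300))
        hm = heatmap_matrix([prof], "nterm")
        assert hm.values.shape == (1, 100)
        assert (hm.values == 30).all()
        assert (hm.support == 1).all()

    def test_129aa_protein_exact_coverage(self):
        prof = window_scan(ProteinRecord(id="x", sequence="A" * 129))
        nterm = heatmap_matrix([prof], "nterm")
        assert (nterm.support == 1).all()
        core = heatmap_matrix([prof], "core")
        assert (core.support == 0).all()
        assert np.isnan(core.values).all()  # missing, never zero-filled

    def test_group_mean_and_support(self):
        p1 = window_scan(ProteinRecord(id="a", sequence="KK" + "A" * 120))
        p2 = window_scan(ProteinRecord(id="b", sequence="DDDD" + "A" * 120))
        hm = heatmap_matrix([p1, p2], "nterm", group_by={"a": "g", "b": "g"})
        assert hm.row_ids == ["g"]
        assert hm.values[0, 0] == pytest.approx((2 + -4) / 2)
        assert hm.support[0, 0] == 2

    def test_tile_support_never_exceeds_group_size(self, random_records):
        profiles = scan_proteome(random_records)
        group_by = {p.protein_id: "odd" if i % 2 else "even" for i, p in enumerate(profiles)}
        sizes = {"odd": sum(1 for v in group_by.values() if v == "odd")}
        sizes["even"] = len(profiles) - sizes["odd"]
        for region in ("nterm", "core", "cterm"):
            hm = heatmap_matrix(profiles, region, group_by=group_by)
            for i, label in enumerate(hm.row_ids):
                assert hm.support[i].max() <= sizes[label]

    def test_single_protein_row_equals_profile(self, random_records):
        prof = window_scan(random_records[0])
        hm = heatmap_matrix([prof], "nterm")
        np.testing.assert_array_equal(hm.values[0], prof.window_charges[:100])

    def test_cterm_alignment(self):
        # 60 aa: 31 windows; final window (start 31) covers the last 30 residues
        prof = window_scan(ProteinRecord(id="x", sequence="A" * 30 + "K" * 30))
        hm = heatmap_matrix([prof], "cterm")
        assert hm.starts[-1] == -30
        assert hm.values[0, -1] == 30

    def test_unknown_region_raises(self):
        with pytest.raises(ValueError):
            heatmap_matrix([], "middle")


class TestGroupProfiles:
    def test_single_protein_group_equals_prefix(self, random_records):
        rec = random_records[0]
        prof = window_scan(rec)
        out = group_mean_window_profile([rec], upto_start=100, group_by={rec.id: "g"})
        means, support = out["g"]
        np.testing.assert_array_equal(means[: prof.n_windows], prof.window_charges[:100])
        assert (support[: min(prof.n_windows, 100)] == 1).all()

    def test_empty_group_omitted_with_warning(self, random_records, caplog):
        group_by = {random_records[0].id: "present", "GHOST": "absent"}
        with caplog.at_level("WARNING"):
            out = group_mean_window_profile(random_records, group_by=group_by)
        assert "absent" not in out
        assert "omitting empty group" in caplog.text

    def test_planted_bias_separates_groups(self):
        biased = [ProteinRecord(id=f"b{i}", sequence="M" + "K" * 10 + "A" * 100)
                  for i in range(5)]
        flat = [ProteinRecord(id=f"f{i}", sequence="M" + "A" * 110) for i in range(5)]
        group_by = {r.id: ("biased" if r.id.startswith("b") else "flat") for r in biased + flat}
        out = group_mean_window_profile(biased + flat, group_by=group_by)
        assert (out["biased"][0][:10] > out["flat"][0][:10]).all()


class TestCorrelations:
    def test_identical_first_last_r2_one(self):
        # palindromic charge layout: first and last windows share the charge
        recs = [
            ProteinRecord(id=f"p{i}", sequence="K" * i + "A" * (60 - 2 * i) + "K" * i)
            for i in range(1, 8)
        ]
        res = nc_terminal_correlation(recs)
        assert res.r_squared == pytest.approx(1.0)
        assert res.n == 7

    def test_uncorrelated_simulation_near_zero(self, rng):
        recs = []
        for i in range(1000):
            first = "".join(rng.choice(list("KDA"), size=30))
            last = "".join(rng.choice(list("KDA"), size=30))
            recs.append(ProteinRecord(id=f"u{i}", sequence=first + last))
        res = nc_terminal_correlation(recs)
        assert res.r_squared < 0.01

    def test_constant_first_window_reported_missing(self):
        recs = [ProteinRecord(id=f"c{i}", sequence="A" * 30 + "K" * i + "A" * (30 - i))
                for i in range(5)]
        res = nc_terminal_correlation(recs)
        assert math.isnan(res.coefficient)

    def test_short_proteins_excluded_and_min_n(self):
        recs = [ProteinRecord(id="s", sequence="A" * 59)] * 1 + [
            ProteinRecord(id=f"l{i}", sequence="A" * 60) for i in range(2)
        ]
        with pytest.raises(ValueError, match="at least 3"):
            nc_terminal_correlation(recs)


class TestTraitCorrelation:
    def test_gaussian_linear_uses_pearson(self, rng):
        x = rng.normal(size=500)
        y = 2 * x + rng.normal(scale=0.5, size=500)
        res = correlate_with_trait(x, y)
        assert res.method == "pearson"
        assert res.coefficient > 0.9

    def test_heavy_tails_fall_back_to_spearman(self, rng):
        x = rng.lognormal(sigma=2.0, size=500)
        y = x + rng.lognormal(sigma=2.0, size=500)
        res = correlate_with_trait(x, y)
        assert res.method == "spearman"

    def test_constant_margin_missing(self):
        res = correlate_with_trait([1.0] * 10, list(range(10)))
        assert math.isnan(res.coefficient)

    def test_small_n_instructs_explicit_choice(self):
        with pytest.raises(ValueError, match="explicit"):
            correlate_with_trait([1, 2, 3], [1, 2, 3])


class TestSupercharged:
    def test_positive_stretch_with_context(self):
        prof = window_scan("K" * 30 + "A" * 30)
        stretches = find_supercharged(prof)
        assert len(stretches) == 1
        s = stretches[0]
        assert (s.start, s.peak_charge, s.sign) == (1, 30.0, 1)
        assert s.context == "K" * 30 + "A" * 30
        assert not s.truncated

    def test_no_stretch_in_neutral_protein(self):
        assert find_supercharged(window_scan("A" * 100)) == []

    def test_negative_stretch_and_truncation(self):
        prof = window_scan("D" * 30 + "A" * 10)
        stretches = find_supercharged(prof)
        assert len(stretches) == 1
        assert stretches[0].sign == -1
        assert stretches[0].truncated
        assert stretches[0].context == "D" * 30 + "A" * 10

    def test_overlapping_windows_collapse_to_one_run(self):
        # 40 consecutive K: windows starting 1..27 hold >= 14 of them,
        # collapsing into a single maximal run
        prof = window_scan("K" * 40 + "A" * 30)
        stretches = find_supercharged(prof)
        assert len(stretches) == 1
        assert (stretches[0].start, stretches[0].end) == (1, 27)
        assert stretches[0].peak_charge == 30.0
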