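"""Generators: determinism, planted structure, analytic expectations."""

import numpy as np
import pytest

from chargescape.charge_landscape import find_supercharged, per_position_mean_charge, window_scan
from chargescape.ribo_occupancy import metagene, occupancy_analysis
from chargescape.synthetic_data import (
    PositionalBias,
    ProteomeGenSpec,
    RiboGenSpec,
    SuperchargePlant,
    default_occupancy_response,
    expected_position_charge,
    gen_mp_scores,
    gen_proteome,
    gen_ribo_counts,
)


class TestProteomeGen:
    def test_same_seed_identical(self):
        spec = ProteomeGenSpec(n_proteins=50, seed=7, signal_fraction=0.2)
        recs1, truth1 = gen_proteome(spec)
        recs2, truth2 = gen_proteome(spec)
        assert [r.sequence for r in recs1] == [r.sequence for r in recs2]
        assert truth1.equals(truth2)

    def test_different_seed_differs(self):
        recs1, _ = gen_proteome(ProteomeGenSpec(n_proteins=20, seed=1))
        recs2, _ = gen_proteome(ProteomeGenSpec(n_proteins=20, seed=2))
        assert any(a.sequence != b.sequence for a, b in zip(recs1, recs2))

    def test_all_start_with_met_and_min_length(self):
        recs, _ = gen_proteome(ProteomeGenSpec(n_proteins=100, seed=3))
        assert all(r.sequence[0] == "M" for r in recs)
        assert all(len(r) >= 60 for r in recs)

    def test_planted_supercharged_recovered_at_offset(self):
        spec = ProteomeGenSpec(
            n_proteins=30, seed=5, supercharged=SuperchargePlant(count=10, target=15, offset=40)
        )
        recs, truth = gen_proteome(spec)
        planted = truth[truth.feature == "supercharged"]
        assert len(planted) == 10
        by_id = {r.id: r for r in recs}
        for row in planted.itertuples(index=False):
            stretches = find_supercharged(window_scan(by_id[row.accession]))
            assert row.offset in [s.start for s in stretches]
            hit = next(s for s in stretches if s.start == row.offset)
            assert hit.peak_charge == row.target

    def test_negative_supercharged_plant(self):
        spec = ProteomeGenSpec(
            n_proteins=5, seed=5, supercharged=SuperchargePlant(count=5, target=-14, offset=35)
        )
        recs, truth = gen_proteome(spec)
        for rec in recs:
            stretches = find_supercharged(window_scan(rec))
            assert any(s.start == 35 and s.sign == -1 for s in stretches)

    def test_infeasible_target_rejected(self):
        spec = ProteomeGenSpec(
            n_proteins=5, seed=0, supercharged=SuperchargePlant(count=1, target=31)
        )
        with pytest.raises(ValueError, match="infeasible"):
            gen_proteome(spec)

    def test_planted_nterm_charges_exact(self):
        targets = tuple(range(-8, 9))
        spec = ProteomeGenSpec(n_proteins=len(targets), seed=9, nterm_charges=targets)
        recs, _ = gen_proteome(spec)
        for rec, target in zip(recs, targets):
            assert window_scan(rec).first_window_charge == target
            assert rec.sequence[0] == "M"

    def test_signal_fraction_flags(self):
        recs, truth = gen_proteome(ProteomeGenSpec(n_proteins=100, seed=2, signal_fraction=0.3))
        flagged = [r for r in recs if r.has_signal_peptide]
        assert len(flagged) == 30
        assert set(truth[truth.feature == "signal_peptide"].accession) == {
            r.id for r in flagged
        }

    def test_positional_bias_shifts_expected_charge(self):
        spec = ProteomeGenSpec(
            n_proteins=1, seed=0, biases=(PositionalBias("KR", 3, 10, 0.15),)
        )
        flat = ProteomeGenSpec(n_proteins=1, seed=0)
        biased_mean, _ = expected_position_charge(spec, 5)
        base_mean, _ = expected_position_charge(flat, 5)
        outside_mean, _ = expected_position_charge(spec, 20)
        assert biased_mean > base_mean
        assert outside_mean == pytest.approx(base_mean)

    def test_bias_recovery_within_3se(self):
        # planted K/R boost at positions 3..10 recovered by positional means
        spec = ProteomeGenSpec(
            n_proteins=800, seed=17, biases=(PositionalBias("KR", 3, 10, 0.15),)
        )
        recs, _ = gen_proteome(spec)
        means = per_position_mean_charge(recs)
        for pos in (3, 6, 10, 15, 25):
            mu, var = expected_position_charge(spec, pos)
            se = np.sqrt(var / len(recs))
            assert abs(means[pos - 1] - mu) <= 3 * se


class TestRiboGen:
    def test_flat_response_gives_flat_metagene(self):
        recs, _ = gen_proteome(ProteomeGenSpec(n_proteins=150, seed=4))
        profiles, expectation = gen_ribo_counts(
            recs, RiboGenSpec(seed=4, response=lambda q: 1.0, noise="poisson")
        )
        curve = metagene(profiles, metagene_length=120)
        # flat at 1.0 up to Monte-Carlo noise: no start-codon ramp
        assert np.nanmean(curve.mean) == pytest.approx(1.0, abs=0.02)
        assert np.nanmax(np.abs(curve.mean - 1.0)) < 0.3
        assert abs(curve.mean[:30].mean() - curve.mean[90:].mean()) < 0.05
        np.testing.assert_allclose(expectation["expected_auc_ratio"], 1.0)

    def test_depth_scaling_leaves_auc_ratio_unchanged(self):
        charges = tuple([8] * 40 + [0] * 40)
        recs, _ = gen_proteome(ProteomeGenSpec(n_proteins=80, seed=6, nterm_charges=charges))
        profiles, _ = gen_ribo_counts(recs, RiboGenSpec(seed=6))
        _, auc1 = occupancy_analysis(recs, profiles)
        for p in profiles:
            p.counts = p.counts * 10
        _, auc10 = occupancy_analysis(recs, profiles)
        merged = auc1.merge(auc10, on="group")
        np.testing.assert_allclose(
            merged["auc_ratio_vs_reference_x"], merged["auc_ratio_vs_reference_y"], atol=1e-12
        )

    def test_expectation_table_is_closed_form(self):
        # one gene per group, uniform length: ratio = m*L/(91*m + L - 91)
        charges = (8, 0)
        recs, _ = gen_proteome(
            ProteomeGenSpec(n_proteins=2, seed=8, nterm_charges=charges,
                            length_log_sigma=0.0, length_log_mean=np.log(300))
        )
        length = len(recs[0].sequence)
        assert len(recs[1].sequence) == length
        _, expectation = gen_ribo_counts(recs, RiboGenSpec(seed=8))
        m = default_occupancy_response(8)
        analytic = (m * length / (91 * m + length - 91)) / (length / length)
        got = expectation.set_index("group").loc[">=+8", "expected_auc_ratio"]
        assert got == pytest.approx(analytic, rel=1e-9)

    def test_determinism(self):
        recs, _ = gen_proteome(ProteomeGenSpec(n_proteins=30, seed=10))
        p1, _ = gen_ribo_counts(recs, RiboGenSpec(seed=3))
        p2, _ = gen_ribo_counts(recs, RiboGenSpec(seed=3))
        assert all((a.counts == b.counts).all() for a, b in zip(p1, p2))

    def test_nonpositive_multiplier_rejected(self):
        recs, _ = gen_proteome(ProteomeGenSpec(n_proteins=5, seed=0))
        with pytest.raises(ValueError, match="positive"):
            gen_ribo_counts(recs, RiboGenSpec(seed=0, response=lambda q: 0.0))


class TestMPScores:
    def test_same_seed_identical(self):
        recs, _ = gen_proteome(ProteomeGenSpec(n_proteins=40, seed=12))
        s1 = gen_mp_scores(recs, seed=5)
        s2 = gen_mp_scores(recs, seed=5)
        assert s1.equals(s2)

    def test_charge_coupling_sign(self):
        charges = tuple([6] * 150 + [-6] * 150)
        recs, _ = gen_proteome(ProteomeGenSpec(n_proteins=300, seed=13, nterm_charges=charges))
        scores = gen_mp_scores(recs, coupling_charge=0.5, noise_sd=0.5, seed=13)
        pos = scores.iloc[:150]["mp_score"].mean()
        neg = scores.iloc[150:]["mp_score"].mean()
        assert pos > neg + 3.0  # planted effect: 0.5 * 12 = 6 score units apart

    def test_orf_lengths_consistent_with_sequence(self):
        recs, _ = gen_proteome(ProteomeGenSpec(n_proteins=10, seed=14))
        scores = gen_mp_scores(recs, seed=14)
        for rec, orf in zip(recs, scores["orf_length_nt"]):
            assert orf == 3 * (len(rec.sequence) + 1)
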