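"""Synthetic-experiment generator: round-trip fidelity and recovery."""

import numpy as np
import pandas as pd
import pytest

import osrt
from osrt.simulate import SimulationParams


class TestParams:
    def test_curve_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(p_attempt=(0.5,) * 8, p_grammar=(0.5,) * 6,
                             p_sequence=(0.5,) * 8)

    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            SimulationParams(carryover_prob=1.2)

    def test_scenarios_have_expected_shapes(self):
        sc = osrt.default_scenarios()
        fs = sc["fs-learner"]
        assert fs.group == "FS" and fs.n_blocks == 8
        # rising sequence knowledge over the learning blocks
        assert list(fs.p_sequence[:6]) == sorted(fs.p_sequence[:6])
        rs = sc["rs-grammar-only"]
        assert rs.n_blocks == 6 and all(p == 0.5 for p in rs.p_sequence)
        null = sc["null"]
        assert len(set(null.p_attempt)) == 1 == len(set(null.p_grammar))


class TestSimulateParticipant:
    def test_task_timing_respected(self, fs_stream):
        params = osrt.default_scenarios()["fs-learner"]
        _, events, _ = osrt.simulate_participant(params, fs_stream, seed=3)
        assert len(events) == 864
        dur = events["offset_ms"] - events["onset_ms"]
        assert (dur <= 3000).all()
        gaps = events["onset_ms"].to_numpy()[1:] - events["offset_ms"].to_numpy()[:-1]
        assert np.allclose(gaps, 500.0)  # ISI duration

    def test_round_trip_identity_without_noise(self, noise_free_participant):
        rec = noise_free_participant["records"]
        truth = noise_free_participant["truth"]
        m = rec.merge(truth, on=["participant", "trial", "block"], how="left")
        usable = m[m["usable"]]
        assert (usable["semantic"] == usable["label"]).mean() == 1.0

    def test_no_attempts_means_all_stuck(self, fs_stream):
        params = SimulationParams(p_attempt=(0.0,) * 8).noise_free()
        gaze, events, truth = osrt.simulate_participant(params, fs_stream, seed=5)
        rec = osrt.classify_isis(gaze, events, fs_stream, osrt.semantic_table())
        usable = rec[rec["usable"]]
        assert (usable["semantic"] == "stuck").all()

    def test_certain_attempts_all_main(self, fs_stream):
        params = SimulationParams(p_attempt=(1.0,) * 8, p_grammar=(1.0,) * 8,
                                  p_sequence=(1.0,) * 8).noise_free()
        gaze, events, _ = osrt.simulate_participant(params, fs_stream, seed=5)
        rec = osrt.classify_isis(gaze, events, fs_stream, osrt.semantic_table())
        usable = rec[rec["usable"] & (rec["block"] != 7)]
        assert (usable["semantic"] == "main").all()

    def test_carryover_rate_recovered(self, fs_stream):
        params = SimulationParams(multi_region_prob=1.0, carryover_prob=0.9)
        gaze, events, truth = osrt.simulate_participant(params, fs_stream, seed=13)
        rec = osrt.classify_isis(gaze, events, fs_stream, osrt.semantic_table())
        # among ISIs whose final anticipation moved away from the previous
        # target, count those whose first ISI fixation stayed on it
        fixes = osrt.detect_fixations(gaze)
        onsets = events["onset_ms"].to_numpy()
        offsets = events["offset_ms"].to_numpy()
        first_on_prev = []
        for t in range(1, len(onsets)):
            sel = fixes[(fixes["offset"] > offsets[t - 1])
                        & (fixes["onset"] <= onsets[t])]
            if len(sel) < 2:
                continue
            first = sel.iloc[0]
            region = osrt.assign_region(first["x"], first["y"])
            first_on_prev.append(region == events["target_loc"].iloc[t - 1])
        rate = np.mean(first_on_prev)
        # binomial tolerance at ~500+ multi-region ISIs
        assert rate == pytest.approx(0.9, abs=0.05)

    def test_block_rates_recover_latent_curves(self, fs_stream):
        params = osrt.default_scenarios()["fs-learner"]
        gaze, events, truth = osrt.simulate_participant(params, fs_stream, seed=17)
        rec = osrt.classify_isis(gaze, events, fs_stream, osrt.semantic_table())
        rates = osrt.block_rates(rec)
        for b in (1, 4, 6):
            pa = params.p_attempt[b - 1]
            pg = params.p_grammar[b - 1]
            ps = params.p_sequence[b - 1]
            expect_main = 100 * pa * pg * ps
            expect_stuck = 100 * ((1 - pa) + pa * (1 - pg)
                                  * params.ungrammatical_stuck_ratio)
            row = rates[rates["block"] == b].iloc[0]
            n = row["n_usable"]
            # ~4 binomial standard errors
            tol_main = 400 * np.sqrt(expect_main / 100 * (1 - expect_main / 100) / n)
            tol_stuck = 400 * np.sqrt(expect_stuck / 100 * (1 - expect_stuck / 100) / n)
            assert row["pct_main"] == pytest.approx(expect_main, abs=tol_main)
            assert row["pct_stuck"] == pytest.approx(expect_stuck, abs=tol_stuck)


class TestSimulateCohort:
    def test_same_master_seed_reproduces_cohort(self):
        params = osrt.default_scenarios()["null"]
        g1, e1, t1, s1 = osrt.simulate_cohort(3, params, seed=99)
        g2, e2, t2, s2 = osrt.simulate_cohort(3, params, seed=99)
        pd.testing.assert_frame_equal(g1, g2)
        pd.testing.assert_frame_equal(e1, e2)
        assert np.array_equal(s1.targets, s2.targets)

    def test_zero_between_sd_keeps_curves_identical(self, fs_stream):
        params = osrt.default_scenarios()["fs-learner"]
        _, events, truth, _ = osrt.simulate_cohort(3, params, between_sd=0.0, seed=4)
        # identical latent curves: per-participant stuck rates agree within
        # binomial noise; just assert the draw used the same parameters by
        # checking attempt rates are near the shared curve
        att = truth.groupby(["participant", "block"])["attempt"].mean().unstack()
        for b in (1, 8):
            assert att[b].std() < 0.08

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            osrt.simulate_cohort(3, "null", between_sd=-0.1, seed=1)

    def test_group_design_sizes(self):
        fs = osrt.default_scenarios()["fs-learner"]
        rs = osrt.default_scenarios()["rs-grammar-only"]
        _, e_fs, _, s_fs = osrt.simulate_cohort(2, fs, seed=1)
        _, e_rs, _, s_rs = osrt.simulate_cohort(2, rs, seed=1)
        assert len(s_fs) == 864 and len(s_rs) == 648
        assert e_fs.groupby("participant").size().eq(864).all()
        assert e_rs.groupby("participant").size().eq(648).all()

    def test_rs_grammar_only_splits_grammatical_labels_evenly(self):
        rs = osrt.default_scenarios()["rs-grammar-only"]
        gaze, events, truth, stream = osrt.simulate_cohort(2, rs, between_sd=0.0,
                                                           seed=6)
        rec = osrt.classify_isis(gaze, events, stream, osrt.semantic_table())
        rates = osrt.block_rates(rec)
        diff = (rates["pct_main"] - rates["pct_interference"]).mean()
        assert abs(diff) < 6.0  # chance-level sequence choice
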