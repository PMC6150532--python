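"""The synthetic-data generator: determinism, construction guarantees, and
consistency with the analysis modules that consume its output."""

import numpy as np
import pandas as pd
import pytest

from usvdyad.behavior import classify_session
from usvdyad.io import default_geometry
from usvdyad.synth import (
    BehaviorScript,
    BoutSpec,
    EmissionEvent,
    SexEffectSpec,
    ValidationError,
    make_dyad_events,
    simulate_array_audio,
    simulate_feature_table,
    simulate_trajectories,
    synth_usv,
)


class TestTrajectories:
    def test_scripted_bouts_are_recovered_exactly(self):
        script = BehaviorScript(
            bouts=[
                BoutSpec("following", 40, 20, leader_id="male"),
                BoutSpec("not_close", 100, 25),
                BoutSpec("following", 200, 30, leader_id="female"),
            ],
            n_frames=300,
        )
        tracks, _ = simulate_trajectories(script, seed=3)
        got = sorted(
            (iv.mouse_id, iv.kind, iv.start_frame, iv.end_frame)
            for iv in classify_session(tracks["male"], tracks["female"])
        )
        assert got == sorted(
            [
                ("female", "following", 40, 59),
                ("male", "followed", 40, 59),
                ("male", "not_close", 100, 124),
                ("female", "not_close", 100, 124),
                ("male", "following", 200, 229),
                ("female", "followed", 200, 229),
            ]
        )

    def test_nine_frame_bout_is_rejected_by_classifier(self):
        script = BehaviorScript(bouts=[BoutSpec("following", 50, 9, leader_id="male")], n_frames=150)
        tracks, _ = simulate_trajectories(script, seed=4)
        assert classify_session(tracks["male"], tracks["female"]) == []

    def test_not_close_distance_at_least_15cm_by_construction(self):
        script = BehaviorScript(bouts=[BoutSpec("not_close", 20, 40)], n_frames=100)
        tracks, labels = simulate_trajectories(script, seed=5)
        d = np.hypot(*(tracks["male"].xy - tracks["female"].xy).T)
        assert np.all(d[20:60] >= 0.15)
        assert np.all(d[:20] < 0.15)

    def test_positions_stay_inside_arena(self):
        tracks, _ = simulate_trajectories(BehaviorScript(bouts=[], n_frames=500), seed=6)
        for tr in tracks.values():
            assert np.all(tr.xy >= 0) and np.all(tr.xy <= 0.762)

    def test_headings_match_movement_direction(self):
        from usvdyad.behavior import kinematics

        tracks, _ = simulate_trajectories(BehaviorScript(bouts=[], n_frames=200), seed=7)
        tr = tracks["male"]
        _, direction = kinematics(tr)
        mid = slice(10, 190)
        diff = np.abs(np.angle(np.exp(1j * (direction[mid] - tr.heading[mid]))))
        assert np.nanmax(diff) < np.deg2rad(5)

    def test_same_seed_identical_tracks(self):
        script = BehaviorScript(bouts=[BoutSpec("following", 10, 15, leader_id="male")], n_frames=60)
        t1, _ = simulate_trajectories(script, seed=8)
        t2, _ = simulate_trajectories(script, seed=8)
        np.testing.assert_array_equal(t1["male"].xy, t2["male"].xy)
        np.testing.assert_array_equal(t1["female"].heading, t2["female"].heading)

    def test_overlapping_bouts_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            BehaviorScript(
                bouts=[BoutSpec("following", 0, 20, leader_id="male"), BoutSpec("not_close", 10, 20)],
                n_frames=100,
            )

    def test_bout_past_session_end_rejected(self):
        with pytest.raises(ValidationError):
            BehaviorScript(bouts=[BoutSpec("not_close", 90, 20)], n_frames=100)


class TestChirps:
    def test_sample_count(self):
        ev = EmissionEvent("m", 0.0, 0.020, 70_000, 70_000)
        assert len(synth_usv(ev, 250_000)) == 5000

    def test_instantaneous_frequency_is_linear(self):
        ev = EmissionEvent("m", 0.0, 0.020, 60_000, 80_000)
        w = synth_usv(ev, 250_000)
        # analytic instantaneous frequency from the Hilbert phase
        from scipy.signal import hilbert

        phase = np.unwrap(np.angle(hilbert(w)))
        inst = np.diff(phase) / (2 * np.pi) * 250_000
        core = inst[500:-500]  # skip envelope ramps
        t = np.arange(len(w) - 1)[500:-500] / 250_000
        expect = 60_000 + 1e6 * t
        assert np.max(np.abs(core - expect)) < 500

    def test_nyquist_violation_raises(self):
        ev = EmissionEvent("m", 0.0, 0.02, 100_000, 110_000)
        with pytest.raises(ValidationError, match="sample rate"):
            synth_usv(ev, 200_000)

    def test_band_limits_enforced(self):
        with pytest.raises(ValidationError):
            EmissionEvent("m", 0.0, 0.02, 20_000, 70_000)


class TestArrayAudio:
    def test_equidistant_source_gives_identical_channels_up_to_gain(self):
        # mouse on the vertical centreline (nose displaced +y): microphone
        # pairs mirror-symmetric about that line receive identical audio
        from usvdyad.behavior import MouseTrack

        geo = default_geometry()
        centre = np.array([0.381, 0.381])
        track = MouseTrack(
            "m",
            np.tile(centre, (40, 1)),
            np.full(40, 0.07),
            np.full(40, 0.03),
            np.full(40, np.pi / 2),
        )
        ev = EmissionEvent("m", 0.1, 0.02, 60_000, 80_000)
        audio, truth = simulate_array_audio({"m": track}, [ev], geo, noise_sd=0.0, seed=0)
        # mics 0/2 = bottom corners, 4/6 = top corners, 3/7 = side midpoints
        for a, b in ((0, 2), (4, 6), (3, 7)):
            np.testing.assert_allclose(audio[:, a], audio[:, b], atol=1e-12)

    def test_zero_events_gives_pure_noise_or_silence(self):
        tracks, _ = simulate_trajectories(BehaviorScript(bouts=[], n_frames=30), seed=1)
        audio, truth = simulate_array_audio(tracks, [], default_geometry(), noise_sd=0.0, seed=2)
        assert np.all(audio == 0)
        assert len(truth) == 0

    def test_event_outside_track_duration_rejected(self):
        tracks, _ = simulate_trajectories(BehaviorScript(bouts=[], n_frames=30), seed=1)
        ev = EmissionEvent("male", 5.0, 0.02, 60_000, 70_000)
        with pytest.raises(ValidationError, match="duration"):
            simulate_array_audio(tracks, [ev], default_geometry())

    def test_same_seed_identical_audio(self):
        tracks, _ = simulate_trajectories(BehaviorScript(bouts=[], n_frames=60), seed=1)
        events = make_dyad_events(tracks, 3, seed=2)
        a1, _ = simulate_array_audio(tracks, events, default_geometry(), noise_sd=0.01, seed=9)
        a2, _ = simulate_array_audio(tracks, events, default_geometry(), noise_sd=0.01, seed=9)
        np.testing.assert_array_equal(a1, a2)


class TestFeatureTables:
    def test_default_male_bandwidth_median_matches_spec(self):
        table = simulate_feature_table(
            n_sessions=1, counts_per_sex={"male": 100_000, "female": 100_000}, seed=11
        )
        males = table[table["emitter"] == "male"]
        females = table[table["emitter"] == "female"]
        assert abs(males["bandwidth_hz"].median() - 7_900) / 7_900 < 0.02
        assert abs(females["bandwidth_hz"].median() - 6_100) / 6_100 < 0.02

    def test_identical_sexes_straddle_zero(self):
        from usvdyad.stats import monte_carlo_index

        eff = SexEffectSpec()
        eff.bandwidth_hz["female"] = eff.bandwidth_hz["male"]
        table = simulate_feature_table(
            n_sessions=1, counts_per_sex={"male": 50_000, "female": 50_000}, effects=eff, seed=12
        )
        dist = monte_carlo_index(table, "bandwidth_hz", seed=13)
        # the index distribution straddles zero: ~50% positive, allowing
        # for the finite table's own median offset
        assert 400 <= dist.n_positive <= 600

    def test_feature_invariants_hold_rowwise(self):
        table = simulate_feature_table(n_sessions=3, seed=14)
        np.testing.assert_allclose(
            table["bandwidth_hz"], table["high_freq_hz"] - table["low_freq_hz"], rtol=0, atol=1e-9
        )
        assert (table["low_freq_hz"] <= table["mean_freq_hz"]).all()
        assert (table["mean_freq_hz"] <= table["high_freq_hz"]).all()
        assert (table["low_freq_hz"] >= 30_000).all()
        assert (table["high_freq_hz"] <= 110_000).all()

    def test_marginals_are_non_gaussian(self):
        from usvdyad.stats import ks_nongaussian

        table = simulate_feature_table(
            n_sessions=1, counts_per_sex={"male": 5_000, "female": 50}, seed=15
        )
        males = table[table["emitter"] == "male"]
        assert ks_nongaussian(males["bandwidth_hz"].to_numpy()) < 0.01

    def test_males_outnumber_females_per_session(self):
        table = simulate_feature_table(n_sessions=6, seed=16)
        counts = table.groupby(["date", "emitter"]).size().unstack()
        assert (counts["male"] > counts["female"]).mean() >= 5 / 6

    def test_same_seed_identical_tables(self):
        t1 = simulate_feature_table(n_sessions=2, seed=17)
        t2 = simulate_feature_table(n_sessions=2, seed=17)
        pd.testing.assert_frame_equal(t1, t2)

    def test_nonpositive_scale_rejected(self):
        eff = SexEffectSpec()
        eff.bandwidth_hz["male"] = (7_900.0, -0.1)
        with pytest.raises(ValidationError):
            SexEffectSpec(bandwidth_hz=eff.bandwidth_hz)
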