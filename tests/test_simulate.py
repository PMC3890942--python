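import numpy as np
import pytest

from percross import (
    EnvConfig,
    ScannerAgent,
    SimulationError,
    StationaryAgent,
    TurnTakerAgent,
    generate_dataset,
    make_scanner_agent,
    make_turn_taker_agent,
    simulate_trial,
    turn_taking_score,
    binarize_movement,
)


class _BadAgent(StationaryAgent):
    def step(self, t, pos, stim_prev):
        return float("nan"), False


class TestSimulateTrial:
    def test_stationary_pair_without_overlap_has_no_stimulation(self, short_cfg):
        rec = simulate_trial(
            [StationaryAgent(), StationaryAgent()],
            short_cfg,
            seed=1,
            starts=[0.0, 300.0],
            static_pos=[100.0, 400.0],
        )
        assert not rec.stim(0).any() and not rec.stim(1).any()
        assert rec.clicks == []
        assert np.array_equal(rec.pos[:, 0], rec.pos[:, -1])

    def test_full_circle_traverse_hits_expected_objects(self, short_cfg):
        # player 0 sweeps the whole circle at 1 unit/step while player 1 parks;
        # stimulation occurs exactly near the partner avatar, partner shadow
        # and own static, at hand-computable steps
        rec = simulate_trial(
            [ScannerAgent(speed=1.0, span=600.0), StationaryAgent()],
            short_cfg,
            seed=1,
            starts=[0.0, 300.0],
            static_pos=[100.0, 500.0],
        )
        # during the outward sweep pos[t] = t, so the steps with stimulation
        # are hand-computable: within 4 units of the own static (100), the
        # partner avatar (300) or the partner's shadow (450)
        assert np.allclose(rec.pos[0, :601], np.arange(601) % 600.0)
        expected = np.zeros(600, dtype=bool)
        for centre in (100, 300, 450):
            expected[np.abs(np.arange(600) - centre) < 4] = True
        assert np.array_equal(rec.stim(0)[:600], expected)

    def test_shadow_touch_is_asymmetric(self, short_cfg):
        # player 0 parked on player 1's shadow: stim only for player 0
        rec = simulate_trial(
            [StationaryAgent(), StationaryAgent()],
            short_cfg,
            seed=1,
            starts=[451.0, 300.0],
            static_pos=[100.0, 100.0],
        )
        assert rec.stim(0).all()
        assert not rec.stim(1).any()

    def test_mutual_avatar_contact_is_symmetric(self, short_cfg):
        rec = simulate_trial(
            [StationaryAgent(), StationaryAgent()],
            short_cfg,
            seed=1,
            starts=[300.0, 302.0],
            static_pos=[100.0, 500.0],
        )
        ov0, ov1 = rec.overlap_series(0), rec.overlap_series(1)
        assert np.array_equal(ov0["avatar"], ov1["avatar"])
        assert ov0["avatar"].all()

    def test_nonfinite_velocity_names_player_and_step(self, short_cfg):
        with pytest.raises(SimulationError, match="player 0 .* step 1"):
            simulate_trial([_BadAgent(), StationaryAgent()], short_cfg, seed=1)

    def test_invariants_on_random_trials(self, short_cfg, rng):
        L = short_cfg.space_length
        for _ in range(5):
            seed = int(rng.integers(0, 2**31))
            rec = simulate_trial(
                [ScannerAgent(speed=1.3, span=200.0), ScannerAgent(speed=0.7, span=350.0)],
                short_cfg,
                seed=seed,
            )
            rec.validate()
            assert ((rec.pos >= 0) & (rec.pos < L)).all()
            # rigid link: shadow velocity equals avatar velocity each step
            dv_avatar = np.diff(rec.pos, axis=1) % L
            dv_shadow = np.diff(rec.shadow_pos, axis=1) % L
            assert np.allclose(dv_avatar, dv_shadow)
            for p in (0, 1):
                ov = rec.overlap_series(p)
                assert np.array_equal(
                    rec.stim(p), ov["avatar"] | ov["shadow"] | ov["static"]
                )

    def test_determinism(self, short_cfg):
        ctor = lambda: [ScannerAgent(speed=1.0, span=300.0), ScannerAgent(speed=0.5, span=100.0)]
        a = simulate_trial(ctor(), short_cfg, seed=42)
        b = simulate_trial(ctor(), short_cfg, seed=42)
        assert np.array_equal(a.pos, b.pos)
        assert a.clicks == b.clicks


class TestAgents:
    def test_scanner_span_zero_is_stationary(self, short_cfg):
        agent = make_scanner_agent(speed=1.0, span=0.0)
        rec = simulate_trial(
            [agent, StationaryAgent()], short_cfg, seed=1,
            starts=[0.0, 300.0], static_pos=[200.0, 500.0],
        )
        assert (rec.pos[0] == rec.pos[0, 0]).all()

    def test_scanner_full_circle_patrol_period(self, short_cfg):
        rec = simulate_trial(
            [make_scanner_agent(speed=1.0, span=600.0), StationaryAgent()],
            short_cfg, seed=1, starts=[0.0, 300.0], static_pos=[200.0, 500.0],
        )
        # speed 1, span 600: back at the start after 1200 steps
        assert rec.pos[0, 1200] == pytest.approx(rec.pos[0, 0], abs=1e-9)

    def test_scanner_determinism_given_seed(self):
        a = ScannerAgent(speed=1.0, span=100.0, seed=9, jitter=0.1)
        b = ScannerAgent(speed=1.0, span=100.0, seed=9, jitter=0.1)
        steps_a = [a.step(t, 0.0, False)[0] for t in range(1, 50)]
        steps_b = [b.step(t, 0.0, False)[0] for t in range(1, 50)]
        assert steps_a == steps_b

    def test_turn_takers_in_contact_approach_perfect_exchange(self, short_cfg):
        ctrls = [
            TurnTakerAgent(role=0, burst_steps=500, click_exchanges=1),
            TurnTakerAgent(role=1, burst_steps=500, click_exchanges=1),
        ]
        rec = simulate_trial(
            ctrls, short_cfg, seed=1, starts=[300.0, 302.0], static_pos=[100.0, 500.0],
        )
        # a whole exchange cycle: 500 active + 500 passive, complementary
        b0 = binarize_movement(rec.pos[0], short_cfg)
        b1 = binarize_movement(rec.pos[1], short_cfg)
        s = turn_taking_score(b0[1:1001], b1[1:1001])
        assert s.tt > 0.95

    def test_turn_taker_vs_distant_stationary_never_engages(self):
        # in a 1 s trial the seeker covers only ~100 units; everything it
        # can sense sits further away, so no contact and no click
        cfg1 = EnvConfig(trial_duration=1.0)
        ctrls = [
            TurnTakerAgent(role=0, seek_direction=1, burst_steps=100, click_exchanges=1),
            StationaryAgent(),
        ]
        rec = simulate_trial(
            ctrls, cfg1, seed=1, starts=[0.0, 300.0], static_pos=[200.0, 500.0]
        )
        assert not rec.stim(0).any()
        assert rec.click_step(0) is None

    def test_make_turn_taker_validates_burst(self):
        with pytest.raises(ValueError):
            make_turn_taker_agent(burst_steps=0)


class TestGenerateDataset:
    def test_counts_and_determinism(self):
        a = generate_dataset(2, 3, "mixed", seed=5)
        b = generate_dataset(2, 3, "mixed", seed=5)
        assert len(a.recordings) == 6
        assert all(
            np.array_equal(x.pos, y.pos) for x, y in zip(a.recordings, b.recordings)
        )
        assert a.ground_truth.equals(b.ground_truth)
        assert a.questionnaires.equals(b.questionnaires)

    def test_stationary_scenario_has_no_clicks(self):
        ds = generate_dataset(1, 2, "stationary", seed=3)
        assert not ds.ground_truth["clicked"].any()
        assert all(not rec.clicks for rec in ds.recordings)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            generate_dataset(1, 1, "chaos", seed=0)

    def test_turn_taker_ground_truth_is_avatar(self):
        ds = generate_dataset(1, 3, "turn_takers", seed=8)
        clicked = ds.ground_truth[ds.ground_truth["clicked"]]
        assert len(clicked) == 6  # both players click in every trial
        assert (clicked["true_target"] == "avatar").all()

    def test_scanner_truth_is_a_single_object(self):
        ds = generate_dataset(2, 4, "scanners", seed=8)
        clicked = ds.ground_truth[ds.ground_truth["clicked"]]
        assert (clicked["player"] == 0).all()
        assert clicked["true_target"].isin(["avatar", "shadow", "static"]).all()
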