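"""Task environments and input schedules."""
import numpy as np
import pytest

from taskspace import (
    EconChoiceConfig,
    EconChoiceEnv,
    ReversalConfig,
    ReversalEnv,
    TwoStageConfig,
    TwoStageEnv,
    econ_expected_value,
    econ_input_profile,
    make_econ_schedule,
    make_reversal_schedule,
    make_twostage_schedule,
)


class TestReversalEnv:
    def test_contingency_and_block_flip(self):
        env = ReversalEnv(ReversalConfig())
        env.reset()
        assert env.step(0)["reward"] == 1    # A rewarded in block 0
        env.trial = 50
        assert env.step(1)["reward"] == 0
        env.trial = 100                      # block 2: contingency reversed
        assert env.step(0)["reward"] == 0
        assert env.step(1)["reward"] == 1

    def test_always_correct_agent_reward_rate_is_one(self):
        env = ReversalEnv(ReversalConfig())
        env.reset()
        rewards = [env.step(env.rewarded_option())["reward"] for _ in range(400)]
        assert np.mean(rewards) == 1.0


class TestReversalSchedule:
    def test_event_rows(self):
        cfg = ReversalConfig()
        s = make_reversal_schedule(0, 1, cfg)
        assert s.inputs.shape == (3, 900)
        window = slice(200, 700)
        assert np.all(s.inputs[0, window] == 1) and np.all(s.inputs[2, window] == 1)
        assert s.inputs[1].sum() == 0
        outside = np.concatenate([s.inputs[:, :200].ravel(), s.inputs[:, 700:].ravel()])
        assert np.all(outside == 0)
        assert s.decision_time == 900

    def test_unrewarded_and_lesioned(self):
        cfg = ReversalConfig()
        s = make_reversal_schedule(1, 0, cfg)
        assert s.inputs[2].sum() == 0 and s.inputs[1].sum() == 500
        lesion = cfg.replace(reward_input_present=False)
        s2 = make_reversal_schedule(1, 1, lesion)
        assert s2.inputs[2].sum() == 0
        # lesion inertness: schedules agree regardless of the outcome shown
        s3 = make_reversal_schedule(1, 0, lesion)
        assert np.array_equal(s2.inputs, s3.inputs)

    def test_binary_schedule(self):
        s = make_reversal_schedule(0, 1, ReversalConfig())
        assert set(np.unique(s.inputs)) <= {0.0, 1.0}


class TestTwoStageEnv:
    def test_transition_frequencies(self):
        env = TwoStageEnv(TwoStageConfig())
        env.reset(5)
        outs = [env.step(0) for _ in range(10000)]
        freq_b1 = np.mean([o["intermediate"] == 0 for o in outs])
        se = np.sqrt(0.8 * 0.2 / 10000)
        assert abs(freq_b1 - 0.8) < 3 * se

    def test_reward_contingency_flips_each_block(self):
        env = TwoStageEnv(TwoStageConfig())
        env.reset(1)
        assert env.good_intermediate(trial=0) == 0
        assert env.good_intermediate(trial=50) == 1
        assert env.good_intermediate(trial=100) == 0

    def test_degenerate_transition(self):
        env = TwoStageEnv(TwoStageConfig(common_prob=1.0))
        env.reset(2)
        assert all(env.step(1)["intermediate"] == 1 for _ in range(50))

    def test_random_agent_reward_rate_near_half(self):
        env = TwoStageEnv(TwoStageConfig())
        env.reset(3)
        rng = np.random.default_rng(0)
        rewards = [env.step(int(rng.integers(2)))["reward"] for _ in range(4000)]
        assert abs(np.mean(rewards) - 0.5) < 3 * np.sqrt(0.25 / 4000)


class TestTwoStageSchedule:
    def test_sequential_events(self):
        cfg = TwoStageConfig()
        s = make_twostage_schedule(0, 0, 1, cfg)
        assert s.inputs.shape == (6, 1900)
        assert np.all(s.inputs[0, 200:700] == 1)      # A1
        assert np.all(s.inputs[2, 700:1200] == 1)     # B1
        assert np.all(s.inputs[4, 1200:1700] == 1)    # R
        assert s.inputs[5].sum() == 0                 # N silent on reward
        assert s.inputs[[1, 3]].sum() == 0

    def test_nonreward_unit(self):
        s = make_twostage_schedule(1, 1, 0, TwoStageConfig())
        assert s.inputs[4].sum() == 0
        assert np.all(s.inputs[5, 1200:1700] == 1)

    def test_lesion_variants(self):
        full_lesion = TwoStageConfig(reward_input_present=False,
                                     nonreward_input_present=False)
        s = make_twostage_schedule(0, 1, 1, full_lesion)
        assert s.inputs[4].sum() == 0 and s.inputs[5].sum() == 0
        r_only = TwoStageConfig(reward_input_present=False)
        s2 = make_twostage_schedule(0, 1, 0, r_only)
        assert s2.inputs[5].sum() == 500    # N retained

    def test_event_order_swap(self):
        s = make_twostage_schedule(0, 0, 1, TwoStageConfig(event_order="B-first"))
        assert np.all(s.inputs[2, 200:700] == 1)      # B first
        assert np.all(s.inputs[0, 700:1200] == 1)     # then A


class TestEconTask:
    cfg = EconChoiceConfig()

    def test_profile_shape_constants(self):
        # ratio of the raw profile at two reference times pins the four
        # sigmoid constants: g(475)=0.452325, g(700)=0.499724
        f = econ_input_profile(np.array([475.0, 700.0]), 8, 8, 0, self.cfg)
        assert f[0] / f[1] == pytest.approx(0.452325 / 0.499724, abs=1e-5)

    def test_block_max_offer_peaks_at_one(self):
        t = np.arange(1, 1401, dtype=float)
        f = econ_input_profile(t, 8, 8, 0, self.cfg)
        assert f.max() == pytest.approx(1.0, abs=1e-12)
        assert np.all(f[t < 300] == 0) and np.all(f[t >= 1300] == 0)

    def test_min_offer_is_silent(self):
        t = np.arange(1, 1401, dtype=float)
        assert np.all(econ_input_profile(t, 0, 8, 0, self.cfg) == 0)

    def test_degenerate_range_raises(self):
        with pytest.raises(ValueError):
            econ_input_profile(500.0, 1, 2, 2, self.cfg)

    def test_step_profile_variant(self):
        cfg = self.cfg.replace(step_profile=True)
        t = np.arange(1, 1401, dtype=float)
        f = econ_input_profile(t, 4, 8, 0, cfg)
        assert set(np.unique(f)) == {0.0, 0.5}

    def test_schedule_bounds(self):
        s = make_econ_schedule((3, 4), self.cfg)
        assert s.inputs.shape == (2, 1400)
        assert s.inputs.max() <= 1.0 and s.inputs.min() >= 0.0

    @pytest.mark.parametrize(
        "probs, mags, gamma, expected",
        [((0.5, 0.5), (1, 2), 2.0, 2.0),
         ((1.0, 0.0), (3, 5), 2.0, 6.0),
         ((0.3, 0.7), (0, 0), 2.0, 0.0)],
    )
    def test_expected_value(self, probs, mags, gamma, expected):
        assert econ_expected_value(probs, mags, gamma) == pytest.approx(expected)

    def test_offer_draws_exclude_zero_pair(self):
        env = EconChoiceEnv(self.cfg)
        env.reset(4)
        offers = [env.draw_offers() for _ in range(500)]
        assert (0, 0) not in offers
        ma, mb = zip(*offers)
        assert set(ma) <= set(self.cfg.offers_A) and set(mb) <= set(self.cfg.offers_B)

    def test_reward_magnitudes(self):
        # default: value units normalized by the largest option value (8)
        env = EconChoiceEnv(self.cfg)
        env.reset(1)
        assert env.step(0, (3, 5))["reward"] == pytest.approx(6.0 / 8.0)
        assert env.step(1, (3, 5))["reward"] == pytest.approx(5.0 / 8.0)
        raw = EconChoiceEnv(self.cfg.replace(normalize_reward=False))
        raw.reset(1)
        assert raw.step(0, (3, 5))["reward"] == 6.0   # gamma * m_A
        assert raw.step(1, (3, 5))["reward"] == 5.0
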