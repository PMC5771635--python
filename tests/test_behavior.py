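"""Behavioral analyses: stay tables, TS index, regressions, psychometrics,
and the value-selectivity taxonomy."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from taskspace import (
    PsychometricModel,
    StayTable,
    factor_regression,
    lagged_state_regression,
    stay_table,
    ts_index,
    value_regression_taxonomy,
    value_variables,
    VALUE_VARIABLES,
)


def _twostage_log(choices, intermediates, rewards, block_type="B1"):
    choices = np.asarray(choices)
    common = (np.asarray(intermediates) == choices).astype(int)
    return pd.DataFrame({
        "trial": np.arange(len(choices)),
        "choice": choices,
        "intermediate": intermediates,
        "common": common,
        "reward": rewards,
        "block_type": block_type,
    })


class TestStayTable:
    def test_always_repeat_agent(self):
        rng = np.random.default_rng(0)
        n = 400
        log = _twostage_log(np.zeros(n, int), rng.integers(2, size=n),
                            rng.integers(2, size=n))
        table = stay_table(log)
        assert all(p == 1.0 for p in table.probs.values())

    def test_win_stay_lose_shift(self):
        rng = np.random.default_rng(1)
        n = 1000
        choices = np.zeros(n, int)
        rewards = rng.integers(2, size=n)
        for t in range(1, n):
            choices[t] = choices[t - 1] if rewards[t - 1] else 1 - choices[t - 1]
        log = _twostage_log(choices, rng.integers(2, size=n), rewards)
        table = stay_table(log)
        assert table.probs["CR"] == 1.0 and table.probs["RR"] == 1.0
        assert table.probs["CN"] == 0.0 and table.probs["RN"] == 0.0

    def test_rare_classification(self):
        # choice A1 followed by B2 is a rare transition
        log = _twostage_log([0, 0], [1, 0], [1, 0])
        assert log.loc[0, "common"] == 0
        table = stay_table(log)
        assert table.counts["RR"] == (1, 1)

    def test_requires_intermediates(self):
        with pytest.raises(ValueError):
            stay_table(pd.DataFrame({"choice": [0, 1], "reward": [0, 1]}))


class TestTSIndex:
    @pytest.mark.parametrize(
        "probs, expected",
        [
            ({"CR": 1, "RN": 1, "CN": 0, "RR": 0}, 1.0),
            ({"CR": 0.5, "RN": 0.5, "CN": 0.5, "RR": 0.5}, 0.0),
            ({"CR": 0.8, "RN": 0.8, "CN": 0.4, "RR": 0.4}, 1 / 3),
        ],
    )
    def test_reference_values(self, probs, expected):
        table = StayTable(probs=probs, counts={})
        assert ts_index(table) == pytest.approx(expected, abs=1e-9)

    @given(st.lists(st.floats(0, 1), min_size=4, max_size=4))
    @settings(max_examples=200, deadline=None)
    def test_bounded(self, ps):
        probs = dict(zip(("CR", "CN", "RR", "RN"), ps))
        if sum(ps) == 0:
            with pytest.raises(ValueError):
                ts_index(StayTable(probs=probs, counts={}))
        else:
            assert -1.0 <= ts_index(StayTable(probs=probs, counts={})) <= 1.0

    def test_unity_iff_no_antistructure_stays(self):
        table = StayTable(probs={"CR": 0.7, "RN": 0.2, "CN": 0.0, "RR": 0.0},
                          counts={})
        assert ts_index(table) == 1.0


class TestStayPooling:
    def test_pooled_counts_and_probs(self):
        from taskspace.behavior import pool_stay_tables

        a = StayTable(probs={"CR": 1.0, "CN": 0.0, "RR": 0.5, "RN": 0.5},
                      counts={"CR": (10, 10), "CN": (0, 10), "RR": (5, 10),
                              "RN": (5, 10)})
        b = StayTable(probs={"CR": 0.0, "CN": 1.0, "RR": 0.5, "RN": 0.5},
                      counts={"CR": (0, 10), "CN": (10, 10), "RR": (10, 20),
                              "RN": (10, 20)})
        pooled = pool_stay_tables([a, b])
        assert pooled.counts["CR"] == (10, 20)
        assert pooled.probs["CR"] == 0.5 and pooled.probs["CN"] == 0.5
        assert pooled.probs["RR"] == 0.5

    def test_ts_variance_shrinks_with_counts(self):
        from taskspace.behavior import ts_index_variance

        def table(n):
            return StayTable(
                probs={"CR": 0.6, "CN": 0.4, "RR": 0.45, "RN": 0.55},
                counts={k: (0, n) for k in ("CR", "CN", "RR", "RN")},
            )
        v_small, v_big = ts_index_variance(table(50)), ts_index_variance(table(5000))
        assert v_small > v_big > 0
        assert v_small == pytest.approx(100 * v_big, rel=1e-9)


class TestLaggedRegression:
    def test_random_agent_shows_no_dependence(self):
        rng = np.random.default_rng(5)
        n = 3000
        log = _twostage_log(rng.integers(2, size=n), rng.integers(2, size=n),
                            rng.integers(2, size=n))
        res = lagged_state_regression(log, lags=5)
        assert (res["p"] < 0.01).mean() < 0.15

    def test_lag2_generator_detected(self):
        rng = np.random.default_rng(6)
        n = 3000
        choices = np.zeros(n, int)
        rewards = rng.integers(2, size=n)
        inter = rng.integers(2, size=n)
        for t in range(2, n):
            # favour the lag-2 intermediate's associated option after reward
            if rewards[t - 2] and rng.random() < 0.85:
                choices[t] = inter[t - 2]
            else:
                choices[t] = rng.integers(2)
        log = _twostage_log(choices, inter, rewards)
        res = lagged_state_regression(log, lags=4)
        lag2 = res[res["lag"] == 2]
        others = res[res["lag"].isin([3, 4])]
        assert (lag2["p"] < 1e-4).any()
        assert others["coef"].abs().max() < lag2["coef"].abs().max()

    def test_too_short_log_rejected(self):
        log = _twostage_log([0, 1] * 10, [0, 1] * 10, [1, 0] * 10)
        with pytest.raises(ValueError):
            lagged_state_regression(log, lags=10)


class TestFactorRegression:
    def test_pure_perseveration(self):
        rng = np.random.default_rng(7)
        n = 2000
        choices = np.zeros(n, int)
        for t in range(1, n):
            choices[t] = choices[t - 1] if rng.random() < 0.85 else 1 - choices[t - 1]
        log = _twostage_log(choices, rng.integers(2, size=n), rng.integers(2, size=n))
        res = factor_regression(log)
        assert res.loc["Stay", "coef"] > 1.0 and res.loc["Stay", "p"] < 1e-6
        assert abs(res.loc["TransXOut", "coef"]) < 0.3

    def test_random_agent(self):
        rng = np.random.default_rng(8)
        n = 2000
        log = _twostage_log(rng.integers(2, size=n), rng.integers(2, size=n),
                            rng.integers(2, size=n))
        res = factor_regression(log)
        assert (res["p"] > 0.01).all()


class TestPsychometric:
    @staticmethod
    def _synthetic_log(rho, slope, n=4000, seed=9):
        rng = np.random.default_rng(seed)
        m_a = rng.integers(0, 4, size=n)
        m_b = rng.integers(0, 9, size=n)
        keep = (m_a > 0) | (m_b > 0)
        m_a, m_b = m_a[keep], m_b[keep]
        with np.errstate(divide="ignore"):
            x = np.where((m_a > 0) & (m_b > 0),
                         np.log(np.maximum(m_b, 1) / np.maximum(m_a, 1)), 0.0)
        p_b = 1 / (1 + np.exp(-slope * (x - np.log(rho))))
        p_b = np.where(m_a == 0, 1.0, np.where(m_b == 0, 0.0, p_b))
        choice = (rng.random(len(p_b)) < p_b).astype(int)
        return pd.DataFrame({"offer_A": m_a, "offer_B": m_b, "choice": choice})

    def test_recovers_relative_value_two(self):
        fit = PsychometricModel.from_log(self._synthetic_log(2.0, 4.0)).fit()
        assert 1.8 <= fit.relative_value <= 2.2
        assert "relative value" in fit.summary()

    def test_symmetric_behavior_gives_unity(self):
        fit = PsychometricModel.from_log(self._synthetic_log(1.0, 4.0, seed=10)).fit()
        assert fit.relative_value == pytest.approx(1.0, abs=0.1)

    def test_forced_choices_follow_nonzero_offer(self):
        log = self._synthetic_log(2.0, 4.0, seed=11)
        forced = log[(log["offer_A"] == 0) | (log["offer_B"] == 0)]
        assert np.array_equal(forced["choice"], (forced["offer_A"] == 0).astype(int))

    def test_degenerate_fit_raises(self):
        log = pd.DataFrame({"offer_A": [0, 1] * 10, "offer_B": [1, 0] * 10,
                            "choice": [1, 0] * 10})
        with pytest.raises(ValueError, match="interior"):
            PsychometricModel.from_log(log).fit()


class TestValueTaxonomy:
    @staticmethod
    def _econ_log(n=600, seed=12):
        rng = np.random.default_rng(seed)
        m_a = rng.integers(0, 4, size=n)
        m_b = rng.integers(0, 9, size=n)
        choice = (m_b > 2 * m_a).astype(int)
        flip = rng.random(n) < 0.15
        choice[flip] = 1 - choice[flip]
        return pd.DataFrame({"offer_A": m_a, "offer_B": m_b, "choice": choice})

    def test_variable_definitions(self):
        log = pd.DataFrame({"offer_A": [1, 2], "offer_B": [4, 1], "choice": [1, 0]})
        v = value_variables(log, gamma=2.0)
        assert list(v.columns) == VALUE_VARIABLES
        assert v.loc[0, "chosen value"] == 4.0 and v.loc[0, "other value"] == 2.0
        assert v.loc[1, "chosen value"] == 4.0 and v.loc[1, "value ratio"] == 0.25
        assert np.isnan(v.loc[0, "value A chosen"])
        assert v.loc[1, "chosen juice"] == 0.0

    def test_constructed_neurons_classified(self):
        log = self._econ_log()
        v = value_variables(log, gamma=2.0)
        rng = np.random.default_rng(13)
        n = len(log)
        rates = np.column_stack([
            0.1 + 0.05 * v["chosen value"] + rng.normal(0, 0.01, n),
            0.2 + 0.04 * v["offer value B"] + rng.normal(0, 0.01, n),
            np.full(n, 0.3) + rng.normal(0, 0.01, n),
        ])
        frame, counts = value_regression_taxonomy(rates, v)
        assert frame.loc[0, "category"] == "chosen value"
        assert frame.loc[1, "category"] == "offer value B"
        assert frame.loc[2, "category"] == "unclassified"
        assert counts["chosen value"] >= 1

    def test_ratio_trials_with_zero_chosen_value_excluded(self):
        log = pd.DataFrame({"offer_A": [0, 2], "offer_B": [3, 0], "choice": [0, 1]})
        v = value_variables(log)
        assert np.isnan(v["value ratio"]).all()
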