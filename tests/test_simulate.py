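import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lcsmed as L
from lcsmed.simulate import (
    ConfigError,
    MEDIATORS,
    WEEKLY_TEXT_COUNTS,
    _child_seed,
)

# single-estimate Monte-Carlo SDs for the n=4000 recovery example,
# estimated beforehand from a 200-replicate independent rerun of the
# generative equations with plain numpy least squares
MC_SD_N4000 = {"a": 0.1863, "b": 0.0217, "c_prime": 0.3012}


class TestBlockRandomization:
    def test_single_block_splits_evenly(self):
        arms = L.stratified_block_randomize(["f"] * 10, block_size=10, seed=3)
        assert arms.sum() == 5

    def test_every_complete_block_splits_evenly(self):
        arms = L.stratified_block_randomize(["f"] * 20, block_size=10, seed=4)
        assert arms[:10].sum() == 5 and arms[10:].sum() == 5

    def test_deterministic_in_seed(self):
        labels = ["f"] * 13 + ["m"] * 9
        a1 = L.stratified_block_randomize(labels, 10, seed=7)
        a2 = L.stratified_block_randomize(labels, 10, seed=7)
        a3 = L.stratified_block_randomize(labels, 10, seed=8)
        assert np.array_equal(a1, a2)
        assert not np.array_equal(a1, a3)  # seed actually matters

    def test_odd_block_size_rejected(self):
        with pytest.raises(ConfigError):
            L.stratified_block_randomize(["f"] * 10, block_size=5, seed=0)

    @given(
        st.lists(st.sampled_from(["f", "m", "x"]), min_size=1, max_size=60),
        st.sampled_from([2, 4, 10]),
        st.integers(0, 10_000),
    )
    @settings(max_examples=100, deadline=None)
    def test_marginal_imbalance_bound(self, labels, block_size, seed):
        arms = L.stratified_block_randomize(labels, block_size, seed)
        n_strata = len(set(labels))
        imbalance = abs(2 * arms.sum() - len(arms))
        assert imbalance <= n_strata * block_size / 2


class TestGenerateTrial:
    def test_null_generator_is_flat(self):
        zero = {v: 0.0 for v in ("bdi",) + MEDIATORS}
        st_params = L.StructuralParameters(
            a={m: 0.0 for m in MEDIATORS},
            b={m: 0.0 for m in MEDIATORS},
            c_prime=0.0,
            control_drift=dict(zero),
            residual_sd=dict(zero),
            interval_noise_sd=0.0,
        )
        table, _ = L.generate_trial(
            L.SimulationConfig(n_participants=60, structural=st_params, seed=2)
        )
        for v in ("bdi",) + MEDIATORS:
            for w in (1, 2, 3):
                change = table[f"{v}_{w}"] - table[f"{v}_{w-1}"]
                assert (change == 0).all()

    def test_scores_respect_instrument_bounds(self, default_trial):
        table, _ = default_trial
        reg = L.default_registry()
        for v in ("bdi",) + MEDIATORS:
            for w in range(4):
                col = table[f"{v}_{w}"].dropna()
                assert col.between(reg[v].score_min, reg[v].score_max).all()

    def test_baseline_eligibility_floor(self, default_trial):
        table, _ = default_trial
        assert (table["bdi_0"] >= 20).all()
        assert (table["phq9_0"] >= 10).all()

    def test_deterministic_in_seed(self):
        t1, g1 = L.generate_trial(L.SimulationConfig(seed=9))
        t2, g2 = L.generate_trial(L.SimulationConfig(seed=9))
        pd.testing.assert_frame_equal(t1, t2)
        assert g1 == g2

    def test_ground_truth_records_parameters(self, default_trial):
        table, truth = default_trial
        st_params = L.StructuralParameters()
        assert truth["a"] == st_params.a
        assert truth["total_effect"] == pytest.approx(st_params.total_effect)
        assert truth["n_treatment"] + truth["n_control"] == len(table)

    def test_zero_a_paths_give_zero_indirect(self):
        st_params = L.StructuralParameters(a={m: 0.0 for m in MEDIATORS})
        assert all(v == 0 for v in st_params.indirect.values())
        cfg = L.SimulationConfig(n_participants=4000, structural=st_params, seed=21)
        table, _ = L.generate_trial(cfg)
        fit = L.SingleMediatorLCS(mediator="bads", n_boot=0).fit(table)
        # fitted indirect consistent with a structural zero (Sobel scale)
        sobel = np.sqrt(
            fit.b_["bads"].estimate ** 2 * fit.a_["bads"].se ** 2
            + fit.a_["bads"].estimate ** 2 * fit.b_["bads"].se ** 2
        )
        assert abs(fit.indirect_["bads"]) < 3 * max(sobel, 1e-6)

    def test_recovery_large_sample_example(self):
        # a=6, b=-0.7, c'=-4 single-mediator configuration at n=4000
        st_params = L.StructuralParameters(
            a={"bads": 6.0, "cds": 0.0, "ptq": 0.0},
            b={"bads": -0.7, "cds": 0.0, "ptq": 0.0},
            c_prime=-4.0,
        )
        cfg = L.SimulationConfig(n_participants=4000, structural=st_params, seed=1)
        table, _ = L.generate_trial(cfg)
        fit = L.SingleMediatorLCS(mediator="bads", n_boot=0).fit(table)
        assert abs(fit.a_["bads"].estimate - 6.0) < 3 * MC_SD_N4000["a"]
        assert abs(fit.b_["bads"].estimate - (-0.7)) < 3 * MC_SD_N4000["b"]
        assert abs(fit.c_prime_.estimate - (-4.0)) < 3 * MC_SD_N4000["c_prime"]

    def test_infeasible_truncation_rejected(self):
        with pytest.raises(ConfigError, match="truncation"):
            L.SimulationConfig(truncation={"bdi": (0, 20), "bads": (0, 54),
                                           "cds": (0, 70), "ptq": (0, 60)})

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = L.SimulationConfig(n_participants=50, seed=5)
        path = tmp_path / "sim.yaml"
        cfg.to_yaml(path)
        assert L.SimulationConfig.from_yaml(path) == cfg


class TestMissingness:
    def test_full_retention_is_identity(self, default_trial):
        table, _ = default_trial
        out = L.apply_missingness(table, (1.0, 1.0, 1.0), seed=0)
        pd.testing.assert_frame_equal(out, table)

    def test_zero_retention_removes_wave(self, default_trial):
        table, _ = default_trial
        out = L.apply_missingness(table, (1.0, 1.0, 0.0), seed=0)
        assert out["bdi_3"].isna().all()
        assert out["bdi_0"].notna().all()  # baseline untouched
        assert out["bdi_1"].notna().all()

    def test_retention_rate_binomial(self):
        table, _ = L.generate_trial(L.SimulationConfig(n_participants=5000, seed=3))
        out = L.apply_missingness(table, (0.8, 0.8, 0.8), seed=13)
        for w in (1, 2, 3):
            rate = out[f"bdi_{w}"].notna().mean()
            assert abs(rate - 0.8) < 3 * np.sqrt(0.8 * 0.2 / 5000)

    def test_monotone_mode_is_dropout(self):
        table, _ = L.generate_trial(L.SimulationConfig(n_participants=400, seed=3))
        out = L.apply_missingness(table, (0.7, 0.7, 0.7), seed=5, monotone=True)
        missing_2 = out["bdi_2"].isna()
        assert out.loc[missing_2, "bdi_3"].isna().all()


class TestMessageSchedule:
    def test_protocol_arithmetic(self):
        s = L.build_message_schedule()
        assert s.n_treatment_days == 32
        assert s.total_messages == 474
        assert round(s.mean_messages_per_day, 1) == 14.8
        assert s.total_prompts == 198
        assert sum(WEEKLY_TEXT_COUNTS) == 474

    def test_weekly_counts_land_in_their_week(self):
        s = L.build_message_schedule()
        per_week = np.add.reduceat(np.asarray(s.messages), np.arange(0, 32, 4))
        assert tuple(per_week) == WEEKLY_TEXT_COUNTS

    def test_largest_remainder_split_is_even(self):
        s = L.build_message_schedule()
        for w in range(8):
            days = np.asarray(s.messages[4 * w: 4 * w + 4])
            assert days.max() - days.min() <= 1

    def test_bad_weekly_sum_rejected(self):
        with pytest.raises(ConfigError):
            L.build_message_schedule(weekly_counts=(62,) * 8)


class TestEngagement:
    def test_full_responder_is_completer(self):
        s = L.build_message_schedule()
        out = L.simulate_engagement(s, [1.0], seed=0)
        assert out["total_responses"].iloc[0] == 198
        assert bool(out["completer"].iloc[0])

    def test_non_responder(self):
        s = L.build_message_schedule()
        out = L.simulate_engagement(s, [0.0], seed=0)
        assert out["total_responses"].iloc[0] == 0
        assert not bool(out["completer"].iloc[0])

    def test_completion_threshold_rule(self):
        s = L.build_message_schedule()
        rng = np.random.default_rng(4)
        out = L.simulate_engagement(s, rng.beta(1.2, 0.25, 200), seed=6)
        # the completer flag is exactly the >= 192-response rule
        assert (out["completer"] == (out["total_responses"] >= 192)).all()
        daily = out[[c for c in out.columns if c.startswith("responses_day_")]]
        assert (daily.to_numpy() <= np.asarray(s.prompts)[None, :]).all()

    def test_threshold_above_prompts_rejected(self):
        s = L.build_message_schedule()
        with pytest.raises(ConfigError):
            L.simulate_engagement(s, [1.0], completion_threshold=199, seed=0)


def test_operation_streams_are_distinct():
    seeds = {_child_seed(7, k) for k in range(6)}
    assert len(seeds) == 6 and all(0 <= s < 2**31 for s in seeds)
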