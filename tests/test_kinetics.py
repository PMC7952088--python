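"""Dwell extraction, exponential fits, rate decomposition and Kd."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polfret import simulate
from polfret.hmm import StatePath
from polfret.kinetics import (decompose_rates, estimate_kd, extract_dwells,
                              fd_bin_width, fit_dwell_rate, fraction_bound,
                              transition_frequencies)


def path(labels, frame_dt=0.1, trace_id="t"):
    return StatePath(labels=np.asarray(labels), frame_dt=frame_dt,
                     trace_id=trace_id)


class TestExtractDwells:
    def test_three_dwell_example_with_censoring(self):
        # P P P N N P at 0.1 s/frame
        table = extract_dwells([path([0, 0, 0, 1, 1, 0])])
        df = table.df
        assert df["duration_s"].tolist() == pytest.approx([0.3, 0.2, 0.1])
        assert df["left_censored"].tolist() == [True, False, False]
        assert df["right_censored"].tolist() == [False, False, True]
        assert df["next_state"].tolist() == [1, 0, -1]
        assert df["prev_state"].tolist() == [-1, 0, 1]

    def test_single_state_path_fully_censored(self):
        table = extract_dwells([path([0] * 10)])
        assert len(table.df) == 1
        assert table.df["left_censored"].iloc[0]
        assert table.df["right_censored"].iloc[0]
        assert table.durations(0).size == 0

    def test_durations_conserve_valid_time(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 3, 500)
        labels[100:120] = -1
        table = extract_dwells([path(labels)])
        assert table.df["duration_s"].sum() == pytest.approx(
            np.sum(labels >= 0) * 0.1
        )

    def test_gap_breaks_dwells_and_censors_boundaries(self):
        table = extract_dwells([path([0, 0, -1, 0, 0])])
        assert len(table.df) == 2
        assert table.df["right_censored"].iloc[0]
        assert table.df["left_censored"].iloc[1]


class TestFdBinWidth:
    def test_iqr_two_with_eight_points(self):
        x = np.array([0.0, 1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 4.0])
        assert fd_bin_width(x) == pytest.approx(2.0)

    def test_one_to_eight(self):
        assert fd_bin_width(np.arange(1.0, 9.0)) == pytest.approx(3.5)

    @given(st.floats(min_value=0.1, max_value=100.0))
    @settings(deadline=None, max_examples=25)
    def test_scale_equivariance(self, c):
        x = np.array([0.2, 0.5, 0.9, 1.7, 2.1, 3.0, 4.8, 7.5])
        assert fd_bin_width(c * x) == pytest.approx(
            c * fd_bin_width(x), rel=1e-9
        )

    def test_zero_iqr_falls_back_with_warning(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 9.0])
        with pytest.warns(RuntimeWarning, match="IQR"):
            w = fd_bin_width(x)
        assert w == pytest.approx(8.0 / np.sqrt(8))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fd_bin_width(np.array([1.0, 2.0, 3.0]))


class TestFitDwellRate:
    def test_recovers_known_exponential_rate(self):
        rng = np.random.default_rng(11)
        x = rng.exponential(0.5, 5000)  # k = 2.0 /s
        k, se, k_mle = fit_dwell_rate(x)
        assert k == pytest.approx(2.0, rel=0.05)
        assert abs(k - k_mle) / k_mle < 0.10
        assert se < 0.2

    def test_time_rescaling_halves_rate(self):
        rng = np.random.default_rng(12)
        x = rng.exponential(0.5, 3000)
        k1, _, _ = fit_dwell_rate(x)
        k2, _, _ = fit_dwell_rate(2.0 * x)
        assert k2 == pytest.approx(k1 / 2.0, rel=0.02)

    def test_quantized_dwells_fit_with_frame_aligned_bins(self):
        rng = np.random.default_rng(13)
        x = np.ceil(rng.exponential(0.5, 5000) / 0.1) * 0.1
        k, _, _ = fit_dwell_rate(x, frame_dt=0.1)
        assert k == pytest.approx(2.0, rel=0.08)

    def test_too_few_dwells_rejected(self):
        with pytest.raises(ValueError, match="20"):
            fit_dwell_rate(np.ones(5))


class TestTransitionFrequencies:
    def test_deterministic_repeating_pattern(self):
        # every trace shows P -> N -> P -> U exactly once
        paths = [path([0, 0, 1, 1, 0, 0, 2, 2], trace_id=f"t{i}")
                 for i in range(60)]
        freqs = transition_frequencies(paths, sample_size=50, n_boot=20,
                                       seed=0)
        f_pn = freqs[(0, 1)]
        f_pu = freqs[(0, 2)]
        assert f_pn[0] == pytest.approx(50.0)  # one per sampled trace
        assert f_pn[0] == pytest.approx(f_pu[0])
        assert f_pn[1] == 0.0  # identical traces: no bootstrap spread

    def test_branching_ratio_two_to_one(self):
        rng = np.random.default_rng(3)
        paths = []
        for i in range(100):
            labels = []
            for _ in range(30):
                labels += [0] * int(rng.integers(1, 6))
                labels += [1 if rng.random() < 2 / 3 else 2]
            paths.append(path(labels, trace_id=f"t{i}"))
        freqs = transition_frequencies(paths, seed=0)
        ratio = freqs[(0, 1)][0] / freqs[(0, 2)][0]
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_same_seed_reproduces(self):
        paths = [path([0, 1, 0, 2] * 5, trace_id=f"t{i}") for i in range(10)]
        a = transition_frequencies(paths, sample_size=5, n_boot=10, seed=42)
        b = transition_frequencies(paths, sample_size=5, n_boot=10, seed=42)
        assert a == b

    def test_small_dataset_reduces_sample_size_with_warning(self):
        paths = [path([0, 1, 0], trace_id=f"t{i}") for i in range(3)]
        with pytest.warns(RuntimeWarning, match="reducing"):
            freqs = transition_frequencies(paths, sample_size=50, seed=0)
        assert (0, 1) in freqs


class TestDecomposeRates:
    def test_three_to_two_split(self):
        est = decompose_rates(
            {0: (10.0, 0.0)},
            {(0, 1): (3.0, 0.0), (0, 2): (2.0, 0.0)},
        )
        assert est.k_micro[(0, 1)][0] == pytest.approx(6.0)
        assert est.k_micro[(0, 2)][0] == pytest.approx(4.0)

    def test_single_exit_channel_keeps_k_obs(self):
        est = decompose_rates({0: (1.7, 0.1)}, {(0, 1): (12.0, 2.0)})
        assert est.k_micro[(0, 1)][0] == pytest.approx(1.7)

    def test_micro_rates_sum_to_k_obs(self):
        est = decompose_rates(
            {0: (5.0, 0.2), 1: (2.0, 0.1)},
            {(0, 1): (7.0, 1.0), (0, 2): (3.0, 0.5), (1, 0): (4.0, 0.6),
             (1, 2): (9.0, 1.1)},
        )
        for i, (k_i, _) in est.k_obs.items():
            total = sum(k for (a, _), (k, _) in est.k_micro.items() if a == i)
            assert total == pytest.approx(k_i, abs=1e-9)

    def test_invariant_to_frequency_rescaling(self):
        f1 = {(0, 1): (3.0, 0.0), (0, 2): (2.0, 0.0)}
        f2 = {key: (10 * v[0], 0.0) for key, v in f1.items()}
        a = decompose_rates({0: (10.0, 0.0)}, f1)
        b = decompose_rates({0: (10.0, 0.0)}, f2)
        assert a.k_micro[(0, 1)][0] == pytest.approx(b.k_micro[(0, 1)][0])

    def test_zero_total_frequency_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            decompose_rates({0: (1.0, 0.0)}, {(0, 1): (0.0, 0.0)})


class TestFractionBound:
    def test_half_bound(self):
        p = path([0] * 50 + [1] * 50)
        f, _ = fraction_bound([p], unbound_state=0, n_boot=10, seed=0)
        assert f == pytest.approx(0.5)

    def test_fully_bound(self):
        p = path([1] * 100)
        f, _ = fraction_bound([p], unbound_state=0, n_boot=10, seed=0)
        assert f == 1.0

    def test_stationary_bound_probability_recovered(self):
        # U <-> P with k_on = 0.4, k_off = 0.6: bound fraction 0.4
        scheme = simulate.binding_only_scheme(k_on=0.4, k_off=0.6)
        rng = np.random.default_rng(9)
        paths = [
            StatePath(
                labels=simulate.simulate_state_path(scheme, 60.0, 0.1, rng),
                frame_dt=0.1, trace_id=f"t{i}",
            )
            for i in range(100)
        ]
        f, sd = fraction_bound(paths, unbound_state=0, seed=0)
        assert f == pytest.approx(0.4, abs=0.03)
        assert 0 < sd < 0.1


class TestEstimateKd:
    @pytest.mark.parametrize(
        "f_b,expected", [(0.5, 5.0), (1.0, 0.0), (0.2, 20.0)]
    )
    def test_closed_form(self, f_b, expected):
        est = estimate_kd(f_b, 0.0, pol_total_nM=5.0)
        assert est.kd_nM == pytest.approx(expected)

    def test_delta_method_sd(self):
        est = estimate_kd(0.5, 0.01, pol_total_nM=5.0)
        assert est.kd_sd_nM == pytest.approx(5.0 * 0.01 / 0.25)

    def test_zero_bound_flags_infinite_kd(self):
        with pytest.warns(RuntimeWarning, match="unbounded"):
            est = estimate_kd(0.0, 0.0)
        assert np.isinf(est.kd_nM)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            estimate_kd(1.5)


class TestCensoringPolicy:
    def test_complete_dwell_selection_biases_rate_up_in_short_windows(self):
        """When dwells are comparable to the observation window, keeping
        only complete (uncensored) dwells selects the short ones and
        overestimates the decay rate; the censored pieces are themselves
        exponential by memorylessness, so including them reduces that
        selection bias. (With dwells much shorter than the window, as in
        the default datasets, both choices agree.)"""
        rng = np.random.default_rng(21)
        # dwells comparable to the observation window, so truncation bites
        scheme = simulate.binding_only_scheme(k_on=0.25, k_off=0.25)
        paths = [
            StatePath(
                labels=simulate.simulate_state_path(scheme, 12.0, 0.1, rng),
                frame_dt=0.1, trace_id=f"t{i}",
            )
            for i in range(400)
        ]
        table = extract_dwells(paths)
        k_excl, _, _ = fit_dwell_rate(table.durations(1), frame_dt=0.1)
        k_incl, _, _ = fit_dwell_rate(
            table.durations(1, include_censored=True), frame_dt=0.1
        )
        assert k_excl > 0.25  # selection bias of complete dwells
        assert abs(k_incl - 0.25) < abs(k_excl - 0.25)
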