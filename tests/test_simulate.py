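"""Kinetic simulator: CTMC realization, quantization and rendering."""

import numpy as np
import pytest
from scipy import stats as sps

from polfret import simulate
from polfret.simulate import (KineticScheme, PhotophysicsModel, render_trace,
                              simulate_dataset, simulate_state_path)


def two_state_scheme(k01=1.0, k10=1.0):
    return KineticScheme(
        state_names=["P", "N"],
        rate_matrix=np.array([[0.0, k01], [k10, 0.0]]),
        bound_flags=np.array([True, True]),
        fret_means=np.array([0.8, 0.6]),
        fret_sds=np.array([0.0, 0.0]),
    )


class TestStatePath:
    def test_zero_rates_stay_in_start_state(self):
        scheme = two_state_scheme(0.0, 0.0)
        path = simulate_state_path(scheme, 10.0, 0.1, seed=0, start_state=0)
        assert path.size == 100
        assert np.all(path == 0)

    def test_symmetric_two_state_occupancy_is_half(self):
        scheme = two_state_scheme(1.0, 1.0)
        path = simulate_state_path(scheme, 1e4, 0.1, seed=1)
        occ = np.mean(path == 0)
        assert occ == pytest.approx(0.5, abs=0.02)

    def test_mean_dwell_matches_total_exit_rate(self):
        # state P with total exit rate 2/s -> mean dwell 0.5 s
        scheme = two_state_scheme(2.0, 2.0)
        rng = np.random.default_rng(3)
        states, times = simulate._gillespie_events(scheme, 12000.0, rng, 0)
        dwell = np.diff(times)  # completed dwells only
        d0 = dwell[states[:-1] == 0]
        assert d0.size >= 1e4
        assert np.mean(d0) == pytest.approx(0.5, rel=0.02)

    def test_dwell_times_are_exponential(self):
        scheme = two_state_scheme(2.0, 2.0)
        rng = np.random.default_rng(4)
        states, times = simulate._gillespie_events(scheme, 12000.0, rng, 0)
        d0 = np.diff(times)[states[:-1] == 0][:10_000]
        _, p = sps.kstest(d0, "expon", args=(0.0, 0.5))
        assert p > 0.01

    def test_bound_fraction_converges_to_stationary(self, pol1_scheme):
        pi = pol1_scheme.stationary_distribution()
        bound_true = pi[pol1_scheme.bound_flags].sum()
        rng = np.random.default_rng(5)
        frames = [simulate_state_path(pol1_scheme, 100.0, 0.1, rng)
                  for _ in range(100)]  # 10^4 s total
        lab = np.concatenate(frames)
        bound = np.mean(pol1_scheme.bound_flags[lab])
        assert bound == pytest.approx(bound_true, abs=0.02)

    def test_invalid_arguments(self):
        scheme = two_state_scheme()
        with pytest.raises(ValueError):
            simulate_state_path(scheme, 0.0, 0.1, seed=0)
        with pytest.raises(ValueError):
            simulate_state_path(scheme, 10.0, -0.1, seed=0)


class TestSchemeValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            two_state_scheme(-1.0, 1.0)

    def test_two_unbound_states_rejected(self):
        with pytest.raises(ValueError, match="unbound"):
            KineticScheme(
                state_names=["U", "U2"],
                rate_matrix=np.zeros((2, 2)),
                bound_flags=np.array([False, False]),
                fret_means=np.array([0.05, 0.05]),
                fret_sds=np.array([0.0, 0.0]),
            )

    def test_fret_mean_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="fret_means"):
            KineticScheme(
                state_names=["P"],
                rate_matrix=np.zeros((1, 1)),
                bound_flags=np.array([True]),
                fret_means=np.array([1.5]),
                fret_sds=np.array([0.0]),
            )


def noiseless_phot(total=1000.0):
    return PhotophysicsModel(
        total_intensity=total, background_d=0.0, background_a=0.0,
        noise_sd=0.0, leakage_alpha=0.0, bleach_rate=0.0,
    )


class TestRendering:
    def test_deterministic_intensity_split(self):
        scheme = two_state_scheme()
        trace = render_trace(
            np.zeros(5, dtype=int), scheme, noiseless_phot(), 1, seed=0
        )
        np.testing.assert_allclose(trace.donor, 200.0)
        np.testing.assert_allclose(trace.acceptor, 800.0)

    def test_scheme2_unbound_frames_are_dark(self):
        scheme = KineticScheme(
            state_names=["U", "P"], rate_matrix=np.zeros((2, 2)),
            bound_flags=np.array([False, True]),
            fret_means=np.array([0.05, 0.6]),
            fret_sds=np.array([0.0, 0.0]),
        )
        trace = render_trace(
            np.zeros(4, dtype=int), scheme, noiseless_phot(), 2, seed=0
        )
        np.testing.assert_allclose(trace.donor, 0.0)
        np.testing.assert_allclose(trace.acceptor, 0.0)

    def test_fret_ratio_inverts_noiseless_rendering(self, pol1_scheme):
        scheme = KineticScheme(
            state_names=pol1_scheme.state_names,
            rate_matrix=pol1_scheme.rate_matrix,
            bound_flags=pol1_scheme.bound_flags,
            fret_means=pol1_scheme.fret_means,
            fret_sds=np.zeros(3),
        )
        path = np.array([0, 1, 2, 1, 0, 2])
        phot = PhotophysicsModel(
            total_intensity=350.0, background_d=20.0, background_a=15.0,
            noise_sd=0.0, leakage_alpha=0.08, bleach_rate=0.0,
        )
        trace = render_trace(path, scheme, phot, 1, seed=0)
        donor = trace.donor - phot.background_d
        acceptor = (trace.acceptor - phot.background_a
                    - phot.leakage_alpha * donor)
        e = acceptor / (acceptor + donor)
        np.testing.assert_allclose(e, scheme.fret_means[path], atol=1e-12)

    def test_bleach_zeroes_both_channels(self):
        scheme = two_state_scheme()
        phot = PhotophysicsModel(
            total_intensity=1000.0, background_d=0.0, background_a=0.0,
            noise_sd=0.0, leakage_alpha=0.0, bleach_rate=5.0,
        )
        trace = render_trace(np.zeros(600, dtype=int), scheme, phot, 1,
                             seed=2)
        assert trace.bleach_index is not None
        np.testing.assert_allclose(trace.donor[trace.bleach_index:], 0.0)
        np.testing.assert_allclose(trace.acceptor[trace.bleach_index:], 0.0)
        assert np.all(trace.donor[: trace.bleach_index] > 0)

    def test_invalid_labeling_scheme(self):
        scheme = two_state_scheme()
        with pytest.raises(ValueError, match="labeling_scheme"):
            render_trace(np.zeros(3, dtype=int), scheme, noiseless_phot(),
                         3, seed=0)


class TestDataset:
    def test_same_seed_is_bit_identical(self, pol1_scheme, photophysics):
        a, _ = simulate_dataset(pol1_scheme, photophysics, 5, 10.0, 0.1, 1,
                                seed=7)
        b, _ = simulate_dataset(pol1_scheme, photophysics, 5, 10.0, 0.1, 1,
                                seed=7)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.donor, tb.donor)
            np.testing.assert_array_equal(ta.acceptor, tb.acceptor)
            assert ta.bleach_index == tb.bleach_index

    def test_zero_traces_rejected(self, pol1_scheme, photophysics):
        with pytest.raises(ValueError, match="n_traces"):
            simulate_dataset(pol1_scheme, photophysics, 0, 10.0, 0.1, 1,
                             seed=0)

    def test_ground_truth_matches_trace_lengths(self, default_dataset):
        ts, truth = default_dataset
        assert len(truth.state_paths) == len(ts)
        for trace, path in zip(ts, truth.state_paths):
            assert len(trace) == path.size
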