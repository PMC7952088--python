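"""Global HMM training and Viterbi idealization."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from polfret import hmm
from polfret.hmm import (HmmModel, StatePath, fit_global_hmm, select_n_states,
                         viterbi_decode, viterbi_path)


def random_model_and_obs(rng, max_states=3, max_frames=8):
    k = int(rng.integers(1, max_states + 1))
    n = int(rng.integers(2, max_frames + 1))
    transmat = rng.dirichlet(np.ones(k), size=k)
    startprob = rng.dirichlet(np.ones(k))
    model = HmmModel(
        means=np.sort(rng.uniform(0, 1, k)),
        variances=rng.uniform(0.002, 0.05, k),
        transmat=transmat,
        startprob=startprob,
    )
    x = rng.uniform(-0.2, 1.2, n)
    return model, x


def brute_force_map_path(model, x):
    """Exhaustive argmax over all state sequences (lexicographic ties)."""
    log_b = model.log_emission(x)
    log_a = np.log(model.transmat)
    log_pi = np.log(model.startprob)
    best, best_lp = None, -np.inf
    for seq in itertools.product(range(model.n_states), repeat=x.size):
        lp = log_pi[seq[0]] + log_b[0, seq[0]]
        for t in range(1, x.size):
            lp += log_a[seq[t - 1], seq[t]] + log_b[t, seq[t]]
        if lp > best_lp:
            best, best_lp = seq, lp
    return np.asarray(best)


class TestViterbi:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            model, x = random_model_and_obs(rng)
            np.testing.assert_array_equal(
                viterbi_path(model, x), brute_force_map_path(model, x)
            )

    def test_single_state_labels_everything_zero(self):
        model = HmmModel(
            means=np.array([0.5]), variances=np.array([0.01]),
            transmat=np.ones((1, 1)), startprob=np.ones(1),
        )
        assert np.all(viterbi_path(model, np.linspace(0, 1, 20)) == 0)

    def test_identical_states_tie_breaks_to_lower_index(self):
        model = HmmModel(
            means=np.array([0.5, 0.5]), variances=np.array([0.01, 0.01]),
            transmat=np.full((2, 2), 0.5), startprob=np.array([0.5, 0.5]),
        )
        assert np.all(viterbi_path(model, np.full(10, 0.5)) == 0)

    def test_extreme_observations_do_not_produce_nan(self):
        model = HmmModel(
            means=np.array([0.2, 0.8]), variances=np.array([1e-4, 1e-4]),
            transmat=np.array([[0.9, 0.1], [0.1, 0.9]]),
            startprob=np.array([0.5, 0.5]),
        )
        path = viterbi_path(model, np.array([50.0, -50.0, 0.8]))
        assert path.shape == (3,)
        assert np.all((path == 0) | (path == 1))

    def test_decode_skips_gaps_in_analysis_region(self):
        from polfret.correct import FretTrace

        model = HmmModel(
            means=np.array([0.2, 0.8]), variances=np.array([0.01, 0.01]),
            transmat=np.array([[0.9, 0.1], [0.1, 0.9]]),
            startprob=np.array([0.5, 0.5]),
        )
        e = np.array([0.8, 0.8, np.nan, 0.2, 0.2])
        valid = np.array([True, True, False, True, True])
        ft = FretTrace(E=e, valid_mask=valid, bound_mask=valid, frame_dt=0.1)
        path = viterbi_decode(model, ft)
        np.testing.assert_array_equal(path.labels, [1, 1, -1, 0, 0])
        segs = path.segments()
        assert segs == [(1, 0, 2), (0, 3, 2)]


class TestEmTraining:
    def test_one_state_fit_equals_pooled_moments(self):
        rng = np.random.default_rng(0)
        seqs = [rng.normal(0.6, 0.1, n) for n in (30, 50, 20)]
        model = fit_global_hmm(seqs, n_states=1, seed=0)
        pooled = np.concatenate(seqs)
        assert model.means[0] == pytest.approx(pooled.mean(), abs=1e-9)
        assert model.variances[0] == pytest.approx(pooled.var(), abs=1e-9)

    def test_loglik_nondecreasing_over_iterations(self, pn_observations):
        obs, _ = pn_observations
        model = fit_global_hmm(obs[:10], n_states=2, seed=1)
        diffs = np.diff(model.ll_history)
        assert np.all(diffs >= -1e-8)

    def test_two_state_parameter_recovery(self, pn_scheme, pn_observations):
        obs, _ = pn_observations
        model = fit_global_hmm(obs, n_states=2, seed=0)
        # canonical order: state 0 = N (0.6), state 1 = P (0.8)
        assert model.means[0] == pytest.approx(0.6, abs=0.02)
        assert model.means[1] == pytest.approx(0.8, abs=0.02)
        q = pn_scheme.rate_matrix.copy()
        np.fill_diagonal(q, -q.sum(axis=1))
        true_frame = expm(q * 0.1)  # order P, N
        assert model.transmat[1, 0] == pytest.approx(
            true_frame[0, 1], rel=0.2
        )
        assert model.transmat[0, 1] == pytest.approx(
            true_frame[1, 0], rel=0.2
        )

    def test_well_separated_states_decode_accurately(self):
        rng = np.random.default_rng(5)
        means = np.array([0.2, 0.8])
        truth, obs = [], []
        for _ in range(20):
            p = (rng.random(300) < 0.5).astype(int)
            # sticky path: switch with prob 0.1
            for t in range(1, p.size):
                if rng.random() > 0.1:
                    p[t] = p[t - 1]
            truth.append(p)
            obs.append(means[p] + 0.03 * rng.standard_normal(p.size))
        model = fit_global_hmm(obs, n_states=2, seed=0)
        agree = total = 0
        for p, x in zip(truth, obs):
            path = viterbi_path(model, x)
            agree += int(np.sum(path == p))
            total += p.size
        assert agree / total >= 0.99

    def test_needs_enough_frames(self):
        with pytest.raises(ValueError, match="10 valid frames"):
            fit_global_hmm([np.array([0.5, 0.6])], n_states=1)

    def test_canonical_order_is_seed_independent(self, pn_observations):
        obs, _ = pn_observations
        m1 = fit_global_hmm(obs[:15], n_states=2, seed=0)
        m2 = fit_global_hmm(obs[:15], n_states=2, seed=99)
        assert np.all(np.diff(m1.means) >= 0)
        np.testing.assert_allclose(m1.means, m2.means, atol=5e-3)

    def test_matches_hmmlearn_reference(self, pn_observations):
        """Independent cross-check of the EM fit against hmmlearn."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        obs, _ = pn_observations
        seqs = obs[:15]
        ours = fit_global_hmm(seqs, n_states=2, seed=0)
        ref = hmmlearn.GaussianHMM(
            n_components=2, covariance_type="diag", n_iter=500, tol=1e-4,
            random_state=0,
        )
        x = np.concatenate(seqs)[:, None]
        lengths = [len(s) for s in seqs]
        ref.fit(x, lengths)
        ref_means = np.sort(ref.means_.ravel())
        np.testing.assert_allclose(ours.means, ref_means, atol=0.01)
        ref_ll = ref.score(x, lengths)
        assert ours.log_likelihood == pytest.approx(ref_ll, abs=5.0)


class TestModelSelection:
    def test_two_state_data_selects_two(self, pn_observations):
        obs, _ = pn_observations
        chosen, table = select_n_states(obs[:15], [1, 2, 3, 4], seed=0)
        assert chosen == 2
        bics = table.set_index("n_states")["bic"]
        assert bics[1] > bics[2]  # adding the true second state helps

    def test_single_state_data_selects_one(self):
        rng = np.random.default_rng(2)
        obs = [rng.normal(0.5, 0.05, 200) for _ in range(5)]
        chosen, _ = select_n_states(obs, [1, 2, 3], seed=0)
        assert chosen == 1

    def test_empty_candidates_rejected(self, pn_observations):
        obs, _ = pn_observations
        with pytest.raises(ValueError):
            select_n_states(obs[:5], [], seed=0)


class TestModelSerialization:
    def test_json_round_trip(self, tmp_path, pn_observations):
        obs, _ = pn_observations
        model = fit_global_hmm(obs[:10], n_states=2, seed=0)
        path = tmp_path / "model.json"
        model.save(path)
        back = HmmModel.load(path)
        np.testing.assert_allclose(back.means, model.means)
        np.testing.assert_allclose(back.transmat, model.transmat)

    def test_invalid_transition_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            HmmModel(
                means=np.array([0.2, 0.8]), variances=np.array([0.01, 0.01]),
                transmat=np.array([[0.9, 0.2], [0.1, 0.9]]),
                startprob=np.array([0.5, 0.5]),
            )
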