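"""Model core: emission weights, decoding, likelihood, and learning.

Small-instance behavior is checked against brute-force path enumeration;
the density-emission log-likelihood is cross-checked against hmmlearn's
GaussianHMM on identical parameters.
"""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import norm

from boutseg import (
    HMMParams,
    LabelSet,
    baum_welch,
    emission_weight,
    forward_backward,
    label_states,
    sample_hmm_observations,
    supervised_fit,
    viterbi,
)
from boutseg.errors import InsufficientLabelsError, MomentError, ParameterError
from boutseg.trace_io import OFF, ON

from conftest import make_trace


def random_params(rng):
    stay = rng.uniform(0.5, 0.99, 2)
    pi_on = rng.uniform(0.05, 0.95)
    return HMMParams(
        pi_on=pi_on, pi_off=1 - pi_on,
        a_on_on=stay[0], a_on_off=1 - stay[0],
        a_off_on=1 - stay[1], a_off_off=stay[1],
        mu_on=rng.uniform(-0.1, 0.3), mu_off=rng.uniform(-0.6, -0.05),
        sigma_on=rng.uniform(0.05, 0.4), sigma_off=rng.uniform(0.05, 0.4),
    )


def path_log_score(path, obs, params, emission):
    """Log score of one explicit state path (independent of the DP code)."""
    if emission == "cdf":
        def logb(s, x):
            return float(np.log(emission_weight(x, s, params)))
    else:
        def logb(s, x):
            return float(norm.logpdf(x, params.mu[s], params.sigma[s]))
    A = params.transmat
    total = float(np.log(params.pi[path[0]])) + logb(path[0], obs[0])
    for t in range(1, len(obs)):
        total += float(np.log(A[path[t - 1], path[t]])) + logb(path[t], obs[t])
    return total


def brute_force_best_path(obs, params, emission="cdf"):
    best, best_score = None, -np.inf
    for path in itertools.product((ON, OFF), repeat=len(obs)):
        s = path_log_score(path, obs, params, emission)
        if s > best_score:
            best, best_score = path, s
    return np.array(best), best_score


def brute_force_loglik(obs, params, emission="density"):
    scores = [
        path_log_score(path, obs, params, emission)
        for path in itertools.product((ON, OFF), repeat=len(obs))
    ]
    return float(logsumexp(scores))


class TestEmissionWeight:
    def test_half_at_state_mean(self):
        p = random_params(np.random.default_rng(0))
        assert np.isclose(emission_weight(p.mu_on, ON, p), 0.5)
        assert np.isclose(emission_weight(p.mu_off, OFF, p), 0.5)

    def test_one_sigma_above_mean(self):
        p = random_params(np.random.default_rng(1))
        # numerically integrated standard normal CDF at +1
        from scipy.integrate import quad
        phi1 = 0.5 + quad(lambda z: np.exp(-z * z / 2) / np.sqrt(2 * np.pi), 0, 1)[0]
        assert np.isclose(emission_weight(p.mu_on + p.sigma_on, ON, p), phi1, atol=1e-9)

    def test_monotone_in_observation(self):
        p = random_params(np.random.default_rng(2))
        xs = np.linspace(-1, 1, 41)
        on = emission_weight(xs, ON, p)
        off = emission_weight(xs, OFF, p)
        assert np.all(np.diff(on) >= 0)
        assert np.all(np.diff(off) <= 0)

    def test_clamped_to_weight_floor(self):
        p = random_params(np.random.default_rng(3))
        assert emission_weight(-1e6, ON, p) >= 1e-12


class TestViterbi:
    def test_single_observation_picks_higher_weighted_state(self):
        p = random_params(np.random.default_rng(4))
        x = p.mu_on + 3 * p.sigma_on
        assert viterbi(np.array([x]), p)[0] == ON

    def test_symmetric_tie_resolves_to_all_on(self):
        p = HMMParams(pi_on=.5, pi_off=.5, a_on_on=.8, a_on_off=.2,
                      a_off_on=.2, a_off_off=.8,
                      mu_on=0.2, mu_off=-0.2, sigma_on=0.1, sigma_off=0.1)
        path = viterbi(np.zeros(6), p)
        assert np.all(path == ON)

    @pytest.mark.parametrize("emission", ["cdf", "density"])
    def test_matches_enumeration_on_random_instances(self, emission):
        rng = np.random.default_rng(42)
        for _ in range(25):
            T = int(rng.integers(1, 11))
            p = random_params(rng)
            obs = rng.normal(0, 0.3, T)
            expect, expect_score = brute_force_best_path(obs, p, emission)
            got = viterbi(obs, p, emission=emission)
            got_score = path_log_score(got, obs, p, emission)
            assert np.isclose(got_score, expect_score, atol=1e-9)
            assert np.array_equal(got, expect)

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            HMMParams(pi_on=.7, pi_off=.7, a_on_on=.9, a_on_off=.1,
                      a_off_on=.1, a_off_off=.9, mu_on=0, mu_off=0,
                      sigma_on=.1, sigma_off=.1)


class TestForwardBackward:
    def test_single_point_closed_form(self):
        p = random_params(np.random.default_rng(5))
        x = np.array([0.1])
        post = forward_backward(x, p, emission="cdf")
        w = np.array([p.pi_on * emission_weight(0.1, ON, p),
                      p.pi_off * emission_weight(0.1, OFF, p)])
        assert np.allclose(post.gamma[0], w / w.sum())
        assert np.isclose(post.log_likelihood, np.log(w.sum()))

    def test_gamma_rows_sum_to_one(self):
        rng = np.random.default_rng(6)
        obs = rng.normal(0, 0.3, 200)
        post = forward_backward(obs, random_params(rng))
        assert np.allclose(post.gamma.sum(axis=1), 1.0, atol=1e-9)

    @pytest.mark.parametrize("emission", ["cdf", "density"])
    def test_loglik_matches_exhaustive_path_sum(self, emission):
        rng = np.random.default_rng(7)
        for _ in range(20):
            T = int(rng.integers(1, 11))
            p = random_params(rng)
            obs = rng.normal(0, 0.3, T)
            post = forward_backward(obs, p, emission=emission)
            assert np.isclose(post.log_likelihood,
                              brute_force_loglik(obs, p, emission), atol=1e-9)

    def test_loglik_agrees_with_hmmlearn(self):
        hmm = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(8)
        p = random_params(rng)
        obs = rng.normal(0, 0.3, 500)
        model = hmm.GaussianHMM(n_components=2, covariance_type="diag",
                                init_params="")
        model.startprob_ = p.pi
        model.transmat_ = p.transmat
        model.means_ = p.mu[:, None]
        model.covars_ = (p.sigma ** 2)[:, None]
        ref = model.score(obs[:, None])
        ours = forward_backward(obs, p, emission="density").log_likelihood
        assert np.isclose(ours, ref, atol=1e-8)


class TestBaumWelch:
    def test_loglik_nondecreasing(self):
        true = HMMParams(pi_on=.5, pi_off=.5, a_on_on=.9, a_on_off=.1,
                         a_off_on=.1, a_off_off=.9, mu_on=.1, mu_off=-.3,
                         sigma_on=.1, sigma_off=.15)
        obs, _ = sample_hmm_observations(true, 500, seed=0)
        fit = baum_welch(obs, max_iter=50)
        assert np.all(np.diff(fit.log_likelihoods) >= -1e-8)

    def test_zero_iterations_returns_init(self):
        rng = np.random.default_rng(9)
        init = random_params(rng)
        fit = baum_welch(rng.normal(0, 1, 50), init=init, max_iter=0)
        assert fit.params == init

    def test_fixed_point(self):
        true = HMMParams(pi_on=.5, pi_off=.5, a_on_on=.95, a_on_off=.05,
                         a_off_on=.05, a_off_off=.95, mu_on=.05, mu_off=-.3,
                         sigma_on=.1, sigma_off=.1)
        obs, _ = sample_hmm_observations(true, 2000, seed=1)
        fit = baum_welch(obs, tol=1e-8)
        refit = baum_welch(obs, init=fit.params, tol=1e-8, max_iter=5)
        rel = abs(refit.log_likelihoods[-1] - fit.log_likelihoods[-1])
        assert rel <= 1e-6 * abs(fit.log_likelihoods[-1])

    def test_recovers_known_parameters(self):
        true = HMMParams(pi_on=.5, pi_off=.5, a_on_on=.95, a_on_off=.05,
                         a_off_on=.05, a_off_off=.95, mu_on=.05, mu_off=-.3,
                         sigma_on=.1, sigma_off=.1)
        obs, _ = sample_hmm_observations(true, 10_000, seed=2)
        p = baum_welch(obs).params
        if p.mu_on < p.mu_off:  # relabel
            p = HMMParams.from_arrays(p.pi[::-1], p.transmat[::-1, ::-1].copy(),
                                      p.mu[::-1], p.sigma[::-1])
        assert abs(p.a_on_on - 0.95) < 0.02
        assert abs(p.a_off_off - 0.95) < 0.02
        assert abs(p.mu_on - 0.05) < 0.05
        assert abs(p.mu_off + 0.30) < 0.05


class TestSupervisedFit:
    def test_hand_counted_20_point_fixture(self):
        deltas = np.array([0.1, 0.12, 0.08, 0.11, 0.09, 0.1, 0.13, 0.07, 0.1, 0.11,
                           -0.3, -0.28, -0.33, -0.29, -0.31, -0.3, -0.27, -0.32,
                           -0.3, -0.29])
        labels = LabelSet(1, [ON] * 10 + [OFF] * 10)
        p = supervised_fit(deltas, labels)
        assert p.a_on_on == pytest.approx(9 / 10, abs=1e-12)
        assert p.a_on_off == pytest.approx(1 / 10, abs=1e-12)
        assert p.a_off_off == pytest.approx(1.0, abs=1e-12)
        assert p.a_off_on == pytest.approx(0.0, abs=1e-12)
        assert p.pi_on == 1.0 and p.pi_off == 0.0
        assert p.mu_on == pytest.approx(np.mean(deltas[:10]), abs=1e-12)
        assert p.sigma_off == pytest.approx(np.std(deltas[10:], ddof=1), abs=1e-12)

    def test_single_state_labels_rejected(self):
        with pytest.raises(InsufficientLabelsError):
            supervised_fit(np.zeros(5), LabelSet(1, [ON] * 5))

    def test_zero_variance_floors_sigma(self):
        deltas = np.array([0.2, 0.2, 0.2, -0.4, -0.3])
        p = supervised_fit(deltas, LabelSet(1, [ON, ON, ON, OFF, OFF]))
        assert p.mu_on == pytest.approx(0.2)
        assert p.sigma_on == 1e-3

    def test_too_few_points_for_moments(self):
        with pytest.raises((MomentError, InsufficientLabelsError)):
            supervised_fit(np.array([0.1, -0.2, 0.1]), LabelSet(1, [ON, OFF, ON]))

    def test_consistent_with_own_viterbi_labels(self):
        """Counting transitions of its own decode reproduces a self-consistent fit."""
        true = HMMParams(pi_on=.5, pi_off=.5, a_on_on=.95, a_on_off=.05,
                         a_off_on=.1, a_off_off=.9, mu_on=.1, mu_off=-.4,
                         sigma_on=.08, sigma_off=.12)
        obs, _ = sample_hmm_observations(true, 3000, seed=3)
        p1 = supervised_fit(obs, LabelSet(1, viterbi(obs, true, emission="density")))
        dec = viterbi(obs, p1, emission="density")
        p2 = supervised_fit(obs, LabelSet(1, dec))
        counts = np.zeros((2, 2))
        for a, b in zip(dec[:-1], dec[1:]):
            counts[a, b] += 1
        assert p2.a_on_on == pytest.approx(counts[ON, ON] / counts[ON].sum())
        assert p2.a_off_off == pytest.approx(counts[OFF, OFF] / counts[OFF].sum())


class TestLabelStates:
    def test_decodes_well_separated_alternation(self):
        p = HMMParams(pi_on=.5, pi_off=.5, a_on_on=.5, a_on_off=.5,
                      a_off_on=.5, a_off_off=.5, mu_on=.5, mu_off=-.5,
                      sigma_on=.05, sigma_off=.05)
        # build a trace whose deltas alternate between the two state means
        egg = [30.0]
        pattern = [ON, OFF] * 10
        for s in pattern[1:]:
            egg.append(egg[-1] + (0.5 if s == ON else -0.5))
        tr = make_trace(egg)
        dec = label_states(tr, p)
        assert np.array_equal(dec[1:], pattern[1:])

    def test_constant_trace_with_on_friendly_params_is_all_on(self):
        p = HMMParams(pi_on=.5, pi_off=.5, a_on_on=.9, a_on_off=.1,
                      a_off_on=.1, a_off_off=.9, mu_on=0.0, mu_off=-.5,
                      sigma_on=.1, sigma_off=.1)
        tr = make_trace([36.0] * 20)
        assert np.all(label_states(tr, p) == ON)

    def test_invariant_to_constant_temperature_offset(self, clear_fixture):
        trace, _ = clear_fixture
        p = HMMParams(pi_on=.5, pi_off=.5, a_on_on=.97, a_on_off=.03,
                      a_off_on=.06, a_off_off=.94, mu_on=.02, mu_off=-.25,
                      sigma_on=.1, sigma_off=.12)
        shifted = make_trace(trace.egg_temp[:500] + 5.0, interval=30.0)
        base = make_trace(trace.egg_temp[:500], interval=30.0)
        assert np.array_equal(label_states(base, p), label_states(shifted, p))


class TestParamsConfig:
    def test_round_trip(self, tmp_path):
        p = random_params(np.random.default_rng(10))
        path = tmp_path / "params.conf"
        p.to_file(path)
        assert HMMParams.from_file(path) == p

    def test_exactly_ten_keys(self, tmp_path):
        p = random_params(np.random.default_rng(11))
        path = tmp_path / "params.conf"
        p.to_file(path)
        keys = [line.split("=")[0].strip() for line in open(path) if line.strip()]
        assert len(keys) == 10 and len(set(keys)) == 10

    def test_missing_key_rejected(self, tmp_path):
        p = random_params(np.random.default_rng(12))
        path = tmp_path / "params.conf"
        p.to_file(path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]))
        with pytest.raises(ParameterError, match="missing"):
            HMMParams.from_file(path)
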