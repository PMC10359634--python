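"""HMM idealization: EM fitting, model selection, Viterbi decoding."""

import numpy as np
import pytest

from ribofret.hmm import (
    HmmModel,
    fit_hmm,
    posterior_probabilities,
    select_model,
    stabilize_for_decoding,
    viterbi,
)
from ribofret.traces import AnnotatedTrace, Trace


def make_atrace(fret, dt=0.1):
    n = fret.size
    tr = Trace("m", dt, np.full(n, 500.0), np.full(n, 500.0))
    return AnnotatedTrace(trace=tr, fret=fret, arrival_frame=0, bleach_frame=None,
                          acceptor_bleach_frame=None, usable_start=0, usable_end=n,
                          qc={"passed": True})


def markov_fret(rng, n, a01, a10, means=(0.22, 0.34), sd=0.0):
    states = np.zeros(n, dtype=int)
    s = 0
    for i in range(n):
        states[i] = s
        u = rng.random()
        if s == 0 and u < a01:
            s = 1
        elif s == 1 and u < a10:
            s = 0
    fret = np.array(means)[states] + (rng.normal(0, sd, n) if sd > 0 else 0.0)
    return states, fret


def forward_loglik(x, means, sds, transmat, startprob):
    """Independent forward-algorithm implementation for oracle scoring."""
    from scipy.stats import norm
    n, K = x.size, len(means)
    logB = np.stack([norm.logpdf(x, means[k], sds[k]) for k in range(K)], axis=1)
    alpha = np.log(startprob) + logB[0]
    for t in range(1, n):
        m = alpha[:, None] + np.log(transmat)
        alpha = logB[t] + np.logaddexp.reduce(m, axis=0)
    return np.logaddexp.reduce(alpha)


class TestFitHmm:
    def test_noiseless_alternating_recovery(self):
        rng = np.random.default_rng(0)
        _, fret = markov_fret(rng, 2000, 0.05, 0.1, sd=1e-4)
        m = fit_hmm([fret], K=2, frame_interval=0.1, n_restarts=3, seed=0)
        assert m.means == pytest.approx([0.22, 0.34], abs=1e-3)
        assert m.transmat[0, 1] == pytest.approx(0.05, abs=0.015)
        assert m.transmat[1, 0] == pytest.approx(0.1, abs=0.03)

    def test_pooled_recovery_at_low_snr(self):
        """100 pooled noisy traces, true means 0.22/0.34: recovered within
        +/-0.02."""
        rng = np.random.default_rng(1)
        fret_set = [markov_fret(rng, 300, 0.04, 0.09, sd=0.04)[1] for _ in range(100)]
        m = fit_hmm(fret_set, K=2, frame_interval=0.1, n_restarts=3, seed=0)
        assert m.means[0] == pytest.approx(0.22, abs=0.02)
        assert m.means[1] == pytest.approx(0.34, abs=0.02)

    def test_em_beats_random_parameterization_oracle(self):
        """On a 50-frame trace the EM log-likelihood is at least as good as
        the best of 1000 random parameterizations, scored by an independent
        forward algorithm."""
        rng = np.random.default_rng(2)
        _, fret = markov_fret(rng, 50, 0.1, 0.15, sd=0.03)
        m = fit_hmm([fret], K=2, frame_interval=0.1, n_restarts=5, seed=0)
        em_ll = forward_loglik(fret, m.means, m.sds, m.transmat, m.startprob)
        best = -np.inf
        for _ in range(1000):
            means = np.sort(rng.uniform(0.0, 0.6, 2))
            sds = rng.uniform(0.01, 0.2, 2)
            a = rng.uniform(0.01, 0.99, 2)
            tm = np.array([[1 - a[0], a[0]], [a[1], 1 - a[1]]])
            sp = rng.dirichlet([1, 1])
            best = max(best, forward_loglik(fret, means, sds, tm, sp))
        assert em_ll >= best - 1e-6

    def test_degenerate_constant_data_flagged(self):
        m = fit_hmm([np.full(200, 0.25)], K=2, frame_interval=0.1, n_restarts=2, seed=0)
        assert m.non_identifiable

    def test_label_order_canonicalized(self):
        rng = np.random.default_rng(3)
        _, fret = markov_fret(rng, 1000, 0.05, 0.1, sd=0.03)
        m = fit_hmm([fret], K=2, frame_interval=0.1, n_restarts=3, seed=0)
        assert m.means[0] < m.means[1]

    def test_transition_recovery_with_pooled_transitions(self):
        """>= 5000 pooled transitions: off-diagonal transition
        probabilities recovered within 10% relative error."""
        rng = np.random.default_rng(4)
        fret_set = [markov_fret(rng, 600, 0.05, 0.10, sd=0.03)[1] for _ in range(150)]
        m = fit_hmm(fret_set, K=2, frame_interval=0.1, n_restarts=3, seed=0)
        assert m.transmat[0, 1] == pytest.approx(0.05, rel=0.10)
        assert m.transmat[1, 0] == pytest.approx(0.10, rel=0.10)


class TestSelectModel:
    def test_single_gaussian_selects_one_state(self):
        rng = np.random.default_rng(5)
        data = [rng.normal(0.25, 0.03, 400) for _ in range(5)]
        K, _ = select_model(data, K_candidates=(1, 2), frame_interval=0.1,
                            n_restarts=2, seed=0)
        assert K == 1

    def test_two_state_data_selects_two_states(self):
        """Clear two-state data selects K = 2 in >= 18 of 20 seeded runs."""
        wins = 0
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            data = [markov_fret(rng, 400, 0.06, 0.1, sd=0.04)[1] for _ in range(4)]
            K, _ = select_model(data, K_candidates=(1, 2), frame_interval=0.1,
                                n_restarts=2, seed=s)
            wins += K == 2
        assert wins >= 18

    def test_three_levels_with_off_baseline(self):
        rng = np.random.default_rng(6)
        seq = np.concatenate([
            rng.normal(0.02, 0.03, 300),   # FRET-off baseline
            rng.normal(0.22, 0.03, 300),
            rng.normal(0.34, 0.03, 300),
            rng.normal(0.02, 0.03, 200),
        ])
        K, _ = select_model([seq], K_candidates=(1, 2, 3), frame_interval=0.1,
                            n_restarts=3, seed=0)
        assert K == 3


class TestViterbi:
    def _model(self, sd=0.03):
        return HmmModel(
            n_states=2, means=np.array([0.22, 0.34]), sds=np.array([sd, sd]),
            transmat=np.array([[0.95, 0.05], [0.1, 0.9]]),
            startprob=np.array([0.7, 0.3]),
            log_likelihood=0.0, n_obs=0, frame_interval=0.1,
        )

    def test_noiseless_trace_decodes_exactly(self):
        rng = np.random.default_rng(7)
        states, fret = markov_fret(rng, 500, 0.05, 0.1, sd=1e-5)
        path = viterbi(make_atrace(fret), self._model(sd=0.02))
        np.testing.assert_array_equal(path.states, states)

    def test_decoding_matches_brute_force_enumeration(self):
        """12-frame trace: Viterbi equals exhaustive search over all 2^12
        state sequences scored by an independently coded joint likelihood."""
        from scipy.stats import norm
        rng = np.random.default_rng(8)
        _, fret = markov_fret(rng, 12, 0.2, 0.3, sd=0.05)
        m = self._model(sd=0.05)
        path = viterbi(make_atrace(fret), m)
        best_seq, best_ll = None, -np.inf
        for code in range(2**12):
            seq = [(code >> i) & 1 for i in range(12)]
            ll = np.log(m.startprob[seq[0]]) + norm.logpdf(fret[0], m.means[seq[0]], m.sds[seq[0]])
            for t in range(1, 12):
                ll += np.log(m.transmat[seq[t - 1], seq[t]])
                ll += norm.logpdf(fret[t], m.means[seq[t]], m.sds[seq[t]])
            if ll > best_ll:
                best_seq, best_ll = seq, ll
        np.testing.assert_array_equal(path.states, best_seq)

    def test_frame_accuracy_at_high_snr(self):
        """SNR ~5, dwells >= 10 frames: >= 99% of frames correctly
        assigned."""
        rng = np.random.default_rng(9)
        correct = total = 0
        for _ in range(25):
            states, fret = markov_fret(rng, 400, 0.04, 0.05, sd=0.024)
            path = viterbi(make_atrace(fret), self._model(sd=0.024))
            correct += int(np.sum(path.states == states))
            total += states.size
        assert correct / total >= 0.99

    def test_single_frame_excursions_not_qualified(self):
        """Injected 1-frame excursions of sub-threshold amplitude are not
        amplitude-qualified."""
        fret = np.full(200, 0.22)
        for i in (50, 120):
            fret[i] = 0.27  # below half the 0.12 state separation above 0.22
        rng = np.random.default_rng(10)
        fret = fret + rng.normal(0, 0.005, 200)
        path = viterbi(make_atrace(fret), self._model(sd=0.012))
        if path.transition_frames.size:
            assert not path.qualified.any()
        assert path.n_qualified_transitions() == 0

    def test_posterior_rows_sum_to_one(self):
        rng = np.random.default_rng(11)
        _, fret = markov_fret(rng, 300, 0.05, 0.1, sd=0.03)
        post = posterior_probabilities(fret, self._model())
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_stabilized_decoding_caps_widths(self):
        m = HmmModel(
            n_states=2, means=np.array([0.22, 0.34]), sds=np.array([0.06, 0.03]),
            transmat=np.array([[0.95, 0.05], [0.1, 0.9]]),
            startprob=np.array([0.5, 0.5]),
            log_likelihood=0.0, n_obs=0, frame_interval=0.1,
        )
        d = stabilize_for_decoding(m, max_width_ratio=1.15)
        assert d.sds[0] == pytest.approx(0.03 * 1.15)
        assert m.sds[0] == 0.06  # original untouched
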