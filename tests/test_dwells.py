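"""Dwell extraction, censored mixture MLE, arrival/hyperbolic fits."""

import numpy as np
import pandas as pd
import pytest

from ribofret.dwells import (
    _geometric_compound,
    extract_dwells,
    first_event_times,
    fit_arrival_kinetics,
    fit_dwell_distribution,
    fit_exp_mixture,
    fit_hyperbolic,
    fit_hyperbolic_shared,
    fit_linear_concentration,
    km_conditional_mean,
    rotating_fraction,
    wash_comparison,
)


class FakePath:
    """Minimal idealized-path stand-in for dwell/transition logic."""

    def __init__(self, states, dt=0.1, molecule="m", qualified=None):
        self.states = np.asarray(states, dtype=int)
        self.frame_interval = dt
        self.molecule = molecule
        self.condition = {}
        tf = np.flatnonzero(np.diff(self.states) != 0) + 1
        self.transition_frames = tf
        self.qualified = np.ones(tf.size, dtype=bool) if qualified is None \
            else np.asarray(qualified, dtype=bool)

    @property
    def n_frames(self):
        return self.states.size

    @property
    def duration(self):
        return self.n_frames * self.frame_interval

    def n_qualified_transitions(self, min_flank_frames=1):
        if self.transition_frames.size == 0:
            return 0
        bounds = np.concatenate([[0], self.transition_frames, [self.n_frames]])
        runs = np.diff(bounds)
        return sum(
            1 for i in range(self.transition_frames.size)
            if self.qualified[i] and runs[i] >= min_flank_frames and runs[i + 1] >= min_flank_frames
        )


class TestExtractDwells:
    def test_interior_dwell_with_censored_flanks(self):
        p = FakePath([0, 0, 1, 1, 1, 0], dt=0.1)
        tab = extract_dwells([p], min_dwell_frames=1)
        interior = tab[~(tab.left_censored | tab.right_censored)]
        assert len(interior) == 1
        assert interior.iloc[0]["state"] == 1
        assert interior.iloc[0]["duration_s"] == pytest.approx(0.3)
        flanks = tab[tab.left_censored | tab.right_censored]
        assert set(flanks["state"]) == {0}

    def test_first_dwell_uncensored_in_delivery_mode(self):
        p = FakePath([0, 0, 1, 1, 1, 0], dt=0.1)
        tab = extract_dwells([p], min_dwell_frames=1, first_dwell_censored=False)
        assert not tab.iloc[0]["left_censored"]
        assert tab.iloc[-1]["right_censored"]

    def test_all_static_paths_only_censored(self):
        tab = extract_dwells([FakePath([0] * 50), FakePath([1] * 50)], min_dwell_frames=1)
        assert len(tab) == 2
        assert tab["left_censored"].all() or tab["right_censored"].all()
        assert (~(tab.left_censored | tab.right_censored)).sum() == 0

    def test_short_runs_merged_into_neighbors(self):
        p = FakePath([0] * 10 + [1] + [0] * 10)
        tab = extract_dwells([p], min_dwell_frames=2)
        assert len(tab) == 1
        assert tab.iloc[0]["duration_s"] == pytest.approx(2.1)

    def test_empty_path_set(self):
        tab = extract_dwells([], min_dwell_frames=2)
        assert tab.empty


class TestExpMixtureMle:
    def test_exact_exponential_rate_within_one_percent(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(2.0, 100_000)
        fit = fit_exp_mixture(t, None, 1)
        assert fit.params["k1"] == pytest.approx(0.5, rel=0.01)

    def test_mixture_recovery_and_grid_search_oracle(self):
        """0.7 Exp(0.1 s) + 0.3 Exp(2 s), n = 5000: parameters within 10%
        of truth and the MLE is at least as likely as the best point of an
        independent 2-D grid search."""
        rng = np.random.default_rng(1)
        n = 5000
        fast = rng.random(n) < 0.7
        t = np.where(fast, rng.exponential(0.1, n), rng.exponential(2.0, n))
        fit = fit_exp_mixture(t, None, 2, seed=0)
        assert fit.params["tau1"] == pytest.approx(0.1, rel=0.10)
        assert fit.params["tau2"] == pytest.approx(2.0, rel=0.10)
        assert fit.params["w1"] == pytest.approx(0.7, abs=0.05)

        def loglik(w1, t1, t2):
            return np.sum(np.log(w1 / t1 * np.exp(-t / t1) + (1 - w1) / t2 * np.exp(-t / t2)))

        grid_best = max(
            loglik(w1, t1, t2)
            for w1 in np.linspace(0.4, 0.9, 11)
            for t1 in np.linspace(0.05, 0.3, 15)
            for t2 in np.linspace(1.0, 3.0, 15)
        )
        ours = loglik(fit.params["w1"], fit.params["tau1"], fit.params["tau2"])
        assert ours >= grid_best - 1e-6

    def test_censored_mle_versus_naive_mean_bias(self):
        """Right-censoring at a fixed horizon: the censored MLE recovers the
        true mean while the naive mean over uncensored dwells is biased low."""
        rng = np.random.default_rng(2)
        n = 5000
        x = rng.exponential(2.0, n)
        cens = x > 3.0
        obs = np.minimum(x, 3.0)
        fit = fit_exp_mixture(obs, cens, 1)
        assert fit.mean == pytest.approx(2.0, rel=0.05)
        naive = obs[~cens].mean()
        assert naive < 1.5  # strong downward bias of the naive estimator

    def test_weight_floor_blocks_immortal_component(self):
        rng = np.random.default_rng(3)
        n = 2000
        x = rng.exponential(1.0, n)
        cens = x > 5.0
        obs = np.minimum(x, 5.0)
        fit = fit_exp_mixture(obs, cens, 2, seed=0)
        assert min(fit.params["w1"], 1 - fit.params["w1"]) >= 0.02 - 1e-9
        assert fit.params["tau2"] <= 3.0 * obs.max() + 1e-6

    def test_model_selection_single_vs_double(self):
        rng = np.random.default_rng(4)
        dwells = pd.DataFrame({
            "molecule": "m", "condition": "", "state": "NON",
            "duration_s": rng.exponential(1.0, 2000),
            "left_censored": False, "right_censored": False,
            "prev_state": None, "next_state": None,
        })
        fit = fit_dwell_distribution(dwells, "NON", model="auto")
        assert fit.model == "single-exp"

    def test_too_few_dwells_warns(self):
        rng = np.random.default_rng(5)
        dwells = pd.DataFrame({
            "molecule": "m", "condition": "", "state": "NON",
            "duration_s": rng.exponential(1.0, 25),
            "left_censored": False, "right_censored": False,
            "prev_state": None, "next_state": None,
        })
        sub = dwells.iloc[:21]
        with pytest.warns(UserWarning):
            fit_dwell_distribution(sub.iloc[:21].assign(duration_s=rng.exponential(1.0, 21)),
                                   "NON", model="single-exp", min_uncensored=30)

    def test_geometric_compound_preserves_mean_scaling(self):
        w, taus = np.array([0.75, 0.25]), np.array([0.047, 1.379])
        for rho in (0.1, 0.4, 0.6):
            w2, t2 = _geometric_compound(w, taus, rho)
            assert float(np.dot(w2, t2)) == pytest.approx(np.dot(w, taus) / (1 - rho), rel=1e-6)
            assert np.all(w2 >= 0) and np.all(t2 > 0)

    def test_km_conditional_mean_on_exponential(self):
        rng = np.random.default_rng(6)
        x = rng.exponential(1.0, 20000)
        cens = np.zeros(x.size, bool)
        # memorylessness: E[T | T >= a] = a + 1
        assert km_conditional_mean(x, cens, 0.5) == pytest.approx(1.5, rel=0.05)


class TestRotatingFraction:
    def test_all_static(self):
        frac, per = rotating_fraction([FakePath([0] * 100) for _ in range(10)])
        assert frac == 0.0 and per == 0.0

    def test_exactly_two_transitions_each(self):
        paths = [FakePath([0] * 10 + [1] * 10 + [0] * 10) for _ in range(5)]
        frac, per = rotating_fraction(paths, min_flank_frames=2)
        assert frac == 1.0 and per == 2.0

    def test_constructed_30_percent_mixture(self):
        dyn = [FakePath([0] * 10 + [1] * 10 + [0] * 10) for _ in range(30)]
        static = [FakePath([0] * 30) for _ in range(70)]
        frac, _ = rotating_fraction(dyn + static)
        assert frac == pytest.approx(0.30, abs=1e-12)


class TestArrivalKinetics:
    def test_exact_exponential_rate(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(10.0, 10_000)
        per, _ = fit_arrival_kinetics({50.0: (t, np.ones(t.size, bool))})
        assert per[50.0]["k_obs"] == pytest.approx(0.1, rel=0.02)

    def test_perfect_linear_triple_slope(self):
        conc = np.array([6.25, 25.0, 50.0])
        rates = 3.5e-3 * conc  # per-nM slope 3.5e-3 <=> 3.5 per uM
        fit = fit_linear_concentration(conc, rates, through_origin=True)
        assert fit.params["slope_uM_s"] == pytest.approx(3.5, rel=1e-9)
        fit2 = fit_linear_concentration(conc, rates, through_origin=False)
        assert fit2.params["slope_uM_s"] == pytest.approx(3.5, rel=1e-6)

    def test_cure_model_recovers_rate_with_never_arriving_fraction(self):
        rng = np.random.default_rng(8)
        n = 2000
        active = rng.random(n) < 0.7
        t = np.where(active, rng.exponential(10.0, n), np.inf)
        event = t < 300.0
        times = np.where(event, t, 300.0)
        per, _ = fit_arrival_kinetics({50.0: (times, event)})
        assert per[50.0]["k_obs"] == pytest.approx(0.1, rel=0.05)
        assert per[50.0]["active_fraction"] == pytest.approx(0.7, abs=0.04)

    def test_single_concentration_has_no_slope(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(10.0, 100)
        per, fit = fit_arrival_kinetics({50.0: (t, np.ones(t.size, bool))})
        assert fit is None and 50.0 in per


class TestHyperbolic:
    def test_exact_points_recovered(self):
        c = np.array([10.0, 50.0, 100.0, 500.0, 1000.0])
        y = 1.0 * c / (30.0 + c)
        fit = fit_hyperbolic(c, y)
        assert fit.params["k_max"] == pytest.approx(1.0, rel=1e-4)
        assert fit.params["K_half_nM"] == pytest.approx(30.0, rel=1e-3)
        assert fit.params["saturation_nM"] == pytest.approx(270.0, rel=1e-3)

    def test_constant_rates_flagged_degenerate(self):
        c = np.array([10.0, 100.0, 1000.0])
        y = np.full(3, 0.5)
        fit = fit_hyperbolic(c, y)
        assert fit.flags  # K_half unidentifiable

    def test_noisy_recovery_and_grid_oracle(self):
        """5% noise on k_max = 1, K_half = 30 nM: both within 15% and the
        least-squares solution matches a dense independent grid search."""
        rng = np.random.default_rng(10)
        c = np.array([5.0, 15.0, 30.0, 60.0, 120.0, 300.0, 600.0])
        y = 1.0 * c / (30.0 + c) * (1 + rng.normal(0, 0.05, c.size))
        fit = fit_hyperbolic(c, y)
        assert fit.params["k_max"] == pytest.approx(1.0, rel=0.15)
        assert fit.params["K_half_nM"] == pytest.approx(30.0, rel=0.15)

        def sse(km, kh):
            return np.sum((y - km * c / (kh + c)) ** 2)

        grid = [
            (km, kh)
            for km in np.linspace(0.7, 1.3, 61)
            for kh in np.linspace(10, 60, 101)
        ]
        g_km, g_kh = min(grid, key=lambda p: sse(*p))
        assert abs(fit.params["k_max"] - g_km) < 0.02
        assert abs(fit.params["K_half_nM"] - g_kh) < 1.0

    def test_linear_limit_at_low_concentration(self):
        """For c << K_half the hyperbola reduces to a line of slope
        k_max / K_half."""
        kmax, kh = 1.0, 200.0
        c = np.array([0.5, 1.0, 2.0, 4.0])
        y = kmax * c / (kh + c)
        lin = fit_linear_concentration(c, y, through_origin=True)
        assert lin.params["slope_uM_s"] == pytest.approx(1e3 * kmax / kh, rel=0.02)

    def test_shared_khalf_joint_fit(self):
        rng = np.random.default_rng(11)
        c = np.array([10.0, 100.0, 200.0, 500.0, 1000.0])
        fast = 1.0 * c / (100.0 + c) * (1 + rng.normal(0, 0.1, 5))
        slow = 0.2 * c / (100.0 + c) * (1 + rng.normal(0, 0.03, 5))
        fit = fit_hyperbolic_shared(c, [fast, slow])
        assert fit.params["k_max_1"] == pytest.approx(1.0, rel=0.15)
        assert fit.params["k_max_2"] == pytest.approx(0.2, rel=0.10)
        assert fit.params["K_half_nM"] == pytest.approx(100.0, rel=0.35)


class TestFirstEvents:
    def test_identical_first_events_degenerate(self):
        paths = [FakePath([0] * 50 + [1] * 10 + [0] * 10) for _ in range(10)]
        fit, tab = first_event_times(paths)
        assert fit.model == "degenerate"
        assert fit.mean == pytest.approx(5.0)
        assert tab["event"].all()

    def test_exponential_first_events_recovered(self):
        """Single-exponential first events, mean 6 s, n = 500: recovered
        within 10%."""
        rng = np.random.default_rng(12)
        paths = []
        for i in range(500):
            n = 1200
            first = min(int(rng.exponential(6.0) / 0.1), n - 20)
            states = [0] * first + [1] * 10 + [0] * (n - first - 10)
            paths.append(FakePath(states, molecule=f"m{i}"))
        fit, _ = first_event_times(paths, model="single-exp")
        assert fit.mean == pytest.approx(6.0, rel=0.10)

    def test_slow_first_fast_subsequent(self):
        """First-event mean exceeds subsequent-dwell mean when the first
        transition is rate-limited (GDP-like delivery)."""
        rng = np.random.default_rng(13)
        paths = []
        for i in range(200):
            n = 2000
            first = min(int(rng.exponential(8.4) / 0.1), n - 200)
            states = [0] * first
            s = 1
            while len(states) < n:
                states += [s] * max(int(rng.exponential(1.0) / 0.1), 1)
                s = 1 - s
            paths.append(FakePath(states[:n], molecule=f"m{i}"))
        fit, _ = first_event_times(paths, model="single-exp")
        tab = extract_dwells(paths, min_dwell_frames=1, first_dwell_censored=False)
        interior = tab[~(tab.left_censored | tab.right_censored)]
        assert fit.params["empirical_mean"] > interior["duration_s"].mean()


class TestWash:
    def test_static_after_wash(self):
        pre = [0] * 50 + [1] * 50 + [0] * 50 + [1] * 50
        paths = [FakePath(pre + [1] * 200) for _ in range(10)]
        tab = wash_comparison(paths, wash_time=20.0, window=15.0)
        assert tab["post_wash"].sum() == 0
        assert tab["pre_wash"].mean() > 0

    def test_unchanged_kinetics_symmetric_counts(self):
        rng = np.random.default_rng(14)
        paths = []
        for i in range(120):
            states, s = [], 0
            while len(states) < 600:
                states += [s] * max(int(rng.exponential(1.5) / 0.1), 1)
                s = 1 - s
            paths.append(FakePath(states[:600], molecule=f"m{i}"))
        tab = wash_comparison(paths, wash_time=30.0, window=25.0)
        pre, post = tab["pre_wash"].mean(), tab["post_wash"].mean()
        assert abs(pre - post) < 0.25 * max(pre, post)
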