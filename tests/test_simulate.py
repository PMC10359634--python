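"""Synthetic trace generator: state paths, camera integration, experiments."""

import numpy as np
import pytest

from ribofret.simulate import (
    CameraModel,
    DeliveryModel,
    ExpMixture,
    KineticScheme,
    StatePath,
    integrate_camera,
    simulate_experiment,
    simulate_state_path,
)


def oracle_renewal_transition_count(mean_a, mean_b, duration, n_rep, rng):
    """Independent renewal-theory oracle: brute-force alternating renewal
    simulation with plain exponential draws."""
    counts = []
    for _ in range(n_rep):
        t, state, n = 0.0, 0, 0
        while True:
            t += rng.exponential(mean_a if state == 0 else mean_b)
            if t >= duration:
                break
            state = 1 - state
            n += 1
        counts.append(n)
    return np.mean(counts)


class TestStatePath:
    def test_single_state_scheme_is_one_dwell(self, rng):
        scheme = KineticScheme(states=("ROT",))
        p = simulate_state_path(scheme, 100.0, rng)
        assert p.states == ["ROT"]
        assert p.n_transitions == 0
        assert p.dwell_records() == [("ROT", 0.0, 100.0)]

    def test_zero_duration_is_empty(self, rng, two_state_scheme):
        p = simulate_state_path(two_state_scheme, 0.0, rng)
        assert p.n_transitions == 0
        assert p.entry_times.size == 0

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError):
            ExpMixture(weights=(0.5, 0.4), taus=(1.0, 2.0))
        with pytest.raises(ValueError):
            ExpMixture(weights=(0.5, 0.5), taus=(1.0, -2.0))

    def test_transition_count_matches_renewal_oracle(self, rng, two_state_scheme):
        """Mean transition count over many replicates agrees with an
        independently coded renewal simulation (approx 2T / (tau_a+tau_b))."""
        duration, n_rep = 169.0, 400
        counts = [
            simulate_state_path(two_state_scheme, duration, rng).n_transitions
            for _ in range(n_rep)
        ]
        ours = np.mean(counts)
        oracle = oracle_renewal_transition_count(0.97, 0.38, duration, n_rep,
                                                 np.random.default_rng(999))
        expected = 2 * duration / (0.97 + 0.38)
        se = np.std(counts) / np.sqrt(n_rep)
        assert abs(ours - oracle) < 4 * se * np.sqrt(2)
        assert abs(ours - expected) < 5 * se

    def test_static_molecules_never_transition(self, rng):
        scheme = KineticScheme(
            states=("SEMI", "NON"),
            dwell_dists={"SEMI": ExpMixture.single(0.1), "NON": ExpMixture.single(0.1)},
            static_fraction=1.0,
            static_state="SEMI",
        )
        p = simulate_state_path(scheme, 50.0, rng)
        assert p.states == ["SEMI"]

    def test_mixture_median_bisection(self):
        mix = ExpMixture(weights=(0.75, 0.25), taus=(0.047, 1.379))
        assert mix.median() == pytest.approx(0.05, abs=0.002)
        single = ExpMixture.single(2.0)
        assert single.median() == pytest.approx(2.0 * np.log(2), rel=1e-6)


class TestCameraIntegration:
    def test_single_state_zero_noise_exact_fret(self, rng, quiet_photo, camera_100ms):
        path = StatePath(entry_times=np.array([0.0]), states=["SEMI"], end_time=60.0)
        tr = integrate_camera(path, quiet_photo, camera_100ms, rng, add_noise=False)
        fret = tr.acceptor / (tr.acceptor + tr.donor)
        np.testing.assert_allclose(fret, 0.22, atol=1e-12)

    def test_midframe_transition_averages_states(self, rng, quiet_photo):
        # SEMI -> NON exactly mid-frame: that frame's FRET is (0.22+0.34)/2
        cam = CameraModel(exposure_s=0.100, n_frames=10)
        path = StatePath(entry_times=np.array([0.0, 0.45]), states=["SEMI", "NON"],
                         end_time=1.0)
        tr = integrate_camera(path, quiet_photo, cam, rng, add_noise=False)
        fret = tr.acceptor / (tr.acceptor + tr.donor)
        assert fret[4] == pytest.approx(0.28, abs=1e-12)
        assert fret[3] == pytest.approx(0.22, abs=1e-12)
        assert fret[5] == pytest.approx(0.34, abs=1e-12)

    def test_short_dwell_full_frame_fraction_matches_overlap_oracle(self, rng, quiet_photo):
        """0.05 s excursions at 100 ms exposure: the fraction producing at
        least one frame fully in the new state matches brute-force phase
        enumeration (zero: a 0.05 s dwell can never cover a full 0.1 s frame)."""
        cam = CameraModel(exposure_s=0.100, n_frames=20)
        L, dt = 0.05, 0.100
        phases = np.linspace(0.0, dt, 41, endpoint=False)
        n_full_ours = 0
        n_full_oracle = 0
        for ph in phases:
            t0 = 1.0 + ph
            path = StatePath(entry_times=np.array([0.0, t0, t0 + L]),
                             states=["SEMI", "NON", "SEMI"], end_time=2.0)
            tr = integrate_camera(path, quiet_photo, cam, rng, add_noise=False)
            fret = tr.acceptor / (tr.acceptor + tr.donor)
            n_full_ours += int(np.any(np.abs(fret - 0.34) < 1e-9))
            # oracle: a frame [kdt, (k+1)dt) lies fully inside [t0, t0+L)
            k = np.arange(cam.n_frames)
            n_full_oracle += int(np.any((k * dt >= t0) & ((k + 1) * dt <= t0 + L)))
        assert n_full_oracle == 0
        assert n_full_ours == n_full_oracle

    def test_channel_anticorrelation_invariant(self, rng, quiet_photo, camera_100ms,
                                               two_state_scheme):
        """Zero noise, no bleach: I_D + I_A is constant across frames."""
        path = simulate_state_path(two_state_scheme, 60.0, rng)
        tr = integrate_camera(path, quiet_photo, camera_100ms, rng, add_noise=False)
        total = tr.donor + tr.acceptor
        np.testing.assert_allclose(total, total[0], rtol=1e-9)

    def test_frames_with_changes_converge_to_transition_count(self, rng, two_state_scheme):
        """As exposure shrinks on a nested grid, the number of frames
        containing a state change grows monotonically to the true count."""
        path = simulate_state_path(two_state_scheme, 60.0, rng)
        times = path.entry_times[1:]  # transition epochs
        counts = []
        for k in range(6):
            dt = 0.1 / 2**k
            counts.append(np.unique(np.floor(times / dt).astype(int)).size)
        assert all(b >= a for a, b in zip(counts, counts[1:]))
        assert counts[-1] == path.n_transitions


class TestExperiment:
    def test_inactive_molecules_are_background_only(self, photo, camera_100ms):
        delivery = DeliveryModel(mode="delivery", concentration_nM=50.0,
                                 window_s=60.0, active_fraction=0.0)
        scheme = KineticScheme(states=("SEMI", "NON"),
                               dwell_dists={"SEMI": ExpMixture.single(1.0),
                                            "NON": ExpMixture.single(1.0)})
        exp = simulate_experiment(scheme, photo, delivery, camera_100ms,
                                  n_molecules=5, seed=0)
        for tr in exp.traces:
            assert abs(tr.donor.mean() - photo.background) < 5 * photo.noise_sd
            assert abs(tr.acceptor.mean() - photo.background) < 5 * photo.noise_sd

    def test_arrival_rate_contract(self):
        """50 nM at 3.5 uM^-1 s^-1 gives exponential arrivals at 0.175 s^-1."""
        d = DeliveryModel(mode="delivery", k_on=3.5, concentration_nM=50.0,
                          window_s=300.0)
        assert d.arrival_rate == pytest.approx(0.175)
        from ribofret.simulate import _molecule_rng
        draws = []
        for i in range(2000):
            r = _molecule_rng(7, i)
            r.random()
            draws.append(r.exponential(1.0 / d.arrival_rate))
        assert np.mean(draws) == pytest.approx(1 / 0.175, rel=0.05)

    def test_seed_determinism_and_counter_stability(self, two_state_scheme, photo,
                                                    camera_100ms, preformed):
        e1 = simulate_experiment(two_state_scheme, photo, preformed, camera_100ms,
                                 n_molecules=4, seed=42)
        e2 = simulate_experiment(two_state_scheme, photo, preformed, camera_100ms,
                                 n_molecules=4, seed=42)
        for a, b in zip(e1.traces, e2.traces):
            np.testing.assert_array_equal(a.donor, b.donor)
            np.testing.assert_array_equal(a.acceptor, b.acceptor)
        # growing n_molecules leaves existing molecules bit-identical
        e3 = simulate_experiment(two_state_scheme, photo, preformed, camera_100ms,
                                 n_molecules=6, seed=42)
        np.testing.assert_array_equal(e1.traces[3].donor, e3.traces[3].donor)

    def test_wash_to_static_scheme_stops_transitions(self, photo, camera_100ms):
        scheme = KineticScheme(states=("SEMI", "NON"),
                               dwell_dists={"SEMI": ExpMixture.single(0.5),
                                            "NON": ExpMixture.single(0.5)})
        frozen = KineticScheme(states=("SEMI", "NON"),
                               dwell_dists={"SEMI": ExpMixture.single(1e9),
                                            "NON": ExpMixture.single(1e9)})
        delivery = DeliveryModel(mode="preformed", window_s=60.0)
        exp = simulate_experiment(scheme, photo, delivery, camera_100ms,
                                  n_molecules=10, seed=3,
                                  wash_time=30.0, wash_scheme=frozen)
        assert exp.truth.transitions_after(30.0) == 0
        assert exp.truth.transitions_after(0.0) > 0
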