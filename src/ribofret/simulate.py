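"""Synthetic two-color smFRET trace generation.

Emulates the statistical structure of intersubunit-rotation FRET experiments
on surface-immobilized ribosomes: delayed FRET appearance from
pseudo-first-order 60S arrival, alternating two-state (semi-rotated <->
non-rotated) exchange with exponential-mixture dwells, a static
(non-rotating) subpopulation, donor/acceptor photobleaching, camera frame
integration and additive detector noise.  Every simulated experiment carries
its continuous-time ground truth so downstream stages can be verified by
parameter recovery.

Units: seconds everywhere internally; ligand concentrations in nM;
bimolecular rate constants in uM^-1 s^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .traces import Trace

__all__ = [
    "ExpMixture",
    "KineticScheme",
    "PhotophysicsModel",
    "DeliveryModel",
    "CameraModel",
    "StatePath",
    "GroundTruth",
    "SimulatedExperiment",
    "simulate_state_path",
    "integrate_camera",
    "simulate_molecule",
    "simulate_experiment",
]


@dataclass(frozen=True)
class ExpMixture:
    """Finite mixture of exponentials specifying a dwell-time distribution.

    ``weights[i]`` is the probability a dwell is drawn from component ``i``
    with mean duration ``taus[i]`` seconds.
    """

    weights: tuple[float, ...]
    taus: tuple[float, ...]

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        t = np.asarray(self.taus, dtype=float)
        if w.shape != t.shape or w.ndim != 1 or w.size == 0:
            raise ValueError("weights and taus must be equal-length 1-D sequences")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must be >= 0 and sum to 1 within 1e-9")
        if np.any(t <= 0):
            raise ValueError("mixture mean dwells must be positive")

    @property
    def mean(self) -> float:
        return float(np.dot(self.weights, self.taus))

    def survival(self, t: float) -> float:
        return float(sum(w * math.exp(-t / tau) for w, tau in zip(self.weights, self.taus)))

    def median(self) -> float:
        """Continuous median, by bisection on the survival function."""
        lo, hi = 0.0, 10.0 * max(self.taus)
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if self.survival(mid) > 0.5:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def sample(self, rng: np.random.Generator, component: Optional[int] = None) -> float:
        if component is None:
            component = int(rng.choice(len(self.weights), p=np.asarray(self.weights)))
        return float(rng.exponential(self.taus[component]))

    @classmethod
    def single(cls, tau: float) -> "ExpMixture":
        return cls(weights=(1.0,), taus=(float(tau),))


@dataclass(frozen=True)
class KineticScheme:
    """Two-state (or static one-state) exchange kinetics of one condition.

    ``states`` are ordered labels, conventionally ``("SEMI", "NON")`` for the
    semi-rotated/non-rotated exchange or a single label (e.g. ``("ROT",)``)
    for a GDPNP-stabilized static population.  ``dwell_dists`` maps each
    dynamic state to its exponential-mixture dwell distribution.

    ``static_fraction`` of molecules never transition and sit in
    ``static_state`` for their whole observation.  ``first_dwell_dists``
    optionally overrides the distribution of the first dwell only (used to
    emulate a slow first transition, e.g. eEF2-GDP delivery).

    ``heterogeneity`` selects how double-exponential dwells arise: per-dwell
    mixture draws (``"dwell"``, default) or molecule-level components
    (``"molecule"``: each molecule commits to one mixture component per
    state for its lifetime).
    """

    states: tuple[str, ...]
    dwell_dists: dict = field(default_factory=dict)
    static_fraction: float = 0.0
    static_state: Optional[str] = None
    initial_state_probs: Optional[tuple[float, ...]] = None
    first_dwell_dists: Optional[dict] = None
    heterogeneity: str = "dwell"
    condition: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.states:
            raise ValueError("scheme needs at least one state")
        if len(self.states) > 2:
            raise ValueError("alternating renewal schemes support at most two dynamic states")
        if not 0.0 <= self.static_fraction <= 1.0:
            raise ValueError("static_fraction must lie in [0, 1]")
        if len(self.states) > 1:
            for s in self.states:
                if s not in self.dwell_dists:
                    raise ValueError(f"missing dwell distribution for state {s!r}")
        if self.heterogeneity not in ("dwell", "molecule"):
            raise ValueError("heterogeneity must be 'dwell' or 'molecule'")

    @property
    def is_static(self) -> bool:
        return len(self.states) == 1

    def initial_probs(self) -> np.ndarray:
        if self.initial_state_probs is not None:
            p = np.asarray(self.initial_state_probs, dtype=float)
        elif self.is_static:
            p = np.array([1.0])
        else:
            # stationary occupancy of the alternating renewal process
            m = np.array([self.dwell_dists[s].mean for s in self.states])
            p = m / m.sum()
        return p / p.sum()


@dataclass(frozen=True)
class PhotophysicsModel:
    """Emission and photobleaching parameters.

    State FRET means imply channel intensities through
    ``I_A = I_total * E`` and ``I_D = I_total * (1 - E)``, keeping
    ``I_D + I_A`` constant across unbleached states (channel
    anti-correlation).  Bleach lifetimes are exponential; donor bleaching
    drops both channels to background, acceptor bleaching returns the donor
    to the full total intensity (FRET loss).
    """

    fret_means: dict
    total_intensity: float = 1000.0
    noise_sd: float = 30.0
    donor_bleach_tau: float = 200.0
    acceptor_bleach_tau: float = 400.0
    background: float = 50.0

    def __post_init__(self):
        for s, e in self.fret_means.items():
            if not 0.0 < e < 1.0:
                raise ValueError(f"state {s!r}: implied FRET must lie in (0, 1)")
        if self.total_intensity <= 0 or self.donor_bleach_tau <= 0 or self.acceptor_bleach_tau <= 0:
            raise ValueError("intensities and bleach lifetimes must be positive")

    def channel_intensities(self, state: str) -> tuple[float, float]:
        e = self.fret_means[state]
        return self.total_intensity * (1.0 - e), self.total_intensity * e


@dataclass(frozen=True)
class DeliveryModel:
    """Ligand (60S subunit) arrival model.

    In ``delivery`` mode arrival waiting times are exponential with rate
    ``k_on * concentration`` (pseudo-first-order); in ``preformed`` mode the
    complex exists from t = 0.  ``active_fraction`` of molecules are
    binding-competent; the rest never show FRET.
    """

    mode: str = "preformed"
    k_on: float = 3.5            # uM^-1 s^-1
    concentration_nM: float = 50.0
    window_s: float = 300.0
    active_fraction: float = 1.0

    def __post_init__(self):
        if self.mode not in ("delivery", "preformed"):
            raise ValueError("mode must be 'delivery' or 'preformed'")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValueError("active_fraction must lie in [0, 1]")
        if self.window_s <= 0:
            raise ValueError("observation window must be positive")

    @property
    def arrival_rate(self) -> float:
        """Pseudo-first-order arrival rate k_obs in s^-1."""
        return self.k_on * self.concentration_nM * 1e-3


@dataclass(frozen=True)
class CameraModel:
    """Frame integration parameters."""

    exposure_s: float = 0.100
    n_frames: int = 3000

    def __post_init__(self):
        if self.exposure_s <= 0:
            raise ValueError("exposure must be positive")
        if self.n_frames < 0:
            raise ValueError("frame count must be non-negative")

    @property
    def duration(self) -> float:
        return self.exposure_s * self.n_frames


@dataclass
class StatePath:
    """Ground-truth continuous-time state trajectory of one molecule.

    ``entry_times[i]`` is when the molecule entered ``states[i]``;
    the path covers ``[entry_times[0], end_time)``.
    """

    entry_times: np.ndarray
    states: list
    end_time: float

    def __post_init__(self):
        self.entry_times = np.asarray(self.entry_times, dtype=float)
        if self.entry_times.size != len(self.states):
            raise ValueError("entry_times and states must have equal length")
        if self.entry_times.size:
            if np.any(np.diff(self.entry_times) <= 0):
                raise ValueError("entry times must be strictly increasing")
            for a, b in zip(self.states[:-1], self.states[1:]):
                if a == b:
                    raise ValueError("consecutive states must differ")

    @property
    def start_time(self) -> float:
        return float(self.entry_times[0]) if self.entry_times.size else self.end_time

    @property
    def n_transitions(self) -> int:
        return max(0, len(self.states) - 1)

    def dwell_records(self) -> list[tuple[str, float, float]]:
        """(state, start, end) triples; the last dwell ends at ``end_time``."""
        out = []
        for i, s in enumerate(self.states):
            t0 = self.entry_times[i]
            t1 = self.entry_times[i + 1] if i + 1 < len(self.states) else self.end_time
            out.append((s, float(t0), float(t1)))
        return out

    def state_at(self, t: float):
        if not self.entry_times.size or t < self.entry_times[0] or t >= self.end_time:
            return None
        i = int(np.searchsorted(self.entry_times, t, side="right")) - 1
        return self.states[i]


def simulate_state_path(
    scheme: KineticScheme,
    duration: float,
    rng: np.random.Generator,
    start_time: float = 0.0,
    static: Optional[bool] = None,
    initial_state: Optional[str] = None,
    equilibrium_start: bool = False,
) -> StatePath:
    """Alternating-state renewal trajectory over ``[start_time, start_time + duration)``.

    Each dwell is drawn from its state's exponential mixture; static
    molecules (Bernoulli with ``static_fraction``) produce a single dwell
    spanning the whole duration.  ``duration = 0`` yields an empty path.

    With ``equilibrium_start`` the trajectory is observed mid-course (a
    pre-formed complex): the initial state is drawn from the stationary
    occupancy and the first dwell from the equilibrium residual-lifetime
    distribution (for an exponential mixture: component chosen with
    length-biased weights ``w_i tau_i``, then an exponential residual).
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    end = start_time + duration
    if duration == 0:
        return StatePath(entry_times=np.empty(0), states=[], end_time=end)
    if static is None:
        static = bool(rng.random() < scheme.static_fraction)
    if initial_state is None:
        p = scheme.initial_probs()
        initial_state = scheme.states[int(rng.choice(len(scheme.states), p=p))]
    if static or scheme.is_static:
        if scheme.is_static:
            s0 = scheme.states[0]
        elif scheme.static_state is not None:
            s0 = scheme.static_state
        else:
            s0 = initial_state
        return StatePath(entry_times=np.array([start_time]), states=[s0], end_time=end)

    mol_components: dict = {}
    if scheme.heterogeneity == "molecule":
        for s in scheme.states:
            mix = scheme.dwell_dists[s]
            mol_components[s] = int(rng.choice(len(mix.weights), p=np.asarray(mix.weights)))

    times = [start_time]
    states = [initial_state]
    t = start_time
    first = True
    while True:
        s = states[-1]
        comp = mol_components.get(s) if scheme.heterogeneity == "molecule" else None
        if first and scheme.first_dwell_dists and s in scheme.first_dwell_dists:
            mix = scheme.first_dwell_dists[s]
            t += mix.sample(rng, component=comp)
        elif first and equilibrium_start:
            mix = scheme.dwell_dists[s]
            wlb = np.asarray(mix.weights) * np.asarray(mix.taus)
            c = int(rng.choice(len(mix.taus), p=wlb / wlb.sum()))
            t += float(rng.exponential(mix.taus[c]))
        else:
            mix = scheme.dwell_dists[s]
            t += mix.sample(rng, component=comp)
        first = False
        if t >= end:
            break
        other = scheme.states[1 - scheme.states.index(s)]
        times.append(t)
        states.append(other)
    return StatePath(entry_times=np.asarray(times), states=states, end_time=end)


def _piecewise_cumint(breaks: np.ndarray, values: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Cumulative integral of a piecewise-constant function at times ``t``.

    ``values[i]`` holds on ``[breaks[i], breaks[i+1])``; breaks has one more
    entry than values.
    """
    seg = np.diff(breaks) * values
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return np.interp(t, breaks, cum)


def integrate_camera(
    path: StatePath,
    photo: PhotophysicsModel,
    cam: CameraModel,
    rng: np.random.Generator,
    arrival_time: Optional[float] = None,
    donor_bleach: float = np.inf,
    acceptor_bleach: float = np.inf,
    molecule: str = "mol",
    condition: Optional[dict] = None,
    add_noise: bool = True,
    dark: bool = False,
) -> Trace:
    """Render a state path into a camera-integrated two-channel trace.

    Per frame, each channel's noiseless intensity is the occupancy-time-
    weighted average of the state intensities, with background before
    arrival and after bleaching; bleach events truncate the signal mid-frame
    with partial-frame weighting.  Additive Gaussian noise per channel per
    frame models detector/EMCCD noise.
    """
    arrival = path.start_time if arrival_time is None else arrival_time
    t_end = cam.duration
    # breakpoints: frame-covering piecewise-constant signal description
    events = [0.0]
    seg_d: list[float] = []
    seg_a: list[float] = []

    def push(t_next: float, i_d: float, i_a: float):
        if t_next > events[-1]:
            events.append(t_next)
            seg_d.append(i_d)
            seg_a.append(i_a)

    bg = photo.background
    itot = photo.total_intensity
    if dark:
        # binding-incompetent surface spot: background only in both channels
        push(t_end, bg, bg)
        arrival = t_end + 1.0
    # pre-arrival: donor-only signal (acceptor absent until 60S arrives)
    pre_end = min(arrival, t_end, donor_bleach)
    push(pre_end, bg + itot, bg)
    if pre_end < min(arrival, t_end):  # donor bleached before arrival
        push(t_end, bg, bg)
    elif arrival < t_end:
        signal_end = min(path.end_time, donor_bleach, acceptor_bleach, t_end)
        for s, t0, t1 in path.dwell_records():
            if t0 >= signal_end:
                break
            i_d, i_a = photo.channel_intensities(s)
            push(min(t1, signal_end), bg + i_d, bg + i_a)
        if signal_end < t_end:
            if acceptor_bleach < donor_bleach and acceptor_bleach <= signal_end + 1e-12:
                # acceptor bleached first: donor recovers the full budget
                push(min(donor_bleach, t_end), bg + itot, bg)
            push(t_end, bg, bg)
    breaks = np.asarray(events)
    vd = np.asarray(seg_d)
    va = np.asarray(seg_a)
    edges = np.arange(cam.n_frames + 1) * cam.exposure_s
    cd = _piecewise_cumint(breaks, vd, edges)
    ca = _piecewise_cumint(breaks, va, edges)
    donor = np.diff(cd) / cam.exposure_s
    acceptor = np.diff(ca) / cam.exposure_s
    if add_noise and photo.noise_sd > 0:
        donor = donor + rng.normal(0.0, photo.noise_sd, donor.size)
        acceptor = acceptor + rng.normal(0.0, photo.noise_sd, acceptor.size)
    return Trace(
        molecule=molecule,
        frame_interval=cam.exposure_s,
        donor=donor,
        acceptor=acceptor,
        condition=dict(condition or {}),
    )


@dataclass
class GroundTruth:
    """Simulator truth serialized alongside a trace set."""

    molecules: pd.DataFrame   # molecule, arrival_s, donor_bleach_s, acceptor_bleach_s, static, active
    dwells: pd.DataFrame      # molecule, state, start_s, end_s

    def transitions_after(self, t: float) -> int:
        d = self.dwells
        # a transition happens at each dwell start except the first per molecule
        starts = d.groupby("molecule", sort=False)["start_s"].transform("min")
        trans = d[d["start_s"] > starts]
        return int((trans["start_s"] >= t).sum())


@dataclass
class SimulatedExperiment:
    traces: list
    truth: GroundTruth
    scheme: KineticScheme
    photo: PhotophysicsModel
    delivery: DeliveryModel
    camera: CameraModel
    seed: int
    condition_name: str = ""


def _molecule_rng(seed: int, index: int) -> np.random.Generator:
    # counter-based fan-out: molecule i's stream is independent of n_molecules
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(index,))))


def simulate_molecule(
    index: int,
    scheme: KineticScheme,
    photo: PhotophysicsModel,
    delivery: DeliveryModel,
    cam: CameraModel,
    seed: int,
    wash_time: Optional[float] = None,
    wash_scheme: Optional[KineticScheme] = None,
    condition: Optional[dict] = None,
):
    rng = _molecule_rng(seed, index)
    name = f"mol{index:05d}"
    active = bool(rng.random() < delivery.active_fraction)
    if delivery.mode == "delivery":
        arrival = rng.exponential(1.0 / delivery.arrival_rate) if active else np.inf
    else:
        arrival = 0.0 if active else np.inf
    window = min(delivery.window_s, cam.duration)
    donor_bleach = acceptor_bleach = np.inf
    if np.isfinite(arrival) and arrival < window:
        donor_bleach = arrival + rng.exponential(photo.donor_bleach_tau)
        acceptor_bleach = arrival + rng.exponential(photo.acceptor_bleach_tau)
        sig_end = min(window, donor_bleach, acceptor_bleach)
        if wash_time is not None and wash_scheme is not None and wash_time < sig_end and wash_time > arrival:
            pre = simulate_state_path(scheme, wash_time - arrival, rng, start_time=arrival,
                                      equilibrium_start=delivery.mode == "preformed")
            last_state = pre.states[-1] if pre.states else None
            post = simulate_state_path(
                wash_scheme, sig_end - wash_time, rng, start_time=wash_time,
                initial_state=last_state if last_state in wash_scheme.states else None,
            )
            # join, dropping a duplicated boundary state
            times = list(pre.entry_times)
            states = list(pre.states)
            for t, s in zip(post.entry_times, post.states):
                if states and s == states[-1]:
                    continue
                times.append(t)
                states.append(s)
            path = StatePath(entry_times=np.asarray(times), states=states, end_time=sig_end)
        else:
            path = simulate_state_path(scheme, sig_end - arrival, rng, start_time=arrival,
                                       equilibrium_start=delivery.mode == "preformed")
    else:
        arrival = np.inf
        path = StatePath(entry_times=np.empty(0), states=[], end_time=0.0)
    trace = integrate_camera(
        path, photo, cam, rng,
        arrival_time=arrival if np.isfinite(arrival) else cam.duration + 1.0,
        donor_bleach=donor_bleach,
        acceptor_bleach=acceptor_bleach,
        molecule=name,
        condition=condition,
        dark=not active,
    )
    info = {
        "molecule": name,
        "arrival_s": arrival if np.isfinite(arrival) else np.nan,
        "donor_bleach_s": donor_bleach if np.isfinite(donor_bleach) else np.nan,
        "acceptor_bleach_s": acceptor_bleach if np.isfinite(acceptor_bleach) else np.nan,
        "static": bool(path.states and path.n_transitions == 0 and not scheme.is_static),
        "active": active,
    }
    dwells = [
        {"molecule": name, "state": s, "start_s": a, "end_s": b}
        for s, a, b in path.dwell_records()
    ]
    return trace, info, dwells


def simulate_experiment(
    scheme: KineticScheme,
    photo: PhotophysicsModel,
    delivery: DeliveryModel,
    camera: CameraModel,
    n_molecules: int,
    seed: int,
    wash_time: Optional[float] = None,
    wash_scheme: Optional[KineticScheme] = None,
    condition_name: str = "",
) -> SimulatedExperiment:
    """Simulate a full single-condition experiment with ground truth.

    Identical configuration + seed gives bit-identical trace sets; the
    per-molecule random streams are fanned out by a counter-based scheme so
    growing ``n_molecules`` leaves existing molecules unchanged.
    """
    if n_molecules < 0:
        raise ValueError("n_molecules must be non-negative")
    cond = dict(scheme.condition)
    cond["condition"] = condition_name
    traces, infos, dwell_rows = [], [], []
    for i in range(n_molecules):
        t, info, dw = simulate_molecule(
            i, scheme, photo, delivery, camera, seed,
            wash_time=wash_time, wash_scheme=wash_scheme, condition=cond,
        )
        traces.append(t)
        infos.append(info)
        dwell_rows.extend(dw)
    truth = GroundTruth(
        molecules=pd.DataFrame(infos),
        dwells=pd.DataFrame(dwell_rows, columns=["molecule", "state", "start_s", "end_s"]),
    )
    return SimulatedExperiment(
        traces=traces, truth=truth, scheme=scheme, photo=photo,
        delivery=delivery, camera=camera, seed=seed, condition_name=condition_name,
    )
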