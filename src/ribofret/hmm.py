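"""Gaussian-emission HMM idealization of FRET trajectories.

Each usable frame is assigned to a discrete FRET state by a hidden Markov
model with Gaussian emissions, fitted by maximum-likelihood EM with
emission and transition parameters pooled across all traces of a condition.
The number of states is chosen by a penalized-likelihood (BIC) criterion;
decoding uses the Viterbi path.  States are always reported sorted by
ascending emission mean so labels are comparable across fits.

The EM engine is ``hmmlearn``'s GaussianHMM; pooling, quantile-based
initialization with random restarts, canonical relabeling, model selection
and transition amplitude qualification are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from hmmlearn.hmm import GaussianHMM

from .traces import AnnotatedTrace

__all__ = ["HmmModel", "IdealizedPath", "fit_hmm", "select_model", "viterbi"]


@dataclass
class HmmModel:
    """Fitted pooled HMM: K states with shared emissions and transitions."""

    n_states: int
    means: np.ndarray          # ascending FRET means
    sds: np.ndarray
    transmat: np.ndarray       # per-frame transition matrix
    startprob: np.ndarray
    log_likelihood: float
    n_obs: int
    frame_interval: float
    converged: bool = True
    non_identifiable: bool = False

    @property
    def n_params(self) -> int:
        k = self.n_states
        return 2 * k + k * (k - 1) + (k - 1)

    @property
    def bic(self) -> float:
        """Penalized-likelihood criterion (lower is better)."""
        return -2.0 * self.log_likelihood + self.n_params * np.log(max(self.n_obs, 1))

    @property
    def separation(self) -> float:
        """Smallest distance between adjacent state means (FRET units)."""
        if self.n_states < 2:
            return np.inf
        return float(np.min(np.diff(self.means)))

    def to_hmmlearn(self) -> GaussianHMM:
        m = GaussianHMM(n_components=self.n_states, covariance_type="diag", init_params="")
        m.startprob_ = self.startprob.copy()
        m.transmat_ = self.transmat.copy()
        m.means_ = self.means.reshape(-1, 1).copy()
        m.covars_ = (self.sds**2).reshape(-1, 1).copy()
        return m

    def report(self) -> str:
        lines = [
            f"Gaussian-emission HMM, K = {self.n_states}, "
            f"frame interval {self.frame_interval} s",
            f"log-likelihood {self.log_likelihood:.3f} on {self.n_obs} frames, "
            f"BIC {self.bic:.3f}",
        ]
        for i in range(self.n_states):
            lines.append(f"  state {i}: mean FRET {self.means[i]:.4f}, sd {self.sds[i]:.4f}")
        lines.append("  transition matrix (per frame):")
        for row in self.transmat:
            lines.append("    " + "  ".join(f"{p:.5f}" for p in row))
        if self.non_identifiable:
            lines.append("  WARNING: fit flagged non-identifiable (collapsed states)")
        return "\n".join(lines)


@dataclass
class IdealizedPath:
    """Per-frame discrete state assignment over a trace's usable window."""

    molecule: str
    states: np.ndarray             # int labels in [0, K)
    start_frame: int
    frame_interval: float
    fret: np.ndarray               # raw FRET over the same window
    model: HmmModel
    transition_frames: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    qualified: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    condition: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.states.size

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval

    def n_qualified_transitions(self, min_flank_frames: int = 1) -> int:
        """Count amplitude-qualified transitions with both flanking dwells
        lasting at least ``min_flank_frames`` frames."""
        if self.transition_frames.size == 0:
            return 0
        bounds = np.concatenate([[0], self.transition_frames, [self.n_frames]])
        runs = np.diff(bounds)
        ok = 0
        for i in range(self.transition_frames.size):
            if self.qualified[i] and runs[i] >= min_flank_frames and runs[i + 1] >= min_flank_frames:
                ok += 1
        return ok


def _prepare(fret_set: Sequence[np.ndarray]) -> tuple[np.ndarray, list[int]]:
    xs, lengths = [], []
    for f in fret_set:
        v = np.asarray(f, dtype=float)
        v = v[np.isfinite(v)]
        if v.size:
            xs.append(v)
            lengths.append(v.size)
    if not xs:
        raise ValueError("no usable frames to fit")
    return np.concatenate(xs).reshape(-1, 1), lengths


def _init_model(K: int, x: np.ndarray, rng: np.random.Generator, jitter: float) -> GaussianHMM:
    qs = np.quantile(x, [(2 * i + 1) / (2 * K) for i in range(K)])
    means = qs + (rng.normal(0.0, jitter, K) if jitter > 0 else 0.0)
    sd = max(np.std(x) / max(K, 1), 1e-3)
    m = GaussianHMM(
        n_components=K, covariance_type="diag",
        init_params="", params="stmc",
        n_iter=500, tol=1e-6, min_covar=1e-8,
    )
    m.startprob_ = np.full(K, 1.0 / K)
    if K == 1:
        tm = np.ones((1, 1))
    else:
        tm = np.full((K, K), 0.05 / (K - 1))
        np.fill_diagonal(tm, 0.95)
    m.transmat_ = tm
    m.means_ = np.sort(means).reshape(-1, 1)
    m.covars_ = np.full((K, 1), sd**2)
    return m


def _canonicalize(m: GaussianHMM) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    means = m.means_.ravel()
    order = np.argsort(means)
    sds = np.sqrt(np.asarray(m.covars_).reshape(m.n_components, -1)[:, 0])
    trans = m.transmat_[np.ix_(order, order)]
    start = m.startprob_[order]
    return means[order], sds[order], trans, start


def fit_hmm(
    fret_set: Sequence[np.ndarray],
    K: int,
    frame_interval: float,
    n_restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
) -> HmmModel:
    """Pooled maximum-likelihood EM fit of a K-state Gaussian HMM.

    All traces of a condition share emission and transition parameters.
    Initialization is a quantile split of the pooled FRET values; restarts
    jitter the initial means.  The best local optimum by log-likelihood is
    returned, states sorted by mean.  Constant (degenerate) data produce a
    fit flagged ``non_identifiable`` for K > 1.
    """
    if K not in (1, 2, 3):
        raise ValueError("K must be 1, 2 or 3")
    x, lengths = _prepare(fret_set)
    rng = np.random.default_rng(seed)
    data_sd = float(np.std(x))
    best: Optional[GaussianHMM] = None
    best_ll = -np.inf
    for r in range(max(n_restarts, 1)):
        m = _init_model(K, x, rng, jitter=0.0 if r == 0 else 0.5 * data_sd + 1e-3)
        m.tol = tol
        try:
            m.fit(x, lengths)
            ll = m.score(x, lengths)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if ll > best_ll:
            best, best_ll = m, ll
    if best is None:
        raise RuntimeError("all EM restarts failed")
    means, sds, trans, start = _canonicalize(best)
    sep = np.min(np.diff(means)) if K > 1 else np.inf
    non_ident = bool(K > 1 and (data_sd < 1e-12 or sep < max(np.max(sds), 1e-6) / 4))
    return HmmModel(
        n_states=K, means=means, sds=sds, transmat=trans, startprob=start,
        log_likelihood=float(best_ll), n_obs=int(x.size),
        frame_interval=frame_interval,
        converged=bool(best.monitor_.converged),
        non_identifiable=non_ident,
    )


def select_model(
    fret_set: Sequence[np.ndarray],
    K_candidates: Sequence[int] = (1, 2),
    frame_interval: float = 0.1,
    **kwargs,
) -> tuple[int, dict]:
    """Fit each candidate K and select the best by the penalized criterion.

    On FRET-on windows (the zero-FRET off state is excised upstream by the
    arrival/bleach annotation) the default candidate set is {1, 2}.
    Returns ``(K_star, fits)``.
    """
    fits = {K: fit_hmm(fret_set, K, frame_interval, **kwargs) for K in K_candidates}
    usable = {K: f for K, f in fits.items() if not f.non_identifiable}
    pool = usable if usable else fits
    K_star = min(pool, key=lambda K: pool[K].bic)
    return K_star, fits


def stabilize_for_decoding(model: HmmModel, max_width_ratio: float = 1.15) -> HmmModel:
    """Decoding copy of a model with emission widths capped near the
    narrowest state's width.

    Camera time-averaging inflates the apparent width of states that host
    invisible fast excursions; a wider emission makes Viterbi stickier and
    shifts the decoder's event-detection floor from sample to sample.
    Capping the widths keeps the decoder's sensitivity calibrated while the
    reported (raw) fit is untouched.
    """
    if model.n_states < 2:
        return model
    cap = max_width_ratio * float(np.min(model.sds))
    sds = np.minimum(model.sds, cap)
    if np.allclose(sds, model.sds):
        return model
    from dataclasses import replace
    return replace(model, sds=sds)


def viterbi(
    atrace: AnnotatedTrace,
    model: HmmModel,
    qualify_fraction: float = 0.5,
) -> IdealizedPath:
    """Most-probable state sequence over the usable window.

    Transitions are annotated amplitude-qualified when the mean FRET of the
    two flanking dwell segments differs by at least ``qualify_fraction``
    times the fitted state separation; unqualified transitions are treated
    as noise excursions by downstream counting.
    """
    fret = atrace.usable_fret
    finite = np.isfinite(fret)
    vals = np.where(finite, fret, np.nanmedian(fret) if finite.any() else 0.0)
    if vals.size == 0:
        return IdealizedPath(
            molecule=atrace.trace.molecule, states=np.empty(0, dtype=int),
            start_frame=atrace.usable_start, frame_interval=atrace.frame_interval,
            fret=fret, model=model, condition=atrace.trace.condition,
        )
    m = model.to_hmmlearn()
    states = m.predict(vals.reshape(-1, 1))
    tf = np.flatnonzero(np.diff(states) != 0) + 1
    qualified = np.zeros(tf.size, dtype=bool)
    if tf.size:
        sep = model.separation if np.isfinite(model.separation) else 0.0
        bounds = np.concatenate([[0], tf, [states.size]])
        seg_means = np.array([
            np.nanmean(np.where(finite[a:b], fret[a:b], np.nan)) if finite[a:b].any() else np.nan
            for a, b in zip(bounds[:-1], bounds[1:])
        ])
        for i in range(tf.size):
            dm = abs(seg_means[i + 1] - seg_means[i])
            qualified[i] = bool(np.isfinite(dm) and dm >= qualify_fraction * sep)
    return IdealizedPath(
        molecule=atrace.trace.molecule, states=states,
        start_frame=atrace.usable_start, frame_interval=atrace.frame_interval,
        fret=fret, model=model, transition_frames=tf, qualified=qualified,
        condition=atrace.trace.condition,
    )


def posterior_probabilities(fret: np.ndarray, model: HmmModel) -> np.ndarray:
    """Per-frame posterior state probabilities (rows sum to 1)."""
    vals = np.asarray(fret, dtype=float)
    vals = vals[np.isfinite(vals)]
    return model.to_hmmlearn().predict_proba(vals.reshape(-1, 1))
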