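"""Population-level FRET summaries.

Histograms and one/two-component Gaussian decompositions of pooled FRET
values, and post-synchronized density heatmaps in which many trajectories
are aligned at a common event (60S arrival or a chosen state transition)
before computing a time-resolved, per-column-normalized FRET density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

__all__ = ["GaussianFit", "SyncHeatmap", "fit_fret_gaussians", "build_sync_heatmap"]

_Z95 = 1.959963984540054


@dataclass
class GaussianFit:
    """Gaussian mixture decomposition of a FRET distribution."""

    weights: np.ndarray
    means: np.ndarray          # ascending
    sds: np.ndarray
    n: int
    log_likelihood: float
    bic: float
    bic_alternative: float     # the competing (other-K) model's BIC
    mean_ci: list              # (lo, hi) per component
    flags: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.means.size

    def report(self) -> str:
        lines = [f"Gaussian mixture, {self.n_components} component(s), n = {self.n}"]
        for w, m, s, (lo, hi) in zip(self.weights, self.means, self.sds, self.mean_ci):
            lines.append(f"  w = {w:.3f}, mean = {m:.4f} [{lo:.4f}, {hi:.4f}], sd = {s:.4f}")
        for f in self.flags:
            lines.append(f"  FLAG: {f}")
        return "\n".join(lines)


def _fit_gmm(x: np.ndarray, k: int, seed: int) -> GaussianMixture:
    gm = GaussianMixture(
        n_components=k, covariance_type="full", n_init=5,
        random_state=seed, reg_covar=1e-8, max_iter=500,
    )
    gm.fit(x)
    return gm


def fit_fret_gaussians(
    values: np.ndarray,
    components: int | str = "auto",
    seed: int = 0,
    min_values: int = 100,
) -> GaussianFit:
    """EM mixture fit on raw (unclamped) FRET values.

    ``components`` may be 1, 2 or ``"auto"`` (single-vs-double selection by
    BIC).  A two-component fit whose means are closer than a quarter of the
    pooled sd is flagged non-identifiable and collapsed to the
    single-component fit.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)].reshape(-1, 1)
    if x.size < min_values:
        raise ValueError(f"need at least {min_values} FRET values, got {x.size}")
    fits = {k: _fit_gmm(x, k, seed) for k in (1, 2)}
    bics = {k: fits[k].bic(x) for k in fits}
    if components == "auto":
        k = min(bics, key=bics.get)
    else:
        k = int(components)
        if k not in (1, 2):
            raise ValueError("components must be 1, 2 or 'auto'")
    gm = fits[k]
    flags = []
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.reshape(k, -1)[:, 0])
    weights = gm.weights_
    if k == 2:
        pooled_sd = float(np.sqrt(np.dot(weights, sds**2)))
        too_close = abs(means[1] - means[0]) < pooled_sd / 4
        # a forced two-component fit that the penalized criterion rejects is
        # a split of a single population, not two states
        unsupported = bics[2] >= bics[1]
        if too_close or unsupported:
            flags.append("two-component fit non-identifiable; collapsed to single component")
            gm = fits[1]
            k = 1
            means = gm.means_.ravel()
            sds = np.sqrt(gm.covariances_.reshape(1, -1)[:, 0])
            weights = gm.weights_
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    n = x.size
    mean_ci = [
        (m - _Z95 * s / np.sqrt(max(n * w, 1.0)), m + _Z95 * s / np.sqrt(max(n * w, 1.0)))
        for w, m, s in zip(weights, means, sds)
    ]
    return GaussianFit(
        weights=weights, means=means, sds=sds, n=int(n),
        log_likelihood=float(gm.score(x) * n),
        bic=float(bics[k]), bic_alternative=float(bics[2 if k == 1 else 1]),
        mean_ci=mean_ci, flags=flags,
    )


@dataclass
class SyncHeatmap:
    """Post-synchronized FRET density: time-offset bins x FRET bins.

    ``density[i, j]`` is the fraction of frames in time column ``j`` falling
    in FRET bin ``i``; every populated column sums to 1.
    """

    density: np.ndarray
    time_edges: np.ndarray
    fret_edges: np.ndarray
    event: str
    n_traces: int
    n_excluded: int

    @property
    def time_centers(self) -> np.ndarray:
        return 0.5 * (self.time_edges[:-1] + self.time_edges[1:])

    @property
    def fret_centers(self) -> np.ndarray:
        return 0.5 * (self.fret_edges[:-1] + self.fret_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.density, index=self.fret_centers, columns=np.round(self.time_centers, 6))

    def column_profile(self, t_lo: float, t_hi: float) -> np.ndarray:
        """Average FRET density over a time-offset range (renormalized)."""
        sel = (self.time_centers >= t_lo) & (self.time_centers < t_hi)
        prof = self.density[:, sel].sum(axis=1)
        s = prof.sum()
        return prof / s if s > 0 else prof


def _qualifying_events(path, event: str, min_flank_frames: int) -> list[int]:
    """Frames of qualified transitions matching ``event`` (e.g. "low_to_high")."""
    if path is None or path.transition_frames.size == 0:
        return []
    bounds = np.concatenate([[0], path.transition_frames, [path.n_frames]])
    runs = np.diff(bounds)
    out = []
    for i, tf in enumerate(path.transition_frames):
        if not _transition_matches(path, i, event):
            continue
        if not path.qualified[i]:
            continue
        if runs[i] < min_flank_frames or runs[i + 1] < min_flank_frames:
            continue
        out.append(int(tf))
    return out


def build_sync_heatmap(
    atraces: Sequence,
    paths: Optional[Sequence] = None,
    event: str = "arrival",
    window: tuple[float, float] = (-5.0, 20.0),
    fret_bin: float = 0.02,
    fret_range: tuple[float, float] = (-0.2, 1.2),
    first_only: bool = True,
    min_flank_frames: int = 2,
    clamp: bool = True,
) -> SyncHeatmap:
    """Align traces at a common event and accumulate a 2-D FRET density.

    ``event`` is ``"arrival"`` or a transition spec such as ``"low_to_high"``
    (synchronizing on semi-rotated -> non-rotated transitions).  Molecules
    lacking the event are excluded, with the count reported.  Time bins
    equal the frame interval; each populated time column is normalized to
    sum 1.  By default only the first qualifying event per molecule is used.
    """
    atraces = list(atraces)
    if paths is None:
        paths = [None] * len(atraces)
    dt = atraces[0].frame_interval if atraces else 0.1
    t_lo, t_hi = window
    n_t = int(round((t_hi - t_lo) / dt))
    time_edges = t_lo + np.arange(n_t + 1) * dt
    f_lo, f_hi = fret_range
    n_f = int(round((f_hi - f_lo) / fret_bin))
    fret_edges = f_lo + np.arange(n_f + 1) * fret_bin
    counts = np.zeros((n_f, n_t))
    n_used = n_excluded = 0
    for at, p in zip(atraces, paths):
        fret = at.usable_fret
        if fret.size == 0:
            n_excluded += 1
            continue
        if event == "arrival":
            evs = [0]  # usable windows start at arrival
        elif "_to_" in event:
            evs = _qualifying_events(p, event, min_flank_frames)
            if first_only and evs:
                evs = evs[:1]
        else:
            raise ValueError(f"unknown synchronization event {event!r}")
        if not evs:
            n_excluded += 1
            continue
        n_used += 1
        vals = np.clip(fret, 0.0, 1.0) if clamp else fret
        frames = np.arange(fret.size)
        for ef in evs:
            rel_t = (frames - ef) * dt
            ok = np.isfinite(vals) & (rel_t >= t_lo) & (rel_t < t_hi - 1e-12)
            if not ok.any():
                continue
            ti = np.floor((rel_t[ok] - t_lo) / dt + 1e-9).astype(int)
            fi = np.floor((vals[ok] - f_lo) / fret_bin).astype(int)
            good = (fi >= 0) & (fi < n_f) & (ti >= 0) & (ti < n_t)
            np.add.at(counts, (fi[good], ti[good]), 1.0)
    col = counts.sum(axis=0)
    density = np.divide(counts, col, out=np.zeros_like(counts), where=col > 0)
    if n_used == 0:
        import warnings
        warnings.warn("no traces carried the synchronization event; heatmap is empty", stacklevel=2)
    return SyncHeatmap(
        density=density, time_edges=time_edges, fret_edges=fret_edges,
        event=event, n_traces=n_used, n_excluded=n_excluded,
    )


def _transition_matches(path, i: int, event: str) -> bool:
    lo_s, hi_s = event.split("_to_")
    label = {0: "low", 1: "high"}
    tf = path.transition_frames[i]
    frm = label.get(int(path.states[tf - 1]), str(path.states[tf - 1]))
    to = label.get(int(path.states[tf]), str(path.states[tf]))
    return (frm, to) == (lo_s, hi_s)
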