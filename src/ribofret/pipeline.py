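"""End-to-end orchestration: simulate -> process -> idealize -> kinetics -> distributions.

Runs every condition of an :class:`~ribofret.config.ExperimentConfig`
through the full analysis and assembles a machine-readable summary
(per-condition FRET state means, dwell fits, rotating fractions, arrival
kinetics and concentration-dependence fits).  Outputs embed the
configuration hash and global seed; a fixed seed reproduces every file
bit-identically.

Dwell-time fits are restricted to molecules showing at least one
amplitude-qualified transition: molecules that never transition contribute
no interior dwells and would otherwise enter only as extreme censored
observations dominated by the static subpopulation.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io as rio
from .config import ConditionConfig, ExperimentConfig
from .distributions import build_sync_heatmap, fit_fret_gaussians
from .dwells import (
    analyze_two_state_dwells,
    extract_dwells,
    first_event_times,
    fit_arrival_kinetics,
    rotating_fraction,
    wash_comparison,
)
from .hmm import fit_hmm, stabilize_for_decoding, viterbi
from .simulate import simulate_experiment
from .traces import annotate_traces

logger = logging.getLogger("ribofret")

ALL_STAGES = ("simulate", "process", "idealize", "kinetics", "dists")

_STATE_NAMES = {0: "SEMI", 1: "NON"}


class StageError(RuntimeError):
    def __init__(self, stage: str, condition: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for condition {condition!r}: {cause}")
        self.stage = stage
        self.condition = condition
        self.cause = cause


def _condition_seed(base_seed: int, index: int) -> int:
    return int((base_seed + 7919 * (index + 1)) % (2**31 - 1))


def run_condition(cond: ConditionConfig, seed: int, stages: Sequence[str] = ALL_STAGES) -> dict:
    """Run one condition through the requested stages; returns a result dict
    with intermediates (experiment, annotations, paths) and a summary."""
    out: dict = {"name": cond.name, "summary": {"name": cond.name, "n_molecules": cond.n_molecules}}
    summary = out["summary"]

    if "simulate" in stages:
        exp = simulate_experiment(
            scheme=cond.scheme, photo=cond.photo, delivery=cond.delivery,
            camera=cond.camera, n_molecules=cond.n_molecules, seed=seed,
            wash_time=cond.wash_time_s, wash_scheme=cond.wash_scheme,
            condition_name=cond.name,
        )
        out["experiment"] = exp
        summary["seed"] = seed
    if "process" not in stages or "experiment" not in out:
        return out

    ana = cond.analysis
    atraces = annotate_traces(out["experiment"].traces, arrival_m=ana.arrival_m_consecutive)
    passed = [a for a in atraces if a.qc["passed"] and a.usable_end - a.usable_start >= 10]
    out["annotated"] = atraces
    out["passed"] = passed
    summary["n_qc_passed"] = len(passed)
    for a in atraces:
        if not a.qc["passed"]:
            logger.debug("%s: QC fail (%s)", a.trace.molecule, a.qc)
    if "idealize" not in stages:
        return out
    if not passed:
        summary["error"] = "no traces passed QC"
        return out

    K = ana.hmm_states
    fret_set = [a.usable_fret_clean for a in passed]
    model = fit_hmm(fret_set, K, cond.camera.exposure_s,
                    n_restarts=ana.hmm_restarts, seed=seed)
    decode_model = stabilize_for_decoding(model)
    paths = [viterbi(a, decode_model) for a in passed]
    out["model"] = model
    out["paths"] = paths
    summary["hmm"] = {
        "K": K,
        "means": [float(m) for m in model.means],
        "sds": [float(s) for s in model.sds],
        "log_likelihood": model.log_likelihood,
        "non_identifiable": model.non_identifiable,
    }
    if "kinetics" not in stages:
        return out

    frac, per_trace = rotating_fraction(paths, min_flank_frames=ana.min_flank_frames)
    summary["rotating_fraction"] = frac
    summary["transitions_per_trace"] = per_trace

    if K >= 2:
        dynamic = [p for p in paths if p.n_qualified_transitions(ana.min_dwell_frames) >= 1]
        out["dynamic_paths"] = dynamic
        dwells = extract_dwells(dynamic, min_dwell_frames=ana.min_dwell_frames,
                                state_names=_STATE_NAMES,
                                first_dwell_censored=cond.delivery.mode == "preformed")
        out["dwells"] = dwells
        if not dwells.empty:
            try:
                res = analyze_two_state_dwells(
                    dwells, states=("SEMI", "NON"), model=ana.dwell_model,
                    frame_interval=cond.camera.exposure_s,
                    min_dwell_frames=ana.min_dwell_frames,
                    dead_time_frames=ana.dead_time_frames,
                    correct_missed=ana.correct_missed_events,
                    seed=seed,
                )
                out["dwell_fits"] = res["fits"]
                summary["dwells"] = {
                    s: {
                        "model": f.model,
                        "params": {k: float(v) for k, v in f.params.items()},
                        "mean_s": float(f.mean),
                        "mean_corrected_s": float(f.mean_corrected),
                        "median_s": float(f.median),
                        "median_model_s": float(f.median_model),
                        "n": f.n,
                    }
                    for s, f in res["fits"].items()
                }
                summary["dead_time_s"] = res["dead_time"]
            except (ValueError, RuntimeError) as e:
                summary["dwell_fit_error"] = str(e)
        fe_fit, fe_tab = first_event_times(paths, min_flank_frames=ana.min_flank_frames, seed=seed)
        out["first_events"] = fe_tab
        summary["first_event"] = {
            "model": fe_fit.model,
            "params": {k: float(v) for k, v in fe_fit.params.items()},
            "mean_s": float(fe_fit.mean) if np.isfinite(fe_fit.mean) else None,
            "n_events": int(fe_tab["event"].sum()),
        }
    if cond.wash_time_s is not None and "paths" in out:
        # wash time is absolute; convert to each path's window-relative time
        tab_paths, rel = [], []
        for p, a in zip(paths, passed):
            t0 = a.usable_start * a.frame_interval
            if cond.wash_time_s > t0:
                tab_paths.append(p)
                rel.append(cond.wash_time_s - t0)
        rows = []
        for p, r in zip(tab_paths, rel):
            rows.append(wash_comparison([p], r, min_flank_frames=ana.min_flank_frames))
        if rows:
            import pandas as pd
            wtab = pd.concat(rows, ignore_index=True)
            out["wash"] = wtab
            summary["wash"] = {
                "pre_mean": float(wtab["pre_wash"].mean()),
                "post_mean": float(wtab["post_wash"].mean()),
                "n": int(len(wtab)),
            }
    if "dists" not in stages:
        return out

    pooled = np.concatenate([a.usable_fret_clean for a in passed]) if passed else np.array([])
    if pooled.size >= 100:
        try:
            gf = fit_fret_gaussians(pooled, components="auto", seed=seed)
            out["gaussians"] = gf
            summary["fret_gaussians"] = {
                "weights": [float(w) for w in gf.weights],
                "means": [float(m) for m in gf.means],
                "sds": [float(s) for s in gf.sds],
                "flags": gf.flags,
            }
        except ValueError as e:
            summary["fret_gaussians_error"] = str(e)
    event = "arrival" if cond.delivery.mode == "delivery" else "low_to_high"
    try:
        hm = build_sync_heatmap(passed, out.get("paths"), event=event,
                                window=(-2.0, 10.0), min_flank_frames=ana.min_flank_frames)
        out["heatmap"] = hm
        summary["heatmap"] = {"event": event, "n_traces": hm.n_traces, "n_excluded": hm.n_excluded}
    except (ValueError, IndexError) as e:
        summary["heatmap_error"] = str(e)
    return out


def arrival_analysis(results: dict, through_origin: bool = False) -> dict:
    """Cross-condition arrival kinetics: per-concentration censored
    exponential fits and the bimolecular slope in uM^-1 s^-1."""
    arrivals: dict = {}
    for name, res in results.items():
        if "annotated" not in res:
            continue
        cond = res.get("condition")
        if cond is None or cond.delivery.mode != "delivery":
            continue
        conc = cond.delivery.concentration_nM
        times, events = [], []
        for a in res["annotated"]:
            end = (a.bleach_frame if a.bleach_frame is not None else a.trace.n_frames)
            end_s = min(end * a.frame_interval, cond.delivery.window_s)
            if a.arrival_frame is not None:
                times.append(a.arrival_time)
                events.append(True)
            else:
                times.append(end_s)
                events.append(False)
        arrivals[conc] = (np.asarray(times), np.asarray(events))
    if not arrivals:
        return {}
    per, fit = fit_arrival_kinetics(arrivals, through_origin=through_origin)
    out = {
        "per_concentration": {
            str(c): {"k_obs_s": d["k_obs"], "se": d["k_obs_se"],
                     "active_fraction": d["active_fraction"],
                     "n": d["n"], "n_events": d["n_events"]}
            for c, d in per.items()
        }
    }
    if fit is not None:
        out["slope_uM_s"] = fit.params["slope_uM_s"]
        out["slope_ci"] = list(fit.ci["slope_uM_s"])
        if "intercept_s" in fit.params:
            out["intercept_s"] = fit.params["intercept_s"]
    return out


def run_pipeline(
    config: ExperimentConfig,
    stages: Sequence[str] = ALL_STAGES,
    outdir: Optional[str] = None,
) -> dict:
    """Execute the pipeline over all conditions of a configuration.

    An empty ``stages`` performs configuration validation only.  Stage
    failures halt with a stage-tagged error; outputs written so far are
    preserved.  Re-running with the same config and seed reproduces the
    summary bit-identically.
    """
    config.validate()
    report: dict = {
        "experiment": config.name,
        "seed": config.seed,
        "config_hash": config.config_hash,
        "conditions": {},
    }
    if not stages:
        report["validated"] = True
        return report
    results: dict = {}
    outpath = Path(outdir) if outdir else None
    if outpath:
        outpath.mkdir(parents=True, exist_ok=True)
    for i, cond in enumerate(config.conditions):
        seed = _condition_seed(config.seed, i)
        try:
            res = run_condition(cond, seed, stages=stages)
        except Exception as e:  # noqa: BLE001 - tag and re-raise with context
            if outpath:
                _write_summary(outpath, report)
            raise StageError("condition", cond.name, e) from e
        res["condition"] = cond
        results[cond.name] = res
        report["conditions"][cond.name] = res["summary"]
        if outpath:
            if "experiment" in res:
                rio.write_ground_truth(outpath / f"{cond.name}.truth", res["experiment"].truth)
            if "annotated" in res:
                rio.write_annotations(outpath / f"{cond.name}.annotations.tsv", res["annotated"])
            if "dwells" in res and not res["dwells"].empty:
                rio.write_dwell_table(outpath / f"{cond.name}.dwells.tsv", res["dwells"])
            if "wash" in res:
                res["wash"].to_csv(outpath / f"{cond.name}.wash.tsv", sep="\t", index=False)
    if "kinetics" in stages:
        arr = arrival_analysis(results)
        if arr:
            report["arrival_kinetics"] = arr
    if outpath:
        _write_summary(outpath, report)
    report["_results"] = results
    return report


def _write_summary(outpath: Path, report: dict) -> None:
    clean = {k: v for k, v in report.items() if not k.startswith("_")}
    (outpath / "summary.json").write_text(json.dumps(clean, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)
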