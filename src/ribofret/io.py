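"""Reading and writing trace sets, ground truth and analysis tables.

Trace sets are stored as one HDF5 container per experiment
(``/traces/<id>/{donor,acceptor}`` with exposure and condition attributes)
plus a plain comma-separated long-format export (one row per frame per
molecule).  Ground truth, dwell tables and idealized paths go to flat
tab/comma-separated files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .traces import Trace

__all__ = [
    "write_traceset_h5", "read_traceset_h5",
    "write_traceset_csv", "read_traceset_csv",
    "write_ground_truth", "read_ground_truth",
    "write_dwell_table", "read_dwell_table",
    "write_idealized_paths", "write_annotations",
]


def write_traceset_h5(path, traces: Sequence[Trace], attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("traces")
        for t in traces:
            tg = g.create_group(t.molecule)
            tg.create_dataset("donor", data=t.donor, compression="gzip")
            tg.create_dataset("acceptor", data=t.acceptor, compression="gzip")
            tg.attrs["frame_interval"] = t.frame_interval
            tg.attrs["condition"] = json.dumps(t.condition)
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def read_traceset_h5(path) -> list[Trace]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f["traces"]):
            tg = f["traces"][name]
            out.append(Trace(
                molecule=name,
                frame_interval=float(tg.attrs["frame_interval"]),
                donor=tg["donor"][:],
                acceptor=tg["acceptor"][:],
                condition=json.loads(tg.attrs.get("condition", "{}")),
            ))
    return out


def write_traceset_csv(path, traces: Sequence[Trace]) -> None:
    frames = []
    for t in traces:
        frames.append(pd.DataFrame({
            "molecule": t.molecule,
            "frame": np.arange(t.n_frames),
            "time_s": t.times,
            "donor": t.donor,
            "acceptor": t.acceptor,
            "frame_interval": t.frame_interval,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traceset_csv(path, frame_interval: float | None = None) -> list[Trace]:
    """Plain comma-separated import: either the long format written by
    :func:`write_traceset_csv` or a two-column-per-molecule wide table
    (``<id>_donor``, ``<id>_acceptor``) for external data."""
    df = pd.read_csv(path)
    out = []
    if "molecule" in df.columns:
        for mol, sub in df.groupby("molecule", sort=True):
            dt = float(sub["frame_interval"].iloc[0]) if "frame_interval" in sub else frame_interval
            out.append(Trace(molecule=str(mol), frame_interval=dt,
                             donor=sub["donor"].to_numpy(), acceptor=sub["acceptor"].to_numpy()))
        return out
    if frame_interval is None:
        raise ValueError("frame_interval is required for wide-format imports")
    stems = sorted({c[:-6] for c in df.columns if c.endswith("_donor")})
    for stem in stems:
        out.append(Trace(
            molecule=stem, frame_interval=frame_interval,
            donor=df[f"{stem}_donor"].to_numpy(),
            acceptor=df[f"{stem}_acceptor"].to_numpy(),
        ))
    return out


def write_ground_truth(prefix, truth) -> None:
    prefix = Path(prefix)
    truth.molecules.to_csv(prefix.with_suffix(".molecules.csv"), index=False)
    truth.dwells.to_csv(prefix.with_suffix(".dwells.csv"), index=False)


def read_ground_truth(prefix):
    from .simulate import GroundTruth
    prefix = Path(prefix)
    return GroundTruth(
        molecules=pd.read_csv(prefix.with_suffix(".molecules.csv")),
        dwells=pd.read_csv(prefix.with_suffix(".dwells.csv")),
    )


def write_dwell_table(path, dwells: pd.DataFrame) -> None:
    dwells.to_csv(path, sep="\t", index=False)


def read_dwell_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_idealized_paths(path, paths) -> None:
    rows = []
    for p in paths:
        for j in range(p.n_frames):
            frame = p.start_frame + j
            rows.append((p.molecule, frame, frame * p.frame_interval,
                         int(p.states[j]), p.fret[j]))
    pd.DataFrame(rows, columns=["molecule", "frame", "time_s", "state", "fret"]) \
        .to_csv(path, sep="\t", index=False)


def write_annotations(path, atraces) -> None:
    rows = []
    for a in atraces:
        rows.append({
            "molecule": a.trace.molecule,
            "arrival_s": a.arrival_time if a.arrival_time is not None else "",
            "bleach_s": a.bleach_frame * a.frame_interval if a.bleach_frame is not None else "",
            "usable_start": a.usable_start,
            "usable_end": a.usable_end,
            "snr": a.qc.get("snr", ""),
            "qc_flags": ";".join(k for k, v in a.qc.items() if v is True),
            "qc_passed": a.qc.get("passed", ""),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
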