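"""TSV/JSON persistence for the pipeline's tabular schemas.

All on-disk formats are plain tab-separated text:

* traces:      trace_id, frame, donor, acceptor  (+ frame_time in JSON sidecar)
* bursts:      burst_id, f_donor, f_acceptor, duration
* titrations:  concentration_M, replicate, response
* peak lists:  residue, dH_ppm, dN_ppm, intensity
* histograms:  bin_lo, bin_hi, height
* frame records: epoch, traj, frame, D, descriptor0...

Ground-truth parameters travel in JSON sidecars next to the data.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fret import BIN_EDGES, FretHistogram, IntensityTrace


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def traces_to_frame(traces) -> pd.DataFrame:
    rows = []
    for tr in traces:
        rows.append(
            pd.DataFrame(
                {
                    "trace_id": tr.trace_id,
                    "frame": np.arange(len(tr)),
                    "donor": tr.donor,
                    "acceptor": tr.acceptor,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_traces(traces, path, frame_time: float | None = None) -> None:
    write_tsv(traces_to_frame(traces), path)
    if frame_time is not None:
        sidecar = Path(path).with_suffix(".json")
        sidecar.write_text(json.dumps({"frame_time": frame_time}))


def read_traces(path, frame_time: float | None = None) -> list[IntensityTrace]:
    df = read_tsv(path)
    if frame_time is None:
        sidecar = Path(path).with_suffix(".json")
        frame_time = (
            json.loads(sidecar.read_text())["frame_time"]
            if sidecar.exists()
            else 0.1
        )
    out = []
    for tid, grp in df.groupby("trace_id", sort=False):
        grp = grp.sort_values("frame")
        out.append(
            IntensityTrace(
                donor=grp["donor"].to_numpy(),
                acceptor=grp["acceptor"].to_numpy(),
                frame_time=frame_time,
                trace_id=str(tid),
            )
        )
    return out


def write_histogram(hist: FretHistogram, path) -> None:
    write_tsv(hist.to_frame(), path)


def read_histogram(path) -> FretHistogram:
    df = read_tsv(path)
    heights = df["height"].to_numpy(float)
    n_frames = int(df.attrs.get("n_frames", 0)) or max(
        int(round(1 / heights[heights > 0].min())), 1
    )
    return FretHistogram(heights=heights, n_frames=n_frames, bin_edges=BIN_EDGES.copy())


def write_json(obj, path) -> None:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, frozenset):
            return sorted(o)
        raise TypeError(f"cannot serialize {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))


def read_json(path):
    return json.loads(Path(path).read_text())
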