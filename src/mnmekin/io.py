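"""Plain-text I/O for traces and inhibition grids.

Trace CSV: comma-separated, '.' decimal, time always in seconds.  Header
comment lines starting '#' carry the channel and metadata as JSON; the
column header is ``time_s,signal[,replicate_id]``.  Files without a
replicate_id column are read as a single replicate.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import InhibitionGrid
from .trace import Trace

__all__ = ["write_trace", "read_trace", "write_grid", "read_grid"]

_FMT = "%.17g"  # full double precision for lossless round trips


def write_trace(trace: Trace | list[Trace], path) -> Path:
    """Write one trace (or a list of replicates) to CSV with a JSON header."""
    path = Path(path)
    traces = trace if isinstance(trace, list) else [trace]
    first = traces[0]
    meta = {
        "channel": first.channel,
        "noise_sd": first.noise_sd,
        "n_replicates": len(traces) if len(traces) > 1 else first.n_replicates,
        "seed": first.seed,
        "construct_label": first.construct_label,
        **first.meta,
    }
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# mnmekin trace\n# meta: {json.dumps(meta)}\n")
        if len(traces) == 1:
            fh.write("time_s,signal\n")
            for t, y in zip(first.time, first.signal):
                fh.write(f"{_FMT % t},{_FMT % y}\n")
        else:
            fh.write("time_s,signal,replicate_id\n")
            for r, tr in enumerate(traces):
                for t, y in zip(tr.time, tr.signal):
                    fh.write(f"{_FMT % t},{_FMT % y},{r}\n")
    return path


def read_trace(path) -> Trace | list[Trace]:
    """Read a trace CSV; returns a list when the file holds replicates."""
    path = Path(path)
    meta: dict = {}
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# meta:"):
                meta = json.loads(line[len("# meta:"):])
    df = pd.read_csv(path, comment="#")
    missing = {"time_s", "signal"} - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    channel = meta.pop("channel", "mant")
    kwargs = dict(noise_sd=meta.pop("noise_sd", 0.0),
                  seed=meta.pop("seed", None),
                  construct_label=meta.pop("construct_label", ""))
    meta.pop("n_replicates", None)

    def build(sub: pd.DataFrame, n_rep: int = 1) -> Trace:
        t = sub["time_s"].to_numpy(float)
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("non-monotone time in trace CSV")
        return Trace(channel, t, sub["signal"].to_numpy(float),
                     n_replicates=n_rep, meta=dict(meta), **kwargs)

    if "replicate_id" not in df.columns:
        return build(df)
    reps = [build(sub) for _, sub in df.groupby("replicate_id", sort=True)]
    return reps[0] if len(reps) == 1 else reps


def write_grid(grid: InhibitionGrid, path) -> Path:
    """Write an inhibition grid as long-form CSV (substrate_uM,inhibitor_uM,rate)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# mnmekin grid\n# meta: "
                 f"{json.dumps({'inhibitor': grid.inhibitor_name})}\n")
        fh.write("substrate_uM,inhibitor_uM,rate\n")
        for _, row in grid.to_frame().iterrows():
            fh.write(f"{_FMT % row.substrate_uM},{_FMT % row.inhibitor_uM},"
                     f"{_FMT % row.rate}\n")
    return path


def read_grid(path) -> InhibitionGrid:
    path = Path(path)
    name = "GDP"
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("# meta:"):
                name = json.loads(line[len("# meta:"):]).get("inhibitor", name)
            if not line.startswith("#"):
                break
    df = pd.read_csv(path, comment="#")
    return InhibitionGrid.from_frame(df, inhibitor_name=name)
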