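"""Plain-text input/output: release-event CSV, histogram CSV, calcium
traces and run logs.

Events CSV schema (version 1): header comment ``# boutonsim-events v1``
followed by columns trial,time_ms,vesicle,pathway.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

EVENTS_SCHEMA = "# boutonsim-events v1"
_EVENT_COLUMNS = ["trial", "time_ms", "vesicle", "pathway"]


def write_events(events: pd.DataFrame, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(EVENTS_SCHEMA + "\n")
        events.to_csv(fh, index=False, columns=_EVENT_COLUMNS)


def read_events(path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# boutonsim-events"):
            raise ValueError(f"{path}: missing events schema header")
        df = pd.read_csv(fh)
    if list(df.columns) != _EVENT_COLUMNS:
        raise ValueError(f"{path}: unexpected columns {list(df.columns)}")
    for line_no, (_, row) in enumerate(df.iterrows(), start=3):
        if not np.isfinite(row["time_ms"]):
            raise ValueError(f"{path}: malformed row at line {line_no}")
    df["trial"] = df["trial"].astype(int)
    df["vesicle"] = df["vesicle"].astype(int)
    return df


def write_histogram(hist, path) -> None:
    df = pd.DataFrame({
        "t_start_ms": hist.edges_ms[:-1],
        "rate_per_ms": hist.rate_per_ms,
        "std": hist.rate_std,
    })
    df.to_csv(path, index=False)


def write_trace(trace, path) -> None:
    pd.DataFrame({"time_ms": trace.time_ms,
                  "conc_uM": trace.conc_um}).to_csv(path, index=False)


def read_trace(path):
    from .spatial import CalciumTrace
    df = pd.read_csv(path)
    return CalciumTrace(df["time_ms"].to_numpy(), df["conc_uM"].to_numpy())


def write_metadata(meta: dict, path) -> None:
    Path(path).write_text(json.dumps(meta, indent=2, default=str))


def setup_run_log(output_dir, name: str = "boutonsim") -> logging.Logger:
    """Per-run text log recording seeds and effective parameters."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger = logging.getLogger(name)
    logger.setLevel(logging.INFO)
    handler = logging.FileHandler(out / f"{name}.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    return logger
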