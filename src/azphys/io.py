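"""Trace and table I/O: CSV/NPZ current traces with JSON protocol
sidecars, CmEstimate tables as CSV."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .params import VoltageProtocol
from .synth_ephys import CurrentTrace


def save_trace(trace: CurrentTrace, path, protocol: VoltageProtocol | None
               = None) -> None:
    """Write a trace as .npz (compact) or .csv (columns time_ms, I_pA,
    valid); a protocol, if given, goes to a <path>.json sidecar."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, time_ms=trace.times(), i_pA=trace.i_pA,
                 valid=trace.valid, fs_khz=trace.fs_khz, t0_ms=trace.t0_ms)
    elif path.suffix == ".csv":
        pd.DataFrame({"time_ms": trace.times(), "I_pA": trace.i_pA,
                      "valid": trace.valid.astype(int)}).to_csv(path,
                                                               index=False)
    else:
        raise ValueError("trace path must end in .npz or .csv")
    if protocol is not None:
        with open(str(path) + ".json", "w") as fh:
            json.dump(asdict(protocol), fh, indent=1)


def load_trace(path) -> CurrentTrace:
    path = Path(path)
    if path.suffix == ".npz":
        d = np.load(path)
        return CurrentTrace(d["i_pA"], float(d["fs_khz"]), float(d["t0_ms"]),
                            d["valid"].astype(bool))
    if path.suffix == ".csv":
        df = pd.read_csv(path)
        t = df["time_ms"].to_numpy()
        fs = 1.0 / np.median(np.diff(t))
        valid = (df["valid"].to_numpy().astype(bool) if "valid" in df
                 else None)
        return CurrentTrace(df["I_pA"].to_numpy(), fs, float(t[0]), valid)
    raise ValueError("trace path must end in .npz or .csv")


def load_protocol(path) -> VoltageProtocol:
    with open(path) as fh:
        d = json.load(fh)
    if "step_table" in d:
        d["step_table"] = tuple(tuple(x) for x in d["step_table"])
    return VoltageProtocol(**d)


def save_cm_estimate(est, path) -> None:
    """CmEstimate table as CSV (t_ms, cm_fF, gm_nS, gs_nS, g_dc_nS, valid)."""
    tab = est.table.copy()
    tab["valid"] = tab["valid"].astype(int)
    tab.to_csv(path, index=False)
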