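"""EPSC amplitude extraction and train/ratio analyses.

Amplitude convention: per stimulus, amplitude = |minimum of the trace in
the search window - mean of the local pre-stimulus baseline|.  Stimulus
artifacts are blanked ([t_stim, t_stim + blank_ms)); the search window is
[t_stim + blank_ms, t_stim + search_ms) truncated at the next stimulus.
During trains, later baselines ride on residual decay of earlier EPSCs;
no summation correction is applied (measured-amplitude convention).

Because extracellular stimulation recruits multiple fibers, absolute
amplitudes are flagged as multi-fiber quantities; cross-group inference
should default to normalized or within-cell ratio quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, WindowError
from .synth_ephys import CurrentTrace

__all__ = [
    "EpscTrain",
    "extract_epsc_amplitudes",
    "correct_holding",
    "potentiation_ratio",
    "dcgiv_remaining",
    "summarize_train",
]


def correct_holding(amplitude_pA: float, v_hold_mV: float) -> float:
    """Rescale an amplitude measured at v_hold to its value at -70 mV,
    assuming a 0 mV reversal potential (linear driving force)."""
    if v_hold_mV >= 0:
        raise InvalidParameterError("V_hold must be negative")
    return amplitude_pA * (-70.0) / v_hold_mV


@dataclass
class EpscTrain:
    """Per-stimulus EPSC amplitudes from one sweep.

    amps_pA are magnitudes as measured at v_hold; amps_corr_pA are
    corrected to -70 mV.  norm_amps is amps_corr normalised to the first
    response (NaN, with ``degenerate`` set, if the first response is 0).
    """

    amps_pA: np.ndarray
    v_hold_mV: float
    stim_times_ms: np.ndarray
    multi_fiber: bool = True
    cell_id: str = ""
    condition: str = ""

    @property
    def amps_corr_pA(self) -> np.ndarray:
        return np.array([correct_holding(a, self.v_hold_mV)
                         for a in self.amps_pA])

    @property
    def degenerate(self) -> bool:
        return not (self.amps_pA[0] > 0)

    @property
    def norm_amps(self) -> np.ndarray:
        if self.degenerate:
            return np.full_like(self.amps_pA, np.nan)
        return self.amps_pA / self.amps_pA[0]

    @property
    def ppr(self) -> float:
        """Paired-pulse ratio (second/first amplitude)."""
        if self.amps_pA.size < 2 or self.degenerate:
            return float("nan")
        return float(self.amps_pA[1] / self.amps_pA[0])

    @property
    def stim_freq_hz(self) -> float:
        if self.stim_times_ms.size < 2:
            return float("nan")
        return 1000.0 / float(np.mean(np.diff(self.stim_times_ms)))


def extract_epsc_amplitudes(trace: CurrentTrace, stim_times_ms,
                            search_ms: float = 15.0, base_ms: float = 2.0,
                            blank_ms: float = 1.0, v_hold_mV: float = -70.0,
                            cell_id: str = "", condition: str = "") -> EpscTrain:
    """Measure per-stimulus EPSC amplitudes from a stimulus-aligned trace.

    Raises WindowError if a search window would overlap a blank window of
    the next stimulus (i.e. search_ms exceeding the inter-stimulus
    interval is truncated; a blank wider than the interval is an error).
    """
    stim = np.asarray(list(stim_times_ms), float)
    if stim.size == 0 or np.any(np.diff(stim) <= 0):
        raise InvalidParameterError("stimulus times must be strictly increasing")
    isi = np.diff(stim)
    if isi.size and blank_ms >= isi.min():
        raise WindowError("blank window covers an entire inter-stimulus interval")
    amps = []
    for k, tk in enumerate(stim):
        next_t = stim[k + 1] if k + 1 < stim.size else np.inf
        s0 = tk + blank_ms
        s1 = min(tk + search_ms, next_t)
        if s1 <= s0:
            raise WindowError("search window overlaps artifact blank")
        sl = trace.window_slice(s0, s1)
        b1 = tk
        b0 = max(tk - base_ms, trace.t0_ms)
        bsl = trace.window_slice(b0, b1)
        base = trace.i_pA[bsl].mean()
        amps.append(max(0.0, float(base - trace.i_pA[sl].min())))
    return EpscTrain(np.asarray(amps), v_hold_mV, stim, True, cell_id,
                     condition)


def potentiation_ratio(amplitudes: pd.DataFrame, condition_pair,
                       amp_col: str = "amp_corr_pA") -> pd.DataFrame:
    """Within-cell ratio of mean first-EPSC amplitudes between two
    conditions (condition2 / condition1 of ``condition_pair``).

    ``amplitudes`` is tidy with columns cell, condition and the amplitude
    column.  Cells missing either condition are excluded (listed in the
    ``excluded`` attribute of the returned frame).  The orientation is
    recorded in the output metadata columns."""
    c1, c2 = condition_pair
    rows, excluded = [], []
    for cell, sub in amplitudes.groupby("cell"):
        m1 = sub.loc[sub["condition"] == c1, amp_col]
        m2 = sub.loc[sub["condition"] == c2, amp_col]
        if len(m1) == 0 or len(m2) == 0:
            excluded.append(cell)
            continue
        rows.append({"cell": cell, "ratio": float(m2.mean() / m1.mean()),
                     "numerator": c2, "denominator": c1})
    out = pd.DataFrame(rows)
    out.attrs["excluded"] = excluded
    return out


def dcgiv_remaining(pre_amps, post_amps) -> float:
    """Remaining response fraction after DCG-IV: mean(post)/mean(pre).

    Used to verify mossy-fiber identity (remaining < 0.3 expected).
    Returns NaN for a zero pre-drug mean."""
    pre = np.asarray(list(pre_amps), float)
    post = np.asarray(list(post_amps), float)
    if pre.size < 3 or post.size < 3:
        raise InvalidParameterError("need >= 3 amplitudes before and after")
    if pre.mean() == 0:
        return float("nan")
    return float(post.mean() / pre.mean())


def summarize_train(trains: list[EpscTrain]) -> pd.DataFrame:
    """Group mean +- SEM time course across cells, absolute (-70 mV
    corrected) and first-normalized.

    Trains longer than the shortest in the group are truncated to the
    common stimulus count (the truncation is recorded in
    ``attrs['truncated_from']``).  Degenerate trains (zero first response)
    contribute to the absolute but not the normalized summary."""
    if len(trains) == 0:
        raise InvalidParameterError("empty group")
    n_stim = min(t.amps_pA.size for t in trains)
    truncated = [t.cell_id for t in trains if t.amps_pA.size > n_stim]
    abs_mat = np.vstack([t.amps_corr_pA[:n_stim] for t in trains])
    norm_rows = [t.norm_amps[:n_stim] for t in trains if not t.degenerate]
    norm_mat = np.vstack(norm_rows) if norm_rows else np.full((1, n_stim), np.nan)

    def sem(m):
        if m.shape[0] < 2:
            return np.zeros(m.shape[1])
        return m.std(axis=0, ddof=1) / np.sqrt(m.shape[0])

    out = pd.DataFrame({
        "stim_index": np.arange(1, n_stim + 1),
        "mean_amp_pA": abs_mat.mean(axis=0),
        "sem_amp_pA": sem(abs_mat),
        "mean_norm": norm_mat.mean(axis=0),
        "sem_norm": sem(norm_mat),
        "n_cells": abs_mat.shape[0],
    })
    out.attrs["truncated_from"] = truncated
    return out
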