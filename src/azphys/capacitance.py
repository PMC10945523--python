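"""Sine + DC membrane-capacitance estimation (Lindau-Neher technique).

A sinusoidal command rides on the holding potential; correlating the
current with sin/cos at the stimulus frequency over an integer number of
cycles yields the complex admittance Y = A + iB, and the mean current
yields the DC conductance G_dc.  For the three-element circuit (series
conductance Gs into Gm || Cm) the inversion is closed-form:

    Gs = A + B^2 / (A - G_dc)
    Gm = Gs * G_dc * (A - G_dc) / ((A - G_dc)^2 + B^2) * ... (computed
         directly from T = Y Gs / (Gs - Y); Gm = Re T, Cm = Im T / w)

derived from Y = Gs (Gm + iwCm) / (Gs + Gm + iwCm) and
G_dc = Gs Gm / (Gs + Gm).  Physical solutions require B > 0 and
A > G_dc >= 0; blocks violating this (e.g. by noise) are flagged invalid
rather than clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, NonPhysicalError, WindowError
from .params import CircuitParams, VoltageProtocol
from .synth_ephys import CurrentTrace, simulate_sine_dc_trace

__all__ = [
    "lockin_extract",
    "invert_admittance",
    "calibrate_phase",
    "estimate_cm_timeseries",
    "measure_cm_jump",
    "CmEstimate",
    "CapJump",
]


def _samples_per_cycle(trace: CurrentTrace, protocol: VoltageProtocol) -> int:
    spc = trace.fs_khz * 1000.0 / protocol.sine_freq_hz
    if abs(spc - round(spc)) > 1e-9:
        raise WindowError("sine period is not an integer number of samples")
    return int(round(spc))


def lockin_extract(trace: CurrentTrace, protocol: VoltageProtocol,
                   block_cycles: int = 1, calibration: complex = 1.0 + 0.0j,
                   leak_pA: float = 0.0) -> pd.DataFrame:
    """Per-block complex admittance and DC conductance.

    Each block spans ``block_cycles`` full sine cycles.  Within a block the
    mean is removed, then A (real) and B (imaginary) are the sin/cos
    correlation amplitudes divided by the sine amplitude; the calibration
    factor rotates/scales Y to compensate recording-chain phase and gain
    (see :func:`calibrate_phase`).  G_dc = (mean current - leak)/V_hold.

    Blocks containing any invalid sample yield NaN rows (gap markers).
    Returns a DataFrame with columns t_ms (block start), A_nS, B_nS,
    g_dc_nS, ok.
    """
    if block_cycles < 1:
        raise WindowError("block_cycles must be >= 1")
    if protocol.v_hold_mV == 0:
        raise InvalidParameterError("V_hold must be nonzero for G_dc")
    spc = _samples_per_cycle(trace, protocol)
    nblk = spc * block_cycles
    nblocks = trace.n // nblk
    omega = protocol.omega
    t = trace.times()
    vs = protocol.sine_amp_mV

    rows = []
    for b in range(nblocks):
        sl = slice(b * nblk, (b + 1) * nblk)
        tb = t[sl]
        if not trace.valid[sl].all():
            rows.append({"t_ms": tb[0], "A_nS": np.nan, "B_nS": np.nan,
                         "g_dc_nS": np.nan, "ok": False})
            continue
        i_blk = trace.i_pA[sl]
        i_mean = i_blk.mean()
        i_ac = i_blk - i_mean
        a = 2.0 / (nblk * vs) * np.sum(i_ac * np.sin(omega * tb))
        bq = 2.0 / (nblk * vs) * np.sum(i_ac * np.cos(omega * tb))
        y = (a + 1j * bq) * calibration
        g_dc = (i_mean - leak_pA) / protocol.v_hold_mV
        rows.append({"t_ms": tb[0], "A_nS": y.real, "B_nS": y.imag,
                     "g_dc_nS": g_dc, "ok": True})
    return pd.DataFrame(rows)


def calibrate_phase(protocol: VoltageProtocol, fs_khz: float,
                    g_ref_nS: float = 1.0,
                    process=None) -> complex:
    """Complex calibration factor from a known-resistor reference.

    A pure resistor of conductance g_ref is simulated (or recorded via the
    user-supplied ``process(trace) -> DataFrame`` hook for real hardware),
    passed through the lock-in, and the factor that maps the measured
    phasor back to the ideal (g_ref + 0j) is returned.  Recording chains
    add low-pass filter phase and attenuation; for the ideal simulated
    chain the factor is 1."""
    ideal = g_ref_nS + 0.0j
    if process is None:
        # a resistor is the Gs->resistor limit: Gm huge, Cm tiny
        circ = CircuitParams(cm_baseline_fF=1e-6, gm_nS=1e9, gs_nS=g_ref_nS)
        trace = simulate_sine_dc_trace(
            circ, VoltageProtocol(v_hold_mV=protocol.v_hold_mV,
                                  sine_amp_mV=protocol.sine_amp_mV,
                                  sine_freq_hz=protocol.sine_freq_hz),
            fs_khz=fs_khz, post_ms=10.0)
        est = lockin_extract(trace, protocol, block_cycles=1)
    else:
        est = process()
    est = est[est["ok"]]
    y = complex(est["A_nS"].mean(), est["B_nS"].mean())
    return ideal / y


def invert_admittance(a_nS: float, b_nS: float, g_dc_nS: float,
                      omega_rad_per_ms: float):
    """Closed-form three-element inversion.

    Returns (Cm_fF, Gm_nS, Gs_nS).  Raises NonPhysicalError when the
    measured (A, B, G_dc) admits no physical circuit (B <= 0 means no
    capacitive signal; A <= G_dc is impossible for positive elements).
    """
    if b_nS <= 0:
        raise NonPhysicalError("B <= 0: no capacitive signal")
    if g_dc_nS < 0 or a_nS <= g_dc_nS:
        raise NonPhysicalError("requires A > G_dc >= 0")
    gs = a_nS + b_nS**2 / (a_nS - g_dc_nS)
    y = a_nS + 1j * b_nS
    t = y * gs / (gs - y)          # Gm + i w Cm
    gm = t.real
    cm_pF = t.imag / omega_rad_per_ms
    if cm_pF <= 0 or gm < 0:
        raise NonPhysicalError("inversion produced non-physical elements")
    return cm_pF * 1000.0, gm, gs


@dataclass
class CmEstimate:
    """Block time series of circuit parameters from admittance inversion.

    ``table`` columns: t_ms (block start), cm_fF, gm_nS, gs_nS, g_dc_nS,
    valid.  block_ms is the block duration."""

    table: pd.DataFrame
    block_ms: float

    def valid_between(self, t0: float, t1: float) -> pd.DataFrame:
        tab = self.table
        sel = (tab["t_ms"] >= t0 - 1e-9) & (tab["t_ms"] + self.block_ms
                                            <= t1 + 1e-9)
        return tab[sel]


def estimate_cm_timeseries(trace: CurrentTrace, protocol: VoltageProtocol,
                           block_cycles: int = 1,
                           calibration: complex | None = None,
                           dead_time_ms: float = 10.0,
                           leak_pA: float = 0.0) -> CmEstimate:
    """Lock-in extraction followed by per-block circuit inversion.

    Blocks overlapping the depolarizing pulse, or the dead time after it
    (tail currents), are marked invalid.  Blocks whose inversion is
    non-physical (noise) are likewise flagged rather than clipped.
    """
    if calibration is None:
        calibration = calibrate_phase(protocol, trace.fs_khz)
    adm = lockin_extract(trace, protocol, block_cycles, calibration, leak_pA)
    omega = protocol.omega
    block_ms = block_cycles * 1000.0 / protocol.sine_freq_hz

    has_pulse = protocol.pulse_dur_ms > 0
    blank_lo = protocol.pulse_start_ms
    blank_hi = protocol.pulse_end_ms + dead_time_ms

    rows = []
    for _, r in adm.iterrows():
        t0 = r["t_ms"]
        in_blank = has_pulse and (t0 + block_ms > blank_lo + 1e-9
                                  and t0 < blank_hi - 1e-9)
        if (not r["ok"]) or in_blank:
            rows.append({"t_ms": t0, "cm_fF": np.nan, "gm_nS": np.nan,
                         "gs_nS": np.nan, "g_dc_nS": r["g_dc_nS"],
                         "valid": False})
            continue
        try:
            cm, gm, gs = invert_admittance(r["A_nS"], r["B_nS"],
                                           r["g_dc_nS"], omega)
        except NonPhysicalError:
            rows.append({"t_ms": t0, "cm_fF": np.nan, "gm_nS": np.nan,
                         "gs_nS": np.nan, "g_dc_nS": r["g_dc_nS"],
                         "valid": False})
            continue
        rows.append({"t_ms": t0, "cm_fF": cm, "gm_nS": gm, "gs_nS": gs,
                     "g_dc_nS": r["g_dc_nS"], "valid": True})
    return CmEstimate(pd.DataFrame(rows), block_ms)


@dataclass(frozen=True)
class CapJump:
    """Capacitance jump around a depolarizing pulse."""

    delta_cm_fF: float
    baseline_window_ms: tuple
    post_window_ms: tuple
    baseline_sd_fF: float
    n_baseline: int
    n_post: int


def measure_cm_jump(est: CmEstimate, pulse_start_ms: float,
                    pulse_end_ms: float, baseline_win_ms: float = 50.0,
                    post_offset_ms: float = 10.0,
                    post_win_ms: float = 50.0) -> CapJump:
    """dCm = mean(Cm in post window) - mean(Cm in baseline window).

    Baseline is the ``baseline_win_ms`` ending at pulse start; the post
    window starts ``post_offset_ms`` after pulse end (default ~10 ms, past
    the tail-current dead time).  Both windows are half-open [start, end).
    A window that touches invalid blocks raises WindowError.
    """
    if post_offset_ms < 0:
        raise WindowError("post_offset must be >= 0")
    b0, b1 = pulse_start_ms - baseline_win_ms, pulse_start_ms
    p0, p1 = pulse_end_ms + post_offset_ms, pulse_end_ms + post_offset_ms + post_win_ms
    base = est.valid_between(b0, b1)
    post = est.valid_between(p0, p1)
    if len(base) == 0 or len(post) == 0:
        raise WindowError("window contains no blocks")
    if (~base["valid"]).any() or (~post["valid"]).any():
        raise WindowError("window overlaps invalid blocks (pulse/dead time)")
    delta = float(post["cm_fF"].mean() - base["cm_fF"].mean())
    sd = float(base["cm_fF"].std(ddof=1)) if len(base) > 1 else 0.0
    return CapJump(delta, (b0, b1), (p0, p1), sd, len(base), len(post))
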