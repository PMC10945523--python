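"""Forward models for voltage-clamp recordings.

The patched bouton is a three-element circuit (series conductance Gs into
Gm || Cm).  For the sine + DC stimulus the membrane-potential ODE

    Cm dVm/dt = Gs (V(t) - Vm) - Gm Vm

is linear with sinusoidal-plus-constant forcing, so each protocol segment
has a closed-form solution (particular sinusoid/constant plus a decaying
exponential).  The simulator evaluates that solution at the sample times,
which makes the steady-state phasor exact to machine precision -- the
property the lock-in estimator is validated against.

Capacitance switches from Cm_baseline to Cm_baseline + Cm_step at the end
of the depolarizing pulse (exocytosis adds membrane); Vm is continuous
across the switch.  Samples inside the pulse are flagged invalid, mirroring
the fact that capacitance cannot be read out during the large conductance
changes of the pulse itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, WindowError
from .params import (CaChannelParams, CircuitParams, ReleaseParams,
                     TrainParams, VoltageProtocol)

__all__ = [
    "CurrentTrace",
    "simulate_sine_dc_trace",
    "simulate_ca_current",
    "simulate_depletion_dataset",
    "simulate_epsc_train",
    "ca_current_peak_analytic",
    "tm_amplitudes",
]


@dataclass
class CurrentTrace:
    """Uniformly sampled current trace.

    i_pA      : samples, inward currents negative
    fs_khz    : sampling rate (kHz)
    t0_ms     : time of the first sample
    valid     : per-sample validity mask (False during pulses/artifacts)
    """

    i_pA: np.ndarray
    fs_khz: float
    t0_ms: float = 0.0
    valid: np.ndarray = None

    def __post_init__(self):
        self.i_pA = np.asarray(self.i_pA, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.i_pA.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.i_pA.shape:
            raise InvalidParameterError("validity mask must match samples")
        if self.fs_khz <= 0:
            raise InvalidParameterError("sampling rate must be > 0")

    @property
    def n(self) -> int:
        return self.i_pA.size

    def times(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n) / self.fs_khz

    def window_slice(self, t_start_ms: float, t_end_ms: float) -> slice:
        """Half-open sample window [t_start, t_end)."""
        if t_end_ms <= t_start_ms:
            raise WindowError("empty window")
        i0 = int(np.ceil((t_start_ms - self.t0_ms) * self.fs_khz - 1e-9))
        i1 = int(np.ceil((t_end_ms - self.t0_ms) * self.fs_khz - 1e-9))
        i0, i1 = max(i0, 0), min(i1, self.n)
        if i1 <= i0:
            raise WindowError(
                f"window [{t_start_ms}, {t_end_ms}) ms contains no samples")
        return slice(i0, i1)


# ---------------------------------------------------------------------------
# sine + DC circuit model
# ---------------------------------------------------------------------------

def _segment_solution(t, t0, vm0, gs, gm, cm_pF, v_hold, v_sine, omega,
                      sine_on):
    """Exact Vm(t) and command V(t) on one constant-parameter segment."""
    a = (gs + gm) / cm_pF                       # 1/ms
    c0 = gs * v_hold / (gs + gm)
    if sine_on and v_sine != 0.0:
        h = gs / (gs + gm + 1j * omega * cm_pF)
        vm_p = c0 + v_sine * np.imag(h * np.exp(1j * omega * t))
        vm_p0 = c0 + v_sine * np.imag(h * np.exp(1j * omega * t0))
        v_cmd = v_hold + v_sine * np.sin(omega * t)
    else:
        vm_p = np.full_like(np.asarray(t, float), c0)
        vm_p0 = c0
        v_cmd = np.full_like(np.asarray(t, float), v_hold)
    vm = vm_p + (vm0 - vm_p0) * np.exp(-a * (t - t0))
    return vm, v_cmd


def admittance_forward(circuit: CircuitParams, omega_rad_per_ms: float,
                       cm_fF: float | None = None) -> complex:
    """Analytic admittance Y(w) = Gs(Gm + iwCm)/(Gs + Gm + iwCm) in nS."""
    gs, gm = circuit.gs_nS, circuit.gm_nS
    cm_pF = (circuit.cm_baseline_fF if cm_fF is None else cm_fF) / 1000.0
    return gs * (gm + 1j * omega_rad_per_ms * cm_pF) / (
        gs + gm + 1j * omega_rad_per_ms * cm_pF)


def simulate_sine_dc_trace(circuit: CircuitParams,
                           protocol: VoltageProtocol,
                           fs_khz: float = 50.0,
                           seed: int | None = None,
                           post_ms: float = 120.0) -> CurrentTrace:
    """Simulate the pipette current of the three-element circuit under a
    sine + DC protocol, with an optional capacitance step at pulse end.

    The sine is suspended during the depolarizing pulse (the read-out is
    invalid there anyway); its phase reference is absolute time, so it
    resumes phase-coherently afterwards.
    """
    if fs_khz < 10:
        raise InvalidParameterError("fs must be >= 10 kHz")
    samples_per_cycle = fs_khz * 1000.0 / protocol.sine_freq_hz
    if abs(samples_per_cycle - round(samples_per_cycle)) > 1e-9:
        raise InvalidParameterError(
            "sampling rate must give an integer number of samples per sine cycle")

    total_ms = protocol.pulse_end_ms + post_ms
    n = int(round(total_ms * fs_khz))
    t = np.arange(n) / fs_khz
    omega = protocol.omega

    # segment boundaries in sample indices
    has_pulse = protocol.pulse_dur_ms > 0
    ps, pe = protocol.pulse_start_ms, protocol.pulse_end_ms
    i_ps = int(round(ps * fs_khz)) if has_pulse else n
    i_pe = int(round(pe * fs_khz)) if has_pulse else n

    i_out = np.empty(n)
    valid = np.ones(n, dtype=bool)
    gs, gm = circuit.gs_nS, circuit.gm_nS
    cm0_pF = circuit.cm_baseline_fF / 1000.0
    cm1_pF = (circuit.cm_baseline_fF + circuit.cm_step_fF) / 1000.0

    # start from the DC operating point (sine transient settles in ~Cm/Gs)
    vm = gs * protocol.v_hold_mV / (gs + gm)

    segments = []
    if has_pulse:
        segments = [
            (0, i_ps, protocol.v_hold_mV, protocol.sine_amp_mV, True, cm0_pF, True),
            (i_ps, i_pe, protocol.pulse_level_mV, 0.0, False, cm0_pF, False),
            (i_pe, n, protocol.v_hold_mV, protocol.sine_amp_mV, True, cm1_pF, True),
        ]
    else:
        segments = [(0, n, protocol.v_hold_mV, protocol.sine_amp_mV, True,
                     cm0_pF, True)]

    for i0, i1, vh, vs, sine_on, cm_pF, is_valid in segments:
        if i1 <= i0:
            continue
        t0 = i0 / fs_khz
        tk = t[i0:i1]
        vm_seg, v_cmd = _segment_solution(tk, t0, vm, gs, gm, cm_pF, vh, vs,
                                          omega, sine_on)
        i_out[i0:i1] = gs * (v_cmd - vm_seg)
        valid[i0:i1] = is_valid
        # carry the state to the segment end (exact)
        t_end = i1 / fs_khz
        vm_end, _ = _segment_solution(np.array([t_end]), t0, vm, gs, gm,
                                      cm_pF, vh, vs, omega, sine_on)
        vm = float(vm_end[0])

    if circuit.noise_sd_pA > 0:
        rng = np.random.default_rng(seed)
        i_out = i_out + rng.normal(0.0, circuit.noise_sd_pA, size=n)

    return CurrentTrace(i_out, fs_khz, 0.0, valid)


# ---------------------------------------------------------------------------
# Ca2+ current model
# ---------------------------------------------------------------------------

def ca_current_peak_analytic(chan: CaChannelParams, v_mV: float,
                             duration_ms: float | None = None,
                             condition: str = "WT") -> float:
    """Signed current (pA) at the end of a step to v_mV (steady state if
    duration is None)."""
    scale = chan.ko_scale if condition == "KO" else 1.0
    m = chan.m_inf(v_mV)
    if duration_ms is not None:
        m = m * (1.0 - np.exp(-duration_ms / chan.tau_act_ms))
    return float(scale * chan.g_max_nS * m * (v_mV - chan.e_rev_mV))


def simulate_ca_current(chan: CaChannelParams, v_step_mV: float,
                        duration_ms: float, fs_khz: float = 50.0,
                        seed: int | None = None, condition: str = "WT",
                        pre_ms: float = 2.0, noise_sd_pA: float = 0.0
                        ) -> CurrentTrace:
    """Ca2+ current during a step depolarization.

    The activation gate relaxes exponentially from 0 to m_inf(V) with
    tau_act; I = g_max * m * (V - E_rev), inward negative.  Baseline
    before the pulse is zero current (leak-subtracted convention)."""
    if duration_ms <= 0:
        raise InvalidParameterError("duration must be > 0")
    scale = chan.ko_scale if condition == "KO" else 1.0
    n_pre = int(round(pre_ms * fs_khz))
    n_pulse = int(round(duration_ms * fs_khz))
    t_pulse = np.arange(n_pulse) / fs_khz
    m = chan.m_inf(v_step_mV) * (1.0 - np.exp(-t_pulse / chan.tau_act_ms))
    i_pulse = scale * chan.g_max_nS * m * (v_step_mV - chan.e_rev_mV)
    i = np.concatenate([np.zeros(n_pre), i_pulse])
    if noise_sd_pA > 0:
        rng = np.random.default_rng(seed)
        i = i + rng.normal(0.0, noise_sd_pA, size=i.size)
    return CurrentTrace(i, fs_khz, -pre_ms)


# ---------------------------------------------------------------------------
# duration-response (depletion) data set
# ---------------------------------------------------------------------------

def simulate_depletion_dataset(rel: ReleaseParams, chan: CaChannelParams,
                               durations_ms, seed: int | None = None,
                               condition: str = "WT", v_step_mV: float = 10.0,
                               noise_sd_fF: float = 0.0,
                               current_noise_sd_pA: float = 0.0):
    """Per-duration table of (pulse duration, peak Ca2+ current, dCm).

    dCm(T) = rrp * (1 - exp(-T / tau_eff)) where tau_eff = tau_release
    divided by the Hill factor I^n / (I^n + K^n) of the steady-state peak
    current, so that smaller currents slow pool depletion.
    """
    import pandas as pd

    durations = np.asarray(list(durations_ms), dtype=float)
    if durations.size == 0 or np.any(durations <= 0):
        raise InvalidParameterError("durations must be non-empty and positive")
    rng = np.random.default_rng(seed)
    i_inf = abs(ca_current_peak_analytic(chan, v_step_mV, None, condition))
    tau_eff = rel.tau_eff_ms(i_inf)
    rows = []
    for T in durations:
        i_peak = abs(ca_current_peak_analytic(chan, v_step_mV, T, condition))
        if current_noise_sd_pA > 0:
            i_peak += rng.normal(0.0, current_noise_sd_pA)
        dcm = rel.rrp_size_fF * (1.0 - np.exp(-T / tau_eff))
        if noise_sd_fF > 0:
            dcm += rng.normal(0.0, noise_sd_fF)
        rows.append({"duration_ms": T, "i_peak_pA": i_peak, "dcm_fF": dcm,
                     "condition": condition})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# EPSC train generator (Tsodyks-Markram style)
# ---------------------------------------------------------------------------

def tm_amplitudes(tm: TrainParams, stim_times_ms) -> np.ndarray:
    """Analytic EPSC amplitude sequence of the facilitation/depression
    recursion; this is the generator's ground truth for extraction tests."""
    stim = np.asarray(list(stim_times_ms), dtype=float)
    if stim.size == 0:
        raise InvalidParameterError("need at least one stimulus")
    u, r = 0.0, 1.0
    t_prev = None
    amps = []
    for tk in stim:
        if t_prev is not None:
            dt = tk - t_prev
            u = u * np.exp(-dt / tm.tau_facil_ms)
            r = 1.0 - (1.0 - r) * np.exp(-dt / tm.tau_rec_ms)
        u = u + tm.u_increment * (1.0 - u)
        amps.append(tm.a_max_pA * u * r)
        r = r * (1.0 - u)
        t_prev = tk
    return np.asarray(amps)


def _epsc_kernel(t_ms: np.ndarray, tau_rise: float, tau_decay: float
                 ) -> np.ndarray:
    """Difference-of-exponentials kernel normalised to unit peak."""
    t_peak = (tau_rise * tau_decay / (tau_decay - tau_rise)
              * np.log(tau_decay / tau_rise))
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    h = np.where(t_ms >= 0,
                 np.exp(-np.maximum(t_ms, 0) / tau_decay)
                 - np.exp(-np.maximum(t_ms, 0) / tau_rise), 0.0)
    return h / peak


def simulate_epsc_train(tm: TrainParams, stim_times_ms, fs_khz: float = 20.0,
                        seed: int | None = None, v_hold_mV: float = -70.0,
                        post_ms: float = 50.0, artifact: bool = True):
    """Simulate a stimulus-evoked EPSC train at a CA3 pyramidal cell.

    Returns (trace, true_amplitudes).  EPSCs are inward (negative); the
    trace includes a brief biphasic stimulus artifact in the first 0.6 ms
    after each stimulus (the artifact window the extraction step blanks).
    Amplitudes are generated at -70 mV; for other holding potentials they
    scale linearly with driving force assuming a 0 mV reversal.
    """
    stim = np.asarray(list(stim_times_ms), dtype=float)
    if np.any(np.diff(stim) <= 0):
        raise InvalidParameterError("stimulus times must be strictly increasing")
    amps = tm_amplitudes(tm, stim) * (v_hold_mV / -70.0)
    total = stim[-1] + post_ms
    n = int(round(total * fs_khz))
    t = np.arange(n) / fs_khz
    trace = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for tk, a in zip(stim, amps):
        trace -= a * _epsc_kernel(t - tk, tm.tau_rise_ms, tm.tau_decay_ms)
    if artifact:
        for tk in stim:
            sl = slice(int(round(tk * fs_khz)),
                       min(int(round((tk + 0.6) * fs_khz)), n))
            half = (sl.stop - sl.start) // 2
            trace[sl.start:sl.start + half] += 2000.0
            trace[sl.start + half:sl.stop] -= 2000.0
            valid[sl] = False
    if tm.noise_sd_pA > 0:
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, tm.noise_sd_pA, size=n)
    return CurrentTrace(trace, fs_khz, 0.0, valid), amps
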