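"""Fits for exocytosis kinetics and Ca2+-current properties.

Covers: peak-current and total-charge measurement on traces, the
single-exponential readily-releasable-pool depletion fit
dCm(T) = C_inf (1 - exp(-T/tau)), the activation-time-constant fit,
IV-curve construction with an optional Boltzmann x driving-force fit, and
the Hill fit dCm = C_max I^n / (I^n + K^n) with the cooperativity n fixed
(n = 3 by default).

All fits are unweighted least squares (optional 1/SEM^2 weights), with
time constants parameterized on a log scale to keep them positive, and
multi-start initial values to avoid local minima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitError, InvalidParameterError, WindowError
from .params import CaChannelParams
from .synth_ephys import CurrentTrace

__all__ = [
    "peak_current",
    "total_ca_charge",
    "fit_depletion",
    "fit_activation_tau",
    "build_iv",
    "fit_boltzmann_iv",
    "fit_hill",
    "DepletionFit",
    "HillFit",
]


def _baseline(trace: CurrentTrace, pulse_start_ms: float,
              base_ms: float = 2.0) -> float:
    try:
        sl = trace.window_slice(max(trace.t0_ms, pulse_start_ms - base_ms),
                                pulse_start_ms)
    except WindowError:
        return 0.0
    return float(trace.i_pA[sl].mean())


def peak_current(trace: CurrentTrace, window_ms: tuple[float, float],
                 signed: bool = False) -> float:
    """Extremal inward current in the window after baseline subtraction.

    Baseline is the mean over the 2 ms preceding the window (0 if the
    trace starts at the window).  Returns the magnitude (pA) by default,
    or the signed value with ``signed=True``."""
    t0, t1 = window_ms
    sl = trace.window_slice(t0, t1)
    base = _baseline(trace, t0)
    seg = trace.i_pA[sl] - base
    ext = seg[np.argmax(np.abs(seg))]
    return float(ext) if signed else float(abs(ext))


def total_ca_charge(trace: CurrentTrace, window_ms: tuple[float, float]
                    ) -> float:
    """Time integral of the (baseline-subtracted) current over the window,
    trapezoid rule, returned as a magnitude in pC (pA*ms = fC)."""
    t0, t1 = window_ms
    sl = trace.window_slice(t0, t1)
    base = _baseline(trace, t0)
    seg = trace.i_pA[sl] - base
    q_fC = np.trapezoid(seg, dx=1.0 / trace.fs_khz)
    return float(abs(q_fC)) / 1000.0


@dataclass(frozen=True)
class DepletionFit:
    c_inf_fF: float
    tau_ms: float
    residual_rms_fF: float
    cov: np.ndarray       # covariance of (C_inf, tau)

    def predict(self, t_ms):
        t = np.asarray(t_ms, float)
        return self.c_inf_fF * (1.0 - np.exp(-t / self.tau_ms))


def _ls_multistart(resid, starts, **kw):
    best, fallback = None, None
    for x0 in starts:
        try:
            sol = least_squares(resid, x0, xtol=1e-12, ftol=1e-12,
                                gtol=1e-12, max_nfev=2000, **kw)
        except Exception:
            continue
        if np.isfinite(sol.cost):
            if fallback is None or sol.cost < fallback.cost:
                fallback = sol
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    # a solver that stopped on max_nfev at a finite optimum is still a
    # usable (flagged-by-covariance) fit; only total failure raises
    best = best if best is not None else fallback
    if best is None:
        raise FitError("least-squares fit failed from every start")
    return best


def _cov_from_solution(sol, n_obs):
    """Gauss-Newton covariance: s^2 (J^T J)^-1 in the fit parameterization."""
    _, s, vt = np.linalg.svd(sol.jac, full_matrices=False)
    threshold = np.finfo(float).eps * max(sol.jac.shape) * s[0]
    s = s[s > threshold]
    vt = vt[: s.size]
    dof = max(n_obs - sol.x.size, 1)
    s2 = 2.0 * sol.cost / dof
    return (vt.T / s**2) @ vt * s2


def fit_depletion(data: pd.DataFrame, weights=None) -> DepletionFit:
    """Fit dCm(T) = C_inf (1 - exp(-T/tau)) to a duration-response table.

    ``data`` needs columns duration_ms and dcm_fF with at least three
    distinct durations.  Internally parameterized as (C_inf, log tau) with
    multi-start over tau in {10, 50, 200} ms.  The reported covariance is
    transformed back to (C_inf, tau).
    """
    t = np.asarray(data["duration_ms"], float)
    y = np.asarray(data["dcm_fF"], float)
    if np.unique(t).size < 3:
        raise InvalidParameterError("need >= 3 distinct durations")
    w = np.ones_like(y) if weights is None else np.sqrt(np.asarray(weights))

    def resid(x):
        c, ltau = x
        return w * (c * (1.0 - np.exp(-t / np.exp(ltau))) - y)

    c0 = max(y.max(), 1.0)
    sol = _ls_multistart(resid, [(c0, np.log(s)) for s in (10.0, 50.0, 200.0)])
    c_inf, tau = sol.x[0], float(np.exp(sol.x[1]))
    cov_l = _cov_from_solution(sol, y.size)
    jac = np.array([[1.0, 0.0], [0.0, tau]])   # d(C,tau)/d(C,log tau)
    cov = jac @ cov_l @ jac.T
    rms = float(np.sqrt(np.mean(resid(sol.x) ** 2)))
    if c_inf <= 0:
        raise FitError("depletion fit converged to non-positive pool size")
    return DepletionFit(float(c_inf), tau, rms, cov)


def fit_activation_tau(trace: CurrentTrace, window_ms: tuple[float, float],
                       min_tau_ms: float | None = None) -> float:
    """Single-exponential activation fit I(t) = I_ss (1 - exp(-(t-t0)/tau))
    on the current magnitude inside the pulse window; returns tau (ms).

    ``min_tau_ms`` defaults to two sample intervals; a fitted tau below it
    (a step-like onset) raises FitError flagging the resolution limit."""
    t0, t1 = window_ms
    sl = trace.window_slice(t0, t1)
    t = trace.times()[sl] - t0
    y = np.abs(trace.i_pA[sl])
    if min_tau_ms is None:
        min_tau_ms = 2.0 / trace.fs_khz
    if y.max() <= 0:
        raise FitError("no current in window")

    def resid(x):
        i_ss, ltau = x
        return i_ss * (1.0 - np.exp(-t / np.exp(ltau))) - y

    sol = _ls_multistart(resid, [(y.max(), np.log(s))
                                 for s in (0.3, 1.0, 3.0)])
    tau = float(np.exp(sol.x[1]))
    if tau < min_tau_ms:
        raise FitError(
            f"activation tau {tau:.3g} ms below resolution ({min_tau_ms:.3g} ms)")
    return tau


def build_iv(traces: dict[float, CurrentTrace],
             window_ms: tuple[float, float]) -> pd.DataFrame:
    """Signed peak current per voltage level, ordered by V.

    ``traces`` maps step level (mV) -> trace; missing levels are simply
    absent rows (no interpolation).  Columns: v_mV, i_peak_pA (signed).
    """
    rows = []
    for v in sorted(traces):
        rows.append({"v_mV": float(v),
                     "i_peak_pA": peak_current(traces[v], window_ms,
                                               signed=True)})
    return pd.DataFrame(rows)


def fit_boltzmann_iv(iv: pd.DataFrame,
                     p0: tuple = (1.0, -5.0, 7.0, 65.0)):
    """Fit I(V) = g (V - E_rev) / (1 + exp(-(V - V_half)/k)) to an IV table.

    Returns dict with g_max_nS, v_half_mV, k_slope_mV, e_rev_mV."""
    v = np.asarray(iv["v_mV"], float)
    i = np.asarray(iv["i_peak_pA"], float)

    def resid(x):
        g, vh, k, e = x
        return g * (v - e) / (1.0 + np.exp(-(v - vh) / k)) - i

    sol = _ls_multistart(resid, [p0, (0.5, -20.0, 5.0, 50.0),
                                 (2.0, 0.0, 10.0, 80.0)])
    g, vh, k, e = sol.x
    if k <= 0 or g <= 0:
        raise FitError("IV fit converged to non-physical gating parameters")
    return {"g_max_nS": float(g), "v_half_mV": float(vh),
            "k_slope_mV": float(k), "e_rev_mV": float(e)}


@dataclass(frozen=True)
class HillFit:
    c_max_fF: float
    k_pA: float
    n: float
    residual_rms_fF: float
    c_max_fixed: bool

    def predict(self, i_pA):
        i = np.asarray(i_pA, float)
        return self.c_max_fF * i**self.n / (i**self.n + self.k_pA**self.n)


def fit_hill(i_pA, dcm_fF, n: float = 3.0,
             c_max_fixed: float | None = None) -> HillFit:
    """Fit dCm = C_max I^n / (I^n + K^n) with the Hill coefficient fixed.

    C_max is free by default; pass ``c_max_fixed`` to constrain it (e.g.
    to a plateau measured independently).  Requires >= 3 points (2 when
    C_max is fixed) and at least two distinct currents.
    """
    i = np.asarray(list(i_pA), float)
    y = np.asarray(list(dcm_fF), float)
    min_pts = 2 if c_max_fixed is not None else 3
    if i.size < min_pts:
        raise InvalidParameterError(f"need >= {min_pts} points")
    if np.any(i <= 0):
        raise InvalidParameterError("currents must be positive magnitudes")
    if np.unique(i).size < 2:
        raise FitError("all currents identical: K is unidentifiable")

    k_starts = [np.median(i), i.min(), i.max()]
    if c_max_fixed is not None:
        def resid(x):
            k = np.exp(x[0])
            return c_max_fixed * i**n / (i**n + k**n) - y
        sol = _ls_multistart(resid, [(np.log(k),) for k in k_starts])
        c_max, k = float(c_max_fixed), float(np.exp(sol.x[0]))
    else:
        def resid(x):
            c, lk = x
            k = np.exp(lk)
            return c * i**n / (i**n + k**n) - y
        c0 = max(y.max(), 1.0)
        sol = _ls_multistart(resid, [(c0, np.log(k)) for k in k_starts])
        c_max, k = float(sol.x[0]), float(np.exp(sol.x[1]))
    if c_max <= 0:
        raise FitError("Hill fit converged to non-positive C_max")
    rms = float(np.sqrt(np.mean(resid(sol.x) ** 2)))
    return HillFit(c_max, k, float(n), rms, c_max_fixed is not None)
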