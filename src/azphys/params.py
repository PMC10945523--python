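"""Parameter containers for the synthetic generators and recording protocols.

Unit conventions used throughout the package
--------------------------------------------
time        ms          voltage      mV
current     pA          conductance  nS
capacitance fF at API boundaries (pF internally, so that pA = nS * mV
            and pF * mV/ms = pA hold without conversion factors)
frequency   Hz in protocol definitions, kHz for sampling rates
length      nm (pixel size in nm/px)

Inward membrane currents are stored as negative numbers; fitted or
reported amplitudes are magnitudes (documented per function).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .errors import InvalidParameterError


@dataclass(frozen=True)
class CircuitParams:
    """Three-element patch-clamp circuit: series (access) conductance Gs
    feeding the parallel combination of membrane conductance Gm and
    membrane capacitance Cm.

    Cm_step models the capacitance added by exocytosis at the end of a
    depolarizing pulse.  noise_sd is additive Gaussian current noise.
    """

    cm_baseline_fF: float = 1000.0
    gm_nS: float = 1.0
    gs_nS: float = 20.0   # 50 MOhm access resistance
    cm_step_fF: float = 0.0
    noise_sd_pA: float = 0.0

    def __post_init__(self) -> None:
        if self.cm_baseline_fF <= 0:
            raise InvalidParameterError("Cm_baseline must be > 0")
        if self.gm_nS <= 0 or self.gs_nS <= 0:
            raise InvalidParameterError("conductances must be > 0")
        if self.cm_step_fF < 0:
            raise InvalidParameterError("Cm_step must be >= 0")
        if self.noise_sd_pA < 0:
            raise InvalidParameterError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CaChannelParams:
    """Boltzmann-gated, exponentially activating Ca2+ conductance.

    Defaults reproduce a P/Q-type-like current at a mossy-fiber bouton:
    activation threshold near -20 mV, peak inward current near +10 mV
    (~44 pA with the default g_max), activation tau 1.4 ms.  ko_scale
    multiplies g_max for the knockout condition (0.7 = 30% reduction).
    """

    g_max_nS: float = 0.894
    v_half_mV: float = -5.0
    k_slope_mV: float = 7.0
    e_rev_mV: float = 65.0
    tau_act_ms: float = 1.4
    ko_scale: float = 0.7

    def __post_init__(self) -> None:
        if self.k_slope_mV <= 0:
            raise InvalidParameterError("k_slope must be > 0")
        if not (0 < self.ko_scale <= 1):
            raise InvalidParameterError("ko_scale must be in (0, 1]")
        if self.tau_act_ms <= 0:
            raise InvalidParameterError("tau_act must be > 0")
        if self.g_max_nS <= 0:
            raise InvalidParameterError("g_max must be > 0")

    def m_inf(self, v_mV: float):
        import numpy as np

        return 1.0 / (1.0 + np.exp(-(np.asarray(v_mV, float) - self.v_half_mV)
                                   / self.k_slope_mV))


@dataclass(frozen=True)
class ReleaseParams:
    """Readily-releasable-pool depletion with Hill-type current dependence.

    The pool (rrp_size_fF of membrane) empties with effective time
    constant tau_eff = tau_release / h(I), h(I) = I^n / (I^n + K^n), so
    smaller Ca2+ currents slow release.  With the defaults the effective
    constant at the wild-type peak current (44 pA) is ~59 ms.
    """

    rrp_size_fF: float = 52.0
    tau_release_ms: float = 45.0
    hill_K_pA: float = 30.0
    hill_n: float = 3.0

    def __post_init__(self) -> None:
        if self.rrp_size_fF <= 0:
            raise InvalidParameterError("rrp_size must be > 0")
        if self.tau_release_ms <= 0:
            raise InvalidParameterError("tau_release must be > 0")
        if self.hill_K_pA < 0:
            raise InvalidParameterError("hill_K must be >= 0")

    def hill_factor(self, i_peak_pA: float) -> float:
        i = abs(float(i_peak_pA))
        if i == 0:
            return 0.0
        n = self.hill_n
        return i**n / (i**n + self.hill_K_pA**n)

    def tau_eff_ms(self, i_peak_pA: float) -> float:
        h = self.hill_factor(i_peak_pA)
        if h == 0:
            return float("inf")
        return self.tau_release_ms / h


@dataclass(frozen=True)
class TrainParams:
    """Tsodyks-Markram-style short-term plasticity generator for EPSC
    trains.  Facilitation variable u increments by U at each stimulus and
    decays with tau_facil; resources R deplete by the released fraction
    and recover with tau_rec.  Amplitude_k = a_max * u_k * R_k.

    Defaults give ~2-fold paired-pulse facilitation at 20 ms for the
    wild-type utilisation (U = 0.05); U = 0.01 yields the strongly
    facilitating (~10-fold across a 50 Hz train) knockout phenotype.
    """

    a_max_pA: float = 18900.0
    u_increment: float = 0.05
    tau_facil_ms: float = 400.0
    tau_rec_ms: float = 2000.0
    tau_rise_ms: float = 0.3
    tau_decay_ms: float = 4.0
    noise_sd_pA: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.u_increment <= 1):
            raise InvalidParameterError("u_increment must be in (0, 1]")
        for name in ("a_max_pA", "tau_facil_ms", "tau_rec_ms",
                     "tau_rise_ms", "tau_decay_ms"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.tau_decay_ms <= self.tau_rise_ms:
            raise InvalidParameterError("tau_decay must exceed tau_rise")


@dataclass(frozen=True)
class VoltageProtocol:
    """Sine + DC stimulus: a sine (default 30 mV, 1000 Hz) superimposed
    on the holding potential (-80 mV), optionally interrupted by a square
    depolarizing pulse.  step_table describes IV-style step families."""

    v_hold_mV: float = -80.0
    sine_amp_mV: float = 30.0
    sine_freq_hz: float = 1000.0
    pulse_start_ms: float = 0.0
    pulse_dur_ms: float = 0.0
    pulse_level_mV: float = 10.0
    step_table: tuple = ()   # ((level_mV, duration_ms), ...)

    def __post_init__(self) -> None:
        if self.sine_freq_hz <= 0:
            raise InvalidParameterError("sine_freq must be > 0")
        if self.pulse_dur_ms < 0:
            raise InvalidParameterError("pulse_dur must be >= 0")
        for lev, _dur in self.step_table:
            if abs(lev) > 100:
                raise InvalidParameterError("step levels must be within +-100 mV")

    @property
    def omega(self) -> float:
        """Angular frequency in rad/ms."""
        import math

        return 2.0 * math.pi * self.sine_freq_hz / 1000.0

    @property
    def pulse_end_ms(self) -> float:
        return self.pulse_start_ms + self.pulse_dur_ms


@dataclass(frozen=True)
class ImageSceneParams:
    """Parameters of a synthetic four-channel STED/confocal field.

    Stated-world values: 10 nm pixels, ~2-3 Cav clusters per AZ (zero-
    truncated Poisson means 2.5 WT / 2.3 KO), Cav-Munc13-1 centroid
    separation 61 nm, KO per-cluster Cav intensity scale 0.78.  Geometry
    and photon-budget defaults (terminal area, AZ area, cluster photon
    scales, backgrounds, PSF widths) are conventional choices for
    mossy-fiber imagery and are fully configurable.
    """

    field_px: int = 1024
    pixel_nm: float = 10.0
    n_terminals: int = 3
    n_small_terminals: int = 3
    terminal_area_um2: float = 2.0
    small_terminal_area_um2: float = 0.3
    az_per_terminal_mean: float = 6.0
    az_area_um2: float = 0.07
    az_area_sigma_log: float = 0.25
    munc_clusters_per_az_mean: float = 2.5
    cav_clusters_per_az_mean_wt: float = 2.5
    cav_clusters_per_az_mean_ko: float = 2.3
    cluster_intensity: float = 6000.0       # mean Cav per-cluster integral (counts)
    munc_cluster_intensity: float = 1400.0
    intensity_gamma_shape: float = 4.0
    ko_intensity_scale: float = 0.78
    cav_munc_distance_nm: float = 61.0
    cav_munc_jitter_nm: float = 10.0
    cluster_sigma_nm: float = 15.0          # intrinsic Cav cluster extent (Gaussian sigma)
    munc_cluster_sigma_nm: float = 15.0     # intrinsic Munc13-1 cluster extent
    cluster_sigma_scales: bool = True       # sigma ~ sqrt(integral): brighter = bigger
    munc_pedestal: float = 25.0             # diffuse Munc13-1 AZ fill (counts/px)
    pedestal_margin_nm: float = 20.0        # pedestal extends past the nominal AZ edge
    pedestal_taper_nm: float = 30.0         # soft pedestal edge (Gaussian sigma)
    psf_fwhm_sted_nm: float = 50.0
    psf_fwhm_confocal_nm: float = 250.0
    vglut_intensity: float = 60.0           # counts/px inside terminals
    psd_intensity: float = 40000.0          # PSD-95 per-synapse integral
    background_sted: float = 1.0
    background_confocal: float = 5.0
    noise_model: str = "both"               # poisson | gaussian | both | none
    gaussian_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.pixel_nm <= 0:
            raise InvalidParameterError("pixel_nm must be > 0")
        if not (0 < self.ko_intensity_scale <= 1):
            raise InvalidParameterError("ko_intensity_scale must be in (0, 1]")
        for name in ("n_terminals", "n_small_terminals"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.noise_model not in ("poisson", "gaussian", "both", "none"):
            raise InvalidParameterError("noise_model must be poisson|gaussian|both|none")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PipelineParams:
    """Tunable parameters of the STED quantification pipeline.

    The AZ-mask step (unsharp mask + Otsu binarization) and the analysis
    gates (VGLUT1/PSD-95 colocalization within d_coloc, exclusion of
    small VGLUT1-positive terminals) expose every threshold because none
    is dictated by physics.  The deconvolution kernel "radius" of 40 nm
    is interpreted as the Gaussian sigma (see docs/methods.md).
    """

    unsharp_sigma_px: float = 5.0
    unsharp_amount: float = 1.0
    min_az_area_nm2: float = 10000.0
    cluster_unsharp_sigma_px: float = 3.0
    cluster_unsharp_amount: float = 8.0
    min_cluster_area_nm2: float = 400.0
    d_coloc_nm: float = 100.0
    terminal_min_area_um2: float = 1.0
    background_guard_nm: float = 100.0
    psf_kernel_radius_nm: float = 40.0   # Gaussian "radius"; sigma = radius/2
    rl_post_smooth_px: float = 1.0       # regularizing smooth after RL updates
    rl_iterations: int = 20
    confocal_smooth_px: float = 2.0

    def to_dict(self) -> dict:
        return asdict(self)
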