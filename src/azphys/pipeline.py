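"""End-to-end demo orchestration: synthesize -> analyze -> compare.

``run_demo`` reproduces the study's analysis shapes on synthetic data:

* presynaptic capacitance: sine+DC trace, lock-in estimation, jump
  measurement; duration-response datasets per simulated terminal with
  depletion and Hill fits; peak-current WT/KO comparison (t test).
* EPSC trains at 50 Hz: amplitude extraction, paired-pulse ratios,
  group time courses, permutation curve comparison.
* imaging: rendered WT/KO fields (one per simulated animal), the full
  STED quantification pipeline, per-animal aggregation, exact
  Mann-Whitney comparisons of intensity, cluster count and NND.

Everything is driven by one RunConfig (seed + parameter blocks); every
output table is regenerable from the resolved config and seed alone.
Tables are the contract; no figures are produced.
"""

from __future__ import annotations

import dataclasses
import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .capacitance import estimate_cm_timeseries, measure_cm_jump
from .epsc import extract_epsc_amplitudes, summarize_train
from .errors import InvalidParameterError
from .exo_models import fit_depletion, fit_hill
from .params import (CaChannelParams, CircuitParams, ImageSceneParams,
                     PipelineParams, ReleaseParams, TrainParams,
                     VoltageProtocol)
from .stats import exact_mann_whitney, permutation_curve_test, t_test
from .sted_quant import aggregate_per_animal, quantify_field
from .synth_ephys import (simulate_depletion_dataset, simulate_epsc_train,
                          simulate_sine_dc_trace)
from .synth_imaging import render_sted_field

__all__ = ["RunConfig", "run_demo", "load_config"]

# a compact scene that keeps the demo fast; the library default
# (ImageSceneParams) is the full 1024-px field
DEMO_SCENE = dict(field_px=512, n_terminals=1, n_small_terminals=1,
                  az_per_terminal_mean=8.0)


@dataclass
class RunConfig:
    """Resolved configuration of a demo run.

    Parameter blocks are plain dicts of overrides applied to the
    corresponding dataclasses; unknown keys are rejected at load time.
    ``ko_effects=False`` sets every KO effect size to its WT value (the
    null world used for calibration)."""

    seed: int = 0
    n_cells: int = 6
    n_animals: int = 4
    fields_per_animal: int = 1
    durations_ms: tuple = (5.0, 10.0, 20.0, 50.0, 100.0)
    dcm_noise_sd_fF: float = 3.0
    current_noise_sd_pA: float = 2.0
    n_train_stim: int = 25
    train_freq_hz: float = 50.0
    ko_effects: bool = True
    hill_ca_scales: tuple = (0.45, 0.6, 0.8, 1.0, 1.25)
    scene: dict = field(default_factory=lambda: dict(DEMO_SCENE))
    circuit: dict = field(default_factory=dict)
    channel: dict = field(default_factory=dict)
    release: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    pipeline: dict = field(default_factory=dict)

    _BLOCKS = {"scene": ImageSceneParams, "circuit": CircuitParams,
               "channel": CaChannelParams, "release": ReleaseParams,
               "train": TrainParams, "pipeline": PipelineParams}

    def __post_init__(self):
        for name, cls in self._BLOCKS.items():
            block = getattr(self, name)
            allowed = {f.name for f in dataclasses.fields(cls)}
            unknown = set(block) - allowed
            if unknown:
                raise InvalidParameterError(
                    f"unknown keys in '{name}' block: {sorted(unknown)}")

    def build(self, name: str, **extra):
        cls = self._BLOCKS[name]
        return cls(**{**getattr(self, name), **extra})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["durations_ms"] = list(self.durations_ms)
        d["hill_ca_scales"] = list(self.hill_ca_scales)
        return d


def load_config(path) -> RunConfig:
    """Load a YAML config, rejecting unknown top-level or block keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    allowed = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
    for key in ("durations_ms", "hill_ca_scales"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_capacitance(cfg: RunConfig, seed: int) -> dict:
    """One sine+DC recording per genotype with a pool-sized jump."""
    release = cfg.build("release")
    out = {}
    for g, s in zip(("WT", "KO"), _child_seeds(seed, 2)):
        circ = cfg.build("circuit", cm_step_fF=release.rrp_size_fF,
                         noise_sd_pA=2.0)
        proto = VoltageProtocol(pulse_start_ms=100.0, pulse_dur_ms=100.0)
        trace = simulate_sine_dc_trace(circ, proto, fs_khz=50.0, seed=s)
        est = estimate_cm_timeseries(trace, proto)
        jump = measure_cm_jump(est, proto.pulse_start_ms, proto.pulse_end_ms)
        out[g] = {"delta_cm_fF": jump.delta_cm_fF,
                  "baseline_sd_fF": jump.baseline_sd_fF,
                  "true_step_fF": circ.cm_step_fF}
    return out


def _stage_depletion(cfg: RunConfig, seed: int):
    chan = cfg.build("channel")
    release = cfg.build("release")
    seeds = _child_seeds(seed, 2 * cfg.n_cells)
    tables, fits = [], []
    for gi, g in enumerate(("WT", "KO")):
        cond = g if cfg.ko_effects else "WT"
        cell_tabs = []
        for ci in range(cfg.n_cells):
            df = simulate_depletion_dataset(
                release, chan, cfg.durations_ms,
                seed=seeds[gi * cfg.n_cells + ci], condition=cond,
                noise_sd_fF=cfg.dcm_noise_sd_fF,
                current_noise_sd_pA=cfg.current_noise_sd_pA)
            df["condition"] = g
            df["cell"] = f"{g}{ci}"
            cell_tabs.append(df)
        tab = pd.concat(cell_tabs, ignore_index=True)
        tables.append(tab)
        fit = fit_depletion(tab)
        fits.append({"genotype": g, "c_inf_fF": fit.c_inf_fF,
                     "tau_ms": fit.tau_ms,
                     "residual_rms_fF": fit.residual_rms_fF})
    data = pd.concat(tables, ignore_index=True)
    t_max = max(cfg.durations_ms)
    imax = data["duration_ms"] == t_max
    wt = data[imax & (data["condition"] == "WT")]["i_peak_pA"]
    ko = data[imax & (data["condition"] == "KO")]["i_peak_pA"]
    t, df_, p = t_test(wt, ko)
    stats = {"i_peak_t": t, "i_peak_df": df_, "i_peak_p": p,
             "unit": "terminal"}
    return data, pd.DataFrame(fits), stats


def _stage_hill(cfg: RunConfig, seed: int):
    """dCm at the longest pulse against peak current, current titrated by
    external-Ca scale factors; Hill fit with n = 3."""
    chan = cfg.build("channel")
    release = cfg.build("release")
    rng = np.random.default_rng(seed)
    t_max = max(cfg.durations_ms)
    i_base = abs(chan.g_max_nS * float(chan.m_inf(10.0))
                 * (10.0 - chan.e_rev_mV))
    rows = []
    for s in cfg.hill_ca_scales:
        i_pk = i_base * s
        tau_eff = release.tau_eff_ms(i_pk)
        dcm = release.rrp_size_fF * (1 - np.exp(-t_max / tau_eff))
        rows.append({"ca_scale": s, "i_peak_pA": i_pk,
                     "dcm_fF": dcm + rng.normal(0, cfg.dcm_noise_sd_fF)})
    tab = pd.DataFrame(rows)
    fit = fit_hill(tab["i_peak_pA"], tab["dcm_fF"], n=3.0)
    return tab, {"c_max_fF": fit.c_max_fF, "k_pA": fit.k_pA, "n": fit.n,
                 "residual_rms_fF": fit.residual_rms_fF}


def _stage_epsc(cfg: RunConfig, seed: int):
    stim = np.arange(cfg.n_train_stim) * 1000.0 / cfg.train_freq_hz + 10.0
    seeds = _child_seeds(seed, 2 * cfg.n_cells)
    trains = {"WT": [], "KO": []}
    for gi, g in enumerate(("WT", "KO")):
        u = cfg.build("train").u_increment
        if g == "KO" and cfg.ko_effects:
            u = u / 10.0   # low release probability: strong train facilitation
        tm = cfg.build("train", u_increment=u, noise_sd_pA=20.0)
        for ci in range(cfg.n_cells):
            trace, _ = simulate_epsc_train(
                tm, stim, seed=seeds[gi * cfg.n_cells + ci])
            train = extract_epsc_amplitudes(trace, stim, cell_id=f"{g}{ci}",
                                            condition=g)
            trains[g].append(train)
    summaries = {g: summarize_train(ts) for g, ts in trains.items()}
    curves_wt = np.vstack([t.norm_amps for t in trains["WT"]])
    curves_ko = np.vstack([t.norm_amps for t in trains["KO"]])
    stat, p = permutation_curve_test(curves_wt, curves_ko, n_perm=999,
                                     seed=_child_seeds(seed, 3)[2])
    ppr = pd.DataFrame(
        [{"genotype": g, "cell": t.cell_id, "ppr": t.ppr}
         for g in trains for t in trains[g]])
    return summaries, ppr, {"train_perm_stat": stat, "train_perm_p": p,
                            "unit": "cell"}


def _stage_imaging(cfg: RunConfig, seed: int):
    pipe = cfg.build("pipeline")
    n_fields = cfg.n_animals * cfg.fields_per_animal
    seeds = _child_seeds(seed, 2 * n_fields)
    records = []
    for gi, g in enumerate(("WT", "KO")):
        scene = cfg.build("scene")
        if g == "KO" and not cfg.ko_effects:
            scene = cfg.build(
                "scene", ko_intensity_scale=1.0,
                cav_clusters_per_az_mean_ko=scene.cav_clusters_per_az_mean_wt)
        k = 0
        for a in range(cfg.n_animals):
            for f in range(cfg.fields_per_animal):
                imgset, _truth = render_sted_field(
                    scene, condition=g, seed=seeds[gi * n_fields + k],
                    field_id=f"{g}_a{a}_f{f}", animal_id=f"{g}_a{a}")
                k += 1
                records.append(quantify_field(imgset, pipe))
    az_records = pd.concat(records, ignore_index=True)
    per_animal = aggregate_per_animal(az_records)
    stats = {"unit": "animal"}
    for metric in ("cav_intensity", "n_cav_clusters", "mean_nnd_nm"):
        wt = per_animal.loc[per_animal["genotype"] == "WT", metric].dropna()
        ko = per_animal.loc[per_animal["genotype"] == "KO", metric].dropna()
        u, p = exact_mann_whitney(wt, ko)
        stats[f"{metric}_U"] = u
        stats[f"{metric}_p"] = p
    return az_records, per_animal, stats


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_demo(cfg: RunConfig, out_dir=None) -> dict:
    """Run every stage; optionally write the result bundle under out_dir.

    Returns a dict with the per-stage tables and statistics.  Outputs are
    deterministic functions of (config, seed); rerunning with the same
    resolved config reproduces every table byte for byte.
    """
    t_start = time.time()
    stage_seeds = _child_seeds(cfg.seed, 5)
    result, timings = {}, {}

    def run_stage(name, fn, *args):
        t0 = time.time()
        try:
            out = fn(cfg, *args)
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        timings[name] = time.time() - t0
        return out

    result["capacitance"] = run_stage("capacitance", _stage_capacitance,
                                      stage_seeds[0])
    dep_data, dep_fits, dep_stats = run_stage("depletion", _stage_depletion,
                                              stage_seeds[1])
    result["depletion"] = {"data": dep_data, "fits": dep_fits,
                           "stats": dep_stats}
    hill_tab, hill_fit = run_stage("hill", _stage_hill, stage_seeds[2])
    result["hill"] = {"data": hill_tab, "fit": hill_fit}
    epsc_summ, ppr, epsc_stats = run_stage("epsc", _stage_epsc,
                                           stage_seeds[3])
    result["epsc"] = {"summaries": epsc_summ, "ppr": ppr,
                      "stats": epsc_stats}
    az_records, per_animal, img_stats = run_stage("imaging", _stage_imaging,
                                                  stage_seeds[4])
    result["imaging"] = {"az_records": az_records, "per_animal": per_animal,
                         "stats": img_stats}
    result["stats"] = {"depletion": dep_stats, "epsc": epsc_stats,
                       "imaging": img_stats}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "resolved_config.yaml", "w") as fh:
            yaml.safe_dump(cfg.to_dict(), fh)
        dep_data.to_csv(out / "depletion_data.csv", index=False)
        dep_fits.to_csv(out / "depletion_fits.csv", index=False)
        hill_tab.to_csv(out / "hill_data.csv", index=False)
        for g, s in epsc_summ.items():
            s.to_csv(out / f"epsc_train_{g}.csv", index=False)
        ppr.to_csv(out / "epsc_ppr.csv", index=False)
        az_records.to_csv(out / "az_records.csv", index=False)
        per_animal.to_csv(out / "per_animal.csv", index=False)
        with open(out / "stats.json", "w") as fh:
            json.dump({"capacitance": result["capacitance"],
                       "hill_fit": hill_fit, **result["stats"]}, fh,
                      indent=1)
        with open(out / "run_log.json", "w") as fh:
            json.dump({"seed": cfg.seed, "azphys_version": __version__,
                       "python": platform.python_version(),
                       "numpy": np.__version__,
                       "timings_s": {k: round(v, 2)
                                     for k, v in timings.items()},
                       "total_s": round(time.time() - t_start, 2)}, fh,
                      indent=1)
    return result
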