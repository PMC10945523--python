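"""Simulate the raw recordings every later step consumes.

Writes example sine+DC capacitance traces (with a pool-sized capacitance
jump) and a family of Ca2+-current step responses for both genotypes to
results/01_recordings/, as NPZ traces with JSON protocol sidecars.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from azphys.io import save_trace
from azphys.params import CaChannelParams, CircuitParams, VoltageProtocol
from azphys.synth_ephys import simulate_ca_current, simulate_sine_dc_trace

OUT = Path(__file__).resolve().parents[1] / "results" / "01_recordings"


def main(seed: int) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    proto = VoltageProtocol(pulse_start_ms=100.0, pulse_dur_ms=100.0)
    for g in ("WT", "KO"):
        circ = CircuitParams(cm_step_fF=52.0 if g == "WT" else 41.0,
                             noise_sd_pA=2.0)
        trace = simulate_sine_dc_trace(circ, proto, fs_khz=50.0,
                                       seed=int(rng.integers(2**31 - 1)))
        save_trace(trace, OUT / f"sine_dc_{g}.npz", proto)
        print(f"{g}: sine+DC trace with a {circ.cm_step_fF:.0f} fF "
              f"capacitance step -> sine_dc_{g}.npz")

    chan = CaChannelParams()
    levels = list(np.arange(-80.0, 71.0, 10.0))
    for g in ("WT", "KO"):
        for v in levels:
            tr = simulate_ca_current(chan, v, 5.0, fs_khz=50.0,
                                     condition=g,
                                     seed=int(rng.integers(2**31 - 1)),
                                     noise_sd_pA=1.0)
            save_trace(tr, OUT / f"ica_{g}_{int(v):+d}mV.npz")
    with open(OUT / "iv_protocol.json", "w") as fh:
        json.dump({"levels_mV": levels, "duration_ms": 5.0,
                   "interval_s": 2.0}, fh, indent=1)
    print(f"IV families ({len(levels)} levels x 2 genotypes) -> {OUT}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(ap.parse_args().seed)
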