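#!/usr/bin/env python
"""Multiphase decomposition of constant-force binding traces.

Decomposes synthetic traces of the three observed regimes — triphasic
(compaction then two elongations, moderate force), biphasic elongation
(low force) and monophasic compaction (high force / noncooperative) — and
tabulates recovered vs generating parameters.  Writes
results/binding_phases.csv.
"""
import pathlib

import numpy as np
import pandas as pd

from gp32filament.kinetics import decompose_binding_trace
from gp32filament.synthetic import GeneratorSpec, gen_binding_trace

RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)

REGIMES = {
    # name: amplitudes (nm), rates (s^-1), duration (s), force (pN)
    "triphasic_15pN": ((-250.0, 120.0, 150.0), (0.5, 0.05, 0.005), 1200.0, 15.0),
    "biphasic_5pN": ((0.0, 120.0, 150.0), (0.5, 0.05, 0.005), 1200.0, 5.0),
    "monophasic_30pN": ((-180.0, 0.0, 0.0), (0.25, 0.05, 0.005), 120.0, 30.0),
}


def main():
    rows = []
    for name, (amps, rates, duration, force) in REGIMES.items():
        tr = gen_binding_trace(2800.0, amps, rates, duration,
                               GeneratorSpec(seed=21, noise_sd=5.0, dt=0.25),
                               force=force, concentration=100.0)
        dec = decompose_binding_trace(tr)
        for i, (a_true, k_true) in enumerate(zip(amps, rates), start=1):
            if a_true == 0.0:
                continue
            a_fit = dec.amplitudes[i - 1]
            k_fit = dec.rates[i - 1]
            rows.append({
                "regime": name, "phase": i,
                "dx_true_nm": a_true, "dx_fit_nm": a_fit,
                "k_true_per_s": k_true, "k_fit_per_s": k_fit,
                "dx_err_pct": 100 * abs(a_fit - a_true) / abs(a_true),
                "k_err_pct": 100 * abs(k_fit - k_true) / k_true,
            })
        print(f"{name}: phases {dec.present_phases}, "
              f"x_eq {dec.x_eq:.0f} nm (true {2800 + sum(amps):.0f})")
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "binding_phases.csv", index=False)
    print("largest amplitude error: %.1f%%, largest rate error: %.1f%%"
          % (df["dx_err_pct"].max(), df["k_err_pct"].max()))


if __name__ == "__main__":
    main()
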