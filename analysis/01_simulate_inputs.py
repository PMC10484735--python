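#!/usr/bin/env python
"""Generate one example of every synthetic input class, with ground truth.

Emits the file formats the rest of the pipeline consumes (delimited text
plus JSON truth sidecars) under scratch/synthetic_inputs/.  All later
analysis scripts regenerate their inputs in memory from the same seeds, so
this step exists to document the on-disk interface, not to feed them.
"""
import pathlib

import numpy as np

from gp32filament import io as gio
from gp32filament.polymer import PolymerParams
from gp32filament.synthetic import (
    GeneratorSpec,
    gen_afm_image,
    gen_binding_trace,
    gen_chain_2d,
    gen_dissociation_trace,
    gen_fec,
    gen_rate_series,
)

OUT = pathlib.Path(__file__).resolve().parents[1] / "scratch" / "synthetic_inputs"
OUT.mkdir(parents=True, exist_ok=True)


def sidecar(obj_meta, path):
    gio.save_json(obj_meta, path.with_suffix(path.suffix + ".truth.json"))


def main():
    # noncooperative-truncate-like FEC (FJC, 0.510 nm/nt, p = 1.9 nm)
    fec = gen_fec(PolymerParams(0.510, 8100, 1.9), "FJC",
                  np.linspace(0.5, 10.0, 50),
                  GeneratorSpec(seed=1, noise_sd=1.0))
    gio.write_fec(fec, OUT / "fec_fjc.csv")
    sidecar(fec.meta, OUT / "fec_fjc.csv")

    # triphasic binding trace at 15 pN / 100 nM-like conditions
    tr = gen_binding_trace(2800.0, (-250.0, 120.0, 150.0),
                           (0.5, 0.05, 0.005), 1200.0,
                           GeneratorSpec(seed=2, noise_sd=5.0, dt=0.25),
                           force=15.0, concentration=100.0)
    gio.write_trace(tr, OUT / "trace_binding.csv")
    sidecar(tr.meta, OUT / "trace_binding.csv")

    # overcrowding-regime dissociation trace
    td = gen_dissociation_trace(-0.4, 150.0, 0.15, 300.0,
                                GeneratorSpec(seed=3, noise_sd=5.0, dt=0.25),
                                x0=2500.0, force=15.0)
    gio.write_trace(td, OUT / "trace_dissociation.csv")
    sidecar(td.meta, OUT / "trace_dissociation.csv")

    # deposited 2-D chains (5 molecules) and one height image
    chains = [gen_chain_2d(20.0, 2500.0,
                           GeneratorSpec(seed=100 + i, arc_step=5.0),
                           molecule_id=f"mol{i}") for i in range(5)]
    gio.write_backbone_traces(chains, OUT / "backbone_traces.csv")
    img = gen_afm_image(gen_chain_2d(20.0, 600.0,
                                     GeneratorSpec(seed=200, arc_step=2.0)),
                        GeneratorSpec(seed=201, noise_sd=0.01))
    gio.write_afm_image(img, OUT / "afm_image.txt")

    # compaction-rate-vs-concentration series (two-step law)
    series = gen_rate_series("two_step", {"k_b": 0.003, "k_c": 1.5},
                             np.array([5., 20., 50., 100., 300., 600., 1000.]),
                             GeneratorSpec(seed=4), rel_noise=0.05)
    gio.write_rate_series(series, OUT / "rates_two_step.csv")
    sidecar(series.meta, OUT / "rates_two_step.csv")

    print(f"wrote example inputs under {OUT}")


if __name__ == "__main__":
    main()
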