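"""Run configuration and end-to-end pipeline orchestration.

``run_pipeline`` executes any subset of the four analysis stages —
force–extension fits, kinetic trace decomposition, helix geometry sweep and
AFM persistence analysis — over lists of input files, collecting per-item
results and failures into a single deterministic JSON-serializable report.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from . import __version__
from . import afm as _afm
from . import helix as _helix
from . import io as _io
from . import kinetics as _kin
from . import polymer as _poly
from .constants import Constants

log = logging.getLogger("gp32filament")


@dataclass
class RunConfig:
    """Tunable parameters of a pipeline run (units: pN, nm, s, nM)."""

    kBT: float = 4.11
    fjc_f_max: float = 10.0
    wlc_f_max: float = 5.0
    bin_width: float = 1.0
    smooth_window_s: float = 1.0
    depth_sd: float = 3.0
    alpha: float = 0.05
    resample_step: float = 5.0
    tc_l_max: float = 100.0
    contact_radius: float = 4.0
    helix_R: float = 2.1
    helix_L: float = 0.56
    helix_h: float = 2.8
    helix_bss_ref: float = 7.0
    seed: int = 0
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("kBT", "fjc_f_max", "wlc_f_max", "bin_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def constants(self) -> Constants:
        return Constants(kBT=self.kBT)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage_fec(config: RunConfig, paths: Sequence) -> tuple[dict, dict]:
    results, errors = {}, {}
    for p in paths:
        try:
            fec = _io.read_fec(p)
            model = str(fec.meta.get("model", "FJC")).upper()
            if model == "WLC":
                fit = _poly.fit_wlc(fec, config.wlc_f_max,
                                    constants=config.constants)
            else:
                fit = _poly.fit_fjc(fec, config.fjc_f_max,
                                    constants=config.constants)
            results[str(p)] = _io.to_jsonable(fit)
        except Exception as exc:  # noqa: BLE001 - per-file failures are collected
            errors[str(p)] = f"{type(exc).__name__}: {exc}"
    return results, errors


def _stage_kinetics(config: RunConfig, paths: Sequence) -> tuple[dict, dict]:
    results, errors = {}, {}
    for p in paths:
        try:
            trace = _io.read_trace(p)
            if trace.phase_label == "dissociation":
                dec = _kin.decompose_dissociation_trace(trace)
            else:
                dec = _kin.decompose_binding_trace(
                    trace, config.smooth_window_s, config.depth_sd, config.alpha)
            results[str(p)] = _io.to_jsonable(dec)
        except Exception as exc:  # noqa: BLE001
            errors[str(p)] = f"{type(exc).__name__}: {exc}"
    return results, errors


def _stage_helix(config: RunConfig, paths: Sequence) -> tuple[dict, dict]:
    results, errors = {}, {}
    for p in paths:
        try:
            meta, df = _io._read_delim(p)
            table = dict(zip(df["concentration_nM"].astype(float),
                             df["L_prime_nm_per_nt"].astype(float)))
            sweep = _helix.helix_sweep(table, config.helix_R, config.helix_L,
                                       config.helix_h, config.helix_bss_ref)
            results[str(p)] = {str(c): _io.to_jsonable(hp)
                               for c, hp in sweep.items()}
        except Exception as exc:  # noqa: BLE001
            errors[str(p)] = f"{type(exc).__name__}: {exc}"
    return results, errors


def _stage_afm(config: RunConfig, paths: Sequence) -> tuple[dict, dict]:
    results, errors = {}, {}
    for p in paths:
        try:
            traces = _io.read_backbone_traces(p)
            segments = [_afm.longest_loopfree_segment(t, config.contact_radius)
                        for t in traces]
            profile = _afm.tangent_correlation(segments, config.resample_step)
            fit = _afm.fit_persistence_2d(profile, config.tc_l_max)
            results[str(p)] = {
                "n_molecules": len(traces),
                "contour_lengths_nm": [_afm.trace_contour_length(t)
                                       for t in traces],
                "persistence_fit": _io.to_jsonable(fit),
            }
        except Exception as exc:  # noqa: BLE001
            errors[str(p)] = f"{type(exc).__name__}: {exc}"
    return results, errors


_STAGES = {
    "fec": _stage_fec,
    "kinetics": _stage_kinetics,
    "helix": _stage_helix,
    "afm": _stage_afm,
}


def run_pipeline(config: RunConfig,
                 inputs: Mapping[str, Sequence]) -> tuple[dict, bool]:
    """Execute the configured stages over the given input files.

    ``inputs`` maps stage name ("fec", "kinetics", "helix", "afm") to a list
    of file paths.  Per-file failures are collected under ``errors`` without
    aborting the other stages; the boolean return is True when no stage
    recorded a failure.  With ``config.outdir`` set, the report is written
    there as ``report.json`` (deterministic: no timestamps, sorted keys).
    """
    unknown = set(inputs) - set(_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    report = {
        "package": "gp32filament",
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
        "errors": {},
    }
    for stage in sorted(inputs):
        log.info("stage %s: %d inputs", stage, len(inputs[stage]))
        results, errors = _STAGES[stage](config, inputs[stage])
        report["stages"][stage] = results
        if errors:
            report["errors"][stage] = errors
    ok = not report["errors"]
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _io.save_json(report, outdir / "report.json")
    return report, ok
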