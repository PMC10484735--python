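"""Readers and writers for delimited-text curves, traces and images.

File conventions: CSV/TSV with named columns; optional metadata header
lines prefixed ``#`` holding ``key=value`` pairs.  Height images are plain
numeric text grids with a JSON sidecar (same path + ``.json``) carrying the
pixel size and metadata.  All numerics round-trip at full double precision.
"""
from __future__ import annotations

import dataclasses
import io as _io
import json
import math
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .afm import AFMImage, BackboneTrace
from .errors import SchemaError, ValidationError
from .kinetics import RateSeries, TimeExtensionTrace
from .polymer import ForceExtensionCurve

__all__ = [
    "read_fec", "write_fec",
    "read_trace", "write_trace",
    "read_backbone_traces", "write_backbone_traces",
    "read_afm_image", "write_afm_image",
    "read_rate_series", "write_rate_series",
    "to_jsonable", "save_json", "load_json",
]

_FLOAT_FMT = "%.17g"


def _parse_meta_value(raw: str):
    raw = raw.strip()
    try:
        v = float(raw)
        return int(v) if v.is_integer() and "." not in raw and "e" not in raw.lower() else v
    except ValueError:
        return raw


def _read_delim(path) -> Tuple[dict, pd.DataFrame]:
    path = Path(path)
    meta: dict = {}
    body_lines: List[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if "=" in stripped:
                    key, _, val = stripped.partition("=")
                    meta[key.strip()] = _parse_meta_value(val)
            elif line.strip():
                body_lines.append(line)
    if not body_lines:
        raise SchemaError(f"{path}: no data rows")
    df = pd.read_csv(_io.StringIO("".join(body_lines)), sep=None, engine="python")
    return meta, df


def _require(df: pd.DataFrame, columns, path) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")


def _write_delim(path, meta: dict, df: pd.DataFrame) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_fec(path) -> ForceExtensionCurve:
    """Read a force–extension curve (columns force_pN, extension_nm)."""
    meta, df = _read_delim(path)
    _require(df, ("force_pN", "extension_nm"), path)
    direction = str(meta.pop("direction", "stretch"))
    return ForceExtensionCurve(df["force_pN"].to_numpy(),
                               df["extension_nm"].to_numpy(),
                               direction=direction, meta=meta)


def write_fec(fec: ForceExtensionCurve, path) -> None:
    meta = {"direction": fec.direction, **fec.meta}
    _write_delim(path, meta,
                 pd.DataFrame({"force_pN": fec.force, "extension_nm": fec.extension}))


def read_trace(path) -> TimeExtensionTrace:
    """Read a time–extension trace (columns time_s, extension_nm).

    Metadata headers force_pN, concentration_nM and phase become the
    trace's force, concentration and phase label.
    """
    meta, df = _read_delim(path)
    _require(df, ("time_s", "extension_nm"), path)
    t = df["time_s"].to_numpy(dtype=float)
    if t.size >= 2 and np.any(np.diff(t) <= 0):
        raise ValidationError(f"{path}: time_s must be strictly increasing")
    force = float(meta.pop("force_pN", 0.0))
    conc = float(meta.pop("concentration_nM", 0.0))
    phase = str(meta.pop("phase", "binding"))
    return TimeExtensionTrace(t, df["extension_nm"].to_numpy(dtype=float),
                              force, conc, phase, meta)


def write_trace(trace: TimeExtensionTrace, path) -> None:
    meta = {"force_pN": trace.force, "concentration_nM": trace.concentration,
            "phase": trace.phase_label, **{k: v for k, v in trace.meta.items()
                                           if not isinstance(v, (tuple, list, dict))}}
    _write_delim(path, meta,
                 pd.DataFrame({"time_s": trace.time, "extension_nm": trace.extension}))


def read_backbone_traces(path) -> List[BackboneTrace]:
    """Read ordered backbone traces (columns molecule_id, x_nm, y_nm)."""
    _, df = _read_delim(path)
    _require(df, ("molecule_id", "x_nm", "y_nm"), path)
    out = []
    for mol, grp in df.groupby("molecule_id", sort=False):
        out.append(BackboneTrace(grp[["x_nm", "y_nm"]].to_numpy(dtype=float),
                                 str(mol)))
    return out


def write_backbone_traces(traces, path) -> None:
    frames = [pd.DataFrame({"molecule_id": tr.molecule_id,
                            "x_nm": tr.points[:, 0], "y_nm": tr.points[:, 1]})
              for tr in traces]
    _write_delim(path, {}, pd.concat(frames, ignore_index=True))


def read_afm_image(path) -> AFMImage:
    """Read a height grid (plain text) with its JSON sidecar (<path>.json)."""
    path = Path(path)
    heights = np.loadtxt(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta: dict = {}
    pixel_size = 1.0
    background = None
    if sidecar.exists():
        with open(sidecar) as fh:
            side = json.load(fh)
        pixel_size = float(side.pop("pixel_size", 1.0))
        background = side.pop("background", None)
        meta = side
    return AFMImage(heights, pixel_size,
                    None if background is None else float(background), meta)


def write_afm_image(image: AFMImage, path) -> None:
    path = Path(path)
    np.savetxt(path, image.heights, fmt=_FLOAT_FMT)
    side = {"pixel_size": image.pixel_size, "background": image.background,
            **to_jsonable(image.meta)}
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(side, fh, indent=1, sort_keys=True)


def read_rate_series(path) -> RateSeries:
    """Read a rate series (columns abscissa, rate[, uncertainty])."""
    meta, df = _read_delim(path)
    _require(df, ("abscissa", "rate"), path)
    unc = df["uncertainty"].to_numpy(dtype=float) if "uncertainty" in df.columns else None
    kind = str(meta.pop("kind", "force"))
    return RateSeries(df["abscissa"].to_numpy(dtype=float),
                      df["rate"].to_numpy(dtype=float), unc, kind, meta)


def write_rate_series(series: RateSeries, path) -> None:
    data = {"abscissa": series.abscissa, "rate": series.rates}
    if series.rate_uncertainties is not None:
        data["uncertainty"] = series.rate_uncertainties
    meta = {"kind": series.kind,
            **{k: v for k, v in series.meta.items()
               if not isinstance(v, (tuple, list, dict))}}
    _write_delim(path, meta, pd.DataFrame(data))


def to_jsonable(obj):
    """Recursively convert dataclasses / numpy values to JSON-safe types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: to_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return [to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float):
        if math.isnan(obj):
            return None
        if math.isinf(obj):
            return "inf" if obj > 0 else "-inf"
        return obj
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    return obj


def save_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(to_jsonable(obj), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_json(path):
    with open(path) as fh:
        return json.load(fh)
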