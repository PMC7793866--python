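"""File formats: CSV traces/curves/FRAP tables, TIFF images, JSON reports.

Lag axes are stored in milliseconds on disk (the convention of instrument
exports) and converted to seconds on read; everything in memory is seconds.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .correlator import CorrelationCurve, IntensityTrace

__all__ = [
    "read_trace_csv", "write_trace_csv",
    "read_acf_csv", "write_acf_csv",
    "read_frap_csv", "write_frap_csv",
    "read_image", "write_image", "read_mask",
    "write_json_report",
]

MS_PER_S = 1e3


def read_trace_csv(path) -> IntensityTrace:
    """Read a binned photon-count trace.

    Accepts either two columns ``time_s,counts`` (bin width inferred from the
    time step) or a single ``counts`` column with the bin width in a header
    comment line ``# bin_width_s=<value>``.
    """
    path = Path(path)
    bin_width = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "bin_width_s=" in line:
                bin_width = float(line.split("bin_width_s=")[1])
    df = pd.read_csv(path, comment="#")
    if "counts" not in df.columns:
        raise ValueError(f"{path}: expected a 'counts' column")
    if "time_s" in df.columns:
        t = df["time_s"].to_numpy(dtype=float)
        if t.size < 2:
            raise ValueError(f"{path}: need at least two rows to infer bin width")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise ValueError(f"{path}: time_s must be strictly increasing")
        bin_width = float(np.median(steps))
    if bin_width is None:
        raise ValueError(f"{path}: no time_s column and no '# bin_width_s=' header")
    return IntensityTrace(bin_width=bin_width, counts=df["counts"].to_numpy(dtype=np.int64))


def write_trace_csv(trace: IntensityTrace, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# bin_width_s={trace.bin_width!r}\n")
        fh.write("counts\n")
        np.savetxt(fh, trace.counts, fmt="%d")


def read_acf_csv(path) -> CorrelationCurve:
    """Read a correlation curve with columns ``lag_ms,g`` and optional ``sd``."""
    df = pd.read_csv(path, comment="#")
    for col in ("lag_ms", "g"):
        if col not in df.columns:
            raise ValueError(f"{path}: expected columns lag_ms,g (got {list(df.columns)})")
    lags_ms = df["lag_ms"].to_numpy(dtype=float)
    if np.any(lags_ms <= 0):
        raise ValueError(f"{path}: lag_ms values must be positive")
    sd = df["sd"].to_numpy(dtype=float) if "sd" in df.columns else None
    return CorrelationCurve(lags=lags_ms / MS_PER_S, g=df["g"].to_numpy(dtype=float), sd=sd)


def write_acf_csv(curve: CorrelationCurve, path) -> None:
    data = {"lag_ms": curve.lags * MS_PER_S, "g": curve.g}
    if curve.sd is not None:
        data["sd"] = curve.sd
    pd.DataFrame(data).to_csv(path, index=False)


def read_frap_csv(path):
    """Read a FRAP table ``time_s,i_bleach,i_cell,i_background`` -> four arrays."""
    df = pd.read_csv(path, comment="#")
    cols = ("time_s", "i_bleach", "i_cell", "i_background")
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return tuple(df[c].to_numpy(dtype=float) for c in cols)


def write_frap_csv(times, i_bleach, i_cell, i_background, path) -> None:
    pd.DataFrame(
        {"time_s": times, "i_bleach": i_bleach, "i_cell": i_cell,
         "i_background": i_background}
    ).to_csv(path, index=False)


def read_image(path) -> np.ndarray:
    img = tifffile.imread(path)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a single-plane 2D image, got shape {img.shape}")
    return np.asarray(img)


def write_image(image: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(image))


def read_mask(path) -> np.ndarray:
    """Read a binary mask image: non-zero pixels are True."""
    return read_image(path) > 0


def write_json_report(report: dict, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o).__name__}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=default)
        fh.write("\n")
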