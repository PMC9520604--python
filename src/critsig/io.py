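"""On-disk formats: sparse spike-list rasters, walk traces, run configs.

Rasters travel as CSV spike lists — one ``neuron_id,time_bin`` row per
spike, 0-based, preceded by a comment header carrying the matrix shape and
bin width — so any table tool can read them and round trips are lossless.
Run configurations are YAML mappings of the dataclass fields.
"""

from __future__ import annotations

import io as _io
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .network import BrunelParams
from .types import Raster
from .walks import WalkTrace

__all__ = ["read_raster", "write_raster", "read_walk", "write_walk",
           "load_config", "save_config", "params_from_config", "ParseError"]

_HEADER = "# critsig-raster n_neurons={n} n_bins={b} bin_ms={ms}\n"


class ParseError(ValueError):
    pass


def write_raster(raster: Raster, path) -> None:
    ids, bins = np.nonzero(raster.spikes)
    with open(path, "w") as fh:
        fh.write(_HEADER.format(n=raster.n_neurons, b=raster.n_bins,
                                ms=raster.bin_ms))
        fh.write("neuron_id,time_bin\n")
        for i, t in zip(ids, bins):
            fh.write(f"{i},{t}\n")


def read_raster(path) -> Raster:
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines or not lines[0].startswith("# critsig-raster"):
        raise ParseError(f"{path}: missing critsig-raster header (line 1)")
    header = dict(tok.split("=") for tok in lines[0].split()[2:])
    n_neurons = int(header["n_neurons"])
    n_bins = int(header["n_bins"])
    bin_ms = float(header.get("bin_ms", 1.0))
    df = pd.read_csv(_io.StringIO("\n".join(lines[1:])))
    spikes = np.zeros((n_neurons, n_bins), dtype=np.uint8)
    if len(df):
        ids = df["neuron_id"].to_numpy()
        bins = df["time_bin"].to_numpy()
        for col, vals, hi in (("neuron_id", ids, n_neurons),
                              ("time_bin", bins, n_bins)):
            bad = np.flatnonzero((vals < 0) | (vals >= hi))
            if len(bad):
                raise ParseError(
                    f"{path}: {col} out of range at data line {bad[0] + 1}")
        if df.duplicated().any():
            line = int(np.flatnonzero(df.duplicated().to_numpy())[0]) + 1
            raise ParseError(f"{path}: duplicate (neuron, bin) at data line {line}")
        spikes[ids, bins] = 1
    return Raster(spikes=spikes, bin_ms=bin_ms)


def write_walk(trace: WalkTrace, path) -> None:
    pd.DataFrame({"step": np.arange(len(trace.values)),
                  "value": trace.values}).to_csv(path, index=False)


def read_walk(path, kind: str = "coin_flip") -> WalkTrace:
    df = pd.read_csv(path)
    if "value" not in df.columns:
        raise ParseError(f"{path}: expected columns step,value")
    return WalkTrace(values=df["value"].to_numpy(), kind=kind,
                     params_ref=str(path))


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def params_from_config(cfg: dict) -> BrunelParams:
    """Build network parameters from the ``network:`` section of a config."""
    section = cfg.get("network", cfg)
    fields = set(BrunelParams.__dataclass_fields__)
    unknown = set(section) - fields
    if unknown:
        raise ParseError(f"unknown network parameters: {sorted(unknown)}")
    return BrunelParams(**section)


def params_to_config(params: BrunelParams) -> dict:
    return {"network": asdict(params)}
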