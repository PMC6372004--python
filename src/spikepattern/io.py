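"""Text interchange: spike trains as delimited text, configs as YAML.

The spike-train format is two-column CSV with header ``afferent,time_s``:
0-based afferent index and time in seconds written with 17 significant
digits, so a write/read cycle is bit-exact.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from .spikegen import PatternConfig, SpikeTrainSet

__all__ = [
    "write_spike_trains",
    "read_spike_trains",
    "write_config",
    "read_config",
]


def write_spike_trains(path, spikes: SpikeTrainSet) -> None:
    """Write events as ``afferent,time_s`` CSV (17 significant digits)."""
    df = pd.DataFrame({"afferent": spikes.afferents, "time_s": spikes.times})
    with open(path, "w") as fh:
        fh.write(f"# duration_s={spikes.duration!r} N={spikes.N}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_spike_trains(path) -> SpikeTrainSet:
    """Read a spike-train CSV written by :func:`write_spike_trains`."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("missing metadata header line")
        meta = dict(kv.split("=") for kv in header[1:].split())
        df = pd.read_csv(fh, float_precision="round_trip")
    return SpikeTrainSet(
        afferents=df["afferent"].to_numpy(),
        times=df["time_s"].to_numpy(),
        duration=float(meta["duration_s"]),
        N=int(meta["N"]),
    )


def write_config(path, config: PatternConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def read_config(path) -> PatternConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PatternConfig(**data)
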