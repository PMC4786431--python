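"""Reading and writing the pipeline's file formats.

Spike trains travel as two-column CSV (trial_id, spike_time_s); voltage
traces as single-column CSV with ``fs``/``t0`` header metadata; image
stacks as one multipage TIFF per channel plus a JSON sidecar holding
frame times, the stimulus window, and any ground truth; configs as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import ImageStackPair, SpikeTrain, StimulusProtocol, VoltageTrace

__all__ = [
    "write_spike_trains",
    "read_spike_trains",
    "write_voltage_trace",
    "read_voltage_trace",
    "write_stack_pair",
    "read_stack_pair",
    "read_config",
    "protocol_from_dict",
]


def write_spike_trains(trains: list[SpikeTrain], path) -> None:
    rows = [
        {"trial_id": tr.trial_id or str(i), "spike_time_s": t}
        for i, tr in enumerate(trains)
        for t in tr.times
    ]
    pd.DataFrame(rows, columns=["trial_id", "spike_time_s"]).to_csv(path, index=False)


def read_spike_trains(
    path, protocol: StimulusProtocol | None = None,
    t_start: float = 0.0, t_stop: float | None = None,
) -> list[SpikeTrain]:
    df = pd.read_csv(path, dtype={"trial_id": str})
    return [
        SpikeTrain(
            np.sort(grp["spike_time_s"].to_numpy(float)),
            protocol=protocol, trial_id=str(tid), t_start=t_start, t_stop=t_stop,
        )
        for tid, grp in df.groupby("trial_id", sort=True)
    ]


def write_voltage_trace(trace: VoltageTrace, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs={trace.fs}\n# t0={trace.t0}\n")
        fh.write("voltage\n")
        np.savetxt(fh, trace.samples, fmt="%.9g")


def read_voltage_trace(path) -> VoltageTrace:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, val = line[1:].split("=", 1)
            meta[key.strip()] = float(val)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        samples = pd.read_csv(fh)["voltage"].to_numpy(float)
    return VoltageTrace(samples, fs=meta["fs"], t0=meta.get("t0", 0.0))


def write_stack_pair(
    pair: ImageStackPair, directory, prefix: str = "stack", sidecar: dict | None = None
) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(d / f"{prefix}_cfp.tif", pair.cfp.astype(np.float32))
    tifffile.imwrite(d / f"{prefix}_yfp.tif", pair.yfp.astype(np.float32))
    meta = {"frame_times": pair.frame_times.tolist()}
    if sidecar:
        meta.update(sidecar)
    (d / f"{prefix}.json").write_text(json.dumps(meta, indent=1))


def read_stack_pair(directory, prefix: str = "stack") -> tuple[ImageStackPair, dict]:
    d = Path(directory)
    cfp = tifffile.imread(d / f"{prefix}_cfp.tif")
    yfp = tifffile.imread(d / f"{prefix}_yfp.tif")
    meta = json.loads((d / f"{prefix}.json").read_text())
    pair = ImageStackPair(cfp, yfp, np.asarray(meta["frame_times"], dtype=float))
    return pair, meta


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def protocol_from_dict(d: dict) -> StimulusProtocol:
    return StimulusProtocol(
        kind=d["kind"],
        onset=float(d["onset"]),
        duration=float(d["duration"]),
        power=float(d.get("power", 0.0)),
        pulse_on=float(d.get("pulse_on", 100.0)),
        pulse_off=float(d.get("pulse_off", 100.0)),
        n_pulses=int(d.get("n_pulses", 0)),
    )
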