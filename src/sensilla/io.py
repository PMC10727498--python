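"""Reading and writing the pipeline's on-disk formats.

Simulated (or real) recordings travel as HDF5 with one group per
bee/location/sensillum/stimulus holding the trace and, when available,
the ground-truth spike table; spike tables and feature tables are tidy
CSV.  Configuration round-trips through YAML with the seed mandatory.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .core import Recording, VoltageTrace


def save_recordings_h5(recordings: list[Recording], path: str | Path) -> None:
    """Write recordings to HDF5 (groups /bee/<location>/<sensillum>/<stimulus>)."""
    with h5py.File(path, "w") as f:
        for rec in recordings:
            t = rec.trace
            grp = f.require_group(f"{t.bee_id}/{t.location}/{t.sensillum_id}/{t.stimulus}")
            grp.create_dataset("trace", data=t.samples, compression="gzip")
            grp.attrs["sample_rate"] = t.sample_rate
            if rec.truth is not None:
                grp.create_dataset("truth_time_s", data=rec.truth["time_s"].to_numpy())
                grp.create_dataset(
                    "truth_unit",
                    data=np.array(rec.truth["unit"], dtype="S8"),
                )


def load_recordings_h5(path: str | Path) -> list[Recording]:
    recordings = []
    with h5py.File(path, "r") as f:
        for bee in f:
            for location in f[bee]:
                for sens in f[bee][location]:
                    for stim in f[bee][location][sens]:
                        grp = f[bee][location][sens][stim]
                        trace = VoltageTrace(
                            samples=grp["trace"][...],
                            sample_rate=float(grp.attrs["sample_rate"]),
                            location=location,
                            bee_id=bee,
                            sensillum_id=sens,
                            stimulus=stim,
                        )
                        truth = None
                        if "truth_time_s" in grp:
                            truth = pd.DataFrame(
                                {
                                    "time_s": grp["truth_time_s"][...],
                                    "unit": [
                                        u.decode() for u in grp["truth_unit"][...]
                                    ],
                                }
                            )
                        recordings.append(Recording(trace=trace, truth=truth))
    return recordings


def recordings_index(recordings: list[Recording]) -> pd.DataFrame:
    """Index CSV content: one row per recording."""
    return pd.DataFrame(
        [
            {
                "bee": r.trace.bee_id,
                "location": r.trace.location,
                "sensillum": r.trace.sensillum_id,
                "stimulus": r.trace.stimulus,
                "sample_rate": r.trace.sample_rate,
                "duration_s": r.trace.duration,
                "has_truth": r.truth is not None,
            }
            for r in recordings
        ]
    )


def load_trace_csv(
    path: str | Path,
    sample_rate: float,
    location: str,
    bee_id: str = "",
    sensillum_id: str = "",
    stimulus: str = "",
) -> VoltageTrace:
    """Thin loader for a single-column (or time,voltage) CSV trace.

    Covers externally deposited recordings stored as plain CSV; the
    voltage column is taken as the last column.
    """
    df = pd.read_csv(path)
    return VoltageTrace(
        samples=df.iloc[:, -1].to_numpy(dtype=float),
        sample_rate=sample_rate,
        location=location,
        bee_id=bee_id,
        sensillum_id=sensillum_id,
        stimulus=stimulus,
    )


def save_config_yaml(config: dict, path: str | Path) -> None:
    if "seed" not in config:
        raise ValueError("config must carry a seed")
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def load_config_yaml(path: str | Path) -> dict:
    config = yaml.safe_load(Path(path).read_text())
    if not isinstance(config, dict) or "seed" not in config:
        raise ValueError("config must be a mapping with a mandatory seed")
    return config
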