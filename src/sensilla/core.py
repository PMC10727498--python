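"""Core containers shared across the pipeline.

A tip recording captures the summed extracellular activity of the 2-4
gustatory receptor neurons (GRNs) housed in one taste sensillum.  The
containers here carry a recording and its derived spike-level objects
through filtering, detection, burst segmentation and unit assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Mouthpart locations: galea, labial palp segments III and IV.
LOCATIONS = ("Gal", "LPIII", "LPIV")

#: Fixed GRN-type order used everywhere downstream (population vectors,
#: feature tables).  3 galeal units + 2 units per labial-palp segment.
GRN_TYPES = ("Gal1", "Gal2", "Gal3", "LPIII1", "LPIII2", "LPIV1", "LPIV2")


@dataclass
class VoltageTrace:
    """One electrode signal from a single sensillum stimulation.

    Parameters
    ----------
    samples : ndarray
        Signal values, trace units.  Time zero is stimulus contact onset.
    sample_rate : float
        Sampling frequency in Hz (recordings are digitised at 30 kHz).
    location : str
        One of ``Gal``, ``LPIII``, ``LPIV``.
    bee_id, sensillum_id, stimulus : str
        Identity of the animal, the sensillum within the animal, and the
        tastant applied.
    """

    samples: np.ndarray
    sample_rate: float
    location: str
    bee_id: str = ""
    sensillum_id: str = ""
    stimulus: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def with_samples(self, samples: np.ndarray) -> "VoltageTrace":
        return VoltageTrace(
            samples=samples,
            sample_rate=self.sample_rate,
            location=self.location,
            bee_id=self.bee_id,
            sensillum_id=self.sensillum_id,
            stimulus=self.stimulus,
        )


@dataclass
class SpikeTrain:
    """Detected spike times (s from stimulation onset) with peak amplitudes."""

    times: np.ndarray
    peak_amplitudes: np.ndarray
    source: VoltageTrace | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.peak_amplitudes = np.asarray(self.peak_amplitudes, dtype=float)
        if self.times.size != self.peak_amplitudes.size:
            raise ValueError("times and peak_amplitudes differ in length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class BurstSet:
    """Partition of a galeal spike train into bursts.

    ``bursts`` is a list of (member spike indices, end-of-burst index);
    the end-of-burst (EOB) spike is always the last member of its burst.
    """

    bursts: list[tuple[np.ndarray, int]]
    isi_threshold: float

    def __len__(self) -> int:
        return len(self.bursts)

    @property
    def eob_indices(self) -> np.ndarray:
        return np.array([e for _, e in self.bursts], dtype=int)


@dataclass
class GalealLabels:
    """Per-spike unit labels for a galeal recording: Gal1/Gal2/Gal3."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)

    def counts(self) -> dict[str, int]:
        vals, n = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(vals.tolist(), n.tolist()))


@dataclass
class Recording:
    """A voltage trace together with (optional) ground-truth annotation.

    ``truth`` has columns ``time_s`` and ``unit`` when the recording comes
    from the simulator; it is ``None`` for real data.
    """

    trace: VoltageTrace
    truth: pd.DataFrame | None = None


def spike_table(
    trace: VoltageTrace, times: np.ndarray, amplitudes: np.ndarray, units: np.ndarray
) -> pd.DataFrame:
    """Tidy per-spike table used as the pipeline's on-disk interchange."""
    return pd.DataFrame(
        {
            "bee": trace.bee_id,
            "location": trace.location,
            "sensillum": trace.sensillum_id,
            "stimulus": trace.stimulus,
            "time_s": np.asarray(times, dtype=float),
            "amplitude": np.asarray(amplitudes, dtype=float),
            "unit": np.asarray(units, dtype=object),
        }
    )
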