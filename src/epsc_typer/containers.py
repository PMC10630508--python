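"""Shared data containers for recordings, event tables, and AP trains.

Sign convention (used everywhere): traces store the recorded current at a
holding potential of -80 mV, so synaptic events are *negative* (inward)
deflections in pA; event feature tables store positive magnitudes, and
``ln_amplitude`` / ``ln_charge`` are natural logs of those magnitudes
(amplitude in pA, charge in fC; 1 pA*ms = 1 fC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: columns of an event feature table, in canonical order
EVENT_COLUMNS = [
    "cell_id",
    "event_time_ms",
    "amplitude_pA",
    "charge_fC",
    "rise_10_90_ms",
    "decay_tau_ms",
    "ln_amplitude",
    "ln_charge",
    "source",
]


@dataclass
class SweepRecording:
    """A sampled current trace in pA with its recording metadata."""

    samples: np.ndarray
    sampling_rate: float  # Hz
    sweep_id: str = "sweep0"
    holding_potential: float = -80.0  # mV
    rs_start: float | None = None  # MOhm
    rs_end: float | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("trace samples must be finite")

    @property
    def duration_ms(self) -> float:
        return self.samples.size / self.sampling_rate * 1000.0

    def times_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate * 1000.0


@dataclass
class CellEventSet:
    """All extracted events of one cell plus the QC metadata."""

    cell_id: str
    events: pd.DataFrame
    condition: str = "NR"
    rs_start: float | None = None
    rs_end: float | None = None

    @property
    def n_events(self) -> int:
        return len(self.events)


@dataclass
class APTrain:
    """Peak times of the 10 presynaptic action potentials of one sweep."""

    ap_peak_times: np.ndarray  # ms, strictly increasing
    freq: float  # Hz
    sweep_id: str = "sweep0"

    def __post_init__(self):
        self.ap_peak_times = np.asarray(self.ap_peak_times, dtype=float)
        if np.any(np.diff(self.ap_peak_times) <= 0):
            raise ValueError("AP peak times must be strictly increasing")

    @property
    def isi_ms(self) -> float:
        return 1000.0 / self.freq


def make_ap_train(freq: float, start_ms: float = 50.0, n_ap: int = 10,
                  sweep_id: str = "sweep0") -> APTrain:
    """Regular train of ``n_ap`` AP peak times at the given frequency."""
    if freq <= 0:
        raise ValueError("freq must be positive")
    times = start_ms + np.arange(n_ap) * (1000.0 / freq)
    return APTrain(ap_peak_times=times, freq=freq, sweep_id=sweep_id)


@dataclass
class GroundTruth:
    """Ground truth emitted by the synthetic generator.

    ``events`` has one row per event summed into the trace (time, label,
    amplitude, charge, source); ``release`` has one row per (sweep, AP) with
    the true Bernoulli outcome; ``async_events`` lists asynchronous release
    times.  The latter two are empty for miniature-EPSC recordings.
    """

    events: pd.DataFrame
    release: pd.DataFrame = field(default_factory=pd.DataFrame)
    async_events: pd.DataFrame = field(default_factory=pd.DataFrame)
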