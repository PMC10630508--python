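"""Event detection, feature extraction, and recording-quality filtering.

Detection runs on a low-pass-filtered, baseline-subtracted copy of the
trace (threshold crossing of the inward-current magnitude); amplitude,
charge and kinetics are then measured on the unfiltered trace relative to
a per-event pre-onset baseline.  Charge is the trapezoidal integral of the
baseline-subtracted current over the event window (1 pA*ms = 1 fC).

QC follows the recording-exclusion rules of the analysis: series
resistance at most 30 MOhm for miniature-EPSC cells (40 MOhm for pairs),
at most 15% series-resistance drift, and at least 200 events per
miniature-EPSC cell.  The resistance cap is applied to the value at the
start of the recording; drift over the recording is policed separately by
the 15% rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .containers import EVENT_COLUMNS, CellEventSet, SweepRecording

__all__ = [
    "SweepRecording",
    "CellEventSet",
    "EVENT_COLUMNS",
    "detect_events",
    "measure_amplitude_charge",
    "rise_time_10_90",
    "fit_decay_tau",
    "qc_filter_cells",
    "events_from_ground_truth",
]

RS_LIMIT = {"mini": 30.0, "pair": 40.0}
RS_DRIFT_LIMIT = 0.15
MIN_EVENTS_MINI = 200


def measure_amplitude_charge(segment: np.ndarray, baseline: float,
                             sampling_rate: float) -> tuple[float, float]:
    """Amplitude (pA) and charge (fC) of a trace segment.

    Amplitude is ``|extremum - baseline|``; charge is the absolute
    trapezoidal integral of the baseline-subtracted segment.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.size < 2:
        raise ValueError("segment must contain at least 2 samples")
    dev = seg - baseline
    amplitude = float(np.max(np.abs(dev)))
    dt_ms = 1000.0 / sampling_rate
    charge = float(abs(np.trapezoid(dev, dx=dt_ms)))
    return amplitude, charge


def rise_time_10_90(segment: np.ndarray, sampling_rate: float) -> float:
    """10-90% rise time (ms) of a positive-going, baseline-zero segment.

    Crossing times are linearly interpolated between samples.
    """
    seg = np.asarray(segment, dtype=float)
    ipk = int(np.argmax(seg))
    if ipk == 0:
        raise ValueError("peak at first sample; no rising phase")
    peak = seg[ipk]
    dt_ms = 1000.0 / sampling_rate

    def first_crossing(level: float) -> float:
        idx = np.flatnonzero(seg[: ipk + 1] >= level)
        i = int(idx[0])
        if i == 0:
            return 0.0
        y0, y1 = seg[i - 1], seg[i]
        frac = (level - y0) / (y1 - y0) if y1 != y0 else 0.0
        return (i - 1 + frac) * dt_ms

    return first_crossing(0.9 * peak) - first_crossing(0.1 * peak)


def fit_decay_tau(segment: np.ndarray, sampling_rate: float,
                  floor_frac: float = 0.05) -> float:
    """Decay constant (ms) from a log-linear fit of the falling phase.

    ``segment`` starts at the (positive) peak; samples below
    ``floor_frac`` of the peak are ignored.  Returns NaN if fewer than
    3 usable samples.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.size < 3 or seg[0] <= 0:
        return float("nan")
    keep = seg > floor_frac * seg[0]
    # use the contiguous run from the peak
    stop = int(np.argmin(keep)) if not keep.all() else seg.size
    seg = seg[:stop]
    if seg.size < 3:
        return float("nan")
    t = np.arange(seg.size) / sampling_rate * 1000.0
    slope, _ = np.polyfit(t, np.log(seg), 1)
    if slope >= 0:
        return float("nan")
    return float(-1.0 / slope)


def _lowpass(y: np.ndarray, sampling_rate: float, cutoff_hz: float) -> np.ndarray:
    nyq = sampling_rate / 2.0
    if cutoff_hz >= nyq * 0.95:
        return y.copy()
    sos = signal.butter(4, cutoff_hz / nyq, output="sos")
    return signal.sosfiltfilt(sos, y)


def detect_events(trace: SweepRecording, threshold: float = 5.0,
                  min_separation: float = 10.0, lowpass_hz: float = 1000.0,
                  cell_id: str | None = None) -> pd.DataFrame:
    """Detect inward synaptic events in a current trace.

    Parameters
    ----------
    trace : SweepRecording
        Recorded sweep (events are negative deflections).
    threshold : float
        Minimum baseline-subtracted peak magnitude, pA.
    min_separation : float
        Minimum peak-to-peak separation in ms ("well-isolated" criterion).
    lowpass_hz : float
        Detection filter cutoff.

    Returns
    -------
    DataFrame
        One row per event with the canonical feature columns plus
        ``onset_time_ms`` and ``peak_time_ms``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    y_raw = trace.samples
    if y_raw.size == 0:
        raise ValueError("empty trace")
    fs = trace.sampling_rate
    dt_ms = 1000.0 / fs

    # positive-up magnitude, global baseline from the median
    inv = -(y_raw - np.median(y_raw))
    flt = _lowpass(inv, fs, lowpass_hz)

    distance = max(1, int(round(min_separation / dt_ms)))
    peaks, _ = signal.find_peaks(flt, height=threshold, distance=distance)
    sigma = 1.4826 * float(np.median(np.abs(flt - np.median(flt))))

    rows = []
    for k, ipk in enumerate(peaks):
        # onset: walk back to the last sample at the noise floor
        level = max(0.02 * flt[ipk], 2.0 * sigma)
        i = ipk
        lo_stop = peaks[k - 1] if k > 0 else 0
        while i > lo_stop and flt[i - 1] > level:
            i -= 1
        onset = i
        # local baseline from a 2 ms pre-onset window on the raw trace
        b0 = max(0, onset - int(round(2.0 / dt_ms)))
        baseline = float(np.mean(inv[b0:onset])) if onset > b0 else float(inv[onset])

        next_onset = peaks[k + 1] if k + 1 < len(peaks) else inv.size
        # refine the peak on the raw trace near the filtered peak
        w0 = max(onset, ipk - int(round(0.5 / dt_ms)))
        w1 = min(inv.size, ipk + int(round(0.5 / dt_ms)) + 1)
        ipk_raw = w0 + int(np.argmax(inv[w0:w1]))
        amplitude = float(inv[ipk_raw] - baseline)
        if amplitude < threshold:
            continue

        tau_d = fit_decay_tau(inv[ipk_raw:next_onset] - baseline, fs)
        span = int(round((5.0 * tau_d) / dt_ms)) if np.isfinite(tau_d) else int(
            round(50.0 / dt_ms)
        )
        end = min(inv.size, max(ipk_raw + 2, onset + span), next_onset)
        _, charge = measure_amplitude_charge(y_raw[onset:end],
                                             float(np.median(y_raw)) - baseline, fs)
        rise_seg = inv[onset : ipk_raw + 1] - baseline
        try:
            rise = rise_time_10_90(rise_seg, fs)
        except ValueError:
            rise = dt_ms
        if amplitude <= 0 or charge <= 0:
            continue
        rows.append(
            dict(
                cell_id=cell_id if cell_id is not None else trace.sweep_id,
                event_time_ms=onset * dt_ms,
                amplitude_pA=amplitude,
                charge_fC=charge,
                rise_10_90_ms=rise,
                decay_tau_ms=tau_d,
                ln_amplitude=float(np.log(amplitude)),
                ln_charge=float(np.log(charge)),
                source="mini",
                onset_time_ms=onset * dt_ms,
                peak_time_ms=ipk_raw * dt_ms,
            )
        )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS + ["onset_time_ms", "peak_time_ms"])


def events_from_ground_truth(events: pd.DataFrame) -> pd.DataFrame:
    """Canonical feature table from a generator ground-truth table."""
    out = pd.DataFrame(
        {
            "cell_id": events["cell_id"],
            "event_time_ms": events["event_time_ms"],
            "amplitude_pA": events["amplitude_pA"],
            "charge_fC": events["charge_fC"],
            "rise_10_90_ms": np.nan,
            "decay_tau_ms": events.get("tau_decay_ms", np.nan),
            "ln_amplitude": np.log(events["amplitude_pA"]),
            "ln_charge": np.log(events["charge_fC"]),
            "source": events.get("source", "mini"),
        }
    )
    if "sweep_id" in events:
        out["sweep_id"] = events["sweep_id"].to_numpy()
    if "ap_index" in events:
        out["ap_index"] = events["ap_index"].to_numpy()
    return out


def qc_filter_cells(cells: list[CellEventSet], context: str = "mini"
                    ) -> tuple[list[CellEventSet], pd.DataFrame]:
    """Apply the recording-exclusion rules.

    Returns the kept cells and a table of ``(cell_id, reason)`` exclusions;
    reasons are ``missing_qc``, ``rs_high``, ``rs_drift``, ``too_few_events``.
    """
    if context not in RS_LIMIT:
        raise ValueError("context must be 'mini' or 'pair'")
    limit = RS_LIMIT[context]
    kept: list[CellEventSet] = []
    excluded: list[dict] = []
    for cell in cells:
        reason = None
        if cell.rs_start is None or cell.rs_end is None:
            reason = "missing_qc"
        elif cell.rs_start > limit:
            reason = "rs_high"
        elif abs(cell.rs_end - cell.rs_start) / cell.rs_start > RS_DRIFT_LIMIT:
            reason = "rs_drift"
        elif context == "mini" and cell.n_events < MIN_EVENTS_MINI:
            reason = "too_few_events"
        if reason is None:
            kept.append(cell)
        else:
            excluded.append(dict(cell_id=cell.cell_id, reason=reason))
    return kept, pd.DataFrame(excluded, columns=["cell_id", "reason"])
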