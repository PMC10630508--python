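"""Short-term dynamics and asynchronous release from paired recordings.

For each of the 10 presynaptic APs in a train, an evoked success is an
event whose peak falls within 3 ms after the AP peak (window half-open on
the left, closed at +3 ms; the first event in the window is measured when
several occur).  Per AP index and stimulation frequency:

* success rate: fraction of sweeps with a success;
* strength: mean evoked amplitude with failures counted as 0 pA;
* potency: mean amplitude over successes only (NaN when none),

so ``strength = success_rate * potency`` wherever potency is defined.
Asynchronous release for AP i is the event rate in the window from
``t_i + 3 ms`` to the next AP peak (after the last AP: one inter-stimulus
interval), half-open ``[start, end)``; success and asynchronous windows
partition each inter-AP interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import APTrain, make_ap_train

__all__ = [
    "APTrain",
    "make_ap_train",
    "PairTrainRecord",
    "per_ap_measures",
    "summarize_dynamics",
    "async_release_rate",
    "intersomatic_distance",
    "export_model_table",
    "SUCCESS_WINDOW_MS",
]

SUCCESS_WINDOW_MS = 3.0


def per_ap_measures(event_times: np.ndarray, event_amplitudes: np.ndarray,
                    train: APTrain, window_ms: float = SUCCESS_WINDOW_MS
                    ) -> pd.DataFrame:
    """Per-AP success/amplitude/latency for one sweep.

    An AP is a success iff at least one event peak lies in
    ``(t_AP, t_AP + window_ms]``; the first such event is measured.
    """
    t = np.asarray(event_times, dtype=float)
    amp = np.asarray(event_amplitudes, dtype=float)
    order = np.argsort(t, kind="stable")
    t, amp = t[order], amp[order]
    if train.freq > 1000.0 / window_ms:
        raise ValueError("AP interval shorter than the success window")
    rows = []
    for i, t_ap in enumerate(train.ap_peak_times):
        in_win = np.flatnonzero((t > t_ap) & (t <= t_ap + window_ms))
        if in_win.size:
            j = int(in_win[0])
            rows.append(
                dict(
                    sweep_id=train.sweep_id,
                    ap_index=i + 1,
                    success=True,
                    amplitude_pA=float(amp[j]),
                    latency_ms=float(t[j] - t_ap),
                )
            )
        else:
            rows.append(
                dict(
                    sweep_id=train.sweep_id,
                    ap_index=i + 1,
                    success=False,
                    amplitude_pA=0.0,
                    latency_ms=np.nan,
                )
            )
    return pd.DataFrame(rows)


def async_release_rate(event_times: np.ndarray, train: APTrain,
                       window_ms: float = SUCCESS_WINDOW_MS) -> pd.DataFrame:
    """Per-AP asynchronous release rate (Hz) for one sweep.

    Window for AP i < 10: ``[t_i + window_ms, t_{i+1})``; for the last AP
    the window length is one inter-stimulus interval.
    """
    t = np.asarray(event_times, dtype=float)
    t_ap = train.ap_peak_times
    isi = train.isi_ms
    rows = []
    for i in range(t_ap.size):
        w0 = t_ap[i] + window_ms
        w1 = t_ap[i + 1] if i + 1 < t_ap.size else t_ap[i] + isi
        dur_s = (w1 - w0) / 1000.0
        n = int(np.count_nonzero((t >= w0) & (t < w1)))
        rows.append(
            dict(
                sweep_id=train.sweep_id,
                ap_index=i + 1,
                n_events=n,
                window_ms=w1 - w0,
                rate_hz=n / dur_s if dur_s > 0 else np.nan,
            )
        )
    return pd.DataFrame(rows)


@dataclass
class PairTrainRecord:
    """All sweeps of one pair at one frequency, measured per AP."""

    pair_id: str
    pair_type: str
    freq: float
    measures: pd.DataFrame  # rows: sweep_id, ap_index, success, amplitude_pA, latency_ms
    async_rates: pd.DataFrame = field(default_factory=pd.DataFrame)
    condition: str = "NR"
    soma_offsets: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def n_sweeps(self) -> int:
        return self.measures["sweep_id"].nunique()


def summarize_dynamics(record: PairTrainRecord, min_sweeps: int = 5) -> pd.DataFrame:
    """Per-AP success rate, strength, and potency of one record."""
    if len(record.measures) == 0:
        raise ValueError("empty record")
    if record.n_sweeps < min_sweeps:
        raise ValueError(
            f"need at least {min_sweeps} sweeps, got {record.n_sweeps}"
        )
    g = record.measures.groupby("ap_index", sort=True)
    out = pd.DataFrame(
        {
            "success_rate": g["success"].mean(),
            "strength_pA": g["amplitude_pA"].mean(),
            "potency_pA": g.apply(
                lambda d: d.loc[d["success"], "amplitude_pA"].mean(),
                include_groups=False,
            ),
        }
    ).reset_index()
    out.insert(0, "pair_id", record.pair_id)
    out.insert(1, "pair_type", record.pair_type)
    out.insert(2, "condition", record.condition)
    out.insert(3, "freq_hz", record.freq)
    return out


def intersomatic_distance(offsets) -> float:
    """Euclidean distance (um) between the two somata from (dx, dy, dz)."""
    v = np.asarray(offsets, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("offsets must be finite")
    return float(np.sqrt(np.sum(v**2)))


def export_model_table(summaries: list[pd.DataFrame],
                       async_summaries: list[pd.DataFrame] | None = None
                       ) -> pd.DataFrame:
    """Long-format analysis-ready table for mixed-model packages.

    One row per (cell, pair type, condition, frequency, AP, parameter):
    columns ``cell_id, pair_type, condition, freq_hz, ap_index, parameter,
    value`` with parameters ``success_rate``, ``strength_pA``,
    ``potency_pA`` and, when asynchronous summaries are supplied,
    ``async_rate_hz``.  Missing factor levels raise.
    """
    frames = []
    for s in summaries:
        melted = s.melt(
            id_vars=["pair_id", "pair_type", "condition", "freq_hz", "ap_index"],
            value_vars=["success_rate", "strength_pA", "potency_pA"],
            var_name="parameter",
            value_name="value",
        )
        frames.append(melted)
    if async_summaries:
        for s in async_summaries:
            frames.append(
                s.rename(columns={"rate_hz": "value"}).assign(
                    parameter="async_rate_hz"
                )[
                    ["pair_id", "pair_type", "condition", "freq_hz", "ap_index",
                     "parameter", "value"]
                ]
            )
    table = pd.concat(frames, ignore_index=True).rename(
        columns={"pair_id": "cell_id"}
    )
    factor_cols = ["cell_id", "pair_type", "condition", "freq_hz", "ap_index",
                   "parameter"]
    if table[factor_cols].isna().any().any():
        bad = table[factor_cols].isna().any()
        raise ValueError(
            f"missing factor levels in columns: {list(bad[bad].index)}"
        )
    return table[factor_cols + ["value"]]
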