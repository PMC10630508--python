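"""End-to-end recovery benchmarks of the analysis pipeline.

Each function builds synthetic inputs with known ground truth at the
generator's default study conditions, runs the corresponding analysis
stage from scratch, and reports how well the generating quantities are
recovered.  They are used by the acceptance checks and are convenient for
profiling changes to the pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import synthio, trains as trains_mod
from .containers import SweepRecording
from .events import detect_events, events_from_ground_truth
from .idealize import BetaKernel, LifNeuron, lif_playback, synthesize_idealized_trace
from .typing import classify_pair, classify_with_model, fit_rotation_model

__all__ = [
    "clustering_recovery",
    "pair_typing_accuracy",
    "train_statistics_recovery",
    "idealization_closure",
]


def clustering_recovery(n_cells: int = 20, events_per_cell: int = 200,
                        seed: int = 0) -> dict:
    """Label recovery of the rotation/GMM typing on two-arm cells.

    Cells draw their S-proportion from U(0.1, 0.9).  Returns per-cell
    adjusted Rand indices and the mean absolute error of the estimated
    S-proportions.
    """
    rng = np.random.default_rng(seed)
    aris, errs = [], []
    for k in range(n_cells):
        sf = float(rng.uniform(0.1, 0.9))
        spec = synthio.CellSpec(
            cell_id=f"cell{k:02d}", s_fraction=sf,
            seed=int(rng.integers(2**31 - 1)),
        )
        ev = synthio.sample_cell_events(spec, n_events=events_per_cell)
        tab = events_from_ground_truth(ev)
        model = fit_rotation_model(tab, seed=seed)
        typed = classify_with_model(tab, model)
        aris.append(float(adjusted_rand_score(ev["true_label"], typed["label"])))
        errs.append(
            float(abs((typed["label"] == "S").mean() - (ev["true_label"] == "S").mean()))
        )
    return dict(
        ari_per_cell=aris,
        min_ari=float(np.min(aris)),
        mean_ari=float(np.mean(aris)),
        s_proportion_mae=float(np.mean(errs)),
        n_cells=n_cells,
    )


def pair_typing_accuracy(n_per_class: int = 100, n_sweeps: int = 15,
                         seed: int = 0) -> dict:
    """Pair-type recovery: in-cell sEPSC model classifies the evoked events."""
    rng = np.random.default_rng(seed)
    records = []
    for ptype in ("S", "F", "Mixed"):
        for k in range(n_per_class):
            spec = synthio.PairSpec(
                pair_id=f"{ptype}{k:03d}", pair_type=ptype,
                freq=float(synthio.PAIR_FREQS[k % 4]), n_sweeps=n_sweeps,
                seed=int(rng.integers(2**31 - 1)),
            )
            _, truth = synthio.sample_pair_events(spec)
            ev = events_from_ground_truth(truth.events)
            model = fit_rotation_model(ev[ev["source"] == "spontaneous"], seed=seed)
            uni = classify_with_model(ev[ev["source"] == "unitary"], model)
            records.append(dict(truth=ptype, assigned=classify_pair(uni)))
    df = pd.DataFrame(records)
    acc = float((df["truth"] == df["assigned"]).mean())
    confusion = df.groupby(["truth", "assigned"]).size().unstack(fill_value=0)
    return dict(accuracy=acc, n_pairs=len(df), confusion=confusion)


def train_statistics_recovery(n_sweeps: int = 200, seed: int = 0) -> dict:
    """Per-AP success-rate and asynchronous-rate recovery at known truth.

    Measurement runs on the event tables the way it would on detected
    events (sources are not consulted), so the expected success
    probability includes the chance of a background event landing in the
    3-ms window, and the expected asynchronous-window rate includes the
    background rate.  Reports worst-case errors in units of the binomial
    / Poisson standard error, and the largest violation of the
    strength = success_rate x potency identity.
    """
    spec = synthio.PairSpec(
        pair_id="recov", pair_type="S", freq=20.0, n_sweeps=n_sweeps, seed=seed
    )
    trains, truth = synthio.sample_pair_events(spec)
    ev = truth.events
    measures, rates = [], []
    for train in trains:
        sub = ev[ev["sweep_id"] == train.sweep_id]
        measures.append(
            trains_mod.per_ap_measures(
                sub["event_time_ms"].to_numpy(), sub["amplitude_pA"].to_numpy(), train
            )
        )
        rates.append(
            trains_mod.async_release_rate(
                sub.loc[sub["source"] != "unitary", "event_time_ms"].to_numpy(), train
            )
        )
    record = trains_mod.PairTrainRecord(
        pair_id=spec.pair_id, pair_type="S", freq=spec.freq,
        measures=pd.concat(measures, ignore_index=True),
    )
    summary = trains_mod.summarize_dynamics(record)

    # success: evoked Bernoulli OR a background event in the 3-ms window
    p_bg = 1.0 - np.exp(-spec.background_rate * 3.0 / 1000.0)
    succ_z = []
    for i, p in enumerate(spec.per_ap_release_prob, start=1):
        p_exp = 1.0 - (1.0 - p) * (1.0 - p_bg)
        se = np.sqrt(p_exp * (1 - p_exp) / n_sweeps)
        got = summary.loc[summary["ap_index"] == i, "success_rate"].item()
        succ_z.append(abs(got - p_exp) / se)

    rate_tab = pd.concat(rates).groupby("ap_index")[["rate_hz", "window_ms"]].mean()
    async_z = []
    for i, f in enumerate(spec.async_facilitation, start=1):
        lam = spec.async_base_rate * f + spec.background_rate
        win_s = rate_tab.loc[i, "window_ms"] / 1000.0
        se = np.sqrt(lam / (win_s * n_sweeps))
        async_z.append(abs(rate_tab.loc[i, "rate_hz"] - lam) / se)

    ok = summary["potency_pA"].notna()
    identity_err = float(
        np.max(
            np.abs(
                summary.loc[ok, "strength_pA"]
                - summary.loc[ok, "success_rate"] * summary.loc[ok, "potency_pA"]
            )
        )
    )
    return dict(
        success_rate_max_z=float(np.max(succ_z)),
        async_rate_max_z=float(np.max(async_z)),
        strength_identity_max_err_pa=identity_err,
        n_sweeps=n_sweeps,
    )


def idealization_closure(seed: int = 0) -> dict:
    """Synthesize -> detect -> measure closure and LIF oracle agreement."""
    kernel = BetaKernel(amplitude=1.0, tau_rise=1.0, tau_decay=8.0)
    strengths = np.linspace(10, 50, 10)
    tr = synthesize_idealized_trace(kernel, strengths, freq=10.0)
    rec = SweepRecording(samples=-tr.samples, sampling_rate=tr.sampling_rate)
    det = detect_events(rec, threshold=5.0).sort_values("event_time_ms")
    if len(det) != 10:
        rel_err = float("inf")
    else:
        rel_err = float(
            np.max(np.abs(det["amplitude_pA"].to_numpy() - strengths) / strengths)
        )

    neuron = LifNeuron()
    i_pa, gain, dur_ms = 5.0, 25.0, 1000.0
    fs = 10_000.0
    const = np.full(int(dur_ms / 1000.0 * fs), i_pa)
    _, n_spikes, _ = lif_playback(const, gain=gain, neuron=neuron, sampling_rate=fs)
    drive = neuron.r_input * gain * i_pa * 1e-3
    isi = neuron.tau_m * np.log(
        (drive - (neuron.v_reset - neuron.v_rest))
        / (drive - (neuron.v_threshold - neuron.v_rest))
    ) + neuron.refractory
    t_first = neuron.tau_m * np.log(drive / (drive - (neuron.v_threshold - neuron.v_rest)))
    expected = 1 + int((dur_ms - t_first) // isi)

    tr40 = synthesize_idealized_trace(kernel, np.linspace(2, 10, 10), freq=40.0)
    counts = [lif_playback(tr40, gain=g)[1] for g in (5, 10, 15, 20, 25, 30)]
    monotone = bool(all(b >= a for a, b in zip(counts, counts[1:])))

    return dict(
        strength_recovery_max_rel_err=rel_err,
        lif_spike_count=int(n_spikes),
        lif_expected_spike_count=int(expected),
        lif_count_abs_diff=int(abs(n_spikes - expected)),
        gain_monotone=monotone,
    )
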