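"""File formats, configuration, and the end-to-end pipeline driver.

Trace container: HDF5 with datasets ``/sweeps/<id>/current`` (pA) and
attributes ``sampling_rate_hz``, ``holding_mV``, optional ``rs_start`` /
``rs_end``; AP trains as ``/sweeps/<id>/ap_peak_times_ms``.  Tables are
UTF-8 comma-separated CSV with '.' decimals and a header; times in ms,
currents in pA, charge in fC.  Every run writes a manifest carrying the
config hash and seeds so artifacts from different runs cannot be mixed
silently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import synthio, trains as trains_mod
from .containers import APTrain, CellEventSet, EVENT_COLUMNS, SweepRecording
from .events import detect_events, events_from_ground_truth, qc_filter_cells
from .kernels import eval_kernel
from .idealize import (
    LifNeuron,
    fit_beta_kernel,
    fit_strength_trend,
    lif_playback,
    synthesize_idealized_trace,
)
from .typing import RotationModel, classify_pair, classify_with_model, fit_rotation_model

__all__ = [
    "PipelineConfig",
    "write_traces_h5",
    "read_traces_h5",
    "write_events_csv",
    "read_events_csv",
    "write_model_json",
    "read_model_json",
    "config_hash",
    "run_pipeline",
]

REQUIRED_EVENT_COLUMNS = [
    "cell_id",
    "event_time_ms",
    "amplitude_pA",
    "charge_fC",
]


# ---------------------------------------------------------------------------
# containers on disk


def write_traces_h5(path, sweeps: list[SweepRecording],
                    ap_trains: list[APTrain] | None = None,
                    config_digest: str | None = None) -> None:
    trains_by_id = {t.sweep_id: t for t in (ap_trains or [])}
    with h5py.File(path, "w") as f:
        if config_digest:
            f.attrs["config_hash"] = config_digest
        grp = f.create_group("sweeps")
        for sw in sweeps:
            g = grp.create_group(sw.sweep_id)
            g.create_dataset("current", data=sw.samples)
            g.attrs["sampling_rate_hz"] = sw.sampling_rate
            g.attrs["holding_mV"] = sw.holding_potential
            if sw.rs_start is not None:
                g.attrs["rs_start"] = sw.rs_start
            if sw.rs_end is not None:
                g.attrs["rs_end"] = sw.rs_end
            if sw.sweep_id in trains_by_id:
                t = trains_by_id[sw.sweep_id]
                d = g.create_dataset("ap_peak_times_ms", data=t.ap_peak_times)
                d.attrs["freq_hz"] = t.freq


def read_traces_h5(path) -> tuple[list[SweepRecording], list[APTrain]]:
    sweeps: list[SweepRecording] = []
    ap_trains: list[APTrain] = []
    with h5py.File(path, "r") as f:
        for sid in f["sweeps"]:
            g = f["sweeps"][sid]
            sweeps.append(
                SweepRecording(
                    samples=g["current"][...],
                    sampling_rate=float(g.attrs["sampling_rate_hz"]),
                    sweep_id=sid,
                    holding_potential=float(g.attrs.get("holding_mV", -80.0)),
                    rs_start=(float(g.attrs["rs_start"]) if "rs_start" in g.attrs else None),
                    rs_end=(float(g.attrs["rs_end"]) if "rs_end" in g.attrs else None),
                )
            )
            if "ap_peak_times_ms" in g:
                d = g["ap_peak_times_ms"]
                ap_trains.append(
                    APTrain(
                        ap_peak_times=d[...],
                        freq=float(d.attrs["freq_hz"]),
                        sweep_id=sid,
                    )
                )
    return sweeps, ap_trains


def write_events_csv(path, events: pd.DataFrame) -> None:
    events.to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events CSV {path} is missing required column(s): {missing}")
    if "ln_amplitude" not in df.columns:
        df["ln_amplitude"] = np.log(df["amplitude_pA"])
    if "ln_charge" not in df.columns:
        df["ln_charge"] = np.log(df["charge_fC"])
    return df


def write_model_json(path, model: RotationModel) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def read_model_json(path) -> RotationModel:
    return RotationModel.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# configuration


@dataclasses.dataclass
class PipelineConfig:
    """Serializable configuration of a full pipeline run."""

    seed: int = 0
    n_cells: int = 3
    events_per_cell: int = 250
    n_pairs_per_type: int = 1
    pair_sweeps: int = 12
    pair_freqs: tuple = (10.0, 40.0)
    render_trace_cell: bool = True
    trace_duration_s: float = 20.0
    detection_threshold_pa: float = 5.0
    min_separation_ms: float = 10.0
    playback_gain: float = 25.0
    stages: tuple = ("simulate", "detect", "type", "trains", "idealize", "playback")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("pair_freqs", "stages"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pair_freqs"] = list(d["pair_freqs"])
        d["stages"] = list(d["stages"])
        return d


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# pipeline driver


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run simulate -> detect -> type -> trains -> idealize -> playback.

    Writes all outputs plus a manifest into ``out_dir`` and returns it.
    Stage toggles are honored; downstream stages refuse to run without
    their upstream products.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config_hash(config)
    stages = set(config.stages)
    rng = np.random.default_rng(config.seed)

    cell_specs = []
    pair_specs = []
    mini_events = None
    typed_all = None
    models: dict[str, RotationModel] = {}

    if "simulate" in stages:
        s_fracs = rng.uniform(0.2, 0.8, config.n_cells)
        cell_specs = [
            synthio.CellSpec(
                cell_id=f"cell{i:02d}",
                s_fraction=float(s_fracs[i]),
                seed=int(rng.integers(2**31 - 1)),
            )
            for i in range(config.n_cells)
        ]
        tables = [
            synthio.sample_cell_events(cs, n_events=config.events_per_cell)
            for cs in cell_specs
        ]
        mini_truth = pd.concat(tables, ignore_index=True)
        mini_events = events_from_ground_truth(mini_truth)
        write_events_csv(out / "mini_events.csv", mini_events)
        mini_truth.to_csv(out / "mini_ground_truth.csv", index=False)

        for ptype in ("S", "F", "Mixed"):
            for freq in config.pair_freqs:
                pair_specs.append(
                    synthio.PairSpec(
                        pair_id=f"pair_{ptype}",
                        pair_type=ptype,
                        freq=float(freq),
                        n_sweeps=config.pair_sweeps,
                        seed=int(rng.integers(2**31 - 1)),
                    )
                )
        if config.render_trace_cell:
            rec, truth = synthio.generate_mepsc_trace(
                cell_specs[0], duration_s=config.trace_duration_s
            )
            write_traces_h5(out / "traces.h5", [rec], config_digest=digest)
            truth.events.to_csv(out / "trace_ground_truth.csv", index=False)

    if "detect" in stages:
        if not (out / "traces.h5").exists():
            raise RuntimeError("detect stage requires the simulate stage's traces.h5")
        sweeps, _ = read_traces_h5(out / "traces.h5")
        det = pd.concat(
            [
                detect_events(
                    sw,
                    threshold=config.detection_threshold_pa,
                    min_separation=config.min_separation_ms,
                )
                for sw in sweeps
            ],
            ignore_index=True,
        )
        write_events_csv(out / "detected_events.csv", det)

    if "type" in stages:
        if mini_events is None:
            raise RuntimeError("type stage requires the simulate stage's event tables")
        cells = [
            CellEventSet(
                cell_id=cs.cell_id,
                events=mini_events[mini_events["cell_id"] == cs.cell_id],
                rs_start=cs.rs_start,
                rs_end=cs.rs_end,
            )
            for cs in cell_specs
        ]
        kept, excl = qc_filter_cells(cells, context="mini")
        excl.to_csv(out / "qc_exclusions.csv", index=False)
        typed_parts = []
        props = []
        for cell in kept:
            model = fit_rotation_model(cell.events, seed=config.seed, cell_id=cell.cell_id)
            models[cell.cell_id] = model
            write_model_json(out / f"model_{cell.cell_id}.json", model)
            typed = classify_with_model(cell.events, model)
            typed_parts.append(typed)
            props.append(
                dict(
                    cell_id=cell.cell_id,
                    s_proportion=float((typed["label"] == "S").mean()),
                    theta_deg=model.theta_star_deg,
                    low_confidence=model.low_confidence,
                )
            )
        typed_all = pd.concat(typed_parts, ignore_index=True)
        write_events_csv(out / "typed_events.csv", typed_all)
        pd.DataFrame(props).to_csv(out / "cell_proportions.csv", index=False)

    summaries = []
    async_summaries = []
    if "trains" in stages:
        if "type" not in stages:
            raise RuntimeError(
                "trains stage requires the type stage (in-cell sEPSC models)"
            )
        pair_rows = []
        for spec in pair_specs:
            ap_trains, truth = synthio.sample_pair_events(spec)
            ev = events_from_ground_truth(truth.events)
            spont = ev[ev["source"] == "spontaneous"]
            model = fit_rotation_model(spont, seed=config.seed, cell_id=spec.pair_id)
            uni = classify_with_model(ev[ev["source"] == "unitary"], model)
            ptype_hat = classify_pair(uni)
            pair_rows.append(
                dict(
                    pair_id=spec.pair_id,
                    freq_hz=spec.freq,
                    true_type=spec.pair_type,
                    assigned_type=ptype_hat,
                    intersomatic_um=trains_mod.intersomatic_distance(spec.soma_offsets),
                )
            )
            measures = []
            rates = []
            for train in ap_trains:
                sub = ev[ev["sweep_id"] == train.sweep_id]
                evoked = sub[sub["source"].isin(["unitary", "spontaneous"])]
                measures.append(
                    trains_mod.per_ap_measures(
                        evoked["event_time_ms"].to_numpy(),
                        evoked["amplitude_pA"].to_numpy(),
                        train,
                    )
                )
                late = sub[sub["source"].isin(["async", "spontaneous"])]
                rates.append(
                    trains_mod.async_release_rate(late["event_time_ms"].to_numpy(), train)
                )
            record = trains_mod.PairTrainRecord(
                pair_id=spec.pair_id,
                pair_type=spec.pair_type,
                freq=spec.freq,
                measures=pd.concat(measures, ignore_index=True),
                async_rates=pd.concat(rates, ignore_index=True),
                soma_offsets=spec.soma_offsets,
            )
            summ = trains_mod.summarize_dynamics(record)
            summaries.append(summ)
            g = record.async_rates.groupby("ap_index")["rate_hz"].mean().reset_index()
            g.insert(0, "pair_id", spec.pair_id)
            g.insert(1, "pair_type", spec.pair_type)
            g.insert(2, "condition", "NR")
            g.insert(3, "freq_hz", spec.freq)
            async_summaries.append(g)
        pd.DataFrame(pair_rows).to_csv(out / "pair_types.csv", index=False)
        pd.concat(summaries, ignore_index=True).to_csv(
            out / "per_ap_summary.csv", index=False
        )
        pd.concat(async_summaries, ignore_index=True).to_csv(
            out / "async_rates.csv", index=False
        )
        table = trains_mod.export_model_table(summaries, async_summaries)
        table.to_csv(out / "model_table.csv", index=False)

    ideal_rows = []
    if "idealize" in stages:
        if not summaries:
            raise RuntimeError("idealize stage requires the trains stage's summaries")
        traces = {}
        for summ in summaries:
            ptype = summ["pair_type"].iloc[0]
            freq = float(summ["freq_hz"].iloc[0])
            spec = next(
                s for s in pair_specs if s.pair_type == ptype and s.freq == freq
            )
            # average uEPSC of the condition, rendered noiselessly
            label = ptype if ptype in ("S", "F") else "S"
            pop = spec.population(label)
            fs = 10_000.0
            t = np.arange(int(0.06 * fs)) / fs * 1000.0
            seg = spec.potency(label) * eval_kernel(t - 1.0, pop.tau_rise, pop.tau_decay)
            kernel = fit_beta_kernel(seg, fs)
            intercept, slope, series = fit_strength_trend(
                summ.sort_values("ap_index")["strength_pA"].to_numpy()
            )
            ideal = synthesize_idealized_trace(
                kernel, series, freq, pair_type=ptype, condition="NR"
            )
            traces[(ptype, freq)] = ideal
            ideal_rows.append(
                dict(
                    pair_type=ptype,
                    freq_hz=freq,
                    intercept_pa=intercept,
                    slope_pa_per_ap=slope,
                    tau_rise_ms=kernel.tau_rise,
                    tau_decay_ms=kernel.tau_decay,
                )
            )
        write_traces_h5(
            out / "idealized.h5",
            [
                SweepRecording(
                    samples=tr.samples,
                    sampling_rate=tr.sampling_rate,
                    sweep_id=f"ideal_{pt}_{int(fq)}Hz",
                )
                for (pt, fq), tr in traces.items()
            ],
            config_digest=digest,
        )
        pd.DataFrame(ideal_rows).to_csv(out / "idealized_params.csv", index=False)

        if "playback" in stages:
            rows = []
            for (ptype, freq), tr in traces.items():
                _, n_spikes, _ = lif_playback(tr, gain=config.playback_gain)
                rows.append(
                    dict(
                        pair_type=ptype,
                        freq_hz=freq,
                        gain=config.playback_gain,
                        spike_count=n_spikes,
                    )
                )
            pd.DataFrame(rows).to_csv(out / "playback_spikes.csv", index=False)

    manifest = dict(
        config=config.to_dict(),
        config_hash=digest,
        stages_run=sorted(stages),
        outputs=sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
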