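"""Synthetic EPSC recordings with ground truth.

Emulates the statistical structure of the recordings the analysis assumes:

* miniature/spontaneous EPSC traces containing two event populations
  (slow "S" and fast "F") whose ln(amplitude)/ln(charge) points fall on two
  slope-1 arms with distinct offsets, in per-cell proportions;
* paired-recording sweeps with trains of 10 presynaptic APs at 5/10/20/40 Hz,
  facilitating per-AP release probabilities, ~1 ms evoked latency,
  stimulus-locked plus asynchronous release, and background spontaneous
  events so every pair carries an in-cell sEPSC basis;
* recording noise and series-resistance QC metadata.

Amplitudes are lognormal per arm and ln(charge) = ln(amplitude) + offset +
noise; per-event decay constants are solved from the drawn charge/amplitude
ratio, so rendered traces reproduce the drawn features exactly.  Every event
summed into a trace has exactly one ground-truth row.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import APTrain, GroundTruth, SweepRecording, make_ap_train
from .kernels import charge_factor, eval_kernel, solve_tau_decay

__all__ = [
    "EventPopulationSpec",
    "CellSpec",
    "PairSpec",
    "default_populations",
    "sample_cell_events",
    "generate_mepsc_trace",
    "sample_pair_events",
    "generate_pair_sweeps",
    "PAIR_FREQS",
]

PAIR_FREQS = (5.0, 10.0, 20.0, 40.0)


@dataclass(frozen=True)
class EventPopulationSpec:
    """One event population: amplitude/charge statistics and kinetics.

    ``ln(charge) = ln(amplitude) + charge_offset + N(0, charge_noise_sd)``,
    charge in fC, amplitude in pA, kinetics in ms, rate in Hz.
    """

    label: str
    mean_ln_amplitude: float
    sd_ln_amplitude: float
    charge_offset: float
    charge_noise_sd: float
    tau_rise: float
    tau_decay: float
    rate: float

    def __post_init__(self):
        if self.label not in ("S", "F"):
            raise ValueError("population label must be 'S' or 'F'")
        if not (self.tau_decay > self.tau_rise > 0):
            raise ValueError("need tau_decay > tau_rise > 0")
        if self.sd_ln_amplitude < 0 or self.charge_noise_sd < 0:
            raise ValueError("sd terms must be >= 0")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")


def default_populations() -> tuple[EventPopulationSpec, EventPopulationSpec]:
    """Default S (slow, high charge) and F (fast, high amplitude) populations.

    Charge offsets equal the log of the kernel charge factor so drawn
    features and rendered kinetics agree; S carries more charge per pA,
    F has the larger amplitudes, matching the two-arm geometry of the
    amplitude-vs-charge scatter the typing stage exploits.
    """
    s = EventPopulationSpec(
        label="S",
        mean_ln_amplitude=float(np.log(15.0)),
        sd_ln_amplitude=0.35,
        charge_offset=float(np.log(charge_factor(1.0, 8.0))),
        charge_noise_sd=0.15,
        tau_rise=1.0,
        tau_decay=8.0,
        rate=2.0,
    )
    f = EventPopulationSpec(
        label="F",
        mean_ln_amplitude=float(np.log(25.0)),
        sd_ln_amplitude=0.35,
        charge_offset=float(np.log(charge_factor(0.3, 2.0))),
        charge_noise_sd=0.15,
        tau_rise=0.3,
        tau_decay=2.0,
        rate=1.0,
    )
    return s, f


@dataclass(frozen=True)
class CellSpec:
    """One simulated cell: populations, S-proportion, noise, and QC metadata."""

    cell_id: str = "cell0"
    condition: str = "NR"
    s_fraction: float | None = None  # None: implied by the population rates
    populations: tuple[EventPopulationSpec, EventPopulationSpec] = field(
        default_factory=default_populations
    )
    noise_sd: float = 2.0  # pA
    rs_start: float = 15.0  # MOhm
    rs_end: float = 16.0
    seed: int = 0

    def __post_init__(self):
        if self.s_fraction is not None and not (0.0 <= self.s_fraction <= 1.0):
            raise ValueError("s_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        labels = sorted(p.label for p in self.populations)
        if labels != ["F", "S"]:
            raise ValueError("populations must be one 'S' and one 'F' spec")

    def population(self, label: str) -> EventPopulationSpec:
        for p in self.populations:
            if p.label == label:
                return p
        raise KeyError(label)

    def effective_rates(self) -> dict[str, float]:
        """Per-population rates; s_fraction, when set, splits the total rate."""
        total = sum(p.rate for p in self.populations)
        if self.s_fraction is None or total == 0:
            return {p.label: p.rate for p in self.populations}
        return {"S": total * self.s_fraction, "F": total * (1.0 - self.s_fraction)}


def _draw_population_features(pop: EventPopulationSpec, n: int,
                              rng: np.random.Generator) -> pd.DataFrame:
    """Draw n (amplitude, charge, kinetics) feature rows for one population."""
    ln_amp = rng.normal(pop.mean_ln_amplitude, pop.sd_ln_amplitude, n)
    ln_q = ln_amp + pop.charge_offset + rng.normal(0.0, pop.charge_noise_sd, n)
    amp = np.exp(ln_amp)
    q = np.exp(ln_q)
    tau_d = np.array(
        [solve_tau_decay(pop.tau_rise, qi / ai) for qi, ai in zip(q, amp)]
    )
    return pd.DataFrame(
        {
            "true_label": pop.label,
            "amplitude_pA": amp,
            "charge_fC": q,
            "tau_rise_ms": pop.tau_rise,
            "tau_decay_ms": tau_d,
        }
    )


def sample_cell_events(spec: CellSpec, duration_s: float | None = None,
                       n_events: int | None = None,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw ground-truth mEPSC events for one cell.

    Either ``duration_s`` (homogeneous Poisson event times per population) or
    ``n_events`` (fixed count, labels Bernoulli(s_fraction), times uniform on
    100 s) must be given.
    """
    if (duration_s is None) == (n_events is None):
        raise ValueError("give exactly one of duration_s or n_events")
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    rates = spec.effective_rates()
    parts: list[pd.DataFrame] = []
    if duration_s is not None:
        if duration_s <= 0:
            raise ValueError("duration must be positive")
        horizon_ms = duration_s * 1000.0
        for label in ("S", "F"):
            n = rng.poisson(rates[label] * duration_s)
            df = _draw_population_features(spec.population(label), n, rng)
            df["event_time_ms"] = np.sort(rng.uniform(0.0, horizon_ms, n))
            parts.append(df)
    else:
        sf = spec.s_fraction
        if sf is None:
            total = sum(rates.values())
            sf = rates["S"] / total if total > 0 else 0.5
        n_s = int(rng.binomial(n_events, sf))
        horizon_ms = 100_000.0
        for label, n in (("S", n_s), ("F", n_events - n_s)):
            df = _draw_population_features(spec.population(label), n, rng)
            df["event_time_ms"] = np.sort(rng.uniform(0.0, horizon_ms, n))
            parts.append(df)

    events = pd.concat(parts, ignore_index=True)
    events = events.sort_values("event_time_ms", ignore_index=True)
    events.insert(0, "cell_id", spec.cell_id)
    events["source"] = "mini"
    return events


def _render_events(n_samples: int, sampling_rate: float,
                   events: pd.DataFrame) -> np.ndarray:
    """Sum negative-going kernels into a zero-baseline trace (pA)."""
    trace = np.zeros(n_samples)
    dt_ms = 1000.0 / sampling_rate
    for row in events.itertuples(index=False):
        i0 = int(np.ceil(row.event_time_ms / dt_ms))
        span_ms = row.tau_decay_ms * 8.0
        i1 = min(n_samples, i0 + int(span_ms / dt_ms) + 1)
        if i0 >= n_samples:
            continue
        t = np.arange(i0, i1) * dt_ms - row.event_time_ms
        trace[i0:i1] -= row.amplitude_pA * eval_kernel(
            t, row.tau_rise_ms, row.tau_decay_ms
        )
    return trace


def generate_mepsc_trace(spec: CellSpec, duration_s: float,
                         sampling_rate: float = 10_000.0
                         ) -> tuple[SweepRecording, GroundTruth]:
    """Render a continuous mEPSC recording plus its ground truth.

    The trace is baseline (0 pA) + summed negative kernels + Gaussian noise.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(spec.seed)
    events = sample_cell_events(spec, duration_s=duration_s, rng=rng)
    n_samples = int(round(duration_s * sampling_rate))
    trace = _render_events(n_samples, sampling_rate, events)
    if spec.noise_sd > 0:
        trace = trace + rng.normal(0.0, spec.noise_sd, n_samples)
    rec = SweepRecording(
        samples=trace,
        sampling_rate=sampling_rate,
        sweep_id=f"{spec.cell_id}_mini",
        rs_start=spec.rs_start,
        rs_end=spec.rs_end,
    )
    return rec, GroundTruth(events=events)


# ---------------------------------------------------------------------------
# paired recordings


@dataclass(frozen=True)
class PairSpec:
    """One simulated PC->SOM pair at one stimulation frequency.

    ``per_ap_release_prob`` are the 10 per-AP Bernoulli success
    probabilities; ``async_facilitation`` multiplies ``async_base_rate``
    in each inter-AP window.  ``potency_amplitude`` maps the synapse type
    to its mean evoked amplitude (pA).  Background spontaneous events use
    the cell populations so each pair carries an sEPSC basis for typing.
    """

    pair_id: str = "pair0"
    pair_type: str = "Mixed"  # S, F, or Mixed
    freq: float = 20.0
    n_sweeps: int = 15
    per_ap_release_prob: tuple = (0.30, 0.37, 0.43, 0.49, 0.55, 0.60, 0.65, 0.69, 0.72, 0.75)
    potency_amplitude: tuple[tuple[str, float], ...] = (("S", 20.0), ("F", 30.0))
    potency_ln_sd: float = 0.25
    latency_mean_ms: float = 1.0
    latency_sd_ms: float = 0.3
    async_base_rate: float = 5.0  # Hz
    async_facilitation: tuple = (1.0, 1.2, 1.5, 1.8, 2.1, 2.4, 2.7, 3.0, 3.2, 3.4)
    background_rate: float = 3.0  # Hz of spontaneous events over the sweep
    background_s_fraction: float = 0.5
    intertrain_interval_s: float = 10.0  # trains delivered every 10 s
    populations: tuple[EventPopulationSpec, EventPopulationSpec] = field(
        default_factory=default_populations
    )
    soma_offsets: tuple[float, float, float] = (30.0, 40.0, 10.0)  # um
    rs_start: float = 20.0
    rs_end: float = 21.0
    seed: int = 0

    def __post_init__(self):
        if self.pair_type not in ("S", "F", "Mixed"):
            raise ValueError("pair_type must be S, F, or Mixed")
        if self.freq not in PAIR_FREQS:
            raise ValueError(f"freq must be one of {PAIR_FREQS}")
        if len(self.per_ap_release_prob) != 10:
            raise ValueError("need 10 per-AP release probabilities")
        p = np.asarray(self.per_ap_release_prob, float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("release probabilities must be in [0, 1]")
        if len(self.async_facilitation) != 10:
            raise ValueError("need 10 asynchronous facilitation multipliers")
        if self.async_base_rate < 0 or np.any(np.asarray(self.async_facilitation) < 0):
            raise ValueError("asynchronous rates must be >= 0")

    def population(self, label: str) -> EventPopulationSpec:
        for pop in self.populations:
            if pop.label == label:
                return pop
        raise KeyError(label)

    def potency(self, label: str) -> float:
        return dict(self.potency_amplitude)[label]

    def sweep_duration_ms(self, start_ms: float = 50.0, tail_ms: float = 100.0) -> float:
        return start_ms + 10 * 1000.0 / self.freq + tail_ms


def _draw_typed_event(pop: EventPopulationSpec, ln_amp_mean: float, ln_amp_sd: float,
                      rng: np.random.Generator) -> tuple[float, float, float]:
    """(amplitude, charge, tau_decay) for one event on the population's arm."""
    ln_amp = rng.normal(ln_amp_mean, ln_amp_sd)
    ln_q = ln_amp + pop.charge_offset + rng.normal(0.0, pop.charge_noise_sd)
    amp, q = float(np.exp(ln_amp)), float(np.exp(ln_q))
    return amp, q, float(solve_tau_decay(pop.tau_rise, q / amp))


def sample_pair_events(spec: PairSpec, start_ms: float = 50.0,
                       rng: np.random.Generator | None = None
                       ) -> tuple[list[APTrain], GroundTruth]:
    """Draw ground-truth event tables for all sweeps of one pair (no traces).

    Per sweep: a 10-AP train; per AP a Bernoulli(success) draw, with the
    evoked event ~1 ms after the AP peak; asynchronous events from a
    piecewise-constant-rate Poisson process on [t_i + 3 ms, t_{i+1}) (one
    inter-stimulus interval after the last AP), thinned out of the 3-ms
    success windows; background spontaneous events over the whole sweep.

    Trains are delivered every ``intertrain_interval_s``, so spontaneous
    events also accrue between sweeps at ``background_rate``; these carry
    ``sweep_id = "<pair_id>_intertrial"`` and, with the in-sweep background,
    form the in-cell sEPSC basis used to type the evoked events.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    isi = 1000.0 / spec.freq
    dur_ms = spec.sweep_duration_ms(start_ms=start_ms)

    trains: list[APTrain] = []
    ev_rows: list[dict] = []
    rel_rows: list[dict] = []
    async_rows: list[dict] = []

    for s in range(spec.n_sweeps):
        sweep_id = f"{spec.pair_id}_f{int(spec.freq)}_s{s:02d}"
        train = make_ap_train(spec.freq, start_ms=start_ms, sweep_id=sweep_id)
        trains.append(train)
        t_ap = train.ap_peak_times

        # evoked (unitary) events: Bernoulli per AP
        for i in range(10):
            success = bool(rng.random() < spec.per_ap_release_prob[i])
            amp = 0.0
            if success:
                label = (
                    spec.pair_type
                    if spec.pair_type in ("S", "F")
                    else ("S" if rng.random() < 0.5 else "F")
                )
                pop = spec.population(label)
                amp, q, tau_d = _draw_typed_event(
                    pop, float(np.log(spec.potency(label))), spec.potency_ln_sd, rng
                )
                lat = float(
                    np.clip(rng.normal(spec.latency_mean_ms, spec.latency_sd_ms), 0.2, 2.9)
                )
                ev_rows.append(
                    dict(
                        cell_id=spec.pair_id,
                        sweep_id=sweep_id,
                        event_time_ms=t_ap[i] + lat,
                        true_label=label,
                        amplitude_pA=amp,
                        charge_fC=q,
                        tau_rise_ms=pop.tau_rise,
                        tau_decay_ms=tau_d,
                        source="unitary",
                        ap_index=i + 1,
                    )
                )
            rel_rows.append(
                dict(
                    sweep_id=sweep_id,
                    ap_index=i + 1,
                    success=success,
                    amplitude_pA=amp,
                )
            )

        # asynchronous release: piecewise-constant-rate Poisson between APs
        for i in range(10):
            w0 = t_ap[i] + 3.0
            w1 = t_ap[i + 1] if i < 9 else t_ap[i] + isi
            rate = spec.async_base_rate * spec.async_facilitation[i]
            if rate <= 0 or w1 <= w0:
                continue
            n = rng.poisson(rate * (w1 - w0) / 1000.0)
            times = np.sort(rng.uniform(w0, w1, n))
            for t in times:
                label = (
                    spec.pair_type
                    if spec.pair_type in ("S", "F")
                    else ("S" if rng.random() < 0.5 else "F")
                )
                pop = spec.population(label)
                amp, q, tau_d = _draw_typed_event(
                    pop, pop.mean_ln_amplitude, pop.sd_ln_amplitude, rng
                )
                ev_rows.append(
                    dict(
                        cell_id=spec.pair_id,
                        sweep_id=sweep_id,
                        event_time_ms=float(t),
                        true_label=label,
                        amplitude_pA=amp,
                        charge_fC=q,
                        tau_rise_ms=pop.tau_rise,
                        tau_decay_ms=tau_d,
                        source="async",
                        ap_index=i + 1,
                    )
                )
                async_rows.append(
                    dict(sweep_id=sweep_id, ap_index=i + 1, event_time_ms=float(t))
                )

        # background spontaneous events (the in-cell sEPSC basis)
        n_bg = rng.poisson(spec.background_rate * dur_ms / 1000.0)
        for t in np.sort(rng.uniform(0.0, dur_ms, n_bg)):
            label = "S" if rng.random() < spec.background_s_fraction else "F"
            pop = spec.population(label)
            amp, q, tau_d = _draw_typed_event(
                pop, pop.mean_ln_amplitude, pop.sd_ln_amplitude, rng
            )
            ev_rows.append(
                dict(
                    cell_id=spec.pair_id,
                    sweep_id=sweep_id,
                    event_time_ms=float(t),
                    true_label=label,
                    amplitude_pA=amp,
                    charge_fC=q,
                    tau_rise_ms=pop.tau_rise,
                    tau_decay_ms=tau_d,
                    source="spontaneous",
                    ap_index=0,
                )
            )

    # spontaneous events between trains (not rendered into sweep traces)
    inter_ms = max(spec.intertrain_interval_s * 1000.0 - dur_ms, 0.0)
    n_inter = rng.poisson(spec.background_rate * inter_ms / 1000.0 * spec.n_sweeps)
    for t in np.sort(rng.uniform(0.0, inter_ms * spec.n_sweeps, n_inter)):
        label = "S" if rng.random() < spec.background_s_fraction else "F"
        pop = spec.population(label)
        amp, q, tau_d = _draw_typed_event(
            pop, pop.mean_ln_amplitude, pop.sd_ln_amplitude, rng
        )
        ev_rows.append(
            dict(
                cell_id=spec.pair_id,
                sweep_id=f"{spec.pair_id}_intertrial",
                event_time_ms=float(t),
                true_label=label,
                amplitude_pA=amp,
                charge_fC=q,
                tau_rise_ms=pop.tau_rise,
                tau_decay_ms=tau_d,
                source="spontaneous",
                ap_index=0,
            )
        )

    events = pd.DataFrame(
        ev_rows,
        columns=[
            "cell_id",
            "sweep_id",
            "event_time_ms",
            "true_label",
            "amplitude_pA",
            "charge_fC",
            "tau_rise_ms",
            "tau_decay_ms",
            "source",
            "ap_index",
        ],
    )
    if len(events):
        events = events.sort_values(["sweep_id", "event_time_ms"], ignore_index=True)
    truth = GroundTruth(
        events=events,
        release=pd.DataFrame(
            rel_rows, columns=["sweep_id", "ap_index", "success", "amplitude_pA"]
        ),
        async_events=pd.DataFrame(
            async_rows, columns=["sweep_id", "ap_index", "event_time_ms"]
        ),
    )
    return trains, truth


def generate_pair_sweeps(spec: PairSpec, sampling_rate: float = 10_000.0,
                         noise_sd: float = 2.0, start_ms: float = 50.0
                         ) -> tuple[list[SweepRecording], list[APTrain], GroundTruth]:
    """Render every sweep of one pair as a current trace plus ground truth."""
    rng = np.random.default_rng(spec.seed)
    trains, truth = sample_pair_events(spec, start_ms=start_ms, rng=rng)
    dur_ms = spec.sweep_duration_ms(start_ms=start_ms)
    n_samples = int(round(dur_ms / 1000.0 * sampling_rate))
    sweeps: list[SweepRecording] = []
    for train in trains:
        ev = truth.events[truth.events["sweep_id"] == train.sweep_id]
        trace = _render_events(n_samples, sampling_rate, ev)
        if noise_sd > 0:
            trace = trace + rng.normal(0.0, noise_sd, n_samples)
        sweeps.append(
            SweepRecording(
                samples=trace,
                sampling_rate=sampling_rate,
                sweep_id=train.sweep_id,
                rs_start=spec.rs_start,
                rs_end=spec.rs_end,
            )
        )
    return sweeps, trains, truth


def idealized_presets() -> dict:
    """Per-(type, condition, frequency) strength series for playback.

    Twelve conditions: S/F/Mixed x NR/DE x 10/40 Hz.  The series emulate
    the qualitative short-term dynamics of the recorded connection types:
    S-containing connections facilitate more steeply at 40 Hz than at
    10 Hz, F-only connections carry the same modest series at both
    frequencies, and deprivation (DE) dampens every series except the
    40 Hz F series, which it boosts.  Values are pA; kinetics come from
    the default populations (Mixed uses the S kernel, whose slower decay
    dominates summation).
    """
    nr = {
        ("S", 10.0): np.linspace(2.0, 6.0, 10),
        ("S", 40.0): np.linspace(3.0, 14.0, 10),
        ("F", 10.0): np.full(10, 4.25),
        ("F", 40.0): np.full(10, 4.25),
        ("Mixed", 10.0): np.linspace(2.5, 7.0, 10),
        ("Mixed", 40.0): np.linspace(3.5, 16.0, 10),
    }
    out = {}
    for (ptype, freq), series in nr.items():
        out[(ptype, "NR", freq)] = series.copy()
        if ptype == "F" and freq == 40.0:
            out[(ptype, "DE", freq)] = series * 1.3
        else:
            out[(ptype, "DE", freq)] = series * 0.7
    return out


def pair_spec_for_frequencies(base: PairSpec) -> list[PairSpec]:
    """The same pair at all four stimulation frequencies, seeds offset."""
    return [
        replace(base, freq=f, seed=base.seed + 1000 * k)
        for k, f in enumerate(PAIR_FREQS)
    ]
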