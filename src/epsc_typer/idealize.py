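"""Idealized unitary-current traces and leaky integrate-and-fire playback.

The per-AP strength series of a condition is fit with a straight line in
the AP index; a beta-function kernel (unit-peak difference of
exponentials) is fit to the average unitary EPSC; the kernel is then
repeated at the train's inter-stimulus spacing and scaled so each
repetition's isolated peak equals the linearized strength at that index.
Synthesized playback traces are positive-going command currents in pA
(the recorded inward currents are inverted for injection).

The playback target is a leaky integrate-and-fire stand-in for the real
neuron: membrane time constant tau_m, resting potential and input
resistance with the recorded population means as defaults, a fixed
threshold/reset and an absolute refractory period.  It is an explicit
surrogate; only qualitative spike-count comparisons are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .kernels import eval_kernel, peak_factor

__all__ = [
    "BetaKernel",
    "IdealizedTrace",
    "LifNeuron",
    "KernelFitRejected",
    "fit_strength_trend",
    "fit_beta_kernel",
    "synthesize_idealized_trace",
    "lif_playback",
]


class KernelFitRejected(ValueError):
    """Raised when the kernel fit does not describe the segment."""


@dataclass
class BetaKernel:
    """Fitted unit-peak difference-of-exponentials kernel."""

    amplitude: float  # pA, peak magnitude
    tau_rise: float  # ms
    tau_decay: float  # ms
    onset_latency: float = 0.0  # ms from segment start
    residual_rms: float = 0.0

    @property
    def peak_factor(self) -> float:
        """Normalization constant of the underlying double exponential."""
        return float(peak_factor(self.tau_rise, self.tau_decay))

    def evaluate(self, t_ms: np.ndarray) -> np.ndarray:
        return self.amplitude * eval_kernel(
            np.asarray(t_ms, float) - self.onset_latency, self.tau_rise, self.tau_decay
        )


@dataclass
class IdealizedTrace:
    """Playback command current built from a scaled, repeated kernel."""

    samples: np.ndarray  # pA, positive-going
    sampling_rate: float  # Hz
    strength_series: np.ndarray  # pA, 10 values
    freq: float  # Hz
    stim_times_ms: np.ndarray = field(default_factory=lambda: np.array([]))
    pair_type: str | None = None
    condition: str | None = None


def fit_strength_trend(per_ap_strengths) -> tuple[float, float, np.ndarray]:
    """OLS line through the 10 per-AP strengths against AP index 1..10.

    Returns ``(intercept, slope, linearized_series)``.
    """
    y = np.asarray(per_ap_strengths, dtype=float)
    if y.size != 10:
        raise ValueError("expected 10 per-AP strength values")
    if not np.all(np.isfinite(y)):
        raise ValueError("strength values must be finite")
    idx = np.arange(1, 11, dtype=float)
    if np.unique(y).size < 2:
        return float(y[0]), 0.0, y.copy()
    slope, intercept = np.polyfit(idx, y, 1)
    return float(intercept), float(slope), intercept + slope * idx


def fit_beta_kernel(segment: np.ndarray, sampling_rate: float,
                    reject_snr: float = 3.0) -> BetaKernel:
    """Least-squares beta-kernel fit to an average uEPSC segment.

    ``segment`` is positive-going (baseline-subtracted magnitude).  The fit
    is rejected when the fitted peak is less than ``reject_snr`` times the
    residual RMS, i.e. the segment is not event-like.
    """
    y = np.asarray(segment, dtype=float)
    if y.size < 8:
        raise ValueError("segment too short for a kernel fit")
    t = np.arange(y.size) / sampling_rate * 1000.0

    ipk = int(np.argmax(y))
    a0 = max(float(y[ipk]), 1e-6)
    t0_0 = max(t[ipk] - 1.0, 0.0)

    def model(tt, a, tr, td, t0):
        if not (td > tr > 0):
            return np.full_like(tt, 1e6)
        return a * eval_kernel(tt - t0, tr, td)

    last_err = None
    for tr0, td0 in ((0.5, 4.0), (0.2, 1.5), (1.5, 10.0)):
        try:
            popt, _ = curve_fit(
                model, t, y, p0=[a0, tr0, td0, t0_0],
                bounds=([0, 1e-3, 2e-3, -5.0], [np.inf, 50.0, 500.0, t[-1]]),
                maxfev=20000,
            )
            a, tr, td, t0 = popt
            if td <= tr:
                raise RuntimeError("degenerate kinetics")
            resid = y - model(t, *popt)
            rms = float(np.sqrt(np.mean(resid**2)))
            if a < reject_snr * rms:
                raise KernelFitRejected(
                    f"fitted peak {a:.3g} pA below {reject_snr} x residual RMS {rms:.3g}"
                )
            return BetaKernel(
                amplitude=float(a), tau_rise=float(tr), tau_decay=float(td),
                onset_latency=float(t0), residual_rms=rms,
            )
        except KernelFitRejected:
            raise
        except Exception as err:  # try the next initialization
            last_err = err
    raise KernelFitRejected(f"kernel fit failed for all initializations: {last_err}")


def synthesize_idealized_trace(kernel: BetaKernel, strengths, freq: float,
                               sampling_rate: float = 10_000.0,
                               pre_ms: float = 50.0, tail_ms: float = 200.0,
                               pair_type: str | None = None,
                               condition: str | None = None) -> IdealizedTrace:
    """Linear superposition of 10 kernels at the train's ISI spacing.

    Each repetition is scaled so its *isolated* peak equals the strength at
    that index; with decay constants approaching the inter-stimulus
    interval the superposed peaks ride on the previous tail (linear
    summation, documented rather than corrected).
    """
    strengths = np.asarray(strengths, dtype=float)
    if strengths.size != 10:
        raise ValueError("expected 10 strength values")
    isi = 1000.0 / freq
    stim = pre_ms + np.arange(10) * isi
    dur_ms = pre_ms + 9 * isi + tail_ms
    n = int(round(dur_ms / 1000.0 * sampling_rate))
    t = np.arange(n) / sampling_rate * 1000.0
    trace = np.zeros(n)
    for t_stim, s in zip(stim, strengths):
        trace += s * eval_kernel(t - t_stim, kernel.tau_rise, kernel.tau_decay)
    return IdealizedTrace(
        samples=trace, sampling_rate=sampling_rate,
        strength_series=strengths.copy(), freq=freq, stim_times_ms=stim,
        pair_type=pair_type, condition=condition,
    )


@dataclass
class LifNeuron:
    """Leaky integrate-and-fire parameters.

    Resting potential and input resistance default to the recorded
    population means; time constant, threshold, reset and refractory
    period are surrogate defaults.
    """

    v_rest: float = -63.5  # mV
    r_input: float = 400.0  # MOhm
    tau_m: float = 20.0  # ms
    v_threshold: float = -40.0  # mV
    v_reset: float = -55.0  # mV
    refractory: float = 2.0  # ms

    def __post_init__(self):
        if self.v_threshold <= self.v_rest:
            raise ValueError("v_threshold must exceed v_rest")
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")


def lif_playback(trace: IdealizedTrace | np.ndarray, gain: float = 25.0,
                 neuron: LifNeuron | None = None,
                 sampling_rate: float | None = None,
                 dt_ms: float = 0.025) -> tuple[np.ndarray, int, np.ndarray]:
    """Play a current trace into the LIF neuron and count spikes.

    Exact exponential-Euler update per step (the drive is held constant
    within each step); the integration step is at most ``dt_ms`` (<=0.05 ms
    enforced), subdividing trace samples as needed.  1 MOhm * 1 pA =
    1e-3 mV, so the drive in mV is ``r_input * gain * I * 1e-3``.

    Returns ``(voltage at trace resolution, spike_count, spike_times_ms)``.
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    if dt_ms > 0.05:
        raise ValueError("integration step must be <= 0.05 ms")
    if neuron is None:
        neuron = LifNeuron()
    if isinstance(trace, IdealizedTrace):
        current = trace.samples
        fs = trace.sampling_rate
    else:
        current = np.asarray(trace, dtype=float)
        if sampling_rate is None:
            raise ValueError("sampling_rate required for a bare array")
        fs = sampling_rate

    dt_trace = 1000.0 / fs
    nsub = max(1, int(np.ceil(dt_trace / dt_ms)))
    h = dt_trace / nsub
    decay = np.exp(-h / neuron.tau_m)

    v = neuron.v_rest
    v_out = np.empty(current.size)
    spikes = []
    refr_left = 0.0
    for i in range(current.size):
        drive = neuron.v_rest + neuron.r_input * gain * current[i] * 1e-3
        for _ in range(nsub):
            if refr_left > 0:
                refr_left -= h
                v = neuron.v_reset
                continue
            v = drive + (v - drive) * decay
            if v >= neuron.v_threshold:
                spikes.append(i * dt_trace)
                v = neuron.v_reset
                refr_left = neuron.refractory
        v_out[i] = v
    return v_out, len(spikes), np.asarray(spikes)
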