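# Methods

## The typing model

Events are represented as points $(\ln A, \ln Q)$ with $A$ the peak
amplitude (pA, positive magnitude of the inward current) and $Q$ the
charge transfer (fC, absolute trapezoidal integral of the
baseline-subtracted current; 1 pA·ms = 1 fC).  In this plane a population
of events that scales multiplicatively in amplitude while keeping its
kinetics forms a slope-1 arm, with the arm's vertical offset equal to the
log of charge per unit amplitude — a pure function of the event kinetics.
Two kinetic classes therefore appear as two parallel arms, and the axis
that separates them is $\ln Q - \ln A$ up to a tilt that depends on the
amplitude distributions.

The rotation search makes no use of that geometry a priori.  For each
angle $\theta$ on a 1° grid over $[0°, 90°)$ the points are rotated, and
three statistics of the rotated data are computed: the width $a(\theta)$
of the modal interval of dimension 2 under Hartigan's dip test, the range
$b(\theta)$ of dimension 1, and the AIC $c(\theta)$ of a two-component
univariate Gaussian mixture along dimension 2 ($\mathrm{AIC} = 2k - 2\ell$
with $k = 5$).  The three terms have incommensurate units, so each is
z-scored across the grid before forming the objective
$(a - c) + (b - c)$; because $c$ enters twice negatively, the selected
angle is in effect the one that minimizes the mixture AIC relative to the
dip and range terms.  Rotation beyond 90° only permutes axes, hence the
half-quadrant grid.

At $\theta^*$ a final two-component mixture is fit and events are
hard-clustered at a posterior threshold of 0.5 (ties assigned to S,
deterministically).  The component whose events carry the greater
posterior-weighted mean $\ln Q$ is mapped to S, since the slow class is
defined by its larger charge transfer.  Models fitted to a cell's
spontaneous events classify the same cell's evoked unitary events after
rotating them by the cell's own $\theta^*$; a connected pair is then
typed S when ≥ 80 % of unitary posteriors favor S, F when ≤ 20 % do, and
Mixed otherwise (the 0.2/0.8 cutoffs operationalize "posteriors clustered
near 0 or 1" and are configurable; at least 20 classified events are
required).

### Dip statistic

`epsc_typer._dip` implements the dip from first principles: the dip of a
sample is half the largest deviation committed while shrinking a
candidate modal interval, alternating between the greatest convex
minorant of the empirical cdf's lower corner points and the least concave
majorant of its upper corner points, until the gap between the two hulls
inside the interval is explained by the committed deviations.  Ties in
the data are handled exactly.  The test suite checks the implementation
against an independent linear-programming oracle that minimizes the
sup-norm distance to a unimodal cdf directly (enumerating mode positions,
convexity/concavity as linear constraints) — exhaustively for every
multiset of size ≤ 8 over three support points, and on random samples.
The returned modal interval is the final hull bracket; its width is the
$a(\theta)$ term above.

### Mixture fitting

The univariate mixtures are fit with scikit-learn's `GaussianMixture`
(diagonal covariance, variance floor $10^{-4}$ of the sample variance).
During the θ scan a single deterministic quantile-based initialization is
used (means at the 25th/75th percentiles) — the scan needs 90 fits per
cell and the deterministic init makes it reproducible and fast; the final
fit at $\theta^*$ adds 10 random restarts and keeps the best
log-likelihood.  The rotation objective's z-scores depend on the grid, so
the "refit after rotating to the optimum" fixed point holds to within a
couple of grid steps rather than exactly; the near-optimal region is flat
for well-separated arms and any angle in it yields the same labels.

When no rotation changes the mixture AIC by more than 0.25 per event
across the whole grid (an isotropic cloud, for instance), no arm geometry
is present and the model is flagged `low_confidence`.

## Event detection and QC

Detection thresholds a low-pass-filtered (4-pole Butterworth, 1 kHz
default, zero-phase) baseline-subtracted copy of the trace; peaks must
exceed the threshold (default 5 pA) and be separated by the
`min_separation` (default 10 ms), which operationalizes "well-isolated".
The event onset is the last pre-peak sample at the noise floor
(max of 2 % of peak and 2 robust SDs); amplitude is measured on the
unfiltered trace against a 2-ms pre-onset baseline; the decay constant
comes from a log-linear fit of the falling phase; charge integrates from
onset to onset + 5 fitted decay constants, truncated at the next onset to
prevent double counting.  Acquisition systems each apply their own
detection criteria, so these defaults are explicit package choices and
all configurable — recovery of planted events is what the tests certify.

QC keeps cells with series resistance at the start of the recording at
most 30 MΩ (miniature-EPSC context) or 40 MΩ (paired context), drift at
most 15 %, and (miniature context) at least 200 events; exclusions are
returned with machine-readable reasons.  The cap is applied to the start
value — drift is policed by its own rule — since the exclusion threshold
is defined without a time point.

## Train analysis

Success windows are $(t_{AP}, t_{AP}+3\,\mathrm{ms}]$ (closed right
edge); the first event in a window is measured when several occur.
Strength averages amplitudes with failures as zeros and potency averages
successes only — the standard quantal-analysis conventions for these
terms — so strength = success rate ×
potency is an algebraic identity wherever potency is defined, and the
pipeline asserts it.  Asynchronous windows run from +3 ms to the next AP
peak, half-open; after the tenth AP the window length is one
inter-stimulus interval (a symmetric convention).
Success and asynchronous windows partition each inter-AP interval.
Intersomatic distance is the Euclidean norm of the (dx, dy, dz) offsets.
`export_model_table` emits one row per (cell, type, condition, frequency,
AP, parameter) for external mixed-model fitting; fitting itself is out of
scope here.

## Idealization and playback

The per-AP strength series of a condition is linearized by OLS on AP
index 1–10.  The "beta function" kernel is implemented as the unit-peak
difference of exponentials
$B(t) = (e^{-t/\tau_d} - e^{-t/\tau_r})/\mathrm{peak}$, whose integral
has the closed form $(\tau_d-\tau_r)/\mathrm{peak}$ — the historical
parameterization is ambiguous, so the normalization constant is stored
with every fit.  Kernel fits reject segments whose fitted peak is below
3× the residual RMS.  At 10 kHz sampling with noise at 10 % of peak, the
rise constant of the default slow kernel spans ~10 samples and trades off
against the onset latency; even the truth-initialized maximum-likelihood
fit then carries ~7 % median error in $\tau_r$, so only amplitude and
decay recover to 5 % — an identifiability limit of the conditions, not of
the optimizer.

Idealized traces superpose 10 kernels at the inter-stimulus spacing, each
scaled so its isolated peak equals the linearized strength; when the
decay approaches the inter-stimulus interval the summation is left linear
and documented.  Playback currents are positive-going command currents
(recorded inward events are inverted for injection).

The playback target is a leaky integrate-and-fire surrogate for the real
neuron: $\tau_m \dot V = -(V - V_{rest}) + R\,g\,I(t)$ with
$V_{rest} = -63.5$ mV and $R = 400$ MΩ (recorded population means), gain
$g = 25$, and surrogate defaults $\tau_m = 20$ ms, threshold −40 mV,
reset −55 mV, refractory 2 ms.  Integration is exact exponential-Euler
with step ≤ 0.05 ms (default 0.025 ms, subdividing trace samples), so the
constant-current interspike interval matches the closed form
$\tau_m \ln\frac{RgI - (V_{reset}-V_{rest})}{RgI - (V_{thr}-V_{rest})}$
plus the refractory period.  Spike counts from this surrogate support
qualitative comparisons only (e.g. facilitating, frequency-dependent
strength series drive more spikes at 40 Hz than 10 Hz; flat series do
not); they are not predictions of real-neuron spike counts.

## Synthetic data: what it does and does not emulate

The generator draws, per population, $\ln A \sim \mathcal N(\mu, \sigma)$
and $\ln Q = \ln A + \mathrm{offset} + \mathcal N(0, \sigma_Q)$ — the
lognormal-per-arm form is an assumption; the true amplitude/charge
distribution families of real recordings are not known.  Each event's decay constant is solved (Brent) from its
drawn $Q/A$ ratio, so rendered traces reproduce the drawn features
exactly and the fast event-table path and the trace path share one
generative draw.  Defaults: S kinetics $\tau_r = 1$, $\tau_d = 8$ ms with
mean amplitude 15 pA; F kinetics $\tau_r = 0.3$, $\tau_d = 2$ ms with
mean amplitude 25 pA; $\sigma = 0.35$, $\sigma_Q = 0.15$; arm offsets
equal the log kernel charge factors (2.38 and 1.03), giving the
two-parallel-arm geometry with ~0.95 ln-unit separation along the
$(\ln Q - \ln A)/\sqrt2$ axis.  mEPSC rates default to 2 Hz (S) + 1 Hz
(F); when a cell-level S-fraction is given it splits the total rate.
Traces are rendered at 10 kHz with 2 pA Gaussian noise at a −80 mV
holding potential.

Paired sweeps use 10-AP trains (default 15 sweeps, within the 10–20
typically analyzed per frequency) with facilitating per-AP release probabilities (0.30 → 0.75),
~1 ms evoked latency (clipped into the 3-ms window), evoked amplitudes
lognormal around per-type potencies (S 20 pA, F 30 pA, ln-SD 0.25),
asynchronous release from a piecewise-constant-rate Poisson process
(base 5 Hz, facilitation 1 → 3.4 across APs) thinned out of success
windows, and 3 Hz background spontaneous events.  Trains repeat every
10 s, so spontaneous events also accrue between sweeps; together with the
in-sweep background they provide each pair's ≥ 200-event sEPSC basis.

Not emulated: dendritic cable filtering, series-resistance filtering of
kinetics, amplitude–distance correlations, non-stationary noise, vesicle
depletion or calcium dynamics behind facilitation, and any mechanistic
content of the deprivation conditions (NR/DE/AD are parameter-preset
labels only; the idealized-playback presets encode the qualitative
pattern that S-containing series facilitate more steeply at 40 Hz while
F-only series do not, and that deprivation dampens all series except the
40 Hz F series).  Passing tests therefore certify the correctness of the
analysis on data satisfying the generator's assumptions, not performance
on real recordings with overlapping events or drifting baselines.

## Benchmark problem sizes

The recovery benchmarks in `epsc_typer.evaluation` use 20 cells × 200
events for clustering, 100 pairs per class × 15 sweeps for pair typing,
200 sweeps for train-statistic recovery, and the demo pipeline runs 2–3
cells and 6 pair-frequency conditions — sizes chosen to match realistic
per-cell event counts and sweep counts while keeping a full desk-side
rerun in minutes on one CPU.
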