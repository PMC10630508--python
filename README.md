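# epsc-typer

Analysis pipeline for excitatory synaptic currents recorded on cortical
somatostatin (SOM) interneurons.  SOM cells in visual cortex receive two
kinetically distinct classes of AMPA-receptor EPSCs — a slow, high-charge
class (S-type) and a fast, high-amplitude class (F-type) — and single
presynaptic pyramidal cells can make either or both kinds of synapse.
`epsc-typer` implements the full desk-side analysis of such recordings:

* **Unsupervised kinetic typing.**  Each cell's events are points
  $(\ln A, \ln Q)$ (amplitude in pA, charge transfer in fC).  A rotation
  angle is chosen by grid search with the cost function

  $$\theta^* = \arg\max_\theta \,\bigl(a(\theta) - c(\theta)\bigr) + \bigl(b(\theta) - c(\theta)\bigr)$$

  where, after rotating by $\theta$: $a$ is the width of the modal
  interval of dimension 2 under **Hartigan's dip test** (implemented here
  from scratch and verified against a definitional linear-programming
  oracle), $b$ is the range of dimension 1, and $c$ is the **AIC of a
  two-component Gaussian mixture** fit along dimension 2 (terms z-scored
  across the grid).  The mixture at $\theta^*$ hard-clusters events at a
  posterior threshold of 0.5; the component with the greater mean
  $\ln Q$ is S.
* **Evoked-event classification.**  The mixture fit to a cell's
  spontaneous events classifies the same cell's evoked unitary EPSCs
  (rotated by the same $\theta^*$), and connected pairs are typed
  S / F / Mixed from the distribution of posteriors.
* **Short-term dynamics and asynchronous release.**  For 10-AP trains at
  5/10/20/40 Hz: per-AP success rate, strength (failures as 0 pA) and
  potency (successes only) from a 3-ms post-AP window, so
  strength = success rate × potency; asynchronous release rate from the
  window between +3 ms and the next AP.  Results export as long-format
  tables ready for mixed-model packages.
* **Idealized traces and playback.**  Per-AP strengths are linearized by
  OLS, a beta-function kernel (unit-peak difference of exponentials) is
  fit to the average unitary EPSC, and the scaled, repeated kernel forms
  an idealized command current, played into a leaky integrate-and-fire
  stand-in neuron (rest −63.5 mV, input resistance 400 MΩ, gain 25×).
* **Synthetic recordings with ground truth.**  A generator emulates
  every input the pipeline consumes — two-population mEPSC traces,
  paired-recording sweeps with facilitating release and asynchronous
  events, noise and series-resistance metadata — so every stage is
  testable without any experimental data.

## Worked example

```python
from epsc_typer import synthio
from epsc_typer.events import events_from_ground_truth
from epsc_typer.typing import fit_rotation_model, classify_with_model, s_proportion

spec = synthio.CellSpec(cell_id="c0", s_fraction=0.6, seed=1)
events = synthio.sample_cell_events(spec, n_events=200)
table = events_from_ground_truth(events)
model = fit_rotation_model(table, seed=0)
typed = classify_with_model(table, model)
print(f"theta* = {model.theta_star_deg:.0f} deg")
print(f"S proportion = {s_proportion(typed):.2f}")
print(f"accuracy vs truth = {(typed['label'] == events['true_label']).mean():.2f}")
```

prints

```
theta* = 52 deg
S proportion = 0.60
accuracy vs truth = 1.00
```

i.e. the grid search finds the rotation that isolates the charge-per-
amplitude axis separating the two arms (near 45° plus a tilt from the
amplitude difference between populations), recovers the generating
60 % S-proportion exactly, and labels every event correctly.

The same stages are available from the shell:

```sh
epsc-typer simulate --seed 1 --out run/
epsc-typer detect --in run/traces.h5 --threshold 5 --out run/events.csv
epsc-typer type --events run/events.csv --out run/typed.csv
epsc-typer run --seed 1 --out run_full/   # full pipeline incl. playback
```

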