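# rankcode

Population rank-order coding analysis of retinal ganglion cell (RGC)
responses to flashed gratings.

When a grating is flashed onto the retina, hundreds of RGCs fire in a
characteristic order — the *wave of first spikes* (WFS).  Even when single
cells are too noisy for their absolute first-spike latencies to identify
the stimulus, the relative order of firing across the population can.
`rankcode` provides the analyses needed to quantify this population code
and a synthetic spike-train simulator to exercise them with known ground
truth:

* **Rank similarity.** The WFS evoked by two stimuli is compared with the
  Spearman rank correlation ρ of the population latency ranks (ρ = 1 for
  identical firing orders, −1 for opposite orders), giving stimulus-pair
  similarity matrices, phase-tuning curves ρ(0°, φ), and the
  trial-shuffling loss (Δ − Δs)/Δ that isolates the contribution of
  trial-to-trial noise correlations.
* **Partial information decomposition (PID).** For a pair of spike-count
  responses (R₁, R₂) and stimulus S, the Williams–Beer decomposition
  splits I(S; R₁,R₂) into redundancy (expectation of the minimum specific
  information minᵢ I(S=s; Rᵢ)), the unique informations
  Unqᵢ = I(S;Rᵢ) − Red, and synergy
  Syn = I(S;R₁,R₂) − Unq₁ − Unq₂ − Red, all in bits.  A subsampling
  extrapolation (estimates on k = 1, 2, … random partitions of the trials,
  degree-2 polynomial intercept at k → 0) corrects the limited-sampling
  bias of every underlying quantity.
* **Bayesian decoding.** A MAP classifier identifies the grating phase
  (8 alternatives, chance 1/8) from four codes: independent spike counts,
  independent first-spike latencies (Gaussian KDE, σ = 10 ms), and rank
  order codes built from the pairwise firing-order probabilities
  P(Lᵢ > Lⱼ | φ) applied to latencies (the WFS read-out) or to counts.
  Confusion matrices, population-size sweeps and observation-window sweeps
  quantify how much information the relative activities carry, with how
  few neurons, and how fast.
* **Synthetic data.** A generative model of ON/OFF/ON-OFF units with
  Gaussian receptive fields driven by square-wave gratings, explicit
  first-spike latencies, Poisson evoked/spontaneous spikes, and a shared
  per-block latency jitter that produces realistic noise correlations.
  Preprocessing utilities mirror a real recording pipeline: duplicate-unit
  removal by spike coincidence, ON/OFF classification by bias index
  (ON − OFF)/(ON + OFF), and Rayleigh-test responsiveness selection.

## Worked example

```python
import numpy as np
import rankcode as rc
from rankcode.decode import DecoderConfig, run_task
from rankcode.features import extract_counts, extract_latencies
from rankcode.ranksim import wfs_distance_matrix

ensemble = rc.make_grating_ensemble([1600, 800, 400, 200], microns_per_degree=30.0,
                                    n_phases=8, n_trials=30)
params = rc.default_population(n_units=60, seed=1)
dataset = rc.simulate_population(params, ensemble, seed=2)

latencies = extract_latencies(dataset)          # first spike in (0, 0.5] s
counts = extract_counts(dataset)

# WFS similarity: nearby phases evoke similar firing orders
rho = wfs_distance_matrix(latencies)
print(f"rho(0deg, 45deg)  = {rho.rho(8, 9):.3f}")
print(f"rho(0deg, 180deg) = {rho.rho(8, 12):.3f}")

# PID of one spike-count pair at the second spatial frequency
stim = ensemble.stimuli_for_frequency(1)
pair = counts.select_stimuli(stim)
labels = np.repeat(np.arange(8), 30)
res = rc.pid_pair(rc.estimate_joint(pair.values[0].ravel(),
                                    pair.values[1].ravel(), labels))
print(f"pair PID: red={res.red:.3f} unq=({res.unq1:.3f},{res.unq2:.3f}) "
      f"syn={res.syn:.3f} bits")

# phase discrimination with the rank order code on latencies
cm = run_task(latencies.select_stimuli(stim),
              DecoderConfig(code="roc_latency", n_configurations=20, seed=3))
print(f"roc_latency fraction correct: {cm.fraction_correct:.3f} (chance 0.125)")
```

prints

```
rho(0deg, 45deg)  = 0.310
rho(0deg, 180deg) = -0.218
pair PID: red=1.081 unq=(0.125,0.370) syn=1.039 bits
roc_latency fraction correct: 0.980 (chance 0.125)
```

The firing order is far more similar between gratings 45° apart than
between opposite phases; a substantial share of the pair information is
synergistic (the plug-in estimate here is upward-biased — see
`pid_pair_bias_corrected`); and the rank order code identifies the phase
almost perfectly from 60 noisy model cells.

A YAML-driven pipeline (`rankcode run --config cfg.yaml`) chains
simulation, preprocessing, feature extraction and all analyses into tidy
CSV outputs with a checksummed manifest; the `simulate`, `preprocess`,
`rankdist`, `pid`, `decode`, `sweep-pop` and `sweep-window` subcommands
expose the individual stages.

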