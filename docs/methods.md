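# Methods

This note documents the models and estimators implemented in `rankcode`,
the choices made where the design was genuinely open, and what the
synthetic data can and cannot establish.

## Stimulus model

Stimuli are square-wave gratings of luminance ±1, parameterised by the bar
width b (µm on the retina; spatial period 2b, so the spatial frequency in
cycles/degree is m/(2b) for a retinal magnification of m µm/°, 30 µm/° by
default).  Eight phases step the grating by b/4 per 45°.  Stimuli are
indexed by ascending frequency, then phase.  Each trial is a 0.5 s flash
followed by a 1.0 s uniform gray mask; analyses default to the flash
window, which captures the entire evoked response of the model cells.
Quoted cpd values are truncated (not rounded) to three decimals, matching
the convention of the experimental literature this design follows
(`printed_frequencies`).

## Synthetic population model

Each unit has an isotropic Gaussian receptive field (RF) of SD r
(default ≈ 120 µm, i.e. RF diameters in the 200–300 µm range typical of
mouse RGCs), a polarity class, and rate/latency parameters.  The drive is
computed in closed form: the RF-weighted signed mean of the grating over
±3r (a sum of normal-CDF increments across bar intervals), rectified by
polarity — ON keeps the positive part, OFF the negative, ON-OFF the
absolute value — and scaled by the unit's maximal evoked rate.  Mean
first-spike latency shortens with drive as
`latency_mean_base / (0.1 + rate/max_rate)`, so strongly driven cells fire
both more and earlier, giving the wave of first spikes a decodable
signal.  This is a deliberately minimal phenomenological model: no
biophysics, no temporal RF, no surround.

Spike generation per (unit, stimulus, trial):

1. an explicit first evoked spike, Gaussian around the mean latency
   (truncated at 0) — drawn explicitly so latency statistics are directly
   controllable; count oracles must add this one spike to the Poisson
   expectation;
2. further evoked spikes as a Poisson process at the evoked rate from the
   first spike to flash offset;
3. spontaneous spikes as a homogeneous Poisson process over the whole
   trial (default rates log-normal around ~1.5 Hz; the spontaneous-rate
   distribution across real units is not well characterised, so this is
   config-exposed, not asserted).

Trial-to-trial latency noise has an independent per-unit component
(default SD 60 ms, comparable to the mean latency — individual latencies
are deliberately unreliable) and a shared component: one offset per trial
*block* (drawn once per trial index, common to all stimuli of that block,
N(0, 50 ms) by default), scaled per unit by a `jitter_gain` drawn from
N(1, 0.6) clipped at 0.  Two modelling points matter here:

* A *homogeneous* additive offset cannot change within-trial ranks; the
  heterogeneous gains are what make the shared variability visible to
  rank-based statistics, so matched-trial pairing preserves it and trial
  shuffling destroys it (the noise-correlation signature).
* The gain spread is kept below 1 so that E(g₁−g₂)² < E g²: the SD of
  pairwise latency differences stays below the individual latency SD when
  the shared jitter dominates, as variance algebra requires for
  predominantly common noise.

All randomness derives from one seed with sub-streams keyed per (unit,
stimulus, trial), so any subset of the data is reproducible in isolation
and the zero-noise configuration is bit-for-bit deterministic.

## Preprocessing

*Duplicate removal.*  Spike-sorted units detected on neighbouring
electrodes (within one 42 µm pitch) are compared by the fraction of
coincident spikes (±2 frames of a 7.06 kHz clock, ≈ ±0.28 ms), computed
relative to the smaller unit's spike count so that a subset-duplicate is
detected symmetrically.  Pairs above 5% are resolved iteratively —
largest overlap first, retaining the unit with more spikes — and the
procedure is idempotent.  (The acquisition-clock definition of the
coincidence window is adopted; sub-microsecond readings of "coincidence"
are not.)

*ON/OFF classification.*  Full-field 2 s white / 2 s black epochs; the
instantaneous rate is the spike train convolved with a Gaussian (SD
25 ms).  The ON (OFF) amplitude is the peak rate within 0.5 s of the
white (black) onset — the window length is a documented default, as the
appropriate value depends on response transience.  The bias index
(ON − OFF)/(ON + OFF) spans −1 (pure OFF) to +1 (pure ON); classes are
OFF below −0.33, ON above +0.33, ON-OFF in between, with the boundary
values assigned to ON-OFF (interval notation in the literature is
ambiguous at the endpoints; a convention had to be fixed).  Units with no
response in either window are flagged unclassified rather than divided by
zero.

*Responsiveness.*  Units are kept when their first-spike latencies,
mapped to circular phases as 2π·latency/flash_duration, are non-uniform
by the Rayleigh test (standard Zar large-n approximation,
p = exp(√(1+4n+4(n²−R²)) − (1+2n)) with R the resultant length).  Trials
consumed by the test are reported so their blocks can be excluded
downstream.  Units with fewer than two latencies are excluded with a
warning, not an error.

## Rank similarity

Population latency vectors are converted to midranks; censored trials
(no spike in the window) share the maximal tied rank — a censored unit is
"slower than everyone", preserving first-spike ordering semantics without
discarding units (dropping them instead is available as an option).
ρ is canonically the Pearson correlation of midranks.  The classical
shortcut 1 − 6(Σd² + Σcf)/(n(n²−1)) with tie terms cf = m(m²−1)/12 is
also provided; the two agree exactly only without ties (the shortcut's
tie correction is not equivalent to Pearson-on-midranks), so the Pearson
form is authoritative and the agreement is property-tested on tie-free
inputs.

Cross-stimulus ρ defaults to *matched* trial pairing (trial t with trial
t — same block, preserving block-shared noise), with all-pairs and
seeded shuffled pairings as alternatives; identical-stimulus diagonal
entries use distinct trial pairs only and measure reliability.  The
shuffle-loss statistic per frequency is (Δ − Δs)/Δ with
Δ = ρ(0°,45°) − ρ(0°,180°), Δs the same under random re-pairing
(averaged over shuffles, SEM reported); it is flagged undefined when
Δ = 0.

## Partial information decomposition

Plug-in distributions are estimated from spike counts over the flash
window; response alphabets are the observed counts, optionally capped.
Redundancy is the expectation over p(s) of the minimum specific
information, where the specific information I(S=s; Rᵢ) is the KL
divergence between p(rᵢ|s) and p(rᵢ); unique and synergistic terms follow
by subtraction, all in bits with 0·log 0 ≡ 0.  The
redundancy–synergy index RSI = I(S;R₁,R₂) − I(S;R₁) − I(S;R₂) equals
Syn − Red.  The plug-in components satisfy the decomposition identities
to 1e−12 and are non-negative by construction (property-tested over
thousands of random tables).  `delta_i_independent` reports the
information lost by ignoring within-stimulus correlations; it is exactly
zero for conditionally independent responses and is *not* sign-definite
in general, so no non-negativity is asserted.

Bias correction: each D_KL(Rᵢ|S=s ‖ Rᵢ), I(S;Rᵢ) and I(S;R₁,R₂) is
re-estimated on stratified random partitions of the trials into
k = 1…4 parts (4 points give a stable degree-2 fit at around a hundred
trials per stimulus), averaging over the k disjoint subsets *and* over 10
independent random partitionings per k — the partition assignment is
auxiliary randomness, and marginalising it materially reduces the
intercept variance of the extrapolation.  The degree-2 polynomial's value
at k = 0 is the corrected estimate; the PID is recomposed from corrected
quantities using the full-data p(s).  Corrected components can violate
non-negativity; they are reported with a flag, never clipped.

## Decoding

MAP classification with a uniform prior over 8 phases; ties break to the
lowest phase index for determinism.  Per-unit likelihoods (count PMFs,
latency KDE with σ = 10 ms mixed with an explicit censored outcome) are
combined by summing log-likelihoods under independence.  For the rank
order codes, the training set provides per-pair Bernoulli probabilities
P̂(Lᵢ > Lⱼ | φ) = (#later + α)/(T + 2α) with pseudocount α = 1 (raw
empirical order probabilities can be 0 or 1, which would make test
log-likelihoods infinite); ties and censored-vs-censored comparisons
count as "not later", and a censored unit is later than any observed
one.  The population likelihood multiplies the pairwise terms over all
n(n−1)/2 pairs.  Pairs overlap, so this is a pseudo-likelihood (naive
Bayes over pairs) — the simplest consistent aggregation of a per-pair
response model; no claim of calibration is made, only of ranking
performance.  The count code uses the per-trial count in the window with
an empirical PMF (a Poisson model would be an alternative; empirical was
chosen to avoid distributional assumptions).

Train/test splits are random halves per phase (default, 150
configurations) or all-but-one with the held-out trial cycling through
configurations.  Performance is the mean of the diagonal of the
column-normalised confusion matrix.  Population-size sweeps average over
random unit subsets; window sweeps re-extract features per window.

## Pipeline

A YAML `RunConfig` drives simulate → features → {rankdist, pid, decode};
per-stage seeds derive from the global seed as
(seed XOR crc32(stage)) mod 2³¹ so stages rerun in isolation reproduce
their outputs.  All outputs are tidy CSV; a manifest with SHA-256
checksums is written last, so outputs lacking a manifest are stale.
Tables and curves are emitted rather than figures.

## Problem sizes used in the test suite

Exact toy decompositions and estimator identity suites run on enumerated
or randomly generated tables (≥1000).  The seeded directional benchmarks
use a 300-unit population, 8 phases × 100 trials at one spatial
frequency, with 3–5 random subsets and 6–8 train/test configurations per
point — sizes chosen so the full suite exercises every code path at
realistic population scale while each benchmark remains a property test
(direction and ordering), not a precision measurement.

## What the synthetic data does and does not show

The generator reproduces the qualitative regime of interest: phase-tuned
spike counts, individually unreliable latencies (SD comparable to the
mean), censored trials, spontaneous activity, and block-shared latency
variability that rank codes exploit and trial shuffling destroys.  It
omits much of real retinal structure — cell-type-specific kinetics,
temporal RFs, surround antagonism, spatial mosaics, adaptation, and any
stimulus beyond flashed square-wave gratings.  Passing benchmarks
therefore establish that the estimators and decoders behave correctly and
directionally as theory predicts on data with known ground truth; they do
not by themselves establish effect sizes in recorded retinae.
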