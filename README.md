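# msdyn — EEG microstate segmentation and temporal dynamics

`msdyn` is a Python library for resting-state EEG microstate analysis and for
the statistical characterization of the resulting state sequences. It is
aimed at researchers who want the full chain — from a multichannel voltage
matrix to cohort-level statistics — as small, testable, importable pieces,
with a synthetic generator that provides ground truth for every stage.

## What it computes

**Segmentation.** The global field power of an average-referenced recording,

GFP(t) = sqrt( (1/C) Σ_c (v_c(t) − v̄(t))² ),

is band-passed (2–20 Hz, zero-phase FIR), smoothed with a 5-tap Gaussian, and
its local maxima — the moments of highest topographic signal-to-noise — are
clustered with polarity-invariant atomize-and-agglomerate hierarchical
clustering (AAHC) into k = 4 microstate templates A–D. Segmentation quality
is the global explained variance

GEV = Σ_t (GFP_t · corr(v_t, T_{a(t)}))² / Σ_t GFP_t²,

the GFP-weighted squared spatial correlation between each map and its
assigned template. Group templates are built by exhaustive permutation
alignment across subjects, and every sample is then back-fitted to the
template of highest |spatial correlation|, yielding a categorical sequence
X_t ∈ {A, B, C, D}.

**Temporal properties.** Mean duration (lifespan), occurrence rate, coverage,
and transition matrices T_ij = P(X_{t+1}=S_j | X_t=S_i) in per-sample mode
(self-transitions included) and segment mode (distinct-state jumps only).

**Sequence dynamics.** Likelihood-ratio (G) tests against chi-squared nulls
for Markovianity of order 0/1/2, for stationarity of T across time blocks,
and for the symmetry T_ij = T_ji; all G statistics carry the Williams
small-sample correction so their type-I error is calibrated at realistic
sequence lengths. Memory beyond these nulls is quantified by the
autoinformation function (time-lagged mutual information, in bits)

I(τ) = H(X_t) + H(X_{t+τ}) − H(X_t, X_{t+τ}),

globally and per state (binary indicator sequences), with a closed-form
Markov-chain oracle `markov_aif_closed_form` for validation.

**Cohort statistics.** Pooled-variance two-sample t-tests, Bonferroni–Holm
correction within feature families (12 transitions; 4 durations; 4
occurrence rates), Cohen's d, and numeric normality diagnostics.

**Synthetic ground truth.** `msdyn.synthetic` plants K orthogonal unit-norm
topographies driven by a semi-Markov sequence (configurable jump matrix;
geometric or gamma dwell, default mean 80 ms), amplitude-modulates them with
a rectified 10 Hz carrier (so GFP peaks twice per cycle), and adds Gaussian
noise at a configurable signal/noise RMS ratio. Two-cohort generation with a
planted transition-probability difference supports power studies.

## Worked example

`examples/01_simulate_and_segment.py` simulates 2 minutes of 31-channel EEG
at snr 4 and runs the segmentation stack:

```
2761 GFP peaks clustered, GEV = 0.926
template A: |spatial corr| to planted map = 0.979
template B: |spatial corr| to planted map = 0.983
template C: |spatial corr| to planted map = 0.986
template D: |spatial corr| to planted map = 0.982
```

GEV = 0.926 says the four templates explain 92.6% of the GFP-weighted
topographic variance at the peaks; correlations near 1 mean the planted maps
were recovered up to polarity. `examples/03_sequence_tests.py` contrasts
gamma-dwell (non-Markovian) with geometric-dwell (first-order Markov)
sequences:

```
gamma-dwell sequence (alpha = 0.01):
  Markov order 0: G =  272039.3, df =   9, p = 0 -> rejected
  Markov order 1: G =     378.2, df =  36, p = 1.19e-58 -> rejected
  Markov order 2: G =     252.9, df = 144, p = 5.49e-08 -> rejected
geometric-dwell sequence (alpha = 0.01):
  Markov order 1: G =      41.2, df =  36, p = 0.254 -> consistent
  Markov order 2: G =      77.8, df = 144, p = 1 -> consistent
```

The other examples cover back-fitting and temporal properties (`02`) and a
52-vs-61-subject cohort comparison with a planted ΔTr(B→D) = −0.10 (`04`),
where the planted transition survives Holm correction with d ≈ 6 at this
effect size and recording length.

A thin CLI mirrors the library:
`msdyn simulate|peaks|cluster|group-templates|backfit|props|infotheory|compare|run`.

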