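# Methods

## The model

Resting-state EEG is modeled as a sequence of quasi-stable scalp
topographies (microstates): at each instant the average-referenced scalp map
v(t) ∈ R^C is, up to amplitude and noise, one of K unit-norm, zero-mean
template maps. The categorical process X_t recording which template is
active is the object of the temporal analyses. Polarity is treated as
meaningless throughout (spontaneous oscillations flip sign within a state),
so every comparison between maps uses the absolute spatial Pearson
correlation and every template estimate is a sign-free principal component.

## Segmentation pipeline

1. **Average reference** — subtract the instantaneous channel mean
   (idempotent; GFP is invariant to any per-sample offset common to all
   channels).
2. **Band-pass 2–20 Hz** — zero-phase windowed FIR with heuristic transition
   bands, delegated to `mne.filter.filter_data`. The contract (probe tones:
   ≤5% amplitude loss in band, ≥20 dB one octave outside, zero group delay)
   is what the tests pin down; the exact taps are an implementation detail.
3. **GFP** — spatial standard deviation per sample, population convention
   (divide by C). The divide-by-C choice is stated explicitly because both
   conventions circulate; it cancels in GEV and affects nothing downstream
   except the absolute GFP scale.
4. **Smoothing** — Gaussian-weighted moving average, 5 taps, σ = 1.0 sample
   (kernel ≈ [0.054, 0.244, 0.403, 0.244, 0.054]), reflection at the edges.
   Only the window length is conventional; σ is this package's choice.
5. **Peaks** — interior strict local maxima g(t−1) < g(t) ≥ g(t+1); plateaus
   contribute their first sample; endpoints excluded; 0-based indices. When
   more than `max_peaks` (default 10,000) peaks exist, a uniform random
   subsample without replacement is drawn (seeded, deterministic).
6. **AAHC** — every peak map starts as its own cluster; repeatedly the
   cluster with the smallest GEV contribution is dissolved and each orphan
   map reassigned to the surviving cluster of highest squared spatial
   correlation (ties → lowest cluster index); affected templates are
   recomputed as the dominant eigenvector of the members' outer-product sum,
   which keeps the procedure polarity-free. Deterministic for a fixed input
   order. k = 4 by default.
7. **Group templates** — iterative permutation alignment: subjects' sets are
   matched to a running reference by the best of the K! label permutations
   (exhaustive — exact for K = 4) with per-map sign alignment, then the
   reference is recomputed as the aligned mean, renormalized, until the
   matching stabilizes. This is a deliberate design choice over second-level
   clustering: it is deterministic and exactly optimal per iteration.
   A packaged canonical map set (A: left-posterior→right-anterior gradient,
   B: its mirror, C: occipital-symmetric, D: fronto-central peak, computed
   once from standard 10–20 electrode positions) fixes the A–D label order
   when the montage matches; it never affects any numeric result.
8. **Back-fitting** — label(t) = argmax over templates of |corr(v(t), T)|;
   an optional correlation floor marks samples UNASSIGNED (default 0 = no
   floor, matching the no-smoothing default). Optional variants:
   `backfit_peaks` (label GFP peaks only, nearest-peak interpolation) and
   `reject_short_segments` (merge runs below a duration floor). Both are off
   by default.

## Temporal properties

Durations and occurrence rates use interior segments only (the first and
last runs are truncated by the recording edges); a state absent from the
interior reports NaN, not zero. Transition matrices come in two counting
modes: per-sample (all consecutive ordered pairs, diagonal included — the
X_{t+1}|X_t formalism used by the sequence tests) and segment (distinct-state
jumps, zero diagonal — the mode used for cohort comparison of transition
probabilities). UNASSIGNED samples break pairs. Rows never observed are left
as zeros and flagged rather than imputed.

## Sequence tests

All five tests are likelihood-ratio (G) statistics referred to chi-squared
distributions; zero-count cells contribute 0 (the x·ln x → 0 limit). Each
test at α = 0.01 by default; cohort summaries report the fraction of
subjects significant.

* **Markov order m (m = 0, 1, 2)** — the null "X_{t+1} depends on the past
  only through the last m labels" decomposes exactly into one independence
  test per conditioning context, G summed over contexts, df = K^m (K−1)² for
  full-support sequences.
* **Stationarity** — per source state, an independence test between block
  index and destination state over B non-overlapping blocks of length L;
  df = (B−1) K (K−1); evaluated on a 2–40 s block grid (step 2 s) by
  default. Overlapping blocks (a literal reading of the usual description)
  are available behind `overlap=True`, but they violate the independence
  assumption of the chi-squared reference, so non-overlapping is the
  default.
* **Symmetry** — G = 2 Σ_{i≠j} n_ij ln(2 n_ij/(n_ij + n_ji)). For counts
  from a single trajectory the classical df = K(K−1)/2 is wrong: in- and
  out-flows of every state balance to within one event, pinning K−1 linear
  combinations of (n_ij − n_ji), so the statistic is chi-squared with
  (K−1)(K−2)/2 df. This was verified by simulation (KS agreement with
  χ²(3) at p = 0.82 over 500 reversible-chain trajectories; with df = 6 the
  test rejects essentially never). For K = 2 the constraint makes symmetry
  automatic and the test degenerates to p = 1.

**Williams correction.** Raw G statistics are biased upward by O(1/n); for
the order-2 test (256 cells) this inflates the nominal 1% rejection rate to
about 8% on sparse-cell chains at n = 5000. All Markov and stationarity
tests therefore apply the Williams (1976) correction per conditioning
stratum by default (`williams=False` restores plain G). Measured type-I
rates with the correction lie between 0.004 and 0.016 across the nulls
exercised in the tests — inside the 99% binomial band around 0.01 at 1000
replicates.

## Autoinformation

I(τ) = H(X_t) + H(X_{t+τ}) − H(joint), plug-in estimates over all valid
pairs, log base 2 (bits — the base is this package's choice), lag grid
0..4000 ms by default. I(0) equals the marginal entropy. Per-state curves
are the AIF of the binary indicator 1{X_t = s}; at lag 0 they equal the
binary entropy of that state's coverage. The plug-in estimator carries the
usual upward bias of order df/(2 n ln 2); the closed-form oracle for a
stationary first-order chain (joint = diag(π)·T^τ) bounds the agreement
checked in tests (sup-norm < 0.01 bits at n = 2·10^5 over lags ≤ 50).

## Cohort statistics

Pooled-variance Student t (df = n1 + n2 − 2 — the pooled form is forced by
the degrees of freedom the analysis is meant to report for 52 + 61
subjects), two-sided. Holm's step-down correction is applied within feature
families — the 12 off-diagonal transitions as one family, 4 durations as
another, 4 occurrence rates as a third. Cohen's d uses the (n−1)-weighted
pooled SD, sign convention group1 − group2. The visual normality check is
replaced by numeric diagnostics (skewness, excess kurtosis, Shapiro–Wilk).

## The synthetic generator

`SimulationConfig` defaults encode the study conditions the package targets:
31 channels (a 32-electrode 10–20 cap with one lead sacrificed to ECG),
250 Hz, 480 s, K = 4, mean dwell 80 ms, carrier 10 Hz, snr 4. The forward
model is v(t) = a(t)·T[x(t)] + ε with a(t) = |sin(2πf t)| scaled to unit
RMS — the rectified carrier makes GFP peak twice per alpha cycle, matching
the empirical GFP-peak rate — and ε i.i.d. Gaussian per channel scaled to
the requested signal/noise RMS ratio. Dwells are geometric by default
(memoryless: the sample-level process is then exactly first-order Markov,
the right null for calibration) with a gamma option (shape 2) whose
non-geometric dwells make the sequence non-Markovian at every low order —
the regime real microstate sequences occupy. Planted templates are exactly
orthogonal (Gram–Schmidt in the zero-mean subspace): real microstate maps
correlate more, but orthogonality gives the cleanest identifiability
ground truth. Cohort generation perturbs jump-matrix entries and
renormalizes the touched rows; per-subject seeds are spawned
deterministically from a master seed.

What the generator does **not** emulate: volume conduction and realistic
spatial noise correlation, ocular/muscle/MR artifacts, 1/f background
spectra, inter-subject topography variability beyond noise, and
amplitude–state coupling. Passing tests therefore demonstrate algorithmic
correctness and statistical calibration on a faithful state-sequence model,
not robustness to real-world artifact structure.

### Known measurement properties (by construction)

* Per-sample back-fitting fragments dwells: the carrier amplitude dips to
  zero twice per cycle and label noise at the troughs splits segments, so
  raw mean durations read far below the planted dwell (~20 ms vs 80 ms at
  snr 8) even though segment-level transition probabilities are recovered
  within ±0.05. Peak-interpolation labeling instead quantizes boundaries to
  the half-carrier period and overshoots (~100 ms). Duration recovery is
  therefore validated on the generator's planted label sequences; recovered
  durations from back-fitting are comparable *between* cohorts (the
  fragmentation is common-mode) but are not unbiased dwell estimates.
* GFP peak count equals 2·f·duration exactly on the rendered recording;
  after the 2–20 Hz filter, segment-boundary topography blending adds ~16%
  extra small maxima. Peak subsampling makes this immaterial downstream.

## Problem sizes and numerics

Tests and the acceptance script use 60–480 s subjects, up to 10,000 peaks
per subject, 1000-replicate calibration runs at sequence length 5000, and
20-replicate power runs at 52 + 61 subjects — sizes chosen so the full suite
runs in a few minutes while keeping every Monte-Carlo interval informative.
Ties in AAHC reassignment and back-fitting resolve to the lowest state
index; template eigenvectors come from symmetric eigendecomposition of
C × C scatter matrices; all randomness flows through
`numpy.random.default_rng` seeds carried in configs and provenance records.

## Limitations

The AAHC schedule is greedy: it matches the exhaustive-partition optimum on
well-separated inputs (asserted in tests) but carries no global optimality
guarantee. Degrees of freedom assume full-support sequences; contexts never
observed simply drop out of G and df. The stationarity grid treats blocks as
independent chains, ignoring the single shared boundary sample between
adjacent blocks. Explained variance is computed at the clustered peaks, not
over all samples.
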