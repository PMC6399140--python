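"""Information-theoretic characterization of microstate label sequences.

The label sequence X_t is treated as a finite categorical stochastic process
and probed with likelihood-ratio (G) goodness-of-fit tests against chi-squared
nulls:

* Markovianity of order 0, 1 and 2 — does the next label depend on nothing,
  the current label, or the two most recent labels;
* stationarity — is the transition matrix constant across time blocks of a
  given length;
* symmetry — is P(i -> j) equal to P(j -> i) for every state pair.

Temporal memory beyond these parametric nulls is quantified by the
autoinformation function (AIF): the time-lagged mutual information
I(tau) = H(X_t) + H(X_{t+tau}) - H(X_t, X_{t+tau}) in bits, computed for the
global sequence and for single-state indicator sequences.

Zero-count cells contribute 0 to every G statistic (the x*ln(x) -> 0 limit);
degrees of freedom follow the classical likelihood-ratio counts.
"""
from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.stats import chi2

from .datatypes import (
    UNASSIGNED,
    InvalidConfigError,
    InvalidInputError,
    LabelSequence,
    TransitionMatrix,
    UndefinedResultError,
)
from .synthetic import stationary_distribution

LOG2 = np.log(2.0)


@dataclass
class MarkovTestResult:
    """One G-test outcome: statistic, degrees of freedom, p-value, verdict."""

    test: str                     # markov0 | markov1 | markov2 | stationarity | symmetry
    g_statistic: float
    df: int
    p_value: float
    alpha: float
    significant: bool

    @classmethod
    def from_g(cls, test: str, g: float, df: int, alpha: float
               ) -> "MarkovTestResult":
        p = float(chi2.sf(g, df))
        return cls(test, float(g), int(df), p, alpha, p < alpha)


@dataclass
class AIFCurve:
    """Autoinformation values (bits) on a grid of time lags."""

    lags: np.ndarray          # samples
    values: np.ndarray        # bits, >= 0
    sampling_rate: float
    scope: str = "global"     # or "state:<name>"

    @property
    def lags_ms(self) -> np.ndarray:
        return self.lags * 1000.0 / self.sampling_rate


def _valid_tuples(labels: np.ndarray, length: int) -> np.ndarray:
    """Stacked windows of ``length`` consecutive assigned labels (rows)."""
    n = labels.size - length + 1
    if n < 1:
        raise InvalidInputError("sequence shorter than the tuple length")
    cols = [labels[i:i + n] for i in range(length)]
    tup = np.stack(cols, axis=1)
    return tup[(tup != UNASSIGNED).all(axis=1)]


def _xlogy_sum(n: np.ndarray, num: np.ndarray, den: np.ndarray) -> float:
    """2 * sum over observed cells of n * ln(n*num / den)."""
    mask = n > 0
    return float(2.0 * np.sum(n[mask] * np.log(n[mask] * num[mask]
                                               / den[mask])))


def _require_states(labels: np.ndarray) -> None:
    real = labels[labels != UNASSIGNED]
    if real.size == 0 or np.unique(real).size < 2:
        raise UndefinedResultError(
            "test undefined for a constant or empty sequence")


def _independence_g(table: np.ndarray, williams: bool) -> float:
    """G statistic of independence in one contingency table, optionally
    divided by the Williams (1976) small-sample correction factor."""
    n = table.sum()
    ri = table.sum(axis=1)
    cj = table.sum(axis=0)
    expected = np.outer(ri, cj)
    g = _xlogy_sum(table, np.full_like(table, n), expected + (table == 0))
    if williams and n > 0:
        r_eff = int(np.count_nonzero(ri))
        c_eff = int(np.count_nonzero(cj))
        if r_eff > 1 and c_eff > 1:
            q = 1.0 + ((n * np.sum(1.0 / ri[ri > 0]) - 1)
                       * (n * np.sum(1.0 / cj[cj > 0]) - 1)
                       / (6.0 * n * (r_eff - 1) * (c_eff - 1)))
            g /= q
    return g


def _conditional_markov_g(labels: np.ndarray, k: int, order: int,
                          williams: bool) -> tuple[float, int]:
    """Stratified conditional-independence G for Markovianity of ``order``.

    The null 'X_{t+1} depends on the past only through the last ``order``
    labels' decomposes exactly into, per conditioning context (stratum), an
    independence test between the label preceding the context and the label
    following it.  Returns (sum of per-stratum G, sum of per-stratum df).
    """
    tup = _valid_tuples(labels, order + 2)
    if tup.shape[0] == 0:
        raise InvalidInputError("no valid tuples for the requested order")
    ctx = np.zeros(tup.shape[0], dtype=np.int64)
    for c in range(1, order + 1):
        ctx = ctx * k + tup[:, c]
    rows, cols = tup[:, 0], tup[:, -1]
    g_total, df_total = 0.0, 0
    for s in range(k ** order):
        mask = ctx == s
        if not mask.any():
            continue
        table = np.bincount(rows[mask] * k + cols[mask],
                            minlength=k * k).reshape(k, k).astype(float)
        g_total += _independence_g(table, williams)
        df_total += (k - 1) ** 2
    return g_total, df_total


def markov_order0_test(seq: LabelSequence, alpha: float = 0.01,
                       williams: bool = True) -> MarkovTestResult:
    """G-test of zero-order Markovianity: P(X_{t+1}) = P(X_{t+1} | X_t).

    G = 2 sum_ij n_ij ln(n_ij n / (n_i. n_.j)) with df = (K-1)^2 when all
    states occur.  The Williams small-sample correction (on by default)
    removes the O(1/n) upward bias of G so the chi-squared reference is
    calibrated at realistic sequence lengths.
    """
    _require_states(seq.labels)
    g, df = _conditional_markov_g(seq.labels, seq.n_states, 0, williams)
    return MarkovTestResult.from_g("markov0", g, df, alpha)


def markov_order1_test(seq: LabelSequence, alpha: float = 0.01,
                       williams: bool = True) -> MarkovTestResult:
    """G-test of first-order Markovianity:
    P(X_{t+1} | X_t, X_{t-1}) = P(X_{t+1} | X_t).

    Equivalent to G = 2 sum n_ijk ln(n_ijk n_.j. / (n_ij. n_.jk)) summed over
    triples, df = K (K-1)^2 for full-support sequences: the statistic
    decomposes into one independence test per current-state stratum, each
    Williams-corrected by default.
    """
    _require_states(seq.labels)
    g, df = _conditional_markov_g(seq.labels, seq.n_states, 1, williams)
    return MarkovTestResult.from_g("markov1", g, df, alpha)


def markov_order2_test(seq: LabelSequence, alpha: float = 0.01,
                       williams: bool = True) -> MarkovTestResult:
    """G-test of second-order Markovianity over label quadruples,
    conditioning on (X_{t-1}, X_t); df = K^2 (K-1)^2 for full support.

    Quadruple cells are sparse even at typical recording lengths, which
    inflates the raw G badly; the per-stratum Williams correction restores
    the nominal type-I error.
    """
    _require_states(seq.labels)
    g, df = _conditional_markov_g(seq.labels, seq.n_states, 2, williams)
    return MarkovTestResult.from_g("markov2", g, df, alpha)


def _pair_counts(labels: np.ndarray, k: int) -> np.ndarray:
    pairs = _valid_tuples(labels, 2)
    return np.bincount(pairs[:, 0] * k + pairs[:, 1],
                       minlength=k * k).reshape(k, k).astype(float)


def stationarity_test(seq: LabelSequence, block_length: float,
                      alpha: float = 0.01, overlap: bool = False,
                      williams: bool = True) -> MarkovTestResult:
    """G-test of transition-matrix constancy across time blocks.

    ``block_length`` is in seconds.  Blocks are non-overlapping by default
    (overlapping blocks violate the chi-squared independence assumption; pass
    ``overlap=True`` for 50%-step overlapping blocks).  With per-block pair
    counts n^b_ij and pooled counts n_ij:
    G = 2 sum_b sum_ij n^b_ij ln(n^b_ij n_i. / (n_ij n^b_i.)),
    df = (B-1) K (K-1) for full support — per source state this is an
    independence test between block index and destination, Williams-corrected
    by default.
    """
    k = seq.n_states
    _require_states(seq.labels)
    block = int(round(block_length * seq.sampling_rate))
    if block < 2:
        raise InvalidConfigError("block length must cover >= 2 samples")
    step = block // 2 if overlap else block
    starts = range(0, seq.n_samples - block + 1, step)
    blocks = [_pair_counts(seq.labels[s:s + block], k) for s in starts]
    if len(blocks) < 2:
        raise InvalidConfigError("need >= 2 blocks; shorten the block length")
    stacked = np.stack(blocks)  # B x K x K
    n_blocks = stacked.shape[0]
    g, df = 0.0, 0
    for i in range(k):
        table = stacked[:, i, :]  # B x K: block index vs destination
        if table.sum() == 0:
            continue
        g += _independence_g(table.astype(float), williams)
        df += (n_blocks - 1) * (k - 1)
    return MarkovTestResult.from_g("stationarity", g, df, alpha)


def symmetry_test(seq: LabelSequence, alpha: float = 0.01) -> MarkovTestResult:
    """G-test of transition symmetry P(i -> j) = P(j -> i).

    G = 2 sum_{i != j} n_ij ln(2 n_ij / (n_ij + n_ji)).

    For counts from a single trajectory the K(K-1)/2 pairwise differences are
    not free: in- and out-flows of every state balance to within one event,
    which pins K-1 linear combinations of (n_ij - n_ji) at ~0.  The statistic
    is therefore chi-squared with df = (K-1)(K-2)/2 (verified by simulation
    against reversible chains); the familiar K(K-1)/2 applies only to
    independently sampled pairs.  For K = 2 the constraint makes symmetry
    automatic and the test degenerates (p = 1).
    """
    k = seq.n_states
    _require_states(seq.labels)
    n_ij = _pair_counts(seq.labels, k)
    off = ~np.eye(k, dtype=bool)
    if n_ij[off].sum() == 0:
        raise UndefinedResultError("no off-diagonal transitions observed")
    sym = n_ij + n_ij.T
    n = np.where(off, n_ij, 0.0)
    g = _xlogy_sum(n, np.full_like(n, 2.0), sym + (n == 0))
    df = (k - 1) * (k - 2) // 2
    if df == 0:
        return MarkovTestResult("symmetry", float(g), 0, 1.0, alpha, False)
    return MarkovTestResult.from_g("symmetry", g, df, alpha)


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)) / LOG2)


def _mi_at_lag(labels: np.ndarray, k: int, lag: int) -> float:
    """Plug-in mutual information (bits) between X_t and X_{t+lag}."""
    if lag == 0:
        a = labels[labels != UNASSIGNED]
        return _entropy_bits(np.bincount(a, minlength=k) / a.size)
    a, b = labels[:-lag], labels[lag:]
    ok = (a != UNASSIGNED) & (b != UNASSIGNED)
    a, b = a[ok], b[ok]
    joint = np.bincount(a * k + b, minlength=k * k).reshape(k, k) / a.size
    return (_entropy_bits(joint.sum(axis=1)) + _entropy_bits(joint.sum(axis=0))
            - _entropy_bits(joint.ravel()))


def aif(seq: LabelSequence, max_lag_ms: float = 4000.0) -> AIFCurve:
    """Autoinformation function on the lag grid 0 .. max_lag (samples).

    Plug-in (maximum-likelihood) estimate from all valid sample pairs, in
    bits.  Lags reaching beyond the sequence truncate the grid with a warning.
    """
    k = seq.n_states
    max_lag = int(round(max_lag_ms * seq.sampling_rate / 1000.0))
    if max_lag >= seq.n_samples:
        warnings.warn("max lag exceeds the sequence; truncating the lag grid",
                      stacklevel=2)
        max_lag = seq.n_samples - 1
    lags = np.arange(max_lag + 1)
    values = np.array([_mi_at_lag(seq.labels, k, int(lag)) for lag in lags])
    return AIFCurve(lags, values, seq.sampling_rate, scope="global")


def partial_aif(seq: LabelSequence, state: int | str,
                max_lag_ms: float = 4000.0) -> AIFCurve:
    """AIF of the binary indicator 1{X_t = state} (one microstate's memory)."""
    if isinstance(state, str):
        if state not in seq.state_names:
            raise UndefinedResultError(f"unknown state {state!r}")
        state = seq.state_names.index(state)
    if not np.any(seq.labels == state):
        raise UndefinedResultError("state absent from the sequence")
    indicator = np.where(seq.labels == UNASSIGNED, UNASSIGNED,
                         (seq.labels == state).astype(np.int64))
    ind_seq = LabelSequence(indicator, seq.sampling_rate,
                            state_names=["other", str(seq.state_names[state])])
    curve = aif(ind_seq, max_lag_ms)
    return AIFCurve(curve.lags, curve.values, seq.sampling_rate,
                    scope=f"state:{seq.state_names[state]}")


def markov_aif_closed_form(transition: np.ndarray | TransitionMatrix,
                           lag: int) -> float:
    """Exact AIF of a stationary first-order Markov chain at one lag (bits).

    With stationary distribution pi and joint P = diag(pi) T^lag:
    I(lag) = 2 H(pi) - H(P).  Serves as the independent oracle for the
    plug-in estimator.
    """
    t = (transition.probs if isinstance(transition, TransitionMatrix)
         else np.asarray(transition, dtype=float))
    pi = stationary_distribution(t)
    joint = np.diag(pi) @ np.linalg.matrix_power(t, lag)
    return 2.0 * _entropy_bits(pi) - _entropy_bits(joint.ravel())


def cohort_summary(results: list[MarkovTestResult]) -> float:
    """Fraction of subjects whose test came out significant."""
    if not results:
        raise InvalidInputError("empty result list")
    return sum(r.significant for r in results) / len(results)


def stationarity_profile(seq: LabelSequence, block_grid_s: np.ndarray,
                         alpha: float = 0.05, overlap: bool = False
                         ) -> list[MarkovTestResult]:
    """Stationarity test across a grid of block lengths (seconds)."""
    return [stationarity_test(seq, float(b), alpha=alpha, overlap=overlap)
            for b in block_grid_s]
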