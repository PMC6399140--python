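"""Synthetic resting-state EEG with planted microstate structure.

The generator produces the ground truth every downstream stage is tested
against: K unit-norm topographies activated one at a time by a semi-Markov
state sequence (Markov jump chain between distinct states, i.i.d. dwell
times), amplitude-modulated by a rectified alpha-band carrier so that GFP
maxima occur twice per carrier cycle, plus additive channel noise at a
configurable signal-to-noise ratio.  Bare categorical sequences of known
Markov order are also provided for calibrating the sequence-level tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import (
    EEGRecording,
    InvalidConfigError,
    InvalidInputError,
    LabelSequence,
    TemplateSet,
    TransitionMatrix,
    default_state_names,
)


def _uniform_jump_matrix(k: int) -> np.ndarray:
    """Zero-diagonal jump matrix with uniform off-diagonal probabilities."""
    if k == 1:
        return np.ones((1, 1))
    m = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(m, 0.0)
    return m


@dataclass
class SimulationConfig:
    """Parameters of one synthetic subject.

    Defaults emulate an 8-minute, 31-channel 10-20-montage recording sampled
    at 250 Hz with four microstates dwelling ~80 ms, riding a 10 Hz carrier.
    """

    n_channels: int = 31
    n_states: int = 4
    sampling_rate: float = 250.0
    duration: float = 480.0
    transition_matrix: np.ndarray | None = None
    dwell_mean: float = 80.0  # ms
    dwell_dist: str = "geometric"  # or "gamma"
    gamma_shape: float = 2.0
    carrier_freq: float = 10.0
    snr: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise InvalidConfigError("n_states must be >= 1")
        if self.transition_matrix is None:
            self.transition_matrix = _uniform_jump_matrix(self.n_states)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        t = self.transition_matrix
        if t.shape != (self.n_states, self.n_states):
            raise InvalidConfigError("transition_matrix must be K x K")
        if np.any(t < 0) or np.any(t > 1):
            raise InvalidConfigError("jump probabilities must lie in [0, 1]")
        if self.n_states > 1:
            if np.any(np.diag(t) != 0):
                raise InvalidConfigError("jump matrix must have zero diagonal")
            if np.any(np.abs(t.sum(axis=1) - 1.0) > 1e-12):
                raise InvalidConfigError("jump matrix rows must sum to 1")
        if self.dwell_mean <= 0:
            raise InvalidConfigError("dwell_mean must be positive (ms)")
        if self.dwell_dist not in ("geometric", "gamma"):
            raise InvalidConfigError("dwell_dist must be 'geometric' or 'gamma'")
        if self.gamma_shape <= 0:
            raise InvalidConfigError("gamma_shape must be positive")
        if self.snr <= 0:
            raise InvalidConfigError("snr must be positive")
        n = self.duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise InvalidConfigError(
                "duration x sampling_rate must be an integer sample count")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    @property
    def dwell_mean_samples(self) -> float:
        return self.dwell_mean * self.sampling_rate / 1000.0


@dataclass
class SyntheticGroundTruth:
    """Everything planted in one synthetic subject."""

    templates: TemplateSet
    labels: LabelSequence
    jump_matrix: TransitionMatrix
    config: SimulationConfig


def make_templates(n_channels: int, n_states: int, seed: int) -> TemplateSet:
    """Draw K planted topographies: zero-mean, unit-norm, mutually orthogonal.

    Gaussian draws are projected onto the average-reference subspace and
    Gram-Schmidt orthogonalized, so pairwise spatial correlation is exactly 0
    (well under the 0.5 ceiling real microstate maps respect).
    """
    if n_states < 2:
        raise InvalidConfigError("n_states must be >= 2")
    if n_channels <= n_states:
        raise InvalidConfigError("need more channels than states")
    rng = np.random.default_rng(seed)
    maps = np.empty((n_states, n_channels))
    for i in range(n_states):
        for _ in range(100):
            v = rng.standard_normal(n_channels)
            v -= v.mean()
            for j in range(i):
                v -= (v @ maps[j]) * maps[j]
            norm = np.linalg.norm(v)
            if norm > 1e-6:
                maps[i] = v / norm
                break
        else:  # pragma: no cover - probability zero for float draws
            raise InvalidConfigError("could not draw independent maps")
    return TemplateSet(maps=maps, labels=default_state_names(n_states))


def _draw_dwells(rng: np.random.Generator, n: int, config: SimulationConfig
                 ) -> np.ndarray:
    """Dwell lengths in samples (integer, >= 1)."""
    mean = config.dwell_mean_samples
    if config.dwell_dist == "geometric":
        p = min(1.0, 1.0 / max(mean, 1.0))
        return rng.geometric(p, size=n)
    shape = config.gamma_shape
    draws = rng.gamma(shape, mean / shape, size=n)
    return np.maximum(1, np.rint(draws).astype(np.int64))


def sample_state_sequence(config: SimulationConfig) -> LabelSequence:
    """Semi-Markov label sequence: jump chain + i.i.d. dwell times.

    With geometric dwells the per-sample process is first-order Markov; with
    gamma dwells (shape != 1) it is non-Markovian at every low order, which
    is the regime resting-state microstate sequences empirically occupy.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    k = config.n_states
    if k == 1:
        return LabelSequence(np.zeros(n, dtype=np.int64), config.sampling_rate,
                             default_state_names(1))
    jump_cdf = np.cumsum(config.transition_matrix, axis=1)
    # oversample segments in blocks until the sample budget is covered
    mean_seg = max(config.dwell_mean_samples, 1.0)
    states: list[np.ndarray] = []
    lengths: list[np.ndarray] = []
    total = 0
    current = int(rng.integers(k))
    while total < n:
        block = max(16, int(1.2 * (n - total) / mean_seg) + 4)
        dw = _draw_dwells(rng, block, config)
        st = np.empty(block, dtype=np.int64)
        u = rng.random(block)
        for b in range(block):
            st[b] = current
            current = int(np.searchsorted(jump_cdf[current], u[b], side="right"))
        states.append(st)
        lengths.append(dw)
        total += int(dw.sum())
    labels = np.repeat(np.concatenate(states), np.concatenate(lengths))[:n]
    return LabelSequence(labels, config.sampling_rate, default_state_names(k))


def sample_markov_sequence(transition: np.ndarray, n: int, seed: int,
                           order: int = 1) -> LabelSequence:
    """Sequence with exactly the requested dependence structure.

    order=1 draws a first-order chain from ``transition`` (diagonal allowed),
    started from its stationary distribution; order=0 draws i.i.d. samples
    from that stationary distribution.
    """
    t = np.asarray(transition, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise InvalidConfigError("transition matrix must be square")
    if np.any(t < 0) or np.any(np.abs(t.sum(axis=1) - 1.0) > 1e-9):
        raise InvalidConfigError("transition matrix must be row-stochastic")
    if order not in (0, 1):
        raise InvalidConfigError("order must be 0 or 1")
    k = t.shape[0]
    pi = stationary_distribution(t)
    rng = np.random.default_rng(seed)
    if order == 0:
        labels = rng.choice(k, size=n, p=pi)
        return LabelSequence(labels.astype(np.int64), 1.0,
                             default_state_names(k))
    cdf = np.cumsum(t, axis=1)
    labels = np.empty(n, dtype=np.int64)
    labels[0] = rng.choice(k, p=pi)
    u = rng.random(n)
    for i in range(1, n):
        labels[i] = np.searchsorted(cdf[labels[i - 1]], u[i], side="right")
    return LabelSequence(labels, 1.0, default_state_names(k))


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Leading left eigenvector of a row-stochastic matrix, normalized."""
    t = np.asarray(transition, dtype=float)
    vals, vecs = np.linalg.eig(t.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    if abs(vals[idx] - 1.0) > 1e-8:
        raise InvalidConfigError("matrix has no unit eigenvalue")
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    s = pi.sum()
    if s == 0:
        raise InvalidConfigError("degenerate stationary distribution")
    return pi / s


def render_eeg(labels: LabelSequence, templates: TemplateSet,
               config: SimulationConfig, *, noise: bool = True
               ) -> EEGRecording:
    """Forward model: v(t) = a(t) * template[x(t)] + noise.

    a(t) = |sin(2 pi f t)| scaled to unit RMS, so GFP maxima track the
    carrier amplitude maxima (twice per cycle, as the alpha rhythm does to
    real GFP).  Noise is zero-mean Gaussian per channel, scaled to
    signal-RMS / noise-RMS = config.snr.
    """
    if templates.k < labels.labels.max() + 1:
        raise InvalidInputError("label values exceed template count")
    n = labels.n_samples
    t = np.arange(n) / config.sampling_rate
    carrier = np.abs(np.sin(2 * np.pi * config.carrier_freq * t))
    rms = np.sqrt(np.mean(carrier ** 2))
    carrier = carrier / rms
    signal = carrier[None, :] * templates.maps[labels.labels].T
    if noise:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xEE6]))
        eps = rng.standard_normal(signal.shape)
        sig_rms = np.sqrt(np.mean(signal ** 2))
        eps *= sig_rms / (config.snr * np.sqrt(np.mean(eps ** 2)))
        signal = signal + eps
    return EEGRecording(signal, config.sampling_rate,
                        channel_labels=[f"ch{i:02d}" for i in
                                        range(templates.n_channels)])


def simulate_subject(config: SimulationConfig, *, templates: TemplateSet | None
                     = None, render: bool = True
                     ) -> tuple[EEGRecording | None, SyntheticGroundTruth]:
    """One subject end to end: templates, labels, and (optionally) the EEG."""
    if templates is None:
        templates = make_templates(config.n_channels, config.n_states,
                                   seed=config.seed)
    labels = sample_state_sequence(config)
    counts = np.zeros((config.n_states,) * 2, dtype=np.int64)
    jump = TransitionMatrix(config.transition_matrix, counts, mode="segment",
                            state_names=list(templates.labels))
    truth = SyntheticGroundTruth(templates, labels, jump, config)
    rec = render_eeg(labels, templates, config) if render else None
    return rec, truth


def perturb_jump_matrix(base: np.ndarray, effect: dict[tuple[int, int], float]
                        ) -> np.ndarray:
    """Add per-entry deltas to a zero-diagonal jump matrix, renormalizing
    each touched row.  Raises if any probability leaves [0, 1]."""
    t = np.array(base, dtype=float)
    for (i, j), delta in effect.items():
        if i == j:
            raise InvalidConfigError("cannot perturb the (zero) diagonal")
        t[i, j] += delta
    if np.any(t < -1e-12) or np.any(t > 1 + 1e-12):
        raise InvalidConfigError("perturbation drives a probability outside [0,1]")
    t = np.clip(t, 0.0, None)
    sums = t.sum(axis=1)
    if np.any(sums <= 0):
        raise InvalidConfigError("perturbation empties a row")
    return t / sums[:, None]


def generate_cohorts(n_per_group: tuple[int, int],
                     base_config: SimulationConfig,
                     effect: dict[tuple[int, int], float] | None,
                     seed: int, *, render: bool = True, shared_templates: bool
                     = True) -> tuple[list, list]:
    """Two cohorts of synthetic subjects differing only in the jump matrix.

    Group 1 uses the base jump matrix; group 2 uses base + effect with the
    touched rows renormalized.  Per-subject seeds are spawned deterministically
    from ``seed``.  Returns two lists of (EEGRecording | None,
    SyntheticGroundTruth).
    """
    t2 = (perturb_jump_matrix(base_config.transition_matrix, effect)
          if effect else np.array(base_config.transition_matrix))
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in ss.spawn(sum(n_per_group) + 1)]
    templates = (make_templates(base_config.n_channels, base_config.n_states,
                                seed=child_seeds[-1])
                 if shared_templates else None)
    groups: tuple[list, list] = ([], [])
    idx = 0
    for g, (n_g, matrix) in enumerate(
            zip(n_per_group, (base_config.transition_matrix, t2))):
        for _ in range(n_g):
            cfg = replace(base_config, transition_matrix=np.array(matrix),
                          seed=child_seeds[idx])
            groups[g].append(simulate_subject(cfg, templates=templates,
                                              render=render))
            idx += 1
    return groups
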