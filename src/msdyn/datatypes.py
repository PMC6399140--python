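"""Core containers shared across the pipeline.

Everything downstream of raw EEG flows through four objects: the recording
itself (channels x samples), the set of microstate template topographies, the
per-sample label sequence, and the transition matrix of that sequence.  All
are lightweight dataclasses around numpy arrays with validated invariants.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Label value marking samples that no template claimed (below the
#: correlation floor during back-fitting).
UNASSIGNED: int = -1

#: Default state names for the canonical four-class decomposition.
STATE_NAMES_K4 = ("A", "B", "C", "D")


class InvalidInputError(ValueError):
    """A data object violates an operation's preconditions."""


class InvalidConfigError(ValueError):
    """A configuration value is outside its admissible range."""


class UndefinedResultError(ValueError):
    """The requested quantity is mathematically undefined for this input
    (zero-variance map, absent state, degenerate test, ...)."""


def default_state_names(k: int) -> list[str]:
    """A, B, C, D, then S4, S5, ... for k beyond the canonical four."""
    base = list(STATE_NAMES_K4)
    if k <= 4:
        return base[:k]
    return base + [f"S{i}" for i in range(4, k)]


@dataclass
class EEGRecording:
    """Multichannel EEG: a channels x samples voltage matrix (microvolts)."""

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidInputError("EEG data must be channels x samples")
        if self.data.shape[0] < 2:
            raise InvalidInputError("an EEG recording needs >= 2 channels")
        if not np.all(np.isfinite(self.data)):
            raise InvalidInputError("EEG data contains non-finite values")
        if self.sampling_rate <= 0:
            raise InvalidInputError("sampling_rate must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise InvalidInputError("channel_labels length != channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass
class TemplateSet:
    """K unit-norm, zero-mean microstate topographies (K x C).

    Polarity is meaningless: a TemplateSet represents the same object as its
    row-wise negation, and all comparisons use absolute spatial correlation.
    """

    maps: np.ndarray
    labels: list[str] = field(default_factory=list)
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise InvalidInputError("template maps must be K x C")
        means = self.maps.mean(axis=1)
        norms = np.linalg.norm(self.maps, axis=1)
        if np.any(np.abs(means) > 1e-8) or np.any(np.abs(norms - 1.0) > 1e-8):
            # normalize rather than reject: inputs may carry benign float drift
            self.maps = self.maps - self.maps.mean(axis=1, keepdims=True)
            norms = np.linalg.norm(self.maps, axis=1)
            if np.any(norms == 0):
                raise InvalidInputError("zero-variance template map")
            self.maps = self.maps / norms[:, None]
        if not self.labels:
            self.labels = default_state_names(self.k)
        if len(self.labels) != self.k:
            raise InvalidInputError("labels length != number of maps")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


@dataclass
class GFPSeries:
    """Global field power per sample: the spatial standard deviation of the
    average-referenced scalp map (microvolts, nonnegative)."""

    values: np.ndarray
    sampling_rate: float
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InvalidInputError("GFP must be a 1-D series")
        if np.any(self.values < -1e-12):
            raise InvalidInputError("GFP values must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass
class PeakSet:
    """Sample indices (0-based, strictly increasing) of GFP local maxima,
    possibly subsampled to at most ``max peaks`` entries."""

    indices: np.ndarray
    n_total: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.ndim != 1:
            raise InvalidInputError("peak indices must be 1-D")
        if self.indices.size > 1 and np.any(np.diff(self.indices) <= 0):
            raise InvalidInputError("peak indices must be strictly increasing")
        if self.n_total == 0:
            self.n_total = int(self.indices.size)

    @property
    def n_selected(self) -> int:
        return int(self.indices.size)


@dataclass
class LabelSequence:
    """Per-sample microstate labels: the categorical process X_t over states.

    Values are state indices 0..K-1, or ``UNASSIGNED`` (-1) where a
    correlation floor rejected the sample during back-fitting.
    """

    labels: np.ndarray
    sampling_rate: float
    state_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise InvalidInputError("labels must be a 1-D sequence")
        if self.sampling_rate <= 0:
            raise InvalidInputError("sampling_rate must be positive")
        k_seen = int(self.labels.max()) + 1 if self.labels.size else 0
        if not self.state_names:
            self.state_names = default_state_names(max(k_seen, 1))
        if k_seen > len(self.state_names):
            raise InvalidInputError("labels exceed the declared state count")
        if self.labels.size and self.labels.min() < UNASSIGNED:
            raise InvalidInputError("labels must be >= -1")

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_samples(self) -> int:
        return self.labels.shape[0]

    def assigned(self) -> np.ndarray:
        """Boolean mask of samples carrying a real state label."""
        return self.labels != UNASSIGNED


@dataclass
class TransitionMatrix:
    """Row-stochastic matrix T_ij = P(X_{t+1}=S_j | X_t=S_i).

    ``mode='per_sample'`` counts every ordered pair of consecutive samples
    (self-transitions on the diagonal); ``mode='segment'`` counts only jumps
    between consecutive distinct segments (zero diagonal).
    """

    probs: np.ndarray
    counts: np.ndarray
    mode: str = "per_sample"
    state_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.probs.shape != self.counts.shape or self.probs.ndim != 2:
            raise InvalidInputError("probs and counts must be square K x K")
        if self.probs.shape[0] != self.probs.shape[1]:
            raise InvalidInputError("transition matrix must be square")
        row_tot = self.counts.sum(axis=1)
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums[row_tot > 0] - 1.0) > 1e-9):
            raise InvalidInputError("rows with observations must sum to 1")
        if self.mode == "segment" and np.any(np.diag(self.counts) != 0):
            raise InvalidInputError("segment-mode matrix must have zero diagonal")
        if not self.state_names:
            self.state_names = default_state_names(self.k)

    @property
    def k(self) -> int:
        return self.probs.shape[0]

    @property
    def empty_rows(self) -> np.ndarray:
        """States never observed as a transition source (flagged, kept zero)."""
        return self.counts.sum(axis=1) == 0
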