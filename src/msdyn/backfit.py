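"""Back-fitting and microstate temporal properties.

Every sample of the (filtered, average-referenced) recording is labeled with
the template of highest absolute spatial correlation, yielding the categorical
process X_t analyzed downstream.  From the label sequence we extract the
classical microstate statistics: mean duration (lifespan), occurrence rate,
coverage, and transition matrices in both per-sample and segment counting
modes.
"""
from __future__ import annotations

import numpy as np

from .datatypes import (
    UNASSIGNED,
    EEGRecording,
    InvalidInputError,
    LabelSequence,
    TemplateSet,
    TransitionMatrix,
)


def backfit(rec: EEGRecording, templates: TemplateSet, min_corr: float = 0.0
            ) -> LabelSequence:
    """Label each sample with its best-correlated template.

    Correlation is polarity-free (absolute value); samples whose best
    correlation falls below ``min_corr`` are marked UNASSIGNED.  Exact ties
    resolve to the lowest state index.
    """
    if rec.n_channels != templates.n_channels:
        raise InvalidInputError("recording and templates differ in channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(data, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    corr = np.abs(templates.maps @ (data / safe))  # K x T
    labels = np.argmax(corr, axis=0).astype(np.int64)
    best = corr[labels, np.arange(corr.shape[1])]
    labels[(best < min_corr) | (norms == 0)] = UNASSIGNED
    return LabelSequence(labels, rec.sampling_rate,
                         state_names=list(templates.labels))


def backfit_peaks(rec: EEGRecording, templates: TemplateSet,
                  peak_indices: np.ndarray, min_corr: float = 0.0
                  ) -> LabelSequence:
    """Peak-only labeling with nearest-peak interpolation.

    Only the GFP-peak samples (high topographic signal-to-noise) are labeled
    directly; every other sample inherits the label of its nearest peak.
    Coarser than per-sample fitting — boundaries quantize to midpoints between
    peaks — but immune to the label noise at GFP troughs.
    """
    peak_indices = np.asarray(peak_indices, dtype=np.int64)
    if peak_indices.size == 0:
        raise InvalidInputError("need at least one peak index")
    full = backfit(rec, templates, min_corr=min_corr)
    peak_labels = full.labels[peak_indices]
    pos = np.arange(rec.n_samples)
    right = np.searchsorted(peak_indices, pos)
    left = np.clip(right - 1, 0, peak_indices.size - 1)
    right = np.clip(right, 0, peak_indices.size - 1)
    nearest = np.where(np.abs(peak_indices[left] - pos)
                       <= np.abs(peak_indices[right] - pos), left, right)
    return LabelSequence(peak_labels[nearest], rec.sampling_rate,
                         state_names=list(templates.labels))


def reject_short_segments(seq: LabelSequence, min_ms: float,
                          max_passes: int = 20) -> LabelSequence:
    """Merge runs shorter than ``min_ms`` into the longer adjacent run.

    Optional temporal smoothing (off by default everywhere): repeats until no
    run is below the floor or ``max_passes`` is reached.
    """
    min_len = max(1, int(round(min_ms * seq.sampling_rate / 1000.0)))
    labels = seq.labels.copy()
    for _ in range(max_passes):
        change = np.flatnonzero(np.diff(labels)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [labels.size]))
        lens = ends - starts
        short = np.flatnonzero(lens < min_len)
        if short.size == 0:
            break
        for si in short:
            s, e = starts[si], ends[si]
            if s == 0 and e == labels.size:
                break
            if s == 0:
                labels[s:e] = labels[e]
            elif e == labels.size:
                labels[s:e] = labels[s - 1]
            else:
                llen = lens[si - 1]
                rlen = lens[si + 1] if si + 1 < lens.size else 0
                labels[s:e] = labels[s - 1] if llen >= rlen else labels[e]
    return LabelSequence(labels, seq.sampling_rate, list(seq.state_names))


def segments(seq: LabelSequence) -> list[tuple[int, int, int]]:
    """Run-length encoding: maximal runs as (state, start, length), in order,
    with half-open sample intervals [start, start+length)."""
    labels = seq.labels
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [(int(labels[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def _interior_segments(seq: LabelSequence) -> list[tuple[int, int, int]]:
    """Segments minus the first and last (truncated at the recording edges)."""
    segs = segments(seq)
    if len(segs) < 3:
        raise InvalidInputError("need >= 3 segments for duration statistics")
    return segs[1:-1]


def mean_durations(seq: LabelSequence) -> dict[str, float]:
    """Mean lifespan per state in milliseconds, over interior segments only.

    States absent from the interior map to NaN (missing, not zero).
    """
    interior = _interior_segments(seq)
    out: dict[str, float] = {}
    per_sample_ms = 1000.0 / seq.sampling_rate
    for state, name in enumerate(seq.state_names):
        lengths = [ln for (st, _, ln) in interior if st == state]
        out[name] = (float(np.mean(lengths)) * per_sample_ms if lengths
                     else float("nan"))
    return out


def occurrence_rates(seq: LabelSequence) -> dict[str, float]:
    """Interior segment onsets per state divided by analyzed duration (s)."""
    interior = _interior_segments(seq)
    analyzed_s = sum(ln for (_, _, ln) in interior) / seq.sampling_rate
    out: dict[str, float] = {}
    for state, name in enumerate(seq.state_names):
        n_onsets = sum(1 for (st, _, _) in interior if st == state)
        out[name] = n_onsets / analyzed_s
    return out


def coverage(seq: LabelSequence) -> dict[str, float]:
    """Fraction of assigned samples spent in each state (sums to 1)."""
    mask = seq.assigned()
    total = int(mask.sum())
    if total == 0:
        raise InvalidInputError("no assigned samples")
    counts = np.bincount(seq.labels[mask], minlength=seq.n_states)
    return {name: counts[i] / total for i, name in enumerate(seq.state_names)}


def transition_matrix(seq: LabelSequence, mode: str = "per_sample"
                      ) -> TransitionMatrix:
    """Empirical transition matrix of the label sequence.

    per_sample: all ordered consecutive pairs (diagonal included); segment:
    consecutive distinct-segment pairs (zero diagonal).  UNASSIGNED samples
    break pairs.  Empty rows are left as zeros and flagged via
    ``TransitionMatrix.empty_rows``.
    """
    k = seq.n_states
    counts = np.zeros((k, k), dtype=np.int64)
    if mode == "per_sample":
        a, b = seq.labels[:-1], seq.labels[1:]
        ok = (a != UNASSIGNED) & (b != UNASSIGNED)
        if not ok.any():
            raise InvalidInputError("need >= 2 consecutive assigned samples")
        np.add.at(counts, (a[ok], b[ok]), 1)
    elif mode == "segment":
        states = [st for (st, _, _) in segments(seq)]
        pairs = [(a, b) for a, b in zip(states[:-1], states[1:])
                 if a != UNASSIGNED and b != UNASSIGNED]
        if not pairs:
            raise InvalidInputError("need >= 2 segments")
        for a, b in pairs:
            counts[a, b] += 1
    else:
        raise InvalidInputError("mode must be 'per_sample' or 'segment'")
    row = counts.sum(axis=1)
    probs = np.divide(counts, row[:, None], where=row[:, None] > 0,
                      out=np.zeros((k, k)))
    return TransitionMatrix(probs, counts, mode=mode,
                            state_names=list(seq.state_names))


def microstate_properties(seq: LabelSequence) -> dict[str, dict[str, float]]:
    """Duration, occurrence, and coverage per state in one call."""
    return {
        "mean_duration_ms": mean_durations(seq),
        "occurrence_per_s": occurrence_rates(seq),
        "coverage": coverage(seq),
    }
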