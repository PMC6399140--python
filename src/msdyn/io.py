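"""File formats: EEG readers (delimited text, EDF, BrainVision), and writers
for the pipeline's text artifacts (delimited matrices, label files, template
tables, JSON sidecars).

The delimited-matrix dialect is comma-separated with a header row of channel
labels and one row per channel; the sampling rate travels in a JSON sidecar
(`<file>.json`) or is passed explicitly — it is never guessed.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .datatypes import (
    EEGRecording,
    InvalidInputError,
    LabelSequence,
    TemplateSet,
)

__all__ = [
    "read_eeg", "write_delimited", "read_delimited", "write_edf",
    "write_labels", "read_labels", "write_templates", "read_templates",
]


def read_eeg(path: str | Path, fmt: str | None = None,
             sampling_rate: float | None = None) -> EEGRecording:
    """Read a recording from delimited text, EDF, or BrainVision.

    ``fmt`` is sniffed from the extension when omitted (.csv/.txt/.tsv ->
    delimited, .edf -> edf, .vhdr -> brainvision).  Delimited files need a
    sampling rate, either from a `<file>.json` sidecar or the argument.
    """
    path = Path(path)
    if fmt is None:
        ext = path.suffix.lower()
        fmt = {".csv": "delimited", ".txt": "delimited", ".tsv": "delimited",
               ".edf": "edf", ".vhdr": "brainvision"}.get(ext)
        if fmt is None:
            raise InvalidInputError(f"cannot sniff format from {path.name!r}")
    if fmt == "delimited":
        return read_delimited(path, sampling_rate=sampling_rate)
    if fmt == "edf":
        import mne
        raw = mne.io.read_raw_edf(path, preload=True, verbose=False)
        return EEGRecording(raw.get_data() * 1e6, raw.info["sfreq"],
                            list(raw.ch_names), subject_id=path.stem)
    if fmt == "brainvision":
        import mne
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose=False)
        return EEGRecording(raw.get_data() * 1e6, raw.info["sfreq"],
                            list(raw.ch_names), subject_id=path.stem)
    raise InvalidInputError(f"unknown format {fmt!r}")


def read_delimited(path: str | Path, sampling_rate: float | None = None
                   ) -> EEGRecording:
    """Comma-separated channels x samples matrix with a channel-label header."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header:
            raise InvalidInputError(f"{path}: empty file")
        labels = header.split(",")
        try:
            data = np.loadtxt(fh, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise InvalidInputError(f"{path}: malformed matrix: {exc}") from exc
    if data.shape[0] != len(labels):
        raise InvalidInputError(
            f"{path}: {len(labels)} header labels but {data.shape[0]} rows")
    if sampling_rate is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise InvalidInputError(
                f"{path}: sampling rate unknown; provide it or a JSON sidecar")
        sampling_rate = json.loads(sidecar.read_text())["sampling_rate"]
    return EEGRecording(data, float(sampling_rate), labels,
                        subject_id=path.stem)


def write_delimited(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as the delimited dialect plus a JSON sidecar."""
    path = Path(path)
    header = ",".join(rec.channel_labels)
    np.savetxt(path, rec.data, delimiter=",", header=header, comments="",
               fmt="%.17g")  # round-trips float64 exactly
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"sampling_rate": rec.sampling_rate,
                                   "subject_id": rec.subject_id}))


def write_edf(rec: EEGRecording, path: str | Path) -> None:
    """Minimal EDF writer (16-bit, one data record per second).

    Covers the plain continuous-EEG case; physical range is taken from the
    data.  No installed library writes EDF, so this implements the format's
    fixed-width ASCII header + little-endian int16 records directly.
    """
    path = Path(path)
    fs = rec.sampling_rate
    spr = int(round(fs))  # samples per 1 s record
    if abs(spr - fs) > 1e-9:
        raise InvalidInputError("EDF writer requires an integer sampling rate")
    n_rec = int(np.ceil(rec.n_samples / spr))
    padded = np.zeros((rec.n_channels, n_rec * spr))
    padded[:, :rec.n_samples] = rec.data
    pmax = float(np.max(np.abs(padded))) or 1.0
    pmin = -pmax
    dmax, dmin = 32767, -32768
    scaled = np.clip(np.rint((padded - pmin) / (pmax - pmin)
                             * (dmax - dmin) + dmin), dmin, dmax).astype("<i2")

    def f(text: str, width: int) -> bytes:
        s = str(text)[:width]
        return s.ljust(width).encode("ascii")

    nch = rec.n_channels
    header = b"".join([
        f("0", 8), f(rec.subject_id or "X", 80), f("synthetic", 80),
        f("01.01.00", 8), f("00.00.00", 8), f(str(256 * (nch + 1)), 8),
        f("", 44), f(str(n_rec), 8), f("1", 8), f(str(nch), 4),
    ])
    header += b"".join(f(lbl, 16) for lbl in rec.channel_labels)
    header += b"".join(f("EEG", 80) for _ in range(nch))
    header += b"".join(f("uV", 8) for _ in range(nch))
    header += b"".join(f(f"{pmin:.6g}", 8) for _ in range(nch))
    header += b"".join(f(f"{pmax:.6g}", 8) for _ in range(nch))
    header += b"".join(f(str(dmin), 8) for _ in range(nch))
    header += b"".join(f(str(dmax), 8) for _ in range(nch))
    header += b"".join(f("", 80) for _ in range(nch))
    header += b"".join(f(str(spr), 8) for _ in range(nch))
    header += b"".join(f("", 32) for _ in range(nch))
    with path.open("wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(scaled[:, r * spr:(r + 1) * spr].tobytes())


def write_labels(seq: LabelSequence, path: str | Path) -> None:
    """One integer per line (-1 = unassigned) plus a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, seq.labels, fmt="%d")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"sampling_rate": seq.sampling_rate,
                                   "state_names": list(seq.state_names)}))


def read_labels(path: str | Path, sampling_rate: float | None = None,
                state_names: list[str] | None = None) -> LabelSequence:
    path = Path(path)
    labels = np.loadtxt(path, dtype=np.int64, ndmin=1)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        sampling_rate = sampling_rate or meta.get("sampling_rate")
        state_names = state_names or meta.get("state_names")
    if sampling_rate is None:
        raise InvalidInputError(f"{path}: sampling rate unknown")
    return LabelSequence(labels, float(sampling_rate), state_names or [])


def write_templates(ts: TemplateSet, path: str | Path,
                    extra: dict | None = None) -> None:
    """K x C delimited matrix with channel-label header + JSON sidecar."""
    path = Path(path)
    labels = ts.channel_labels or [f"ch{i:02d}" for i in range(ts.n_channels)]
    np.savetxt(path, ts.maps, delimiter=",", header=",".join(labels),
               comments="", fmt="%.17g")
    meta = {"k": ts.k, "state_names": list(ts.labels)}
    meta.update(extra or {})
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_templates(path: str | Path) -> TemplateSet:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip().split(",")
        maps = np.loadtxt(fh, delimiter=",", ndmin=2)
    sidecar = path.with_suffix(path.suffix + ".json")
    state_names: list[str] = []
    if sidecar.exists():
        state_names = json.loads(sidecar.read_text()).get("state_names", [])
    return TemplateSet(maps, labels=state_names, channel_labels=header)
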