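"""Recording container and I/O for intracranial EEG.

A :class:`Recording` holds a channels x samples matrix (microvolts) together
with per-channel metadata (shaft, contact index, gray-matter and resection
flags) and seizure annotations.  Two on-disk dialects are supported:

* EDF (16-bit), read through :mod:`mne` (optional dependency);
* a plain numeric matrix (``.npy`` or delimited text) accompanied by a JSON
  sidecar that supplies the sampling rate, channel metadata and annotations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ChannelInfo",
    "SeizureAnnotation",
    "Recording",
    "read_recording",
    "write_matrix_recording",
]


@dataclass(frozen=True)
class ChannelInfo:
    """Metadata for one (unipolar or bipolar) channel."""

    label: str
    shaft: str = ""
    contact_index: int = 0
    gray_matter: bool = True
    resected: bool = False
    bipolar: bool = False


@dataclass(frozen=True)
class SeizureAnnotation:
    """Seizure onset/termination in samples (0-based, half-open)."""

    onset_sample: int
    termination_sample: int
    seizure_id: str = "sz1"

    def __post_init__(self) -> None:
        if not 0 <= self.onset_sample < self.termination_sample:
            raise ValueError(
                f"invalid annotation {self.seizure_id}: "
                f"onset {self.onset_sample} >= termination {self.termination_sample}"
            )


@dataclass
class Recording:
    """Multichannel iEEG block with metadata.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` float array in microvolts.
    fs
        Sampling rate in Hz.
    channels
        One :class:`ChannelInfo` per row of ``data``.
    annotations
        Seizure onset/termination annotations in samples.
    """

    data: np.ndarray
    fs: float
    channels: list[ChannelInfo]
    annotations: list[SeizureAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel descriptors for "
                f"{self.data.shape[0]} data rows"
            )
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        for ann in self.annotations:
            if ann.termination_sample > self.n_samples:
                raise ValueError(
                    f"annotation {ann.seizure_id} extends past end of recording"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channels]

    def copy_with(self, **kw) -> "Recording":
        out = Recording(
            data=kw.pop("data", self.data.copy()),
            fs=kw.pop("fs", self.fs),
            channels=kw.pop("channels", list(self.channels)),
            annotations=kw.pop("annotations", list(self.annotations)),
        )
        if kw:
            raise TypeError(f"unknown fields {sorted(kw)}")
        return out

    def segment(self, start_sample: int, stop_sample: int) -> "Recording":
        """Extract ``[start_sample, stop_sample)`` without annotations."""
        if not 0 <= start_sample < stop_sample <= self.n_samples:
            raise ValueError("segment bounds out of range")
        return Recording(
            self.data[:, start_sample:stop_sample].copy(),
            self.fs,
            list(self.channels),
            [],
        )


def _annotations_from_seconds(events: Sequence[dict], fs: float) -> list[SeizureAnnotation]:
    out = []
    for ev in events:
        # round-half-up, 0-based samples
        onset = int(np.floor(float(ev["onset_s"]) * fs + 0.5))
        term = int(np.floor(float(ev["termination_s"]) * fs + 0.5))
        out.append(SeizureAnnotation(onset, term, str(ev.get("seizure_id", "sz1"))))
    return out


def _channels_from_sidecar(meta: dict) -> list[ChannelInfo]:
    labels = meta["labels"]
    n = len(labels)

    def _col(key, default):
        vals = meta.get(key)
        if vals is None:
            return [default] * n
        if len(vals) != n:
            raise ValueError(f"sidecar field {key!r} has {len(vals)} entries for {n} labels")
        return vals

    shafts = _col("shaft", "")
    idx = _col("contact_index", 0)
    gray = _col("gray_matter", True)
    res = _col("resected", False)
    bip = _col("bipolar", False)
    return [
        ChannelInfo(str(l), str(s), int(i), bool(g), bool(r), bool(b))
        for l, s, i, g, r, b in zip(labels, shafts, idx, gray, res, bip)
    ]


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording from disk.

    ``format`` is ``"edf"`` or ``"matrix"``; when omitted it is inferred from
    the file suffix (``.edf`` vs anything else).  For the matrix dialect,
    ``path`` points at the data file (``.npy`` or delimited text) and a JSON
    sidecar ``<path>.json`` supplies ``fs``, ``labels`` and optional
    ``shaft`` / ``contact_index`` / ``gray_matter`` / ``resected`` /
    ``events`` fields.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        return _read_edf(path)
    if format == "matrix":
        return _read_matrix(path)
    raise ValueError(f"unknown recording format {format!r}")


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(units="uV")
    channels = [ChannelInfo(label=name) for name in raw.ch_names]
    return Recording(data, float(raw.info["sfreq"]), channels)


def _read_matrix(path: Path) -> Recording:
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "fs" not in meta:
        raise ValueError(f"sidecar {sidecar} lacks required key 'fs'")
    if path.suffix == ".npy":
        data = np.load(path)
    else:
        data = np.loadtxt(path, delimiter=",", ndmin=2)
    channels = _channels_from_sidecar(meta)
    if len(channels) != data.shape[0]:
        raise ValueError(
            f"sidecar lists {len(channels)} labels for a {data.shape[0]}-row matrix"
        )
    anns = _annotations_from_seconds(meta.get("events", []), float(meta["fs"]))
    return Recording(data, float(meta["fs"]), channels, anns)


def write_matrix_recording(rec: Recording, path: str | Path) -> Path:
    """Write the matrix+sidecar dialect (``.npy`` or ``.csv`` by suffix)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".npy":
        np.save(path, rec.data)
    else:
        np.savetxt(path, rec.data, delimiter=",")
    meta = {
        "fs": rec.fs,
        "labels": [c.label for c in rec.channels],
        "shaft": [c.shaft for c in rec.channels],
        "contact_index": [c.contact_index for c in rec.channels],
        "gray_matter": [bool(c.gray_matter) for c in rec.channels],
        "resected": [bool(c.resected) for c in rec.channels],
        "bipolar": [bool(c.bipolar) for c in rec.channels],
        "events": [
            {
                "seizure_id": a.seizure_id,
                "onset_s": a.onset_sample / rec.fs,
                "termination_s": a.termination_sample / rec.fs,
            }
            for a in rec.annotations
        ],
    }
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=1))
    return path
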