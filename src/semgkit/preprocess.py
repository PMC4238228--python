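"""Recording container, delimited-text I/O and band-pass preprocessing.

A :class:`Recording` holds a multichannel surface-EMG signal as a
``(n_samples, n_channels)`` array together with its sampling rate, channel
names and optional movement annotations (onset sample + class label).
Recordings are stored on disk as a plain CSV (one column per channel, header
row of channel names) next to a JSON sidecar carrying the metadata.

The only signal conditioning applied before feature extraction is a
zero-phase Butterworth band-pass (default 5–200 Hz, order 4), which removes
movement artifact below the EMG band and wideband noise above it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal


class FormatError(ValueError):
    """Raised when a recording file on disk is malformed."""


class ParameterError(ValueError):
    """Raised when a processing parameter is out of its valid range."""


@dataclass(frozen=True)
class Annotation:
    """Ground-truth or detected movement onset."""

    onset_sample: int
    label: str


@dataclass
class Recording:
    """Multichannel signal plus metadata; the unit of I/O for the pipeline.

    Parameters
    ----------
    samples
        Array of shape ``(n_samples, n_channels)``, arbitrary amplitude units.
    sampling_rate
        Samples per second, > 0.
    channel_names
        One name per column of ``samples``.
    annotations
        Optional movement onsets, strictly increasing and within bounds.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_names: list[str] = field(default_factory=list)
    annotations: list[Annotation] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.samples.ndim != 2:
            raise FormatError("samples must be a (n_samples, n_channels) array")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.samples.shape[1])]
        if len(self.channel_names) != self.samples.shape[1]:
            raise FormatError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[1]} data columns"
            )
        if self.annotations:
            onsets = [a.onset_sample for a in self.annotations]
            if any(b <= a for a, b in zip(onsets, onsets[1:])):
                raise FormatError("annotation onsets must be strictly increasing")
            if onsets[0] < 0 or onsets[-1] >= self.n_samples:
                raise FormatError("annotation onset outside signal bounds")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.n_samples / self.sampling_rate

    def slice(self, start: int, stop: int) -> "Recording":
        """Sub-recording over ``[start, stop)``; annotations are re-based."""
        ann = None
        if self.annotations is not None:
            ann = [
                Annotation(a.onset_sample - start, a.label)
                for a in self.annotations
                if start <= a.onset_sample < stop
            ]
        return Recording(
            self.samples[start:stop].copy(),
            self.sampling_rate,
            list(self.channel_names),
            ann,
        )


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_recording(recording: Recording, csv_path: str | Path, extra: dict | None = None) -> None:
    """Write ``recording`` as CSV (header = channel names) + JSON sidecar."""
    csv_path = Path(csv_path)
    frame = pd.DataFrame(recording.samples, columns=recording.channel_names)
    # %.17g round-trips float64 exactly
    frame.to_csv(csv_path, index=False, float_format="%.17g")
    meta: dict = {
        "sampling_rate": recording.sampling_rate,
        "channel_names": list(recording.channel_names),
    }
    if recording.annotations is not None:
        meta["labels"] = [
            {"onset_sample": int(a.onset_sample), "class": a.label}
            for a in recording.annotations
        ]
    if extra:
        meta.update(extra)
    _sidecar_path(csv_path).write_text(json.dumps(meta, indent=2))


def read_recording(csv_path: str | Path) -> Recording:
    """Read a CSV + JSON sidecar pair written by :func:`write_recording`.

    Raises
    ------
    FormatError
        If the sidecar is missing, rows are ragged, cells are non-numeric,
        or the header disagrees with the sidecar channel list.
    """
    csv_path = Path(csv_path)
    sidecar = _sidecar_path(csv_path)
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    try:
        frame = pd.read_csv(csv_path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{csv_path}: {exc}") from exc
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"{csv_path}: non-numeric or missing value in data row {row}"
        )
    names = list(frame.columns)
    if "channel_names" in meta and list(meta["channel_names"]) != names:
        raise FormatError(
            f"{csv_path}: header {names} disagrees with sidecar "
            f"{meta['channel_names']}"
        )
    annotations = None
    if "labels" in meta:
        annotations = [
            Annotation(int(d["onset_sample"]), str(d["class"])) for d in meta["labels"]
        ]
    return Recording(
        numeric.to_numpy(dtype=float),
        float(meta["sampling_rate"]),
        names,
        annotations,
    )


def bandpass(
    recording: Recording,
    low_hz: float = 5.0,
    high_hz: float = 200.0,
    order: int = 4,
) -> Recording:
    """Zero-phase Butterworth band-pass filter applied channel by channel.

    The filter is designed in second-order sections and applied
    forward-backward (``sosfiltfilt``), so the output has no group delay and
    the effective magnitude response is the squared design response. Output
    length equals input length.
    """
    nyquist = recording.sampling_rate / 2.0
    if not (0.0 < low_hz < high_hz):
        raise ParameterError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ParameterError(
            f"high_hz {high_hz} must be below the Nyquist frequency {nyquist}"
        )
    sos = signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=recording.sampling_rate, output="sos"
    )
    filtered = signal.sosfiltfilt(sos, recording.samples, axis=0)
    return replace(recording, samples=np.ascontiguousarray(filtered))
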