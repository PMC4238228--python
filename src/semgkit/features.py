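"""Wavelet-packet subband energies and the relative energy features.

A fixed-length multichannel segment is decomposed channel by channel with a
full wavelet-packet tree (default: Symlet-5 mother wavelet, level 3).  The
terminal nodes split the band ``[0, fs/2]`` into ``2^J`` equal-width
subbands.  For channel ``i`` and terminal node ``m`` the subspace energy is

    E[i, m] = sum_k d[i, m](k)^2,

the sum of squared wavelet-packet coefficients.  Two normalisations of these
energies are provided:

* RFBE (relative frequency band energy) — channel i's share of the total
  energy all channels carry in band m:  ``P[i, m] = E[i, m] / sum_i E[i, m]``.
  For each band the entries over channels sum to 1, so the feature encodes
  the cross-channel distribution of activity per band and is invariant to
  global amplitude scaling.
* RWPE (relative wavelet packet energy) — band m's share of channel i's own
  total energy:  ``E[i, m] / sum_m E[i, m]``.  Per channel the entries sum
  to 1; the feature encodes each channel's spectral shape only.

With 4 channels and a level-3 tree both give 32-dimensional vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
import pywt

if TYPE_CHECKING:  # pragma: no cover
    from .onset import SegmentSet


class SegmentLengthError(ValueError):
    """Segment too short for the requested decomposition level."""


class EnergyConsistencyError(ValueError):
    """Internal invariant violated (e.g. negative subband energy)."""


@lru_cache(maxsize=None)
def _node_orders(wavelet: str, level: int) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Terminal node paths in natural (Paley) and in frequency order."""
    wp = pywt.WaveletPacket(np.zeros(2**level), wavelet, maxlevel=level)
    natural = tuple(node.path for node in wp.get_level(level, order="natural"))
    freq = tuple(node.path for node in wp.get_level(level, order="freq"))
    return natural, freq


def band_frequency_ranges(level: int, sampling_rate: float) -> list[tuple[float, float]]:
    """Nominal ``(low, high)`` Hz range of each frequency-ordered subband."""
    width = sampling_rate / 2.0 / 2**level
    return [(r * width, (r + 1) * width) for r in range(2**level)]


@dataclass
class WaveletPacketEnergies:
    """Per-channel, per-terminal-node energies of one segment.

    ``E`` is indexed ``(channel, node)`` with nodes in natural (Paley) order;
    ``freq_order[r]`` gives the natural-order column holding the r-th band
    counted from low to high frequency.  ``K`` holds the per-node coefficient
    counts.
    """

    E: np.ndarray
    level: int
    wavelet_name: str
    node_order: tuple[str, ...]
    freq_order: np.ndarray
    K: np.ndarray
    coefficients: list[list[np.ndarray]] | None = None

    @property
    def n_channels(self) -> int:
        return self.E.shape[0]

    @property
    def n_bands(self) -> int:
        return self.E.shape[1]


def wp_energies(
    segment: np.ndarray,
    wavelet: str = "sym5",
    level: int = 3,
    mode: str = "symmetric",
    keep_coefficients: bool = False,
) -> WaveletPacketEnergies:
    """Full wavelet-packet decomposition and terminal-node energies.

    Parameters
    ----------
    segment
        ``(n_samples, n_channels)`` (or 1-D) array.
    mode
        Boundary extension.  ``"symmetric"`` is the conventional default;
        ``"periodization"`` makes the transform orthonormal so the total
        subband energy equals the time-domain energy exactly (Parseval) —
        exactly, however, only when the segment length is divisible by
        ``2**level`` (otherwise odd-length levels are padded internally and
        the boundary coefficient is counted twice).
    """
    x = np.asarray(segment, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, n_ch = x.shape
    if level < 1:
        raise ValueError("level must be >= 1")
    if n < 2**level:
        raise SegmentLengthError(
            f"segment of {n} samples too short for level {level} "
            f"(need at least {2 ** level})"
        )
    natural, freq = _node_orders(wavelet, level)
    n_bands = 2**level
    E = np.empty((n_ch, n_bands))
    coeffs: list[list[np.ndarray]] | None = [] if keep_coefficients else None
    K = None
    for i in range(n_ch):
        wp = pywt.WaveletPacket(x[:, i], wavelet, mode=mode, maxlevel=level)
        ch_coeffs = [np.asarray(wp[path].data) for path in natural]
        if K is None:
            K = np.array([c.size for c in ch_coeffs])
        E[i] = [float(np.sum(c**2)) for c in ch_coeffs]
        if coeffs is not None:
            coeffs.append(ch_coeffs)
    freq_order = np.array([natural.index(p) for p in freq])
    return WaveletPacketEnergies(
        E=E,
        level=level,
        wavelet_name=wavelet,
        node_order=natural,
        freq_order=freq_order,
        K=K,
        coefficients=coeffs,
    )


def _check_energies(energies: WaveletPacketEnergies) -> np.ndarray:
    E = np.asarray(energies.E, dtype=float)
    if not np.all(np.isfinite(E)):
        raise EnergyConsistencyError("non-finite subband energy")
    if np.any(E < 0):
        raise EnergyConsistencyError("negative subband energy")
    return E


def rfbe(energies: WaveletPacketEnergies) -> np.ndarray:
    """Relative frequency band energy, flattened channel-major.

    ``P[i, m] = E[i, m] / TE[m]`` with ``TE[m] = sum_i E[i, m]``.  A band
    with zero total energy carries no cross-channel information and is set
    to the uniform share ``1 / n_channels``.
    """
    E = _check_energies(energies)
    te = E.sum(axis=0)
    P = np.empty_like(E)
    nonzero = te > 0
    P[:, nonzero] = E[:, nonzero] / te[nonzero]
    P[:, ~nonzero] = 1.0 / E.shape[0]
    return P.reshape(-1)


def rwpe(energies: WaveletPacketEnergies) -> np.ndarray:
    """Relative wavelet packet energy, flattened channel-major.

    Per channel: ``E[i, m] / sum_m E[i, m]``; a channel with zero total
    energy is set to the uniform share ``1 / n_bands``.
    """
    E = _check_energies(energies)
    tot = E.sum(axis=1, keepdims=True)
    P = np.empty_like(E)
    nonzero = tot[:, 0] > 0
    P[nonzero] = E[nonzero] / tot[nonzero]
    P[~nonzero] = 1.0 / E.shape[1]
    return P.reshape(-1)


_METHODS = {"rfbe": rfbe, "rwpe": rwpe}


def feature_names(n_channels: int, level: int, method: str) -> list[str]:
    """Names ``ch{i}_band{m}_{method}`` with m a natural-order node index."""
    return [
        f"ch{i}_band{m}_{method}"
        for i in range(n_channels)
        for m in range(2**level)
    ]


@dataclass
class FeatureMatrix:
    """Samples x features with class labels.

    ``X`` rows are segments; columns follow :func:`feature_names`
    (channel-major, natural node order).
    """

    X: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    method: str

    @property
    def n_segments(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=self.feature_names)
        frame["label"] = self.labels
        return frame

    def save_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path: str | Path, method: str | None = None) -> "FeatureMatrix":
        frame = pd.read_csv(path)
        if "label" not in frame.columns:
            raise ValueError(f"{path}: missing 'label' column")
        labels = frame.pop("label").to_numpy(dtype=object)
        names = list(frame.columns)
        if method is None:
            method = names[0].rsplit("_", 1)[-1] if names else "unknown"
        return cls(frame.to_numpy(dtype=float), labels, names, method)


def extract_features(
    segments: "SegmentSet",
    method: str = "rfbe",
    wavelet: str = "sym5",
    level: int = 3,
    mode: str = "symmetric",
) -> FeatureMatrix:
    """Feature matrix (one row per segment) for a :class:`~semgkit.onset.SegmentSet`."""
    if method not in _METHODS:
        raise ValueError(f"unknown feature method {method!r}; choose from {sorted(_METHODS)}")
    fn = _METHODS[method]
    rows = [
        fn(wp_energies(seg, wavelet=wavelet, level=level, mode=mode))
        for seg in segments.data
    ]
    n_ch = segments.data.shape[2] if len(segments.data) else 0
    return FeatureMatrix(
        X=np.asarray(rows, dtype=float),
        labels=np.asarray(segments.labels, dtype=object),
        feature_names=feature_names(n_ch, level, method),
        method=method,
    )
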