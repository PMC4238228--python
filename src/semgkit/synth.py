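"""Synthetic multichannel surface-EMG generator.

Emulates a forearm-gesture recording session: repeated ~2 s activity bursts
separated by 3 s of rest, four electrode channels, 1500 Hz sampling, with
the burst spectrum confined to the EMG band (20–500 Hz, concentrated near
50–150 Hz).  Class identity is encoded purely in how each subband's energy
is shared across channels (the cross-channel activation pattern of the
underlying muscles); every class has the same per-channel spectral *shape*,
so features that only look at a single channel's spectrum carry no class
information by construction.

Band-limited activity is synthesised directly in the wavelet-packet domain:
independent Gaussian coefficients are drawn for each terminal node of the
same tree the feature extractor uses (per-node variance set by the target
band/channel energy share) and inverse-transformed.  This guarantees the
target subband energy shares are achievable exactly up to boundary and
envelope effects.  Each burst is shaped by a trapezoidal envelope with 50 ms
ramps and superimposed on stationary white Gaussian background noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pywt

from .features import _node_orders
from .preprocess import Annotation, Recording


class ConfigurationError(ValueError):
    """Invalid synthetic-recording configuration."""


DEFAULT_CLASSES: tuple[str, ...] = ("FP", "FS", "HO", "HC")

#: Fraction of total burst energy per frequency-ordered subband
#: (level 3 at 1500 Hz -> 93.75 Hz-wide bands).  Concentrates energy in
#: 0–190 Hz with most of it near 50–150 Hz and a light high-frequency tail.
DEFAULT_BAND_SPECTRUM: np.ndarray = np.array(
    [0.38, 0.34, 0.12, 0.06, 0.04, 0.03, 0.02, 0.01]
)


def default_band_profile(
    classes: Sequence[str] = DEFAULT_CLASSES,
    n_channels: int = 4,
    n_bands: int = 8,
    dominant_gain: float = 2.0,
    secondary_gain: float = 1.45,
) -> dict[str, np.ndarray]:
    """Cross-channel energy-share profiles, one ``(n_channels, n_bands)`` map per class.

    Class ``c`` drives channel ``c`` hardest and channel ``c+1`` moderately
    (amplitude gains ``dominant_gain`` and ``secondary_gain`` over a unit
    baseline), mimicking gesture-specific muscle recruitment.  The share
    pattern is identical in every band, so per-channel spectral shape does
    not depend on class.  Each column (band) sums to 1 over channels.
    """
    profiles: dict[str, np.ndarray] = {}
    for c, name in enumerate(classes):
        gains = np.ones(n_channels)
        gains[c % n_channels] *= dominant_gain
        gains[(c + 1) % n_channels] *= secondary_gain
        energy = gains**2
        shares = energy / energy.sum()
        profiles[name] = np.tile(shares[:, None], (1, n_bands))
    return profiles


@dataclass
class SynthConfig:
    """Study-condition parameters of the synthetic recording session.

    ``band_profile`` maps each class name to a ``(n_channels, 2**level)``
    array of per-band cross-channel energy shares, bands counted in
    frequency order (low to high); each column must sum to 1.
    ``amplitude_snr`` is the ratio of pooled burst RMS to rest-noise RMS.
    ``gain_jitter`` is the log-scale standard deviation of a per-burst,
    per-channel multiplicative gain emulating trial-to-trial variability of
    muscle activation.
    """

    n_channels: int = 4
    classes: tuple[str, ...] = DEFAULT_CLASSES
    sampling_rate: float = 1500.0
    band_profile: dict[str, np.ndarray] | None = None
    band_spectrum: np.ndarray = field(
        default_factory=lambda: DEFAULT_BAND_SPECTRUM.copy()
    )
    burst_duration: float = 2.0
    rest_duration: float = 3.0
    reps_per_class: int = 60
    amplitude_snr: float = 8.0
    noise_rms: float = 1.0
    ramp_duration: float = 0.05
    gain_jitter: float = 0.14
    wavelet: str = "sym5"
    level: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.band_profile is None:
            self.band_profile = default_band_profile(
                self.classes, self.n_channels, 2**self.level
            )
        self.validate()

    @property
    def n_bands(self) -> int:
        return 2**self.level

    def validate(self) -> None:
        if self.n_channels < 1 or self.reps_per_class < 1:
            raise ConfigurationError("n_channels and reps_per_class must be >= 1")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        for name in ("burst_duration", "rest_duration"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.amplitude_snr <= 0 or self.noise_rms <= 0:
            raise ConfigurationError("amplitude_snr and noise_rms must be positive")
        if self.burst_duration * self.sampling_rate < 0.6 * self.sampling_rate:
            raise ConfigurationError(
                "burst_duration must cover at least 600 ms, the longest "
                "segment length analysed"
            )
        spectrum = np.asarray(self.band_spectrum, dtype=float)
        if spectrum.shape != (self.n_bands,) or np.any(spectrum < 0):
            raise ConfigurationError(
                f"band_spectrum must be {self.n_bands} non-negative weights"
            )
        if not math.isclose(float(spectrum.sum()), 1.0, abs_tol=1e-9):
            raise ConfigurationError("band_spectrum must sum to 1")
        assert self.band_profile is not None
        for cls in self.band_profile:
            if cls not in self.classes:
                raise ConfigurationError(f"profile class {cls!r} not in classes")
        for cls in self.classes:
            if cls not in self.band_profile:
                raise ConfigurationError(f"class {cls!r} missing from band_profile")
            prof = np.asarray(self.band_profile[cls], dtype=float)
            if prof.shape != (self.n_channels, self.n_bands):
                raise ConfigurationError(
                    f"band_profile[{cls!r}] must have shape "
                    f"({self.n_channels}, {self.n_bands})"
                )
            if np.any(prof < 0):
                raise ConfigurationError("band_profile weights must be >= 0")
            col_sums = prof.sum(axis=0)
            if np.max(np.abs(col_sums - 1.0)) > 1e-12:
                raise ConfigurationError(
                    f"band_profile[{cls!r}] columns must sum to 1 over channels"
                )
            self.band_profile[cls] = prof

    @property
    def burst_samples(self) -> int:
        return int(round(self.burst_duration * self.sampling_rate))

    @property
    def rest_samples(self) -> int:
        return int(round(self.rest_duration * self.sampling_rate))


def _coeff_len(n: int, wavelet: str, level: int) -> int:
    dec_len = pywt.Wavelet(wavelet).dec_len
    k = n
    for _ in range(level):
        k = pywt.dwt_coeff_len(k, dec_len, "periodization")
    return k


def synth_burst(
    n_samples: int,
    profile: np.ndarray,
    spectrum: np.ndarray,
    wavelet: str,
    level: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Band-limited multichannel Gaussian activity of one burst (no envelope).

    The expected energy of channel ``i`` in frequency-ordered band ``r`` is
    proportional to ``spectrum[r] * profile[i, r]``; absolute scale is
    arbitrary (the caller rescales to the target SNR).
    """
    natural, freq_paths = _node_orders(wavelet, level)
    n_ch = profile.shape[0]
    k = _coeff_len(n_samples, wavelet, level)
    out = np.empty((n_samples, n_ch))
    for i in range(n_ch):
        wp = pywt.WaveletPacket(
            data=None, wavelet=wavelet, mode="periodization", maxlevel=level
        )
        for r, path in enumerate(freq_paths):
            energy = spectrum[r] * profile[i, r] * n_samples
            wp[path] = rng.normal(0.0, math.sqrt(energy / k), k)
        out[:, i] = wp.reconstruct(update=False)[:n_samples]
    return out


def _trapezoid(n: int, ramp: int) -> np.ndarray:
    ramp = min(ramp, n // 2)
    env = np.ones(n)
    if ramp > 0:
        env[:ramp] = np.linspace(0.0, 1.0, ramp, endpoint=False)
        env[n - ramp :] = np.linspace(1.0, 0.0, ramp, endpoint=False)
    return env


def generate_recording(config: SynthConfig) -> Recording:
    """Generate one labelled synthetic session.

    Layout: ``rest, burst, rest, burst, …, rest`` with classes cycling so
    each appears ``reps_per_class`` times.  Ground-truth onsets (start of
    each burst's rising ramp) and class labels are stored in annotations.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_burst = config.burst_samples
    n_rest = config.rest_samples
    n_reps = config.reps_per_class * len(config.classes)
    total = n_rest + n_reps * (n_burst + n_rest)
    samples = rng.normal(0.0, config.noise_rms, (total, config.n_channels))
    env = _trapezoid(n_burst, int(round(config.ramp_duration * config.sampling_rate)))
    spectrum = np.asarray(config.band_spectrum, dtype=float)
    target_rms = config.amplitude_snr * config.noise_rms
    annotations: list[Annotation] = []
    for rep in range(n_reps):
        label = config.classes[rep % len(config.classes)]
        onset = n_rest + rep * (n_burst + n_rest)
        assert config.band_profile is not None
        burst = synth_burst(
            n_burst,
            config.band_profile[label],
            spectrum,
            config.wavelet,
            config.level,
            rng,
        )
        burst *= env[:, None]
        if config.gain_jitter > 0:
            burst *= np.exp(rng.normal(0.0, config.gain_jitter, config.n_channels))
        burst *= target_rms / math.sqrt(float(np.mean(burst**2)))
        samples[onset : onset + n_burst] += burst
        annotations.append(Annotation(onset, label))
    names = [f"ch{i}" for i in range(config.n_channels)]
    return Recording(samples, config.sampling_rate, names, annotations)
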