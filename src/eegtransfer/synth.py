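"""Synthetic two-domain EEG generator.

Emulates the premise that vigilance states differ in their EEG band content:
each class is a :class:`ClassSignature` giving the relative power in the four
classical bands (delta 0.5–4 Hz, theta 4–8 Hz, alpha 8–13 Hz, beta 13–30 Hz).
An epoch is a sum of band-limited oscillators with those powers on top of a
1/f background, optionally passed through a :class:`ShiftSpec` that models the
source→target covariate shift (gain, additive noise, frequency drift).

The source domain carries the five sleep stages, the target the three fatigue
levels.  For transfer experiments the two label spaces are linked by a
ground-truth correspondence — W→Awake, {N1,N2}→Mild Fatigue,
{N3,REM}→Severe Fatigue — purely a synthetic-world convention that makes
transfer gain measurable; each target epoch draws its signature uniformly
from its class's linked source signatures, so with an identity shift the
target class-conditional distributions are exact mixtures of source ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .eeg_core import (DomainDataset, EEGEpoch, FATIGUE3, LabelScheme,
                       ParameterError, SLEEP5)

__all__ = [
    "BANDS", "ClassSignature", "ShiftSpec", "SOURCE_SIGNATURES",
    "TARGET_CLASS_MAP", "generate_epoch", "generate_domain_pair",
    "inject_artifact", "band_power_profile",
]

#: (low, high) Hz edges of the four classical EEG bands, in fixed order.
BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

#: Default epoch geometry: 30 s at 100 Hz = 3000 samples.
DEFAULT_RATE = 100.0
DEFAULT_LENGTH_S = 30.0

#: Relative RMS of the 1/f background vs. the oscillatory part.
BACKGROUND_RMS_FRACTION = 0.3

#: Oscillators drawn per band (random centre frequencies within the band).
_OSC_PER_BAND = 3


@dataclass(frozen=True)
class ClassSignature:
    """Band-power signature of one vigilance class.

    ``band_powers`` is (delta, theta, alpha, beta) relative power;
    ``amplitude_scale`` the RMS of the oscillatory part in µV.
    """

    band_powers: tuple[float, float, float, float]
    amplitude_scale: float = 30.0

    def __post_init__(self):
        if any(p < 0 for p in self.band_powers):
            raise ParameterError("band powers must be nonnegative")
        if not any(p > 0 for p in self.band_powers):
            raise ParameterError("at least one band power must be positive")


@dataclass(frozen=True)
class ShiftSpec:
    """Parametric covariate shift applied to target-domain epochs."""

    gain: float = 1.0
    noise_sd: float = 0.0
    freq_drift: float = 0.0

    def __post_init__(self):
        if not self.gain > 0:
            raise ParameterError("gain must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be nonnegative")

    @property
    def is_identity(self) -> bool:
        return self.gain == 1.0 and self.noise_sd == 0.0 and self.freq_drift == 0.0


IDENTITY_SHIFT = ShiftSpec()

# Stage-typical signatures: wake is alpha/beta-dominant, N1 theta, N2 mixed
# delta/theta at higher amplitude, N3 delta-dominant slow-wave sleep at the
# largest amplitude, REM a low-amplitude theta/beta mixture.
SOURCE_SIGNATURES: dict[str, ClassSignature] = {
    "W":   ClassSignature((0.05, 0.10, 0.50, 0.35), 30.0),
    "N1":  ClassSignature((0.15, 0.60, 0.15, 0.10), 35.0),
    "N2":  ClassSignature((0.45, 0.30, 0.15, 0.10), 45.0),
    "N3":  ClassSignature((0.80, 0.10, 0.05, 0.05), 60.0),
    "REM": ClassSignature((0.10, 0.40, 0.05, 0.45), 30.0),
}

#: Ground-truth sleep-stage → fatigue-level correspondence (synthetic only).
TARGET_CLASS_MAP: dict[str, tuple[str, ...]] = {
    "Awake": ("W",),
    "Mild Fatigue": ("N1", "N2"),
    "Severe Fatigue": ("N3", "REM"),
}


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f^alpha background with alpha = 1, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale, n)
    return pink / (pink.std() + 1e-30)


def generate_epoch(signature: ClassSignature, rate: float = DEFAULT_RATE,
                   length_s: float = DEFAULT_LENGTH_S,
                   shift: ShiftSpec = IDENTITY_SHIFT,
                   seed: int = 0, channel: str = "SYN") -> EEGEpoch:
    """One synthetic epoch: band oscillators + 1/f background, then shift.

    Deterministic given ``seed``.  The oscillatory part is normalised to RMS
    ``signature.amplitude_scale`` before the shift's gain multiplies the whole
    trace and white noise of sd ``shift.noise_sd`` is added.
    """
    rng = np.random.default_rng(seed)
    n = int(round(rate * length_s))
    t = np.arange(n) / rate
    sig = np.zeros(n)
    total_power = sum(signature.band_powers)
    for (lo, hi), power in zip(BANDS.values(), signature.band_powers):
        freqs = rng.uniform(lo, hi, size=_OSC_PER_BAND)
        phases = rng.uniform(0, 2 * np.pi, size=_OSC_PER_BAND)
        if power <= 0:
            continue
        amp = np.sqrt(2.0 * (power / total_power) / _OSC_PER_BAND)
        for f, ph in zip(freqs, phases):
            sig += amp * np.sin(2 * np.pi * (f + shift.freq_drift) * t + ph)
    sig *= signature.amplitude_scale / (sig.std() + 1e-30) if sig.any() else 1.0
    sig += BACKGROUND_RMS_FRACTION * signature.amplitude_scale * _pink_noise(n, rng)
    sig *= shift.gain
    if shift.noise_sd > 0:
        sig = sig + rng.normal(0.0, shift.noise_sd, size=n)
    return EEGEpoch(sig, rate, channel)


def generate_domain_pair(n_per_class: int,
                         source_scheme: LabelScheme = SLEEP5,
                         target_scheme: LabelScheme = FATIGUE3,
                         shift: ShiftSpec = ShiftSpec(gain=1.5, noise_sd=5.0),
                         seed: int = 0,
                         rate: float = DEFAULT_RATE,
                         length_s: float = DEFAULT_LENGTH_S,
                         ) -> tuple[DomainDataset, DomainDataset]:
    """Generate a labeled (source, target) dataset pair.

    Source epochs are unshifted; target epochs receive ``shift`` and draw
    their signatures through :data:`TARGET_CLASS_MAP`.  Exactly
    ``n_per_class`` epochs per class; epoch order is shuffled within each
    domain.  Fully deterministic given ``seed``.
    """
    if n_per_class < 1:
        raise ParameterError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)

    def build(domain: str, scheme: LabelScheme, shift_: ShiftSpec) -> DomainDataset:
        epochs, labels = [], []
        for ci, cname in enumerate(scheme.classes):
            for _ in range(n_per_class):
                if domain == "source":
                    sig = SOURCE_SIGNATURES[cname]
                else:
                    parent = TARGET_CLASS_MAP[cname][
                        rng.integers(len(TARGET_CLASS_MAP[cname]))]
                    sig = SOURCE_SIGNATURES[parent]
                ep_seed = int(rng.integers(2 ** 31))
                epochs.append(generate_epoch(sig, rate, length_s, shift_,
                                             ep_seed, channel="SYN"))
                labels.append(ci)
        order = rng.permutation(len(epochs))
        return DomainDataset(domain, [epochs[i] for i in order], scheme,
                             np.asarray(labels)[order])

    source = build("source", source_scheme, IDENTITY_SHIFT)
    target = build("target", target_scheme, shift)
    return source, target


def inject_artifact(epoch: EEGEpoch, kind: str, magnitude: float,
                    seed: int = 0) -> tuple[EEGEpoch, EEGEpoch]:
    """Contaminate an epoch with a blink- or EMG-like artifact.

    Returns ``(contaminated, clean)`` where ``clean`` is the untouched input
    copy.  ``blink`` adds a slow (< 2 Hz) raised-cosine transient of peak
    amplitude ``magnitude`` µV; ``emg`` adds a 20–45 Hz noise burst of peak
    amplitude ``magnitude`` µV over a 1–3 s interval.
    """
    if magnitude < 0:
        raise ParameterError("magnitude must be nonnegative")
    rng = np.random.default_rng(seed)
    n, rate = epoch.n_samples, epoch.rate
    clean = EEGEpoch(epoch.samples.copy(), rate, epoch.channel)
    art = np.zeros(n)
    if magnitude > 0:
        if kind == "blink":
            width = int(round(0.8 * rate))            # 0.8 s lobe → <2 Hz content
            centre = rng.integers(width, n - width)
            k = np.arange(2 * width)
            pulse = 0.5 * (1 - np.cos(2 * np.pi * k / (2 * width - 1)))  # Hann
            art[centre - width:centre + width] = magnitude * pulse
        elif kind == "emg":
            from scipy import signal as sps
            dur = int(round(rng.uniform(1.0, 3.0) * rate))
            start = rng.integers(0, n - dur)
            burst = rng.standard_normal(dur)
            sos = sps.butter(4, [20.0, min(45.0, rate / 2 * 0.95)],
                             btype="bandpass", fs=rate, output="sos")
            burst = sps.sosfiltfilt(sos, burst)
            burst *= sps.windows.tukey(dur, 0.25)
            burst *= magnitude / (np.abs(burst).max() + 1e-30)
            art[start:start + dur] = burst
        else:
            raise ParameterError(f"unknown artifact kind {kind!r}")
    return EEGEpoch(epoch.samples + art, rate, epoch.channel), clean


def band_power_profile(samples: np.ndarray, rate: float) -> np.ndarray:
    """Relative power in (delta, theta, alpha, beta), summing to 1.

    The FFT-periodogram oracle used throughout the tests.
    """
    samples = np.asarray(samples, dtype=float)
    spec = np.abs(np.fft.rfft(samples - samples.mean())) ** 2
    freqs = np.fft.rfftfreq(samples.size, d=1.0 / rate)
    out = np.array([spec[(freqs >= lo) & (freqs < hi)].sum()
                    for lo, hi in BANDS.values()])
    return out / (out.sum() + 1e-300)
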