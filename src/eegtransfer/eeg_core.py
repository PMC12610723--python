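"""Core data types, file I/O and preprocessing for single-channel EEG.

The unit of analysis is the 30 s epoch: a fixed-length single-channel voltage
trace that receives one class label (a sleep stage in the source domain, a
fatigue level in the target domain).  Preprocessing follows the usual
single-channel pipeline: a 0.5–45 Hz zero-phase bandpass, ICA-based artifact
suppression, and polyphase resampling so that recordings acquired at 128 Hz
can share one network geometry with 100 Hz source data.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal
from sklearn.decomposition import FastICA

__all__ = [
    "EEGError", "ChannelNotFoundError", "FormatError", "ParameterError",
    "EEGEpoch", "LabelScheme", "SLEEP5", "FATIGUE3", "DomainDataset",
    "read_edf", "write_edf", "bandpass_filter", "remove_artifacts_ica",
    "resample", "save_epoch_text", "load_epoch_text", "save_epoch_npz",
    "load_epoch_npz", "save_labels", "load_labels", "EPOCH_LENGTH_S",
]

#: Epoch length in seconds (polysomnography scoring convention; also what the
#: feature-extractor geometry assumes: 30 s at 100 Hz = 3000 samples).
EPOCH_LENGTH_S = 30.0


class EEGError(Exception):
    """Base class for errors raised by this package."""


class ChannelNotFoundError(EEGError, KeyError):
    """A named channel is absent from a recording."""


class FormatError(EEGError, ValueError):
    """A file does not parse as the expected format."""


class ParameterError(EEGError, ValueError):
    """An argument violates an operation's preconditions."""


# --------------------------------------------------------------------- types

@dataclass
class EEGEpoch:
    """One fixed-length single-channel EEG segment.

    Parameters
    ----------
    samples : ndarray
        Voltage values in microvolts, finite.
    rate : float
        Sampling rate in Hz, > 0.
    channel : str
        Electrode label, e.g. ``"O1"`` or ``"Fpz-Cz"``.
    """

    samples: np.ndarray
    rate: float
    channel: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ParameterError("samples must be one-dimensional")
        if not self.rate > 0:
            raise ParameterError(f"rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("samples must all be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def length_s(self) -> float:
        """Duration in seconds (= n_samples / rate exactly)."""
        return self.n_samples / self.rate


@dataclass(frozen=True)
class LabelScheme:
    """An ordered, named set of class labels."""

    name: str
    classes: tuple[str, ...]

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def index(self, class_name: str) -> int:
        try:
            return self.classes.index(class_name)
        except ValueError:
            raise ParameterError(
                f"unknown class {class_name!r} for scheme {self.name}") from None


#: The five AASM sleep stages (legacy N4 merged into N3) — the source task.
SLEEP5 = LabelScheme("sleep5", ("W", "N1", "N2", "N3", "REM"))
#: The three driving-fatigue levels — the target task.
FATIGUE3 = LabelScheme("fatigue3", ("Awake", "Mild Fatigue", "Severe Fatigue"))


@dataclass
class DomainDataset:
    """A labeled collection of epochs belonging to one domain.

    ``labels`` may be None for unlabeled data (e.g. straight from an EDF file
    before annotations are attached).
    """

    domain: str
    epochs: list[EEGEpoch]
    scheme: LabelScheme
    labels: np.ndarray | None = None

    def __post_init__(self):
        if self.domain not in ("source", "target"):
            raise ParameterError(f"domain must be 'source' or 'target', got {self.domain!r}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if len(self.labels) != len(self.epochs):
                raise ParameterError("labels and epochs must have equal length")
            if self.labels.size and (
                    self.labels.min() < 0 or self.labels.max() >= self.scheme.n_classes):
                raise ParameterError("label index out of range for scheme")
        if self.epochs:
            r0, n0 = self.epochs[0].rate, self.epochs[0].n_samples
            for e in self.epochs:
                if e.rate != r0 or e.n_samples != n0:
                    raise ParameterError("all epochs must share rate and length")

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def rate(self) -> float:
        return self.epochs[0].rate

    def as_matrix(self) -> np.ndarray:
        """(n_epochs, n_samples) float64 view of the data."""
        return np.stack([e.samples for e in self.epochs]) if self.epochs else \
            np.empty((0, 0))

    def with_samples(self, mat: np.ndarray, rate: float | None = None) -> "DomainDataset":
        """Copy of the dataset with every epoch's samples replaced row-wise."""
        rate = rate if rate is not None else self.rate
        eps = [EEGEpoch(row, rate, e.channel) for row, e in zip(mat, self.epochs)]
        return DomainDataset(self.domain, eps, self.scheme,
                             None if self.labels is None else self.labels.copy())


# ----------------------------------------------------------------------- EDF

def read_edf(path, channel: str, domain: str = "source",
             scheme: LabelScheme = SLEEP5,
             epoch_length_s: float = EPOCH_LENGTH_S) -> DomainDataset:
    """Read one channel of an EDF recording and cut it into contiguous epochs.

    Epochs are half-open sample intervals ``[k*N, (k+1)*N)`` at the file's
    native rate; a partial trailing segment is discarded.  The returned
    dataset is unlabeled — annotations are attached separately.
    """
    import mne

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted errors on bad headers
        raise FormatError(f"could not parse {path} as EDF: {exc}") from exc
    if channel not in raw.ch_names:
        raise ChannelNotFoundError(
            f"channel {channel!r} not in {path} (has {raw.ch_names})")
    rate = float(raw.info["sfreq"])
    data = raw.get_data(picks=[channel])[0] * 1e6  # mne uses volts; we use µV
    n = int(round(rate * epoch_length_s))
    n_epochs = data.size // n
    epochs = [EEGEpoch(data[k * n:(k + 1) * n], rate, channel)
              for k in range(n_epochs)]
    return DomainDataset(domain, epochs, scheme, None)


def write_edf(path, ds: DomainDataset) -> None:
    """Write a dataset to a minimal single-channel EDF file (16-bit).

    Covers exactly what :func:`read_edf` consumes: one data record per epoch,
    one signal, physical units µV.  Values are quantized to the int16 range
    spanned by the data.
    """
    mat = ds.as_matrix()
    rate = ds.rate
    n_rec, n_samp = mat.shape
    rec_dur = n_samp / rate
    phys_min = float(min(mat.min(), -1.0))
    phys_max = float(max(mat.max(), 1.0))
    dig_min, dig_max = -32768, 32767

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")[:n]
        return b + b" " * (n - len(b))

    hdr = b"".join([
        pad("0", 8),                      # version
        pad("X X X X", 80),               # patient id
        pad("Startdate X X X X", 80),     # recording id
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(str(256 + 256), 8),           # header bytes: 256 + 256*nsignals
        pad("EDF", 44),                   # reserved
        pad(str(n_rec), 8),
        pad(f"{rec_dur:g}", 8),
        pad("1", 4),                      # number of signals
    ])
    sig = b"".join([
        pad(ds.epochs[0].channel or "EEG", 16),
        pad("AgAgCl electrode", 80),
        pad("uV", 8),
        pad(f"{phys_min:.6g}", 8), pad(f"{phys_max:.6g}", 8),
        pad(str(dig_min), 8), pad(str(dig_max), 8),
        pad("", 80),                      # prefiltering
        pad(str(n_samp), 8),
        pad("", 32),                      # reserved
    ])
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    dig = np.round((mat - phys_min) / scale + dig_min).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr + sig)
        fh.write(dig.tobytes())


# ------------------------------------------------------------- preprocessing

def bandpass_filter(ds: DomainDataset, low: float = 0.5,
                    high: float = 45.0) -> DomainDataset:
    """Zero-phase Butterworth bandpass (order 4, applied forward-backward).

    The 0.5–45 Hz default suppresses baseline drift below and power-line
    interference above the EEG band of interest.
    """
    rate = ds.rate
    if not (0 < low < high):
        raise ParameterError(f"need 0 < low < high, got {low}, {high}")
    if high >= rate / 2:
        raise ParameterError(
            f"high cutoff {high} Hz must be below Nyquist ({rate / 2} Hz)")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=rate, output="sos")
    # even-reflection padding: the default odd reflection doubles the slope
    # discontinuity at the epoch edges and leaks stop-band energy back in
    mat = signal.sosfiltfilt(sos, ds.as_matrix(), axis=1, padtype="even")
    return ds.with_samples(mat)


def remove_artifacts_ica(ds: DomainDataset, n_components: int = 8,
                         window_s: float = 2.0,
                         kurtosis_threshold: float = 5.0,
                         lowfreq_fraction: float = 0.6,
                         seed: int = 0) -> DomainDataset:
    """Suppress ocular/EMG artifacts with ICA on a pseudo-multichannel matrix.

    Single-channel data has no spatial mixture for ICA to unmix, so the signal
    is segmented into consecutive fixed-length windows that are stacked as
    pseudo-channels.  FastICA (deflation) separates temporal components; a
    component is rejected when its activation kurtosis exceeds
    ``kurtosis_threshold`` (sparse transients such as blinks) or when more
    than ``lowfreq_fraction`` of its waveform power lies below 4 Hz (slow
    ocular drifts).  Rejected components' contributions are subtracted from
    the original signal, so when nothing is rejected the data pass through
    bit-exactly.
    """
    mat = ds.as_matrix()
    if mat.size == 0 or not np.any(mat):
        return ds.with_samples(mat.copy())
    rate = ds.rate
    win = int(round(window_s * rate))
    flat = mat.reshape(-1)
    n_win = flat.size // win
    if n_components > n_win:
        raise ParameterError(
            f"n_components={n_components} exceeds available windows ({n_win})")
    X = flat[:n_win * win].reshape(n_win, win)  # windows (pseudo-channels) × time

    ica = FastICA(n_components=n_components, algorithm="deflation",
                  whiten="unit-variance", random_state=seed, max_iter=500)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        S = ica.fit_transform(X.T)       # (win, n_components): temporal sources
    A = ica.mixing_                      # (n_win, n_components)

    freqs = np.fft.rfftfreq(win, d=1.0 / rate)
    reject = []
    for k in range(n_components):
        s = S[:, k]
        centred = s - s.mean()
        m2 = np.mean(centred ** 2)
        kurt = np.mean(centred ** 4) / (m2 ** 2 + 1e-300) - 3.0
        spec = np.abs(np.fft.rfft(centred)) ** 2
        low_frac = spec[freqs < 4.0].sum() / (spec.sum() + 1e-300)
        if kurt > kurtosis_threshold or low_frac > lowfreq_fraction:
            reject.append(k)
    if reject:
        artifact = S[:, reject] @ A[:, reject].T   # (win, n_win)
        cleaned = X - artifact.T
    else:
        cleaned = X
    out = flat.copy()
    out[:n_win * win] = cleaned.reshape(-1)
    return ds.with_samples(out.reshape(mat.shape))


def resample(ds: DomainDataset, new_rate: float) -> DomainDataset:
    """Polyphase resampling of every epoch to ``new_rate``.

    The output sample count is ``round(new_rate * length_s)``; band content
    below the lower of the two Nyquist frequencies is preserved.  An identity
    resample returns the samples unchanged.
    """
    if not new_rate > 0:
        raise ParameterError(f"new_rate must be positive, got {new_rate}")
    old_rate = ds.rate
    if new_rate == old_rate:
        return ds.with_samples(ds.as_matrix().copy())
    frac = Fraction(new_rate / old_rate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    mat = signal.resample_poly(ds.as_matrix(), up, down, axis=1)
    n_target = int(round(new_rate * ds.epochs[0].length_s))
    if mat.shape[1] > n_target:
        mat = mat[:, :n_target]
    elif mat.shape[1] < n_target:
        mat = np.pad(mat, ((0, 0), (0, n_target - mat.shape[1])), mode="edge")
    return ds.with_samples(mat, rate=new_rate)


# -------------------------------------------------------------- text I/O

def save_epoch_text(path, ds: DomainDataset) -> None:
    """One epoch per row, tab-delimited, with a ``# rate channel domain scheme`` header."""
    with open(path, "w", newline="") as fh:
        ch = ds.epochs[0].channel if ds.epochs else ""
        fh.write(f"# rate={ds.rate:g} channel={ch} domain={ds.domain} "
                 f"scheme={ds.scheme.name}\n")
        w = csv.writer(fh, delimiter="\t")
        for e in ds.epochs:
            w.writerow(f"{v:.6g}" for v in e.samples)


def load_epoch_text(path) -> DomainDataset:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise FormatError(f"{path}: missing header line")
        meta = dict(tok.split("=", 1) for tok in header[1:].split())
        scheme = {"sleep5": SLEEP5, "fatigue3": FATIGUE3}[meta["scheme"]]
        rate = float(meta["rate"])
        epochs = [EEGEpoch(np.array(row, dtype=float), rate, meta["channel"])
                  for row in csv.reader(fh, delimiter="\t") if row]
    return DomainDataset(meta["domain"], epochs, scheme, None)


def save_epoch_npz(path, ds: DomainDataset) -> None:
    """Compressed binary container for epoch sets (numpy .npz)."""
    np.savez_compressed(
        path, samples=ds.as_matrix(), rate=ds.rate,
        channel=ds.epochs[0].channel if ds.epochs else "",
        domain=ds.domain, scheme=ds.scheme.name,
        labels=ds.labels if ds.labels is not None else np.array([]))


def load_epoch_npz(path) -> DomainDataset:
    with np.load(path, allow_pickle=False) as z:
        rate = float(z["rate"])
        channel = str(z["channel"])
        scheme = {"sleep5": SLEEP5, "fatigue3": FATIGUE3}[str(z["scheme"])]
        epochs = [EEGEpoch(row, rate, channel) for row in z["samples"]]
        labels = z["labels"] if z["labels"].size else None
        domain = str(z["domain"])
    return DomainDataset(domain, epochs, scheme, labels)


def save_labels(path, ds: DomainDataset) -> None:
    """Two-column delimited text: epoch_index, class_name."""
    if ds.labels is None:
        raise ParameterError("dataset has no labels to save")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for i, lab in enumerate(ds.labels):
            w.writerow([i, ds.scheme.classes[lab]])


def load_labels(path, ds: DomainDataset) -> DomainDataset:
    labels = np.full(len(ds), -1, dtype=np.int64)
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row:
                continue
            idx, name = int(row[0]), row[1]
            labels[idx] = ds.scheme.index(name)
    if (labels < 0).any():
        raise FormatError(f"{path}: labels missing for some epochs")
    return DomainDataset(ds.domain, ds.epochs, ds.scheme, labels)
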