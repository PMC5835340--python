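"""EEG functional connectivity: correlation and phase-locking value (PLV).

A recording (channels x time, with a pre-stimulus baseline) is turned into a
symmetric connectivity matrix — Pearson correlation, or band-resolved PLV
from Morlet-wavelet phases — and flattened into the N(N-1)/2 upper-triangle
feature vector used for classification.

PLV estimator
-------------
Instantaneous phase at a center frequency ``f`` is extracted with a complex
Morlet atom ``exp(-t^2 / 2 sigma_t^2) exp(2 i pi f t)`` with ``sigma_t = 7/f``.
The recording's nonoverlapping 1-s post-stimulus segments form the averaging
ensemble: for each within-epoch time bin, PLV is the modulus of the mean unit
phasor of the phase difference across epochs; the per-bin values are then
averaged over bins, and finally over the band's center frequencies.  Baseline
normalization ((value - baseline mean) / baseline SD, per center frequency,
before band averaging) uses the same estimator on the pre-stimulus epochs.

Samples closer than the truncated wavelet support (4 sigma_t) to a recording
edge are flagged invalid; epochs that are not fully valid are excluded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "EEGRecording", "FrequencyBand", "ConnectivityMatrix", "WaveletTransform",
    "FeatureDataset", "bandpass_filter", "common_average_reference",
    "correlation_matrix", "wavelet_phase", "plv_pair", "plv_matrix",
    "baseline_normalize", "vectorize", "devectorize", "build_dataset",
]


# ---------------------------------------------------------------------------
# domain types

@dataclass
class EEGRecording:
    """One trial: channels x time samples, with the baseline before onset."""

    samples: np.ndarray
    sampling_rate: float
    channel_labels: list[str] = field(default_factory=list)
    stimulus_onset: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time array")
        if self.samples.shape[0] < 2:
            raise ValueError("at least 2 channels required")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel_labels length mismatch")
        if not (0 <= self.stimulus_onset <= self.samples.shape[1]):
            raise ValueError("stimulus_onset outside the recording")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass(frozen=True)
class FrequencyBand:
    """Named frequency band with the discrete grid PLV is evaluated on.

    The named bands follow the usual EEG nomenclature: Low = delta + theta
    (1-8 Hz; the 1 Hz floor matches the recording band-pass), Medium =
    alpha + beta (8-30 Hz), High = gamma (30-80 Hz), beta = 14-30 Hz.
    ``center_freqs`` default to 1 Hz spacing across [f_min, f_max].
    """

    name: str
    f_min: float
    f_max: float
    center_freqs: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.f_min < self.f_max:
            raise ValueError("need f_min < f_max")
        if not self.center_freqs:
            grid = np.arange(math.ceil(self.f_min), math.floor(self.f_max) + 1, 1.0)
            object.__setattr__(self, "center_freqs", tuple(float(f) for f in grid))
        if not self.center_freqs:
            raise ValueError("empty center-frequency grid")
        for f in self.center_freqs:
            if not (self.f_min <= f <= self.f_max):
                raise ValueError(f"center frequency {f} outside [{self.f_min}, {self.f_max}]")

    @classmethod
    def low(cls) -> "FrequencyBand":
        return cls("Low", 1.0, 8.0)

    @classmethod
    def medium(cls) -> "FrequencyBand":
        return cls("Medium", 8.0, 30.0)

    @classmethod
    def high(cls) -> "FrequencyBand":
        return cls("High", 30.0, 80.0)

    @classmethod
    def beta(cls) -> "FrequencyBand":
        return cls("beta", 14.0, 30.0)

    @classmethod
    def named(cls, name: str) -> "FrequencyBand":
        table = {"low": cls.low, "medium": cls.medium, "high": cls.high,
                 "beta": cls.beta}
        try:
            return table[name.lower()]()
        except KeyError:
            raise ValueError(f"unknown band name {name!r}; use one of {sorted(table)}")


@dataclass
class ConnectivityMatrix:
    """Symmetric weighted adjacency matrix over channels, zero diagonal."""

    values: np.ndarray
    measure: str                      # correlation | plv | plv_normalized
    band: FrequencyBand | None = None
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise ValueError("values must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("connectivity matrix must have zero diagonal")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(n)]

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


@dataclass
class WaveletTransform:
    """Complex Morlet coefficients of one signal at one frequency."""

    coefficients: np.ndarray
    frequency: float
    sigma_t: float
    sampling_rate: float
    valid: np.ndarray                 # bool mask, False inside the edge margin

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.coefficients)

    @property
    def phase(self) -> np.ndarray:
        """Instantaneous phase in (-pi, pi]."""
        ph = np.angle(self.coefficients)
        # np.angle returns [-pi, pi]; fold -pi onto +pi for the open interval
        ph[ph == -np.pi] = np.pi
        return ph


@dataclass
class FeatureDataset:
    """Trials x edges feature matrix with labels and the edge->column map."""

    X: np.ndarray
    y: np.ndarray
    edge_index: list[tuple[int, int]]
    channel_labels: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != len(self.y):
            raise ValueError("X and y length mismatch")
        if not np.all(np.abs(self.y) == 1):
            raise ValueError("labels must be +/-1")
        if self.X.shape[1] != len(self.edge_index):
            raise ValueError("edge_index must map every column")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def edge_names(self) -> list[str]:
        return [f"{i}-{j}" for i, j in self.edge_index]


# ---------------------------------------------------------------------------
# preprocessing

def bandpass_filter(recording: EEGRecording, f_lo: float, f_hi: float,
                    numtaps: int | None = None) -> EEGRecording:
    """Zero-phase FIR band-pass; length preserved.

    The default tap count scales with ``sampling_rate / f_lo`` so the lower
    transition band is resolved; it is capped by the signal length filtfilt
    can pad.
    """
    fs = recording.sampling_rate
    if not (0 < f_lo < f_hi < fs / 2):
        raise ValueError(f"invalid band edges ({f_lo}, {f_hi}) for fs={fs}")
    n = recording.n_samples
    if numtaps is None:
        numtaps = int(round(3.3 * fs / f_lo)) | 1
        numtaps = min(numtaps, max(3, (n - 2) // 3) | 1)
    taps = sps.firwin(numtaps, [f_lo, f_hi], pass_zero=False, fs=fs)
    padlen = min(3 * numtaps, n - 1)
    filtered = sps.filtfilt(taps, [1.0], recording.samples, axis=-1, padlen=padlen)
    return EEGRecording(samples=filtered, sampling_rate=fs,
                        channel_labels=list(recording.channel_labels),
                        stimulus_onset=recording.stimulus_onset)


def common_average_reference(recording: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous mean over channels from every channel."""
    ref = recording.samples.mean(axis=0, keepdims=True)
    return EEGRecording(samples=recording.samples - ref,
                        sampling_rate=recording.sampling_rate,
                        channel_labels=list(recording.channel_labels),
                        stimulus_onset=recording.stimulus_onset)


# ---------------------------------------------------------------------------
# correlation

def correlation_matrix(recording: EEGRecording,
                       window: tuple[int, int] | None = None) -> ConnectivityMatrix:
    """Pearson correlation over a sample window (default: post-stimulus)."""
    if window is None:
        window = (recording.stimulus_onset, recording.n_samples)
    lo, hi = window
    seg = recording.samples[:, lo:hi]
    if seg.shape[1] < 2:
        raise ValueError("correlation window must contain >= 2 samples")
    sd = seg.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [recording.channel_labels[i] for i in dead]
        raise ValueError(f"zero-variance channel(s) in window: {names}")
    r = np.corrcoef(seg)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    r = (r + r.T) / 2
    return ConnectivityMatrix(values=r, measure="correlation",
                              channel_labels=list(recording.channel_labels))


# ---------------------------------------------------------------------------
# Morlet wavelet phase and PLV

def _morlet_kernel(f: float, fs: float, sigma_t: float) -> np.ndarray:
    """Truncated (+-4 sigma_t) complex Morlet atom, unit gain at ``f``."""
    half = int(math.ceil(4 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    envelope = np.exp(-t ** 2 / (2 * sigma_t ** 2))
    psi = envelope * np.exp(2j * np.pi * f * t)
    # 2/sum(envelope): a unit-amplitude cosine at f maps to amplitude ~1
    return psi * (2.0 / envelope.sum())


def _wavelet_coefficients(x: np.ndarray, f: float, fs: float,
                          sigma_t: float) -> tuple[np.ndarray, int]:
    """Complex coefficients for 1-D or (channels x time) input.

    Implemented as correlation with the atom; because the Gaussian envelope
    is even, correlating with psi equals convolving with psi, so a pure
    cosine at ``f`` yields phase advancing at +2*pi*f.
    """
    psi = _morlet_kernel(f, fs, sigma_t)
    half = (len(psi) - 1) // 2
    if x.shape[-1] < len(psi):
        raise ValueError(
            f"signal length {x.shape[-1]} shorter than wavelet support {len(psi)} "
            f"(f={f} Hz, sigma_t={sigma_t:.3g} s)")
    if x.ndim == 1:
        coeff = sps.fftconvolve(x, psi, mode="same")
    else:
        coeff = sps.fftconvolve(x, psi[None, :], mode="same", axes=-1)
    return coeff, half


def wavelet_phase(signal: np.ndarray, f: float, sampling_rate: float,
                  sigma_t: float | None = None) -> WaveletTransform:
    """Morlet transform of one signal at frequency ``f`` (sigma_t = 7/f)."""
    if f <= 0:
        raise ValueError("frequency must be positive")
    if f >= sampling_rate / 2:
        raise ValueError(f"frequency {f} at or above Nyquist ({sampling_rate / 2})")
    if sigma_t is None:
        sigma_t = 7.0 / f
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("wavelet_phase expects a 1-D signal")
    coeff, half = _wavelet_coefficients(x, f, sampling_rate, sigma_t)
    valid = np.zeros(len(x), dtype=bool)
    valid[half:len(x) - half] = True
    return WaveletTransform(coefficients=coeff, frequency=f, sigma_t=sigma_t,
                            sampling_rate=sampling_rate, valid=valid)


def plv_pair(phases_x: np.ndarray, phases_y: np.ndarray) -> float:
    """PLV of two per-epoch phase series (epochs x time bins).

    Per time bin, the modulus of the mean unit phasor of the phase
    difference across epochs; then the average over time bins.
    """
    px = np.atleast_2d(np.asarray(phases_x, dtype=float))
    py = np.atleast_2d(np.asarray(phases_y, dtype=float))
    if px.shape != py.shape:
        raise ValueError(f"phase arrays differ in shape: {px.shape} vs {py.shape}")
    if px.shape[0] < 1 or px.size == 0:
        raise ValueError("need at least one epoch with samples")
    phasor = np.exp(1j * (px - py))
    per_bin = np.abs(phasor.mean(axis=0))
    return float(per_bin.mean())


def baseline_normalize(series: np.ndarray, baseline: tuple[int, int]) -> np.ndarray:
    """(value - baseline mean) / baseline SD along the last axis.

    ``baseline`` is a half-open index range into the same series.  Applied
    per center frequency before any band averaging.
    """
    x = np.asarray(series, dtype=float)
    lo, hi = baseline
    base = x[..., lo:hi]
    if base.shape[-1] < 2:
        raise ValueError("baseline range must contain >= 2 bins")
    mu = base.mean(axis=-1, keepdims=True)
    sd = base.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero baseline SD; cannot normalize")
    return (x - mu) / sd


def _epoch_starts(first: int, last: int, length: int, valid_lo: int,
                  valid_hi: int, align: str) -> list[int]:
    """Start indices of nonoverlapping epochs fully inside validity bounds."""
    starts = []
    if align == "forward":
        s = first
        while s + length <= last:
            if s >= valid_lo and s + length <= valid_hi:
                starts.append(s)
            s += length
    else:  # backward from `last`
        s = last - length
        while s >= first:
            if s >= valid_lo and s + length <= valid_hi:
                starts.append(s)
            s -= length
        starts.reverse()
    return starts


def _plv_timecourse(unit: np.ndarray, starts: list[int], length: int) -> np.ndarray:
    """Per-bin cross-channel PLV (N x N x length) over the epoch ensemble."""
    epochs = np.stack([unit[:, s:s + length] for s in starts])   # E x N x L
    binwise = np.ascontiguousarray(epochs.transpose(2, 0, 1))    # L x E x N
    mean_phasor = binwise.transpose(0, 2, 1).conj() @ binwise / len(starts)
    return np.abs(mean_phasor).transpose(1, 2, 0)


def plv_matrix(recording: EEGRecording, band: FrequencyBand,
               epoch_length: float = 1.0, normalize: bool = False,
               sigma_t_factor: float = 7.0) -> ConnectivityMatrix:
    """Band-averaged PLV connectivity matrix of one recording.

    Per center frequency: extract phases, segment the post-stimulus interval
    into nonoverlapping epochs (the ensemble), compute the per-bin PLV
    timecourse, optionally z-score it against the pre-stimulus baseline
    epochs, and average over bins.  Per-frequency matrices are averaged
    arithmetically across the band's grid.
    """
    fs = recording.sampling_rate
    L = int(round(epoch_length * fs))
    if L < 1:
        raise ValueError("epoch_length too short for the sampling rate")
    if not band.center_freqs:
        raise ValueError("empty band grid")
    n = recording.n_channels
    onset = recording.stimulus_onset
    total = np.zeros((n, n))
    offdiag = ~np.eye(n, dtype=bool)
    for f in band.center_freqs:
        if f >= fs / 2:
            raise ValueError(f"center frequency {f} at or above Nyquist")
        sigma_t = sigma_t_factor / f
        coeff, half = _wavelet_coefficients(recording.samples, f, fs, sigma_t)
        mag = np.abs(coeff)
        mag[mag == 0] = 1.0
        unit = coeff / mag
        valid_lo, valid_hi = half, recording.n_samples - half
        post = _epoch_starts(onset, recording.n_samples, L, valid_lo, valid_hi,
                             "forward")
        if not post:
            raise ValueError(
                f"no fully valid post-stimulus epoch at {f} Hz "
                f"(wavelet margin {half} samples)")
        plv_t = _plv_timecourse(unit, post, L)               # N x N x L
        if normalize:
            base = _epoch_starts(0, onset, L, valid_lo, onset, "backward")
            if not base:
                raise ValueError(
                    f"no fully valid baseline epoch at {f} Hz "
                    f"(wavelet margin {half} samples)")
            base_t = _plv_timecourse(unit, base, L)
            mu = base_t.mean(axis=-1)
            sd = base_t.std(axis=-1)
            if np.any(sd[offdiag] == 0):
                raise ValueError(f"zero baseline PLV SD at {f} Hz")
            sd[~offdiag] = 1.0                               # diagonal unused
            value = ((plv_t - mu[..., None]) / sd[..., None]).mean(axis=-1)
        else:
            value = plv_t.mean(axis=-1)
        total += value
    out = total / len(band.center_freqs)
    np.fill_diagonal(out, 0.0)
    out = (out + out.T) / 2
    return ConnectivityMatrix(values=out,
                              measure="plv_normalized" if normalize else "plv",
                              band=band,
                              channel_labels=list(recording.channel_labels))


# ---------------------------------------------------------------------------
# vectorization

def vectorize(matrix: ConnectivityMatrix | np.ndarray,
              atol: float = 1e-8) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Strict upper triangle in row-major (i<j) order, plus the edge map."""
    values = matrix.values if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(values, values.T, atol=atol):
        raise ValueError("matrix is not symmetric within tolerance")
    n = values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    edge_index = list(zip(iu.tolist(), ju.tolist()))
    return values[iu, ju].copy(), edge_index


def devectorize(vector: np.ndarray, n_channels: int) -> np.ndarray:
    """Inverse of :func:`vectorize`: symmetric matrix with zero diagonal."""
    vector = np.asarray(vector, dtype=float)
    expected = n_channels * (n_channels - 1) // 2
    if vector.shape != (expected,):
        raise ValueError(f"expected {expected} entries for {n_channels} channels")
    out = np.zeros((n_channels, n_channels))
    iu, ju = np.triu_indices(n_channels, k=1)
    out[iu, ju] = vector
    out[ju, iu] = vector
    return out


def build_dataset(recordings: list[EEGRecording], labels,
                  measure: str = "plv",
                  band: FrequencyBand | None = None,
                  epoch_length: float = 1.0,
                  corr_window: tuple[int, int] | None = None) -> FeatureDataset:
    """One feature row per recording from the chosen connectivity measure."""
    labels = np.asarray(labels, dtype=int)
    if len(recordings) != len(labels):
        raise ValueError("one label per recording required")
    if not recordings:
        raise ValueError("empty recording list")
    n = recordings[0].n_channels
    chan = recordings[0].channel_labels
    for rec in recordings:
        if rec.n_channels != n or rec.channel_labels != chan:
            raise ValueError("inconsistent channel sets across recordings")
    if measure == "correlation":
        if band is not None:
            logger.warning("measure='correlation' ignores the frequency band %s",
                           band.name)
        mats = [correlation_matrix(rec, corr_window) for rec in recordings]
    elif measure in ("plv", "plv_normalized"):
        if band is None:
            raise ValueError("PLV measures require a frequency band")
        mats = [plv_matrix(rec, band, epoch_length,
                           normalize=(measure == "plv_normalized"))
                for rec in recordings]
    else:
        raise ValueError(f"unknown measure {measure!r}")
    rows, edge_index = [], None
    for m in mats:
        v, idx = vectorize(m)
        rows.append(v)
        edge_index = idx
    provenance = {"measure": measure,
                  "band": None if band is None or measure == "correlation"
                  else band.name,
                  "epoch_length": epoch_length}
    return FeatureDataset(X=np.vstack(rows), y=labels, edge_index=edge_index,
                          channel_labels=list(chan), provenance=provenance)
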