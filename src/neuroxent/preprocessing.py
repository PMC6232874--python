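"""Recording container, FIR band filtering, notch filtering, and epoching.

The analysis operates on resting-state multichannel recordings (the default
montage is the 19-electrode 10–20 set sampled at 200 Hz) decomposed into the
six canonical EEG bands: delta 1–4, theta 4–8, alpha 8–13, beta1 13–19,
beta2 19–30, and gamma 30–70 Hz.  Band filters are linear-phase Hamming-window
FIR designs applied forward–backward (zero phase), so band-limited epochs stay
aligned with the raw signal and with each other.
"""

from __future__ import annotations

import functools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "BandSpec",
    "EpochSet",
    "DEFAULT_CHANNELS",
    "CANONICAL_BANDS",
    "GROUPS",
    "design_bandpass",
    "default_fir_order",
    "notch_filter",
    "band_decompose",
    "segment_epochs",
    "common_average_reference",
]

#: 10–20 montage labels of the default 19-channel configuration.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8", "Cz", "C3", "C4",
    "T3", "T4", "T5", "T6", "Pz", "P3", "P4", "O1", "O2",
)

GROUPS = ("HC", "MCI", "AD")


@dataclass(frozen=True)
class BandSpec:
    """A frequency band with edges in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0.0 < self.low_hz < self.high_hz:
            raise ValueError(f"invalid band edges for {self.name}: {self.low_hz}-{self.high_hz}")


#: The six canonical analysis bands.
CANONICAL_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 1.0, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta1", 13.0, 19.0),
    BandSpec("beta2", 19.0, 30.0),
    BandSpec("gamma", 30.0, 70.0),
)

BAND_ORDER = tuple(b.name for b in CANONICAL_BANDS)


@dataclass
class Recording:
    """A labeled multichannel signal (rows = channels, columns = samples)."""

    subject_id: str
    fs: float
    channels: tuple[str, ...]
    data: np.ndarray
    group: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channels = tuple(self.channels)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be channels x time with one row per channel label")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")
        if self.group is not None and self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Equal-length contiguous epochs of one (subject, band) signal."""

    subject_id: str
    band: str | None
    fs: float
    channels: tuple[str, ...]
    epochs: list[np.ndarray]
    group: str | None = None
    split: str | None = None  # "train" / "test" tag enforced by the pipeline
    n_discarded_samples: int = 0

    @property
    def n_epoch(self) -> int:
        return self.epochs[0].shape[1] if self.epochs else 0


def default_fir_order(low_hz: float, fs: float) -> int:
    """Even FIR order covering >= 3 cycles of the lowest passband frequency."""
    order = math.ceil(3.0 * fs / low_hz)
    return order + (order % 2)


@functools.lru_cache(maxsize=256)
def _design_bandpass_cached(low_hz: float, high_hz: float, fs: float, order: int) -> np.ndarray:
    return signal.firwin(
        order + 1, [low_hz, high_hz], pass_zero=False, window="hamming", fs=fs
    )


def design_bandpass(
    low_hz: float, high_hz: float, fs: float, order: int | None = None
) -> np.ndarray:
    """Linear-phase Hamming-window FIR bandpass coefficients (order + 1 taps)."""
    if order is None:
        order = default_fir_order(low_hz, fs)
    if not 0.0 < low_hz < high_hz < fs / 2.0:
        raise ValueError(f"infeasible band edges {low_hz}-{high_hz} Hz at fs={fs}")
    if order < 2 or order % 2:
        raise ValueError("FIR order must be even and >= 2")
    return _design_bandpass_cached(float(low_hz), float(high_hz), float(fs), int(order))


def _filtfilt(taps: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Zero-phase FIR filtering: odd-extension padding, forward-backward pass.

    FFT convolution keeps long filters cheap; the padding mirrors
    ``scipy.signal.filtfilt``'s default odd extension so startup transients
    decay inside the discarded pad.
    """
    x = np.asarray(data, dtype=np.float64)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    n = x.shape[-1]
    padlen = min(3 * len(taps), n - 1)
    if padlen > 0:
        left = 2.0 * x[..., :1] - x[..., padlen:0:-1]
        right = 2.0 * x[..., -1:] - x[..., -2 : -padlen - 2 : -1]
        xp = np.concatenate([left, x, right], axis=-1)
    else:
        xp = x
    length = xp.shape[-1]
    h = taps[None, :]
    y = signal.fftconvolve(xp, h, mode="full", axes=-1)[..., :length]
    y = signal.fftconvolve(y[..., ::-1], h, mode="full", axes=-1)[..., :length]
    out = y[..., ::-1][..., padlen : padlen + n]
    return out[0] if squeeze else out


def notch_filter(recording: Recording, freq_hz: float = 50.0, bandwidth_hz: float = 2.0) -> Recording:
    """Remove a power-line tone with a zero-phase IIR notch."""
    if not 0.0 < freq_hz < recording.fs / 2.0:
        raise ValueError(f"notch frequency {freq_hz} Hz invalid for fs={recording.fs}")
    b, a = signal.iirnotch(freq_hz, freq_hz / bandwidth_hz, fs=recording.fs)
    filtered = signal.filtfilt(b, a, recording.data, axis=-1)
    return replace(recording, data=filtered)


def band_decompose(
    recording: Recording,
    bands: tuple[BandSpec, ...] = CANONICAL_BANDS,
    order: int | None = None,
) -> dict[str, Recording]:
    """Zero-phase band-filtered copies of a recording, one per band."""
    out: dict[str, Recording] = {}
    for band in bands:
        if band.high_hz >= recording.fs / 2.0:
            raise ValueError(
                f"band {band.name} upper edge {band.high_hz} Hz at or above Nyquist"
            )
        taps = design_bandpass(band.low_hz, band.high_hz, recording.fs, order)
        out[band.name] = replace(recording, data=_filtfilt(taps, recording.data))
    logger.info(
        "band_decompose: subject=%s fs=%g channels=%d bands=%s",
        recording.subject_id, recording.fs, recording.n_channels, list(out),
    )
    return out


def segment_epochs(
    recording: Recording, duration_s: float = 5.0, band: str | None = None
) -> EpochSet:
    """Cut a recording into non-overlapping contiguous epochs.

    The trailing partial epoch is discarded; a recording shorter than one
    epoch is an error.
    """
    n_epoch = int(round(duration_s * recording.fs))
    if n_epoch < 1:
        raise ValueError("epoch duration too short for sampling rate")
    n = recording.n_samples
    if n < n_epoch:
        raise ValueError(
            f"recording of {n} samples shorter than one {n_epoch}-sample epoch"
        )
    count = n // n_epoch
    epochs = [
        recording.data[:, k * n_epoch : (k + 1) * n_epoch].copy() for k in range(count)
    ]
    discarded = n - count * n_epoch
    logger.info(
        "segment_epochs: subject=%s epochs=%d n_epoch=%d discarded=%d",
        recording.subject_id, count, n_epoch, discarded,
    )
    return EpochSet(
        subject_id=recording.subject_id,
        band=band,
        fs=recording.fs,
        channels=recording.channels,
        epochs=epochs,
        group=recording.group,
        n_discarded_samples=discarded,
    )


def common_average_reference(recording: Recording) -> Recording:
    """Subtract the instantaneous mean across channels."""
    return replace(recording, data=recording.data - recording.data.mean(axis=0, keepdims=True))
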