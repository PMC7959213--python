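"""Online EEG preprocessing: downsample, causal bandpass, average reference.

All filters are one-pass (forward-only) so that the chain is usable in a
real-time loop: the output at time ``t`` depends only on inputs at or
before ``t``.  Whole-segment filtering with :func:`scipy.signal.sosfilt`
is mathematically identical to streaming the same filter sample by
sample with carried state, so trials are processed in one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal

__all__ = [
    "EEGSegment",
    "downsample",
    "bandpass",
    "rereference_average",
    "preprocess_online",
    "preprocess_training",
    "DEFAULT_BAND",
    "DEFAULT_ORDER",
]

DEFAULT_BAND = (1.0, 30.0)  # Hz
DEFAULT_ORDER = 6
_ANTIALIAS_ORDER = 8
_ANTIALIAS_REL_CUTOFF = 0.4  # fraction of the output sampling rate


@dataclass
class EEGSegment:
    """A time x channel chunk of (possibly simulated) EEG.

    Attributes
    ----------
    data : np.ndarray
        Shape ``(n_samples, n_channels)``; no NaNs.
    fs : float
        Sampling rate in samples/s.
    channel_names : list of str
        One label per channel.
    """

    data: np.ndarray
    fs: float
    channel_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (time x channel)")
        if self.data.shape[0] < 1:
            raise ValueError("segment must contain at least one sample")
        if np.isnan(self.data).any():
            raise ValueError("segment contains NaNs")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must match channel count")

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.data.shape[1])

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray, fs: float | None = None) -> "EEGSegment":
        return EEGSegment(
            data=data,
            fs=self.fs if fs is None else fs,
            channel_names=list(self.channel_names),
        )


@lru_cache(maxsize=64)
def _design_sos(order: int, lo: float, hi: float | None, fs: float,
                btype: str, dtype_str: str) -> np.ndarray:
    wn = lo if hi is None else (lo, hi)
    sos = signal.butter(order, wn, btype=btype, fs=fs, output="sos")
    return sos.astype(np.dtype(dtype_str))


def downsample(seg: EEGSegment, fs_out: float) -> EEGSegment:
    """Anti-alias filter then decimate to ``fs_out``.

    ``fs_out`` must divide ``seg.fs`` exactly.  The anti-alias filter is
    a causal order-8 Butterworth low-pass at ``0.4 * fs_out``; output
    length is ``floor(n_in * fs_out / fs_in)``.
    """
    ratio = seg.fs / fs_out
    q = int(round(ratio))
    if q < 1 or abs(ratio - q) > 1e-9:
        raise ValueError(
            f"output rate {fs_out} must divide the input rate {seg.fs} exactly"
        )
    if q == 1:
        return seg.copy_with(seg.data.copy())
    sos = _design_sos(
        _ANTIALIAS_ORDER, _ANTIALIAS_REL_CUTOFF * fs_out, None, seg.fs,
        "low", seg.data.dtype.str,
    )
    filtered = signal.sosfilt(sos, seg.data, axis=0)
    # decimated output is small; return to double precision for the
    # narrow-band stages downstream
    return seg.copy_with(filtered[::q].astype(float), fs=float(fs_out))


def bandpass(
    seg: EEGSegment,
    lo: float = DEFAULT_BAND[0],
    hi: float = DEFAULT_BAND[1],
    order: int = DEFAULT_ORDER,
) -> EEGSegment:
    """One-pass (causal) Butterworth band-pass.

    ``order`` is the design order handed to the Butterworth prototype
    (the band-pass transfer function therefore has ``2*order`` poles,
    matching the common "order-N Butterworth band-pass" usage).
    """
    if not (0 < lo < hi < seg.fs / 2):
        raise ValueError(
            f"invalid band ({lo}, {hi}) Hz for sampling rate {seg.fs}"
        )
    sos = _design_sos(order, lo, hi, seg.fs, "bandpass", seg.data.dtype.str)
    return seg.copy_with(signal.sosfilt(sos, seg.data, axis=0))


def rereference_average(seg: EEGSegment) -> EEGSegment:
    """Subtract the instantaneous channel mean from every channel."""
    if seg.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    data = seg.data - seg.data.mean(axis=1, keepdims=True)
    return seg.copy_with(data)


def preprocess_online(
    seg: EEGSegment,
    fs_out: float = 256.0,
    lo: float = DEFAULT_BAND[0],
    hi: float = DEFAULT_BAND[1],
    order: int = DEFAULT_ORDER,
) -> EEGSegment:
    """The real-time chain: downsample -> bandpass -> average reference."""
    return rereference_average(bandpass(downsample(seg, fs_out), lo, hi, order))


def preprocess_training(
    seg: EEGSegment,
    fs_out: float = 256.0,
    lo: float = DEFAULT_BAND[0],
    hi: float = DEFAULT_BAND[1],
    order: int = DEFAULT_ORDER,
) -> EEGSegment:
    """Training-time chain: average reference then the same causal filter.

    Segments still recorded at the acquisition rate are downsampled
    first so training and online data share the model sampling rate.
    """
    if seg.fs != fs_out:
        seg = downsample(seg, fs_out)
    return bandpass(rereference_average(seg), lo, hi, order)
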