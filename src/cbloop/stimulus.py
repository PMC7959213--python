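"""Abstract 1-D stimulus templates for decoder training and scoring.

Two stimulus streams (a face and a spiral) oscillate at the same
frequency in temporal phase opposition.  The decoder never sees the
rendered images, only these unit less one-value-per-sample templates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "StimulusTemplates",
    "make_templates",
    "dominant_frequency",
    "DEFAULT_F0",
    "DEFAULT_FS",
]

DEFAULT_F0 = 1.875  # Hz
DEFAULT_FS = 256.0  # samples/s

_WAVEFORMS = ("sinusoid", "sweep-profile")


@dataclass(frozen=True)
class StimulusTemplates:
    """Phase-opposed stimulus representations.

    Attributes
    ----------
    y_face, y_spiral : np.ndarray
        One value per time sample; equal length; zero mean over an
        integer number of cycles; dominant spectral component at `f0`.
    fs : float
        Sampling rate in samples/s.
    f0 : float
        Oscillation frequency in Hz.
    waveform : str
        Realized waveform, ``"sinusoid"`` or ``"sweep-profile"``.
    """

    y_face: np.ndarray
    y_spiral: np.ndarray
    fs: float
    f0: float
    waveform: str = "sinusoid"

    def __post_init__(self) -> None:
        if self.y_face.shape != self.y_spiral.shape:
            raise ValueError("y_face and y_spiral must have equal length")

    @property
    def n_samples(self) -> int:
        return int(self.y_face.shape[0])

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def slice(self, start: int, stop: int) -> "StimulusTemplates":
        """Sample-index slice of both templates (alignment preserved)."""
        return StimulusTemplates(
            y_face=self.y_face[start:stop],
            y_spiral=self.y_spiral[start:stop],
            fs=self.fs,
            f0=self.f0,
            waveform=self.waveform,
        )

    def template(self, item: str) -> np.ndarray:
        if item == "face":
            return self.y_face
        if item == "spiral":
            return self.y_spiral
        raise ValueError(f"unknown item {item!r}")

    def to_csv(self, path_face, path_spiral) -> None:
        """Export each template as two-column CSV (time_s, value)."""
        t = self.times()
        for path, y in ((path_face, self.y_face), (path_spiral, self.y_spiral)):
            with open(path, "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["time_s", "value"])
                writer.writerows(zip(t, y))


def dominant_frequency(y: np.ndarray, fs: float, pad_factor: int = 32) -> float:
    """Frequency (Hz) of the magnitude-spectrum peak.

    Zero-pads by ``pad_factor`` so the peak is located on a grid much
    finer than ``1/duration`` (signals need not contain a whole number
    of cycles).
    """
    y = np.asarray(y, dtype=float)
    n = int(y.size * pad_factor)
    spec = np.abs(np.fft.rfft(y - y.mean(), n=n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return float(freqs[np.argmax(spec)])


def _phase(f0: float, fs: float, n: int) -> np.ndarray:
    # phase in cycles, face convention: starts at 0
    return f0 * np.arange(n) / fs


def make_templates(
    f0: float = DEFAULT_F0,
    fs: float = DEFAULT_FS,
    duration: float = 5.0,
    waveform: str = "sinusoid",
) -> StimulusTemplates:
    """Construct phase-opposed stimulus templates.

    Parameters
    ----------
    f0 : float
        Oscillation frequency (Hz); must satisfy ``f0 < fs/2``.
    fs : float
        Sampling rate (samples/s).
    duration : float
        Length in seconds; ``duration * fs`` must be a whole number of
        samples.
    waveform : {"sinusoid", "sweep-profile"}
        ``"sinusoid"`` is a pure cosine pair; ``"sweep-profile"`` is a
        zero-mean periodic sawtooth envelope (period ``1/f0``) standing
        in for a cyclic scrambling sweep.

    Returns
    -------
    StimulusTemplates
        With ``y_spiral`` the half-period-shifted (sinusoid: pointwise
        negated) counterpart of ``y_face``.
    """
    if f0 <= 0:
        raise ValueError(f"f0 must be positive, got {f0}")
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    if f0 >= fs / 2:
        raise ValueError(f"f0={f0} must be below the Nyquist frequency {fs / 2}")
    n_float = duration * fs
    n = int(round(n_float))
    if abs(n_float - n) > 1e-9:
        raise ValueError(
            f"duration*fs = {n_float} is not a whole number of samples"
        )
    if waveform not in _WAVEFORMS:
        raise ValueError(f"waveform must be one of {_WAVEFORMS}, got {waveform!r}")

    phase = _phase(f0, fs, n)
    if waveform == "sinusoid":
        y_face = np.cos(2 * np.pi * phase)
        y_spiral = -y_face
    else:
        # zero-mean sawtooth; spiral shifted by half a cycle
        y_face = signal.sawtooth(2 * np.pi * phase, width=0.5)
        y_spiral = signal.sawtooth(2 * np.pi * (phase + 0.5), width=0.5)
    return StimulusTemplates(
        y_face=y_face, y_spiral=y_spiral, fs=float(fs), f0=float(f0),
        waveform=waveform,
    )
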