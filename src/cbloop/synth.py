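"""Synthetic EEG generation and the cue-integration observer.

The forward model is deliberately minimal: the attended and unattended
templates are mixed into every channel through one fixed random spatial
pattern (optionally with small per-channel latency jitter) and buried
in broadband noise.  Free-attention trials carry a latent signed
strength: its sign sets the initially attended item, its magnitude how
strongly the item is attended, so internal evidence is weak and
variable on some trials and strong on others.

The observer combines its own noisy readout of that internal evidence
with the feedback cue into a decision variable ``L = w_int*z +
w_cue*cue + eps`` whose sign is the report.  Confidence rates the
coherence of the integrated percept on a separate channel (optionally
with its own cue weight and noise): thresholds on its magnitude give
the 1-4 rating, so a cue that conflicts with strong internal evidence
can depress confidence without flipping the report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from cbloop.preprocess import EEGSegment
from cbloop.stimulus import StimulusTemplates

__all__ = [
    "EEGGenParams",
    "AttentionTrace",
    "ObserverParams",
    "sample_attention_trace",
    "simulate_trial_eeg",
    "observe_and_report",
    "trial_internal_signal",
    "sample_latent_evidence",
    "fit_observer_params",
]

logger = logging.getLogger(__name__)

_ITEMS = ("face", "spiral")
_NOISE_BAND_LIMIT_HZ = 120.0


@dataclass(frozen=True)
class EEGGenParams:
    """Forward-model parameters for synthetic raw EEG."""

    n_channels: int = 64
    fs_raw: float = 2048.0
    attended_gain: float = 1.0
    unattended_gain: float = 0.3
    noise_sd: float = 1.0
    noise_spectrum: str = "one_over_f"
    switch_prob: float = 0.0
    mixing_seed: int = 0
    noise_seed: int = 0
    lag_jitter_max: float = 0.0  # s, per-channel latency jitter (0 disables)
    strength_tail: float = 1.0   # tail exponent of free-attention strength
    strength_scale: float = 1.0  # mean free-attention strength vs cued (=1)

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if not (self.attended_gain > self.unattended_gain >= 0):
            raise ValueError("require attended_gain > unattended_gain >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.switch_prob <= 1:
            raise ValueError("switch_prob must be in [0, 1]")
        if self.noise_spectrum not in ("white", "one_over_f"):
            raise ValueError(f"unknown noise spectrum {self.noise_spectrum!r}")
        if not 0 <= self.lag_jitter_max < 0.2:
            raise ValueError("lag_jitter_max must be in [0, 0.2) s")
        if self.strength_tail < 1.0:
            raise ValueError("strength_tail must be >= 1")
        if self.strength_scale <= 0:
            raise ValueError("strength_scale must be > 0")


@dataclass(frozen=True)
class AttentionTrace:
    """Piecewise-constant attended item over a trial.

    ``switch_times`` are seconds from trace start; at most one switch by
    default.  ``strength`` scales the evoked response of this trial
    (1.0 for cued training trials).
    """

    duration: float
    initial_state: str
    switch_times: tuple = ()
    strength: float = 1.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.initial_state not in _ITEMS:
            raise ValueError(f"initial_state must be one of {_ITEMS}")
        if any(not 0 < t < self.duration for t in self.switch_times):
            raise ValueError("switch times must lie strictly inside the trial")
        if list(self.switch_times) != sorted(self.switch_times):
            raise ValueError("switch times must be sorted")
        if self.strength < 0:
            raise ValueError("strength must be >= 0")

    def state_at(self, t: float) -> str:
        n_switches = sum(1 for s in self.switch_times if s <= t)
        if n_switches % 2 == 0:
            return self.initial_state
        return "spiral" if self.initial_state == "face" else "face"

    @property
    def final_state(self) -> str:
        return self.state_at(self.duration)

    def face_sign_samples(self, fs: float, n_samples: int) -> np.ndarray:
        """+1 where the face is attended, -1 where the spiral is."""
        t = np.arange(n_samples) / fs
        sign0 = 1.0 if self.initial_state == "face" else -1.0
        flips = np.ones(n_samples)
        for s in self.switch_times:
            flips[t >= s] *= -1.0
        return sign0 * flips

    def has_switch_after(self, t: float) -> bool:
        return any(s > t for s in self.switch_times)


def sample_attention_trace(
    duration: float,
    switch_prob: float,
    seed: int,
    strength: float = 1.0,
    initial_state: str | None = None,
) -> AttentionTrace:
    """Random trace: equiprobable initial item, one uniform switch w.p.
    ``switch_prob``.

    ``initial_state`` may be pinned (the free parameters then are only
    the switch); by default it is drawn from the same seed.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    state = initial_state
    if state is None:
        state = _ITEMS[int(rng.integers(2))]
    switches: tuple = ()
    if rng.random() < switch_prob:
        switches = (float(rng.uniform(0.0, duration)),)
    else:
        rng.uniform(0.0, duration)  # keep the stream aligned across branches
    return AttentionTrace(
        duration=duration,
        initial_state=state,
        switch_times=switches,
        strength=strength,
    )


def _mixing_vector(params: EEGGenParams) -> np.ndarray:
    seed = params.mixing_seed
    for attempt in range(2):
        rng = np.random.default_rng(seed)
        m = rng.standard_normal(params.n_channels)
        norm = np.linalg.norm(m)
        if norm > 1e-12:
            return m / norm
        logger.warning(
            "degenerate all-zero mixing vector from seed %d; regenerating "
            "from seed %d", seed, seed + 1,
        )
        seed += 1
    raise RuntimeError("could not draw a non-degenerate mixing vector")


def _noise(params: EEGGenParams, n_samples: int, seed: int) -> np.ndarray:
    """Channel-major (n_channels, n_samples) noise array."""
    rng = np.random.default_rng([params.noise_seed, seed])
    if params.noise_spectrum == "white":
        return params.noise_sd * rng.standard_normal(
            (params.n_channels, n_samples), dtype=np.float32
        )
    # 1/f power shaping, sampled directly in the frequency domain:
    # amplitudes scale as f^-1/2 above 1 Hz, flat below, zero above the
    # band limit (the anti-alias stage removes that range regardless)
    n_freq = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / params.fs_raw)
    n_band = min(n_freq, int(np.searchsorted(freqs, _NOISE_BAND_LIMIT_HZ)) + 1)
    shape = (1.0 / np.sqrt(np.maximum(freqs[:n_band], 1.0))).astype(np.float32)
    spectrum = np.zeros((params.n_channels, n_freq), dtype=np.complex64)
    spectrum[:, :n_band] = (
        rng.standard_normal((params.n_channels, n_band), dtype=np.float32)
        + 1j * rng.standard_normal((params.n_channels, n_band), dtype=np.float32)
    ) * shape
    colored = np.fft.irfft(spectrum, n=n_samples, axis=1)
    sd = colored.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (params.noise_sd * colored / sd).astype(np.float32)


def _template_value(
    templates: StimulusTemplates, item: str, t: np.ndarray
) -> np.ndarray:
    """Evaluate a template analytically at arbitrary times (periodic)."""
    phase = templates.f0 * t
    if templates.waveform == "sinusoid":
        y = np.cos(2 * np.pi * phase)
        return y if item == "face" else -y
    from scipy.signal import sawtooth

    shift = 0.0 if item == "face" else 0.5
    return sawtooth(2 * np.pi * (phase + shift), width=0.5)


def simulate_trial_eeg(
    templates: StimulusTemplates,
    trace: AttentionTrace,
    params: EEGGenParams,
    seed: int,
) -> EEGSegment:
    """Raw multichannel EEG for one trial.

    Every channel carries ``strength * (g_att * y_attended + g_unatt *
    y_unattended)`` through a fixed random spatial mixing vector, plus
    independent broadband noise.  Deterministic given
    ``(params.mixing_seed, params.noise_seed, seed)``.
    """
    fs = params.fs_raw
    n = int(round(trace.duration * fs))
    t = np.arange(n) / fs
    face_sign = trace.face_sign_samples(fs, n)

    mixing = _mixing_vector(params)
    jitter = np.zeros(params.n_channels)
    if params.lag_jitter_max > 0:
        jrng = np.random.default_rng([params.mixing_seed, 1])
        jitter = jrng.uniform(0.0, params.lag_jitter_max, params.n_channels)

    ga, gu, k = params.attended_gain, params.unattended_gain, trace.strength

    def _source(tc: np.ndarray) -> np.ndarray:
        y_face = _template_value(templates, "face", tc)
        y_spiral = _template_value(templates, "spiral", tc)
        att = np.where(face_sign > 0, y_face, y_spiral)
        unatt = np.where(face_sign > 0, y_spiral, y_face)
        return k * (ga * att + gu * unatt)

    # channel-major build keeps per-channel rows contiguous for filtering
    if params.lag_jitter_max == 0:
        data = np.multiply.outer(mixing, _source(t))
    elif templates.waveform == "sinusoid":
        # cos(w(t-d)) = cos(wt)cos(wd) + sin(wt)sin(wd); for phase-opposed
        # sinusoids the source reduces to face_sign * (ga-gu) * y_face
        w = 2 * np.pi * templates.f0
        coswt, sinwt = np.cos(w * t), np.sin(w * t)
        amp = mixing * k * (ga - gu)
        per_ch = (
            np.multiply.outer(amp * np.cos(w * jitter), coswt)
            + np.multiply.outer(amp * np.sin(w * jitter), sinwt)
        )
        data = per_ch * face_sign
    else:
        data = np.empty((params.n_channels, n))
        for c in range(params.n_channels):
            data[c] = mixing[c] * _source(t - jitter[c])
    # single precision is ample at raw-EEG SNR and halves the bandwidth
    # of the expensive acquisition-rate stages
    data = data.astype(np.float32) + _noise(params, n, seed)
    return EEGSegment(data=data.T, fs=fs)


# ---------------------------------------------------------------------------
# latent evidence and the observer


def mean_abs_normal_power(gamma: float) -> float:
    """``E[|N(0,1)|**gamma]`` (normalizes latent strengths to mean 1)."""
    from scipy.special import gamma as gamma_fn

    return float(2 ** (gamma / 2) * gamma_fn((gamma + 1) / 2) / np.sqrt(np.pi))


def sample_latent_evidence(seed: int, tail_exponent: float = 1.0) -> float:
    """Signed latent evidence ``sign(x) * |x|**tail_exponent`` with x ~ N(0,1).

    Exponents above 1 concentrate mass near zero (weak evidence on most
    trials) while keeping occasional strong-evidence trials.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal()
    return float(np.sign(x) * np.abs(x) ** tail_exponent)


def trial_internal_signal(
    trace: AttentionTrace, internal_noise_sd: float, seed: int
) -> float:
    """The participant's own noisy readout of end-of-trial evidence.

    Signed toward the finally attended item (+ = face), magnitude equal
    to the trial's attention strength plus internal noise.
    """
    sign = 1.0 if trace.final_state == "face" else -1.0
    rng = np.random.default_rng(seed)
    return float(sign * trace.strength + internal_noise_sd * rng.standard_normal())


@dataclass(frozen=True)
class ObserverParams:
    """Reliability-weighted cue-integration observer.

    The report channel thresholds ``L = w_int*z + w_cue*cue + eps`` at
    zero.  The confidence channel rates the coherence of the integrated
    percept: thresholds apply to ``|w_int*z + conf_cue_weight*cue +
    eps_conf|`` where ``conf_cue_weight`` defaults to ``w_cue`` and
    ``eps_conf ~ N(0, conf_noise_sd^2)``.  With both confidence fields
    left ``None`` the channel thresholds |L| itself (report noise
    included).  A ``conf_cue_weight`` above ``w_cue`` makes cue-evidence
    conflict depress confidence more than it sways the report, which is
    what lets confabulations carry high confidence while genuine
    introspection against the cue stays diffident.
    """

    w_int: float = 1.0
    w_cue: float = 0.5
    sigma_obs: float = 0.5
    conf_thresholds: tuple = (0.5, 1.0, 2.0)
    conf_noise_sd: float | None = None
    conf_cue_weight: float | None = None
    internal_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.w_int < 0 or self.w_cue < 0:
            raise ValueError("weights must be >= 0")
        if self.sigma_obs <= 0:
            raise ValueError("sigma_obs must be > 0")
        th = self.conf_thresholds
        if len(th) != 3 or not (th[0] < th[1] < th[2]):
            raise ValueError("conf_thresholds must be 3 strictly increasing values")
        if th[0] < 0:
            raise ValueError("conf_thresholds must be non-negative")
        if self.conf_noise_sd is not None and self.conf_noise_sd < 0:
            raise ValueError("conf_noise_sd must be >= 0 (or None)")
        if self.conf_cue_weight is not None and self.conf_cue_weight < 0:
            raise ValueError("conf_cue_weight must be >= 0 (or None)")
        if self.internal_noise_sd < 0:
            raise ValueError("internal_noise_sd must be >= 0")


_CUE_VALUES = {1: 1.0, -1: -1.0, 0: 0.0}


def observe_and_report(
    signed_internal_evidence: float,
    cue: int,
    params: ObserverParams,
    seed: int,
) -> tuple[str, int]:
    """One report + confidence from the cue-integration observer.

    ``cue`` is +1 (face feedback), -1 (spiral feedback) or 0 (none).
    The decision variable is ``L = w_int*z + w_cue*cue + eps`` with
    ``eps ~ N(0, sigma_obs^2)``; the report is face iff ``L > 0`` (an
    exact tie resolves to face and is logged).  Confidence is 1 plus the
    number of thresholds below the magnitude of the integrated-evidence
    readout (|L| itself when ``conf_noise_sd`` is None).
    """
    if cue not in _CUE_VALUES:
        raise ValueError(f"cue must be one of {sorted(_CUE_VALUES)}, got {cue!r}")
    rng = np.random.default_rng(seed)
    cue_value = _CUE_VALUES[cue]
    mean = params.w_int * signed_internal_evidence + params.w_cue * cue_value
    L = mean + params.sigma_obs * rng.standard_normal()
    if L == 0.0:
        logger.info("observer decision variable exactly 0; resolved to face")
    report = "face" if L >= 0 else "spiral"
    if params.conf_noise_sd is None and params.conf_cue_weight is None:
        conf_var = abs(L)
    else:
        w_cc = params.w_cue if params.conf_cue_weight is None \
            else params.conf_cue_weight
        noise_sd = params.conf_noise_sd or 0.0
        conf_var = abs(
            params.w_int * signed_internal_evidence + w_cc * cue_value
            + noise_sd * rng.standard_normal()
        )
    confidence = 1 + int(np.sum(np.asarray(params.conf_thresholds) < conf_var))
    return report, confidence


# ---------------------------------------------------------------------------
# parameter recovery


def _norm_cdf(x):
    from scipy.special import ndtr

    return ndtr(x)


def fit_observer_params(
    z: np.ndarray,
    cue: np.ndarray,
    report_face: np.ndarray,
    confidence: np.ndarray,
    conf_thresholds: tuple,
    conf_noise_sd: float | None = None,
    conf_cue_weight: float | None = None,
    x0: tuple = (0.8, 0.8, 0.8),
) -> dict:
    """Maximum-likelihood recovery of ``(w_int, w_cue, sigma_obs)``.

    Thresholds are treated as known.  With ``conf_noise_sd=None`` the
    report sign and confidence bin jointly locate ``L`` in one of eight
    intervals of a normal with mean ``w_int*z + w_cue*cue`` and SD
    ``sigma_obs`` (an ordered-probit likelihood); with a separate
    confidence channel the two likelihood factors are independent.
    """
    z = np.asarray(z, dtype=float)
    cue = np.asarray(cue, dtype=float)
    rep = np.asarray(report_face, dtype=bool)
    conf = np.asarray(confidence, dtype=int)
    th = np.asarray(conf_thresholds, dtype=float)
    edges = np.concatenate(([0.0], th, [np.inf]))  # |L| bin edges

    def nll(p):
        w_int, w_cue, sigma = p
        if sigma <= 1e-6 or w_int < 0 or w_cue < 0:
            return 1e12
        mean = w_int * z + w_cue * cue
        lo_edge = edges[conf - 1]
        hi_edge = edges[conf]
        if conf_noise_sd is None:
            # L in (lo, hi) on the reported side
            lo = np.where(rep, lo_edge, -hi_edge)
            hi = np.where(rep, hi_edge, -lo_edge)
            p_cell = _norm_cdf((hi - mean) / sigma) - _norm_cdf((lo - mean) / sigma)
        else:
            p_rep = np.where(
                rep, _norm_cdf(mean / sigma), _norm_cdf(-mean / sigma)
            )
            w_cc = w_cue if conf_cue_weight is None else conf_cue_weight
            mean_c = w_int * z + w_cc * cue
            s = max(conf_noise_sd, 1e-9)
            p_conf = (
                _norm_cdf((hi_edge - mean_c) / s)
                - _norm_cdf((lo_edge - mean_c) / s)
                + _norm_cdf((-lo_edge - mean_c) / s)
                - _norm_cdf((-hi_edge - mean_c) / s)
            )
            p_cell = p_rep * p_conf
        return -np.sum(np.log(np.maximum(p_cell, 1e-300)))

    res = minimize(nll, x0=np.asarray(x0), method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000})
    w_int, w_cue, sigma = res.x
    return {
        "w_int": float(w_int),
        "w_cue": float(w_cue),
        "sigma_obs": float(sigma),
        "nll": float(res.fun),
        "converged": bool(res.success),
    }
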