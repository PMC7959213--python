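"""Trial-level derived quantities.

Internal evidence (IE) is the absolute accumulated difference between
the face and spiral correlation scores over the final 1.5 s of the
decision phase.  The consistency index divides IE by a bootstrap
estimate of the variance of the per-window correlation differences over
the 3 s accumulation period before feedback.  Accuracy compares the
report with the decoded item, and the introspection label classifies
reported deceptive trials as genuine introspection or confabulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from cbloop.decoder import ScoreStream

__all__ = [
    "TrialMetrics",
    "internal_evidence",
    "consistency",
    "label_accuracy",
    "label_introspection",
    "CONSISTENCY_EPS",
    "DEFAULT_N_BOOT",
]

logger = logging.getLogger(__name__)

CONSISTENCY_EPS = 1e-8
DEFAULT_N_BOOT = 1000
DEFAULT_IE_PAIRS = 6          # last 1.5 s at 250 ms hop
DEFAULT_ACCUM_WINDOW = 3.0    # s before feedback for the variance term


@dataclass(frozen=True)
class TrialMetrics:
    ie: float
    signed_ie: float
    consistency: float
    n_boot: int
    boot_seed: int

    def __post_init__(self) -> None:
        if abs(self.ie - abs(self.signed_ie)) > 1e-12:
            raise ValueError("ie must equal |signed_ie|")
        if not np.isfinite(self.consistency) or self.consistency < 0:
            raise ValueError("consistency must be finite and >= 0")


def internal_evidence(
    stream: ScoreStream, n_last: int = DEFAULT_IE_PAIRS
) -> tuple[float, float]:
    """Accumulated face-minus-spiral score difference, last ``n_last`` pairs.

    Returns ``(ie, signed_ie)`` with ``ie = |signed_ie|``; positive
    ``signed_ie`` means evidence for the face.
    """
    if len(stream) < n_last:
        raise ValueError(
            f"stream has {len(stream)} pairs, internal evidence needs {n_last}"
        )
    signed = float(stream.differences()[-n_last:].sum())
    return abs(signed), signed


def consistency(
    stream: ScoreStream,
    accumulation_window: float = DEFAULT_ACCUM_WINDOW,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    n_last: int = DEFAULT_IE_PAIRS,
    summary: str = "mean_of_variances",
) -> float:
    """IE over the bootstrapped variance of recent score differences.

    The numerator is :func:`internal_evidence` (last ``n_last`` pairs);
    the denominator resamples, with replacement and ``n_boot`` times,
    the per-window differences falling in the trailing
    ``accumulation_window`` seconds, and summarizes the resampled
    variances (default: their mean; ``summary="variance_of_means"``
    uses the variance of resampled means instead).  A denominator below
    ``CONSISTENCY_EPS`` is floored and logged.
    """
    n_acc = int(round(accumulation_window / stream.hop))
    if len(stream) < max(n_acc, n_last):
        raise ValueError(
            f"stream has {len(stream)} pairs; consistency needs {n_acc}"
        )
    ie, _ = internal_evidence(stream, n_last=n_last)
    diffs = stream.differences()[-n_acc:]
    rng = np.random.default_rng(seed)
    samples = rng.choice(diffs, size=(n_boot, diffs.size), replace=True)
    if summary == "mean_of_variances":
        denom = float(samples.var(axis=1, ddof=0).mean())
    elif summary == "variance_of_means":
        denom = float(samples.mean(axis=1).var(ddof=0))
    else:
        raise ValueError(f"unknown bootstrap summary {summary!r}")
    if denom < CONSISTENCY_EPS:
        logger.warning(
            "degenerate score-difference variance %.3e floored to %.0e",
            denom,
            CONSISTENCY_EPS,
        )
        denom = CONSISTENCY_EPS
    return ie / denom


def label_accuracy(report: str, decoded: str) -> str:
    """``"correct"`` when the report matches the decoded item."""
    for name, value in (("report", report), ("decoded", decoded)):
        if value not in ("face", "spiral"):
            raise ValueError(f"{name} must be 'face' or 'spiral', got {value!r}")
    return "correct" if report == decoded else "incorrect"


def label_introspection(feedback_type: str, accuracy: str | None) -> str:
    """Genuine introspection vs confabulation, defined on deceptive trials.

    Deceptive + correct -> ``"genuine"``; deceptive + incorrect ->
    ``"confabulation"``; anything else -> ``"n/a"`` (informative-trial
    accuracy does not identify the introspective mechanism).
    """
    if feedback_type not in ("informative", "deceptive", "none"):
        raise ValueError(f"unknown feedback type {feedback_type!r}")
    if feedback_type != "deceptive":
        return "n/a"
    if accuracy not in ("correct", "incorrect"):
        raise ValueError(
            "accuracy must be defined ('correct'/'incorrect') on deceptive "
            f"trials, got {accuracy!r}"
        )
    return "genuine" if accuracy == "correct" else "confabulation"
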