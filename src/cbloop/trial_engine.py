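"""Experiment schedules and closed-loop session simulation.

The main phase is 480 five-second trials in blocks of 160; feedback is
deceptive on an exact 25% of trials per block and reports are requested
on all deceptive trials plus an exact third of informative trials, so
the analyzable counts are 120/120 per participant.  The deceptive /
report assignment is fixed when the schedule is built, before any
decoding happens.  A control block of 160 trials gives no feedback and
requests reports on half the trials.

``run_session`` closes the loop per trial: simulate raw EEG for the
latent attention trace, preprocess, stream correlation scores, decide,
map the decision through the trial plan to a feedback cue, then (second
pass, once the participant's evidence distribution is known for
z-scoring) query the cue-integration observer on report trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cbloop import metrics as _metrics
from cbloop.decoder import BackwardModel, decide, stream_scores
from cbloop.preprocess import preprocess_online
from cbloop.stimulus import StimulusTemplates, make_templates
from cbloop.synth import (
    AttentionTrace,
    EEGGenParams,
    ObserverParams,
    mean_abs_normal_power,
    observe_and_report,
    sample_attention_trace,
    simulate_trial_eeg,
    trial_internal_signal,
)

__all__ = [
    "ScheduleConfig",
    "TrialPlan",
    "TrialRecord",
    "build_schedule",
    "build_control_schedule",
    "run_session",
    "run_control_session",
    "records_to_dataframe",
]

logger = logging.getLogger(__name__)

_OPPOSITE = {"face": "spiral", "spiral": "face"}


@dataclass(frozen=True)
class ScheduleConfig:
    n_main_trials: int = 480
    p_deceptive: float = 0.25
    report_fraction_informative: float = 1.0 / 3.0
    n_control_trials: int = 160
    control_report_fraction: float = 0.5
    trial_duration: float = 5.0
    feedback_duration: float = 0.5
    block_size: int = 160
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_main_trials <= 0 or self.n_control_trials < 0:
            raise ValueError("trial counts must be positive")
        for name in ("p_deceptive", "report_fraction_informative",
                     "control_report_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if self.trial_duration <= 0 or self.feedback_duration < 0:
            raise ValueError("durations must be positive")
        if self.n_main_trials % self.block_size != 0:
            raise ValueError(
                f"{self.n_main_trials} main trials do not split into blocks "
                f"of {self.block_size}"
            )


@dataclass(frozen=True)
class TrialPlan:
    index: int
    phase: str                # "main" | "control"
    feedback_type: str        # "informative" | "deceptive" | "none"
    report_requested: bool
    block: int = 0


@dataclass
class TrialRecord:
    """Everything measured or simulated for one trial."""

    index: int
    phase: str
    feedback_type: str
    report_requested: bool
    decoded: str
    feedback_shown: str                    # "face" | "spiral" | "none"
    true_trace: AttentionTrace
    ie: float
    signed_ie: float
    consistency: float
    latent_evidence: float                 # signed latent strength
    internal_signal: float                 # observer's raw evidence readout
    z_internal: float = np.nan             # z-scored internal_signal
    z_bci: float = np.nan                  # z-scored signed_ie
    report: str | None = None
    confidence: int | None = None
    accuracy: str | None = None            # "correct" | "incorrect"
    introspection_label: str = "n/a"
    late_switch: bool = False              # switch in the last 1.5 s
    boot_seed: int = 0                     # consistency-bootstrap seed

    def validate(self) -> None:
        if self.feedback_type == "deceptive":
            if self.feedback_shown == self.decoded:
                raise ValueError("deceptive trial shows the decoded item")
            if not self.report_requested:
                raise ValueError("deceptive trials must request a report")
        elif self.feedback_type == "informative":
            if self.feedback_shown != self.decoded:
                raise ValueError("informative trial does not show the decoded item")
        elif self.feedback_type == "none":
            if self.feedback_shown != "none":
                raise ValueError("control trial must show no feedback")
        if self.introspection_label != "n/a" and not (
            self.feedback_type == "deceptive" and self.report is not None
        ):
            raise ValueError(
                "introspection label defined off reported deceptive trials"
            )


def _per_block_counts(total: int, n_blocks: int) -> list:
    """Spread ``total`` over blocks as evenly as possible (cumulative
    rounding, deterministic)."""
    cum = np.round(np.arange(1, n_blocks + 1) * total / n_blocks).astype(int)
    return np.diff(np.concatenate(([0], cum))).tolist()


def _shuffled_plans(cfg: ScheduleConfig):
    """Main-phase plans; exact global counts, balanced across blocks."""
    n_dec_f = cfg.n_main_trials * cfg.p_deceptive
    n_dec_total = int(round(n_dec_f))
    if abs(n_dec_f - n_dec_total) > 1e-9:
        raise ValueError(
            f"p_deceptive={cfg.p_deceptive} does not give a whole number of "
            f"deceptive trials in {cfg.n_main_trials}"
        )
    n_inf_total = cfg.n_main_trials - n_dec_total
    n_rep_f = n_inf_total * cfg.report_fraction_informative
    n_rep_total = int(round(n_rep_f))
    if abs(n_rep_f - n_rep_total) > 1e-9:
        raise ValueError(
            f"report_fraction_informative={cfg.report_fraction_informative} "
            f"does not give a whole number of informative report requests"
        )
    rng = np.random.default_rng(cfg.seed)
    plans = []
    n_blocks = cfg.n_main_trials // cfg.block_size
    dec_counts = _per_block_counts(n_dec_total, n_blocks)
    rep_counts = _per_block_counts(n_rep_total, n_blocks)
    for b in range(n_blocks):
        n_dec, n_rep = dec_counts[b], rep_counts[b]
        n_inf = cfg.block_size - n_dec
        kinds = (["deceptive"] * n_dec
                 + ["informative+report"] * n_rep
                 + ["informative"] * (n_inf - n_rep))
        rng.shuffle(kinds)
        for kind in kinds:
            idx = len(plans)
            plans.append(
                TrialPlan(
                    index=idx,
                    phase="main",
                    feedback_type="deceptive" if kind == "deceptive" else "informative",
                    report_requested=kind != "informative",
                    block=b,
                )
            )
    return plans


def build_schedule(cfg: ScheduleConfig):
    """Ordered main-phase trial plans (feedback fixed before decoding)."""
    return _shuffled_plans(cfg)


def build_control_schedule(cfg: ScheduleConfig):
    """No-feedback control block; reports on an exact fraction of trials."""
    n = cfg.n_control_trials
    n_rep_f = n * cfg.control_report_fraction
    n_rep = int(round(n_rep_f))
    if abs(n_rep_f - n_rep) > 1e-9:
        raise ValueError(
            f"control_report_fraction={cfg.control_report_fraction} does not "
            f"give a whole number of report trials"
        )
    rng = np.random.default_rng(cfg.seed + 1)
    flags = np.array([True] * n_rep + [False] * (n - n_rep))
    rng.shuffle(flags)
    return [
        TrialPlan(index=i, phase="control", feedback_type="none",
                  report_requested=bool(flags[i]))
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# closed-loop simulation


def _trial_seeds(session_seed: int, index: int) -> np.ndarray:
    ss = np.random.SeedSequence(entropy=[session_seed, index])
    return ss.generate_state(5)


def _simulate_decision_phase(
    plan: TrialPlan,
    model: BackwardModel,
    gen: EEGGenParams,
    observer: ObserverParams,
    templates: StimulusTemplates,
    session_seed: int,
    trial_duration: float,
    context_duration: float,
    n_boot: int,
):
    seed_latent, seed_trace, seed_noise, seed_internal, seed_boot = (
        int(s) for s in _trial_seeds(session_seed, plan.index)
    )
    rng = np.random.default_rng(seed_latent)
    x = float(rng.standard_normal())
    strength = (gen.strength_scale * abs(x) ** gen.strength_tail
                / mean_abs_normal_power(gen.strength_tail))
    latent = float(np.sign(x) * strength) if x != 0 else strength

    duration = context_duration + trial_duration
    base = sample_attention_trace(
        trial_duration, gen.switch_prob, seed_trace,
        strength=strength,
        initial_state="face" if x >= 0 else "spiral",
    )
    trace = AttentionTrace(
        duration=duration,
        initial_state=base.initial_state,
        switch_times=tuple(t + context_duration for t in base.switch_times),
        strength=strength,
    )

    raw = simulate_trial_eeg(templates, trace, gen, seed_noise)
    proc = preprocess_online(raw, fs_out=model.fs)
    stream = stream_scores(model, proc, templates)
    try:
        decoded = decide(stream)
    except Exception as err:  # pragma: no cover - defensive
        raise RuntimeError(f"decoding failed on trial {plan.index}: {err}") from err
    ie, signed_ie = _metrics.internal_evidence(stream)
    consistency = _metrics.consistency(stream, n_boot=n_boot, seed=seed_boot)

    if plan.feedback_type == "informative":
        shown = decoded
    elif plan.feedback_type == "deceptive":
        shown = _OPPOSITE[decoded]
    else:
        shown = "none"

    internal = trial_internal_signal(trace, observer.internal_noise_sd,
                                     seed_internal)
    late_switch = trace.has_switch_after(duration - 1.5)
    return TrialRecord(
        index=plan.index,
        phase=plan.phase,
        feedback_type=plan.feedback_type,
        report_requested=plan.report_requested,
        decoded=decoded,
        feedback_shown=shown,
        true_trace=trace,
        ie=ie,
        signed_ie=signed_ie,
        consistency=consistency,
        latent_evidence=latent,
        internal_signal=internal,
        late_switch=late_switch,
        boot_seed=seed_boot,
    )


def _zscore(values: np.ndarray) -> np.ndarray:
    sd = values.std(ddof=0)
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def _fill_reports(records, observer, session_seed):
    z_int = _zscore(np.array([r.internal_signal for r in records]))
    z_bci = _zscore(np.array([r.signed_ie for r in records]))
    cue_of = {"face": 1, "spiral": -1, "none": 0}
    for r, zi, zb in zip(records, z_int, z_bci):
        r.z_internal = float(zi)
        r.z_bci = float(zb)
        if not r.report_requested:
            continue
        seed_report = int(_trial_seeds(session_seed, r.index)[4] ^ 0x5EED)
        report, confidence = observe_and_report(
            r.z_internal, cue_of[r.feedback_shown], observer, seed_report
        )
        r.report = report
        r.confidence = confidence
        r.accuracy = _metrics.label_accuracy(report, r.decoded)
        r.introspection_label = _metrics.label_introspection(
            r.feedback_type, r.accuracy
        )
        r.validate()
    return records


def run_session(
    schedule,
    model: BackwardModel,
    gen: EEGGenParams,
    observer: ObserverParams,
    templates: StimulusTemplates | None,
    seed: int,
    trial_duration: float = 5.0,
    context_duration: float = 1.0,
    n_boot: int = 200,
):
    """Simulate one participant's closed-loop session.

    ``context_duration`` seconds of continuing stimulation precede each
    trial (the real stimulus ran across trials), so the score stream
    covers the full 3 s accumulation window before feedback.  Reports
    are filled in a second pass once the participant's internal-evidence
    distribution is available for z-scoring.
    """
    duration = context_duration + trial_duration
    if templates is None or abs(templates.duration - duration) > 1e-9:
        templates = make_templates(fs=model.fs, duration=duration)
    records = [
        _simulate_decision_phase(
            plan, model, gen, observer, templates, seed,
            trial_duration, context_duration, n_boot,
        )
        for plan in schedule
    ]
    return _fill_reports(records, observer, seed)


def run_control_session(
    schedule_control,
    model: BackwardModel,
    gen: EEGGenParams,
    observer: ObserverParams,
    templates: StimulusTemplates | None,
    seed: int,
    **kwargs,
):
    """As :func:`run_session`; plans must be no-feedback control trials."""
    if any(p.feedback_type != "none" for p in schedule_control):
        raise ValueError("control schedule must contain only no-feedback plans")
    return run_session(
        schedule_control, model, gen, observer, templates, seed, **kwargs
    )


def records_to_dataframe(records, participant: int | None = None) -> pd.DataFrame:
    """Tidy one-row-per-trial table (CSV-friendly)."""
    rows = []
    for r in records:
        rows.append(
            {
                "participant": participant,
                "trial": r.index,
                "phase": r.phase,
                "feedback_type": r.feedback_type,
                "report_requested": r.report_requested,
                "decoded": r.decoded,
                "feedback_shown": r.feedback_shown,
                "true_initial_state": r.true_trace.initial_state,
                "true_final_state": r.true_trace.final_state,
                "n_switches": len(r.true_trace.switch_times),
                "late_switch": r.late_switch,
                "attention_strength": r.true_trace.strength,
                "ie": r.ie,
                "signed_ie": r.signed_ie,
                "z_bci": r.z_bci,
                "z_internal": r.z_internal,
                "consistency": r.consistency,
                "boot_seed": r.boot_seed,
                "report": r.report if r.report is not None else "none",
                "confidence": r.confidence if r.confidence is not None else 0,
                "accuracy": r.accuracy if r.accuracy is not None else "none",
                "introspection_label": r.introspection_label,
            }
        )
    df = pd.DataFrame(rows)
    if participant is None:
        df = df.drop(columns=["participant"])
    return df
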