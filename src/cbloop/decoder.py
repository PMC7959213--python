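"""Backward stimulus-reconstruction model.

Training solves a ridge-regularized least-squares mapping from lagged
multichannel EEG to the attended 1-D stimulus template.  Online use
reconstructs a 1-D signal from each 3 s EEG window, correlates it with
the face and spiral templates (one score pair per 250 ms hop), and the
end-of-trial decision averages the last six pairs per item.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from cbloop.preprocess import EEGSegment
from cbloop.stimulus import StimulusTemplates

__all__ = [
    "BackwardModel",
    "ScorePair",
    "ScoreStream",
    "default_lags",
    "build_lagged_design",
    "train_backward_model",
    "solve_ridge",
    "reconstruct",
    "score_window",
    "stream_scores",
    "decide",
    "crossval_accuracy",
    "DEFAULT_WINDOW",
    "DEFAULT_HOP",
    "DEFAULT_N_LAST",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 3.0   # s
DEFAULT_HOP = 0.25     # s
DEFAULT_N_LAST = 6     # score pairs averaged by the decision rule
DEFAULT_RIDGE_GRID = tuple(float(x) for x in np.logspace(-4, 4, 9))


def default_lags(fs: float = 256.0, max_lag: float = 0.5) -> np.ndarray:
    """Lag set 0..max_lag inclusive at the model sampling interval."""
    n = int(round(max_lag * fs))
    return np.arange(n + 1) / fs


@dataclass
class BackwardModel:
    """Lagged linear backward model ``yhat_t = sum_ck w_ck R[t+lag_k, c]``.

    Attributes
    ----------
    weights : np.ndarray
        Shape ``(n_channels, n_lags)``.
    lags : np.ndarray
        Lag values in seconds, sorted ascending; may include negatives.
    ridge_lambda : float
        Relative ridge strength used at training time (scaled by
        ``trace(X'X)/n_features``).
    fs : float
        Model sampling rate (samples/s).
    training_meta : dict
        Free-form provenance (seeds, CV folds, selected lambda, ...).
    """

    weights: np.ndarray
    lags: np.ndarray
    ridge_lambda: float
    fs: float
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.lags = np.asarray(self.lags, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be 2-D (channel x lag)")
        if self.weights.shape[1] != self.lags.shape[0]:
            raise ValueError("weights must have one column per lag")
        if np.any(np.diff(self.lags) <= 0) and self.lags.size > 1:
            raise ValueError("lags must be sorted strictly ascending")
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be >= 0")

    @property
    def n_channels(self) -> int:
        return int(self.weights.shape[0])

    @property
    def n_lags(self) -> int:
        return int(self.weights.shape[1])

    def lag_samples(self) -> np.ndarray:
        return np.round(self.lags * self.fs).astype(int)

    def to_json(self, path) -> None:
        payload = {
            "fs": self.fs,
            "ridge_lambda": self.ridge_lambda,
            "lags_s": self.lags.tolist(),
            "n_channels": self.n_channels,
            "n_lags": self.n_lags,
            "weights_row_major": self.weights.ravel().tolist(),
            "training_meta": self.training_meta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "BackwardModel":
        with open(path) as fh:
            payload = json.load(fh)
        weights = np.asarray(payload["weights_row_major"], dtype=float).reshape(
            payload["n_channels"], payload["n_lags"]
        )
        return cls(
            weights=weights,
            lags=np.asarray(payload["lags_s"], dtype=float),
            ridge_lambda=float(payload["ridge_lambda"]),
            fs=float(payload["fs"]),
            training_meta=payload.get("training_meta", {}),
        )


@dataclass(frozen=True)
class ScorePair:
    """Pearson correlations of the reconstruction with each template."""

    c_face: float
    c_spiral: float
    window_end: float  # seconds from segment start

    def __post_init__(self) -> None:
        for name in ("c_face", "c_spiral"):
            v = getattr(self, name)
            if not np.isfinite(v) or abs(v) > 1 + 1e-9:
                raise ValueError(f"{name}={v} is not a valid correlation")


@dataclass
class ScoreStream:
    """Time-ordered correlation score pairs for one trial."""

    pairs: list
    hop: float = DEFAULT_HOP
    window: float = DEFAULT_WINDOW

    def __len__(self) -> int:
        return len(self.pairs)

    def face_scores(self) -> np.ndarray:
        return np.array([p.c_face for p in self.pairs])

    def spiral_scores(self) -> np.ndarray:
        return np.array([p.c_spiral for p in self.pairs])

    def differences(self) -> np.ndarray:
        """Per-window c_face - c_spiral."""
        return self.face_scores() - self.spiral_scores()


# ---------------------------------------------------------------------------
# design matrices and training


def _valid_range(n_samples: int, lag_samples: np.ndarray) -> tuple[int, int]:
    """Rows t for which R[t+lag] exists for every lag -> [t0, t1)."""
    t0 = int(max(0, -lag_samples.min()))
    t1 = int(n_samples - max(0, lag_samples.max()))
    if t1 <= t0:
        raise ValueError(
            f"segment of {n_samples} samples is shorter than the lag span"
        )
    return t0, t1


def build_lagged_design(
    data: np.ndarray, lag_samples: np.ndarray
) -> tuple[np.ndarray, int]:
    """Lagged design matrix with channel-major feature order.

    Column ``c * n_lags + k`` holds ``data[t + lag_k, c]``.  Returns the
    matrix and the first valid stimulus-time index ``t0``.
    """
    n, n_ch = data.shape
    t0, t1 = _valid_range(n, lag_samples)
    rows = t1 - t0
    n_lags = lag_samples.size
    X3 = np.empty((rows, n_ch, n_lags), dtype=float)
    for k, lag in enumerate(lag_samples):
        X3[:, :, k] = data[t0 + lag : t0 + lag + rows]
    return X3.reshape(rows, n_ch * n_lags), t0


def solve_ridge(
    gram: np.ndarray, xty: np.ndarray, ridge_lambda: float
) -> np.ndarray:
    """Solve ``(X'X + lambda_eff I) w = X'y``.

    ``lambda_eff = ridge_lambda * trace(X'X) / n_features`` so the
    regularization strength is invariant to data duplication and to the
    overall data scale.
    """
    n_feat = gram.shape[0]
    lam_eff = ridge_lambda * np.trace(gram) / n_feat
    a = gram if lam_eff == 0 else gram + lam_eff * np.eye(n_feat)
    try:
        return np.linalg.solve(a, xty)
    except np.linalg.LinAlgError as err:
        if ridge_lambda == 0:
            raise np.linalg.LinAlgError(
                "singular design with ridge_lambda=0; "
                "set ridge_lambda > 0 to regularize"
            ) from err
        raise


def _trial_designs(trials, templates, lag_samples):
    """Per-trial (X, y, gram, xty) at the model sampling rate."""
    designs = []
    for seg, label in trials:
        if abs(seg.fs - templates.fs) > 1e-9:
            raise ValueError(
                f"trial at {seg.fs} Hz does not match template rate {templates.fs}"
            )
        if seg.n_samples > templates.n_samples:
            raise ValueError("trial longer than the stimulus templates")
        X, t0 = build_lagged_design(seg.data, lag_samples)
        y = templates.template(label)[t0 : t0 + X.shape[0]]
        designs.append((X, y, X.T @ X, X.T @ y))
    return designs


def train_backward_model(
    trials,
    templates: StimulusTemplates,
    lags: np.ndarray | None = None,
    ridge_lambda: float = 1e-2,
    training_meta: dict | None = None,
) -> BackwardModel:
    """Fit the backward model on labeled, preprocessed trials.

    Parameters
    ----------
    trials : sequence of (EEGSegment, str)
        Preprocessed segments at the template sampling rate, each
        labeled ``"face"`` or ``"spiral"``.
    templates : StimulusTemplates
        The attended-template source; face trials regress onto
        ``y_face``, spiral trials onto ``y_spiral``.
    lags : array of float, optional
        Lag set in seconds (default 0..0.5 s at the model interval).
    ridge_lambda : float
        Relative ridge strength (see :func:`solve_ridge`).
    """
    labels = [label for _, label in trials]
    for lab in ("face", "spiral"):
        if labels.count(lab) < 2:
            raise ValueError(f"need at least 2 trials per label, {lab} has "
                             f"{labels.count(lab)}")
    fs = templates.fs
    if lags is None:
        lags = default_lags(fs)
    lags = np.asarray(lags, dtype=float)
    lag_samples = np.round(lags * fs).astype(int)
    designs = _trial_designs(trials, templates, lag_samples)
    gram = sum(d[2] for d in designs)
    xty = sum(d[3] for d in designs)
    w = solve_ridge(gram, xty, ridge_lambda)
    meta = dict(training_meta or {})
    meta.setdefault("n_trials", len(trials))
    return BackwardModel(
        weights=w.reshape(len(trials[0][0].channel_names), lags.size),
        lags=lags,
        ridge_lambda=float(ridge_lambda),
        fs=float(fs),
        training_meta=meta,
    )


# ---------------------------------------------------------------------------
# reconstruction and scoring


def reconstruct(model: BackwardModel, seg: EEGSegment) -> tuple[np.ndarray, int]:
    """Reconstruct the 1-D stimulus estimate from an EEG segment.

    Returns ``(yhat, t0)`` where ``yhat[i]`` estimates the stimulus at
    sample ``t0 + i`` of the segment; only samples for which every lag
    is inside the segment are produced (no zero padding).
    """
    if abs(seg.fs - model.fs) > 1e-9:
        raise ValueError(f"segment rate {seg.fs} != model rate {model.fs}")
    if seg.n_channels != model.n_channels:
        raise ValueError("channel count mismatch between segment and model")
    lag_samples = model.lag_samples()
    t0, t1 = _valid_range(seg.n_samples, lag_samples)
    rows = t1 - t0
    # lag-wise matvec accumulation avoids materializing the design matrix
    yhat = np.zeros(rows)
    for k, lag in enumerate(lag_samples):
        yhat += seg.data[t0 + lag : t0 + lag + rows] @ model.weights[:, k]
    return yhat, t0


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def _score_from_yhat(yhat, y_face, y_spiral, window_end):
    c_face = _pearson(yhat, y_face)
    c_spiral = _pearson(yhat, y_spiral)
    if np.isnan(c_face) or np.isnan(c_spiral):
        logger.warning(
            "zero-variance reconstruction at window_end=%.2f s; scores set to 0",
            window_end,
        )
        c_face = 0.0 if np.isnan(c_face) else c_face
        c_spiral = 0.0 if np.isnan(c_spiral) else c_spiral
    return ScorePair(c_face=c_face, c_spiral=c_spiral, window_end=window_end)


def score_window(
    model: BackwardModel,
    seg_window: EEGSegment,
    templates: StimulusTemplates,
    window_start_sample: int = 0,
    window: float = DEFAULT_WINDOW,
) -> ScorePair:
    """Score one analysis window against both templates.

    ``seg_window`` must be exactly ``window`` seconds long.
    ``window_start_sample`` locates the window within the template
    timeline so reconstruction and templates stay phase aligned.
    """
    expected = int(round(window * model.fs))
    if seg_window.n_samples != expected:
        raise ValueError(
            f"window must be exactly {expected} samples, got {seg_window.n_samples}"
        )
    yhat, t0 = reconstruct(model, seg_window)
    lo = window_start_sample + t0
    hi = lo + yhat.size
    if hi > templates.n_samples:
        raise ValueError("window extends past the stimulus templates")
    end = (window_start_sample + seg_window.n_samples) / model.fs
    return _score_from_yhat(
        yhat, templates.y_face[lo:hi], templates.y_spiral[lo:hi], end
    )


def stream_scores(
    model: BackwardModel,
    trial_seg: EEGSegment,
    templates: StimulusTemplates,
    window: float = DEFAULT_WINDOW,
    hop: float = DEFAULT_HOP,
) -> ScoreStream:
    """One score pair per ``hop`` over trailing ``window``-long segments.

    Equivalent to calling :func:`score_window` at every window position;
    the reconstruction is computed once for the whole trial because the
    per-sample formula is identical either way.
    """
    if trial_seg.duration + 1e-9 < window:
        raise ValueError("trial shorter than one analysis window")
    fs = model.fs
    win_n = int(round(window * fs))
    hop_n = int(round(hop * fs))
    yhat, t0 = reconstruct(model, trial_seg)
    lag_hi = max(0, int(model.lag_samples().max()))
    pairs = []
    for end_n in range(win_n, trial_seg.n_samples + 1, hop_n):
        start_n = end_n - win_n
        # valid reconstruction samples for this window
        lo = start_n + t0
        hi = end_n - lag_hi
        y_seg = yhat[lo - t0 : hi - t0]
        pairs.append(
            _score_from_yhat(
                y_seg,
                templates.y_face[lo:hi],
                templates.y_spiral[lo:hi],
                end_n / fs,
            )
        )
    return ScoreStream(pairs=pairs, hop=hop, window=window)


def decide(stream: ScoreStream, n_last: int = DEFAULT_N_LAST) -> str:
    """Average the last ``n_last`` score pairs per item; higher wins.

    Exact ties resolve to ``"face"`` and are logged.
    """
    if len(stream) < n_last:
        raise ValueError(
            f"stream has {len(stream)} pairs, decision needs {n_last}"
        )
    mean_face = stream.face_scores()[-n_last:].mean()
    mean_spiral = stream.spiral_scores()[-n_last:].mean()
    if mean_face == mean_spiral:
        logger.info("decision tie (%.6f); resolved to face", mean_face)
        return "face"
    return "face" if mean_face > mean_spiral else "spiral"


# ---------------------------------------------------------------------------
# cross-validation


def _decide_trial(w, design_X, t0, seg, templates, window, hop, n_last, fs,
                  lag_hi):
    """decide() for one trial given precomputed lagged design."""
    yhat = design_X @ w
    win_n = int(round(window * fs))
    hop_n = int(round(hop * fs))
    pairs = []
    for end_n in range(win_n, seg.n_samples + 1, hop_n):
        lo = (end_n - win_n) + t0
        hi = end_n - lag_hi
        pairs.append(
            _score_from_yhat(
                yhat[lo - t0 : hi - t0],
                templates.y_face[lo:hi],
                templates.y_spiral[lo:hi],
                end_n / fs,
            )
        )
    return decide(ScoreStream(pairs=pairs, hop=hop, window=window), n_last)


def crossval_accuracy(
    trials,
    templates: StimulusTemplates,
    lags: np.ndarray | None = None,
    ridge_grid=DEFAULT_RIDGE_GRID,
    folds: int | None = None,
    inner_folds: int = 5,
    window: float = DEFAULT_WINDOW,
    hop: float = DEFAULT_HOP,
    n_last: int = DEFAULT_N_LAST,
) -> float:
    """Cross-validated accuracy of the full decision rule.

    Outer loop is leave-one-trial-out by default (``folds=None``); with
    ``folds=k`` a contiguous k-fold split is used.  When ``ridge_grid``
    has more than one value, lambda is selected per outer fold on inner
    folds of the outer-training trials.  Deterministic.
    """
    n = len(trials)
    labels = [label for _, label in trials]
    counts = {lab: labels.count(lab) for lab in set(labels)}
    if min(counts.values()) < 2:
        raise ValueError("need at least 2 trials per label")
    fs = templates.fs
    if lags is None:
        lags = default_lags(fs)
    lags = np.asarray(lags, dtype=float)
    lag_samples = np.round(lags * fs).astype(int)
    lag_hi = max(0, int(lag_samples.max()))
    designs = _trial_designs(trials, templates, lag_samples)
    gram_total = sum(d[2] for d in designs)
    xty_total = sum(d[3] for d in designs)
    ridge_grid = [float(g) for g in np.atleast_1d(ridge_grid)]

    if folds is None:
        fold_indices = [[i] for i in range(n)]
    else:
        if folds > n:
            raise ValueError(f"cannot make {folds} folds from {n} trials")
        fold_indices = [list(chunk) for chunk in np.array_split(np.arange(n), folds)]

    def fit_on(indices, lam):
        # per-subset normal equations by subtracting held-out trials
        if len(indices) == n:
            gram, xty = gram_total, xty_total
        else:
            excluded = set(range(n)) - set(indices)
            gram = gram_total - sum(designs[i][2] for i in excluded)
            xty = xty_total - sum(designs[i][3] for i in excluded)
        return solve_ridge(gram, xty, lam)

    hits = 0
    for fold in fold_indices:
        train_idx = [i for i in range(n) if i not in fold]
        if len(ridge_grid) > 1:
            lam = _select_lambda(
                train_idx, ridge_grid, designs, trials, templates,
                inner_folds=inner_folds, window=window, hop=hop,
                n_last=n_last, fs=fs, lag_samples=lag_samples,
                lag_hi=lag_hi,
            )
        else:
            lam = ridge_grid[0]
        w = fit_on(train_idx, lam)
        for i in fold:
            X, _, _, _ = designs[i]
            seg, label = trials[i]
            t0 = _valid_range(seg.n_samples, lag_samples)[0]
            pred = _decide_trial(
                w, X, t0, seg, templates, window, hop, n_last, fs, lag_hi
            )
            hits += pred == label
    return hits / n


def _select_lambda(
    train_idx, ridge_grid, designs, trials, templates,
    inner_folds, window, hop, n_last, fs, lag_samples, lag_hi,
):
    """Pick lambda by k-fold accuracy within the outer-training trials."""
    train_idx = list(train_idx)
    k = min(inner_folds, len(train_idx))
    chunks = [list(c) for c in np.array_split(np.array(train_idx), k)]
    gram_train = sum(designs[i][2] for i in train_idx)
    xty_train = sum(designs[i][3] for i in train_idx)
    best_lam, best_acc = None, -1.0
    for lam in ridge_grid:
        hits, total = 0, 0
        for chunk in chunks:
            gram = gram_train - sum(designs[i][2] for i in chunk)
            xty = xty_train - sum(designs[i][3] for i in chunk)
            try:
                w = solve_ridge(gram, xty, lam)
            except np.linalg.LinAlgError:
                hits = -1
                break
            for i in chunk:
                X, _, _, _ = designs[i]
                seg, label = trials[i]
                t0 = _valid_range(seg.n_samples, lag_samples)[0]
                pred = _decide_trial(
                    w, X, t0, seg, templates, window, hop, n_last, fs, lag_hi
                )
                hits += pred == label
                total += 1
        acc = hits / max(total, 1) if hits >= 0 else -1.0
        if acc > best_acc:
            best_acc, best_lam = acc, lam
    return best_lam
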