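"""Descriptive summaries and a fixed-effects logistic regression.

All headline tables aggregate trials to participant-level means first,
then average across participants with a bootstrap confidence interval
obtained by resampling participants with replacement (1000 iterations,
seeded).  The logistic model regresses report correctness on
within-participant standardized internal evidence and the feedback type
with plain (fixed-effects) IRLS; the tidy per-trial table lets users
refit mixed models externally.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "quartile_bin",
    "confidence_split",
    "normalize_confidence",
    "participant_bootstrap_ci",
    "summarize",
    "headline_tables",
    "fit_logistic_accuracy",
]

logger = logging.getLogger(__name__)

DEFAULT_N_BOOT = 1000


def quartile_bin(values) -> np.ndarray:
    """Within-participant quartile labels 1-4 by empirical percentile.

    Ties are broken by stable rank order; a fully degenerate vector
    (all values equal) maps to quartile 1 with a warning.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 4:
        raise ValueError(f"need at least 4 values to form quartiles, got {n}")
    if np.all(values == values[0]):
        logger.warning("all %d values identical; assigning quartile 1", n)
        return np.ones(n, dtype=int)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    return (ranks * 4) // n + 1


def confidence_split(confidence) -> np.ndarray | str:
    """Median split of the 4-point scale: {1,2} -> Low, {3,4} -> High."""
    scalar = np.isscalar(confidence)
    conf = np.atleast_1d(np.asarray(confidence, dtype=int))
    if np.any((conf < 1) | (conf > 4)):
        bad = conf[(conf < 1) | (conf > 4)][0]
        raise ValueError(f"confidence must be in 1..4, got {bad}")
    out = np.where(conf <= 2, "Low", "High")
    return out.item() if scalar else out


def normalize_confidence(df: pd.DataFrame, participant_col: str = "participant",
                         confidence_col: str = "confidence") -> pd.Series:
    """Per-participant mean-centered confidence ratings."""
    conf = df[confidence_col].astype(float)
    return conf - conf.groupby(df[participant_col]).transform("mean")


def participant_bootstrap_ci(
    participant_means: np.ndarray,
    n_boot: int = DEFAULT_N_BOOT,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile CI of the across-participant mean (resampled participants)."""
    means = np.asarray(participant_means, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, means.size, size=(n_boot, means.size))
    boot = means[idx].mean(axis=1)
    alpha = (1 - level) / 2
    return (
        float(np.quantile(boot, alpha)),
        float(np.quantile(boot, 1 - alpha)),
    )


def _accuracy_numeric(df: pd.DataFrame) -> pd.Series:
    if "accuracy_num" in df:
        return df["accuracy_num"].astype(float)
    return (df["accuracy"] == "correct").astype(float)


def summarize(
    df: pd.DataFrame,
    keys,
    value: str = "accuracy",
    n_boot: int = DEFAULT_N_BOOT,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Across-participant summary of a trial-level quantity.

    Trials are first averaged within participant for every combination
    of ``keys``; the table reports the across-participant mean with a
    participant-resampling bootstrap CI per cell.  Cells with no trials
    appear with ``n_trials=0`` and NaN statistics.
    """
    keys = list(keys)
    data = df.copy()
    if value == "accuracy":
        data["_value"] = _accuracy_numeric(data)
    else:
        data["_value"] = data[value].astype(float)
    data = data[data["report_requested"] & (data["report"] != "none")]
    if data.empty:
        raise ValueError("no reported trials to summarize")

    per_part = (
        data.groupby(["participant"] + keys, observed=True)["_value"]
        .agg(["mean", "size"])
        .reset_index()
    )
    rows = []
    cells = (
        per_part.groupby(keys, observed=True) if keys
        else [((), per_part)]
    )
    for cell_key, cell in cells:
        if not isinstance(cell_key, tuple):
            cell_key = (cell_key,)
        means = cell["mean"].to_numpy()
        lo, hi = participant_bootstrap_ci(means, n_boot=n_boot, level=level,
                                          seed=seed)
        rows.append(
            dict(zip(keys, cell_key))
            | {
                "mean": float(means.mean()),
                "ci_lo": lo,
                "ci_hi": hi,
                "n_participants": int(cell.shape[0]),
                "n_trials": int(cell["size"].sum()),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(keys).reset_index(drop=True) if keys else out


def _with_derived_columns(df: pd.DataFrame) -> pd.DataFrame:
    data = df.copy()
    data["accuracy_num"] = _accuracy_numeric(data)
    reported = data["report_requested"] & (data["report"] != "none")
    data.loc[reported, "confidence_level"] = confidence_split(
        data.loc[reported, "confidence"].to_numpy()
    )
    data["ie_quartile"] = 0
    for _, idx in data.groupby("participant").groups.items():
        data.loc[idx, "ie_quartile"] = quartile_bin(data.loc[idx, "ie"].to_numpy())
    return data


def headline_tables(
    df: pd.DataFrame,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> dict:
    """The four summary tables of the standard report.

    Keys: ``accuracy_by_feedback``, ``accuracy_by_feedback_confidence``,
    ``accuracy_by_ie_quartile``, ``consistency_deceptive`` (consistency
    by accuracy x confidence level, deceptive trials only).
    """
    data = _with_derived_columns(df)
    main = data[data["phase"].isin(["main", "control"])]
    tables = {
        "accuracy_by_feedback": summarize(
            main, ["feedback_type"], n_boot=n_boot, seed=seed
        ),
        "accuracy_by_feedback_confidence": summarize(
            main[main["phase"] == "main"],
            ["feedback_type", "confidence_level"],
            n_boot=n_boot, seed=seed,
        ),
        "accuracy_by_ie_quartile": summarize(
            main[main["phase"] == "main"], ["ie_quartile"],
            n_boot=n_boot, seed=seed,
        ),
        "consistency_deceptive": summarize(
            main[(main["feedback_type"] == "deceptive")],
            ["accuracy", "confidence_level"],
            value="consistency", n_boot=n_boot, seed=seed,
        ),
    }
    return tables


# ---------------------------------------------------------------------------
# fixed-effects logistic regression (IRLS)


def _irls(X: np.ndarray, y: np.ndarray, ridge: float = 0.0,
          tol: float = 1e-8, max_iter: int = 100):
    beta = np.zeros(X.shape[1])
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-10)
        z = eta + (y - mu) / w
        a = X.T @ (w[:, None] * X)
        if ridge > 0:
            a = a + ridge * np.eye(X.shape[1])
        new_beta = np.linalg.solve(a, X.T @ (w * z))
        if np.max(np.abs(new_beta - beta)) < tol:
            beta = new_beta
            converged = True
            break
        beta = new_beta
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    info = X.T @ (w[:, None] * X)
    if ridge > 0:
        info = info + ridge * np.eye(X.shape[1])
    cov = np.linalg.inv(info)
    return beta, cov, converged


def fit_logistic_accuracy(
    df: pd.DataFrame,
    predictors: tuple = ("ie_std", "feedback_informative"),
    ci_level: float = 0.95,
) -> dict:
    """Fixed-effects logistic regression of correctness.

    Internal evidence is standardized within participant; feedback is
    coded 1 for informative, 0 for deceptive.  Separation (diverging
    coefficients or IRLS non-convergence) triggers a ridge fallback,
    flagged in the result.
    """
    from scipy.stats import norm

    data = df[df["report_requested"] & (df["report"] != "none")].copy()
    data = data[data["feedback_type"].isin(["informative", "deceptive"])]
    if data["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    if data["feedback_type"].nunique() < 2:
        raise ValueError("need both feedback types")

    grp = data.groupby("participant")["ie"]
    mean = grp.transform("mean")
    sd = grp.transform("std").replace(0.0, 1.0).fillna(1.0)
    data["ie_std"] = (data["ie"] - mean) / sd
    data["feedback_informative"] = (
        data["feedback_type"] == "informative"
    ).astype(float)

    y = _accuracy_numeric(data).to_numpy()
    X = np.column_stack(
        [np.ones(len(data))] + [data[p].to_numpy(dtype=float) for p in predictors]
    )
    beta, cov, converged = _irls(X, y)
    separated = (not converged) or np.any(np.abs(beta) > 15)
    if separated:
        logger.warning("possible separation; refitting with ridge penalty")
        beta, cov, converged = _irls(X, y, ridge=1e-4 * len(y))

    se = np.sqrt(np.diag(cov))
    zq = norm.ppf(0.5 + ci_level / 2)
    names = ["intercept"] + list(predictors)
    result = {"separation_flag": bool(separated), "converged": bool(converged),
              "n_trials": int(len(y)), "coefficients": {}}
    for i, name in enumerate(names):
        result["coefficients"][name] = {
            "beta": float(beta[i]),
            "se": float(se[i]),
            "odds_ratio": float(np.exp(beta[i])),
            "or_ci": [float(np.exp(beta[i] - zq * se[i])),
                      float(np.exp(beta[i] + zq * se[i]))],
        }
    return result
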