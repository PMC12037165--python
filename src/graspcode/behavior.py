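"""Behavioral statistics and force-signal / component correlations.

Reaction time (go cue to movement onset) and movement time (movement onset
to object touch) are summarized per subject and compared across subjects
with a rank-sum test. The pulling-force trace of each trial is
cross-correlated with its demixed-component projection to ask whether
population components track the physically exerted force.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

__all__ = ["behavior_summary", "force_dpc_correlation", "ForceDpcCorrelation"]


def behavior_summary(trials: pd.DataFrame) -> dict:
    """Per-subject RT/MT mean +- SD and a between-subject rank-sum test.

    Expects correct trials with a ``subject`` column. With exactly two
    subjects, reports the Mann-Whitney/Wilcoxon rank-sum z statistic and
    two-sided p for RT and MT (first subject minus second, normal
    approximation).
    """
    t = trials.loc[trials["correct"]].copy()
    t["rt"] = t["movement_on"] - t["go"]
    t["mt"] = t["touch"] - t["movement_on"]
    if (t["rt"] <= 0).any() or (t["mt"] <= 0).any():
        raise ValueError("nonpositive RT or MT on a correct trial")
    per = t.groupby("subject").agg(
        n=("rt", "size"),
        rt_mean=("rt", "mean"), rt_sd=("rt", "std"),
        mt_mean=("mt", "mean"), mt_sd=("mt", "std"),
    )
    if (per["n"] < 2).any():
        raise ValueError("need >=2 correct trials per subject")
    out = {"per_subject": per}
    subjects = list(per.index)
    if len(subjects) == 2:
        a, b = subjects
        for name in ("rt", "mt"):
            res = stats.ranksums(t.loc[t.subject == a, name], t.loc[t.subject == b, name])
            out[f"{name}_z"] = float(res.statistic)
            out[f"{name}_p"] = float(res.pvalue)
    return out


@dataclass
class ForceDpcCorrelation:
    """Trialwise force/component coupling and its group structure."""

    r2: pd.DataFrame  # columns: trial, dpc_type, force, r2, significant
    proportions: dict[str, float]  # fraction of significant trials per dPC type
    anova: pd.DataFrame  # two-way ANOVA: dpc_type x force level on r2


def _norm_xcorr_max(X: np.ndarray, y: np.ndarray, max_lag: int) -> np.ndarray:
    """max over lags of the squared Pearson r between rows of X and y.

    ``X`` is (m, n) — one row per trace variant (observed or circularly
    shifted null) — and ``y`` a single (n,) trace; returns (m,).
    """
    X = np.atleast_2d(X)
    n = X.shape[1]
    best = np.zeros(X.shape[0])
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            Xa, ya = X[:, : n - lag], y[lag:]
        else:
            Xa, ya = X[:, -lag:], y[: n + lag]
        if Xa.shape[1] < 3:
            continue
        Xc = Xa - Xa.mean(axis=1, keepdims=True)
        yc = ya - ya.mean()
        den = np.sqrt((Xc ** 2).sum(axis=1) * (yc ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(den > 0, Xc @ yc / den, 0.0)
        best = np.maximum(best, r * r)
    return best


def force_dpc_correlation(force_traces: np.ndarray, dpc_traces: dict[str, np.ndarray],
                          force_labels: np.ndarray, step_ms: float = 20.0,
                          max_lag_ms: float = 500.0, n_null: int = 200,
                          conf: float = 0.99,
                          rng: np.random.Generator | int | None = None) -> ForceDpcCorrelation:
    """Cross-correlate each trial's force trace with its component traces.

    ``dpc_traces`` maps a component family name (e.g. "time", "force") to a
    (trials, bins) array of single-trial projections on the same clock as
    ``force_traces``. The statistic per trial is max |r|^2 over lags up to
    ``max_lag_ms``; its null comes from random circular time-shifts of the
    force trace (preserving autocorrelation), and a trial is significant
    when the observed value exceeds the ``conf`` quantile of its null. A
    two-way ANOVA asks whether r2 differs across component families and
    force levels.
    """
    rng = np.random.default_rng(rng)
    F = np.asarray(force_traces, float)
    max_lag = int(round(max_lag_ms / step_ms))
    rows = []
    for name, P in dpc_traces.items():
        P = np.asarray(P, float)
        if P.shape != F.shape:
            raise ValueError(f"dpc_traces[{name!r}] grid mismatch: {P.shape} vs {F.shape}")
        for i in range(F.shape[0]):
            f = F[i]
            peak = np.max(np.abs(f))
            fn = f / peak if peak > 0 else f
            obs = float(_norm_xcorr_max(fn, P[i], max_lag)[0])
            shifts = rng.integers(1, len(fn), n_null)
            shifted = fn[(np.arange(len(fn))[None, :] - shifts[:, None]) % len(fn)]
            null = _norm_xcorr_max(shifted, P[i], max_lag)
            rows.append({"trial": i, "dpc_type": name,
                         "force": str(force_labels[i]), "r2": obs,
                         "significant": bool(obs > np.quantile(null, conf))})
    df = pd.DataFrame(rows)
    props = df.groupby("dpc_type")["significant"].mean().to_dict()
    terms = [f"C({f})" for f in ("dpc_type", "force") if df[f].nunique() > 1]
    if terms:
        formula = "r2 ~ " + (" * ".join(terms) if len(terms) > 1 else terms[0])
        anova = sm.stats.anova_lm(ols(formula, data=df).fit(), typ=2)
    else:
        anova = pd.DataFrame()
    return ForceDpcCorrelation(df, props, anova)
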