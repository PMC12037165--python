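"""Single-unit selectivity: time-resolved auROC, permutation significance,
selectivity classes, and the grip/force independence battery.

auROC(t) compares the firing-rate distributions of the two levels of one
task parameter (side vs precision grip; low vs high force) at each time
bin: 0.5 means indistinguishable, 0 or 1 perfect separation with opposite
preference. dauROC = |auROC - 0.5| is the direction-free modulation
strength. A unit "encodes" a parameter when its pointwise permutation
p-value is below alpha for at least two consecutive bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AurocResult",
    "auroc_timecourse",
    "permutation_mask",
    "classify_selectivity",
    "marginal_independence_test",
    "ellipse_angle",
    "strength_correlation",
    "cross_temporal_correlation",
    "runs_mask",
]


def runs_mask(sig: np.ndarray, min_consec: int = 2, axis: int = -1) -> np.ndarray:
    """Keep only runs of >= min_consec consecutive True along ``axis``."""
    sig = np.asarray(sig, dtype=bool)
    sig = np.moveaxis(sig, axis, -1)
    out = np.zeros_like(sig)
    # run-length via padded diff of the flattened last axis, row by row
    flat = sig.reshape(-1, sig.shape[-1])
    oflat = out.reshape(-1, sig.shape[-1])
    for r in range(flat.shape[0]):
        row = flat[r]
        if not row.any():
            continue
        padded = np.concatenate(([False], row, [False]))
        starts = np.flatnonzero(padded[1:] & ~padded[:-1])
        ends = np.flatnonzero(~padded[1:] & padded[:-1])
        for s, e in zip(starts, ends):
            if e - s >= min_consec:
                oflat[r, s:e] = True
    return np.moveaxis(out, -1, axis)


def auroc_timecourse(rates: np.ndarray, positive: np.ndarray) -> np.ndarray:
    """auROC per unit and time bin (Mann-Whitney formulation).

    ``rates``: (units, trials, bins); ``positive``: boolean (trials,)
    marking the class treated as "greater". Returns (units, bins) values of
    P(rate_pos > rate_neg) + 0.5 * P(tie) over all trial pairs; ties get
    half weight via midranks.
    """
    rates = np.asarray(rates, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError(f"need >=2 trials per class, got {n_pos} and {n_neg}")
    if np.isnan(rates).any():
        raise ValueError("rates contain NaN (missing bins); restrict the window")
    ranks = stats.rankdata(rates, axis=1)  # midranks handle ties
    r_pos = ranks[:, positive, :].sum(axis=1)
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def _null_aurocs(ranks_flat: np.ndarray, positive: np.ndarray, n_perm: int,
                 rng: np.random.Generator, chunk: int = 256):
    """Yield chunks of label-permuted auROC values.

    Ranks are label-free, so a permutation's auROC is just a different
    subset sum of the precomputed midranks — one matmul per chunk.
    """
    n_trials = len(positive)
    n_pos = int(positive.sum())
    n_neg = n_trials - n_pos
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        z = np.zeros((n_trials, m))
        for j in range(m):
            z[rng.permutation(n_trials)[:n_pos], j] = 1.0
        u = ranks_flat @ z - n_pos * (n_pos + 1) / 2.0
        yield u / (n_pos * n_neg)  # (units*bins, m)
        done += m


@dataclass
class AurocResult:
    """Time-resolved selectivity of every unit for one task parameter."""

    auroc: np.ndarray  # (units, bins)
    delta: np.ndarray  # |auroc - 0.5|
    pvalues: np.ndarray
    mask: np.ndarray  # significant runs of >= min_consec bins
    bin_centers: np.ndarray

    @property
    def encodes(self) -> np.ndarray:
        """Per unit: does any significant run exist?"""
        return self.mask.any(axis=1)


def permutation_mask(rates: np.ndarray, positive: np.ndarray, bin_centers: np.ndarray,
                     n_perm: int = 5000, alpha: float = 0.001, min_consec: int = 2,
                     rng: np.random.Generator | int | None = None) -> AurocResult:
    """auROC time courses with pointwise label-permutation significance.

    Two-sided p-values from the |auROC - 0.5| null under label exchange;
    the significance mask keeps runs of >= ``min_consec`` bins with
    p < ``alpha``.
    """
    if n_perm < 1.0 / alpha:
        raise ValueError(f"n_perm={n_perm} cannot resolve alpha={alpha}; need >= {int(1/alpha)}")
    rng = np.random.default_rng(rng)
    rates = np.asarray(rates, dtype=float)
    n_units, n_trials, n_bins = rates.shape
    obs = auroc_timecourse(rates, positive)
    obs_delta = np.abs(obs - 0.5)

    ranks_flat = stats.rankdata(rates, axis=1).transpose(0, 2, 1).reshape(-1, n_trials)
    exceed = np.zeros(n_units * n_bins)
    for null in _null_aurocs(ranks_flat, np.asarray(positive, bool), n_perm, rng):
        exceed += (np.abs(null - 0.5) >= obs_delta.reshape(-1, 1) - 1e-12).sum(axis=1)
    pvals = ((exceed + 1.0) / (n_perm + 1.0)).reshape(n_units, n_bins)
    mask = runs_mask(pvals < alpha, min_consec=min_consec, axis=1)
    return AurocResult(obs, obs_delta, pvals, mask, np.asarray(bin_centers))


def classify_selectivity(grip: AurocResult, force: AurocResult):
    """Label each unit grip_only / force_only / mixed / none.

    A unit is selective for a parameter iff its significance mask has at
    least one run; "mixed" means both masks are nonempty.
    """
    g, f = grip.encodes, force.encodes
    labels = np.where(g & f, "mixed",
                      np.where(g, "grip_only", np.where(f, "force_only", "none")))
    counts = {c: int((labels == c).sum()) for c in ("grip_only", "force_only", "mixed", "none")}
    return labels, counts


def marginal_independence_test(auroc_grip: np.ndarray, auroc_force: np.ndarray,
                               n_bins_hist: int = 10, n_perm: int = 1000,
                               rng: np.random.Generator | int | None = None):
    """Permuted chi-square test of marginal independence at one time bin.

    The observed 2D histogram of (force, grip) auROC pairs across units is
    compared with the product of its 1D marginals; the null distribution
    comes from permuting the force values across units. An angle-free
    complement to :func:`ellipse_angle`.
    """
    rng = np.random.default_rng(rng)
    g = np.asarray(auroc_grip, float)
    f = np.asarray(auroc_force, float)
    if g.shape != f.shape or g.ndim != 1:
        raise ValueError("auroc_grip and auroc_force must be 1D of equal length")
    if len(g) < 20:
        raise ValueError(f"need >=20 units for the marginal test, got {len(g)}")
    edges = np.linspace(0.0, 1.0, n_bins_hist + 1)

    def chi2_of(fv: np.ndarray) -> float:
        obs, _, _ = np.histogram2d(fv, g, bins=[edges, edges])
        pf = obs.sum(axis=1) / obs.sum()
        pg = obs.sum(axis=0) / obs.sum()
        exp = obs.sum() * np.outer(pf, pg)
        m = exp > 0
        return float(((obs[m] - exp[m]) ** 2 / exp[m]).sum())

    first, _, _ = np.histogram2d(f, g, bins=[edges, edges])
    if (first > 0).sum() <= 1:
        raise ValueError("degenerate histogram: all auROC mass in a single cell")
    observed = chi2_of(f)
    null = np.array([chi2_of(rng.permutation(f)) for _ in range(n_perm)])
    p = float((np.sum(null >= observed - 1e-12) + 1) / (n_perm + 1))
    return observed, p, null


def ellipse_angle(points: np.ndarray, conf: float = 0.95):
    """Orientation and 95% ellipse of a 2D (force, grip) auROC scatter.

    Returns ``(theta_deg, semi_axes, center)``: theta is the angle of the
    principal eigenvector of the sample covariance, measured from the
    force (x) axis, in [0, 180); an angle near 90 deg signals that grip
    modulation varies without any covarying force modulation, i.e.
    independence of the two codes.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >=3 points of shape (n, 2)")
    cov = np.cov(pts.T)
    if not np.all(np.isfinite(cov)) or np.allclose(cov, 0):
        raise ValueError("degenerate covariance: points carry no variance")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] <= 0:
        raise ValueError("singular covariance with no principal direction")
    vx, vy = evecs[0, 0], evecs[1, 0]
    theta = np.degrees(np.arctan2(vy, vx)) % 180.0
    scale = stats.chi2.ppf(conf, df=2)
    semi_axes = np.sqrt(scale * np.clip(evals, 0.0, None))
    return float(theta), semi_axes, pts.mean(axis=0)


def _columnwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between matching columns of two (units, bins) arrays."""
    az = a - a.mean(axis=0)
    bz = b - b.mean(axis=0)
    num = (az * bz).sum(axis=0)
    den = np.sqrt((az**2).sum(axis=0) * (bz**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def strength_correlation(delta_grip: np.ndarray, delta_force: np.ndarray,
                         n_shuffle: int = 1000, alpha: float = 0.001,
                         min_consec: int = 2,
                         rng: np.random.Generator | int | None = None):
    """Per-bin Pearson correlation between grip and force modulation strength.

    The null shuffles both dauROC matrices jointly across time and units
    (without replacement), destroying any unit-level coupling while keeping
    the value distribution. Returns (r(t), pvalues, mask).
    """
    rng = np.random.default_rng(rng)
    dg = np.asarray(delta_grip, float)
    df = np.asarray(delta_force, float)
    if dg.shape != df.shape:
        raise ValueError("delta matrices must share one (units, bins) grid")
    r_obs = _columnwise_pearson(dg, df)
    null = np.empty((n_shuffle, dg.shape[1]))
    for s in range(n_shuffle):
        gs = dg.flat[rng.permutation(dg.size)].reshape(dg.shape)
        fs = df.flat[rng.permutation(df.size)].reshape(df.shape)
        null[s] = _columnwise_pearson(gs, fs)
    p = (np.sum(np.abs(null) >= np.abs(r_obs)[None, :] - 1e-12, axis=0) + 1.0) / (n_shuffle + 1.0)
    mask = runs_mask(p < alpha, min_consec=min_consec)
    return r_obs, p, mask


def _lagged_pearson(dg: np.ndarray, df: np.ndarray, lag_bins: np.ndarray) -> np.ndarray:
    """R[t, lag] between grip at bin t and force at bin t+lag; NaN off-grid."""
    n_bins = dg.shape[1]
    out = np.full((n_bins, len(lag_bins)), np.nan)
    for li, l in enumerate(lag_bins):
        if l >= 0:
            sl_g, sl_f = slice(0, n_bins - l), slice(l, n_bins)
        else:
            sl_g, sl_f = slice(-l, n_bins), slice(0, n_bins + l)
        out[sl_g, li] = _columnwise_pearson(dg[:, sl_g], df[:, sl_f])
    return out


def cross_temporal_correlation(delta_grip: np.ndarray, delta_force: np.ndarray,
                               step_ms: float = 20.0, max_lag_ms: float = 400.0,
                               n_shuffle: int = 1000, alpha: float = 0.001,
                               min_consec: int = 2,
                               rng: np.random.Generator | int | None = None):
    """Grip dauROC at each bin vs force dauROC at lags -400..+400 ms.

    Returns (lags_ms, R[t, lag], pvalues, mask); mask requires >=2
    consecutive significant time bins at a lag, and the lag-0 column equals
    :func:`strength_correlation`'s r(t) exactly.
    """
    rng = np.random.default_rng(rng)
    dg = np.asarray(delta_grip, float)
    df = np.asarray(delta_force, float)
    if dg.shape != df.shape:
        raise ValueError("delta matrices must share one (units, bins) grid")
    lag_bins = np.arange(-int(round(max_lag_ms / step_ms)),
                         int(round(max_lag_ms / step_ms)) + 1)
    lags_ms = lag_bins * step_ms
    r_obs = _lagged_pearson(dg, df, lag_bins)
    exceed = np.zeros_like(r_obs)
    for _ in range(n_shuffle):
        gs = dg.flat[rng.permutation(dg.size)].reshape(dg.shape)
        fs = df.flat[rng.permutation(df.size)].reshape(df.shape)
        rn = _lagged_pearson(gs, fs, lag_bins)
        exceed += np.abs(rn) >= np.abs(r_obs) - 1e-12
    p = (exceed + 1.0) / (n_shuffle + 1.0)
    mask = runs_mask(p < alpha, min_consec=min_consec, axis=0)
    mask &= ~np.isnan(r_obs)
    return lags_ms, r_obs, p, mask
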