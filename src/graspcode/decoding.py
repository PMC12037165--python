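"""Cross-temporal population decoding and the generalization index.

A linear maximum-margin classifier is trained on the population vector at
one 100 ms bin and tested at every bin, over repeated random 25-train /
5-test splits per class. Off-diagonal generalization is summarized by a
binary "static" matrix — bin pairs where the off-diagonal accuracy passes a
cluster-based permutation test, exceeds the 99th percentile of a
shuffled-label bootstrap null, and both diagonal bins are individually
significant (Bonferroni) — and by the generalization index: per test bin,
the fraction of train bins within the preparation or execution epoch whose
cross-temporal decoding is static.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.svm import LinearSVC

from .single_unit import runs_mask

__all__ = [
    "decode_timecourse",
    "cross_temporal_matrix",
    "null_matrices",
    "static_bins",
    "generalization_index",
    "epoch_masks",
    "CrossTemporalResult",
]

CHANCE = 0.5


def _splits(labels: np.ndarray, train_per_class: int, test_per_class: int,
            rng: np.random.Generator):
    """One stratified random train/test split of trial indices."""
    train, test = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < train_per_class + test_per_class:
            raise ValueError(
                f"class {c!r} has {len(idx)} trials; need "
                f"{train_per_class + test_per_class} for the split"
            )
        pick = rng.permutation(idx)
        train.append(pick[:train_per_class])
        test.append(pick[train_per_class:train_per_class + test_per_class])
    return np.concatenate(train), np.concatenate(test)


def _fit_bin(Xtr: np.ndarray, ytr: np.ndarray):
    """Standardize on the training fold, then fit a linear max-margin model."""
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd[sd == 0] = 1.0
    clf = LinearSVC(C=1.0, dual="auto", max_iter=5000)
    clf.fit((Xtr - mu) / sd, ytr)
    return clf, mu, sd


def cross_temporal_matrix(rates: np.ndarray, labels: np.ndarray, n_rep: int = 50,
                          train_per_class: int = 25, test_per_class: int = 5,
                          rng: np.random.Generator | int | None = None) -> np.ndarray:
    """M[train_bin, test_bin] accuracy over repeated random splits.

    ``rates``: (units, trials, bins). The diagonal is the plain per-bin
    decoding time course; the same splits serve every train bin within a
    repetition so rows are comparable.
    """
    rng = np.random.default_rng(rng)
    rates = np.asarray(rates, float)
    labels = np.asarray(labels)
    n_bins = rates.shape[2]
    M = np.zeros((n_bins, n_bins))
    for _ in range(n_rep):
        tr, te = _splits(labels, train_per_class, test_per_class, rng)
        Xtr_all = rates[:, tr, :]  # (units, n_tr, bins)
        Xte_all = rates[:, te, :]
        for i in range(n_bins):
            clf, mu, sd = _fit_bin(Xtr_all[:, :, i].T, labels[tr])
            # test the bin-i model at every test bin j
            Z = (Xte_all.transpose(2, 1, 0) - mu) / sd  # (bins, n_te, units)
            pred = clf.decision_function(Z.reshape(-1, Z.shape[2])).reshape(Z.shape[0], -1)
            yhat = np.where(pred > 0, clf.classes_[1], clf.classes_[0])
            M[i] += (yhat == labels[te][None, :]).mean(axis=1)
    return M / n_rep


def decode_timecourse(rates: np.ndarray, labels: np.ndarray, n_rep: int = 50,
                      train_per_class: int = 25, test_per_class: int = 5,
                      rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Per-bin decoding accuracy (the cross-temporal diagonal)."""
    rng = np.random.default_rng(rng)
    rates = np.asarray(rates, float)
    labels = np.asarray(labels)
    n_bins = rates.shape[2]
    acc = np.zeros(n_bins)
    for _ in range(n_rep):
        tr, te = _splits(labels, train_per_class, test_per_class, rng)
        for i in range(n_bins):
            clf, mu, sd = _fit_bin(rates[:, tr, i].T, labels[tr])
            Z = (rates[:, te, i].T - mu) / sd
            acc[i] += (clf.predict(Z) == labels[te]).mean()
    return acc / n_rep


def null_matrices(rates: np.ndarray, labels: np.ndarray, n_null: int = 1000,
                  train_per_class: int = 25, test_per_class: int = 5,
                  rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Shuffled-label bootstrap null: n_null full matrices, one split each."""
    rng = np.random.default_rng(rng)
    labels = np.asarray(labels)
    out = np.empty((n_null, rates.shape[2], rates.shape[2]))
    for s in range(n_null):
        out[s] = cross_temporal_matrix(rates, rng.permutation(labels), n_rep=1,
                                       train_per_class=train_per_class,
                                       test_per_class=test_per_class, rng=rng)
    return out


@dataclass
class CrossTemporalResult:
    """Cross-temporal accuracy matrix with its significance structure."""

    matrix: np.ndarray
    bin_centers: np.ndarray
    diag_significant: np.ndarray  # Bonferroni permutation test per diagonal bin
    pointwise_significant: np.ndarray  # 99th-percentile bootstrap exceedance
    cluster_significant: np.ndarray
    static: np.ndarray  # final binary matrix (runs of >=2 along test time)


def static_bins(M: np.ndarray, null: np.ndarray, bin_centers: np.ndarray,
                min_consec: int = 2, diag_alpha: float = 0.01,
                cluster_alpha: float = 0.01, pointwise_q: float = 95.0,
                chance: float = CHANCE) -> CrossTemporalResult:
    """Binary static matrix from the three-condition criterion.

    A cell (i, j) is static iff (1) it lies in a supra-threshold cluster
    whose mass beats the (1 - cluster_alpha) quantile of the null's maximum
    cluster masses, (2) M[i, j] exceeds the 99th percentile of its own
    shuffled-label null, and (3) both diagonal cells i and j pass a
    Bonferroni-corrected permutation test. Surviving cells are then pruned
    to runs of >= ``min_consec`` along the test-time axis.
    """
    if null.ndim != 3 or null.shape[1:] != M.shape:
        raise ValueError("null must be (n_null, bins, bins) matching M")
    n_null, n_bins, _ = null.shape

    # (3) on-diagonal permutation test, Bonferroni over diagonal bins
    diag_null = null[:, np.arange(n_bins), np.arange(n_bins)]  # (n_null, bins)
    diag_obs = np.diag(M)
    # plain exceedance fraction: an add-one p could never clear the
    # Bonferroni threshold 0.01/n_bins at practical null counts
    p_diag = np.sum(diag_null >= diag_obs[None, :] - 1e-12, axis=0) / n_null
    diag_sig = p_diag < diag_alpha / n_bins

    # (2) cellwise 99th-percentile bootstrap exceedance
    thresh99 = np.percentile(null, 99.0, axis=0)
    pointwise_sig = M > thresh99

    # (1) cluster-based permutation on the matrix plane
    cell_thresh = np.percentile(null, pointwise_q, axis=0)
    supra = M > cell_thresh

    def max_cluster_mass(mat: np.ndarray, sup: np.ndarray) -> float:
        lab, n = ndimage.label(sup, structure=np.ones((3, 3), int))
        if n == 0:
            return 0.0
        return max(float((mat - chance)[lab == k].sum()) for k in range(1, n + 1))

    null_masses = np.array([max_cluster_mass(null[s], null[s] > cell_thresh)
                            for s in range(n_null)])
    mass_thresh = np.percentile(null_masses, 100.0 * (1 - cluster_alpha))
    lab, n_clu = ndimage.label(supra, structure=np.ones((3, 3), int))
    cluster_sig = np.zeros_like(supra)
    for k in range(1, n_clu + 1):
        if float((M - chance)[lab == k].sum()) > mass_thresh:
            cluster_sig |= lab == k

    static = cluster_sig & pointwise_sig & diag_sig[:, None] & diag_sig[None, :]
    static = runs_mask(static, min_consec=min_consec, axis=1)  # along test time
    return CrossTemporalResult(M, np.asarray(bin_centers), diag_sig, pointwise_sig,
                               cluster_sig, static)


def epoch_masks(trials: pd.DataFrame, bin_centers: np.ndarray,
                align: str = "movement_on") -> dict[str, np.ndarray]:
    """Preparation ([mean cue_on, mean go]) and execution ([mean movement
    onset, mean release]) bin masks in alignment-relative coordinates."""
    a = trials[align].mean()
    prep = (bin_centers >= trials["cue_on"].mean() - a) & (bin_centers <= trials["go"].mean() - a)
    execu = (bin_centers >= trials["movement_on"].mean() - a) & (
        bin_centers <= trials["release"].mean() - a)
    for name, m in (("preparation", prep), ("execution", execu)):
        if m.sum() < 2:
            raise ValueError(f"{name} epoch covers <2 bins on this grid")
    if (prep & execu).any():
        raise ValueError("preparation and execution epochs overlap")
    return {"preparation": prep, "execution": execu}


def generalization_index(static: np.ndarray, epochs: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """GI_E(t_test) = fraction of train bins in epoch E static at t_test."""
    out = {}
    for name, mask in epochs.items():
        mask = np.asarray(mask, bool)
        out[name] = static[mask, :].mean(axis=0)
    return out
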