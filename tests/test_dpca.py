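"""Demixed-PCA identities, planted-structure recovery, and classifiers."""

import numpy as np
import pytest
import scipy.linalg as sla
from hypothesis import given, settings
from hypothesis import strategies as st

from graspcode import dpca


def planted_tensor(rng, n_units=60, T=80, w=(0.90, 0.06, 0.02, 0.02), noise=0.0):
    """Additive tensor with an exact variance split across marginalizations.

    Returns (X, parts_dict, grip_axis). Each part is built orthogonal in
    the condition structure, then rescaled to the requested share of total
    squared norm.
    """
    t = np.linspace(0, 1, T)
    time_part = np.outer(rng.normal(size=n_units), np.sin(2 * np.pi * t))
    grip_axis = rng.normal(size=n_units)
    grip_axis /= np.linalg.norm(grip_axis)
    grip_prof = np.exp(-(((t - 0.6) / 0.2) ** 2))
    force_axis = rng.normal(size=n_units)
    force_axis /= np.linalg.norm(force_axis)
    force_prof = np.exp(-(((t - 0.8) / 0.1) ** 2))
    inter_axis = rng.normal(size=n_units)
    inter_axis /= np.linalg.norm(inter_axis)

    X = np.zeros((n_units, 2, 2, T))
    parts = {
        "time": np.zeros_like(X), "grip": np.zeros_like(X),
        "force": np.zeros_like(X), "interaction": np.zeros_like(X),
    }
    for g, sg in enumerate((1.0, -1.0)):
        for f, sf in enumerate((1.0, -1.0)):
            parts["time"][:, g, f] = time_part
            parts["grip"][:, g, f] = sg * np.outer(grip_axis, grip_prof)
            parts["force"][:, g, f] = sf * np.outer(force_axis, force_prof)
            parts["interaction"][:, g, f] = sg * sf * np.outer(inter_axis, force_prof)
    for name, share in zip(("time", "grip", "force", "interaction"), w):
        norm = np.sqrt((parts[name] ** 2).sum())
        parts[name] *= np.sqrt(share) / norm
        X += parts[name]
    if noise:
        X += rng.normal(0, noise, X.shape)
    return X, parts, grip_axis


class TestMarginalize:
    def test_condition_constant_tensor_has_null_condition_parts(self, rng):
        base = rng.normal(size=(10, 1, 1, 20))
        X = np.tile(base, (1, 2, 2, 1))
        parts = dpca.marginalize(X)
        for phi in ("grip", "force", "interaction"):
            np.testing.assert_allclose(parts[phi], 0.0, atol=1e-12)

    def test_constructed_parts_recovered_exactly(self, rng):
        X, built, _ = planted_tensor(rng)
        parts = dpca.marginalize(X)
        for phi in ("time", "grip", "force", "interaction"):
            np.testing.assert_allclose(parts[phi], built[phi], atol=1e-10)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_parts_sum_to_centered_tensor(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(6, 2, 2, 9))
        parts = dpca.marginalize(X)
        recon = sum(parts[p] for p in ("time", "grip", "force", "interaction"))
        np.testing.assert_allclose(recon, parts["_centered"], atol=1e-12)


class TestFitDpca:
    def test_negative_regularization_rejected(self, rng):
        X = rng.normal(size=(5, 2, 2, 6))
        with pytest.raises(ValueError, match="mu"):
            dpca.fit_dpca(X, mu=-1.0)

    def test_merged_marginalization_equals_pca(self, rng):
        X = rng.normal(size=(20, 2, 2, 30))
        parts = dpca.marginalize(X)
        merged = {"all": parts["_centered"], "_centered": parts["_centered"],
                  "_grand_mean": parts["_grand_mean"]}
        model = dpca.fit_dpca(X, n_components=4, mu=0.0, marginalizations=merged)
        Xf = parts["_centered"].reshape(20, -1)
        U = np.linalg.svd(Xf, full_matrices=False)[0][:, :4]
        angles = np.degrees(sla.subspace_angles(model.encoders["all"][:, :4], U))
        assert angles.max() < 1.0

    def test_single_marginalization_limit_equals_pca(self, rng):
        # data with only condition-independent structure: time-dPCA = PCA
        base = rng.normal(size=(15, 1, 1, 40))
        X = np.tile(base, (1, 2, 2, 1))
        model = dpca.fit_dpca(X, n_components=3, mu=0.0)
        parts = dpca.marginalize(X)
        Xf = parts["_centered"].reshape(15, -1)
        U = np.linalg.svd(Xf, full_matrices=False)[0][:, :3]
        angles = np.degrees(sla.subspace_angles(model.encoders["time"][:, :3], U))
        assert angles.max() < 1.0

    def test_planted_grip_axis_recovered(self, rng):
        X, _, grip_axis = planted_tensor(rng, noise=1e-3)
        model = dpca.fit_dpca(X, n_components=3, mu=0.0)
        r = np.corrcoef(model.encoders["grip"][:, 0], grip_axis)[0, 1]
        assert abs(r) >= 0.95

    def test_huge_ridge_shrinks_explained_variance(self, rng):
        X, _, _ = planted_tensor(rng)
        total = float(np.sum(dpca.marginalize(X)["_centered"] ** 2))
        small = dpca.fit_dpca(X, n_components=3, mu=1e-9 * total)
        huge = dpca.fit_dpca(X, n_components=3, mu=1e6 * total)
        for phi in ("time", "grip"):
            assert huge.explained[phi].sum() < 0.01 * small.explained[phi].sum()


class TestExplainedVariance:
    def test_planted_split_recovered_within_two_points(self, rng):
        X, _, _ = planted_tensor(rng, w=(0.90, 0.06, 0.02, 0.02), noise=0.0)
        model = dpca.fit_dpca(X, n_components=5, mu=0.0)
        got = {phi: model.explained[phi].sum() for phi in dpca.MARGINALIZATIONS}
        for phi, want in zip(("time", "grip", "force", "interaction"), (90, 6, 2, 2)):
            assert got[phi] == pytest.approx(want, abs=2.0)

    def test_totals_bounded_by_hundred(self, rng):
        X = rng.normal(size=(12, 2, 2, 15))
        model = dpca.fit_dpca(X, n_components=5, mu=0.0)
        assert sum(v.sum() for v in model.explained.values()) <= 100.0 + 1e-6


class TestComponentClassifier:
    def _session(self, rng, signal=3.0, n_trials=40):
        n_units, T = 30, 50
        grip = np.tile([True, False], n_trials // 2)
        force = np.repeat([True, False], n_trials // 2)
        axis = rng.normal(size=n_units)
        axis /= np.linalg.norm(axis)
        rates = rng.normal(0, 1, (n_units, n_trials, T))
        win = slice(15, 45)  # delay + movement epochs
        sg = np.where(grip, 1.0, -1.0)
        rates[:, :, win] += signal * axis[:, None, None] * sg[None, :, None]
        return rates, grip, force

    def test_planted_grip_code_is_decodable_in_window(self, rng):
        rates, grip, force = self._session(rng)
        X = dpca.trial_average(rates, grip, force)
        model = dpca.fit_dpca(X, n_components=3, mu=0.0)
        dec = dpca.component_classifier(model, rates, grip, force, "grip",
                                        n_iter=30, n_shuffle=30, rng=rng)
        assert dec.mask[20:40].all()
        assert not dec.mask[:10].any()

    def test_label_shuffled_data_not_significant(self, rng):
        hits = 0
        for _ in range(10):
            rates, grip, force = self._session(rng, signal=0.0)
            X = dpca.trial_average(rates, grip, force)
            model = dpca.fit_dpca(X, n_components=2, mu=0.0)
            dec = dpca.component_classifier(model, rates, grip, force, "grip",
                                            n_iter=15, n_shuffle=30, rng=rng)
            hits += dec.mask.any()
        assert hits <= 1

    def test_perfectly_separable_projections_reach_full_accuracy(self, rng):
        rates, grip, force = self._session(rng, signal=50.0)
        X = dpca.trial_average(rates, grip, force)
        model = dpca.fit_dpca(X, n_components=2, mu=0.0)
        dec = dpca.component_classifier(model, rates, grip, force, "grip",
                                        n_iter=20, n_shuffle=5, rng=rng)
        assert dec.accuracy[20:40].min() == pytest.approx(1.0)

    def test_tiny_condition_cell_rejected(self, rng):
        rates = rng.normal(size=(5, 5, 8))
        grip = np.array([True, True, True, False, False])
        force = np.array([True, False, True, False, True])
        X_ok_needed = pytest.raises(ValueError, match="<2 trials")
        with X_ok_needed:
            model = dpca.DpcaModel(
                decoders={"grip": np.ones((1, 5))}, encoders={"grip": np.ones((5, 1))},
                mu=0.0, grand_mean=np.zeros(5), shape=rates.shape,
                explained={"grip": np.array([1.0])})
            dpca.component_classifier(model, rates, grip, force, "grip", rng=rng)
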