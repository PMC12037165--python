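"""Demixed PCA of the trial-averaged population tensor.

The unit x grip x force x time tensor of trial-averaged rates is split into
four marginalizations — condition-independent (time), grip, force, and
their interaction — that sum exactly to the mean-centered tensor. For each
marginalization a reduced-rank ridge regression finds paired decoder/
encoder axes that capture most of that marginalization's variance while
remaining demixed from the others. Single-trial projections onto a decoder
axis feed a nearest-class-mean classifier whose chance level comes from a
label-shuffle Monte Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .single_unit import runs_mask

__all__ = [
    "marginalize",
    "DpcaModel",
    "fit_dpca",
    "explained_variance",
    "component_classifier",
    "first_significant_component",
    "trial_average",
    "ComponentDecoding",
]

MARGINALIZATIONS = ("time", "grip", "force", "interaction")


def trial_average(rates: np.ndarray, grip_pos: np.ndarray, force_pos: np.ndarray) -> np.ndarray:
    """Balanced condition averages: (units, 2, 2, bins) from single trials.

    Equal-weight condition means prevent unequal trial counts from leaking
    condition structure into the time marginalization.
    """
    out = np.empty((rates.shape[0], 2, 2, rates.shape[2]))
    for gi, gmask in enumerate((np.asarray(grip_pos, bool), ~np.asarray(grip_pos, bool))):
        for fi, fmask in enumerate((np.asarray(force_pos, bool), ~np.asarray(force_pos, bool))):
            sel = gmask & fmask
            if not sel.any():
                raise ValueError(f"missing condition cell (grip={gi}, force={fi})")
            out[:, gi, fi, :] = rates[:, sel, :].mean(axis=1)
    return out


def marginalize(X: np.ndarray) -> dict[str, np.ndarray]:
    """Split a (units, n_grip, n_force, time) tensor into marginalizations.

    After removing each unit's grand mean: X_time is the condition mean
    (time-varying, condition-independent); X_grip the grip-conditional mean
    minus X_time; X_force symmetric; X_inter the remainder. The four parts
    sum to the centered tensor exactly.
    """
    X = np.asarray(X, float)
    if X.ndim != 4:
        raise ValueError("expected a (units, grip, force, time) tensor")
    grand = X.mean(axis=(1, 2, 3), keepdims=True)
    Xc = X - grand
    x_time = Xc.mean(axis=(1, 2), keepdims=True)
    x_grip = Xc.mean(axis=2, keepdims=True) - x_time
    x_force = Xc.mean(axis=1, keepdims=True) - x_time
    x_inter = Xc - x_time - x_grip - x_force
    b = np.broadcast_to
    return {
        "time": b(x_time, X.shape).copy(),
        "grip": b(x_grip, X.shape).copy(),
        "force": b(x_force, X.shape).copy(),
        "interaction": x_inter,
        "_centered": Xc,
        "_grand_mean": grand[:, 0, 0, 0],
    }


@dataclass
class DpcaModel:
    """Fitted demixed-PCA axes.

    ``decoders[phi]`` (q x units) projects data onto components of
    marginalization phi; ``encoders[phi]`` (units x q) maps them back.
    Component order within each marginalization follows explained variance.
    """

    decoders: dict[str, np.ndarray]
    encoders: dict[str, np.ndarray]
    mu: float
    grand_mean: np.ndarray
    shape: tuple  # (units, n_grip, n_force, time)
    explained: dict[str, np.ndarray] = field(default_factory=dict)  # % per component
    total_variance: float = 0.0

    def component_order(self) -> list[tuple[str, int, float]]:
        """All components across marginalizations, sorted by variance."""
        items = [(phi, k, float(v)) for phi in self.decoders
                 for k, v in enumerate(self.explained[phi])]
        return sorted(items, key=lambda it: -it[2])


def fit_dpca(X: np.ndarray, n_components: int = 10, mu: float = 1e-6,
             marginalizations: dict[str, np.ndarray] | None = None) -> DpcaModel:
    """Reduced-rank ridge regression per marginalization.

    For each part X_phi, minimize ||X_phi - D F X||^2 + mu ||D F||^2 over
    rank-q D F: the ridge projector A = X_phi X' (X X' + mu I)^{-1} is
    rank-truncated through the SVD of A X, giving orthonormal encoders
    D = U_q and decoders F = U_q' A.
    """
    if mu < 0:
        raise ValueError("regularization mu must be >= 0")
    parts = marginalize(X) if marginalizations is None else marginalizations
    Xc = parts["_centered"]
    n_units = Xc.shape[0]
    q = min(n_components, n_units)
    Xf = Xc.reshape(n_units, -1)
    C = Xf @ Xf.T + mu * np.eye(n_units)
    Cinv = np.linalg.pinv(C) if mu == 0 else np.linalg.inv(C)

    decoders, encoders = {}, {}
    for phi in (k for k in parts if not k.startswith("_")):
        Pf = parts[phi].reshape(n_units, -1)
        A = Pf @ Xf.T @ Cinv
        U, s, _ = np.linalg.svd(A @ Xf, full_matrices=False)
        Uq = U[:, :q]
        encoders[phi] = Uq
        decoders[phi] = Uq.T @ A

    model = DpcaModel(decoders, encoders, float(mu), parts["_grand_mean"], X.shape)
    explained_variance(model, X, parts=parts)
    return model


def explained_variance(model: DpcaModel, X: np.ndarray,
                       parts: dict[str, np.ndarray] | None = None) -> dict[str, np.ndarray]:
    """% of total centered variance captured by each component.

    A component's variance is the reduction in squared reconstruction error
    of its own marginalization, ||X_phi||^2 - ||X_phi - e_k (f_k X)||^2,
    as a share of total centered variance. Because the marginalization
    parts are mutually orthogonal and encoders are orthonormal within a
    marginalization, the retained components can never account for more
    than 100% in total. Results are stored on the model and returned.
    """
    if parts is None:
        parts = marginalize(X)
    Xf = parts["_centered"].reshape(X.shape[0], -1)
    total = float((Xf ** 2).sum())
    out = {}
    for phi in model.decoders:
        D, E = model.decoders[phi], model.encoders[phi]
        target = parts[phi if phi in parts else "_centered"].reshape(X.shape[0], -1)
        proj = D @ Xf  # (q, K)
        # ||X_phi||^2 - ||X_phi - e_k p_k||^2 = 2 <e_k p_k, X_phi> - ||p_k||^2
        cross = np.einsum("uq,qk,uk->q", E, proj, target)
        norms = (proj ** 2).sum(axis=1)
        var = 2 * cross - norms
        out[phi] = 100.0 * var / total
    model.explained = out
    model.total_variance = total
    return out


@dataclass
class ComponentDecoding:
    """Single-trial classification along one demixed component."""

    accuracy: np.ndarray  # (bins,)
    shuffled: np.ndarray  # (n_shuffle, bins)
    mask: np.ndarray  # significant bins (actual beats every shuffle, >= min_consec run)
    marginalization: str
    component: int


def _class_labels(marg: str, grip_pos: np.ndarray, force_pos: np.ndarray) -> np.ndarray:
    g = np.asarray(grip_pos, bool)
    f = np.asarray(force_pos, bool)
    if marg == "grip":
        return g.astype(int)
    if marg == "force":
        return f.astype(int)
    if marg == "interaction":
        return (2 * g + f).astype(int)
    raise ValueError(f"no classifier for marginalization {marg!r}")


def _nearest_mean_accuracy(proj: np.ndarray, labels: np.ndarray, held: np.ndarray) -> np.ndarray:
    """Per-bin accuracy of nearest-training-class-mean on held-out trials."""
    train = np.ones(len(labels), bool)
    train[held] = False
    classes = np.unique(labels)
    means = np.stack([proj[train & (labels == c)].mean(axis=0) for c in classes])  # (C, bins)
    d = np.abs(proj[held][:, None, :] - means[None, :, :])  # (held, C, bins)
    pred = classes[np.argmin(d, axis=1)]
    return (pred == labels[held][:, None]).mean(axis=0)


def component_classifier(model: DpcaModel, rates: np.ndarray, grip_pos: np.ndarray,
                         force_pos: np.ndarray, marginalization: str, component: int = 0,
                         n_iter: int = 100, n_shuffle: int = 100, min_consec: int = 10,
                         rng: np.random.Generator | int | None = None) -> ComponentDecoding:
    """Stratified Monte Carlo leave-group-out decoding along one component.

    Each iteration holds out one trial per condition cell; held-out trials
    are projected on the decoder axis and assigned to the nearest training
    class mean per time bin. Bins are significant when the actual accuracy
    exceeds every one of ``n_shuffle`` label-shuffled accuracies for at
    least ``min_consec`` consecutive bins.
    """
    rng = np.random.default_rng(rng)
    axis = model.decoders[marginalization][component]
    proj = np.einsum("u,utb->tb", axis, rates)  # (trials, bins)
    labels = _class_labels(marginalization, grip_pos, force_pos)
    cells = 2 * np.asarray(grip_pos, bool).astype(int) + np.asarray(force_pos, bool).astype(int)
    for c in np.unique(cells):
        if (cells == c).sum() < 2:
            raise ValueError(f"condition cell {c} has <2 trials")

    def run(lbl: np.ndarray) -> np.ndarray:
        accs = np.empty((n_iter, proj.shape[1]))
        for it in range(n_iter):
            held = np.array([rng.choice(np.flatnonzero(cells == c)) for c in np.unique(cells)])
            accs[it] = _nearest_mean_accuracy(proj, lbl, held)
        return accs.mean(axis=0)

    actual = run(labels)
    shuffled = np.stack([run(rng.permutation(labels)) for _ in range(n_shuffle)])
    mask = runs_mask(actual > shuffled.max(axis=0), min_consec=min_consec)
    return ComponentDecoding(actual, shuffled, mask, marginalization, component)


def first_significant_component(model: DpcaModel, rates: np.ndarray, grip_pos, force_pos,
                                marginalization: str, max_components: int | None = None,
                                rng=None, **kw):
    """Lowest-index component of a marginalization with a nonempty mask.

    Returns (component_index, ComponentDecoding) or (None, last result).
    """
    n = model.decoders[marginalization].shape[0]
    if max_components is not None:
        n = min(n, max_components)
    dec = None
    for k in range(n):
        dec = component_classifier(model, rates, grip_pos, force_pos, marginalization,
                                   component=k, rng=rng, **kw)
        if dec.mask.any():
            return k, dec
    return None, dec
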