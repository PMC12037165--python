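"""End-to-end orchestration: config parsing and staged execution.

A structured text config (INI sections per module) drives the run; each
stage logs its timing and child seed and deposits arrays in the
:class:`~graspcode.io_core.ResultStore`, so identical config + seed
reproduces identical stored results.
"""

from __future__ import annotations

import configparser
import logging
import time
from pathlib import Path

import numpy as np

from . import behavior, decoding, dpca, rates, single_unit, synthetic
from ._seeds import stage_seed
from .io_core import ResultStore, read_inputs, select_correct_trials, write_dataset

__all__ = ["default_config", "load_config", "run_pipeline", "STAGES"]

log = logging.getLogger("graspcode")

STAGES = ("simulate", "rates", "auroc", "independence", "dpca", "decoding", "behavior")


def default_config() -> dict:
    return {
        "task": {"n_trials_per_condition": 30, "rt_mean_ms": 200.0, "rt_sd_ms": 60.0,
                 "mt_mean_ms": 250.0, "mt_sd_ms": 80.0},
        "population": {"n_grip_only": 40, "n_mixed": 20, "n_force_only": 2,
                       "n_null": 38, "gain": 0.5, "coding_scheme": "static"},
        "force": {"low_level": 1.0, "high_level": 2.0, "ramp_ms": 150.0, "noise_sd": 0.05},
        "rates": {"tau_ms": 100.0, "smooth_step_ms": 20.0, "bin_ms": 100.0,
                  "bin_step_ms": 80.0, "window_lo": -2000.0, "window_hi": 2000.0},
        "auroc": {"n_perm": 5000, "alpha": 0.001, "min_consec": 2},
        "independence": {"n_perm": 1000, "bin_stride": 5, "n_shuffle": 1000},
        "dpca": {"n_components": 10, "mu_scale": 1e-6, "n_iter": 100,
                 "n_shuffle": 100, "min_consec": 10, "max_components": 5},
        "decoding": {"n_rep": 50, "train_per_class": 25, "test_per_class": 5,
                     "n_null": 1000, "min_consec": 2},
        "behavior": {"max_lag_ms": 500.0, "n_null": 200},
    }


def load_config(path: str | Path) -> dict:
    """Read a key = value INI config, overlaying the defaults."""
    cp = configparser.ConfigParser()
    with open(path) as fh:
        cp.read_file(fh)
    cfg = default_config()
    for section in cp.sections():
        cfg.setdefault(section, {})
        for key, raw in cp.items(section):
            if key in ("coding_scheme",):
                cfg[section][key] = raw
                continue
            try:
                val = int(raw)
            except ValueError:
                try:
                    val = float(raw)
                except ValueError:
                    val = raw
            cfg[section][key] = val
    return cfg


def _grip_force_pos(trials):
    return (trials["grip"].to_numpy() == "side"), (trials["force"].to_numpy() == "high")


def run_pipeline(config: dict | None = None, out: str | Path = "results", seed: int = 0,
                 stages: tuple[str, ...] | None = None,
                 input_path: str | Path | None = None) -> ResultStore:
    """Execute the requested stages in dependency order.

    With no ``input_path`` a synthetic session is generated from the
    config; otherwise the dataset at that path is loaded. Any stage error
    aborts with the stage name in the exception context.
    """
    cfg = default_config() if config is None else config
    wanted = STAGES if stages is None else tuple(stages)
    store = ResultStore(out)
    store.save_config({"config": cfg, "seed": seed, "stages": list(wanted)})

    state: dict = {}

    def stage(name):
        return name in wanted

    try:
        _run_stages(cfg, store, seed, wanted, input_path, state)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {state.get('current', '?')!r} failed") from exc
    return store


def _run_stages(cfg, store, seed, wanted, input_path, state):
    t0 = time.time()

    def tick(name):
        state["current"] = name
        log.info("stage %s (t=%.1fs, seed=%d)", name, time.time() - t0, stage_seed(seed, name))

    # ---- data
    state["current"] = "load"
    if input_path is not None:
        trials, spikes, force = read_inputs(input_path)
    else:
        tick("simulate")
        task = synthetic.TaskConfig(seed=stage_seed(seed, "task"), **cfg["task"])
        pop = synthetic.make_population(seed=stage_seed(seed, "population"), **cfg["population"])
        fspec = synthetic.ForceSpec(**cfg["force"])
        trials = synthetic.generate_trials(task)
        spikes = synthetic.simulate_spikes(trials, pop, seed=stage_seed(seed, "spikes"))
        force = synthetic.simulate_force(trials, fspec, seed=stage_seed(seed, "forcetrace"))
        if "simulate" in wanted:
            write_dataset(Path(store.path) / "dataset", trials, spikes, force)
    trials = select_correct_trials(trials)
    grip_pos, force_pos = _grip_force_pos(trials)
    rc = cfg["rates"]
    window = (rc["window_lo"], rc["window_hi"])

    smoothed = binned = None
    if any(s in wanted for s in ("rates", "auroc", "independence", "dpca", "decoding")):
        tick("rates")
        smoothed = rates.smooth_rates(spikes, trials, tau_ms=rc["tau_ms"],
                                      step_ms=rc["smooth_step_ms"], window=window)
        binned = rates.bin_rates(spikes, trials, bin_ms=rc["bin_ms"],
                                 step_ms=rc["bin_step_ms"], window=window)
        if "rates" in wanted:
            store.save_arrays("rates", smoothed=smoothed.rates, smooth_centers=smoothed.bin_centers,
                              binned=binned.rates, binned_centers=binned.bin_centers)

    res_g = res_f = None
    if any(s in wanted for s in ("auroc", "independence")):
        tick("auroc")
        ac = cfg["auroc"]
        rng = np.random.default_rng(stage_seed(seed, "auroc"))
        res_g = single_unit.permutation_mask(smoothed.rates, grip_pos, smoothed.bin_centers,
                                             n_perm=ac["n_perm"], alpha=ac["alpha"],
                                             min_consec=ac["min_consec"], rng=rng)
        res_f = single_unit.permutation_mask(smoothed.rates, force_pos, smoothed.bin_centers,
                                             n_perm=ac["n_perm"], alpha=ac["alpha"],
                                             min_consec=ac["min_consec"], rng=rng)
        labels, counts = single_unit.classify_selectivity(res_g, res_f)
        if "auroc" in wanted:
            store.save_arrays("auroc", seed=stage_seed(seed, "auroc"),
                              auroc_grip=res_g.auroc, auroc_force=res_f.auroc,
                              delta_grip=res_g.delta, delta_force=res_f.delta,
                              p_grip=res_g.pvalues, p_force=res_f.pvalues,
                              mask_grip=res_g.mask, mask_force=res_f.mask,
                              bin_centers=res_g.bin_centers,
                              selectivity=np.array([s.encode() for s in labels]),
                              class_counts=np.array([counts[c] for c in
                                                     ("grip_only", "force_only", "mixed", "none")]))

    if "independence" in wanted:
        tick("independence")
        ic = cfg["independence"]
        rng = np.random.default_rng(stage_seed(seed, "independence"))
        stride = int(ic["bin_stride"])
        bins_idx = np.arange(0, res_g.auroc.shape[1], stride)
        chi2 = np.full(len(bins_idx), np.nan)
        chi2_p = np.full(len(bins_idx), np.nan)
        theta = np.full(len(bins_idx), np.nan)
        for k, b in enumerate(bins_idx):
            try:
                c, p, _ = single_unit.marginal_independence_test(
                    res_g.auroc[:, b], res_f.auroc[:, b], n_perm=ic["n_perm"], rng=rng)
                chi2[k], chi2_p[k] = c, p
                theta[k], _, _ = single_unit.ellipse_angle(
                    np.column_stack([res_f.auroc[:, b], res_g.auroc[:, b]]))
            except ValueError:
                continue
        r_t, p_r, mask_r = single_unit.strength_correlation(
            res_g.delta, res_f.delta, n_shuffle=ic["n_shuffle"], rng=rng)
        lags, r_lag, p_lag, mask_lag = single_unit.cross_temporal_correlation(
            res_g.delta, res_f.delta, step_ms=rc["smooth_step_ms"],
            n_shuffle=ic["n_shuffle"], rng=rng)
        store.save_arrays("independence", seed=stage_seed(seed, "independence"),
                          bins_idx=bins_idx, chi2=chi2, chi2_p=chi2_p, theta=theta,
                          strength_r=r_t, strength_p=p_r, strength_mask=mask_r,
                          lags_ms=lags, lag_r=r_lag, lag_p=p_lag, lag_mask=mask_lag)

    model = None
    if any(s in wanted for s in ("dpca", "behavior")):
        tick("dpca")
        dc = cfg["dpca"]
        X = dpca.trial_average(smoothed.rates, grip_pos, force_pos)
        total_var = float(np.sum((X - X.mean(axis=(1, 2, 3), keepdims=True)) ** 2))
        mu = dc["mu_scale"] * total_var
        model = dpca.fit_dpca(X, n_components=dc["n_components"], mu=mu)
        if "dpca" in wanted:
            rng = np.random.default_rng(stage_seed(seed, "dpca"))
            arrays = {"explained_" + phi: model.explained[phi] for phi in model.explained}
            for phi in ("grip", "force", "interaction"):
                k, decres = dpca.first_significant_component(
                    model, smoothed.rates, grip_pos, force_pos, phi,
                    max_components=dc["max_components"], rng=rng,
                    n_iter=dc["n_iter"], n_shuffle=dc["n_shuffle"],
                    min_consec=dc["min_consec"])
                arrays[f"classifier_{phi}_accuracy"] = decres.accuracy
                arrays[f"classifier_{phi}_mask"] = decres.mask
                arrays[f"classifier_{phi}_component"] = np.array(-1 if k is None else k)
            for phi in dpca.MARGINALIZATIONS:
                arrays[f"decoder_{phi}"] = model.decoders[phi]
                arrays[f"encoder_{phi}"] = model.encoders[phi]
            store.save_arrays("dpca", seed=stage_seed(seed, "dpca"),
                              bin_centers=smoothed.bin_centers, **arrays)

    if "decoding" in wanted:
        tick("decoding")
        kc = cfg["decoding"]
        epochs = decoding.epoch_masks(trials, binned.bin_centers)
        arrays = {"bin_centers": binned.bin_centers,
                  "prep_mask": epochs["preparation"], "exec_mask": epochs["execution"]}
        for pname, lab in (("grip", grip_pos), ("force", force_pos)):
            rng = np.random.default_rng(stage_seed(seed, f"decoding/{pname}"))
            M = decoding.cross_temporal_matrix(binned.rates, lab, n_rep=kc["n_rep"],
                                               train_per_class=kc["train_per_class"],
                                               test_per_class=kc["test_per_class"], rng=rng)
            null = decoding.null_matrices(binned.rates, lab, n_null=kc["n_null"],
                                          train_per_class=kc["train_per_class"],
                                          test_per_class=kc["test_per_class"], rng=rng)
            res = decoding.static_bins(M, null, binned.bin_centers, min_consec=kc["min_consec"])
            gi = decoding.generalization_index(res.static, epochs)
            arrays[f"matrix_{pname}"] = M
            arrays[f"static_{pname}"] = res.static
            arrays[f"diag_sig_{pname}"] = res.diag_significant
            arrays[f"gi_prep_{pname}"] = gi["preparation"]
            arrays[f"gi_exec_{pname}"] = gi["execution"]
        store.save_arrays("decoding", seed=stage_seed(seed, "decoding"), **arrays)

    if "behavior" in wanted:
        tick("behavior")
        bc = cfg["behavior"]
        summ = behavior.behavior_summary(trials)
        arrays = {
            "rt_mean": summ["per_subject"]["rt_mean"].to_numpy(),
            "rt_sd": summ["per_subject"]["rt_sd"].to_numpy(),
            "mt_mean": summ["per_subject"]["mt_mean"].to_numpy(),
            "mt_sd": summ["per_subject"]["mt_sd"].to_numpy(),
        }
        if force is not None and model is not None:
            times, traces = force
            proj = {}
            for phi in ("time", "force"):
                axis = model.decoders[phi][0]
                proj[phi] = np.einsum("u,utb->tb", axis, smoothed.rates)
            # force traces share the smoothed 20 ms clock by construction
            if traces.shape[1] == smoothed.rates.shape[2]:
                rng = np.random.default_rng(stage_seed(seed, "behavior"))
                fd = behavior.force_dpc_correlation(
                    traces, proj, trials["force"].to_numpy(),
                    step_ms=rc["smooth_step_ms"], max_lag_ms=bc["max_lag_ms"],
                    n_null=bc["n_null"], rng=rng)
                arrays["r2_time"] = fd.r2.loc[fd.r2.dpc_type == "time", "r2"].to_numpy()
                arrays["r2_force"] = fd.r2.loc[fd.r2.dpc_type == "force", "r2"].to_numpy()
                arrays["prop_significant"] = np.array(
                    [fd.proportions.get("time", np.nan), fd.proportions.get("force", np.nan)])
                arrays["anova_F"] = fd.anova["F"].to_numpy()[:3]
        store.save_arrays("behavior", seed=stage_seed(seed, "behavior"), **arrays)

    state["current"] = "done"
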