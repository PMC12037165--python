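"""Synthetic delayed reach-to-grasp sessions.

Generates task-structured trial tables, inhomogeneous-Poisson spike trains
with configurable grip/force/time coding, and pulling-force traces, so the
whole selectivity/decoding pipeline is testable without recorded data.

The emulated task: the hand rests on a switch; after 800 ms a 300 ms visual
cue instructs the grip (side or precision); after a 1,000 ms delay a second
cue gives the required pulling-force level (low or high) and serves as the
go signal; the animal reaches, touches and pulls the object for at least
500 ms, then releases it and is rewarded. Grip and force are fully crossed,
2 x 2, with equal numbers of correct trials per condition cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import stage_rng
from .io_core import EVENT_COLUMNS, SpikeData, validate_trials

__all__ = [
    "TaskConfig",
    "NeuronSpec",
    "ForceSpec",
    "generate_trials",
    "simulate_spikes",
    "simulate_force",
    "make_population",
    "generate_session",
]

GRIPS = ("side", "precision")
FORCES = ("low", "high")

#: recording extends this far before switch-on / after movement onset (ms)
PRE_RECORD_MS = 600.0
POST_RECORD_MS = 2300.0

_RT_MT_FLOOR_MS = 20.0  # truncation lower bound for reaction/movement times


@dataclass
class TaskConfig:
    """Timing and size parameters of a simulated session.

    Durations are in ms. Reaction and movement times are drawn from normal
    distributions truncated below at 20 ms, so event order is preserved for
    every generated trial.
    """

    n_trials_per_condition: int = 30
    switch_to_cue_ms: float = 800.0
    cue_duration_ms: float = 300.0
    delay_ms: float = 1000.0
    rt_mean_ms: float = 200.0
    rt_sd_ms: float = 60.0
    mt_mean_ms: float = 250.0
    mt_sd_ms: float = 80.0
    pull_latency_ms: float = 50.0
    pull_hold_ms: float = 500.0
    hold_extra_mean_ms: float = 100.0
    hold_extra_sd_ms: float = 30.0
    reward_delay_ms: float = 200.0
    subject: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "switch_to_cue_ms",
            "cue_duration_ms",
            "delay_ms",
            "mt_mean_ms",
            "pull_hold_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"TaskConfig.{name} must be > 0, got {getattr(self, name)}")
        if self.n_trials_per_condition < 1:
            raise ValueError("n_trials_per_condition must be >= 1")
        if self.rt_sd_ms < 0 or self.mt_sd_ms < 0:
            raise ValueError("rt_sd_ms and mt_sd_ms must be >= 0")


@dataclass
class NeuronSpec:
    """Firing-rate model of one simulated unit.

    The instantaneous rate on a trial with grip sign ``s_g`` and force sign
    ``s_f`` (each in {-1, +1}) is

        r(t) = max(0, baseline * profile(t) * (1 + g*s_g*w_g(t)) * (1 + f*s_f*w_f(t)))

    where ``w_g``/``w_f`` are indicator windows anchored to a task event.
    Effects are multiplicative gains, which keeps rates nonnegative for
    |gain| <= 1 and makes auROC-style effect sizes independent of baseline.
    A unit with both gains zero is condition-independent by construction.
    """

    baseline_hz: float = 20.0
    time_profile: Callable[[np.ndarray], np.ndarray] | None = None
    grip_effect: float = 0.0
    force_effect: float = 0.0
    #: (anchor event name, onset ms, offset ms) relative to the anchor
    grip_window: tuple[str, float, float] = ("cue_on", 0.0, 4000.0)
    force_window: tuple[str, float, float] = ("go", 0.0, 3000.0)
    coding_scheme: str = "static"

    def rate(self, t: np.ndarray, events: dict[str, float], s_g: int, s_f: int) -> np.ndarray:
        """Rate (Hz) at trial-clock times ``t`` for one trial's conditions."""
        r = np.full_like(t, float(self.baseline_hz), dtype=float)
        if self.time_profile is not None:
            r = r * np.asarray(self.time_profile(t), dtype=float)
        if self.grip_effect != 0.0:
            ev, on, off = self.grip_window
            w = (t >= events[ev] + on) & (t < events[ev] + off)
            r = r * np.where(w, 1.0 + self.grip_effect * s_g, 1.0)
        if self.force_effect != 0.0:
            ev, on, off = self.force_window
            w = (t >= events[ev] + on) & (t < events[ev] + off)
            r = r * np.where(w, 1.0 + self.force_effect * s_f, 1.0)
        return np.maximum(r, 0.0)


@dataclass
class ForceSpec:
    """Shape of the pulling-force trace.

    Force is ~0 until pull onset, ramps over ``ramp_ms`` to the level set by
    the trial's force condition, holds until release, and ramps back down.
    """

    low_level: float = 1.0
    high_level: float = 2.0
    ramp_ms: float = 150.0
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if not (self.high_level > self.low_level > 0):
            raise ValueError("require high_level > low_level > 0")
        if self.ramp_ms <= 0:
            raise ValueError("ramp_ms must be > 0")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int,
                      lower: float = _RT_MT_FLOOR_MS) -> np.ndarray:
    if sd == 0:
        if mean < lower:
            raise ValueError(f"degenerate duration {mean} below floor {lower}")
        return np.full(size, float(mean))
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_trials(config: TaskConfig) -> pd.DataFrame:
    """Generate a balanced, fully crossed correct-trial table.

    Returns 4 * n_trials_per_condition rows with all event times in ms on
    the trial clock (switch_on = 0). Event order is strictly the task order
    for every row.
    """
    rng = stage_rng(config.seed, "trials")
    n = config.n_trials_per_condition
    grips = np.repeat(GRIPS, 2 * n)
    forces = np.tile(np.repeat(FORCES, n), 2)
    total = 4 * n

    rt = _truncated_normal(rng, config.rt_mean_ms, config.rt_sd_ms, total)
    mt = _truncated_normal(rng, config.mt_mean_ms, config.mt_sd_ms, total)
    hold_extra = np.abs(rng.normal(config.hold_extra_mean_ms, config.hold_extra_sd_ms, total))

    switch_on = np.zeros(total)
    cue_on = switch_on + config.switch_to_cue_ms
    cue_off = cue_on + config.cue_duration_ms
    go = cue_off + config.delay_ms
    movement_on = go + rt
    touch = movement_on + mt
    pull_on = touch + config.pull_latency_ms
    release = pull_on + config.pull_hold_ms + hold_extra
    reward = release + config.reward_delay_ms

    trials = pd.DataFrame(
        {
            "trial_id": np.arange(total),
            "subject": config.subject,
            "grip": grips,
            "force": forces,
            "correct": True,
            "switch_on": switch_on,
            "cue_on": cue_on,
            "cue_off": cue_off,
            "go": go,
            "movement_on": movement_on,
            "touch": touch,
            "pull_on": pull_on,
            "release": release,
            "reward": reward,
        }
    )
    # shuffle presentation order but keep trial_id stable
    order = rng.permutation(total)
    trials = trials.iloc[order].reset_index(drop=True)
    trials["trial_id"] = np.arange(total)
    validate_trials(trials)
    return trials


def _condition_signs(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    s_g = np.where(trials["grip"].to_numpy() == "side", 1, -1)
    s_f = np.where(trials["force"].to_numpy() == "high", 1, -1)
    return s_g, s_f


def _thinning(rng: np.random.Generator, rate_fn, t0: float, t1: float,
              grid: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """Inhomogeneous Poisson spikes on [t0, t1] by thinning.

    ``rates`` is the rate evaluated on ``grid`` (1 ms); the thinning bound
    is the per-trial maximum, exact for the piecewise-smooth rates used here.
    """
    rmax = float(rates.max())
    if rmax <= 0:
        return np.empty(0)
    dur_s = (t1 - t0) / 1000.0
    n = rng.poisson(rmax * dur_s)
    if n == 0:
        return np.empty(0)
    cand = np.sort(rng.uniform(t0, t1, n))
    r_at = np.interp(cand, grid, rates)
    keep = rng.uniform(0.0, rmax, n) < r_at
    return cand[keep]


def simulate_spikes(trials: pd.DataFrame, neurons: Sequence[NeuronSpec], seed: int = 0) -> SpikeData:
    """Draw spike trains for every unit x trial.

    Spikes are an inhomogeneous Poisson process with the rate given by each
    :class:`NeuronSpec`, simulated by thinning against the per-trial rate
    maximum. The recording window runs from 600 ms before switch-on to
    2,300 ms after movement onset, covering the analysis windows used
    downstream. Deterministic under a fixed seed.
    """
    if len(trials) == 0:
        raise ValueError("trials table is empty")
    s_g, s_f = _condition_signs(trials)
    events_per_trial = trials[list(EVENT_COLUMNS)].to_dict("records")
    t_start = np.full(len(trials), -PRE_RECORD_MS)
    t_stop = trials["movement_on"].to_numpy() + POST_RECORD_MS

    all_spikes: list[list[np.ndarray]] = []
    for u, spec in enumerate(neurons):
        rng = stage_rng(seed, f"spikes/unit{u}")
        unit_trains: list[np.ndarray] = []
        for i in range(len(trials)):
            grid = np.arange(t_start[i], t_stop[i] + 1.0, 1.0)
            rates = spec.rate(grid, events_per_trial[i], s_g[i], s_f[i])
            if not np.all(np.isfinite(rates)):
                raise ValueError(f"non-finite rate for unit {u}, trial {i}")
            unit_trains.append(_thinning(rng, spec.rate, t_start[i], t_stop[i], grid, rates))
        all_spikes.append(unit_trains)

    return SpikeData(
        unit_ids=np.arange(len(neurons)),
        included=np.ones(len(neurons), dtype=bool),
        spikes=all_spikes,
        trial_ids=trials["trial_id"].to_numpy(),
        t_start=t_start,
        t_stop=t_stop,
    )


def simulate_force(trials: pd.DataFrame, spec: ForceSpec, seed: int = 0,
                   times: np.ndarray | None = None,
                   align: str = "movement_on") -> tuple[np.ndarray, np.ndarray]:
    """Pulling-force traces on a common clock relative to ``align``.

    Returns ``(times, traces)`` with ``traces`` of shape (trials, len(times)).
    The trace is ~0 before pull onset, ramps linearly over ``ramp_ms`` to the
    condition's level, holds until release, ramps back down, plus additive
    Gaussian noise of sd ``noise_sd``.
    """
    if times is None:
        times = np.arange(-2000.0, 2001.0, 20.0)
    times = np.asarray(times, dtype=float)
    rng = stage_rng(seed, "force")
    align_t = trials[align].to_numpy()
    pull = trials["pull_on"].to_numpy() - align_t
    release = trials["release"].to_numpy() - align_t
    level = np.where(trials["force"].to_numpy() == "high", spec.high_level, spec.low_level)

    t = times[None, :]
    up = np.clip((t - pull[:, None]) / spec.ramp_ms, 0.0, 1.0)
    down = np.clip((t - release[:, None]) / spec.ramp_ms, 0.0, 1.0)
    traces = level[:, None] * (up - down)
    if spec.noise_sd > 0:
        traces = traces + rng.normal(0.0, spec.noise_sd, traces.shape)
    return times, traces


def make_population(
    n_grip_only: int = 40,
    n_mixed: int = 20,
    n_force_only: int = 2,
    n_null: int = 38,
    gain: float = 0.5,
    baseline_hz: float = 20.0,
    coding_scheme: str = "static",
    time_amp: float = 0.0,
    seed: int = 0,
) -> list[NeuronSpec]:
    """Build a population mirroring the selectivity classes of a session.

    ``gain`` = 0.5 gives a 3:1 rate ratio between preferred and
    anti-preferred conditions inside the effect window. Under the "static"
    scheme each selective unit carries one long window from grip cue to
    object release (grip) or from go to release (force); under "dynamic"
    each unit gets a brief effect window whose onset is drawn uniformly
    across the perimovement period, so the population forms a chain of
    successively selective units.

    ``time_amp`` > 0 adds a condition-independent perimovement activation
    bump (gain 1 + time_amp * gaussian, random per-unit latency) to every
    unit, emulating the task-locked firing that dominates population
    variance in recorded sessions.
    """
    if coding_scheme not in ("static", "dynamic"):
        raise ValueError(f"unknown coding_scheme {coding_scheme!r}")
    rng = stage_rng(seed, "population")
    specs: list[NeuronSpec] = []

    def time_profile():
        if time_amp <= 0:
            return None
        # trial-clock bump near the default go/movement period
        center = rng.uniform(2200.0, 3000.0)
        width = rng.uniform(250.0, 500.0)
        amp = time_amp * rng.uniform(0.5, 1.5)
        return lambda t, c=center, w=width, a=amp: 1.0 + a * np.exp(-0.5 * ((t - c) / w) ** 2)

    def windows() -> tuple[tuple[str, float, float], tuple[str, float, float]]:
        if coding_scheme == "static":
            return ("cue_on", 0.0, 4000.0), ("go", 0.0, 3000.0)
        onset_g = rng.uniform(-800.0, 1200.0)  # relative to movement onset
        onset_f = rng.uniform(0.0, 1200.0)
        width = 300.0
        return ("movement_on", onset_g, onset_g + width), ("movement_on", onset_f, onset_f + width)

    for _ in range(n_grip_only):
        wg, wf = windows()
        specs.append(NeuronSpec(baseline_hz=baseline_hz, time_profile=time_profile(),
                                grip_effect=gain * rng.choice([-1, 1]),
                                grip_window=wg, force_window=wf, coding_scheme=coding_scheme))
    for _ in range(n_mixed):
        wg, wf = windows()
        specs.append(NeuronSpec(baseline_hz=baseline_hz, time_profile=time_profile(),
                                grip_effect=gain * rng.choice([-1, 1]),
                                force_effect=gain * rng.choice([-1, 1]),
                                grip_window=wg, force_window=wf, coding_scheme=coding_scheme))
    for _ in range(n_force_only):
        wg, wf = windows()
        specs.append(NeuronSpec(baseline_hz=baseline_hz, time_profile=time_profile(),
                                force_effect=gain * rng.choice([-1, 1]),
                                grip_window=wg, force_window=wf, coding_scheme=coding_scheme))
    for _ in range(n_null):
        specs.append(NeuronSpec(baseline_hz=baseline_hz, time_profile=time_profile(),
                                coding_scheme=coding_scheme))
    return specs


def generate_session(config: TaskConfig, neurons: Sequence[NeuronSpec] | None = None,
                     force_spec: ForceSpec | None = None):
    """Convenience wrapper: trials + spikes + force traces from one seed."""
    if neurons is None:
        neurons = make_population(seed=config.seed)
    if force_spec is None:
        force_spec = ForceSpec()
    trials = generate_trials(config)
    spikes = simulate_spikes(trials, neurons, seed=config.seed)
    times, force = simulate_force(trials, force_spec, seed=config.seed)
    return trials, spikes, (times, force)
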