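"""Firing-rate estimation: causal exponential smoothing and coarse binning.

Two time grids are used downstream: a fine 20 ms grid of causally smoothed
rates (selectivity analyses) and a coarse grid of 100 ms count windows whose
centers step every 80 ms, giving 51 bins across -2,000..+2,000 ms around
movement onset (decoding analyses).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import SpikeData

__all__ = ["RateTensor", "smooth_rates", "bin_rates", "DEFAULT_WINDOW"]

DEFAULT_WINDOW = (-2000.0, 2000.0)

#: causal kernel is truncated at this many decay constants (<1% mass lost)
KERNEL_TRUNCATION_TAUS = 5.0


@dataclass
class RateTensor:
    """units x trials x timebins firing rates (spikes/s) with alignment metadata."""

    rates: np.ndarray
    bin_centers: np.ndarray  # ms relative to the alignment event
    alignment: str
    kernel: dict

    @property
    def n_units(self) -> int:
        return self.rates.shape[0]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[2]

    def __post_init__(self) -> None:
        steps = np.diff(self.bin_centers)
        if len(steps) and (steps <= 0).any():
            raise ValueError("bin_centers must be strictly increasing")


def _check_window(spikes: SpikeData, align_t: np.ndarray, lo: float, hi: float,
                  lookback_ms: float) -> None:
    """Every trial must record [lo - lookback, hi] around its alignment time."""
    need_lo = align_t + lo - lookback_ms
    need_hi = align_t + hi
    bad = np.flatnonzero((need_lo < spikes.t_start) | (need_hi > spikes.t_stop))
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"analysis window [{lo}, {hi}] ms exceeds the recorded extent of "
            f"trial {int(spikes.trial_ids[i])} "
            f"(recorded [{spikes.t_start[i] - align_t[i]:.0f}, "
            f"{spikes.t_stop[i] - align_t[i]:.0f}] ms relative to alignment)"
        )


def smooth_rates(spikes: SpikeData, trials: pd.DataFrame, tau_ms: float = 100.0,
                 step_ms: float = 20.0, window: tuple[float, float] = DEFAULT_WINDOW,
                 align: str = "movement_on") -> RateTensor:
    """Causal exponential filtering of spike trains.

    Each spike contributes (1/tau) * exp(-(t - t_spike)/tau) for
    t >= t_spike; the unit-area kernel makes the trace an instantaneous rate
    in spikes/s. Evaluated every ``step_ms`` on a grid aligned to ``align``.
    """
    lo, hi = window
    align_t = trials[align].to_numpy(dtype=float)
    lookback = KERNEL_TRUNCATION_TAUS * tau_ms
    _check_window(spikes, align_t, lo, hi, lookback)
    centers = np.arange(lo, hi + step_ms / 2, step_ms)
    units = spikes.included_units()
    tau_s = tau_ms / 1000.0

    out = np.zeros((len(units), spikes.n_trials, len(centers)))
    for ui, u in enumerate(units):
        for i in range(spikes.n_trials):
            st = spikes.spikes[u][i] - align_t[i]
            st = st[(st >= lo - lookback) & (st <= hi)]
            if len(st) == 0:
                continue
            dt = centers[None, :] - st[:, None]  # ms
            k = np.where((dt >= 0) & (dt <= lookback), np.exp(-dt / tau_ms), 0.0)
            out[ui, i] = k.sum(axis=0) / tau_s
    return RateTensor(out, centers, align, {"type": "exponential", "tau_ms": tau_ms,
                                            "step_ms": step_ms})


def bin_rates(spikes: SpikeData, trials: pd.DataFrame, bin_ms: float = 100.0,
              step_ms: float = 80.0, window: tuple[float, float] = DEFAULT_WINDOW,
              align: str = "movement_on") -> RateTensor:
    """Spike counts in sliding ``bin_ms`` windows, as spikes/s.

    With the defaults, 100 ms windows whose centers step every 80 ms span
    -2,000..+2,000 ms and give 51 bins (adjacent windows overlap 20 ms).
    """
    lo, hi = window
    align_t = trials[align].to_numpy(dtype=float)
    _check_window(spikes, align_t, lo - bin_ms / 2, hi + bin_ms / 2, 0.0)
    centers = np.arange(lo, hi + step_ms / 2, step_ms)
    edges_lo = centers - bin_ms / 2
    units = spikes.included_units()

    out = np.zeros((len(units), spikes.n_trials, len(centers)))
    for ui, u in enumerate(units):
        for i in range(spikes.n_trials):
            st = spikes.spikes[u][i] - align_t[i]
            if len(st) == 0:
                continue
            counts = ((st[:, None] >= edges_lo[None, :])
                      & (st[:, None] < edges_lo[None, :] + bin_ms)).sum(axis=0)
            out[ui, i] = counts / (bin_ms / 1000.0)
    return RateTensor(out, centers, align, {"type": "boxcar", "width_ms": bin_ms,
                                            "step_ms": step_ms})
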