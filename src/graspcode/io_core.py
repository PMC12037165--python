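"""Data containers, on-disk formats, validation, and the result store.

Trial tables travel as tab-separated text (human-auditable event times);
spike trains, force traces and analysis arrays live in one HDF5 container.
All times are ms on a per-trial clock; downstream analyses align to
movement onset.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "EVENT_COLUMNS",
    "SpikeData",
    "ResultStore",
    "validate_trials",
    "select_correct_trials",
    "write_dataset",
    "read_inputs",
]

log = logging.getLogger("graspcode")

#: task events in their required temporal order
EVENT_COLUMNS = (
    "switch_on",
    "cue_on",
    "cue_off",
    "go",
    "movement_on",
    "touch",
    "pull_on",
    "release",
    "reward",
)

_TRIAL_COLUMNS = ("trial_id", "subject", "grip", "force", "correct") + EVENT_COLUMNS


@dataclass
class SpikeData:
    """Per-unit, per-trial spike trains.

    ``spikes[u][i]`` is a sorted array of spike times (ms, trial clock) for
    unit ``u`` on trial ``i``; ``included`` flags units on motor-cortex
    electrodes — excluded units are retained but never analyzed.
    """

    unit_ids: np.ndarray
    included: np.ndarray
    spikes: list  # list[unit] of list[trial] of ndarray
    trial_ids: np.ndarray
    t_start: np.ndarray  # per-trial recording start (ms, trial clock)
    t_stop: np.ndarray

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_trials(self) -> int:
        return len(self.trial_ids)

    def included_units(self) -> np.ndarray:
        """Indices of analyzable units; error if there are none."""
        idx = np.flatnonzero(self.included)
        if idx.size == 0:
            raise ValueError("no analyzable units: every unit has included=False")
        return idx

    def subset_trials(self, trial_mask: np.ndarray) -> "SpikeData":
        keep = np.flatnonzero(np.asarray(trial_mask))
        return SpikeData(
            unit_ids=self.unit_ids,
            included=self.included,
            spikes=[[unit[i] for i in keep] for unit in self.spikes],
            trial_ids=self.trial_ids[keep],
            t_start=self.t_start[keep],
            t_stop=self.t_stop[keep],
        )


def validate_trials(trials: pd.DataFrame) -> None:
    """Schema and event-order validation; raises ValueError naming the row."""
    missing = [c for c in _TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    bad_grip = ~trials["grip"].isin(["side", "precision"])
    if (bad_grip & trials["correct"]).any():
        row = int(trials.index[bad_grip & trials["correct"]][0])
        raise ValueError(f"invalid or missing grip label on correct trial row {row}")
    bad_force = ~trials["force"].isin(["low", "high"])
    if (bad_force & trials["correct"]).any():
        row = int(trials.index[bad_force & trials["correct"]][0])
        raise ValueError(f"invalid or missing force label on correct trial row {row}")
    ev = trials.loc[trials["correct"], list(EVENT_COLUMNS)].to_numpy(dtype=float)
    if ev.size:
        diffs = np.diff(ev, axis=1)
        bad = np.flatnonzero((diffs < 0).any(axis=1))
        if bad.size:
            row = int(trials.index[trials["correct"]][bad[0]])
            pair_idx = int(np.argmax(diffs[bad[0]] < 0))
            a, b = EVENT_COLUMNS[pair_idx], EVENT_COLUMNS[pair_idx + 1]
            raise ValueError(
                f"event order violated on correct trial row {row}: {b} < {a}"
            )


def select_correct_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Correct trials only; logs per-condition counts; error if empty."""
    out = trials.loc[trials["correct"]].reset_index(drop=True)
    if len(out) == 0:
        raise ValueError("no correct trials in the table")
    counts = out.groupby(["grip", "force"], observed=True).size()
    log.info("correct trials per condition:\n%s", counts.to_string())
    return out


# --------------------------------------------------------------------------
# on-disk dataset: trials.tsv + data.h5


def write_dataset(path: str | Path, trials: pd.DataFrame, spikes: SpikeData,
                  force: tuple[np.ndarray, np.ndarray] | None = None) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    trials.to_csv(path / "trials.tsv", sep="\t", index=False)
    with h5py.File(path / "data.h5", "w") as f:
        g = f.create_group("spikes")
        g.attrs["n_units"] = spikes.n_units
        g.create_dataset("unit_ids", data=np.asarray(spikes.unit_ids))
        g.create_dataset("included", data=np.asarray(spikes.included, dtype=bool))
        g.create_dataset("trial_ids", data=np.asarray(spikes.trial_ids))
        g.create_dataset("t_start", data=np.asarray(spikes.t_start))
        g.create_dataset("t_stop", data=np.asarray(spikes.t_stop))
        # ragged trains flattened with offsets
        flat, offsets = [], [0]
        for unit in spikes.spikes:
            for train in unit:
                flat.append(np.asarray(train, dtype=float))
                offsets.append(offsets[-1] + len(train))
        g.create_dataset("times", data=np.concatenate(flat) if flat else np.empty(0))
        g.create_dataset("offsets", data=np.asarray(offsets, dtype=np.int64))
        if force is not None:
            times, traces = force
            gf = f.create_group("force")
            gf.create_dataset("times", data=np.asarray(times))
            gf.create_dataset("traces", data=np.asarray(traces))
    return path


def read_inputs(path: str | Path):
    """Read ``trials.tsv`` + ``data.h5`` back into validated objects."""
    path = Path(path)
    tsv, h5 = path / "trials.tsv", path / "data.h5"
    if not tsv.exists() or not h5.exists():
        raise FileNotFoundError(f"dataset at {path} needs trials.tsv and data.h5")
    trials = pd.read_csv(tsv, sep="\t")
    trials["correct"] = trials["correct"].astype(bool)
    validate_trials(trials)
    with h5py.File(h5, "r") as f:
        g = f["spikes"]
        times = g["times"][...]
        offsets = g["offsets"][...]
        n_units = int(g.attrs["n_units"])
        trial_ids = g["trial_ids"][...]
        n_trials = len(trial_ids)
        trains: list[list[np.ndarray]] = []
        k = 0
        for _ in range(n_units):
            unit = []
            for _ in range(n_trials):
                unit.append(times[offsets[k]:offsets[k + 1]])
                k += 1
            trains.append(unit)
        spikes = SpikeData(
            unit_ids=g["unit_ids"][...],
            included=g["included"][...].astype(bool),
            spikes=trains,
            trial_ids=trial_ids,
            t_start=g["t_start"][...],
            t_stop=g["t_stop"][...],
        )
        force = None
        if "force" in f:
            force = (f["force/times"][...], f["force/traces"][...])
    spikes.included_units()  # raises on a dataset with nothing to analyze
    return trials, spikes, force


# --------------------------------------------------------------------------
# result store


class ResultStore:
    """Stage-keyed container for analysis outputs.

    Arrays live in ``results.h5`` under ``<stage>/<name>``; the config and
    per-stage seeds that produced them sit alongside in ``provenance.json``,
    so any stored result can be regenerated from the store alone.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.path.mkdir(parents=True, exist_ok=True)
        self._h5 = self.path / "results.h5"
        self._prov = self.path / "provenance.json"

    def save_arrays(self, stage: str, seed: int | None = None, **arrays) -> None:
        with h5py.File(self._h5, "a") as f:
            if stage in f:
                del f[stage]
            g = f.create_group(stage)
            if seed is not None:
                g.attrs["seed"] = int(seed)
            for name, arr in arrays.items():
                g.create_dataset(name, data=np.asarray(arr))
        log.info("stored stage %r (%d arrays)", stage, len(arrays))

    def load_arrays(self, stage: str) -> dict[str, np.ndarray]:
        with h5py.File(self._h5, "r") as f:
            if stage not in f:
                raise KeyError(f"stage {stage!r} not in result store")
            return {k: f[stage][k][...] for k in f[stage]}

    def stages(self) -> list[str]:
        if not self._h5.exists():
            return []
        with h5py.File(self._h5, "r") as f:
            return sorted(f.keys())

    def save_config(self, config: dict) -> None:
        self._prov.write_text(json.dumps(config, indent=2, default=str))

    def load_config(self) -> dict:
        return json.loads(self._prov.read_text())
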