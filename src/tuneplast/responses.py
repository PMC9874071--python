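"""From trial-level spikes to per-unit frequency × intensity response maps.

Spikes are counted in a response window (default 70–270 ms after tone
onset, skipping the 50 ms on-ramp plus response latency) and in an
equal-length spontaneous window immediately preceding onset.  Per-unit
maps are expressed on three scales:

``rate``
    mean evoked spike count per trial divided by the window length
    (spikes/s).
``normalized``
    mean counts divided by the unit's single largest mean count, taken
    jointly over the pre- and post-pairing maps, so the joint maximum is
    exactly 1 and post-pairing amplitude changes stay visible.
``zscore``
    (mean evoked count − mean spontaneous count) / SD of spontaneous
    counts, computed per phase with that phase's spontaneous statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimgrid import StimulusGrid

__all__ = [
    "TrialTable",
    "SpontaneousStats",
    "ResponseMap",
    "count_spikes_in_window",
    "spontaneous_stats",
    "zscore_map",
    "normalize_maps",
    "rate_map",
    "average_over_intensities",
]

PHASES = ("pre", "post")

#: Default evoked-response window (ms after stimulus onset), half-open.
RESPONSE_WINDOW_MS = (70.0, 270.0)
#: Default spontaneous window (ms re onset): the 200 ms before the tone.
SPONT_WINDOW_MS = (-200.0, 0.0)

COUNT_COLUMNS = [
    "unit_id", "phase", "block", "frequency_hz", "intensity_db",
    "evoked_count", "spont_count",
]
EVENT_COLUMNS = [
    "unit_id", "phase", "block", "frequency_hz", "intensity_db", "spike_time_ms",
]


def count_spikes_in_window(spike_times_ms, t0_ms: float, t1_ms: float) -> int:
    """Number of spikes with t0 <= t < t1 (half-open, so adjacent windows never
    double-count a spike)."""
    if not t0_ms < t1_ms:
        raise ValueError("window start must precede window end")
    t = np.asarray(spike_times_ms, dtype=float)
    if t.size == 0:
        return 0
    return int(np.count_nonzero((t >= t0_ms) & (t < t1_ms)))


@dataclass(frozen=True)
class SpontaneousStats:
    """Mean and sample SD of per-trial spontaneous-window spike counts."""

    mean_count: float
    sd_count: float
    n_samples: int

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("spontaneous statistics need at least 2 samples")
        if self.sd_count < 0:
            raise ValueError("sd_count must be non-negative")


class TrialTable:
    """Long-format trial-level spike records for one or many units.

    One row per trial with columns ``unit_id, phase, block, frequency_hz,
    intensity_db, evoked_count, spont_count`` (the *counts* dialect).  The
    *events* dialect — one row per spike with ``spike_time_ms`` relative
    to tone onset, plus a blank-time row for spikeless trials — is
    converted to counts on read via the response/spontaneous windows.
    """

    def __init__(self, records: pd.DataFrame, grid: StimulusGrid | None = None):
        missing = set(COUNT_COLUMNS) - set(records.columns)
        if missing:
            raise ValueError(f"trial table missing columns: {sorted(missing)}")
        bad_phase = set(records["phase"].unique()) - set(PHASES)
        if bad_phase:
            raise ValueError(f"phase must be one of {PHASES}; got {sorted(bad_phase)}")
        for col in ("evoked_count", "spont_count"):
            vals = records[col].to_numpy()
            if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
                raise ValueError(f"{col} must hold non-negative integers")
        if grid is not None:
            known = set(np.round(np.asarray(grid.frequencies_hz, float), 6))
            seen = set(np.round(records["frequency_hz"].unique().astype(float), 6))
            if not seen <= known:
                raise ValueError("trial table contains frequencies outside the grid")
        self.records = records.reset_index(drop=True)
        self.grid = grid

    @property
    def unit_ids(self):
        return sorted(self.records["unit_id"].unique())

    def for_unit(self, unit_id, phase: str) -> pd.DataFrame:
        r = self.records
        return r[(r["unit_id"] == unit_id) & (r["phase"] == phase)]

    def to_csv(self, path) -> None:
        self.records[COUNT_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, grid: StimulusGrid | None = None) -> "TrialTable":
        return cls(pd.read_csv(path), grid=grid)

    @classmethod
    def from_events(
        cls,
        events: pd.DataFrame,
        grid: StimulusGrid | None = None,
        response_window_ms=RESPONSE_WINDOW_MS,
        spont_window_ms=SPONT_WINDOW_MS,
    ) -> "TrialTable":
        """Convert the one-row-per-spike dialect to per-trial counts.

        ``spike_time_ms`` may be NaN/blank to register a trial with no
        spikes.  Spontaneous counts come from ``spont_window_ms`` (times
        relative to onset, negative = before the tone).
        """
        missing = set(EVENT_COLUMNS) - set(events.columns)
        if missing:
            raise ValueError(f"event table missing columns: {sorted(missing)}")
        keys = ["unit_id", "phase", "block", "frequency_hz", "intensity_db"]
        t = events["spike_time_ms"].astype(float)
        evoked = (t >= response_window_ms[0]) & (t < response_window_ms[1])
        spont = (t >= spont_window_ms[0]) & (t < spont_window_ms[1])
        counts = (
            events.assign(evoked_count=evoked.astype(int), spont_count=spont.astype(int))
            .groupby(keys, sort=True, as_index=False)[["evoked_count", "spont_count"]]
            .sum()
        )
        return cls(counts, grid=grid)

    @classmethod
    def events_from_csv(cls, path, grid: StimulusGrid | None = None, **kw) -> "TrialTable":
        return cls.from_events(pd.read_csv(path), grid=grid, **kw)


def spontaneous_stats(trials: TrialTable, unit_id, phase: str) -> SpontaneousStats:
    """Mean and sample SD of spontaneous-window counts for one unit/phase."""
    counts = trials.for_unit(unit_id, phase)["spont_count"].to_numpy(dtype=float)
    return spontaneous_stats_from_counts(counts)


def spontaneous_stats_from_counts(counts) -> SpontaneousStats:
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least 2 spontaneous samples")
    return SpontaneousStats(
        mean_count=float(np.mean(counts)),
        sd_count=float(np.std(counts, ddof=1)),
        n_samples=int(counts.size),
    )


@dataclass
class ResponseMap:
    """Per-unit, per-phase response matrix indexed (intensity, frequency)."""

    unit_id: object
    phase: str
    scale: str  # rate | normalized | zscore
    values: np.ndarray
    grid: StimulusGrid

    def __post_init__(self):
        expected = (self.grid.n_intensities, self.grid.n_frequencies)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != expected:
            raise ValueError(
                f"map shape {self.values.shape} does not match grid {expected}"
            )
        if self.scale not in ("rate", "normalized", "zscore"):
            raise ValueError(f"unknown scale {self.scale!r}")

    def frequency_profile(self) -> np.ndarray:
        return average_over_intensities(self.values)


def _mean_count_matrix(trials: TrialTable, unit_id, phase: str,
                       grid: StimulusGrid) -> np.ndarray:
    """Mean evoked count per (intensity, frequency) cell, averaged over blocks."""
    sub = trials.for_unit(unit_id, phase)
    if sub.empty:
        raise ValueError(f"no trials for unit {unit_id!r} phase {phase!r}")
    piv = sub.pivot_table(
        index="intensity_db", columns="frequency_hz",
        values="evoked_count", aggfunc="mean",
    )
    # frequencies are matched on 6-decimal keys: text serialisation may
    # truncate the last couple of bits of a float
    piv.columns = np.round(piv.columns.to_numpy(dtype=float), 6)
    piv.index = np.round(piv.index.to_numpy(dtype=float), 6)
    piv = piv.reindex(index=np.round(np.asarray(grid.intensities_db, float), 6),
                      columns=np.round(np.asarray(grid.frequencies_hz, float), 6))
    if piv.isna().any().any():
        raise ValueError(
            f"unit {unit_id!r} phase {phase!r} is missing stimulus combinations"
        )
    return piv.to_numpy(dtype=float)


def rate_map(trials: TrialTable, unit_id, phase: str, grid: StimulusGrid,
             window_ms=RESPONSE_WINDOW_MS) -> ResponseMap:
    """Mean firing rate (spikes/s) per stimulus over the response window."""
    window_s = (window_ms[1] - window_ms[0]) / 1000.0
    counts = _mean_count_matrix(trials, unit_id, phase, grid)
    return ResponseMap(unit_id, phase, "rate", counts / window_s, grid)


def zscore_map(trials: TrialTable, unit_id, phase: str, grid: StimulusGrid,
               spont: SpontaneousStats | None = None) -> ResponseMap:
    """z-scored map: (mean evoked − mean spontaneous) / SD(spontaneous).

    Spontaneous statistics are per phase — pairing may change baseline
    firing, and the z-score is defined against the same condition's
    baseline.
    """
    if spont is None:
        spont = spontaneous_stats(trials, unit_id, phase)
    if spont.sd_count <= 0:
        raise ValueError(
            f"unit {unit_id!r} phase {phase!r}: spontaneous SD is zero, "
            "z-score undefined"
        )
    counts = _mean_count_matrix(trials, unit_id, phase, grid)
    z = (counts - spont.mean_count) / spont.sd_count
    return ResponseMap(unit_id, phase, "zscore", z, grid)


def normalize_maps(pre: ResponseMap, post: ResponseMap) -> tuple[ResponseMap, ResponseMap]:
    """Normalize a unit's pre/post rate maps by their joint maximum.

    The maximum is taken jointly over both phases so that a post-pairing
    amplitude reduction remains visible (the post map then peaks below 1).
    """
    if pre.unit_id != post.unit_id:
        raise ValueError("pre and post maps belong to different units")
    joint_max = max(float(np.max(pre.values)), float(np.max(post.values)))
    if joint_max <= 0:
        raise ValueError(f"unit {pre.unit_id!r} has no positive response to normalize")
    return (
        ResponseMap(pre.unit_id, pre.phase, "normalized", pre.values / joint_max, pre.grid),
        ResponseMap(post.unit_id, post.phase, "normalized", post.values / joint_max, post.grid),
    )


def average_over_intensities(values: np.ndarray) -> np.ndarray:
    """Collapse an (intensity × frequency) matrix to a per-frequency profile."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-D (intensity, frequency) matrix")
    return values.mean(axis=0)
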