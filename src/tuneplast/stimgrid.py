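"""Stimulus geometry: log-spaced frequency grids, octave arithmetic, trial schedules.

All downstream analysis works on an octave axis relative to 1 kHz,
``x = log2(f / 1000)``: tuning widths and best-frequency shifts are
reported in octaves, and a Gaussian that is symmetric on the octave axis
matches the FWHM-in-octaves convention used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StimulusGrid",
    "TrialSchedule",
    "ConditioningSpec",
    "make_frequency_grid",
    "octave_distance",
    "make_trial_schedule",
    "default_grid",
]

#: Reference frequency (Hz) for the internal octave axis.
F_REF_HZ = 1000.0

#: Stimulus intensities (dB SPL) of the standard design.
DEFAULT_INTENSITIES_DB = (50.0, 60.0, 70.0, 80.0)


def octave_distance(f_ref_hz: float, f_hz) -> float:
    """Signed distance from ``f_ref_hz`` to ``f_hz`` in octaves, log2(f/f_ref).

    Doubling the frequency is +1 octave; halving it is −1.
    """
    f_ref_hz = np.asarray(f_ref_hz, dtype=float)
    f_hz = np.asarray(f_hz, dtype=float)
    if np.any(f_ref_hz <= 0) or np.any(f_hz <= 0):
        raise ValueError("frequencies must be positive to measure octave distance")
    out = np.log2(f_hz / f_ref_hz)
    return float(out) if out.ndim == 0 else out


def to_octaves(f_hz):
    """Frequency (Hz) -> octaves re 1 kHz."""
    return octave_distance(F_REF_HZ, f_hz)


def from_octaves(x_oct):
    """Octaves re 1 kHz -> frequency (Hz)."""
    return F_REF_HZ * np.power(2.0, np.asarray(x_oct, dtype=float))


@dataclass(frozen=True)
class StimulusGrid:
    """A frequency × intensity pure-tone stimulus set with log2-uniform frequencies."""

    frequencies_hz: tuple
    intensities_db: tuple = DEFAULT_INTENSITIES_DB
    steps_per_octave: int = 4

    def __post_init__(self):
        f = np.asarray(self.frequencies_hz, dtype=float)
        i = np.asarray(self.intensities_db, dtype=float)
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(np.diff(i) <= 0):
            raise ValueError("intensities must be strictly increasing")
        steps = np.diff(np.log2(f))
        if f.size > 1 and np.max(np.abs(steps - 1.0 / self.steps_per_octave)) > 1e-9:
            raise ValueError(
                "frequency spacing is not 1/%d octave" % self.steps_per_octave
            )

    @property
    def n_frequencies(self) -> int:
        return len(self.frequencies_hz)

    @property
    def n_intensities(self) -> int:
        return len(self.intensities_db)

    @property
    def n_combinations(self) -> int:
        return self.n_frequencies * self.n_intensities

    @property
    def octaves(self) -> np.ndarray:
        """Frequency axis in octaves re 1 kHz."""
        return np.log2(np.asarray(self.frequencies_hz, dtype=float) / F_REF_HZ)

    def nearest_frequency(self, f_hz: float) -> float:
        """Grid frequency nearest to ``f_hz`` in log space."""
        f = np.asarray(self.frequencies_hz, dtype=float)
        return float(f[np.argmin(np.abs(np.log2(f) - np.log2(f_hz)))])

    def combinations(self) -> pd.DataFrame:
        """All frequency × intensity combinations, frequency-major order."""
        freqs = np.repeat(self.frequencies_hz, self.n_intensities)
        ints = np.tile(self.intensities_db, self.n_frequencies)
        return pd.DataFrame({"frequency_hz": freqs, "intensity_db": ints})


def make_frequency_grid(
    f_min_hz: float,
    f_max_hz: float,
    steps_per_octave: int = 4,
    intensities_db=DEFAULT_INTENSITIES_DB,
) -> StimulusGrid:
    """Build a log2-uniform frequency grid spanning an exact whole number of octaves.

    The grid is constructed in log2 space and exponentiated, so the octave
    landmarks (1, 2, 4, ... kHz for a 1 kHz start) come out exact to machine
    precision.  With the standard 1–32 kHz span and 4 steps per octave this
    yields the 21-frequency quarter-octave set whose consecutive ratio is
    2^(1/4) ≈ 1.1892.

    Raises
    ------
    ValueError
        If the span ``f_max_hz / f_min_hz`` is not a power of 2, or the
        endpoints / step count are invalid.
    """
    if f_min_hz <= 0:
        raise ValueError("f_min_hz must be positive")
    if steps_per_octave < 1:
        raise ValueError("steps_per_octave must be >= 1")
    span_oct = np.log2(f_max_hz / f_min_hz)
    if span_oct <= 0:
        raise ValueError("f_max_hz must exceed f_min_hz")
    n_oct = round(span_oct)
    if abs(span_oct - n_oct) > 1e-9:
        raise ValueError(
            f"frequency span must be a power of 2; got ratio "
            f"{f_max_hz / f_min_hz:g} ({span_oct:.6f} octaves)"
        )
    n = n_oct * steps_per_octave + 1
    log2f = np.log2(f_min_hz) + np.arange(n) / steps_per_octave
    freqs = np.power(2.0, log2f)
    freqs[0] = f_min_hz
    freqs[-1] = f_max_hz
    return StimulusGrid(
        frequencies_hz=tuple(freqs),
        intensities_db=tuple(float(v) for v in intensities_db),
        steps_per_octave=int(steps_per_octave),
    )


def default_grid() -> StimulusGrid:
    """The standard design: 21 quarter-octave tones 1–32 kHz × 50–80 dB SPL."""
    return make_frequency_grid(1000.0, 32000.0, 4)


@dataclass(frozen=True)
class ConditioningSpec:
    """Pairing protocol metadata: one tone presented repeatedly between phases."""

    pairing_frequency_hz: float
    level_db: float = 80.0
    n_presentations: int = 30
    isi_s: float = 30.0

    def __post_init__(self):
        if self.n_presentations <= 0:
            raise ValueError("n_presentations must be positive")
        if self.pairing_frequency_hz <= 0:
            raise ValueError("pairing frequency must be positive")

    @property
    def pairing_oct(self) -> float:
        return to_octaves(self.pairing_frequency_hz)


@dataclass(frozen=True)
class TrialSchedule:
    """Blocked pseudo-random presentation order of a stimulus grid.

    Each block is an independent uniform permutation of every
    frequency × intensity combination; the per-block RNG substream is
    derived from ``(seed, block)`` so appending blocks never changes
    earlier ones.
    """

    entries: pd.DataFrame = field(repr=False)  # block, frequency_hz, intensity_db
    seed: int = 0

    @property
    def n_trials(self) -> int:
        return len(self.entries)

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)


def make_trial_schedule(grid: StimulusGrid, n_blocks: int, seed: int) -> TrialSchedule:
    """Schedule ``n_blocks`` pseudo-random passes through the full stimulus set.

    For the 21 × 4 design and 10 blocks this gives 840 trials with every
    combination presented exactly 10 times.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    combos = grid.combinations()
    if combos.empty:
        raise ValueError("stimulus grid has no combinations")
    blocks = []
    for b in range(n_blocks):
        rng = np.random.default_rng([int(seed), b])
        perm = rng.permutation(len(combos))
        blk = combos.iloc[perm].reset_index(drop=True)
        blk.insert(0, "block", b)
        blocks.append(blk)
    entries = pd.concat(blocks, ignore_index=True)
    return TrialSchedule(entries=entries, seed=int(seed))


def read_schedule_csv(path) -> pd.DataFrame:
    """Read a schedule written by :meth:`TrialSchedule.to_csv`."""
    df = pd.read_csv(path)
    required = {"block", "frequency_hz", "intensity_db"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"schedule file missing columns: {sorted(missing)}")
    return df
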