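"""Synthetic pairing experiments with known ground truth.

Each simulated unit is a Poisson spiker whose firing rate follows a
Gaussian frequency tuning curve on the octave axis,

    rate(f, I) = spont + s_I * (offset_rate + gain_rate * exp(-((x-bf)/sigma)^2/2))

with ``s_I`` a non-decreasing intensity multiplier for the 50-80 dB SPL
levels.  Evoked and spontaneous spike counts are drawn per trial as
Poisson with the 200 ms window.  Post-pairing, a cell-specific
:class:`PairingEffect` perturbs the unit's true parameters (additive BF
and FWHM changes, multiplicative gain/offset scaling) before sampling —
so every pipeline stage can be checked against exact ground truth.

Default cohort geometry follows the study design: 21 quarter-octave
frequencies x 4 intensities x 10 pseudo-random blocks, cells of
20/17/15/14 units (tPA-above / tPA-below / saline-above / saline-below),
and a conditioning tone placed ~0.5 octave from each unit's true BF on
its assigned side, snapped to the stimulus grid.  The default pairing
effect puts a -0.4 octave BF shift and a +0.12 octave FWHM increase in
the tPA/above cell only, mirroring the repulsive-shift/widening
phenomenology the analysis is built to detect; all other cells are null.

Randomness uses one master seed with per-unit derived substreams, so
changing one unit's parameters never perturbs another unit's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .responses import TrialTable
from .stimgrid import StimulusGrid, default_grid, make_trial_schedule, to_octaves
from .tuning import FWHM_FACTOR

__all__ = [
    "UnitTruth",
    "PairingEffect",
    "CohortConfig",
    "simulate_unit",
    "simulate_cohort",
    "simulate_parameter_cohort",
    "DEFAULT_N_UNITS",
    "DEFAULT_EFFECTS",
]

WINDOW_S = 0.2  # evoked and spontaneous count windows (200 ms)

DEFAULT_N_UNITS = {
    ("tPA", "above"): 20,
    ("tPA", "below"): 17,
    ("saline", "above"): 15,
    ("saline", "below"): 14,
}

DEFAULT_INTENSITY_SCALE = (0.55, 0.70, 0.85, 1.00)


@dataclass(frozen=True)
class UnitTruth:
    """Ground-truth generative parameters for one unit."""

    unit_id: str
    bf_oct: float
    sigma_oct: float
    gain_rate: float     # evoked peak rate above the tuning floor (spikes/s)
    offset_rate: float   # frequency-independent evoked rate (spikes/s)
    spont_rate: float    # baseline rate (spikes/s)
    intensity_scale: tuple = DEFAULT_INTENSITY_SCALE

    def __post_init__(self):
        if min(self.gain_rate, self.offset_rate, self.spont_rate) < 0:
            raise ValueError("rates must be non-negative")
        if self.sigma_oct <= 0:
            raise ValueError("sigma_oct must be positive")
        if np.any(np.diff(self.intensity_scale) < 0):
            raise ValueError("intensity_scale must be non-decreasing")

    @property
    def fwhm_oct(self) -> float:
        return FWHM_FACTOR * self.sigma_oct


@dataclass(frozen=True)
class PairingEffect:
    """Post-pairing change applied to a unit's true parameters."""

    d_bf_oct: float = 0.0
    d_fwhm_oct: float = 0.0
    gain_scale: float = 1.0
    offset_scale: float = 1.0

    def apply(self, truth: UnitTruth) -> UnitTruth:
        sigma = truth.sigma_oct + self.d_fwhm_oct / FWHM_FACTOR
        if sigma <= 0:
            raise ValueError("pairing effect would make sigma non-positive")
        gain = truth.gain_rate * self.gain_scale
        offset = truth.offset_rate * self.offset_scale
        if gain < 0 or offset < 0:
            raise ValueError("pairing effect would make a rate negative")
        return replace(truth, bf_oct=truth.bf_oct + self.d_bf_oct,
                       sigma_oct=sigma, gain_rate=gain, offset_rate=offset)


NULL_EFFECT = PairingEffect()

DEFAULT_EFFECTS = {
    ("tPA", "above"): PairingEffect(d_bf_oct=-0.4, d_fwhm_oct=+0.12),
    ("tPA", "below"): NULL_EFFECT,
    ("saline", "above"): NULL_EFFECT,
    ("saline", "below"): NULL_EFFECT,
}


@dataclass
class CohortConfig:
    """Configuration for a simulated pairing experiment."""

    n_units: dict = field(default_factory=lambda: dict(DEFAULT_N_UNITS))
    effects: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    grid: StimulusGrid = field(default_factory=default_grid)
    n_blocks: int = 10
    seed: int = 0
    pairing_offset_oct: float = 0.5  # distance of the conditioning tone from BF
    # truth distributions
    bf_margin_oct: float = 1.0       # keep true BFs this far inside the grid
    sigma_logmean: float = float(np.log(0.35))
    sigma_logsd: float = 0.30
    gain_shape: float = 10.0
    gain_scale: float = 5.0          # gamma mean 50 spikes/s
    offset_shape: float = 2.0
    offset_scale: float = 1.5        # gamma mean 3 spikes/s
    spont_shape: float = 5.0
    spont_scale: float = 1.0         # gamma mean 5 spikes/s

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is required")
        for cell, n in self.n_units.items():
            if n < 2:
                raise ValueError(f"cell {cell} needs >= 2 units, got {n}")
        missing = set(self.n_units) - set(self.effects)
        if missing:
            raise ValueError(f"no pairing effect given for cells {sorted(missing)}")


def _tuning_rate(truth: UnitTruth, x_oct: np.ndarray,
                 intensity_idx: np.ndarray) -> np.ndarray:
    scale = np.asarray(truth.intensity_scale, dtype=float)[intensity_idx]
    tuned = truth.offset_rate + truth.gain_rate * np.exp(
        -0.5 * ((x_oct - truth.bf_oct) / truth.sigma_oct) ** 2)
    return truth.spont_rate + scale * tuned


def simulate_unit(truth: UnitTruth, schedule, grid: StimulusGrid, phase: str,
                  effect: PairingEffect = NULL_EFFECT, seed: int = 0,
                  unit_index: int = 0) -> pd.DataFrame:
    """Sample one unit's trial counts for one phase.

    The post phase applies ``effect`` to the truth before sampling.
    Returns rows in the counts dialect of :class:`TrialTable`.
    """
    if phase not in ("pre", "post"):
        raise ValueError("phase must be 'pre' or 'post'")
    active = effect.apply(truth) if phase == "post" else truth
    entries = schedule.entries if hasattr(schedule, "entries") else schedule
    x = to_octaves(entries["frequency_hz"].to_numpy(dtype=float))
    ints = np.asarray(grid.intensities_db, dtype=float)
    i_idx = np.searchsorted(ints, entries["intensity_db"].to_numpy(dtype=float))
    rate = _tuning_rate(active, x, i_idx)
    if np.any(rate < 0):
        raise ValueError("negative firing rate in simulation")
    rng = np.random.default_rng([int(seed), int(unit_index),
                                 0 if phase == "pre" else 1])
    evoked = rng.poisson(WINDOW_S * rate)
    spont = rng.poisson(WINDOW_S * active.spont_rate, size=rate.size)
    return pd.DataFrame({
        "unit_id": truth.unit_id, "phase": phase,
        "block": entries["block"].to_numpy(),
        "frequency_hz": entries["frequency_hz"].to_numpy(),
        "intensity_db": entries["intensity_db"].to_numpy(),
        "evoked_count": evoked, "spont_count": spont,
    })


def _draw_truth(cfg: CohortConfig, unit_id: str, unit_index: int) -> UnitTruth:
    rng = np.random.default_rng([int(cfg.seed), 1_000_003, int(unit_index)])
    x = cfg.grid.octaves
    bf = rng.uniform(x[0] + cfg.bf_margin_oct, x[-1] - cfg.bf_margin_oct)
    sigma = float(np.exp(rng.normal(cfg.sigma_logmean, cfg.sigma_logsd)))
    gain = float(rng.gamma(cfg.gain_shape, cfg.gain_scale))
    offset = float(rng.gamma(cfg.offset_shape, cfg.offset_scale))
    spont = float(rng.gamma(cfg.spont_shape, cfg.spont_scale))
    return UnitTruth(unit_id=unit_id, bf_oct=bf, sigma_oct=sigma,
                     gain_rate=gain, offset_rate=offset, spont_rate=spont)


def _pairing_frequency(cfg: CohortConfig, truth: UnitTruth, side: str) -> float:
    """Conditioning tone ~0.5 oct from the true BF on the assigned side,
    snapped to the stimulus grid."""
    sign = 1.0 if side == "above" else -1.0
    target_hz = 1000.0 * 2.0 ** (truth.bf_oct + sign * cfg.pairing_offset_oct)
    f = cfg.grid.nearest_frequency(target_hz)
    # snapping cannot cross the BF for offsets >= one grid step, but guard anyway
    freqs = np.asarray(cfg.grid.frequencies_hz)
    while (to_octaves(f) - truth.bf_oct) * sign <= 0:
        idx = int(np.argmin(np.abs(freqs - f)))
        f = float(freqs[min(max(idx + int(sign), 0), freqs.size - 1)])
    return f


def simulate_cohort(cfg: CohortConfig) -> tuple[TrialTable, pd.DataFrame]:
    """Simulate a full cohort: both phases for every unit in every cell.

    Returns the trial table and a ground-truth table (one row per unit:
    cell assignment, pairing frequency, true pre and post parameters).
    """
    schedule = make_trial_schedule(cfg.grid, cfg.n_blocks, cfg.seed)
    frames, truth_rows = [], []
    unit_index = 0
    for (drug, side), n in sorted(cfg.n_units.items()):
        effect = cfg.effects[(drug, side)]
        for _ in range(n):
            uid = f"u{unit_index:03d}"
            truth = _draw_truth(cfg, uid, unit_index)
            pairing_hz = _pairing_frequency(cfg, truth, side)
            for phase in ("pre", "post"):
                frames.append(simulate_unit(truth, schedule, cfg.grid, phase,
                                            effect=effect, seed=cfg.seed,
                                            unit_index=unit_index))
            post = effect.apply(truth)
            truth_rows.append({
                "unit_id": uid, "drug": drug, "side": side,
                "pairing_frequency_hz": pairing_hz,
                "spont_rate": truth.spont_rate,
                "bf_oct_pre": truth.bf_oct, "bf_oct_post": post.bf_oct,
                "sigma_oct_pre": truth.sigma_oct, "sigma_oct_post": post.sigma_oct,
                "fwhm_oct_pre": truth.fwhm_oct, "fwhm_oct_post": post.fwhm_oct,
                "gain_rate_pre": truth.gain_rate, "gain_rate_post": post.gain_rate,
                "offset_rate_pre": truth.offset_rate,
                "offset_rate_post": post.offset_rate,
            })
            unit_index += 1
    trials = TrialTable(pd.concat(frames, ignore_index=True), grid=cfg.grid)
    return trials, pd.DataFrame(truth_rows)


def simulate_parameter_cohort(seed: int, n_units: dict | None = None,
                              unit_sd: float = 1.0, noise_sd: float = 1.0,
                              effects: dict | None = None) -> pd.DataFrame:
    """Draw a parameter-level cohort directly (no spike simulation).

    Per unit, pre/post values share a Gaussian random intercept
    (``unit_sd``) plus independent phase noise (``noise_sd``); ``effects``
    maps (drug, side) cells to an additive post-phase shift.  With no
    effects this is an exact null for calibrating the mixed ANOVA; with
    effects it is a power probe.  Returns the long format consumed by
    :func:`~tuneplast.stats.mixed_anova` (value column ``value``).
    """
    n_units = dict(DEFAULT_N_UNITS) if n_units is None else n_units
    effects = effects or {}
    rng = np.random.default_rng(int(seed))
    rows = []
    uidx = 0
    for (drug, side), n in sorted(n_units.items()):
        delta = float(effects.get((drug, side), 0.0))
        u = rng.normal(0.0, unit_sd, size=n)
        e = rng.normal(0.0, noise_sd, size=(n, 2))
        for i in range(n):
            uid = f"u{uidx:03d}"
            rows.append({"unit_id": uid, "drug": drug, "side": side,
                         "phase": "pre", "value": u[i] + e[i, 0]})
            rows.append({"unit_id": uid, "drug": drug, "side": side,
                         "phase": "post", "value": u[i] + e[i, 1] + delta})
            uidx += 1
    return pd.DataFrame(rows)
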