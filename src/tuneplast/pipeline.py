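"""End-to-end orchestration: trials -> maps -> fits -> stats -> population.

Every default in :class:`RunConfig` equals the study protocol value
(70-270 ms response window, 0.70 VAF inclusion, quarter-octave 1-32 kHz
grid at 50-80 dB SPL).  A run produces a result bundle whose pieces all
serialize to plain tabular text plus one machine-readable stats document
and a manifest recording config, versions, seeds and per-unit
exclusions (low VAF, pairing-frequency tie).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .population import align_fitted_curves, align_unfitted_curves, test_bf_shift
from .responses import (RESPONSE_WINDOW_MS, ResponseMap, TrialTable,
                        average_over_intensities, normalize_maps, rate_map,
                        zscore_map)
from .stats import PairingStudy, UnitRecord, classify_pairing_side
from .stimgrid import StimulusGrid, make_frequency_grid, to_octaves
from .tuning import GaussianTuningModel

__all__ = ["RunConfig", "PipelineError", "PipelineResult", "run_pipeline",
           "fit_all_units", "FIT_COLUMNS"]

FIT_COLUMNS = ["unit_id", "phase", "scale", "offset", "gain", "bf_hz",
               "bf_oct", "sigma_oct", "fwhm_oct", "vaf", "converged"]

CELLS = ("tPA/above", "tPA/below", "saline/above", "saline/below")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending units."""

    def __init__(self, stage: str, message: str, unit_ids=()):
        self.stage = stage
        self.unit_ids = list(unit_ids)
        suffix = f" (units: {', '.join(map(str, self.unit_ids))})" if unit_ids else ""
        super().__init__(f"[{stage}] {message}{suffix}")


@dataclass
class RunConfig:
    """Analysis configuration; defaults are the study protocol values."""

    f_min_hz: float = 1000.0
    f_max_hz: float = 32000.0
    steps_per_octave: int = 4
    intensities_db: tuple = (50.0, 60.0, 70.0, 80.0)
    window_ms: tuple = RESPONSE_WINDOW_MS
    scale: str = "zscore"          # scale used for the tuning fits
    vaf_threshold: float = 0.70
    n_restarts: int = 7
    width_floor: float = 0.0235
    floor_on: str = "fwhm"
    seed: int = 0

    def __post_init__(self):
        if not self.window_ms[0] < self.window_ms[1]:
            raise ValueError("window start must precede window end")
        if not 0.0 <= self.vaf_threshold <= 1.0:
            raise ValueError("vaf_threshold must lie in [0, 1]")

    def grid(self) -> StimulusGrid:
        return make_frequency_grid(self.f_min_hz, self.f_max_hz,
                                   self.steps_per_octave, self.intensities_db)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window_ms"] = list(self.window_ms)
        d["intensities_db"] = list(self.intensities_db)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {f.name: d[f.name] for f in dataclasses.fields(cls) if f.name in d}
        for key in ("window_ms", "intensities_db"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class UnitMaps:
    """All response maps and profiles for one unit."""

    unit_id: object
    maps: dict          # (phase, scale) -> ResponseMap
    profiles: dict      # (phase, scale) -> per-frequency profile


def preprocess_unit(trials: TrialTable, unit_id, grid: StimulusGrid) -> UnitMaps:
    maps, profiles = {}, {}
    rates = {}
    for phase in ("pre", "post"):
        rates[phase] = rate_map(trials, unit_id, phase, grid)
        maps[(phase, "rate")] = rates[phase]
        maps[(phase, "zscore")] = zscore_map(trials, unit_id, phase, grid)
    norm_pre, norm_post = normalize_maps(rates["pre"], rates["post"])
    maps[("pre", "normalized")] = norm_pre
    maps[("post", "normalized")] = norm_post
    for key, m in maps.items():
        profiles[key] = average_over_intensities(m.values)
    return UnitMaps(unit_id=unit_id, maps=maps, profiles=profiles)


def fit_all_units(trials: TrialTable, config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Fit every unit and phase on the configured scale.

    Returns the fits table (one row per unit x phase) and a dict
    ``unit_id -> {"pre": TuningFitResult, "post": ..., "maps": UnitMaps}``.
    """
    grid = config.grid()
    rows, per_unit = [], {}
    for uid in trials.unit_ids:
        try:
            um = preprocess_unit(trials, uid, grid)
        except ValueError as err:
            raise PipelineError("preprocess", str(err), [uid]) from err
        fits = {}
        for phase in ("pre", "post"):
            profile = um.profiles[(phase, config.scale)]
            try:
                model = GaussianTuningModel(
                    profile, grid.octaves, scale=config.scale,
                    width_floor=config.width_floor, floor_on=config.floor_on)
                fit = model.fit(n_restarts=config.n_restarts)
            except ValueError as err:
                raise PipelineError("fit", str(err), [uid]) from err
            fits[phase] = fit
            rows.append({
                "unit_id": uid, "phase": phase, "scale": config.scale,
                "offset": fit.offset, "gain": fit.gain, "bf_hz": fit.bf_hz,
                "bf_oct": fit.bf_oct, "sigma_oct": fit.sigma_oct,
                "fwhm_oct": fit.fwhm_oct, "vaf": fit.vaf,
                "converged": fit.converged,
            })
        per_unit[uid] = {"pre": fits["pre"], "post": fits["post"], "maps": um}
    fits_df = pd.DataFrame(rows, columns=FIT_COLUMNS)
    return fits_df, per_unit


def build_unit_records(per_unit: dict, metadata: pd.DataFrame,
                       config: RunConfig) -> tuple[list[UnitRecord], list[dict]]:
    """Classify pairing side from the fitted pre-BF and assemble records.

    Units whose pairing frequency exactly equals the fitted pre-BF are
    excluded (side undefined) and reported, never silently assigned.
    """
    meta = metadata.set_index("unit_id")
    records, exclusions = [], []
    for uid, d in per_unit.items():
        if uid not in meta.index:
            raise PipelineError("classify", "unit missing from metadata", [uid])
        drug = str(meta.loc[uid, "drug"])
        pairing_hz = float(meta.loc[uid, "pairing_frequency_hz"])
        try:
            side = classify_pairing_side(d["pre"].bf_oct, to_octaves(pairing_hz))
        except ValueError:
            exclusions.append({"unit_id": uid, "reason": "pairing_tie"})
            continue
        rec = UnitRecord(unit_id=uid, drug=drug, pairing_frequency_hz=pairing_hz,
                         side=side, fit_pre=d["pre"], fit_post=d["post"],
                         vaf_threshold=config.vaf_threshold)
        if not rec.included:
            exclusions.append({
                "unit_id": uid, "reason": "low_vaf",
                "vaf_pre": d["pre"].vaf, "vaf_post": d["post"].vaf,
            })
        records.append(rec)
    return records, exclusions


@dataclass
class PipelineResult:
    """Everything a run produces, with plain-text writers."""

    config: RunConfig
    fits: pd.DataFrame
    records: list
    exclusions: list
    study: object                    # PairingStudyResults
    fitted_curves: pd.DataFrame
    unfitted_curves: pd.DataFrame
    bf_shift_tests: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.fits.to_csv(out / "fits.csv", index=False)
        self.study.flat_anova_table().to_csv(out / "anova.csv", index=False)
        self.study.flat_posthoc_table().to_csv(out / "posthoc.csv", index=False)
        self.fitted_curves.to_csv(out / "population_fitted.csv", index=False)
        self.unfitted_curves.to_csv(out / "population_unfitted.csv", index=False)
        self.bf_shift_tests.to_csv(out / "bf_shift_tests.csv", index=False)
        with open(out / "stats.json", "w") as fh:
            json.dump(self.study.to_dict(), fh, indent=1, default=float)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1, default=str)


def _population_tables(records, per_unit):
    """Fitted and unfitted population curves plus BF-shift tests per cell."""
    fitted_frames, unfitted_frames, shift_rows = [], [], []
    included = [r for r in records if r.included]
    for cell in CELLS:
        cell_recs = [r for r in included if f"{r.drug}/{r.side}" == cell]
        if len(cell_recs) < 2:
            continue
        uids = [r.unit_id for r in cell_recs]
        profiles = {
            phase: {u: per_unit[u]["maps"].profiles[(phase, "normalized")]
                    for u in uids}
            for phase in ("pre", "post")
        }
        for phase in ("pre", "post"):
            fitted_frames.append(
                align_fitted_curves(cell_recs, cell, phase).to_frame())
            unfitted_frames.append(
                align_unfitted_curves(profiles["pre"], profiles[phase], uids,
                                      phase, group=cell).to_frame())
        try:
            tests = test_bf_shift(profiles["pre"], profiles["post"], uids,
                                  group=cell)
        except ValueError:
            continue  # degenerate cell (e.g. zero-variance differences)
        for kind, row in tests.items():
            shift_rows.append({"group": cell, "measure": kind,
                               **dataclasses.asdict(row)})
    if not fitted_frames:
        raise PipelineError("population", "no cell has >= 2 included units")
    return (pd.concat(fitted_frames, ignore_index=True),
            pd.concat(unfitted_frames, ignore_index=True),
            pd.DataFrame(shift_rows))


def run_pipeline(trials: TrialTable, metadata: pd.DataFrame,
                 config: RunConfig | None = None) -> PipelineResult:
    """Execute the full analysis on a trial table plus unit metadata.

    ``metadata`` needs columns ``unit_id, drug, pairing_frequency_hz``.
    Stages: preprocess -> fit -> classify/filter -> stats -> population.
    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    config = config or RunConfig()
    fits_df, per_unit = fit_all_units(trials, config)
    records, exclusions = build_unit_records(per_unit, metadata, config)
    included = [r for r in records if r.included]
    if not included:
        raise PipelineError("filter", "no units pass the VAF threshold")
    try:
        study = PairingStudy.from_unit_records(records).fit()
    except ValueError as err:
        raise PipelineError("stats", str(err)) from err
    fitted, unfitted, shifts = _population_tables(records, per_unit)
    manifest = {
        "package": "tuneplast", "version": __version__,
        "config": config.to_dict(), "seed": config.seed,
        "n_units_total": len(per_unit), "n_units_included": len(included),
        "exclusions": exclusions,
        "versions": {
            "numpy": np.__version__, "pandas": pd.__version__,
        },
    }
    return PipelineResult(config=config, fits=fits_df, records=records,
                          exclusions=exclusions, study=study,
                          fitted_curves=fitted, unfitted_curves=unfitted,
                          bf_shift_tests=shifts, manifest=manifest)
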