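"""End-to-end workflow: clean -> fit -> export reference -> cutoffs -> diagnostics.

`run_all` ties the stages together under a single validated configuration,
writing one artifact per stage plus a manifest; a failure in a later stage
leaves earlier artifacts on disk and names the failing stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cleaning import CleaningConfig, ScreeningReference, run_pipeline
from .cutoffs import cutoffs_to_frame, derive_standard_cutoffs
from .diagnostics import worm_plot, worm_table
from .fitting import FitConfig, export_reference, fit_lms, select_df
from .lms import z_for_dataset
from .reference import (
    load_packaged_reference,
    load_reference,
    write_reference,
)

__all__ = ["RunConfig", "StageFailure", "run_all"]

log = logging.getLogger("abmiref.pipeline")


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated configuration for the full workflow."""

    input: str
    outdir: str
    screening_height_ref: str | None = None
    screening_bmi_ref: str | None = None
    exponents: str = "packaged"  # reference CSV with a p column, or "packaged"
    df: tuple = (1, 4, 3)  # (L, M, S) df triple
    select_df: bool = False
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    grid_step_months: float = 6.0
    worm_bins: int = 8
    worm_min_bin: int = 50
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        paths = [self.input, self.screening_height_ref, self.screening_bmi_ref]
        if self.exponents != "packaged":
            paths.append(self.exponents)
        paths = [p for p in paths if p]
        if len(set(paths)) != len(paths):
            raise ValueError("referenced paths must be distinct")
        for p in paths:
            if not Path(p).exists():
                raise ValueError(f"configured path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cleaning" in raw:
            raw["cleaning"] = CleaningConfig(**raw["cleaning"])
        if "fit" in raw:
            raw["fit"] = FitConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw["fit"].items()
            })
        if "df" in raw:
            raw["df"] = tuple(raw["df"])
        return cls(**raw)


def _load_screening(config: RunConfig) -> ScreeningReference | None:
    if not (config.screening_height_ref and config.screening_bmi_ref):
        return None
    return ScreeningReference(
        height_ref=load_reference(config.screening_height_ref, name="screen_height"),
        bmi_ref=load_reference(config.screening_bmi_ref, name="screen_bmi"),
    )


def run_all(config: RunConfig) -> dict:
    """Execute the workflow; returns the artifact manifest (also written to
    ``manifest.json`` in the output directory)."""
    logging.basicConfig(level=config.log_level)
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"artifacts": {}}

    def _register(key: str, path: Path, rows: int) -> None:
        manifest["artifacts"][key] = {"path": str(path), "rows": rows}
        log.info("artifact %s: %s (%d rows)", key, path, rows)

    stage = "load"
    try:
        records = pd.read_csv(config.input)
        schedule = (
            load_packaged_reference().exponents
            if config.exponents == "packaged"
            else load_reference(config.exponents, name="exponents").exponents
        )
        screening = _load_screening(config)
    except Exception as e:
        raise StageFailure(stage, e) from e

    stage = "clean"
    try:
        cleaned, report = run_pipeline(records, config.cleaning, screening)
        p = outdir / "cleaned.csv"
        cleaned.to_csv(p, index=False)
        _register("cleaned", p, len(cleaned))
        rp = outdir / "cleaning_report.json"
        rp.write_text(json.dumps(report.to_dict(), indent=2))
        _register("cleaning_report", rp, len(report.stages))
    except Exception as e:
        raise StageFailure(stage, e) from e

    stage = "fit"
    try:
        from .allometry import compute_abmi
        from .reference import exponent_at

        fits = {}
        grid_rows = []
        for sex in ("M", "F"):
            sub = cleaned[cleaned["sex"] == sex]
            ages = sub["age_months"].to_numpy(dtype=float)
            p_vals = np.array(
                [exponent_at(schedule, sex, a) for a in ages]
            )
            y = compute_abmi(
                sub["weight_kg"].to_numpy(), sub["height_cm"].to_numpy() / 100.0,
                p_vals,
            )
            if config.select_df:
                fit, table = select_df(ages, y, config.fit, sex=sex)
                table.insert(0, "sex", sex)
                grid_rows.append(table)
            else:
                fit = fit_lms(ages, y, config.df, config.fit, sex=sex)
            fits[sex] = fit
        if grid_rows:
            p = outdir / "df_grid.csv"
            pd.concat(grid_rows).to_csv(p, index=False)
            _register("df_grid", p, sum(len(t) for t in grid_rows))
        lo = max(f.age_lo for f in fits.values())
        hi = min(f.age_hi for f in fits.values())
        step = config.grid_step_months
        grid = np.arange(np.ceil(lo / step) * step, hi + 1e-9, step)
        fitted_ref = export_reference(
            fits, grid, name="fitted_abmi", index_kind="abmi", schedule=schedule
        )
        p = outdir / "reference.csv"
        write_reference(fitted_ref, str(p))
        _register("reference", p, 2 * len(grid))
    except Exception as e:
        raise StageFailure(stage, e) from e

    stage = "cutoffs"
    try:
        from .cutoffs import ANCHOR_AGES_MONTHS, ANCHOR_VALUES, derive_cutoff

        # anchor only at ages the fitted span actually covers
        cuts = [
            derive_cutoff(fitted_ref, sex, age, value, label=label)
            for sex, anchor_ages in ANCHOR_AGES_MONTHS.items()
            for age in anchor_ages
            if fitted_ref.domain(sex)[0] <= age <= fitted_ref.domain(sex)[1]
            for label, value in ANCHOR_VALUES.items()
        ]
        frame = cutoffs_to_frame(cuts)
        p = outdir / "cutoffs.csv"
        frame.to_csv(p, index=False)
        _register("cutoffs", p, len(frame))
    except Exception as e:
        raise StageFailure(stage, e) from e

    stage = "diagnostics"
    try:
        scored = z_for_dataset(cleaned, fitted_ref, schedule)
        ok = scored[scored["flag"] == "ok"]
        panels = worm_plot(
            ok["z"].to_numpy(), ok["age_months"].to_numpy(),
            n_bins=config.worm_bins, min_bin=config.worm_min_bin,
        )
        wt = worm_table(panels)
        p = outdir / "worm.csv"
        wt.to_csv(p, index=False)
        _register("worm", p, len(wt))
    except Exception as e:
        raise StageFailure(stage, e) from e

    mp = outdir / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2))
    return manifest
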