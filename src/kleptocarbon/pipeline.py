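"""End-to-end orchestration: files in, rates and summaries out.

``compute_rates`` is the in-memory core: it builds analysis intervals
from the count series, estimates growth/clearance/ingestion per
interval, attaches the picked-cell measurements (¹⁴C uptake, chl-a,
biovolume) taken at the interval's end day, and assembles the carbon
budget into one :class:`~kleptocarbon.io_formats.RateRecord` per
culture×interval.  ``run_rates`` wraps it with file I/O, config echo and
flag logging for reproducible shell runs.

All analysis stages are deterministic; randomness exists only in the
simulator.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import budget, radiocarbon
from .biovolume import biovolume as _biovolume
from .grazing import GrazingConfig, build_intervals, clearance_ingestion
from .io_formats import (
    CellDimension,
    CountObservation,
    FluorometrySample,
    RateRecord,
    ScintillationPair,
    Treatment,
    read_counts,
    read_dimensions,
    read_fluorometry,
    read_scintillation,
    read_treatments,
    write_rates,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "compute_rates", "run_rates"]


@dataclass
class RunConfig:
    """Flat key-value run configuration (YAML on disk).

    Every constant that enters the carbon budget has a default equal to
    the study's value and is echoed to the log at run time, so silent
    constant drift is impossible.
    """

    counts: str = "counts.csv"
    controls: str | None = "controls.csv"
    scint: str | None = "scint.csv"
    fluor: str | None = "fluor.csv"
    dims: str | None = "dims.csv"
    treatments: str = "treatments.csv"
    rates_out: str = "rates.csv"
    summary_out: str = "summary.csv"
    detection_limit_cells_per_ml: float = 0.5
    negative_grazing_policy: str = "flag_zero"
    interval_mode: str = "dilution_cycle"
    negative_uptake_policy: str = "keep_negative"
    lugol_volume_correction: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)

    def digest(self) -> str:
        """Stable hash of the configuration, for the run log."""
        text = yaml.safe_dump(vars(self), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    def grazing_config(self) -> GrazingConfig:
        return GrazingConfig(
            detection_limit=self.detection_limit_cells_per_ml,
            negative_grazing_policy=self.negative_grazing_policy,
            interval_mode=self.interval_mode,
        )


def _index_by_day(items, tol: float = 1e-6) -> dict[str, list]:
    out: dict[str, list] = {}
    for it in items:
        out.setdefault(it.culture_id, []).append(it)
    return out


def _at_day(items: list, day: float, tol: float = 1e-6):
    return [it for it in items if math.isclose(it.day, day, abs_tol=tol)]


def compute_rates(
    counts: list[CountObservation],
    treatments: dict[str, Treatment],
    controls: list[CountObservation] | None = None,
    scint: list[ScintillationPair] | None = None,
    fluor: list[FluorometrySample] | None = None,
    dims: list[CellDimension] | None = None,
    config: RunConfig | None = None,
) -> list[RateRecord]:
    """Assemble one rate record per culture×interval from raw observations.

    Picked-cell measurements are matched to the interval whose end day
    they were taken on; a missing measurement leaves the dependent
    fields undefined rather than zero.
    """
    config = config or RunConfig()
    gcfg = config.grazing_config()
    intervals = build_intervals(counts, controls, gcfg)

    scint_by = _index_by_day(scint or [])
    fluor_by = _index_by_day(fluor or [])
    dims_by = _index_by_day(dims or [])

    records: list[RateRecord] = []
    for iv in intervals:
        treatment = treatments.get(iv.treatment_id)
        if treatment is None:
            raise KeyError(f"interval {iv.culture_id} ({iv.t0}, {iv.t1}): "
                           f"unknown treatment_id {iv.treatment_id!r}")
        grazing = clearance_ingestion(iv, gcfg)

        bv = None
        cell_dims = _at_day(dims_by.get(iv.culture_id, []), iv.t1)
        if cell_dims:
            vols = [_biovolume(d, config.lugol_volume_correction) for d in cell_dims]
            bv = sum(vols) / len(vols)

        p_daily = None
        uptake_flags: set[str] = set()
        pairs = _at_day(scint_by.get(iv.culture_id, []), iv.t1)
        if pairs:
            if len(pairs) > 1:
                raise ValueError(f"conflicting scintillation pairs for "
                                 f"{iv.culture_id!r} day {iv.t1}")
            p_hourly, uptake_flags = radiocarbon.uptake_hourly(
                pairs[0], config.negative_uptake_policy)
            p_daily = radiocarbon.uptake_daily(p_hourly, treatment)

        chl = None
        samples = _at_day(fluor_by.get(iv.culture_id, []), iv.t1)
        if samples:
            chl = radiocarbon.chl_per_cell(samples[0])

        records.append(budget.assemble(
            iv, grazing, treatment,
            biovolume=bv, p_daily=p_daily, chl_cell=chl,
            uptake_flags=uptake_flags,
        ))
    return records


def run_rates(config: RunConfig, base_dir: str | Path = ".") -> list[RateRecord]:
    """File-level pipeline run: read inputs, compute, write rates + summary.

    Logs the config hash and every budget constant in force, then one
    line per flagged record.  Deterministic for fixed inputs and config.
    """
    base = Path(base_dir)

    def _p(name: str | None) -> Path | None:
        return None if name is None else base / name

    treatments = read_treatments(_p(config.treatments))
    counts = read_counts(_p(config.counts))
    controls_path = _p(config.controls)
    controls = read_counts(controls_path) if controls_path and controls_path.exists() else []
    scint_path = _p(config.scint)
    scint = read_scintillation(scint_path) if scint_path and scint_path.exists() else []
    fluor_path = _p(config.fluor)
    fluor = read_fluorometry(fluor_path) if fluor_path and fluor_path.exists() else []
    dims_path = _p(config.dims)
    dims = read_dimensions(dims_path) if dims_path and dims_path.exists() else []

    logger.info("config %s", config.digest())
    for t in treatments.values():
        logger.info(
            "treatment %s: irradiance=%g prey_target=%g light_hours=%g "
            "prey_carbon=%g carbon_per_volume=%g",
            t.treatment_id, t.irradiance, t.prey_target, t.light_hours,
            t.prey_carbon, t.carbon_per_volume,
        )

    records = compute_rates(counts, treatments, controls, scint, fluor, dims, config)
    for r in records:
        if r.flags:
            logger.info("flagged %s (%g, %g): %s", r.culture_id, r.t0, r.t1,
                        ",".join(sorted(r.flags)))

    write_rates(records, base / config.rates_out)
    budget.summarize(records).to_csv(base / config.summary_out, index=False)
    logger.info("wrote %s and %s (%d records)",
                config.rates_out, config.summary_out, len(records))
    return records
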