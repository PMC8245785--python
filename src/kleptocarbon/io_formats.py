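"""Tabular interchange formats for the carbon-budget pipeline.

All raw observations from the batch-culture experiments — cell counts,
light/dark scintillation DPM pairs, bulk fluorometry readings and cell
linear dimensions — travel as RFC-4180 CSV (UTF-8, "." decimal).  Every
reader validates rows against the domain invariants and reports failures
with the offending row number and field; a file that satisfies the
documented schema never raises.

Derived per-culture-per-interval quantities are written back out as a
``rates.csv`` whose columns mirror :class:`RateRecord` exactly, at full
float precision so a write/read round trip is lossless.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "ValidationError",
    "Treatment",
    "CountObservation",
    "ScintillationPair",
    "FluorometrySample",
    "CellDimension",
    "RateRecord",
    "read_counts",
    "read_scintillation",
    "read_fluorometry",
    "read_dimensions",
    "read_treatments",
    "write_rates",
    "read_rates",
    "write_counts",
    "write_scintillation",
    "write_fluorometry",
    "write_dimensions",
    "write_treatments",
]


class SchemaError(ValueError):
    """A file's header does not match the documented schema."""


class ValidationError(ValueError):
    """A row violates a domain invariant; message carries row number and field."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

SPECIES = ("ciliate", "prey")
PHASES = ("pre_dilution", "post_dilution", "none")
SHAPES = ("sphere", "ellipsoid")


@dataclass(frozen=True)
class Treatment:
    """Experimental condition: irradiance, prey target and conversion constants.

    Parameters
    ----------
    irradiance : float
        Photon flux, µmol photons m⁻² s⁻¹ (> 0).
    prey_target : float
        Target prey density, cells mL⁻¹ (0 during a starvation phase).
    light_hours : float
        Hours of light per day; the cultures ran a 14:10 h light:dark cycle.
    prey_carbon : float
        Carbon content per prey cell, pg C (default 10).
    carbon_per_volume : float
        Ciliate carbon-to-biovolume conversion, pg C µm⁻³ (default 0.19).
    """

    treatment_id: str
    irradiance: float
    prey_target: float = 0.0
    light_hours: float = 14.0
    prey_carbon: float = 10.0
    carbon_per_volume: float = 0.19

    def __post_init__(self) -> None:
        if not self.irradiance > 0:
            raise ValidationError(f"treatment {self.treatment_id!r}: irradiance must be > 0")
        if self.prey_target < 0:
            raise ValidationError(f"treatment {self.treatment_id!r}: prey_target must be >= 0")
        if not 0 < self.light_hours <= 24:
            raise ValidationError(f"treatment {self.treatment_id!r}: light_hours must be in (0, 24]")
        if not self.prey_carbon > 0:
            raise ValidationError(f"treatment {self.treatment_id!r}: prey_carbon must be > 0")
        if not self.carbon_per_volume > 0:
            raise ValidationError(f"treatment {self.treatment_id!r}: carbon_per_volume must be > 0")


@dataclass(frozen=True)
class CountObservation:
    """One density measurement of one species in one culture at one time."""

    culture_id: str
    treatment_id: str
    day: float
    species: str
    density: float
    n_counted: int | None = None
    volume_counted: float | None = None
    phase: str = "none"

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValidationError("day must be >= 0")
        if self.species not in SPECIES:
            raise ValidationError(f"species must be one of {SPECIES}, got {self.species!r}")
        if self.density < 0:
            raise ValidationError("density must be >= 0")
        if self.phase not in PHASES:
            raise ValidationError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.n_counted is not None and self.n_counted < 0:
            raise ValidationError("n_counted must be >= 0")
        if self.volume_counted is not None and not self.volume_counted > 0:
            raise ValidationError("volume_counted must be > 0")
        if self.n_counted is not None and self.volume_counted is not None:
            implied = self.n_counted / self.volume_counted
            # tolerance covers rounding of the reported density
            tol = max(1e-6, 0.005 * max(implied, 1.0))
            if abs(self.density - implied) > tol and round(self.density) != round(implied):
                raise ValidationError(
                    f"density {self.density} inconsistent with "
                    f"n_counted/volume_counted = {implied:g}"
                )


@dataclass(frozen=True)
class ScintillationPair:
    """Matched light/dark DPM for one picked-cell ¹⁴C incubation.

    ``dpm_light``/``dpm_dark`` are the raw counter readings for the processed
    ``counted_volume`` mL of the ``vial_volume`` mL incubation.  ``sa_dpm`` is
    the reading for the ``sa_volume`` mL specific-activity subsample, and
    ``dic`` the dissolved inorganic carbon of the medium (µg C mL⁻¹).
    """

    culture_id: str
    day: float
    dpm_light: float
    dpm_dark: float
    n_cells: int
    incubation_h: float = 3.0
    sa_dpm: float = 1.0
    sa_volume: float = 0.1
    counted_volume: float = 1.9
    vial_volume: float = 2.0
    dic: float = 26.0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValidationError("n_cells must be > 0")
        if not self.incubation_h > 0:
            raise ValidationError("incubation_h must be > 0")
        if not self.dic > 0:
            raise ValidationError("dic must be > 0")
        if not self.sa_dpm > 0:
            raise ValidationError("sa_dpm must be > 0")
        if not 0 < self.sa_volume <= self.vial_volume:
            raise ValidationError("sa_volume must be in (0, vial_volume]")
        if not 0 < self.counted_volume <= self.vial_volume:
            raise ValidationError("counted_volume must be in (0, vial_volume]")


@dataclass(frozen=True)
class FluorometrySample:
    """Total chl-a reading (pg) for a batch of picked cells or a bulk filter.

    ``n_cells`` = 0 marks a bulk prey filter sample, in which case
    ``volume_filtered`` (mL) must be present to normalise per cell downstream.
    """

    culture_id: str
    day: float
    reading: float
    n_cells: int = 20
    volume_filtered: float | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValidationError("n_cells must be >= 0")
        if self.reading < 0:
            raise ValidationError("reading must be >= 0")
        if self.n_cells == 0 and self.volume_filtered is None:
            raise ValidationError("bulk sample (n_cells=0) requires volume_filtered")


@dataclass(frozen=True)
class CellDimension:
    """Length/width (µm) of one Lugol-fixed cell plus its assigned shape."""

    culture_id: str
    day: float
    length: float
    width: float
    shape: str = "ellipsoid"

    def __post_init__(self) -> None:
        if not self.length > 0 or not self.width > 0:
            raise ValidationError("length and width must be > 0")
        if self.shape not in SHAPES:
            raise ValidationError(f"shape must be one of {SHAPES}, got {self.shape!r}")
        if self.length < self.width:
            # transcription-order slips are common; shape math needs length >= width
            logger.warning(
                "culture %s day %s: length %.3g < width %.3g, swapping",
                self.culture_id, self.day, self.length, self.width,
            )
            length, width = self.width, self.length
            object.__setattr__(self, "length", length)
            object.__setattr__(self, "width", width)


@dataclass
class RateRecord:
    """Derived quantities for one culture over one sampling interval.

    ``None`` marks a quantity that could not be computed (missing inputs or
    an undefined ratio); it is never silently replaced by 0.  ``flags`` is a
    set of quality markers (``negative_grazing``, ``depleted_prey``,
    ``negative_uptake``, ``undefined_rate``, ``missing_control``).
    """

    culture_id: str
    treatment_id: str
    t0: float
    t1: float
    mu_y: float | None = None
    mu_x: float | None = None
    g: float | None = None
    F: float | None = None
    I: float | None = None
    P_daily: float | None = None
    chl_cell: float | None = None
    P_chl: float | None = None
    Bv: float | None = None
    C_y: float | None = None
    mu_yC: float | None = None
    C_I: float | None = None
    GGE: float | None = None
    photo_pct: float | None = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.t1 > self.t0:
            raise ValidationError("interval must have t1 > t0")
        if self.photo_pct is not None and not (0 <= self.photo_pct <= 100):
            raise ValidationError("photo_pct must lie in [0, 100]")
        if "negative_grazing" not in self.flags:
            if self.F is not None and self.F < 0:
                raise ValidationError("F < 0 without negative_grazing flag")
            if self.I is not None and self.I < 0:
                raise ValidationError("I < 0 without negative_grazing flag")


RATE_COLUMNS: tuple[str, ...] = (
    "culture_id", "treatment_id", "t0", "t1",
    "mu_y", "mu_x", "g", "F", "I",
    "P_daily", "chl_cell", "P_chl",
    "Bv", "C_y", "mu_yC", "C_I", "GGE", "photo_pct", "flags",
)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _load(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    df = pd.read_csv(path, dtype={"culture_id": str, "treatment_id": str},
                     float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")
    return df


def _opt_int(v) -> int | None:
    return None if v is None or (isinstance(v, float) and math.isnan(v)) else int(v)


def _opt_float(v) -> float | None:
    return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)


def read_counts(path: str | Path) -> list[CountObservation]:
    """Read a counts table; see the counts.csv schema in the docs.

    Raises :class:`SchemaError` for a bad header and :class:`ValidationError`
    (with the 1-based data row number) for an invalid row.
    """
    df = _load(path, ["culture_id", "treatment_id", "day", "species", "density"])
    out: list[CountObservation] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(CountObservation(
                culture_id=str(row.culture_id),
                treatment_id=str(row.treatment_id),
                day=float(row.day),
                species=str(row.species),
                density=float(row.density),
                n_counted=_opt_int(getattr(row, "n_counted", None)),
                volume_counted=_opt_float(getattr(row, "volume_counted", None)),
                phase=str(getattr(row, "phase", "none") or "none"),
            ))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
    _check_day_order(out)
    return out


def _check_day_order(obs: list[CountObservation]) -> None:
    seen: dict[tuple[str, str], float] = {}
    for i, o in enumerate(obs, start=1):
        key = (o.culture_id, o.species)
        if key in seen and o.day < seen[key]:
            raise ValidationError(
                f"row {i}: day {o.day} decreases within culture "
                f"{o.culture_id!r} species {o.species!r}"
            )
        seen[key] = o.day


def read_scintillation(path: str | Path) -> list[ScintillationPair]:
    """Read light/dark vial rows and pair them on (culture_id, day).

    Vials arrive as separate rows with a ``vial`` column (``light``/``dark``);
    an unpaired row is a hard error — silently dropping a dark control would
    bias the uptake calculation.
    """
    df = _load(path, ["culture_id", "day", "vial", "dpm", "n_cells",
                      "incubation_h", "sa_dpm", "sa_volume", "counted_volume",
                      "vial_volume", "dic"])
    groups: dict[tuple[str, float], dict[str, tuple[int, pd.Series]]] = {}
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        vial = str(row["vial"]).strip().lower()
        if vial not in ("light", "dark"):
            raise ValidationError(f"{path} row {i}: vial must be 'light' or 'dark', got {vial!r}")
        key = (str(row["culture_id"]), float(row["day"]))
        slot = groups.setdefault(key, {})
        if vial in slot:
            raise ValidationError(f"{path} row {i}: duplicate {vial} vial for {key}")
        slot[vial] = (i, row)

    pairs: list[ScintillationPair] = []
    for key, slot in groups.items():
        if "light" not in slot or "dark" not in slot:
            have = next(iter(slot))
            i = slot[have][0]
            raise ValidationError(
                f"{path} row {i}: unpaired {have} vial for culture_id={key[0]!r} day={key[1]}"
            )
        il, light = slot["light"]
        _, dark = slot["dark"]
        try:
            pairs.append(ScintillationPair(
                culture_id=key[0],
                day=key[1],
                dpm_light=float(light["dpm"]),
                dpm_dark=float(dark["dpm"]),
                n_cells=int(light["n_cells"]),
                incubation_h=float(light["incubation_h"]),
                sa_dpm=float(light["sa_dpm"]),
                sa_volume=float(light["sa_volume"]),
                counted_volume=float(light["counted_volume"]),
                vial_volume=float(light["vial_volume"]),
                dic=float(light["dic"]),
            ))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} row {il}: {exc}") from exc
    pairs.sort(key=lambda p: (p.culture_id, p.day))
    return pairs


def read_fluorometry(path: str | Path) -> list[FluorometrySample]:
    df = _load(path, ["culture_id", "day", "n_cells", "reading"])
    out: list[FluorometrySample] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(FluorometrySample(
                culture_id=str(row.culture_id),
                day=float(row.day),
                n_cells=int(row.n_cells),
                reading=float(row.reading),
                volume_filtered=_opt_float(getattr(row, "volume_filtered", None)),
            ))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
    return out


def read_dimensions(path: str | Path) -> list[CellDimension]:
    df = _load(path, ["culture_id", "day", "length", "width", "shape"])
    out: list[CellDimension] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            length, width = float(row.length), float(row.width)
            if length < width:
                logger.warning("%s row %d: length < width, swapping", path, i)
                length, width = width, length
            out.append(CellDimension(
                culture_id=str(row.culture_id),
                day=float(row.day),
                length=length,
                width=width,
                shape=str(row.shape),
            ))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
    return out


def read_treatments(path: str | Path) -> dict[str, Treatment]:
    df = _load(path, ["treatment_id", "irradiance", "prey_target"])
    out: dict[str, Treatment] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            t = Treatment(
                treatment_id=str(row.treatment_id),
                irradiance=float(row.irradiance),
                prey_target=float(row.prey_target),
                light_hours=float(getattr(row, "light_hours", 14.0)),
                prey_carbon=float(getattr(row, "prey_carbon", 10.0)),
                carbon_per_volume=float(getattr(row, "carbon_per_volume", 0.19)),
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
        if t.treatment_id in out:
            raise ValidationError(f"{path} row {i}: duplicate treatment_id {t.treatment_id!r}")
        out[t.treatment_id] = t
    return out


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_rates(records: Iterable[RateRecord], path: str | Path) -> None:
    """Write one CSV row per culture×interval in the documented column order.

    Floats are emitted with ``repr`` precision so re-reading reproduces the
    values bit-identically; ``None`` becomes an empty cell; flags are
    ';'-joined in sorted order.
    """
    rows = []
    for r in records:
        d = {}
        for c in RATE_COLUMNS[:-1]:
            v = getattr(r, c)
            if isinstance(v, float):
                v = repr(v)  # shortest round-trippable decimal form
            d[c] = "" if v is None else v
        d["flags"] = ";".join(sorted(r.flags))
        rows.append(d)
    df = pd.DataFrame(rows, columns=list(RATE_COLUMNS))
    df.to_csv(path, index=False)


def read_rates(path: str | Path) -> list[RateRecord]:
    """Inverse of :func:`write_rates`."""
    df = _load(path, list(RATE_COLUMNS))
    out: list[RateRecord] = []
    for row in df.itertuples(index=False):
        kwargs = {}
        for c in RATE_COLUMNS[:-1]:
            v = getattr(row, c)
            if c in ("culture_id", "treatment_id"):
                kwargs[c] = str(v)
            elif c in ("t0", "t1"):
                kwargs[c] = float(v)
            else:
                kwargs[c] = _opt_float(v)
        raw_flags = getattr(row, "flags")
        flags = set() if (not isinstance(raw_flags, str) or not raw_flags) else set(raw_flags.split(";"))
        out.append(RateRecord(flags=flags, **kwargs))
    return out


def _write_df(rows: list[dict], columns: list[str], path: str | Path) -> None:
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def write_counts(obs: Iterable[CountObservation], path: str | Path) -> None:
    _write_df(
        [{"culture_id": o.culture_id, "treatment_id": o.treatment_id, "day": o.day,
          "species": o.species, "density": o.density, "n_counted": o.n_counted,
          "volume_counted": o.volume_counted, "phase": o.phase} for o in obs],
        ["culture_id", "treatment_id", "day", "species", "density",
         "n_counted", "volume_counted", "phase"], path)


def write_scintillation(pairs: Iterable[ScintillationPair], path: str | Path) -> None:
    rows = []
    for p in pairs:
        common = dict(culture_id=p.culture_id, day=p.day, n_cells=p.n_cells,
                      incubation_h=p.incubation_h, sa_dpm=p.sa_dpm,
                      sa_volume=p.sa_volume, counted_volume=p.counted_volume,
                      vial_volume=p.vial_volume, dic=p.dic)
        rows.append({**common, "vial": "light", "dpm": p.dpm_light})
        rows.append({**common, "vial": "dark", "dpm": p.dpm_dark})
    _write_df(rows, ["culture_id", "day", "vial", "dpm", "n_cells", "incubation_h",
                     "sa_dpm", "sa_volume", "counted_volume", "vial_volume", "dic"], path)


def write_fluorometry(samples: Iterable[FluorometrySample], path: str | Path) -> None:
    _write_df(
        [{"culture_id": s.culture_id, "day": s.day, "n_cells": s.n_cells,
          "reading": s.reading, "volume_filtered": s.volume_filtered} for s in samples],
        ["culture_id", "day", "n_cells", "reading", "volume_filtered"], path)


def write_dimensions(dims: Iterable[CellDimension], path: str | Path) -> None:
    _write_df(
        [{"culture_id": d.culture_id, "day": d.day, "length": d.length,
          "width": d.width, "shape": d.shape} for d in dims],
        ["culture_id", "day", "length", "width", "shape"], path)


def write_treatments(treatments: Iterable[Treatment], path: str | Path) -> None:
    _write_df(
        [{"treatment_id": t.treatment_id, "irradiance": t.irradiance,
          "prey_target": t.prey_target, "light_hours": t.light_hours,
          "prey_carbon": t.prey_carbon, "carbon_per_volume": t.carbon_per_volume}
         for t in treatments],
        ["treatment_id", "irradiance", "prey_target", "light_hours",
         "prey_carbon", "carbon_per_volume"], path)
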