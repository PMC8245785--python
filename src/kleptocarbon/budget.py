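"""Assembly of the two-input ciliate carbon budget.

The budget has exactly two carbon sources: ingested prey carbon
C_I = I × (pg C per prey cell) and daily inorganic carbon uptake P.
Carbon-specific growth µ_yC = µ_y × C_y relates the observed division
rate to cellular carbon, and gross growth efficiency GGE = µ_yC / C_I
expresses growth as a fraction of ingested carbon — values above 1 are
legitimate and flag photosynthetic supplementation, not an error.
Percent partitioning splits acquired carbon as 100·P/(P + C_I).

Missing or undefined components propagate as ``None``; they are never
silently coerced to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io_formats import RateRecord, Treatment, ValidationError
from .grazing import GrazingResult, Interval

logger = logging.getLogger(__name__)

__all__ = [
    "ingested_carbon",
    "carbon_specific_growth",
    "gge",
    "partition",
    "assemble",
    "summarize",
]


def ingested_carbon(ingestion: float, treatment: Treatment) -> float:
    """Ingested carbon C_I = I × prey_carbon, pg C cell⁻¹ d⁻¹."""
    if ingestion < 0:
        raise ValidationError("ingestion must be >= 0")
    return ingestion * treatment.prey_carbon


def carbon_specific_growth(mu_y: float, c_y: float) -> float:
    """Carbon-specific growth µ_yC = µ_y × C_y, pg C cell⁻¹ d⁻¹ (sign follows µ_y)."""
    if c_y <= 0:
        raise ValidationError("C_y must be > 0")
    return mu_y * c_y


def gge(mu_yc: float, c_i: float) -> float | None:
    """Gross growth efficiency µ_yC / C_I (dimensionless).

    Values above 1 are retained unclamped — photosynthesis can supplement
    growth beyond what ingestion alone supplies.  C_I = 0 (a starved
    interval) makes the ratio undefined and returns ``None``.
    """
    if c_i < 0:
        raise ValidationError("C_I must be >= 0")
    if c_i == 0:
        return None
    value = mu_yc / c_i
    if value > 1:
        logger.info("GGE %.3g > 1: photosynthetic supplementation", value)
    return value


def partition(p_daily: float, c_i: float) -> tuple[float, float] | None:
    """Percent of acquired carbon from inorganic uptake vs ingestion.

    Returns (photo_pct, ingest_pct) summing to exactly 100, or ``None``
    when both inputs are zero.
    """
    if p_daily < 0 or c_i < 0:
        raise ValidationError("partition inputs must be >= 0")
    total = p_daily + c_i
    if total == 0:
        return None
    # ratio first: p/total <= 1.0 exactly in IEEE, so photo never exceeds 100
    photo = 100.0 * (p_daily / total)
    return photo, 100.0 - photo


@dataclass(frozen=True)
class _UptakeInputs:
    """Optional radiocarbon/fluorometry inputs for one culture×interval."""

    p_daily: float | None = None
    chl_cell: float | None = None
    negative_uptake: bool = False


def assemble(
    interval: Interval,
    grazing: GrazingResult,
    treatment: Treatment,
    biovolume: float | None = None,
    p_daily: float | None = None,
    chl_cell: float | None = None,
    uptake_flags: set[str] | None = None,
) -> RateRecord:
    """Combine per-interval rate estimates into one :class:`RateRecord`.

    Each downstream quantity is computed only when all of its inputs are
    defined; otherwise it stays ``None``.  Flags from the grazing and
    uptake stages are merged into the record.
    """
    flags = set(grazing.flags) | set(uptake_flags or ())

    c_y = ciliate_c = None
    if biovolume is not None:
        from .biovolume import ciliate_carbon
        ciliate_c = ciliate_carbon(biovolume, treatment)
        c_y = ciliate_c

    mu_yc = None
    if grazing.mu_y is not None and c_y is not None and c_y > 0:
        mu_yc = carbon_specific_growth(grazing.mu_y, c_y)

    c_i = None
    if grazing.I is not None:
        effective_i = max(grazing.I, 0.0)
        c_i = ingested_carbon(effective_i, treatment)

    gge_val = None
    if mu_yc is not None and c_i is not None:
        gge_val = gge(mu_yc, c_i)
        if gge_val is None:
            flags.add("undefined_rate")

    p_chl = None
    if p_daily is not None and chl_cell is not None and chl_cell > 0:
        p_chl = p_daily / chl_cell

    photo_pct = None
    if p_daily is not None and c_i is not None:
        split = partition(max(p_daily, 0.0), c_i)
        if split is not None:
            photo_pct = split[0]

    return RateRecord(
        culture_id=interval.culture_id,
        treatment_id=interval.treatment_id or treatment.treatment_id,
        t0=interval.t0,
        t1=interval.t1,
        mu_y=grazing.mu_y,
        mu_x=interval.k_control,
        g=grazing.g,
        F=grazing.F,
        I=grazing.I,
        P_daily=p_daily,
        chl_cell=chl_cell,
        P_chl=p_chl,
        Bv=biovolume,
        C_y=c_y,
        mu_yC=mu_yc,
        C_I=c_i,
        GGE=gge_val,
        photo_pct=photo_pct,
        flags=flags,
    )


_SUMMARY_FIELDS = (
    "mu_y", "mu_x", "g", "F", "I", "P_daily", "chl_cell", "P_chl",
    "Bv", "C_y", "mu_yC", "C_I", "GGE", "photo_pct",
)


def summarize(records: list[RateRecord]) -> pd.DataFrame:
    """Treatment×day group means ± sample STD (ddof=1), long format.

    Groups on (treatment_id, interval end day); one output row per group
    per defined field with columns treatment_id, day, field, mean, std, n.
    Mirrors the means-±-STD presentation convention of the experiments.
    """
    rows = []
    for r in records:
        for f in _SUMMARY_FIELDS:
            v = getattr(r, f)
            if v is not None:
                rows.append({"treatment_id": r.treatment_id, "day": r.t1,
                             "field": f, "value": v})
    if not rows:
        return pd.DataFrame(columns=["treatment_id", "day", "field", "mean", "std", "n"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["treatment_id", "day", "field"], sort=True)["value"]
        .agg(mean="mean", std=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, n="count")
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out
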