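"""Single-cell ¹⁴C inorganic-carbon uptake from light/dark DPM pairs.

Picked cells are incubated with NaH¹⁴CO₃⁻ in paired light and dark vials;
the light-minus-dark disintegration excess, scaled by the medium's
dissolved inorganic carbon and its measured specific activity, gives the
carbon fixed per cell per hour:

    p = [(D_l* − D_d*)/N] · C_m · 10⁶ / (SA_v · V_vial · t)

where D* = DPM × (V_vial / V_counted) corrects the raw reading for the
specific-activity subsample removed before acid treatment, SA_v is the
specific activity per mL of medium, C_m the DIC in µg C mL⁻¹, N the
number of picked cells, t the incubation in hours, and 10⁶ converts
µg → pg.  Daily rates multiply by the photoperiod (14 h light by default).
"""

from __future__ import annotations

from .io_formats import FluorometrySample, ScintillationPair, Treatment, ValidationError

__all__ = [
    "specific_activity",
    "uptake_hourly",
    "uptake_daily",
    "chl_per_cell",
    "chl_specific_uptake",
]

UG_TO_PG = 1e6  # fixed unit conversion, not configurable


def specific_activity(sa_dpm: float, sa_volume: float) -> float:
    """Specific activity of the medium, DPM mL⁻¹."""
    if sa_dpm <= 0 or sa_volume <= 0:
        raise ValidationError("sa_dpm and sa_volume must be > 0")
    return sa_dpm / sa_volume


def uptake_hourly(
    pair: ScintillationPair, negative_policy: str = "keep_negative"
) -> tuple[float, set[str]]:
    """Hourly cellular carbon uptake, pg C cell⁻¹ h⁻¹, with quality flags.

    A dark reading above the light reading gives a negative rate; the
    default policy keeps it (flagged ``negative_uptake``) because clamping
    would bias low-light treatments upward.  ``clamp_zero`` reports 0
    instead, still flagged.
    """
    if negative_policy not in ("keep_negative", "clamp_zero"):
        raise ValueError(f"unknown negative_uptake policy {negative_policy!r}")
    vol_corr = pair.vial_volume / pair.counted_volume
    d_light = pair.dpm_light * vol_corr
    d_dark = pair.dpm_dark * vol_corr
    sa_v = specific_activity(pair.sa_dpm, pair.sa_volume)
    p = ((d_light - d_dark) / pair.n_cells) * pair.dic * UG_TO_PG / (
        sa_v * pair.vial_volume * pair.incubation_h
    )
    flags: set[str] = set()
    if p < 0:
        flags.add("negative_uptake")
        if negative_policy == "clamp_zero":
            p = 0.0
    return p, flags


def uptake_daily(p_hourly: float, treatment: Treatment) -> float:
    """Daily uptake P = light_hours × hourly rate, pg C cell⁻¹ d⁻¹."""
    return treatment.light_hours * p_hourly


def chl_per_cell(sample: FluorometrySample, density: float | None = None) -> float:
    """Per-cell chl-a (pg) from a picked-cell batch or a bulk filter sample.

    Picked-cell batches divide the reading by the number of picked cells.
    Bulk samples (n_cells = 0) need the culture density (cells mL⁻¹) to
    normalise: reading / (density × volume_filtered).
    """
    if sample.n_cells > 0:
        return sample.reading / sample.n_cells
    if density is None or density <= 0:
        raise ValidationError("bulk sample requires a positive paired density")
    assert sample.volume_filtered is not None  # enforced at construction
    return sample.reading / (density * sample.volume_filtered)


def chl_specific_uptake(p_daily: float, chl: float) -> float | None:
    """Chl-a-specific uptake, pg C (pg chl-a)⁻¹ d⁻¹; ``None`` when chl = 0."""
    if chl < 0:
        raise ValidationError("chl must be >= 0")
    if chl == 0:
        return None
    return p_daily / chl
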