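"""Growth, clearance and ingestion rates from batch-culture count series.

Growth rates assume exponential dynamics, µ = (ln N₁ − ln N₀)/t.  Grazing
follows the classic batch-incubation estimator: the prey's exponential
growth coefficient k comes from an ungrazed control monoculture over the
same window, the grazing coefficient is g = k − (ln C₁ − ln C₀)/t, and
clearance F = g/N̄ divides by the *logarithmic-mean* grazer density
N̄ = (N₁ − N₀)/ln(N₁/N₀) — the time-average of an exponentially changing
population, which is the grazer-averaging refinement to the original
prey-side derivation.  Ingestion is I = F·C̄ with C̄ the logarithmic-mean
prey density.

The daily-dilution acclimation protocol and the multi-day starvation
protocol are both handled by :func:`build_intervals`, which turns labelled
count observations into analysis windows that never straddle a dilution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .io_formats import CountObservation

logger = logging.getLogger(__name__)

__all__ = [
    "Interval",
    "GrazingConfig",
    "GrazingResult",
    "growth_rate",
    "frost_mean_density",
    "grazing_coefficient",
    "clearance_ingestion",
    "build_intervals",
]


@dataclass(frozen=True)
class GrazingConfig:
    """Tunables for the grazing estimator.

    detection_limit : prey density substituted when the grazed culture is
        counted at zero — one cell per largest counted volume by default
        (0.5 cells mL⁻¹).
    negative_grazing_policy : ``flag_zero`` reports I = 0 when g < 0 while
        keeping the raw g; ``keep_negative`` propagates negative F and I.
    interval_mode : ``dilution_cycle`` spans post-dilution to the next
        pre-dilution sample; ``consecutive_samples`` pairs successive
        sampling days regardless of phase labels.
    """

    detection_limit: float = 0.5
    negative_grazing_policy: str = "flag_zero"
    interval_mode: str = "dilution_cycle"

    def __post_init__(self) -> None:
        if self.negative_grazing_policy not in ("flag_zero", "keep_negative"):
            raise ValueError(f"unknown negative_grazing_policy {self.negative_grazing_policy!r}")
        if self.interval_mode not in ("dilution_cycle", "consecutive_samples"):
            raise ValueError(f"unknown interval_mode {self.interval_mode!r}")


@dataclass(frozen=True)
class Interval:
    """Densities bracketing one analysis window of one mixed culture."""

    culture_id: str
    t0: float
    t1: float
    N0: float
    N1: float
    C0: float
    C1: float
    k_control: float | None = None
    treatment_id: str = ""

    def __post_init__(self) -> None:
        if not self.t1 > self.t0:
            raise ValueError("interval must have t1 > t0")
        for name in ("N0", "N1", "C0", "C1"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def duration(self) -> float:
        return self.t1 - self.t0


@dataclass
class GrazingResult:
    """Grazing estimates for one interval, with quality flags."""

    mu_y: float | None = None
    g: float | None = None
    F: float | None = None
    I: float | None = None
    flags: set[str] = field(default_factory=set)


def growth_rate(n0: float, n1: float, t: float) -> float | None:
    """Exponential growth rate µ = (ln n₁ − ln n₀)/t in d⁻¹.

    Negative values are valid (mortality).  A zero density makes the rate
    undefined and returns ``None`` — the caller decides how to flag it.
    """
    if t <= 0:
        raise ValueError("t must be > 0")
    if n0 <= 0 or n1 <= 0:
        return None
    return (math.log(n1) - math.log(n0)) / t


def frost_mean_density(x0: float, x1: float) -> float | None:
    """Logarithmic-mean density (x₁ − x₀)/ln(x₁/x₀), cells mL⁻¹.

    Equals the time-average of an exponential trajectory between the two
    densities; continuous at x₁ = x₀ where it returns x₀.  ``None`` for
    non-positive input.
    """
    if x0 <= 0 or x1 <= 0:
        return None
    if math.isclose(x0, x1, rel_tol=1e-12):
        return x0
    return (x1 - x0) / math.log(x1 / x0)


def grazing_coefficient(k_control: float, c0: float, c1: float, t: float) -> float | None:
    """Grazing coefficient g = k − (ln c₁ − ln c₀)/t in d⁻¹ (may be negative)."""
    if t <= 0:
        raise ValueError("t must be > 0")
    if c0 <= 0 or c1 <= 0:
        return None
    return k_control - (math.log(c1) - math.log(c0)) / t


def clearance_ingestion(
    interval: Interval, config: GrazingConfig = GrazingConfig()
) -> GrazingResult:
    """Estimate µ_y, g, clearance F (mL grazer⁻¹ d⁻¹) and ingestion I
    (prey grazer⁻¹ d⁻¹) for one interval.

    Prey counted at zero at the end of the window is replaced by the
    configured detection limit and the record flagged ``depleted_prey``.
    Negative g (prey outgrew its control) is flagged ``negative_grazing``
    and, under the default policy, reported with I = 0 while the raw g is
    retained.
    """
    res = GrazingResult()
    t = interval.duration

    res.mu_y = growth_rate(interval.N0, interval.N1, t)
    if res.mu_y is None:
        res.flags.add("undefined_rate")

    if interval.k_control is None:
        res.flags.add("missing_control")
        return res

    c1 = interval.C1
    if c1 <= 0:
        c1 = config.detection_limit
        res.flags.add("depleted_prey")
    c0 = interval.C0
    if c0 <= 0:
        res.flags.add("undefined_rate")
        return res

    res.g = grazing_coefficient(interval.k_control, c0, c1, t)
    n_bar = frost_mean_density(interval.N0, interval.N1)
    c_bar = frost_mean_density(c0, c1)
    if res.g is None or n_bar is None or c_bar is None or n_bar == 0:
        res.flags.add("undefined_rate")
        return res

    f = res.g / n_bar
    i = f * c_bar
    if res.g < 0:
        res.flags.add("negative_grazing")
        if config.negative_grazing_policy == "flag_zero":
            f, i = 0.0, 0.0
    res.F, res.I = f, i
    return res


# ---------------------------------------------------------------------------
# Interval construction
# ---------------------------------------------------------------------------

def _series(obs: list[CountObservation], species: str) -> list[CountObservation]:
    return sorted((o for o in obs if o.species == species), key=lambda o: (o.day, o.phase))


def _density_at(series: list[CountObservation], day: float, phase: str) -> float | None:
    """Density at a sampling day, preferring the requested dilution phase."""
    candidates = [o for o in series if math.isclose(o.day, day, abs_tol=1e-9)]
    if not candidates:
        return None
    for o in candidates:
        if o.phase == phase:
            return o.density
    return candidates[0].density


def _control_k(
    controls_by_treatment: dict[str, list[CountObservation]],
    treatment_id: str, t0: float, t1: float,
) -> float | None:
    """Mean prey growth rate across paired monocultures over [t0, t1].

    Controls are themselves diluted on sampling days, so the window uses the
    post-dilution density at t0 and the pre-dilution density at t1 when
    phase labels are present.
    """
    series = controls_by_treatment.get(treatment_id)
    if not series:
        return None
    ks = []
    for cid in sorted({o.culture_id for o in series}):
        sub = [o for o in series if o.culture_id == cid]
        c0 = _density_at(sub, t0, "post_dilution")
        c1 = _density_at(sub, t1, "pre_dilution")
        if c0 is None or c1 is None:
            continue
        k = growth_rate(c0, c1, t1 - t0)
        if k is not None:
            ks.append(k)
    return sum(ks) / len(ks) if ks else None


def build_intervals(
    counts: list[CountObservation],
    controls: list[CountObservation] | None = None,
    config: GrazingConfig = GrazingConfig(),
) -> list[Interval]:
    """Turn labelled count observations into analysis intervals.

    Under the acclimation protocol each interval runs from the post-dilution
    sample on day d to the pre-dilution sample on day d+1, so the estimate is
    never contaminated by the dilution jump.  Counts without phase labels
    (the starvation protocol) pair consecutive sampling days.  ``k_control``
    comes from the paired monoculture (matched on treatment_id) over the same
    window; a missing control leaves it ``None`` and is logged.
    """
    controls = controls or []
    controls_by_treatment: dict[str, list[CountObservation]] = {}
    for o in controls:
        if o.species == "prey":
            controls_by_treatment.setdefault(o.treatment_id, []).append(o)

    intervals: list[Interval] = []
    for cid in sorted({o.culture_id for o in counts}):
        obs = [o for o in counts if o.culture_id == cid]
        treatment_id = obs[0].treatment_id
        ciliates = _series(obs, "ciliate")
        prey = _series(obs, "prey")
        if not ciliates:
            continue
        days = sorted({o.day for o in ciliates})
        has_phases = any(o.phase != "none" for o in obs)
        use_dilution = has_phases and config.interval_mode == "dilution_cycle"
        p0, p1 = ("post_dilution", "pre_dilution") if use_dilution else ("none", "none")

        for t0, t1 in zip(days[:-1], days[1:]):
            n0 = _density_at(ciliates, t0, p0)
            n1 = _density_at(ciliates, t1, p1)
            c0 = _density_at(prey, t0, p0)
            c1 = _density_at(prey, t1, p1)
            if n0 is None or n1 is None:
                continue
            k = _control_k(controls_by_treatment, treatment_id, t0, t1)
            if k is None:
                logger.info("culture %s interval (%g, %g): no paired control", cid, t0, t1)
            intervals.append(Interval(
                culture_id=cid, t0=t0, t1=t1,
                N0=n0, N1=n1,
                C0=c0 if c0 is not None else 0.0,
                C1=c1 if c1 is not None else 0.0,
                k_control=k, treatment_id=treatment_id,
            ))
    return intervals
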