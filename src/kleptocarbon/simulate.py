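"""Mechanistic simulator for kleptoplastidic ciliate batch-culture experiments.

The model tracks, per culture: prey density C (cells mL⁻¹), ciliate
density N (cells mL⁻¹), the per-cell chlorophyll pool Q (pg chl-a) held
in sequestered plastids, and per-cell carbon W (pg C).  Euler updates at
``dt`` days:

* prey:      dC/dt = µ_x(Irr)·C − I(C)·N, with light-limited growth
  µ_x = µmax·(1 − e^(−Irr/Ik)) and Monod ingestion I(C) = Imax·C/(K + C);
* plastids:  dQ/dt = q_prey·I(C) − (d0 + d1·Irr)·Q — chl is retained from
  a small fraction of ingested prey and decays faster under stronger
  light (photo-oxidative wear without plastid repair);
* fixation:  P = P_max^B·(1 − e^(−α·Irr/P_max^B))·Q·e^(−k_s·Q), a
  saturating photosynthesis–irradiance response times the chl pool, with
  a self-shading discount for chl-packed cells;
* carbon:    net = a·(prey_carbon·I(C) + P) − R.  A positive balance
  first refills per-cell reserves up to the division threshold W₀ and is
  then converted to division (µ_y = net/W₀); a negative balance drains
  reserves, and once they hit the floor the culture dies at m₀ d⁻¹.

The two experiment designs are emulated end to end: the starvation
design (prey pulse, no dilution, sampling on days 2, 5, 7, 9 and every
2 d after) and the acclimation design (daily dilution of the ciliates
back to target with prey topped up, 2 acclimation days + 3 sampling
days, triplicate split).  Observation files use the exact schemas the
pipeline reads; a truth ledger records the realized per-interval rates
so every downstream estimate can be checked by parameter recovery.
All randomness flows from a single integer seed; identical parameters
give byte-identical files.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    CellDimension,
    CountObservation,
    FluorometrySample,
    ScintillationPair,
    Treatment,
    write_counts,
    write_dimensions,
    write_fluorometry,
    write_scintillation,
    write_treatments,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimParams",
    "SimState",
    "SimOutput",
    "step",
    "prey_growth_rate",
    "ingestion_response",
    "photosynthesis",
    "chl_decay_rate",
    "run_starvation",
    "run_acclimation",
    "observe_sample",
    "PAPER_LIKE",
]


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimParams:
    """Full parameterization of the kleptoplast mixotroph model and its
    measurement-noise model.

    Process parameters
    ------------------
    mu_max_prey : prey maximum growth rate, d⁻¹.
    ik_prey : prey light half-saturation scale, µmol photons m⁻² s⁻¹.
    i_max : maximum ingestion, prey grazer⁻¹ d⁻¹.
    k_half : ingestion half-saturation prey density, cells mL⁻¹.
    q_prey : chl-a retained per ingested prey cell, pg — far below the
        prey's full complement; most chloroplasts are digested.
    d0, d1 : plastid chl decay, d⁻¹ baseline and d⁻¹ per unit irradiance.
    alpha : initial slope of the P–I response, pg C (pg chl)⁻¹ d⁻¹ per
        µmol photons m⁻² s⁻¹.
    p_b_max : chl-specific maximum photosynthesis, pg C (pg chl)⁻¹ d⁻¹.
    k_shade : self-shading coefficient, (pg chl)⁻¹.
    assimilation : fraction of acquired carbon assimilated (0–1].
    respiration : maintenance loss, pg C cell⁻¹ d⁻¹.
    m0 : mortality once reserves are exhausted (or while starved, in
        ``starvation`` mode), d⁻¹.
    biovolume0 : baseline (division-threshold) cell volume, µm³.
    carbon_per_volume : pg C µm⁻³, ties W to biovolume.
    reserve_floor : fraction of baseline carbon below which cells die.
    chl0 : initial per-cell chl of well-fed inoculum, pg.
    prey_carbon : pg C per prey cell.
    mortality_mode : ``carbon_balance`` (default) or ``starvation``.

    Measurement model
    -----------------
    Poisson counting (wells of ``count_well_ml`` until ``count_target``
    individuals or ``count_max_wells`` wells; prey by flow cytometry on
    ``flow_volume_ml``), lognormal DPM and fluorometry errors, normal
    dimension error, constant dark-vial background.  ``noise=False``
    switches every error off for parameter-recovery work.
    """

    # prey and grazing
    mu_max_prey: float = 0.7
    ik_prey: float = 30.0
    i_max: float = 900.0
    k_half: float = 8000.0
    # kleptoplast pool
    q_prey: float = 0.01
    d0: float = 0.045
    d1: float = 0.009
    # photosynthesis
    alpha: float = 0.55
    p_b_max: float = 12.0
    k_shade: float = 0.02
    # carbon balance
    assimilation: float = 0.35
    respiration: float = 80.0
    m0: float = 0.7
    biovolume0: float = 20000.0
    carbon_per_volume: float = 0.19
    reserve_floor: float = 0.88
    chl0: float = 65.0
    prey_carbon: float = 10.0
    mortality_mode: str = "carbon_balance"
    # integration
    dt: float = 0.01
    # measurement model
    noise: bool = True
    count_target: int = 200
    count_well_ml: float = 2.0
    count_max_wells: int = 12
    flow_volume_ml: float = 0.1
    dpm_cv: float = 0.05
    fluor_cv: float = 0.08
    dim_cv: float = 0.05
    dark_dpm: float = 30.0
    sa_dpm_per_ml: float = 2.22e6
    dic: float = 26.0
    light_hours: float = 14.0
    incubation_h: float = 3.0
    picked_cells: int = 20
    n_dims: int = 10
    aspect_ratio: float = 1.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mu_max_prey", "ik_prey", "i_max", "k_half", "q_prey",
                     "d0", "d1", "alpha", "p_b_max", "k_shade", "respiration",
                     "m0", "biovolume0", "carbon_per_volume", "chl0",
                     "prey_carbon", "dt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.assimilation <= 1:
            raise ValueError("assimilation must be in (0, 1]")
        if self.mortality_mode not in ("carbon_balance", "starvation"):
            raise ValueError(f"unknown mortality_mode {self.mortality_mode!r}")

    @property
    def w_base(self) -> float:
        """Division-threshold per-cell carbon, pg."""
        return self.biovolume0 * self.carbon_per_volume

    @property
    def w_min(self) -> float:
        """Reserve floor per-cell carbon, pg."""
        return self.reserve_floor * self.w_base


PAPER_LIKE = SimParams()


@dataclass
class SimState:
    """Instantaneous state of one culture."""

    C: float        # prey, cells mL⁻¹
    N: float        # ciliates, cells mL⁻¹
    Q: float        # per-cell chl-a, pg
    W: float        # per-cell carbon, pg
    time: float = 0.0

    def __post_init__(self) -> None:
        for name in ("C", "N", "Q", "W"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# Process functions
# ---------------------------------------------------------------------------

def prey_growth_rate(params: SimParams, irradiance: float) -> float:
    """Light-limited prey growth µ_x(Irr) = µmax·(1 − e^(−Irr/Ik)), d⁻¹."""
    return params.mu_max_prey * (1.0 - math.exp(-irradiance / params.ik_prey))


def ingestion_response(params: SimParams, prey_density: float) -> float:
    """Monod ingestion I(C) = Imax·C/(K + C), prey grazer⁻¹ d⁻¹."""
    if prey_density <= 0:
        return 0.0
    return params.i_max * prey_density / (params.k_half + prey_density)


def chl_decay_rate(params: SimParams, irradiance: float) -> float:
    """Plastid chl loss rate d0 + d1·Irr, d⁻¹."""
    return params.d0 + params.d1 * irradiance


def photosynthesis(params: SimParams, irradiance: float, chl: float) -> float:
    """Daily per-cell carbon fixation P, pg C cell⁻¹ d⁻¹.

    Saturating P–I response per unit chl times the chl pool, discounted
    by e^(−k_s·Q) for package self-shading.  Zero in darkness or without
    plastids.
    """
    if irradiance <= 0 or chl <= 0:
        return 0.0
    if params.p_b_max == 0:
        return 0.0
    pb = params.p_b_max * (1.0 - math.exp(-params.alpha * irradiance / params.p_b_max))
    return pb * chl * math.exp(-params.k_shade * chl)


@dataclass
class StepDiagnostics:
    """Per-step bookkeeping used for the truth ledger."""

    ingestion: float = 0.0        # prey grazer⁻¹ d⁻¹ at step start
    prey_consumed: float = 0.0    # cells mL⁻¹ removed this step
    carbon_offered: float = 0.0   # pg C mL⁻¹ offered to grazers this step
    p_daily: float = 0.0          # pg C cell⁻¹ d⁻¹ at step start
    mu_y: float = 0.0             # realized instantaneous ciliate rate, d⁻¹


def step(state: SimState, params: SimParams, irradiance: float,
         dt: float | None = None) -> tuple[SimState, StepDiagnostics]:
    """One Euler step; returns the new state and the step's diagnostics.

    All state variables floor at zero; a non-finite update aborts with a
    diagnostic message.
    """
    h = params.dt if dt is None else dt
    if h <= 0:
        raise ValueError("dt must be > 0")

    ing = ingestion_response(params, state.C)
    mu_x = prey_growth_rate(params, irradiance)
    p_daily = photosynthesis(params, irradiance, state.Q)
    decay = chl_decay_rate(params, irradiance)

    consumed = ing * state.N * h                       # cells mL⁻¹
    c_new = state.C + (mu_x * state.C) * h - consumed
    q_new = state.Q + (params.q_prey * ing - decay * state.Q) * h

    net = params.assimilation * (params.prey_carbon * ing + p_daily) - params.respiration

    w_new = state.W
    mu_y = 0.0
    mort = 0.0
    if net >= 0:
        if state.W < params.w_base:
            w_new = min(params.w_base, state.W + net * h)
        else:
            # reserves full: surplus converts to division at constant cell size
            mu_y = net / params.w_base
    else:
        w_new = state.W + net * h
        if params.mortality_mode == "carbon_balance":
            if w_new <= params.w_min:
                w_new = params.w_min
                mort = params.m0
        else:  # starvation-driven: die whenever the balance is negative
            mort = params.m0
            w_new = max(w_new, params.w_min)

    n_new = state.N * math.exp((mu_y - mort) * h)

    new = SimState(
        C=max(c_new, 0.0),
        N=max(n_new, 0.0),
        Q=max(q_new, 0.0),
        W=max(w_new, 0.0),
        time=state.time + h,
    )
    for name in ("C", "N", "Q", "W"):
        if not math.isfinite(getattr(new, name)):
            raise FloatingPointError(
                f"non-finite {name} at t={new.time:.3f} "
                f"(state {dataclasses.asdict(state)})"
            )
    diag = StepDiagnostics(
        ingestion=ing,
        prey_consumed=consumed,
        carbon_offered=consumed * params.prey_carbon,
        p_daily=p_daily,
        mu_y=mu_y - mort,
    )
    return new, diag


# ---------------------------------------------------------------------------
# Observation forward models
# ---------------------------------------------------------------------------

def _count_density(rng: np.random.Generator, params: SimParams, density: float,
                   is_prey: bool) -> tuple[float, int | None, float | None]:
    """Simulate enumeration: Poisson tally over the counting volume.

    Ciliates are counted in fixed wells until the target tally (or the well
    budget) is reached; prey run through the flow cytometer's fixed volume.
    Returns (reported density, n_counted, volume_counted).
    """
    if is_prey:
        volume = params.flow_volume_ml
    else:
        if density > 0:
            wells = math.ceil(params.count_target / (density * params.count_well_ml))
            wells = min(max(wells, 1), params.count_max_wells)
        else:
            wells = params.count_max_wells
        volume = wells * params.count_well_ml
    if not params.noise:
        return density, None, None
    n = int(rng.poisson(density * volume))
    return n / volume, n, volume


def _scintillation(rng: np.random.Generator, params: SimParams, culture_id: str,
                   day: float, p_daily: float) -> ScintillationPair:
    """Forward model of the paired light/dark ¹⁴C incubation.

    The light vial's excess DPM is the algebraic inversion of the uptake
    equation at the true hourly rate; the dark vial sees only background.
    Readings are scaled to the processed (counted) volume and, with noise
    on, jittered lognormally.  The dark DPM never depends on the true rate.
    """
    p_hourly = p_daily / params.light_hours
    sa_v = params.sa_dpm_per_ml
    vial, counted, sa_vol = 2.0, 1.9, 0.1
    signal_total = (p_hourly * params.picked_cells * sa_v * vial
                    * params.incubation_h) / (params.dic * 1e6)
    frac = counted / vial
    d_light = (signal_total + params.dark_dpm) * frac
    d_dark = params.dark_dpm * frac
    sa_dpm = sa_v * sa_vol
    if params.noise:
        def jitter(x: float) -> float:
            cv = params.dpm_cv
            sigma = math.sqrt(math.log(1 + cv * cv))
            return x * rng.lognormal(-0.5 * sigma * sigma, sigma)
        d_light, d_dark, sa_dpm = jitter(d_light), jitter(d_dark), jitter(sa_dpm)
    return ScintillationPair(
        culture_id=culture_id, day=day,
        dpm_light=d_light, dpm_dark=d_dark,
        n_cells=params.picked_cells, incubation_h=params.incubation_h,
        sa_dpm=sa_dpm, sa_volume=sa_vol, counted_volume=counted,
        vial_volume=vial, dic=params.dic,
    )


def _fluorometry(rng: np.random.Generator, params: SimParams, culture_id: str,
                 day: float, chl: float) -> FluorometrySample:
    reading = params.picked_cells * chl
    if params.noise and reading > 0:
        sigma = math.sqrt(math.log(1 + params.fluor_cv ** 2))
        reading *= rng.lognormal(-0.5 * sigma * sigma, sigma)
    return FluorometrySample(culture_id=culture_id, day=day,
                             n_cells=params.picked_cells, reading=reading)


def _dimensions(rng: np.random.Generator, params: SimParams, culture_id: str,
                day: float, w: float) -> list[CellDimension]:
    """Cell dimensions consistent with the current per-cell carbon.

    Biovolume Bv = W / carbon_per_volume maps to a prolate spheroid of the
    configured aspect ratio; each of ``n_dims`` measured cells gets
    independent normal jitter on both axes.
    """
    bv = w / params.carbon_per_volume
    width = (6.0 * bv / (math.pi * params.aspect_ratio)) ** (1.0 / 3.0)
    length = params.aspect_ratio * width
    out = []
    for _ in range(params.n_dims):
        li, wi = length, width
        if params.noise:
            li *= max(1e-6, 1.0 + params.dim_cv * rng.standard_normal())
            wi *= max(1e-6, 1.0 + params.dim_cv * rng.standard_normal())
        if li < wi:
            li, wi = wi, li
        out.append(CellDimension(culture_id=culture_id, day=day,
                                 length=li, width=wi, shape="ellipsoid"))
    return out


def observe_sample(rng: np.random.Generator, params: SimParams, culture_id: str,
                   treatment_id: str, day: float, state: SimState, phase: str,
                   irradiance: float, full: bool) -> dict:
    """Generate the observation rows for one sampling of one culture.

    Counts are taken at every sampling; ``full`` adds the picked-cell
    measurements (scintillation, fluorometry, cell dimensions).
    """
    counts = []
    for species, density in (("ciliate", state.N), ("prey", state.C)):
        dens, n, vol = _count_density(rng, params, density, species == "prey")
        counts.append(CountObservation(
            culture_id=culture_id, treatment_id=treatment_id, day=day,
            species=species, density=dens, n_counted=n, volume_counted=vol,
            phase=phase,
        ))
    out: dict = {"counts": counts, "scint": [], "fluor": [], "dims": []}
    if full:
        p_daily = photosynthesis(params, irradiance, state.Q)
        out["scint"].append(_scintillation(rng, params, culture_id, day, p_daily))
        out["fluor"].append(_fluorometry(rng, params, culture_id, day, state.Q))
        out["dims"].extend(_dimensions(rng, params, culture_id, day, state.W))
    return out


# ---------------------------------------------------------------------------
# Experiment runners
# ---------------------------------------------------------------------------

@dataclass
class SimOutput:
    """Everything one simulated experiment produces.

    ``trajectory`` records the fine-step state of every culture;
    ``truth`` holds the realized per-culture-per-interval rates the
    pipeline is expected to recover; the remaining members are the
    observation rows in the pipeline's input schemas.
    """

    treatments: list[Treatment]
    counts: list[CountObservation]
    control_counts: list[CountObservation]
    scint: list[ScintillationPair]
    fluor: list[FluorometrySample]
    dims: list[CellDimension]
    trajectory: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the standard file set; returns the paths written."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": outdir / "counts.csv",
            "controls": outdir / "controls.csv",
            "scint": outdir / "scint.csv",
            "fluor": outdir / "fluor.csv",
            "dims": outdir / "dims.csv",
            "treatments": outdir / "treatments.csv",
            "truth": outdir / "truth.csv",
        }
        write_counts(self.counts, paths["counts"])
        write_counts(self.control_counts, paths["controls"])
        write_scintillation(self.scint, paths["scint"])
        write_fluorometry(self.fluor, paths["fluor"])
        write_dimensions(self.dims, paths["dims"])
        write_treatments(self.treatments, paths["treatments"])
        self.truth.to_csv(paths["truth"], index=False)
        return paths


class _Accumulator:
    """Integrates grazer-weighted ingestion and consumption over a window."""

    def __init__(self) -> None:
        self.int_in = 0.0      # ∫ I(C)·N dt
        self.int_n = 0.0       # ∫ N dt
        self.consumed = 0.0    # cells mL⁻¹
        self.offered = 0.0     # pg C mL⁻¹

    def add(self, state_n: float, diag: StepDiagnostics, h: float) -> None:
        self.int_in += diag.ingestion * state_n * h
        self.int_n += state_n * h
        self.consumed += diag.prey_consumed
        self.offered += diag.carbon_offered

    @property
    def mean_ingestion(self) -> float:
        """Grazer-weighted mean ingestion, prey grazer⁻¹ d⁻¹ (per day basis)."""
        return self.int_in / self.int_n if self.int_n > 0 else 0.0


def _advance(state: SimState, params: SimParams, irradiance: float,
             days: float, acc: _Accumulator) -> SimState:
    """Integrate one window of ``days`` days, accumulating diagnostics."""
    n_steps = round(days / params.dt)
    if not math.isclose(n_steps * params.dt, days, rel_tol=1e-9):
        raise ValueError(f"window {days} d is not a multiple of dt={params.dt}")
    for _ in range(n_steps):
        n_before = state.N
        state, diag = step(state, params, irradiance)
        acc.add(n_before, diag, params.dt)
    return state


def _truth_row(params: SimParams, culture_id: str, treatment_id: str,
               t0: float, t1: float, s0: SimState, s1: SimState,
               acc: _Accumulator, irradiance: float) -> dict:
    """Realized rates over one interval, in the pipeline's own units."""
    dt_days = t1 - t0
    mu_y = (math.log(s1.N) - math.log(s0.N)) / dt_days if s0.N > 0 and s1.N > 0 else math.nan
    mean_i = acc.mean_ingestion
    p_daily = photosynthesis(params, irradiance, s1.Q)
    c_y = s1.W
    c_i = mean_i * params.prey_carbon
    mu_yc = mu_y * c_y if math.isfinite(mu_y) else math.nan
    gge = mu_yc / c_i if c_i > 0 and math.isfinite(mu_yc) else math.nan
    return {
        "culture_id": culture_id, "treatment_id": treatment_id,
        "t0": t0, "t1": t1,
        "mu_y": mu_y, "I": mean_i, "P_daily": p_daily,
        "chl_cell": s1.Q, "Bv": s1.W / params.carbon_per_volume,
        "C_y": c_y, "C_I": c_i, "mu_yC": mu_yc, "GGE": gge,
        "prey_consumed": acc.consumed, "carbon_offered": acc.offered,
    }


def _traj_row(culture_id: str, treatment_id: str, state: SimState) -> dict:
    return {"culture_id": culture_id, "treatment_id": treatment_id,
            "time": state.time, "C": state.C, "N": state.N,
            "Q": state.Q, "W": state.W}


def run_starvation(
    params: SimParams = PAPER_LIKE,
    irradiances: tuple[float, ...] = (10.0, 40.0, 120.0),
    days: float = 13.0,
    n_replicates: int = 3,
    initial_ciliates: float = 175.0,
    prey_pulse: float = 3.25e4,
    min_density: float = 5.0,
) -> SimOutput:
    """Simulate the starvation design: a prey pulse at day 0, no dilution.

    One acclimated culture per irradiance is split into ``n_replicates``
    at day 0; sampling happens on days 2, 5, 7, 9 and every 2 days after
    until ``days`` or until the ciliates drop below ``min_density``.
    Prey monoculture controls run alongside (diluted to match the mixed
    culture's prey density each sampling day) until prey is depleted.
    The underlying dynamics are deterministic, so replicates share one
    trajectory and differ only through observation noise.
    """
    rng = np.random.default_rng(params.seed)
    sample_days = [2.0, 5.0, 7.0, 9.0]
    d = 11.0
    while d <= days:
        sample_days.append(d)
        d += 2.0

    treatments = []
    counts: list[CountObservation] = []
    controls: list[CountObservation] = []
    scint: list[ScintillationPair] = []
    fluor: list[FluorometrySample] = []
    dims: list[CellDimension] = []
    traj_rows: list[dict] = []
    truth_rows: list[dict] = []

    for irr in irradiances:
        tid = f"I{irr:g}-starve"
        treatments.append(Treatment(
            treatment_id=tid, irradiance=irr, prey_target=0.0,
            light_hours=params.light_hours, prey_carbon=params.prey_carbon,
            carbon_per_volume=params.carbon_per_volume,
        ))
        state = SimState(C=prey_pulse, N=initial_ciliates,
                         Q=params.chl0, W=params.w_base)
        mu_x = prey_growth_rate(params, irr)
        rep_ids = [f"{tid}-r{r + 1}" for r in range(n_replicates)]
        ctrl_id = f"CTRL-{tid}"

        # day-0 observation (counts only; picked-cell work starts at day 2)
        for cid in rep_ids:
            obs = observe_sample(rng, params, cid, tid, 0.0, state, "none", irr, full=False)
            counts.extend(obs["counts"])
        prev_day, prev_state = 0.0, state
        traj_rows.append(_traj_row(tid, tid, state))

        for day in sample_days:
            acc = _Accumulator()
            state = _advance(state, params, irr, day - prev_day, acc)
            traj_rows.append(_traj_row(tid, tid, state))
            for cid in rep_ids:
                obs = observe_sample(rng, params, cid, tid, day, state, "none", irr, full=True)
                counts.extend(obs["counts"])
                scint.extend(obs["scint"])
                fluor.extend(obs["fluor"])
                dims.extend(obs["dims"])
                truth_rows.append(_truth_row(
                    params, cid, tid, prev_day, day, prev_state, state, acc, irr))
            # control monoculture: reset to the mixed culture's prey density
            # while it remains measurable, growing at mu_x in between
            if prev_state.C > 1.0:
                c0 = prev_state.C
                c1 = c0 * math.exp(mu_x * (day - prev_day))
                # phase labels mark the post-reset start and pre-reset end of
                # the control window so interval matching reads the right pair
                for d_, c_, ph in ((prev_day, c0, "post_dilution"),
                                   (day, c1, "pre_dilution")):
                    dens, n, v = _count_density(rng, params, c_, True)
                    controls.append(CountObservation(
                        culture_id=ctrl_id, treatment_id=tid, day=d_,
                        species="prey", density=dens, n_counted=n,
                        volume_counted=v, phase=ph))
            if state.N < min_density:
                break
            prev_day, prev_state = day, state

    return SimOutput(
        treatments=treatments, counts=counts, control_counts=controls,
        scint=scint, fluor=fluor, dims=dims,
        trajectory=pd.DataFrame(traj_rows),
        truth=pd.DataFrame(truth_rows),
    )


def dilute(state: SimState, ciliate_target: float, prey_target: float) -> SimState:
    """The daily dilution operator of the acclimation protocol.

    Both populations are scaled by the factor that returns the ciliates
    to target, then prey is topped up from the monoculture stock to its
    own target.  If the ciliates are already at or below target no
    dilution happens (prey addition only).
    """
    if state.N > ciliate_target > 0:
        f = ciliate_target / state.N
        state = replace(state, N=ciliate_target, C=state.C * f)
    elif state.N < ciliate_target:
        logger.warning(
            "t=%.2f: ciliate density %.2f below target %.2f, prey addition only",
            state.time, state.N, ciliate_target,
        )
    if state.C < prey_target:
        state = replace(state, C=prey_target)
    return state


def run_acclimation(
    params: SimParams = PAPER_LIKE,
    irradiances: tuple[float, ...] = (10.0, 40.0, 120.0),
    prey_targets: tuple[float, ...] = (5e3, 1e4, 4e4),
    days: float = 5.0,
    n_replicates: int = 3,
    ciliate_target: float = 15.0,
    acclimation_days: float = 2.0,
) -> SimOutput:
    """Simulate the acclimation design: daily dilution to fixed targets.

    For every irradiance × prey-density cell, one source culture runs
    ``acclimation_days`` with daily dilution (ciliates back to
    ``ciliate_target`` cells mL⁻¹, prey topped to target), then splits
    into ``n_replicates`` sample bottles for the remaining sampling days.
    Counts are taken before (``pre_dilution``) and after
    (``post_dilution``) every dilution; picked-cell measurements happen
    on the sampling days.  Prey monoculture controls are diluted to the
    same prey target daily.
    """
    rng = np.random.default_rng(params.seed)
    treatments = []
    counts: list[CountObservation] = []
    controls: list[CountObservation] = []
    scint: list[ScintillationPair] = []
    fluor: list[FluorometrySample] = []
    dims: list[CellDimension] = []
    traj_rows: list[dict] = []
    truth_rows: list[dict] = []

    for irr in irradiances:
        mu_x = prey_growth_rate(params, irr)
        for target in prey_targets:
            tid = f"I{irr:g}-P{target:g}"
            treatments.append(Treatment(
                treatment_id=tid, irradiance=irr, prey_target=target,
                light_hours=params.light_hours, prey_carbon=params.prey_carbon,
                carbon_per_volume=params.carbon_per_volume,
            ))
            rep_ids = [f"{tid}-r{r + 1}" for r in range(n_replicates)]
            ctrl_id = f"CTRL-{tid}"

            state = SimState(C=target, N=ciliate_target,
                             Q=params.chl0, W=params.w_base)
            traj_rows.append(_traj_row(tid, tid, state))

            day = 0.0
            # post-dilution observation at day 0 for every future bottle
            for cid in rep_ids:
                obs = observe_sample(rng, params, cid, tid, day, state,
                                     "post_dilution", irr, full=False)
                counts.extend(obs["counts"])
            ctrl_c = target

            while day < days - 1e-9:
                acc = _Accumulator()
                s0 = state
                state = _advance(state, params, irr, 1.0, acc)
                day = round(day + 1.0, 9)
                traj_rows.append(_traj_row(tid, tid, state))
                sampling = day > acclimation_days + 1e-9
                for cid in rep_ids:
                    obs = observe_sample(rng, params, cid, tid, day, state,
                                         "pre_dilution", irr, full=sampling)
                    counts.extend(obs["counts"])
                    scint.extend(obs["scint"])
                    fluor.extend(obs["fluor"])
                    dims.extend(obs["dims"])
                    truth_rows.append(_truth_row(
                        params, cid, tid, day - 1.0, day, s0, state, acc, irr))
                # paired prey monoculture over the same window
                c1 = ctrl_c * math.exp(mu_x * 1.0)
                for d_, c_, ph in ((day - 1.0, ctrl_c, "post_dilution"),
                                   (day, c1, "pre_dilution")):
                    dens, n, v = _count_density(rng, params, c_, True)
                    controls.append(CountObservation(
                        culture_id=ctrl_id, treatment_id=tid, day=d_,
                        species="prey", density=dens, n_counted=n,
                        volume_counted=v, phase=ph))
                ctrl_c = target  # controls are diluted back to target daily

                if day < days - 1e-9:
                    state = dilute(state, ciliate_target, target)
                    traj_rows.append(_traj_row(tid, tid, state))
                    for cid in rep_ids:
                        obs = observe_sample(rng, params, cid, tid, day, state,
                                             "post_dilution", irr, full=False)
                        counts.extend(obs["counts"])

    return SimOutput(
        treatments=treatments, counts=counts, control_counts=controls,
        scint=scint, fluor=fluor, dims=dims,
        trajectory=pd.DataFrame(traj_rows),
        truth=pd.DataFrame(truth_rows),
    )
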