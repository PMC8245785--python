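# Methods

This note documents the science and the numerical choices behind
`kleptocarbon`: the rate estimators the pipeline implements, the
mechanistic model and measurement forward models behind the simulator,
and the design decisions taken where the underlying methods leave room.

## Rate estimators

**Growth.** µ = (ln N₁ − ln N₀)/t between consecutive samplings, with t
in days. Negative values are valid mortality rates. A zero density makes
the rate undefined; undefined quantities propagate as explicit missing
values, never as zeros.

**Grazing.** The batch-incubation estimator: the prey's intrinsic growth
k is measured in an ungrazed control monoculture over the same window;
the grazing coefficient is g = k − (ln C₁ − ln C₀)/t; clearance divides
by the logarithmic-mean grazer density N̄ = (N₁ − N₀)/ln(N₁/N₀) (the
time-average of an exponentially changing population — the grazer-side
refinement of the original prey-side derivation); ingestion is I = F·C̄
with C̄ the log-mean prey density. Conventions:

- Prey counted at zero at the window's end is replaced by a detection
  limit (default 0.5 cells mL⁻¹ ≈ one cell in the largest counted
  volume) and flagged `depleted_prey`; the log formulas need positivity
  and the flag preserves auditability.
- Negative g (prey outgrew its control) is flagged; under the default
  policy I is reported as 0 while the raw g is retained as evidence of
  control mismatch. A `keep_negative` policy propagates the sign.
- Under the daily-dilution protocol, analysis windows run from the
  post-dilution sample on day d to the pre-dilution sample on day d+1,
  so no window straddles a dilution jump. Unlabelled series (the
  starvation protocol) pair consecutive sampling days, including
  multi-day gaps. The control k is matched per window, using the
  control's own post/pre-dilution phases.

**Known accuracy limit.** The estimator assumes clearance constant
within a window. When the feeding response saturates (Monod) and prey
densities swing substantially within a day — exactly what happens at low
prey targets under daily dilution — the recovered I carries a small
systematic bias relative to the true grazer-weighted mean consumption.
On the simulator's zero-noise 3×3 design this bias reaches ≈3% at
design cells where the response bends inside the intra-day prey swing
(the zero-noise recovery test computes these errors); growth and uptake
invert exactly. Users comparing ingestion across treatments should
treat percent-level differences accordingly.

**¹⁴C uptake.** Hourly uptake per cell is
p = [(D_l* − D_d*)/N]·C_m·10⁶/(SA_v·V·t), with the raw light/dark DPM
scaled to vial totals by V_vial/V_counted (2.0/1.9 by default — a 100 µL
specific-activity subsample is removed before acid treatment), SA_v the
specific activity per mL, C_m the DIC in µg C mL⁻¹, and 10⁶ the fixed
µg→pg conversion. Setting `counted_volume = vial_volume` gives a
no-correction mode. Daily P multiplies by the photoperiod (14 h light
default). Negative light-minus-dark differences are kept and flagged by
default; silently clamping them to zero would bias low-rate treatments
upward.

**Biovolume and carbon.** Cells are spheres or prolate spheroids
(V = π/6·L·W², length on the rotation axis — the standard convention for
Lugol-fixed ciliate biometry). Spheres use the mean of length and width
as diameter so the result does not depend on which axis was labelled
"length". Measured rows with length < width are swapped with a warning
rather than rejected (transcription-order slips are common). Carbon
conversions are linear: 0.19 pg C µm⁻³ for the ciliate, 10 pg C per prey
cell; both are configurable, and a multiplicative fixation-shrinkage
hook defaults to 1 (no correction). Cell carbon for a window uses the
mean biovolume of the dimensions measured at the window's end day.

**Budget.** C_I = I·prey_carbon uses gross ingested carbon (not
assimilation-discounted). GGE = µ_y·C_y / C_I is never clamped; values
above 1 are logged informationally. Percent autotrophy is
100·P/(P + C_I) — the only two-source definition consistent with a
budget whose inputs are ingestion and inorganic uptake. Summaries are
treatment×day group means with sample STD (ddof = 1).

## The simulator

The generator is deliberately mechanistic so that "truth" is available
per interval. Per culture it tracks prey density C, ciliate density N,
the per-cell chlorophyll pool Q of sequestered plastids, and per-cell
carbon W:

- prey: dC/dt = µmax·(1 − e^(−Irr/Ik))·C − I(C)·N, Monod ingestion
  I(C) = Imax·C/(K + C);
- plastids: dQ/dt = q_prey·I(C) − (d₀ + d₁·Irr)·Q — a small amount of
  chl is retained per ingested prey, and plastids wear out faster under
  stronger light (no repair machinery in the host);
- photosynthesis: P = P^B_max·(1 − e^(−α·Irr/P^B_max))·Q·e^(−k_s·Q),
  a saturating P–I response per unit chl times the pool, discounted for
  self-shading in chl-packed cells;
- carbon: net = a·(prey_carbon·I(C) + P) − R. A positive balance first
  refills reserves to the division threshold W₀ and then converts to
  division at µ = net/W₀ (constant cell size while healthy); a negative
  balance shrinks the cell, and once W reaches the reserve floor the
  culture dies at m₀ (an alternative `starvation` mode applies m₀
  whenever the balance is negative).

Integration is forward Euler at dt = 0.01 d; the dynamics are smooth and
slow, and halving dt moves 5-day trajectories by under 2% (tested).
State variables floor at zero; a non-finite update aborts with a
diagnostic.

### Default parameterization (the "paper-like" preset)

| parameter | value | units | rationale |
|---|---|---|---|
| µmax_prey | 0.7 | d⁻¹ | cryptophyte growth at 15 °C |
| Ik_prey | 30 | µmol photons m⁻² s⁻¹ | growth saturating above the lowest treatment |
| Imax | 900 | prey grazer⁻¹ d⁻¹ | ingestion ~750 d⁻¹ at the highest prey target |
| K | 8000 | cells mL⁻¹ | response bends within the tested prey range |
| q_prey | 0.01 | pg chl prey⁻¹ | retained chl; most ingested plastids are digested |
| d₀, d₁ | 0.045, 0.009 | d⁻¹, d⁻¹ per µmol photons m⁻² s⁻¹ | chl half-lives 5.1/1.7/0.6 d at 10/40/120 |
| α | 0.55 | pg C (pg chl)⁻¹ d⁻¹ per µmol photons m⁻² s⁻¹ | strong light limitation at 10 |
| P^B_max | 12 | pg C (pg chl)⁻¹ d⁻¹ | chl-specific rates of a few to ~10 |
| k_s | 0.02 | (pg chl)⁻¹ | productivity optimum at Q = 50 pg |
| a | 0.35 | — | assimilation efficiency typical of ciliates |
| R | 80 | pg C cell⁻¹ d⁻¹ | maintenance; just above the maximum assimilated photosynthate, so prey-free cultures never divide |
| m₀ | 0.7 | d⁻¹ | post-exhaustion mortality |
| Bv₀ | 20000 | µm³ | healthy cell volume → W₀ = 3800 pg C |
| reserve floor | 0.88·W₀ | — | starving cells shrink ~12% before dying |
| chl₀ | 65 | pg cell⁻¹ | well-fed cellular chl-a |

With these values the preset reproduces the qualitative physiology the
designs are meant to expose: chl half-life strictly decreasing with
irradiance; after prey depletion, mortality fastest at the highest
irradiance (plastids lost before their carbon is banked), slowest at mid
irradiance (the declining chl pool passes through the self-shading
optimum and photosynthesis nearly covers maintenance), with low light
intermediate (persistently shaded, slow steady drain); growth 0.2–0.7
d⁻¹ rising with prey; GGE ≈ 0.33–0.35; daily uptake of order 10²
pg C cell⁻¹ d⁻¹; and no divisions after prey depletion. A
high-photosynthesis variant (larger P^B_max and a, smaller R and k_s)
drives GGE above 1, demonstrating that the pipeline reports it
unclamped. Absolute survival times are longer and flatter across
irradiance than real starvation cultures show — the P–I form carries no
photoinhibition term, so the high-light collapse is driven by chl loss
alone.

### Measurement forward models

- **Counts.** Ciliates: Poisson tallies over 2 mL wells, repeated until
  200 individuals or 12 wells (the enumeration protocol); reported
  density is tally/volume, so the stored effort fields are exactly
  consistent. Prey: Poisson over a fixed 0.1 mL flow-cytometer volume.
- **Scintillation.** The light vial's excess DPM is the exact algebraic
  inversion of the uptake equation at the model's current rate (hourly =
  daily/14); the dark vial sees only the constant background (30 DPM)
  and never depends on the true rate. Readings are scaled to the
  processed 1.9 mL and jittered lognormally (CV 5%). Stock activity
  follows the 20 µL of 100 µCi mL⁻¹ in 2 mL protocol
  (SA_v = 2.22×10⁶ DPM mL⁻¹); DIC is 26 µg C mL⁻¹, brackish seawater.
- **Fluorometry.** 20 picked cells × Q, lognormal CV 8%.
- **Dimensions.** Biovolume W/0.19 mapped to a prolate spheroid of
  aspect ratio 1.6; 10 cells per sample with 5% normal jitter per axis.

At zero noise every forward model is exactly invertible by the pipeline,
which is what the recovery tests exploit. Seeding is strict: one integer
seed drives all draws, and identical parameters produce byte-identical
files.

### What the generator does and does not emulate

It emulates the two experiment designs end to end: the daily-dilution
operator (scale both populations to restore the ciliate target, then top
prey up to its target; if the ciliates are below target, prey addition
only, with a warning), the triplicate split after acclimation, the
starvation sampling schedule (days 2, 5, 7, 9, then every 2 d), paired
control monocultures with their own dilutions, and the four measurement
channels with realistic noise. It does not emulate demographic
stochasticity (densities are continuous; all randomness is
observational), prey photoacclimation (prey chl per cell is constant),
photoinhibition, nutrient limitation, or behavioural diel feeding
cycles. Passing recovery tests therefore show that the pipeline's
algebra and bookkeeping are correct under realistic noise — not that
real cultures obey the model.

## Pipeline conventions

- CSV (UTF-8, "." decimal) is the interchange format throughout; rates
  are written with shortest round-trippable float representations and
  read back bit-identically.
- Light/dark vials arrive as separate rows paired on (culture, day); an
  unpaired row is a hard error, since silently dropping a dark control
  would bias uptake.
- All analysis stages are deterministic; the configuration (flat YAML)
  is hashed into the run log together with every constant in force, so
  silent constant drift is visible.
- Exit codes: 0 success, 1 computation/input failure, 2 usage/config
  error.

## Validation problem sizes

The recovery battery uses the full 3×3 design with triplicates (135
culture×interval records per run): zero-noise recovery per interval, and
noise robustness as the median over 100 measurement-noise seeds of the
median error of treatment×day means — means over triplicate bottles are
the pipeline's reported output, mirroring the means ± STD convention of
such experiments. The grazing oracle integrates its forward model at
dt = 0.001 d; starvation patterns are simulated over 22 d horizons.
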