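# Methods

## Measurement model

One sample is a nominally 5 × 5 × 3 mm tissue block clamped between two
microchips.  The chip facing the heater side drives a platinum microheater
to a setpoint temperature; the opposite chip reads the transmitted heat
with three RTDs.  Concentric interdigitated electrodes (inner electrode
outer diameter D₁ = 130 µm, outer electrode inner diameter D₂ = 140 µm)
measure a surface resistance on each chip face and a through-tissue bulk
resistance.  The protocol ramps the tissue from 25 to 37 °C in 3 °C steps;
37 °C is the ceiling because collagen is thermally unstable beyond it.
Analyses use the 25 and 37 °C endpoints; intermediate setpoints are kept
in the profiles.

Estimators (all internal computation in SI; Ω·cm and Ω/□ only at I/O):

* `rho_B = R_B·A/l`.  The absolute electrode area `A` is a convention
  (the chip drawing does not pin it down numerically); the default is the
  outer-electrode disc area π(D₂/2)² ≈ 1.539e-8 m².  Forward simulation
  and inversion share the same instance, so recovered resistivities are
  independent of the choice.
* `rho_S = 2π/ln(D₂/D₁)·R_s ≈ 84.8·R_s`.  The two chip faces read the
  same sheet; their surface resistances are averaged before conversion.
* `k = Q·l/(A_contact·ΔT)` with `Q = V·I` and
  `ΔT = T_source − T_sink`.  "Triangulated" sink temperature is the
  unweighted mean of the valid RTD temperatures — no RTD coordinates are
  published, so position-weighted schemes are excluded.  Fewer than three
  valid RTDs fall back to the mean of the rest with a logged warning;
  zero valid readings is a sensor-failure error.  The source temperature
  is the heater setpoint (precalibrated voltage map), not re-derived from
  heater resistance.
* RTD law is first-order linear, `R = R₀(1 + α(T − T₀))`, α = 2.2e-3 /°C:
  a single printed TCR, so no Callendar–Van Dusen quadratic term.
  Calibration is an OLS line through (T, R) pairs.

### Thermal boundary in the forward simulator

The published description fixes the source side (heater at setpoint) but
not the sink side.  The simulator closes the circuit with series
conduction: tissue conductance `k·A/l` from the source face to the sink
chip, and a lumped sink-to-ambient conductance `G_sink` (default
0.01 W/K) to an ambient at 20 °C.  The steady state then gives a strictly
positive ΔT at *every* setpoint, including 25 °C, and the inverse
estimator recovers k exactly in the noiseless limit regardless of the
(arbitrary) `G_sink`, because inversion uses only the observables Q,
T_source and the RTD-read T_sink.  Heater voltage follows a linear
precalibrated map `V(T) = 0.8 + 0.15·(T − 25)` V; current is `Q/V`.

## Synthetic cohort generator

The generator emulates the reference design: 4 patients per preparation
(deparaffinized FFPE and formalin-fixed), paired tumor / adjacent-normal
blocks, 3 technical repeats, i.e. 48 samples and 12 per
group-by-preparation cell.  What is public per cell is a mean ± spread
for each parameter at 25 and 37 °C, the fold-ratio columns, and the
p-values of the group-level tests.  Three modelling decisions bridge the
gap to per-sample data:

1. **Spread reading.**  The published "±" is not labelled SD or SEM.  It
   is read as the SEM of n = 12 samples, so per-sample SD =
   spread·√12.  (Read as SD, the implied cohorts are far tighter and
   every within-group temperature contrast becomes enormously
   significant, contradicting the published p-values.)
2. **Marginals.**  Each parameter's 25 °C and 37 °C values are a
   bivariate *lognormal*, moment-matched to the published mean and
   per-sample SD — resistivities and conductivities are positive,
   right-skewed quantities.  The per-sample fold factor is the ratio of
   the two endpoint draws; between the endpoints resistivities follow
   geometric (log-linear) interpolation with the fold as the single
   shape parameter, and k interpolates linearly.
3. **Endpoint correlation.**  The within-sample correlation between the
   25 and 37 °C draws is what controls the paired-difference spread and
   hence the paired-t significance of the temperature contrast.  It is
   calibrated per cell so that the *median* simulated paired-t p over
   400 common-random-number cohorts (fixed internal seed; deterministic
   and cached) matches the published p-value for that cell, clamped to
   |ρ| ≤ 0.999.  A closed-form moment identity is not used because the
   paired differences are strongly skewed and the realised t statistic
   deviates systematically from the plug-in value.  For a few cells the
   published p is unreachable at any correlation — the published
   marginal spreads bound the paired-difference variance — and the clamp
   leaves those contrasts somewhat more significant than published
   (notably formalin-fixed normal resistivities).  This is a genuine
   identifiability limit of summary-level data, not a tuning target.

Technical repeats are drawn i.i.d. from the group distribution (the cell
is treated as 12 exchangeable samples, consistent with reading the spread
as SEM over 12).  Block geometry is uniform within the published
machining tolerances (±0.15/±0.23/±0.13 mm).

**Noise.**  Every observable gets independent multiplicative Gaussian
noise with a common coefficient of variation (default 2%; no instrument
noise figure is published, so this is a stated instrument-style choice).
For the RTDs the relative error is applied to the measured *temperature
drop* and converted to resistance exactly: a 2% error on a raw RTD
resistance would map through α = 2.2e-3 to ~9 °C temperature errors,
which is not a meaningful instrument model.  With `noise_cv = 0` the full
inverse pipeline reproduces the ground truth to < 1e-9 relative error.

**What passing tests do and do not show.**  The generator reproduces the
group *means*, the direction of every published contrast (tumor higher
rho_B/rho_S, lower k; surface above bulk resistivity), and — through the
correlation calibration — most of the published significance pattern in
the majority of seeds.  It does not model patient-level clustering,
contact-resistance physics, tissue anisotropy, or transient thermal
dynamics, and a single simulated cohort scatters around the published
table exactly as one noisy 12-sample study should.  Agreement here says
the pipeline's statistics behave correctly under the stated model; it is
not evidence about real tissue beyond what the published summaries carry.

## Delineation statistics

Within-group temperature contrasts use the classical paired two-tailed t
(degenerate variance handled explicitly: all-zero differences → p = 1,
constant nonzero difference → p = 0); between-group contrasts at fixed
temperature use Welch's unequal-variance t with Welch–Satterthwaite df.
Parameter combinations use Fisher's combined probability,
χ² = −2Σln pᵢ on 2m df; combination cells are always derived from the
table's own single-parameter cells, never recomputed from raw data.
p-values are reported raw — the original analysis applies no
multiple-testing correction — with an optional Bonferroni flag.
Significance bands: *** p < 0.001, ** p < 0.01, * p < 0.05, ns otherwise;
exact boundary values fall in the less significant band (the published
footnote uses strict inequalities on both ends, leaving boundaries
undefined).

The **summary-input mode** consumes the published single-parameter
p-values directly and recomputes only the combinations; with rounded
2–3-significant-figure inputs the combined cells reproduce the published
ones to within half an ulp of the printed precision (≲5%, mostly ≲0.5%).
The published per-parameter p-values themselves are *not* reproducible —
they require the unpublished raw per-sample data — so the pipeline's raw
mode reproduces their across-seed pattern rather than their values.

**Two-temperature classification.**  A specimen is called tumor when,
across its technical repeats, the paired 25→37 °C rise is significant at
α = 0.05 for both rho_B and rho_S *and* both mean fold changes exceed
3.8 — the midpoint between the published tumor (~4.1–4.8) and normal
(~2.9–3.5) fold ranges, fixed from those printed ranges alone.  The rule
is benchmarked with specimen-level ground truth shared across repeats
(the situation the rule addresses: one specimen, no adjacent-normal
reference); at 2% noise it is essentially error-free.  Applied to
population-drawn cohorts it degrades, because the SEM-derived per-sample
fold dispersion overlaps the threshold heavily — a known limitation of
classifying on summary-calibrated population draws.

## Trench conduction model

The isolation-trench study is reproduced at desk scale with a 2-D
node-centred finite-difference solve of variable-coefficient steady
conduction, harmonic-mean interface conductances, Dirichlet ambient
(25 °C) on the chip underside and far edges, adiabatic elsewhere, and a
configurable out-of-plane depth (default 1 mm) for power normalisation.
Default cross-section: 4 mm wide, 500 µm silicon (k = 150) under tissue
(k = 0.4), heater as a 0.5 mm source strip on the silicon surface, and an
optional pair of air-filled trenches (k = 0.026), 350 µm deep (the
published depth), 100 µm wide at ±0.4 mm — width and placement are not
published and are configuration parameters.  The sparse system is solved
directly, so the residual and the discrete energy balance close to
machine precision (tests require < 0.1%).  `power_for_target` brackets
and bisects the injected power to a heater-mean temperature tolerance.
The model is for *directions* — the trench lowers the power needed at a
given heater temperature and flattens the heater island — not for
quantitative chip temperatures (mesh, material stack and boundary data of
the original 3-D study are unpublished).

## Problem sizes and numerical choices

Default test and analysis sizes: 48-sample cohorts, 10⁴-replicate type-I
checks, 10⁵-replicate Fisher-null KS, 200-dataset sign-flip enumeration
(2⁸) oracle, trench grids of order 10³–10⁴ nodes.  All randomness flows
from a single seed per run through one `numpy` Generator in fixed draw
order; outputs are byte-reproducible and carry provenance headers
(version, seed, config hash).  Tolerances: machine-precision identities
are tested at 1e-9–1e-12 relative; published-value reproductions at the
printed precision of their inputs; stochastic checks at Monte-Carlo-error
scales stated in the tests.
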